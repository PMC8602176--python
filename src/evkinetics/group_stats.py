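"""Nonparametric between-group comparisons of per-animal kinetic summaries.

Rank-based tests are used throughout because group sizes are small
(~10 animals) and neither normality nor equal variance can be assumed:
Kruskal–Wallis (Wilcoxon rank-sum when only two groups are present) as the
omnibus test, followed — only when the omnibus test is significant at
0.05 — by the Steel–Dwass all-pairs procedure, the nonparametric analogue
of Tukey's HSD, which refers the standardized pairwise rank statistic to
the studentized-range distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pk_model import DoseEvent, secondary_params

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "steel_dwass",
    "compare_groups",
    "posthoc_secondary",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class GroupComparison:
    """Omnibus and (gated) pairwise comparison results for one quantity.

    ``pairwise`` is populated only when the omnibus p-value is below 0.05;
    each entry records the test that produced the number.
    """

    groups: dict[str, list[float]]
    omnibus_statistic: float
    omnibus_p: float
    omnibus_test: str
    pairwise: dict[tuple[str, str], dict] | None = None

    def to_dict(self) -> dict:
        return {
            "groups": {k: list(map(float, v)) for k, v in self.groups.items()},
            "omnibus": {
                "test": self.omnibus_test,
                "statistic": self.omnibus_statistic,
                "p_value": self.omnibus_p,
            },
            "pairwise": None
            if self.pairwise is None
            else {f"{a} vs {b}": dict(r) for (a, b), r in self.pairwise.items()},
        }


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]], exact: bool = False
) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected average ranks) and its p-value.

    The default p-value is the chi-square approximation with k-1 degrees
    of freedom.  ``exact=True`` enumerates every assignment of the pooled
    values to groups of the observed sizes and returns P(H >= H_obs) — the
    appropriate reference for very small groups (<= ~6 per group), where
    the chi-square approximation can be off by several hundredths.
    """
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs >= 1 observation")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*samples)
    H = float(H)
    if exact:
        sizes = [len(s) for s in samples]
        count = total = 0
        for parts in _label_partitions(len(pooled), sizes):
            h_perm, _ = stats.kruskal(*(pooled[list(idx)] for idx in parts))
            count += h_perm >= H - 1e-12
            total += 1
        return H, count / total
    return H, float(p)


def _pair_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected standardized two-sample rank statistic for one pair."""
    n, m = len(x), len(y)
    N = n + m
    ranks = stats.rankdata(np.concatenate([x, y]))
    W = ranks[:n].sum()
    expect = n * (N + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 0.0
    return float((W - expect) / math.sqrt(var))


def steel_dwass(
    groups: Mapping[str, Sequence[float]],
    exact: bool = False,
) -> dict[tuple[str, str], dict]:
    """All-pairs rank comparisons with studentized-range multiplicity control.

    For each pair of groups the two-sample rank-sum statistic (pairwise
    ranking, average ranks for ties) is standardized to t and the adjusted
    p-value is P(Q_k >= sqrt(2)|t|) with Q_k the studentized range over k
    groups (infinite degrees of freedom).  ``exact=True`` replaces the
    asymptotic reference by full enumeration of group-label permutations,
    using the null distribution of the maximum pairwise statistic (the
    exact analogue of the Tukey-style adjustment); feasible for small
    groups only (<= ~6 per group).
    """
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    arrays = {lab: np.asarray(groups[lab], dtype=float) for lab in labels}
    if any(len(a) == 0 for a in arrays.values()):
        raise ValueError("empty group")

    observed = {
        (a, b): abs(_pair_statistic(arrays[a], arrays[b]))
        for a, b in itertools.combinations(labels, 2)
    }

    if not exact:
        return {
            pair: {
                "statistic": t,
                "p_value": float(stats.studentized_range.sf(math.sqrt(2.0) * t, k, np.inf)),
                "test": "steel-dwass (studentized range)",
            }
            for pair, t in observed.items()
        }

    sizes = [len(arrays[lab]) for lab in labels]
    pooled = np.concatenate([arrays[lab] for lab in labels])
    max_stats = []
    for assignment in _label_partitions(len(pooled), sizes):
        parts = [pooled[list(idx)] for idx in assignment]
        max_stats.append(
            max(
                abs(_pair_statistic(parts[i], parts[j]))
                for i, j in itertools.combinations(range(k), 2)
            )
        )
    max_stats = np.array(max_stats)
    return {
        pair: {
            "statistic": t,
            "p_value": float(np.mean(max_stats >= t - 1e-12)),
            "test": "steel-dwass (exact permutation)",
        }
        for pair, t in observed.items()
    }


def _label_partitions(n: int, sizes: list[int]):
    """All ways to split indices 0..n-1 into ordered groups of the given sizes."""
    indices = frozenset(range(n))

    def rec(remaining: frozenset, sizes_left: list[int]):
        if not sizes_left:
            yield ()
            return
        for combo in itertools.combinations(sorted(remaining), sizes_left[0]):
            for rest in rec(remaining - set(combo), sizes_left[1:]):
                yield (combo,) + rest

    yield from rec(indices, sizes)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = SIGNIFICANCE_LEVEL,
    exact_pairwise: bool = False,
) -> GroupComparison:
    """Omnibus rank test, then Steel–Dwass pairwise only if significant."""
    H, p = kruskal_wallis(groups)
    test = "wilcoxon rank-sum (kruskal-wallis, k=2)" if len(groups) == 2 else "kruskal-wallis"
    pairwise = None
    if p < alpha:
        pairwise = steel_dwass(groups, exact=exact_pairwise)
    return GroupComparison(
        groups={k: list(map(float, v)) for k, v in groups.items()},
        omnibus_statistic=H,
        omnibus_p=p,
        omnibus_test=test,
        pairwise=pairwise,
    )


def posthoc_secondary(fit) -> pd.DataFrame:
    """Per-animal secondary parameters from a converged fit's EBE parameters.

    Applies the half-life and AUC formulas to each non-excluded animal's
    empirical-Bayes individual parameters (AUC_i = dose_i / Cl_i).  Returns
    a tidy table with one row per animal: id, cell_line, t_half_elim_hr,
    t_half_compt2_hr, t_half_compt3_min, auc_ug_hr_ml.
    """
    if not getattr(fit, "converged", True):
        raise ValueError("post-hoc summaries require a converged fit")
    rows = []
    for subj in fit.data.subjects:
        params = fit.individual_params.get(subj.id)
        if params is None:
            raise ValueError(f"missing empirical Bayes parameters for subject {subj.id}")
        sec = secondary_params(params, DoseEvent(amount=subj.dose.amount))
        rows.append(
            {
                "id": subj.id,
                "cell_line": subj.covariates.get("cell_line"),
                "t_half_elim_hr": sec.t_half_elim,
                "t_half_compt2_hr": sec.t_half_compt2,
                "t_half_compt3_min": sec.t_half_compt3,
                "auc_ug_hr_ml": sec.auc,
            }
        )
    return pd.DataFrame(rows)
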