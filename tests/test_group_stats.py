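"""Rank-based omnibus and all-pairs comparisons against enumeration oracles."""

import itertools
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from evkinetics.group_stats import (
    _pair_statistic,
    compare_groups,
    kruskal_wallis,
    posthoc_secondary,
    steel_dwass,
)
from evkinetics.nlme_engine import Subject
from evkinetics.pk_model import DoseEvent, StructuralParams


class TestKruskalWallis:
    def test_hand_computed_h(self):
        H, _ = kruskal_wallis({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert H == pytest.approx(2.4)

    def test_identical_values(self):
        H, p = kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert H == 0.0 and p == 1.0

    def test_label_permutation_invariance(self, rng):
        g = {"a": rng.normal(size=6).tolist(), "b": rng.normal(size=5).tolist(), "c": rng.normal(size=7).tolist()}
        H1, p1 = kruskal_wallis(g)
        H2, p2 = kruskal_wallis({"c": g["c"], "a": g["a"], "b": g["b"]})
        assert H1 == pytest.approx(H2) and p1 == pytest.approx(p2)

    def test_monotone_transform_invariance(self, rng):
        g = {"a": rng.normal(size=5), "b": rng.normal(size=5)}
        H1, _ = kruskal_wallis(g)
        H2, _ = kruskal_wallis({k: np.exp(v) for k, v in g.items()})
        assert H1 == pytest.approx(H2)

    def test_exact_mode_matches_independent_enumeration(self, rng):
        vals = rng.normal(size=9)
        vals[6:] += 1.5
        groups = {"a": vals[:3], "b": vals[3:6], "c": vals[6:]}
        H, p = kruskal_wallis(groups, exact=True)
        # oracle: brute force over explicit index triples
        idx = list(range(9))
        count = total = 0
        for combo_a in itertools.combinations(idx, 3):
            rest = [i for i in idx if i not in combo_a]
            for combo_b in itertools.combinations(rest, 3):
                combo_c = [i for i in rest if i not in combo_b]
                h_perm = stats.kruskal(vals[list(combo_a)], vals[list(combo_b)], vals[combo_c])[0]
                count += h_perm >= H - 1e-12
                total += 1
        assert total == 1680
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_type_one_error_calibration(self):
        """Omnibus 0.05-level error rate within [0.03, 0.07] at sizes 10/9/9."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            g = {"a": rng.normal(size=10), "b": rng.normal(size=9), "c": rng.normal(size=9)}
            _, p = kruskal_wallis(g)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestSteelDwass:
    def test_identical_groups_p_near_one(self):
        res = steel_dwass({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res[("a", "b")]["p_value"] > 0.99

    def test_exact_mode_agrees_with_wilcoxon_permutation_decisions(self, rng):
        """k=2: exact Steel-Dwass equals the exact permutation Wilcoxon."""
        for _ in range(50):
            x = rng.normal(0, 1, 5)
            y = rng.normal(rng.uniform(0, 2), 1, 5)
            res = steel_dwass({"a": x.tolist(), "b": y.tolist()}, exact=True)
            p_sd = res[("a", "b")]["p_value"]
            t_obs = abs(_pair_statistic(x, y))
            pooled = np.concatenate([x, y])
            ts = []
            for idx in itertools.combinations(range(10), 5):
                rest = [i for i in range(10) if i not in idx]
                ts.append(abs(_pair_statistic(pooled[list(idx)], pooled[rest])))
            p_perm = np.mean(np.array(ts) >= t_obs - 1e-12)
            assert (p_sd < 0.05) == (p_perm < 0.05)
            assert p_sd == pytest.approx(p_perm, abs=1e-12)

    def test_exact_mode_matches_max_statistic_enumeration(self, rng):
        """3/3/3: adjusted p within 0.02 of a full-enumeration oracle."""
        vals = rng.normal(size=9)
        vals[3:6] += 0.8
        groups = {"a": vals[:3].tolist(), "b": vals[3:6].tolist(), "c": vals[6:].tolist()}
        res = steel_dwass(groups, exact=True)
        # oracle: explicit nested loops over the 1680 assignments
        observed = {
            pair: abs(_pair_statistic(np.array(groups[pair[0]]), np.array(groups[pair[1]])))
            for pair in itertools.combinations(groups, 2)
        }
        max_stats = []
        idx = list(range(9))
        for combo_a in itertools.combinations(idx, 3):
            rest = [i for i in idx if i not in combo_a]
            for combo_b in itertools.combinations(rest, 3):
                combo_c = [i for i in rest if i not in combo_b]
                parts = [vals[list(combo_a)], vals[list(combo_b)], vals[list(combo_c)]]
                max_stats.append(
                    max(
                        abs(_pair_statistic(parts[i], parts[j]))
                        for i, j in itertools.combinations(range(3), 2)
                    )
                )
        max_stats = np.array(max_stats)
        for pair, t in observed.items():
            p_oracle = float(np.mean(max_stats >= t - 1e-12))
            assert res[pair]["p_value"] == pytest.approx(p_oracle, abs=0.02)

    def test_asymptotic_close_to_exact_for_moderate_p(self, rng):
        """The studentized-range approximation tracks the exact reference."""
        x = rng.normal(0, 1, 6)
        y = rng.normal(2.0, 1, 6)
        g = {"a": x.tolist(), "b": y.tolist()}
        p_asym = steel_dwass(g)[("a", "b")]["p_value"]
        p_exact = steel_dwass(g, exact=True)[("a", "b")]["p_value"]
        assert p_asym == pytest.approx(p_exact, abs=0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            steel_dwass({"a": [1.0], "b": []})


class TestCompareGroups:
    def test_pairwise_gated_on_omnibus(self, rng):
        null = {"a": rng.normal(size=8).tolist(), "b": rng.normal(size=8).tolist(), "c": rng.normal(size=8).tolist()}
        shifted = {k: (np.array(v) + i * 5.0).tolist() for i, (k, v) in enumerate(null.items())}
        res_null = compare_groups(null)
        res_alt = compare_groups(shifted)
        if res_null.omnibus_p >= 0.05:
            assert res_null.pairwise is None
        assert res_alt.omnibus_p < 0.05
        assert res_alt.pairwise is not None
        assert set(res_alt.pairwise) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_report_serializes(self, rng):
        res = compare_groups({"a": [1, 2, 3], "b": [10, 11, 12]})
        d = res.to_dict()
        assert "omnibus" in d and "pairwise" in d


class TestPosthocSecondary:
    def test_zero_etas_reproduce_typical_values(self):
        params = StructuralParams(v1=28, v2=3057, v3=16, cl=(193,), cl2=111, cl3=21)
        subjects = [
            Subject(id=f"s{i}", dose=DoseEvent(2000), observations=[(2.0, 1.0)], covariates={"cell_line": "clone9"})
            for i in range(3)
        ]
        fake_fit = SimpleNamespace(
            converged=True,
            data=SimpleNamespace(subjects=subjects),
            individual_params={s.id: params for s in subjects},
        )
        table = posthoc_secondary(fake_fit)
        assert len(table) == 3
        assert table["t_half_compt3_min"].iloc[0] == pytest.approx(31.7, rel=0.01)
        assert table["auc_ug_hr_ml"].iloc[0] == pytest.approx(2000 / 193)

    def test_requires_convergence(self):
        with pytest.raises(ValueError):
            posthoc_secondary(SimpleNamespace(converged=False))
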