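"""Closed-form mammillary compartment models for IV-bolus kinetics.

A mammillary model has a central (plasma) compartment exchanging with up to
two peripheral compartments; elimination is first order and may occur from
the central and/or peripheral compartments.  Models are parameterized by
compartment volumes (mL) and clearances (mL/hr): ``cl`` for elimination,
``cl2``/``cl3`` for distribution between the central compartment and
peripherals 2/3.  Micro rate constants follow the standard mapping
``k10 = cl/v1``, ``k12 = cl2/v1``, ``k21 = cl2/v2`` (and likewise for
compartment 3).

Time convention: every public interface accepts sampling times in
**minutes** (the in vivo sampling schedule is expressed in minutes), while
clearances are mL/hr; conversion to hours happens internally.  Secondary
half-lives are reported in hours except the compartment-3 distribution
half-life, reported in minutes to match its fast scale.

Concentrations solve the linear ODE system by eigendecomposition of the
rate matrix, so every structural variant (peripheral elimination,
asymmetric distribution) shares one code path; a dense matrix-exponential
solution is used as a fallback when eigenvalues are numerically
degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ModelSpec",
    "StructuralParams",
    "DoseEvent",
    "SecondaryParams",
    "rate_matrix",
    "predict_concentrations",
    "secondary_params",
    "clearance_from_auc",
    "ml_per_hr_to_ml_per_min",
]

#: Relative eigenvalue-gap threshold below which the eigen-solution is
#: considered degenerate and the ODE fallback is used.
DEGENERACY_TOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Structural skeleton of a mammillary model.

    Parameters
    ----------
    n_compartments
        1, 2 or 3.  Compartment 1 is central (plasma); 2 and 3 are
        peripheral.
    elimination_sites
        Compartments with first-order elimination.  Repeats are allowed
        (parallel elimination pathways from one compartment), so every
        structure in the model-comparison ladder is expressible.
    symmetric_distribution
        If False, each central<->peripheral link carries separate inbound
        and return distributional clearances (``cl2``/``cl2_ret``),
        enabling the "unequal distribution rates" variants.
    """

    n_compartments: int = 3
    elimination_sites: tuple[int, ...] = (1,)
    symmetric_distribution: bool = True

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise ValueError(f"n_compartments must be 1, 2 or 3, got {self.n_compartments}")
        sites = tuple(self.elimination_sites)
        object.__setattr__(self, "elimination_sites", sites)
        if not sites:
            raise ValueError("at least one elimination site is required")
        for s in sites:
            if not 1 <= s <= self.n_compartments:
                raise ValueError(f"elimination site {s} not in model with {self.n_compartments} compartments")

    @property
    def elimination_names(self) -> tuple[str, ...]:
        return tuple("cl" if i == 0 else f"cl_e{i + 1}" for i in range(len(self.elimination_sites)))

    @property
    def structural_names(self) -> tuple[str, ...]:
        """Names of the free structural parameters, in canonical order."""
        names = ["v1"]
        if self.n_compartments >= 2:
            names.append("v2")
        if self.n_compartments >= 3:
            names.append("v3")
        names.extend(self.elimination_names)
        if self.n_compartments >= 2:
            names.append("cl2")
            if not self.symmetric_distribution:
                names.append("cl2_ret")
        if self.n_compartments >= 3:
            names.append("cl3")
            if not self.symmetric_distribution:
                names.append("cl3_ret")
        return tuple(names)

    def to_dict(self) -> dict:
        return {
            "n_compartments": self.n_compartments,
            "elimination_sites": list(self.elimination_sites),
            "symmetric_distribution": self.symmetric_distribution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            n_compartments=int(d["n_compartments"]),
            elimination_sites=tuple(int(s) for s in d["elimination_sites"]),
            symmetric_distribution=bool(d.get("symmetric_distribution", True)),
        )


@dataclass(frozen=True)
class StructuralParams:
    """One subject's kinetic parameters.

    Volumes in mL, clearances in mL/hr.  ``cl`` holds one elimination
    clearance per site in ``ModelSpec.elimination_sites`` (a bare float is
    accepted for the single-site case).  ``cl2_ret``/``cl3_ret`` are the
    peripheral-to-central distributional clearances of asymmetric models;
    when None the link is symmetric (return clearance equals ``cl2``).
    """

    v1: float
    v2: float | None = None
    v3: float | None = None
    cl: tuple[float, ...] = ()
    cl2: float | None = None
    cl3: float | None = None
    cl2_ret: float | None = None
    cl3_ret: float | None = None

    def __post_init__(self) -> None:
        cl = self.cl
        if isinstance(cl, (int, float)):
            cl = (float(cl),)
        object.__setattr__(self, "cl", tuple(float(c) for c in cl))

    def validate(self, spec: ModelSpec) -> None:
        vols = [self.v1, self.v2, self.v3][: spec.n_compartments]
        if any(v is None for v in vols):
            raise ValueError(f"model with {spec.n_compartments} compartments requires volumes {vols}")
        if any(v <= 0 for v in vols):
            raise ValueError("all compartment volumes must be > 0")
        if len(self.cl) != len(spec.elimination_sites):
            raise ValueError(
                f"{len(spec.elimination_sites)} elimination clearance(s) required, got {len(self.cl)}"
            )
        clearances = list(self.cl)
        if spec.n_compartments >= 2:
            if self.cl2 is None:
                raise ValueError("cl2 required for >=2 compartments")
            clearances.append(self.cl2)
        if spec.n_compartments >= 3:
            if self.cl3 is None:
                raise ValueError("cl3 required for 3 compartments")
            clearances.append(self.cl3)
        if not spec.symmetric_distribution:
            if spec.n_compartments >= 2 and self.cl2_ret is None:
                raise ValueError("cl2_ret required for asymmetric distribution")
            if spec.n_compartments >= 3 and self.cl3_ret is None:
                raise ValueError("cl3_ret required for asymmetric distribution")
        if any(c < 0 for c in clearances):
            raise ValueError("clearances must be >= 0")
        if not any(c > 0 for c in self.cl):
            raise ValueError("at least one elimination clearance must be > 0")

    @property
    def cl_total(self) -> float:
        """Total elimination clearance (sum over sites), mL/hr."""
        return float(sum(self.cl))

    def as_dict(self) -> dict[str, float]:
        d: dict[str, float] = {"v1": self.v1}
        for name, val in (
            ("v2", self.v2),
            ("v3", self.v3),
            ("cl2", self.cl2),
            ("cl3", self.cl3),
            ("cl2_ret", self.cl2_ret),
            ("cl3_ret", self.cl3_ret),
        ):
            if val is not None:
                d[name] = float(val)
        for i, c in enumerate(self.cl):
            d["cl" if i == 0 else f"cl_e{i + 1}"] = float(c)
        return d

    @classmethod
    def from_dict(cls, d: dict, spec: ModelSpec | None = None) -> "StructuralParams":
        d = dict(d)
        n_elim = len(spec.elimination_sites) if spec is not None else 1
        cl = [d.pop("cl", 0.0)] + [d.pop(f"cl_e{i + 1}", 0.0) for i in range(1, n_elim)]
        return cls(
            v1=float(d["v1"]),
            v2=float(d["v2"]) if "v2" in d else None,
            v3=float(d["v3"]) if "v3" in d else None,
            cl=tuple(float(c) for c in cl),
            cl2=float(d["cl2"]) if "cl2" in d else None,
            cl3=float(d["cl3"]) if "cl3" in d else None,
            cl2_ret=float(d["cl2_ret"]) if "cl2_ret" in d else None,
            cl3_ret=float(d["cl3_ret"]) if "cl3_ret" in d else None,
        )


@dataclass(frozen=True)
class DoseEvent:
    """Single IV bolus of EV protein (micrograms) into the central compartment at t=0."""

    amount: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.time != 0.0:
            raise ValueError("only t=0 bolus dosing is supported")


@dataclass(frozen=True)
class SecondaryParams:
    """Secondary kinetic parameters derived from structural estimates.

    ``t_half_elim`` and ``t_half_compt2`` in hours, ``t_half_compt3`` in
    minutes, ``auc`` in ug*hr/mL.  Half-lives of absent compartments are
    None.
    """

    t_half_elim: float
    auc: float
    t_half_compt2: float | None = None
    t_half_compt3: float | None = None


def rate_matrix(params: StructuralParams, spec: ModelSpec) -> np.ndarray:
    """First-order rate matrix K (1/hr) with dA/dt = K A, A in amounts.

    Off-diagonal K[j,i] is the transfer rate i+1 -> j+1; each diagonal is
    minus the total outflow (transfer plus elimination) from that
    compartment, so column sums equal minus the elimination rates.
    """
    params.validate(spec)
    n = spec.n_compartments
    vols = np.array([params.v1, params.v2, params.v3][:n], dtype=float)
    K = np.zeros((n, n))
    if n >= 2:
        k12 = params.cl2 / params.v1
        k21 = (params.cl2_ret if params.cl2_ret is not None else params.cl2) / params.v2
        K[1, 0] += k12
        K[0, 1] += k21
    if n >= 3:
        k13 = params.cl3 / params.v1
        k31 = (params.cl3_ret if params.cl3_ret is not None else params.cl3) / params.v3
        K[2, 0] += k13
        K[0, 2] += k31
    for site, cl in zip(spec.elimination_sites, params.cl):
        K[site - 1, site - 1] -= cl / vols[site - 1]
    for i in range(n):
        K[i, i] -= sum(K[j, i] for j in range(n) if j != i)
    return K


def _eig_bolus_conc(K: np.ndarray, v1: float, amount: float, t_hr: np.ndarray) -> np.ndarray | None:
    """Central concentration by eigen-solution; None if degenerate."""
    w, V = np.linalg.eig(K)
    scale = max(np.max(np.abs(w)), 1.0)
    if K.shape[0] > 1:
        gaps = np.abs(w[:, None] - w[None, :])[np.triu_indices(K.shape[0], k=1)]
        if np.min(gaps) < DEGENERACY_TOL * scale:
            return None
    e1 = np.zeros(K.shape[0], dtype=complex)
    e1[0] = amount
    try:
        coef = np.linalg.solve(V, e1)
    except np.linalg.LinAlgError:
        return None
    # C1(t) = sum_k V[0,k] coef_k exp(w_k t) / v1
    conc = (V[0, :] * coef) @ np.exp(np.outer(w, t_hr))
    return np.real(conc) / v1


def _expm_bolus_conc(K: np.ndarray, v1: float, amount: float, t_hr: np.ndarray) -> np.ndarray:
    """Dense matrix-exponential solution, exact for (near-)degenerate
    eigenvalues where the eigendecomposition is ill-conditioned."""
    a0 = np.zeros(K.shape[0])
    a0[0] = amount
    out = np.empty(len(t_hr))
    for i, t in enumerate(t_hr):
        out[i] = (expm(K * float(t)) @ a0)[0]
    return out / v1


def predict_concentrations(
    params: StructuralParams,
    spec: ModelSpec,
    dose: DoseEvent,
    times_min: Sequence[float],
) -> np.ndarray:
    """Central-compartment concentrations (ug/mL) at times given in minutes.

    C(0) equals dose/v1 (bolus initial condition); the profile is a sum of
    decaying exponentials obtained from the eigen-solution of the rate
    matrix, with an ODE fallback for degenerate eigenvalues.
    """
    t = np.asarray(times_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative sampling times are not allowed")
    K = rate_matrix(params, spec)
    t_hr = t / 60.0
    conc = _eig_bolus_conc(K, params.v1, dose.amount, t_hr)
    if conc is None:
        conc = _expm_bolus_conc(K, params.v1, dose.amount, t_hr)
    return conc


def batched_bolus_conc(
    K: np.ndarray, v1: np.ndarray, amount: np.ndarray, t_hr: np.ndarray
) -> np.ndarray:
    """Vectorized central concentrations for a batch of rate matrices.

    Parameters: ``K`` (B, n, n) rate matrices in 1/hr, ``v1`` (B,) central
    volumes, ``amount`` (B,) dose amounts, ``t_hr`` times in hours, shape
    (T,) shared or (B, T) per item.  Returns (B, T) concentrations.  Items
    with degenerate eigenvalues fall back to the ODE integrator
    individually.  This is the hot path of the population-fit engine.
    """
    B, n, _ = K.shape
    t_hr = np.asarray(t_hr, dtype=float)
    t_b = t_hr[None, None, :] if t_hr.ndim == 1 else t_hr[:, None, :]
    w, V = np.linalg.eig(K)
    e1 = np.zeros((B, n), dtype=complex)
    e1[:, 0] = amount
    coef = np.linalg.solve(V, e1[..., None])[..., 0]  # (B, n)
    # (B, n, T) exponentials combined with (B, n) weights; the real part is
    # capped so roundoff-positive eigenvalues of extreme trial parameters
    # cannot overflow (the resulting objective is rejected anyway)
    z = w[..., None] * t_b
    expwt = np.exp(np.clip(z.real, None, 700.0) + 1j * z.imag)
    conc = np.real(np.einsum("bn,bn,bnt->bt", V[:, 0, :], coef, expwt)) / v1[:, None]
    if n > 1:
        gaps = np.abs(w[:, :, None] - w[:, None, :])
        iu = np.triu_indices(n, k=1)
        min_gap = gaps[:, iu[0], iu[1]].min(axis=1)
        scale = np.maximum(np.abs(w).max(axis=1), 1.0)
        bad = min_gap < DEGENERACY_TOL * scale
        for b in np.nonzero(bad)[0]:
            tb = t_hr if t_hr.ndim == 1 else t_hr[b]
            conc[b] = _expm_bolus_conc(K[b], float(v1[b]), float(amount[b]), tb)
    return conc


def secondary_params(params: StructuralParams, dose: DoseEvent) -> SecondaryParams:
    """Half-lives and AUC for a central-elimination model.

    t1/2,elim = ln2*(V1+V2+V3)/Cl (hr); t1/2,compt2 = ln2*V2/Cl2 (hr);
    t1/2,compt3 = ln2*V3/Cl3 (min); AUC = dose/Cl (ug*hr/mL).  These are
    the steady-state style summaries used to compare animals; they treat
    total volume as the effective distribution volume of the terminal
    phase.
    """
    cl = params.cl_total
    if cl <= 0:
        raise ValueError("elimination half-life undefined: total clearance is zero")
    v_total = params.v1 + (params.v2 or 0.0) + (params.v3 or 0.0)
    t_half_elim = math.log(2.0) * v_total / cl
    t2 = None
    if params.v2 is not None and params.cl2 is not None:
        if params.cl2 <= 0:
            raise ValueError("compartment-2 half-life undefined: cl2 is zero")
        t2 = math.log(2.0) * params.v2 / params.cl2
    t3 = None
    if params.v3 is not None and params.cl3 is not None:
        if params.cl3 <= 0:
            raise ValueError("compartment-3 half-life undefined: cl3 is zero")
        t3 = math.log(2.0) * params.v3 / params.cl3 * 60.0  # minutes
    return SecondaryParams(
        t_half_elim=t_half_elim,
        t_half_compt2=t2,
        t_half_compt3=t3,
        auc=dose.amount / cl,
    )


def clearance_from_auc(dose: float, auc: float) -> float:
    """Clearance from total exposure, CL = dose / AUC (units follow inputs)."""
    if auc <= 0:
        raise ValueError("AUC must be > 0")
    return dose / auc


def ml_per_hr_to_ml_per_min(cl_ml_hr: float) -> float:
    """Convert a clearance from mL/hr to mL/min."""
    return cl_ml_hr / 60.0
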