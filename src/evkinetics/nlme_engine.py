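"""Population (nonlinear mixed-effects) fitting of concentration-time data.

The model: each animal's structural parameters are log-normally distributed
around population typical values, P_i = P_tv * exp(eta_i) with
eta ~ N(0, Omega), optionally shifted by exponential covariate effects
(theta * e^coefficient for the animal's covariate level).  Observed
concentrations carry either proportional error, Cobs = C * (1 + eps), or
log-additive error, Cobs = C * exp(eps), which cannot produce negative
concentrations.  Estimation maximizes the FOCE-ELS approximate marginal
likelihood (first-order conditional estimation with interaction); standard
errors come from the numerical Hessian of -2LL at the optimum, with 95%
confidence intervals computed on the log scale and exponentiated so bounds
stay positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._foce import FoceProblem
from .pk_model import DoseEvent, ModelSpec, StructuralParams

__all__ = [
    "Subject",
    "StudyDataset",
    "PopulationModel",
    "FitConfig",
    "FitResult",
    "individual_params",
    "residual_variance",
    "foce_els_objective",
    "fit",
    "covariate_scan",
    "cwres",
    "initial_estimates",
    "simulate_study",
]


@dataclass
class Subject:
    """One animal: dose, covariates, and its concentration-time observations."""

    id: str
    dose: DoseEvent
    observations: list[tuple[float, float]]
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"subject {self.id}: needs >= 1 observation")
        times = [t for t, _ in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"subject {self.id}: observation times must be strictly increasing")
        if any(c < 0 for _, c in self.observations):
            raise ValueError(f"subject {self.id}: concentrations must be >= 0")


@dataclass
class StudyDataset:
    """Analysis set plus the log of excluded animals (id -> reason)."""

    subjects: list[Subject]
    exclusions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        overlap = set(ids) & set(self.exclusions)
        if overlap:
            raise ValueError(f"excluded subjects present in analysis set: {sorted(overlap)}")

    def exclude(self, subject_id: str, reason: str) -> "StudyDataset":
        """New dataset with one animal moved from the analysis set to the log."""
        kept = [s for s in self.subjects if s.id != subject_id]
        if len(kept) == len(self.subjects):
            raise KeyError(subject_id)
        log = dict(self.exclusions)
        log[subject_id] = reason
        return StudyDataset(subjects=kept, exclusions=log)


@dataclass
class PopulationModel:
    """Population model: typical values, covariates, IIV, residual error.

    ``theta`` maps structural-parameter names (see
    ``ModelSpec.structural_names``) to typical values; ``covariate_map``
    maps parameter -> covariate -> level -> coefficient (the reference
    level is simply absent, i.e. coefficient 0); ``omega`` maps the subset
    of parameters carrying inter-individual variability to eta variances
    (diagonal by default; ``omega_corr`` holds optional covariances keyed
    by parameter pairs); ``residual`` is "proportional" or "log_additive"
    with magnitude ``sigma`` (an SD).
    """

    spec: ModelSpec
    theta: dict[str, float]
    omega: dict[str, float] = field(default_factory=dict)
    sigma: float = 0.45
    residual: str = "proportional"
    covariate_map: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    omega_corr: dict[tuple[str, str], float] = field(default_factory=dict)
    #: Optional registry of valid levels per categorical covariate; levels
    #: absent from covariate_map but present here are reference (coef 0),
    #: levels absent from both are rejected as unknown.
    covariate_levels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.spec.structural_names
        missing = [n for n in names if n not in self.theta]
        if missing:
            raise ValueError(f"theta missing structural parameters: {missing}")
        if any(v <= 0 for v in self.theta.values()):
            raise ValueError("typical values must be > 0")
        if any(v < 0 for v in self.omega.values()):
            raise ValueError("omega variances must be >= 0")
        unknown = [n for n in self.omega if n not in names]
        if unknown:
            raise ValueError(f"omega on unknown parameters: {unknown}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.residual not in ("proportional", "log_additive"):
            raise ValueError(f"unknown residual model {self.residual!r}")
        for p, covs in self.covariate_map.items():
            if p not in names:
                raise ValueError(f"covariate on unknown parameter {p!r}")
            for cov, levels in covs.items():
                if any(not np.isfinite(c) for c in levels.values()):
                    raise ValueError(f"non-finite covariate coefficient on {p}/{cov}")

    @property
    def eta_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.spec.structural_names if n in self.omega)

    def omega_matrix(self, eta_names: tuple[str, ...] | None = None) -> np.ndarray:
        names = eta_names if eta_names is not None else self.eta_names
        k = len(names)
        O = np.zeros((k, k))
        for i, a in enumerate(names):
            O[i, i] = self.omega[a]
            for j, b in enumerate(names[:i]):
                c = self.omega_corr.get((a, b), self.omega_corr.get((b, a), 0.0))
                O[i, j] = O[j, i] = c
        eigvals = np.linalg.eigvalsh(O) if k else np.array([])
        if k and eigvals.min() < -1e-10:
            raise ValueError("omega matrix is not positive semi-definite")
        return O

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "theta": dict(self.theta),
            "omega": dict(self.omega),
            "omega_corr": {f"{a}|{b}": v for (a, b), v in self.omega_corr.items()},
            "sigma": self.sigma,
            "residual": self.residual,
            "covariate_map": {
                p: {c: dict(lv) for c, lv in covs.items()} for p, covs in self.covariate_map.items()
            },
            "covariate_levels": {c: list(ls) for c, ls in self.covariate_levels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            theta={k: float(v) for k, v in d["theta"].items()},
            omega={k: float(v) for k, v in d.get("omega", {}).items()},
            omega_corr={
                tuple(k.split("|")): float(v) for k, v in d.get("omega_corr", {}).items()
            },
            sigma=float(d.get("sigma", 0.45)),
            residual=d.get("residual", "proportional"),
            covariate_map={
                p: {c: {l: float(b) for l, b in lv.items()} for c, lv in covs.items()}
                for p, covs in d.get("covariate_map", {}).items()
            },
            covariate_levels={
                c: tuple(ls) for c, ls in d.get("covariate_levels", {}).items()
            },
        )


@dataclass
class FitConfig:
    """Optimizer settings for FOCE-ELS estimation.

    The outer quasi-Newton search runs on log(theta), covariate
    coefficients, the log-Cholesky of omega and log(sigma), capped at
    ``max_iter`` iterations (default mirrors the 1,000-iteration cap of
    the source workflow).  The inner Newton search for each subject's
    conditional mode stops on relative objective change below
    ``inner_tol``.  ``log_floor`` replaces exact-zero observations under
    the log-additive model (None: smallest positive observation / 100).
    """

    max_iter: int = 1000
    restarts: int = 10
    restart_tol: float = 0.02
    outer_ftol: float = 1e-10
    outer_gtol: float = 5e-4
    inner_tol: float = 1e-10
    inner_max_iter: int = 40
    compute_se: bool = True
    estimate_omega_offdiag: bool = False
    hessian_step: float = 1e-2
    log_floor: float | None = None


@dataclass
class FitResult:
    """Converged (or flagged) population fit with diagnostics.

    ``estimates``/``se``/``ci95`` are keyed by packed parameter names
    (theta_*, beta_*, omega_* as variances, sigma).  ``predictions`` is a
    tidy frame (id, time_min, dv, ipred, pred, cwres); ``etas`` and
    ``individual_params`` hold the per-animal empirical Bayes quantities.
    """

    model: PopulationModel
    data: StudyDataset
    minus2ll: float
    n_params: int
    converged: bool
    n_iter: int
    estimates: dict[str, float]
    se: dict[str, float] | None
    ci95: dict[str, tuple[float, float]] | None
    etas: dict[str, np.ndarray]
    individual_params: dict[str, StructuralParams]
    predictions: pd.DataFrame
    message: str = ""

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.n_params

    def parameter_table(self) -> pd.DataFrame:
        """Flat estimate table (parameter, estimate, se, ci_low, ci_high)."""
        rows = []
        for name, est in self.estimates.items():
            se = self.se.get(name) if self.se else None
            lo, hi = self.ci95.get(name, (None, None)) if self.ci95 else (None, None)
            rows.append({"parameter": name, "estimate": est, "se": se, "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def individual_params(
    model: PopulationModel, covariates: dict, eta: dict[str, float] | np.ndarray
) -> StructuralParams:
    """Individual structural parameters P_i = theta * e^covariates * e^eta."""
    names = model.spec.structural_names
    if not isinstance(eta, dict):
        eta = dict(zip(model.eta_names, np.asarray(eta, dtype=float)))
    values: dict[str, float] = {}
    for name in names:
        log_p = math.log(model.theta[name])
        for cov, levels in model.covariate_map.get(name, {}).items():
            val = covariates.get(cov)
            if val is None:
                raise ValueError(f"missing covariate {cov!r}")
            if isinstance(val, str):
                if val in levels:
                    log_p += levels[val]
                else:
                    known = model.covariate_levels.get(cov)
                    if known is not None and val not in known:
                        raise KeyError(f"unknown level {val!r} for covariate {cov!r}")
                    # otherwise: reference level, coefficient 0
            else:
                for center, slope in levels.items():
                    log_p += slope * (float(val) - (float(center) if center else 0.0))
        log_p += eta.get(name, 0.0)
        values[name] = math.exp(log_p)
    return _struct_from_values(values, model.spec)


def _struct_from_values(values: dict[str, float], spec: ModelSpec) -> StructuralParams:
    cl = tuple(values[n] for n in spec.elimination_names)
    return StructuralParams(
        v1=values["v1"],
        v2=values.get("v2"),
        v3=values.get("v3"),
        cl=cl,
        cl2=values.get("cl2"),
        cl3=values.get("cl3"),
        cl2_ret=values.get("cl2_ret"),
        cl3_ret=values.get("cl3_ret"),
    )


def residual_variance(model: PopulationModel, predicted_conc: float) -> float:
    """Observation variance at a model prediction.

    Proportional error: Var(Cobs) = (sigma * C)^2.  Log-additive error
    models Cobs = C * exp(eps), so the returned value is the variance of
    log(Cobs), sigma^2; simulated concentrations are strictly positive.
    """
    if model.residual == "proportional":
        return (model.sigma * predicted_conc) ** 2
    if predicted_conc <= 0:
        raise ValueError("log-additive error undefined for nonpositive prediction")
    return model.sigma**2


def foce_els_objective(
    data: StudyDataset, model: PopulationModel, config: FitConfig | None = None
) -> float:
    """FOCE-ELS approximate marginal -2 log-likelihood of the dataset.

    Includes the n*log(2*pi) normalization constants (and, for the
    log-additive model, the log-scale Jacobian), so values are comparable
    across error models within this implementation.
    """
    config = config or FitConfig()
    problem = FoceProblem(data, model, config)
    return problem.objective(problem.pack(model))


def _model_from_packed(problem: FoceProblem, model: PopulationModel, x: np.ndarray) -> PopulationModel:
    theta_log, beta, omega, sigma = problem.unpack(x)
    lay = problem.layout
    theta = {n: float(math.exp(v)) for n, v in zip(lay.struct_names, theta_log)}
    cov_map: dict[str, dict[str, dict[str, float]]] = {}
    for b, (p, c, l) in enumerate(lay.beta_keys):
        cov_map.setdefault(p, {}).setdefault(c, {})[l] = float(beta[b])
    om = {n: float(omega[i, i]) for i, n in enumerate(lay.eta_names)}
    om_corr = {}
    if lay.omega_offdiag:
        for i, a in enumerate(lay.eta_names):
            for j, b2 in enumerate(lay.eta_names[:i]):
                om_corr[(a, b2)] = float(omega[i, j])
    return replace(
        model, theta=theta, omega=om, omega_corr=om_corr, sigma=float(sigma), covariate_map=cov_map
    )


def fit(data: StudyDataset, model: PopulationModel, config: FitConfig | None = None) -> FitResult:
    """Estimate (theta, covariate coefficients, omega, sigma) by FOCE-ELS.

    Positivity of theta, omega and sigma is enforced by optimizing on the
    log scale.  Non-convergence within ``config.max_iter`` iterations is
    flagged, with parameters still reported; a singular Hessian leaves
    standard errors as None rather than fabricating them.
    """
    config = config or FitConfig()
    problem = FoceProblem(data, model, config)
    x0 = problem.pack(model)
    if config.max_iter == 0:  # evaluation-only: EBEs/diagnostics at the given model
        from types import SimpleNamespace

        res = SimpleNamespace(
            x=x0, fun=problem.objective(x0), success=False, nit=0, message="max_iter=0"
        )
    else:
        options = {
            "maxiter": config.max_iter,
            "ftol": config.outer_ftol,
            "gtol": config.outer_gtol,
            "maxcor": 25,
        }
        bounds = [(-40.0, 40.0)] * len(x0)  # e^40 bounds any log-scale parameter
        res = minimize(
            problem.objective_and_grad, x0, jac=True, method="L-BFGS-B",
            bounds=bounds, options=options,
        )
        # polish restarts: L-BFGS-B can stall early because the warm-started
        # conditional modes make the objective mildly history-dependent; a
        # fresh quasi-Newton memory with cold modes recovers the remainder.
        # config.max_iter is a total budget across restarts, so a flat
        # likelihood cannot consume restarts * max_iter iterations.
        total_nit = res.nit
        for _ in range(config.restarts):
            if total_nit >= config.max_iter:
                break
            options["maxiter"] = config.max_iter - total_nit
            problem._eta_cache[:] = 0.0
            res2 = minimize(
                problem.objective_and_grad, res.x, jac=True, method="L-BFGS-B",
                bounds=bounds, options=options,
            )
            total_nit += res2.nit
            improved = res.fun - res2.fun
            if res2.fun <= res.fun:
                res2.nit = total_nit
                res = res2
            if improved < config.restart_tol:
                break
        res.nit = total_nit
    x_hat = res.x
    converged = bool(res.success) and res.nit < config.max_iter
    final = problem.finalize(x_hat)
    fitted_model = _model_from_packed(problem, model, x_hat)

    names = problem.layout.names
    estimates = _natural_scale(problem, x_hat)
    se: dict[str, float] | None = None
    ci95: dict[str, tuple[float, float]] | None = None
    if config.compute_se:
        se, ci95 = _wald_se_ci(problem, x_hat, names)

    etas = {sid: final["eta"][i].copy() for i, sid in enumerate(problem.subject_ids)}
    indiv: dict[str, StructuralParams] = {}
    for i, sid in enumerate(problem.subject_ids):
        vals = dict(zip(problem.layout.struct_names, final["individual_P"][i]))
        indiv[sid] = _struct_from_values(vals, model.spec)

    rows = []
    for i, subj in enumerate(data.subjects):
        for j, (t, dv) in enumerate(subj.observations):
            rows.append(
                {
                    "id": subj.id,
                    "time_min": t,
                    "dv": dv,
                    "ipred": final["ipred"][i, j],
                    "pred": final["pred"][i, j],
                    "cwres": final["cwres"][i, j],
                }
            )
    predictions = pd.DataFrame(rows)

    return FitResult(
        model=fitted_model,
        data=data,
        minus2ll=float(res.fun),
        n_params=len(x_hat),
        converged=converged,
        n_iter=int(res.nit),
        estimates=estimates,
        se=se,
        ci95=ci95,
        etas=etas,
        individual_params=indiv,
        predictions=predictions,
        message=str(res.message),
    )


def _natural_scale(problem: FoceProblem, x: np.ndarray) -> dict[str, float]:
    lay = problem.layout
    out: dict[str, float] = {}
    for i, name in enumerate(lay.names):
        if name.startswith("theta_") or name == "sigma":
            out[name] = float(math.exp(x[i]))
        elif name.startswith("beta_"):
            out[name] = float(x[i])
        elif name.startswith("omega_"):
            # diagonal entries are log-SD -> report variance
            k = lay.n_theta + lay.n_beta
            if not lay.omega_offdiag or i < k + lay.n_eta:
                out[name] = float(math.exp(2.0 * x[i]))
            else:
                out[name] = float(x[i])  # raw Cholesky off-diagonal
    return out


def _wald_se_ci(problem: FoceProblem, x: np.ndarray, names):
    """SEs from the numerical Hessian of -2LL; CIs exponentiated from log scale."""
    h = problem.config.hessian_step
    d = len(x)
    base_eta = problem._eta_cache.copy()

    def f(xv: np.ndarray) -> float:
        problem._eta_cache = base_eta.copy()
        return problem.objective(xv, inner_cap=8)

    H = np.zeros((d, d))
    f0 = f(x)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fp[i] = f(xp)
        fm[i] = f(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(d):
        for j in range(i + 1, d):
            xpp = x.copy()
            xpp[[i, j]] += h
            xmm = x.copy()
            xmm[[i, j]] -= h
            fij = f(xpp) + f(xmm)
            H[i, j] = H[j, i] = (fij - fp[i] - fm[i] - fp[j] - fm[j] + 2 * f0) / (2 * h**2)
    problem._eta_cache = base_eta
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, None
    diag = np.diag(cov)
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        return None, None
    se_x = np.sqrt(diag)
    se: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    lay = problem.layout
    for i, name in enumerate(names):
        lo, hi = x[i] - 1.96 * se_x[i], x[i] + 1.96 * se_x[i]
        if name.startswith("theta_") or name == "sigma":
            est = math.exp(x[i])
            se[name] = est * se_x[i]  # delta method
            ci[name] = (math.exp(lo), math.exp(hi))
        elif name.startswith("omega_") and (
            not lay.omega_offdiag or i < lay.n_theta + lay.n_beta + lay.n_eta
        ):
            est = math.exp(2.0 * x[i])
            se[name] = 2.0 * est * se_x[i]
            ci[name] = (math.exp(2.0 * lo), math.exp(2.0 * hi))
        else:
            se[name] = float(se_x[i])
            ci[name] = (float(lo), float(hi))
    return se, ci


def cwres(fit_result: FitResult) -> pd.DataFrame:
    """Per-observation conditional weighted residuals of a converged fit.

    Residuals are standardized with the FOCE-linearized marginal mean and
    covariance evaluated at each subject's conditional mode (Cholesky
    whitening); for a correctly specified model they are approximately
    standard normal.
    """
    if not fit_result.converged:
        raise ValueError("CWRES requires a converged fit")
    return fit_result.predictions[["id", "time_min", "cwres"]].copy()


def covariate_scan(
    data: StudyDataset,
    base_model: PopulationModel,
    covariate: str,
    parameter_subsets: list[tuple[str, ...]],
    config: FitConfig | None = None,
    reference_level: str | None = None,
) -> list[dict]:
    """Shotgun covariate scan: one fit per parameter subset, ranked by AIC.

    For each subset, the categorical ``covariate`` is applied exponentially
    to every parameter in the subset (one coefficient per non-reference
    level, initialized at 0; the reference level is fixed at coefficient
    0).  Failed member fits are recorded with their error, not fatal.
    Returns dicts with keys subset, fit, aic (or error), ascending by AIC.
    """
    config = config or FitConfig()
    levels = sorted({str(s.covariates.get(covariate)) for s in data.subjects})
    if reference_level is None:
        reference_level = levels[0]
    other = [l for l in levels if l != reference_level]
    results = []
    for subset in parameter_subsets:
        if subset:
            cov_map = {p: {c: dict(lv) for c, lv in covs.items()} for p, covs in base_model.covariate_map.items()}
            for p in subset:
                cov_map.setdefault(p, {})[covariate] = {l: 0.0 for l in other}
            candidate = replace(
                base_model,
                covariate_map=cov_map,
                covariate_levels={**base_model.covariate_levels, covariate: tuple(levels)},
            )
        else:
            candidate = base_model
        try:
            fr = fit(data, candidate, config)
            results.append({"subset": tuple(subset), "fit": fr, "aic": fr.aic})
        except Exception as exc:  # member failure recorded, scan continues
            results.append({"subset": tuple(subset), "fit": None, "aic": math.inf, "error": str(exc)})
    results.sort(key=lambda r: r["aic"])
    return results


# ---------------------------------------------------------------------------


def initial_estimates(data: StudyDataset, spec: ModelSpec) -> dict[str, float]:
    """Data-driven initial typical values (noncompartmental heuristics).

    V1 from back-extrapolated C(0); Cl from dose over trapezoid-plus-tail
    AUC; terminal volume from Cl and the terminal slope, split across
    peripheral compartments; distributional clearances as fixed fractions
    of Cl.  These play the role of manually chosen best-fit starting
    lines: rough, but inside the basin of attraction.
    """
    c0s, cls, vzs = [], [], []
    for s in data.subjects:
        t = np.array([o[0] for o in s.observations]) / 60.0
        c = np.maximum(np.array([o[1] for o in s.observations]), 1e-12)
        if len(t) >= 2:
            slope0 = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
            c0 = c[0] * math.exp(-slope0 * t[0])
        else:
            c0 = c[0]
        c0s.append(c0)
        auc = np.trapezoid(c, t)
        lam_z = 0.0
        if len(t) >= 3:
            tail = np.polyfit(t[-3:], np.log(c[-3:]), 1)[0]
            # floor the terminal slope at a half-life of twice the study
            # span: noisy late samples otherwise explode the AUC tail
            lam_z = max(-tail, math.log(2.0) / (2.0 * t[-1]))
            auc += c[-1] / lam_z
        cl_i = s.dose.amount / max(auc, 1e-12)
        cls.append(cl_i)
        vzs.append(cl_i / lam_z if lam_z > 0 else 10 * s.dose.amount / c0)
    c0 = float(np.median(c0s))
    cl = float(np.median(cls))
    vz = float(np.median(vzs))
    dose = data.subjects[0].dose.amount
    v1 = max(dose / c0, 1e-6)
    peripheral = max(vz - v1, v1)
    est: dict[str, float] = {"v1": v1}
    if spec.n_compartments == 1:
        pass
    elif spec.n_compartments == 2:
        est["v2"] = peripheral
        est["cl2"] = 0.5 * cl
    else:
        est["v2"] = 0.8 * peripheral
        est["v3"] = max(0.5 * v1, 0.02 * peripheral)
        est["cl2"] = 0.5 * cl
        est["cl3"] = 0.1 * cl
    for name in spec.elimination_names:
        est[name] = cl / len(spec.elimination_names)
    if not spec.symmetric_distribution:
        if "cl2" in est:
            est["cl2_ret"] = est["cl2"]
        if "cl3" in est:
            est["cl3_ret"] = est["cl3"]
    return est


def simulate_study(
    model: PopulationModel,
    design_subjects: list[Subject],
    rng: np.random.Generator,
    residual: str | None = None,
) -> StudyDataset:
    """Simulate one replicate study at the design of ``design_subjects``.

    Draws eta ~ N(0, Omega) per animal, computes model concentrations at
    the design times, and applies the residual-error model (``residual``
    overrides the model's own, e.g. log-additive for predictive checks).
    """
    from .pk_model import predict_concentrations

    resid = residual or model.residual
    omega = model.omega_matrix()
    k = omega.shape[0]
    out = []
    for subj in design_subjects:
        eta = rng.multivariate_normal(np.zeros(k), omega) if k else np.zeros(0)
        params = individual_params(model, subj.covariates, eta)
        times = [t for t, _ in subj.observations]
        conc = predict_concentrations(params, model.spec, subj.dose, times)
        if resid == "proportional":
            obs = conc * (1.0 + model.sigma * rng.standard_normal(len(times)))
        else:
            obs = conc * np.exp(model.sigma * rng.standard_normal(len(times)))
        obs = np.maximum(obs, 0.0)
        out.append(
            Subject(
                id=subj.id,
                dose=subj.dose,
                observations=list(zip(times, obs.tolist())),
                covariates=dict(subj.covariates),
            )
        )
    return StudyDataset(subjects=out)
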