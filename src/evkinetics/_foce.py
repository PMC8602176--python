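"""Vectorized FOCE-ELS objective machinery.

The marginal likelihood of the nonlinear mixed-effects model has no closed
form; FOCE approximates each subject's contribution by linearizing the
subject model in the random effects eta about the conditional mode
eta-hat.  For the proportional error model the residual variance is
evaluated at the individual prediction (FOCE "with interaction"); for the
log-additive model the likelihood is evaluated on the log scale with the
Jacobian term included so objective values are comparable across error
models.

Everything is evaluated in lockstep across subjects: structural parameters
for all subjects (and all finite-difference perturbations of eta) are
assembled into one batch of rate matrices and pushed through one batched
eigen-solve.  This is what makes repeated fitting (bootstrap, simulation
studies) tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pk_model import ModelSpec, batched_bolus_conc

LOG_2PI = math.log(2.0 * math.pi)
_F_FLOOR = 1e-12
_PENALTY = 1e12
#: Objective values above this are log-compressed (monotone), keeping the
#: outer line search numerically sane at absurd trial points while leaving
#: the region around any reasonable optimum untouched.
_COMPRESS_ABOVE = 1e5


def _compress(val: float) -> float:
    if val > _COMPRESS_ABOVE:
        return _COMPRESS_ABOVE + math.log1p(val - _COMPRESS_ABOVE)
    return val


@dataclass
class PackedLayout:
    """Index layout of the packed outer-optimization vector.

    Order: log(theta) per structural parameter, covariate coefficients
    (raw scale), log of omega Cholesky diagonal (= log SD for a diagonal
    omega) then raw off-diagonal Cholesky entries if estimated, log(sigma).
    """

    struct_names: tuple[str, ...]
    beta_keys: tuple[tuple[str, str, str], ...]  # (param, covariate, level)
    eta_names: tuple[str, ...]
    omega_offdiag: bool

    @property
    def n_theta(self) -> int:
        return len(self.struct_names)

    @property
    def n_beta(self) -> int:
        return len(self.beta_keys)

    @property
    def n_eta(self) -> int:
        return len(self.eta_names)

    @property
    def n_omega(self) -> int:
        k = self.n_eta
        return k + (k * (k - 1) // 2 if self.omega_offdiag else 0)

    @property
    def size(self) -> int:
        return self.n_theta + self.n_beta + self.n_omega + 1

    @property
    def names(self) -> tuple[str, ...]:
        names = [f"theta_{p}" for p in self.struct_names]
        names += [f"beta_{p}__{c}__{l}" for p, c, l in self.beta_keys]
        names += [f"omega_{p}" for p in self.eta_names]
        if self.omega_offdiag:
            k = self.n_eta
            for i in range(k):
                for j in range(i):
                    names.append(f"omega_{self.eta_names[i]}_{self.eta_names[j]}")
        names.append("sigma")
        return tuple(names)


class FoceProblem:
    """Precompiled dataset + model-structure context for FOCE-ELS evaluation."""

    def __init__(self, data, model, config):
        from .nlme_engine import FitConfig  # noqa: F401  (type only)

        self.spec: ModelSpec = model.spec
        self.residual = model.residual
        self.config = config
        self.data = data

        subjects = data.subjects
        if not subjects:
            raise ValueError("no subjects in analysis set")
        self.subject_ids = [s.id for s in subjects]
        self.S = len(subjects)

        struct = self.spec.structural_names
        self.layout = PackedLayout(
            struct_names=struct,
            beta_keys=tuple(
                (p, c, l)
                for p in struct
                for c in sorted(model.covariate_map.get(p, {}))
                for l in sorted(model.covariate_map[p][c])
            ),
            eta_names=tuple(n for n in struct if n in model.omega),
            omega_offdiag=bool(config.estimate_omega_offdiag),
        )

        # Padded observation arrays
        self.T = max(len(s.observations) for s in subjects)
        self.y = np.zeros((self.S, self.T))
        self.t_hr = np.zeros((self.S, self.T))
        self.mask = np.zeros((self.S, self.T), dtype=bool)
        self.dose = np.zeros(self.S)
        for i, s in enumerate(subjects):
            ts = [o[0] for o in s.observations]
            ys = [o[1] for o in s.observations]
            n = len(ts)
            self.t_hr[i, :n] = np.asarray(ts) / 60.0
            self.t_hr[i, n:] = self.t_hr[i, n - 1] if n else 0.0
            self.y[i, :n] = ys
            self.mask[i, :n] = True
            self.dose[i] = s.dose.amount
        self.n_obs = int(self.mask.sum())

        pos = self.y[self.mask & (self.y > 0)]
        floor = config.log_floor
        if floor is None:
            floor = (pos.min() / 100.0) if pos.size else 1e-12
        self.log_floor = float(floor)
        ysafe = np.maximum(self.y, self.log_floor)
        self.z = np.where(self.mask, np.log(ysafe), 0.0)

        # Covariate design: X[i, p, b] multiplies beta_b into log-parameter p
        self.X = np.zeros((self.S, len(struct), self.layout.n_beta))
        for b, (p, cov, level) in enumerate(self.layout.beta_keys):
            pi = struct.index(p)
            for i, s in enumerate(subjects):
                val = s.covariates.get(cov)
                if val is None:
                    raise ValueError(f"subject {s.id} missing covariate {cov!r}")
                if isinstance(val, str):
                    self.X[i, pi, b] = 1.0 if val == level else 0.0
                else:  # continuous covariate: coefficient is a slope on centered value
                    center = float(level) if level else 0.0
                    self.X[i, pi, b] = float(val) - center

        # Eta -> parameter map
        self.M = np.zeros((len(struct), self.layout.n_eta))
        for k, name in enumerate(self.layout.eta_names):
            self.M[struct.index(name), k] = 1.0

        self._struct_index = {n: i for i, n in enumerate(struct)}
        self._eta_cache = np.zeros((self.S, self.layout.n_eta))
        self.n_evals = 0

    # ---------------- packing ----------------

    def pack(self, model) -> np.ndarray:
        lay = self.layout
        x = np.empty(lay.size)
        x[: lay.n_theta] = [math.log(model.theta[p]) for p in lay.struct_names]
        off = lay.n_theta
        for b, (p, c, l) in enumerate(lay.beta_keys):
            x[off + b] = model.covariate_map[p][c][l]
        off += lay.n_beta
        omega_mat = model.omega_matrix(lay.eta_names)
        if lay.omega_offdiag:
            L = np.linalg.cholesky(omega_mat + 1e-300 * np.eye(lay.n_eta))
            x[off : off + lay.n_eta] = np.log(np.diag(L))
            pos = off + lay.n_eta
            for i in range(lay.n_eta):
                for j in range(i):
                    x[pos] = L[i, j]
                    pos += 1
            off = pos
        else:
            x[off : off + lay.n_eta] = 0.5 * np.log(np.diag(omega_mat))
            off += lay.n_eta
        x[off] = math.log(model.sigma)
        return x

    def unpack(self, x: np.ndarray):
        lay = self.layout
        theta_log = x[: lay.n_theta]
        off = lay.n_theta
        beta = x[off : off + lay.n_beta]
        off += lay.n_beta
        k = lay.n_eta
        if k:
            L = np.zeros((k, k))
            np.fill_diagonal(L, np.exp(x[off : off + k]))
            if lay.omega_offdiag:
                pos = off + k
                for i in range(k):
                    for j in range(i):
                        L[i, j] = x[pos]
                        pos += 1
                off = pos
            else:
                off += k
            omega = L @ L.T
        else:
            omega = np.zeros((0, 0))
            if lay.omega_offdiag:
                pass
        sigma = math.exp(x[off])
        return theta_log, beta, omega, sigma

    # ---------------- model evaluation ----------------

    def _log_base(self, theta_log: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """(S, n_p) log individual typical parameters (theta * covariates)."""
        return theta_log[None, :] + self.X @ beta

    def _build_K(self, P: np.ndarray) -> np.ndarray:
        """Rate matrices (B, n, n) from parameter arrays (B, n_p), 1/hr."""
        spec = self.spec
        idx = self._struct_index
        n = spec.n_compartments
        B = P.shape[0]
        K = np.zeros((B, n, n))
        v1 = P[:, idx["v1"]]
        if n >= 2:
            v2 = P[:, idx["v2"]]
            cl2 = P[:, idx["cl2"]]
            cl2r = P[:, idx["cl2_ret"]] if "cl2_ret" in idx else cl2
            K[:, 1, 0] += cl2 / v1
            K[:, 0, 1] += cl2r / v2
        if n >= 3:
            v3 = P[:, idx["v3"]]
            cl3 = P[:, idx["cl3"]]
            cl3r = P[:, idx["cl3_ret"]] if "cl3_ret" in idx else cl3
            K[:, 2, 0] += cl3 / v1
            K[:, 0, 2] += cl3r / v3
        vols = [v1] + ([P[:, idx["v2"]]] if n >= 2 else []) + ([P[:, idx["v3"]]] if n >= 3 else [])
        for site, name in zip(spec.elimination_sites, spec.elimination_names):
            K[:, site - 1, site - 1] -= P[:, idx[name]] / vols[site - 1]
        for i in range(n):
            K[:, i, i] -= sum(K[:, j, i] for j in range(n) if j != i)
        return K

    def _conc(self, log_base: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Central concentrations (S, T) at individual parameters."""
        # clip keeps runaway etas from overflowing exp: the resulting huge
        # (finite) rates give an astronomically bad objective instead of a
        # non-finite matrix, so line searches back off gracefully
        P = np.exp(np.clip(log_base + eta @ self.M.T, -200.0, 200.0))
        Km = self._build_K(P)
        self.n_evals += 1
        return batched_bolus_conc(Km, P[:, self._struct_index["v1"]], self.dose, self.t_hr)

    def _conc_jac(self, log_base: np.ndarray, eta: np.ndarray, h: float = 1e-5):
        """f (S,T) and F = df/deta (S,T,K) by forward differences, one batch."""
        S, K = self.S, self.layout.n_eta
        etas = np.broadcast_to(eta[:, None, :], (S, K + 1, K)).copy()
        for k in range(K):
            etas[:, k + 1, k] += h
        flat = etas.reshape(S * (K + 1), K)
        lb = np.repeat(log_base, K + 1, axis=0)
        P = np.exp(np.clip(lb + flat @ self.M.T, -200.0, 200.0))
        Km = self._build_K(P)
        t = np.repeat(self.t_hr, K + 1, axis=0)
        dose = np.repeat(self.dose, K + 1)
        conc = batched_bolus_conc(Km, P[:, self._struct_index["v1"]], dose, t)
        self.n_evals += 1
        conc = conc.reshape(S, K + 1, self.T)
        f = conc[:, 0, :]
        F = (conc[:, 1:, :] - f[:, None, :]) / h
        return f, np.transpose(F, (0, 2, 1))

    # ---------------- conditional (inner) objective ----------------

    def _cond_obj(self, f: np.ndarray, eta: np.ndarray, omega_inv, sigma: float) -> np.ndarray:
        """Per-subject conditional -2 log joint density (S,), up to constants."""
        m = self.mask
        fpos = np.maximum(f, _F_FLOOR)
        if self.residual == "proportional":
            v = (sigma * fpos) ** 2
            terms = np.where(m, (self.y - f) ** 2 / v + np.log(v), 0.0)
        else:
            terms = np.where(m, (self.z - np.log(fpos)) ** 2 / sigma**2, 0.0)
            terms = terms + np.where(m, 2.0 * math.log(sigma), 0.0)
        obj = terms.sum(axis=1)
        if eta.shape[1]:
            obj = obj + np.einsum("sk,kl,sl->s", eta, omega_inv, eta)
        return obj

    def _inner_solve(self, log_base, omega_inv, sigma, eta0, max_iter):
        """Lockstep Newton (Gauss-Newton Hessian) for all subjects' eta-hat."""
        S, K = self.S, self.layout.n_eta
        eta = eta0.copy()
        f, F = self._conc_jac(log_base, eta)
        obj = self._cond_obj(f, eta, omega_inv, sigma)
        for _ in range(max_iter):
            m = self.mask
            fpos = np.maximum(f, _F_FLOOR)
            if self.residual == "proportional":
                v = (sigma * fpos) ** 2
                r = self.y - f
                # d/deta of (r^2/v + log v): chain rule through f and v
                w1 = np.where(m, -2.0 * r / v - 2.0 * r**2 * sigma**2 * fpos / v**2 + 2.0 / fpos, 0.0)
                grad = np.einsum("st,stk->sk", w1, F)
                wh = np.where(m, 2.0 / v, 0.0)
            else:
                G = F / fpos[..., None]
                rz = np.where(m, self.z - np.log(fpos), 0.0)
                grad = np.einsum("st,stk->sk", -2.0 * rz / sigma**2, G)
                wh = np.where(m, 2.0 / sigma**2, 0.0)
                F = G  # GN curvature uses the log-scale Jacobian
            grad = grad + 2.0 * eta @ omega_inv
            H = np.einsum("st,stk,stl->skl", wh, F, F) + 2.0 * omega_inv[None, :, :]
            try:
                step = -np.linalg.solve(H, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = -grad / np.maximum(np.einsum("skk->sk", H), 1.0)
            # backtracking line search, vectorized across subjects; each
            # subject accepts its first improving step
            alpha = np.ones(S)
            accepted = np.zeros(S, dtype=bool)
            best_eta, best_obj = eta.copy(), obj.copy()
            for _ls in range(8):
                trial = eta + (alpha * ~accepted)[:, None] * step
                f_t = self._conc(log_base, trial)
                obj_t = self._cond_obj(f_t, trial, omega_inv, sigma)
                better = (~accepted) & (obj_t < best_obj - 1e-14)
                best_eta[better] = trial[better]
                best_obj[better] = obj_t[better]
                accepted |= better
                if accepted.all():
                    break
                alpha[~accepted] *= 0.5
            improved = obj - best_obj
            eta = best_eta
            f, F = self._conc_jac(log_base, eta)
            new_obj = self._cond_obj(f, eta, omega_inv, sigma)
            done = np.all(improved < self.config.inner_tol * (1.0 + np.abs(obj)))
            obj = new_obj
            if done:
                break
        return eta, f, F, obj

    # ---------------- marginal -2LL ----------------

    def _marginal_m2ll(self, f, F, eta, omega, sigma, per_subject=False):
        """FOCE-linearized marginal -2 log-likelihood (sum or per subject)."""
        S = self.S
        out = np.zeros(S)
        K = self.layout.n_eta
        for i in range(S):
            m = self.mask[i]
            n_i = int(m.sum())
            fi = np.maximum(f[i, m], _F_FLOOR)
            if self.residual == "proportional":
                Fi = F[i][m]
                ri = self.y[i, m] - f[i, m]
                Vi = np.diag((sigma * fi) ** 2)
            else:
                Fi = F[i][m] / fi[:, None]
                ri = self.z[i, m] - np.log(fi)
                Vi = sigma**2 * np.eye(n_i)
            if K:
                cov = Fi @ omega @ Fi.T + Vi
                resid = ri + Fi @ eta[i]
            else:
                cov = Vi
                resid = ri
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                out[i] = _PENALTY
                continue
            out[i] = n_i * LOG_2PI + logdet + resid @ np.linalg.solve(cov, resid)
            if self.residual == "log_additive":
                out[i] += 2.0 * self.z[i, m].sum()
        return out if per_subject else float(out.sum())

    def objective(self, x: np.ndarray, inner_cap: int | None = None) -> float:
        """FOCE-ELS approximate marginal -2LL at packed parameters x."""
        if not np.all(np.isfinite(x)):
            return _compress(_PENALTY)
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                return _compress(self._objective_impl(x, inner_cap))
        except (np.linalg.LinAlgError, FloatingPointError, ValueError, RuntimeError):
            return _compress(_PENALTY)

    def _objective_impl(self, x: np.ndarray, inner_cap: int | None) -> float:
        theta_log, beta, omega, sigma = self.unpack(x)
        log_base = self._log_base(theta_log, beta)
        K = self.layout.n_eta
        if K:
            try:
                omega_inv = np.linalg.inv(omega)
            except np.linalg.LinAlgError:
                return _PENALTY
            cap = inner_cap if inner_cap is not None else self.config.inner_max_iter
            eta, f, F, _ = self._inner_solve(log_base, omega_inv, sigma, self._eta_cache, cap)
            if inner_cap is None:
                self._eta_cache = eta
        else:
            eta = np.zeros((self.S, 0))
            f = self._conc(log_base, eta)
            F = np.zeros((self.S, self.T, 0))
        val = self._marginal_m2ll(f, F, eta, omega, sigma)
        if not np.isfinite(val):
            return _PENALTY
        return val

    def objective_and_grad(self, x: np.ndarray, h: float = 1e-5):
        """Objective with finite-difference gradient.

        Perturbed evaluations warm-start from the base point's conditional
        modes with a capped inner iteration count; forward differences are
        used (the perturbation of eta-hat is second order in h, so the
        envelope-style error stays far below the optimizer's gradient
        tolerance).
        """
        f0 = self.objective(x)
        base_eta = self._eta_cache.copy()
        g = np.empty(len(x))
        for k in range(len(x)):
            xp = x.copy()
            xp[k] += h
            self._eta_cache = base_eta
            fp = self.objective(xp, inner_cap=2)
            g[k] = (fp - f0) / h
        self._eta_cache = base_eta
        return f0, g

    def finalize(self, x: np.ndarray):
        """Full per-subject quantities at the optimum (etas, preds, CWRES)."""
        theta_log, beta, omega, sigma = self.unpack(x)
        log_base = self._log_base(theta_log, beta)
        K = self.layout.n_eta
        if K:
            omega_inv = np.linalg.inv(omega)
            try:
                eta, f, F, _ = self._inner_solve(
                    log_base, omega_inv, sigma, self._eta_cache, self.config.inner_max_iter
                )
            except np.linalg.LinAlgError:
                # stale warm modes can be pathological for the final point;
                # retry cold before giving up
                eta, f, F, _ = self._inner_solve(
                    log_base, omega_inv, sigma, np.zeros_like(self._eta_cache),
                    self.config.inner_max_iter,
                )
        else:
            eta = np.zeros((self.S, 0))
            f = self._conc(log_base, eta)
            F = np.zeros((self.S, self.T, 0))
        pred = self._conc(log_base, np.zeros_like(eta))  # population prediction (eta = 0)
        m2ll = self._marginal_m2ll(f, F, eta, omega, sigma, per_subject=True)
        cwres = self._cwres(f, F, eta, omega, sigma)
        P = np.exp(np.clip(log_base + eta @ self.M.T, -200.0, 200.0))
        return {
            "eta": eta,
            "ipred": f,
            "pred": pred,
            "m2ll_per_subject": m2ll,
            "cwres": cwres,
            "individual_P": P,
            "omega": omega,
            "sigma": sigma,
        }

    def _cwres(self, f, F, eta, omega, sigma):
        """Conditional weighted residuals: Cholesky whitening of the
        FOCE-linearized marginal residual (log scale for log-additive)."""
        out = np.full((self.S, self.T), np.nan)
        K = self.layout.n_eta
        for i in range(self.S):
            m = self.mask[i]
            n_i = int(m.sum())
            fi = np.maximum(f[i, m], _F_FLOOR)
            if self.residual == "proportional":
                Fi = F[i][m]
                ri = self.y[i, m] - f[i, m]
                Vi = np.diag((sigma * fi) ** 2)
            else:
                Fi = F[i][m] / fi[:, None]
                ri = self.z[i, m] - np.log(fi)
                Vi = sigma**2 * np.eye(n_i)
            cov = (Fi @ omega @ Fi.T if K else 0.0) + Vi
            resid = ri + (Fi @ eta[i] if K else 0.0)
            try:
                L = np.linalg.cholesky(cov)
                out[i, m] = np.linalg.solve(L, resid)
            except np.linalg.LinAlgError:
                pass
        return out
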