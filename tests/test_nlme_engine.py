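"""FOCE-ELS engine: exact limits, quadrature oracle, recovery, diagnostics."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from evkinetics.nlme_engine import (
    FitConfig,
    PopulationModel,
    StudyDataset,
    Subject,
    covariate_scan,
    cwres,
    fit,
    foce_els_objective,
    individual_params,
    initial_estimates,
    residual_variance,
    simulate_study,
)
from evkinetics.pk_model import DoseEvent, ModelSpec, StructuralParams, predict_concentrations
from evkinetics.synthetic_data import ArmDesign, StudyDesign, generate_study

TWO_CPT = ModelSpec(n_compartments=2)
THETA2 = {"v1": 10.0, "v2": 50.0, "cl": 5.0, "cl2": 8.0}


def _toy_subjects(n=3, omega=0.2, sigma=0.3, seed=7, times=(5, 30, 120, 480)):
    rng = np.random.default_rng(seed)
    subs = []
    for i in range(n):
        eta = rng.normal(0, math.sqrt(omega))
        p = StructuralParams(v1=THETA2["v1"] * math.exp(eta), v2=50, cl=(5,), cl2=8)
        c = predict_concentrations(p, TWO_CPT, DoseEvent(100), list(times))
        obs = c * np.exp(rng.normal(0, sigma, len(times)))
        subs.append(Subject(id=str(i), dose=DoseEvent(100), observations=list(zip(times, obs.tolist()))))
    return subs


class TestIndividualParams:
    def test_identity_at_reference(self):
        m = PopulationModel(spec=ModelSpec(n_compartments=1), theta={"v1": 100.0, "cl": 5.0})
        p = individual_params(m, {}, np.zeros(0))
        assert p.v1 == pytest.approx(100.0)

    def test_exponential_eta(self):
        m = PopulationModel(
            spec=ModelSpec(n_compartments=1), theta={"v1": 100.0, "cl": 5.0}, omega={"v1": 0.1}
        )
        p = individual_params(m, {}, {"v1": math.log(2.0)})
        assert p.v1 == pytest.approx(200.0)

    def test_exponential_covariate(self):
        m = PopulationModel(
            spec=ModelSpec(n_compartments=1),
            theta={"v1": 100.0, "cl": 5.0},
            covariate_map={"v1": {"cell_line": {"RMC": 0.1}}},
        )
        assert individual_params(m, {"cell_line": "RMC"}, np.zeros(0)).v1 == pytest.approx(110.517, rel=1e-5)
        assert individual_params(m, {"cell_line": "clone9"}, np.zeros(0)).v1 == pytest.approx(100.0)

    def test_unknown_level_rejected(self):
        m = PopulationModel(
            spec=ModelSpec(n_compartments=1),
            theta={"v1": 100.0, "cl": 5.0},
            covariate_map={"v1": {"cell_line": {"RMC": 0.1}}},
            covariate_levels={"cell_line": ("clone9", "RMC")},
        )
        with pytest.raises(KeyError):
            individual_params(m, {"cell_line": "hela"}, np.zeros(0))


class TestResidualVariance:
    def test_proportional_sd(self):
        m = PopulationModel(spec=ModelSpec(n_compartments=1), theta={"v1": 1.0, "cl": 1.0}, sigma=0.45)
        assert math.sqrt(residual_variance(m, 10.0)) == pytest.approx(4.5)

    def test_log_additive_positivity(self, rng):
        m = PopulationModel(
            spec=ModelSpec(n_compartments=1), theta={"v1": 1.0, "cl": 1.0}, sigma=0.45, residual="log_additive"
        )
        draws = 5.0 * np.exp(rng.normal(0, m.sigma, 10**6))
        assert np.all(draws > 0)
        with pytest.raises(ValueError):
            residual_variance(m, 0.0)


class TestObjective:
    def test_pooled_limit_equals_els_regression(self):
        subs = _toy_subjects()
        data = StudyDataset(subjects=subs)
        m = PopulationModel(spec=TWO_CPT, theta=THETA2, omega={}, sigma=0.3, residual="log_additive")
        obj = foce_els_objective(data, m)
        manual = 0.0
        p = StructuralParams(v1=10, v2=50, cl=(5,), cl2=8)
        for s in subs:
            t = [o[0] for o in s.observations]
            z = np.log([o[1] for o in s.observations])
            f = predict_concentrations(p, TWO_CPT, DoseEvent(100), t)
            manual += float(
                np.sum((z - np.log(f)) ** 2) / 0.09
                + len(t) * math.log(0.09)
                + len(t) * math.log(2 * math.pi)
                + 2 * np.sum(z)
            )
        assert obj == pytest.approx(manual, abs=1e-8)

    def test_subject_duplication_doubles_objective(self):
        subs = _toy_subjects()
        data = StudyDataset(subjects=subs)
        dup = StudyDataset(
            subjects=subs
            + [Subject(id=s.id + "d", dose=s.dose, observations=list(s.observations)) for s in subs]
        )
        m = PopulationModel(spec=TWO_CPT, theta=THETA2, omega={"v1": 0.2}, sigma=0.3, residual="log_additive")
        assert foce_els_objective(dup, m) == pytest.approx(2 * foce_els_objective(data, m), rel=1e-10)

    def test_subject_order_invariance(self):
        subs = _toy_subjects()
        m = PopulationModel(spec=TWO_CPT, theta=THETA2, omega={"v1": 0.2}, sigma=0.3)
        a = foce_els_objective(StudyDataset(subjects=subs), m)
        b = foce_els_objective(StudyDataset(subjects=subs[::-1]), m)
        assert a == pytest.approx(b, rel=1e-9)

    @pytest.mark.parametrize("residual", ["log_additive", "proportional"])
    def test_matches_exact_marginal_likelihood(self, residual):
        """FOCE within 0.5 of -2LL from numerical integration over eta."""
        subs = _toy_subjects()
        data = StudyDataset(subjects=subs)
        om, sig = 0.2, 0.3
        m = PopulationModel(spec=TWO_CPT, theta=THETA2, omega={"v1": om}, sigma=sig, residual=residual)
        obj = foce_els_objective(data, m)

        total = 0.0
        for s in subs:
            t = [o[0] for o in s.observations]
            y = np.array([o[1] for o in s.observations])

            def integrand(eta):
                p = StructuralParams(v1=10 * math.exp(eta), v2=50, cl=(5,), cl2=8)
                f = predict_concentrations(p, TWO_CPT, DoseEvent(100), t)
                if residual == "log_additive":
                    ll = -0.5 * np.sum((np.log(y) - np.log(f)) ** 2) / sig**2
                    ll -= len(t) * math.log(sig) + 0.5 * len(t) * math.log(2 * math.pi)
                    ll -= np.sum(np.log(y))  # jacobian to the y scale
                else:
                    v = (sig * f) ** 2
                    ll = -0.5 * np.sum((y - f) ** 2 / v) - 0.5 * np.sum(np.log(2 * math.pi * v))
                return math.exp(ll) * math.exp(-(eta**2) / (2 * om)) / math.sqrt(2 * math.pi * om)

            L, _ = quad(integrand, -4, 4, limit=200)
            total += -2.0 * math.log(L)
        assert obj == pytest.approx(total, abs=0.5)


class TestFit:
    def test_noise_free_exact_recovery(self):
        design = StudyDesign(
            arms={"clone9": ArmDesign(4, StructuralParams(v1=28, v2=3057, v3=16, cl=(193,), cl2=111, cl3=21))},
            omega={},
            sigma=1e-12,
        )
        data, _ = generate_study(design, seed=1)
        m0 = PopulationModel(
            spec=ModelSpec(),
            theta={"v1": 25, "v2": 2500, "v3": 20, "cl": 150, "cl2": 100, "cl3": 25},
            omega={},
            sigma=0.3,
            residual="proportional",
        )
        fr = fit(data, m0, FitConfig(compute_se=False))
        truth = {"theta_v1": 28, "theta_v2": 3057, "theta_v3": 16, "theta_cl": 193, "theta_cl2": 111, "theta_cl3": 21}
        for k, v in truth.items():
            assert fr.estimates[k] == pytest.approx(v, rel=1e-3)

    def test_aic_definition_and_invariants(self, fitted_small):
        fr = fitted_small
        assert fr.aic == pytest.approx(fr.minus2ll + 2 * fr.n_params)
        assert fr.n_iter <= 1000
        for name, (lo, hi) in fr.ci95.items():
            assert lo <= fr.estimates[name] <= hi or name.startswith("beta_")

    def test_one_compartment_fit_reports_convergence_flag(self, small_study):
        """A 1-compartment fit on tri-exponential data may fail; either way the
        result is flagged honestly and parameters are still reported."""
        data, _ = small_study
        spec1 = ModelSpec(n_compartments=1)
        m0 = PopulationModel(
            spec=spec1, theta=initial_estimates(data, spec1), omega={"v1": 0.1}, sigma=0.3, residual="log_additive"
        )
        fr = fit(data, m0, FitConfig(compute_se=False, max_iter=200))
        assert isinstance(fr.converged, bool)
        assert np.isfinite(fr.minus2ll)
        assert fr.estimates["theta_v1"] > 0

    def test_ebe_shrinks_to_prior_mode_as_omega_vanishes(self, small_study):
        data, _ = small_study
        m = PopulationModel(
            spec=ModelSpec(),
            theta={"v1": 28, "v2": 3057, "v3": 16, "cl": 193, "cl2": 111, "cl3": 21},
            omega={"v1": 1e-8},
            sigma=0.45,
            residual="log_additive",
        )
        problem_fit = fit(data, m, FitConfig(compute_se=False, max_iter=0))
        for eta in problem_fit.etas.values():
            assert abs(eta[0]) < 1e-3


class TestCwres:
    def test_fo_formula_on_two_observation_toy(self):
        """Hand-computed FO standardization on one subject, two observations."""
        times = (60.0, 120.0)
        spec1 = ModelSpec(n_compartments=1)
        theta = {"v1": 10.0, "cl": 5.0}
        om, sig = 0.04, 0.1
        y = np.array([8.0, 6.0])
        sub = Subject(id="s", dose=DoseEvent(100), observations=list(zip(times, y.tolist())))
        m = PopulationModel(spec=spec1, theta=theta, omega={"v1": om}, sigma=sig, residual="log_additive")
        fr = fit(StudyDataset(subjects=[sub]), m, FitConfig(compute_se=False, max_iter=0))
        got = fr.predictions["cwres"].to_numpy()

        # oracle: linearize log f about the fitted conditional mode eta-hat
        eta_hat = fr.etas["s"][0]
        t_hr = np.array(times) / 60.0

        def logf(eta):
            v1 = 10.0 * math.exp(eta)
            return np.log(100.0 / v1) - 5.0 * t_hr / v1

        h = 1e-6
        G = (logf(eta_hat + h) - logf(eta_hat - h)) / (2 * h)
        resid = np.log(y) - logf(eta_hat) + G * eta_hat
        cov = om * np.outer(G, G) + sig**2 * np.eye(2)
        L = np.linalg.cholesky(cov)
        oracle = np.linalg.solve(L, resid)
        np.testing.assert_allclose(got, oracle, atol=1e-4)

    def test_correct_model_yields_standardized_residuals(self):
        design = StudyDesign(
            arms={"clone9": ArmDesign(14, StructuralParams(v1=28, v2=3057, v3=16, cl=(193,), cl2=111, cl3=21))},
        )
        data, _ = generate_study(design, seed=11)
        m = PopulationModel(
            spec=ModelSpec(),
            theta={"v1": 28, "v2": 3057, "v3": 16, "cl": 193, "cl2": 111, "cl3": 21},
            omega={"v1": math.log(1.16), "v2": math.log(1.16), "cl": math.log(1.16)},
            sigma=0.45,
            residual="log_additive",
        )
        fr = fit(data, m, FitConfig(compute_se=False))
        table = cwres(fr)
        vals = table["cwres"].dropna().to_numpy()
        assert -0.2 < vals.mean() < 0.2
        assert np.mean(np.abs(vals) > 3) < 0.01

    def test_requires_convergence(self, fitted_small):
        import dataclasses

        broken = dataclasses.replace(fitted_small, converged=False)
        with pytest.raises(ValueError):
            cwres(broken)


class TestCovariateScan:
    def test_empty_subset_reproduces_base_aic(self, two_arm_study):
        data, _ = two_arm_study
        spec = ModelSpec()
        m0 = PopulationModel(
            spec=spec, theta=initial_estimates(data, spec), omega={"v1": 0.1, "v2": 0.1, "cl": 0.1},
            sigma=0.3, residual="log_additive",
        )
        base = fit(data, m0, FitConfig(compute_se=False))
        res = covariate_scan(data, base.model, "cell_line", [()], FitConfig(compute_se=False))
        assert res[0]["aic"] == pytest.approx(base.aic, abs=0.5)

    def test_true_v2_effect_detected(self, two_arm_study):
        data, _ = two_arm_study
        spec = ModelSpec()
        m0 = PopulationModel(
            spec=spec, theta=initial_estimates(data, spec), omega={"v1": 0.1, "v2": 0.1, "cl": 0.1},
            sigma=0.3, residual="log_additive",
        )
        res = covariate_scan(
            data, m0, "cell_line", [(), ("v2",)], FitConfig(compute_se=False),
            reference_level="clone9",
        )
        assert res[0]["subset"] == ("v2",)
        beta = res[0]["fit"].estimates["beta_v2__cell_line__RMC"]
        assert beta == pytest.approx(math.log(752 / 3057), abs=0.6)


class TestSimulateStudy:
    def test_reproducible_and_positive(self, fitted_small):
        rng1 = np.random.default_rng(9)
        rng2 = np.random.default_rng(9)
        s1 = simulate_study(fitted_small.model, fitted_small.data.subjects, rng1, residual="log_additive")
        s2 = simulate_study(fitted_small.model, fitted_small.data.subjects, rng2, residual="log_additive")
        a = [c for s in s1.subjects for _, c in s.observations]
        b = [c for s in s2.subjects for _, c in s.observations]
        assert a == b
        assert min(a) > 0


class TestDatasetInvariants:
    def test_duplicate_ids_rejected(self):
        s = Subject(id="a", dose=DoseEvent(1), observations=[(1.0, 1.0)])
        with pytest.raises(ValueError):
            StudyDataset(subjects=[s, Subject(id="a", dose=DoseEvent(1), observations=[(1.0, 1.0)])])

    def test_exclusion_moves_subject_to_log(self):
        subs = [
            Subject(id=i, dose=DoseEvent(1), observations=[(1.0, 1.0)]) for i in ("a", "b")
        ]
        ds = StudyDataset(subjects=subs).exclude("a", "contamination")
        assert [s.id for s in ds.subjects] == ["b"]
        assert ds.exclusions == {"a": "contamination"}

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            Subject(id="a", dose=DoseEvent(1), observations=[(2.0, 1.0), (2.0, 1.0)])
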