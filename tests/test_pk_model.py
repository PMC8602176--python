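"""Compartment-model math against closed-form and ODE oracles."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from evkinetics.pk_model import (
    DoseEvent,
    ModelSpec,
    StructuralParams,
    clearance_from_auc,
    ml_per_hr_to_ml_per_min,
    predict_concentrations,
    rate_matrix,
    secondary_params,
)

SCHEDULE = [2, 7.5, 15, 30, 60, 120, 240, 480, 960, 1440]


def _random_params(rng, spec: ModelSpec) -> StructuralParams:
    u = lambda lo, hi: float(rng.uniform(lo, hi))
    n = spec.n_compartments
    return StructuralParams(
        v1=u(5, 60),
        v2=u(50, 5000) if n >= 2 else None,
        v3=u(5, 200) if n >= 3 else None,
        cl=tuple(u(10, 400) for _ in spec.elimination_sites),
        cl2=u(10, 300) if n >= 2 else None,
        cl3=u(5, 200) if n >= 3 else None,
    )


class TestRateMatrix:
    def test_single_compartment_is_scalar_rate(self):
        spec = ModelSpec(n_compartments=1)
        K = rate_matrix(StructuralParams(v1=10, cl=(10,)), spec)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(-1.0)

    def test_clone9_central_outflow_includes_k10(self, clone9_params, three_cpt_spec):
        K = rate_matrix(clone9_params, three_cpt_spec)
        # column sum of the central column equals minus the elimination rate
        assert -K[:, 0].sum() == pytest.approx(193.0 / 28.0, rel=1e-12)
        assert -K[:, 0].sum() == pytest.approx(6.893, rel=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize(
        "spec",
        [
            ModelSpec(n_compartments=2),
            ModelSpec(n_compartments=2, elimination_sites=(1, 2)),
            ModelSpec(n_compartments=3),
            ModelSpec(n_compartments=3, elimination_sites=(2, 3)),
            ModelSpec(n_compartments=3, elimination_sites=(1, 1, 2)),
        ],
    )
    def test_mass_balance_columns(self, seed, spec):
        rng = np.random.default_rng(seed)
        params = _random_params(rng, spec)
        K = rate_matrix(params, spec)
        assert np.all(K[~np.eye(spec.n_compartments, dtype=bool)] >= 0)
        elim = np.zeros(spec.n_compartments)
        vols = [params.v1, params.v2, params.v3]
        for site, cl in zip(spec.elimination_sites, params.cl):
            elim[site - 1] += cl / vols[site - 1]
        np.testing.assert_allclose(K.sum(axis=0), -elim, rtol=1e-12, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rate_matrix(StructuralParams(v1=10, cl=(5,)), ModelSpec(n_compartments=3))


class TestPredictions:
    def test_bolus_initial_condition(self):
        spec = ModelSpec(n_compartments=1)
        c = predict_concentrations(StructuralParams(v1=10, cl=(3,)), spec, DoseEvent(100), [0.0])
        assert c[0] == pytest.approx(10.0)

    def test_mono_exponential_one_half_life(self):
        # degenerate 3-compartment: distribution shut off, pure elimination
        spec = ModelSpec(n_compartments=3)
        params = StructuralParams(v1=10, v2=50, v3=20, cl=(10,), cl2=0.0, cl3=0.0)
        t_half_min = math.log(2.0) * 60.0
        c = predict_concentrations(params, spec, DoseEvent(100), [t_half_min])
        assert c[0] == pytest.approx(5.0, rel=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_eigen_solution_matches_ode(self, seed):
        rng = np.random.default_rng(100 + seed)
        spec = ModelSpec(n_compartments=3)
        params = _random_params(rng, spec)
        conc = predict_concentrations(params, spec, DoseEvent(2000), SCHEDULE)
        K = rate_matrix(params, spec)
        sol = solve_ivp(
            lambda t, a: K @ a,
            (0, 24),
            [2000, 0, 0],
            t_eval=np.array(SCHEDULE) / 60.0,
            rtol=1e-12,
            atol=1e-12,
        )
        oracle = sol.y[0] / params.v1
        assert np.max(np.abs(conc - oracle) / oracle) < 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_central_concentration_non_increasing(self, seed):
        rng = np.random.default_rng(200 + seed)
        spec = ModelSpec(n_compartments=3)
        params = _random_params(rng, spec)
        grid = np.linspace(0, 2880, 400)
        c = predict_concentrations(params, spec, DoseEvent(1000), grid)
        assert np.all(np.diff(c) <= 1e-9 * c[0])
        assert np.all(c > 0)

    def test_three_compartment_collapses_to_two(self):
        spec3 = ModelSpec(n_compartments=3)
        spec2 = ModelSpec(n_compartments=2)
        p2 = StructuralParams(v1=28, v2=3057, cl=(193,), cl2=111)
        p3 = StructuralParams(v1=28, v2=3057, v3=1e-7, cl=(193,), cl2=111, cl3=1e-7)
        c2 = predict_concentrations(p2, spec2, DoseEvent(2000), SCHEDULE)
        c3 = predict_concentrations(p3, spec3, DoseEvent(2000), SCHEDULE)
        np.testing.assert_allclose(c3, c2, rtol=1e-5)

    def test_negative_time_rejected(self):
        spec = ModelSpec(n_compartments=1)
        with pytest.raises(ValueError, match="negative"):
            predict_concentrations(StructuralParams(v1=10, cl=(3,)), spec, DoseEvent(100), [-1.0])

    def test_auc_mass_balance(self, clone9_params, three_cpt_spec):
        """Trapezoid AUC over a dense grid plus terminal tail equals dose/Cl."""
        grid = np.linspace(0, 120 * 60.0, 20000)  # 120 hours, minutes
        c = predict_concentrations(clone9_params, three_cpt_spec, DoseEvent(2000), grid)
        auc = np.trapezoid(c, grid / 60.0)
        K = rate_matrix(clone9_params, three_cpt_spec)
        lam_z = -np.max(np.linalg.eigvals(K).real)  # terminal slope
        auc += c[-1] / lam_z
        assert auc == pytest.approx(2000 / 193.0, rel=5e-3)


class TestSecondaryParams:
    @pytest.mark.parametrize(
        "v3, cl3, printed_min",
        [(16.0, 21.0, 31.0), (90.0, 124.0, 30.0), (17.0, 63.0, 11.0)],
        ids=["clone9", "RFL6", "RMC"],
    )
    def test_compartment3_half_life_matches_published(self, v3, cl3, printed_min):
        params = StructuralParams(v1=28, v2=1000, v3=v3, cl=(100,), cl2=100, cl3=cl3)
        sec = secondary_params(params, DoseEvent(2000))
        assert sec.t_half_compt3 == pytest.approx(printed_min, rel=0.05)

    def test_unit_rate_constant(self):
        params = StructuralParams(v1=10, cl=(10,))
        sec = secondary_params(params, DoseEvent(100))
        assert sec.t_half_elim == pytest.approx(math.log(2.0))
        assert sec.t_half_compt2 is None and sec.t_half_compt3 is None

    def test_formulas(self, clone9_params):
        sec = secondary_params(clone9_params, DoseEvent(2000))
        assert sec.t_half_elim == pytest.approx(math.log(2) * 3101 / 193)
        assert sec.t_half_compt2 == pytest.approx(math.log(2) * 3057 / 111)
        assert sec.auc == pytest.approx(2000 / 193)

    def test_zero_clearance_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            secondary_params(
                StructuralParams(v1=10, v2=5, cl=(1,), cl2=0.0), DoseEvent(10)
            )


class TestClearanceFromAuc:
    def test_published_worked_example(self):
        cl = clearance_from_auc(37.0, 1.184)
        assert cl == pytest.approx(31.25, rel=1e-3)
        assert ml_per_hr_to_ml_per_min(cl) == pytest.approx(0.52, abs=0.005)

    def test_identity_and_errors(self):
        assert clearance_from_auc(7.3, 7.3) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            clearance_from_auc(10.0, 0.0)


class TestSerialization:
    def test_round_trip(self, clone9_params, three_cpt_spec):
        d = json.loads(json.dumps(clone9_params.as_dict()))
        back = StructuralParams.from_dict(d, three_cpt_spec)
        assert back == clone9_params
        s = json.loads(json.dumps(three_cpt_spec.to_dict()))
        assert ModelSpec.from_dict(s) == three_cpt_spec

    def test_invariant_enforcement(self):
        with pytest.raises(ValueError):
            StructuralParams(v1=-1, cl=(5,)).validate(ModelSpec(n_compartments=1))
        with pytest.raises(ValueError):
            StructuralParams(v1=10, cl=(0.0,)).validate(ModelSpec(n_compartments=1))
        with pytest.raises(ValueError):
            ModelSpec(n_compartments=2, elimination_sites=(3,))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    v1=st.floats(5, 50),
    v2=st.floats(50, 4000),
    cl=st.floats(20, 400),
    cl2=st.floats(10, 250),
)
def test_two_compartment_auc_identity(v1, v2, cl, cl2):
    """dose/Cl equals integrated exposure for any 2-compartment model."""
    spec = ModelSpec(n_compartments=2)
    params = StructuralParams(v1=v1, v2=v2, cl=(cl,), cl2=cl2)
    # log-spaced grid resolves the fast distribution phase
    grid = np.concatenate([[0.0], np.geomspace(1e-3, 400 * 60, 8000)])
    c = predict_concentrations(params, spec, DoseEvent(1000), grid)
    K = rate_matrix(params, spec)
    lam_z = -np.max(np.linalg.eigvals(K).real)
    auc = np.trapezoid(c, grid / 60.0) + c[-1] / lam_z
    assert auc == pytest.approx(1000 / cl, rel=5e-3)
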