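"""Closed-form concentration model: examples, limits, and the ODE cross-check."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from zolpitox import (
    DoseEvent,
    DoseRegimen,
    StructuralParams,
    TimeGrid,
    conc_profile,
    conc_single_dose,
    default_time_grid,
    ode_oracle,
    typical_tmax_cmax,
)


class TestConcSingleDose:
    def test_zero_before_lag(self, typical_params):
        assert conc_single_dose(typical_params, 10.0, 0.3) == 0.0
        assert conc_single_dose(typical_params, 10.0, 0.0) == 0.0

    def test_value_near_peak_matches_ode(self, typical_params):
        # frozen from the ODE oracle (DOP853, rtol 1e-10) at the typical peak
        c = conc_single_dose(typical_params, 10.0, 0.9749)
        assert c == pytest.approx(138.236, abs=0.01)
        grid = TimeGrid([0.9749])
        c_ode = ode_oracle(typical_params, DoseRegimen.single(10.0), grid)[0]
        assert abs(c - c_ode) / c_ode < 1e-6

    def test_degenerate_ka_equals_ke_is_continuous(self):
        ke = 16.9 / 61.7
        base = StructuralParams(ka=ke, v=61.7, cl=16.9, tlag=0.2)
        c_limit = conc_single_dose(base, 10.0, 1.5)
        assert np.isfinite(c_limit) and c_limit > 0
        for eps in (1e-6, -1e-6):
            near = StructuralParams(ka=ke * (1 + eps), v=61.7, cl=16.9, tlag=0.2)
            assert conc_single_dose(near, 10.0, 1.5) == pytest.approx(c_limit, rel=1e-5)

    def test_invalid_parameters_rejected(self):
        for bad in [dict(ka=-1, v=61.7, cl=16.9), dict(ka=5.4, v=0, cl=16.9),
                    dict(ka=5.4, v=61.7, cl=-2), dict(ka=5.4, v=61.7, cl=16.9, tlag=-0.1)]:
            with pytest.raises(ValueError):
                StructuralParams(**bad)
        with pytest.raises(ValueError):
            conc_single_dose(StructuralParams(ka=5.4, v=61.7, cl=16.9), -10.0, 1.0)

    def test_continuity_at_lag(self, typical_params):
        eps = 1e-9
        just_after = conc_single_dose(typical_params, 10.0, typical_params.tlag + eps)
        assert just_after < 1e-3


class TestConcProfile:
    def test_single_event_matches_pointwise(self, typical_params, single_10mg):
        grid = TimeGrid([0, 0.25, 0.5, 0.75, 1.0, 1.5, 2, 3, 4, 6, 8, 12])
        prof = conc_profile(typical_params, single_10mg, grid)
        expected = np.array([conc_single_dose(typical_params, 10.0, t) for t in grid.times])
        np.testing.assert_allclose(prof, expected, rtol=1e-12)

    def test_linearity_in_amount(self, typical_params):
        grid = default_time_grid()
        two = DoseRegimen([DoseEvent(0.0, 10.0), DoseEvent(0.0, 10.0)])
        one = DoseRegimen.single(20.0)
        np.testing.assert_allclose(
            conc_profile(typical_params, two, grid),
            conc_profile(typical_params, one, grid),
            rtol=1e-12,
        )

    def test_overdose_peak_scales_with_dose(self, typical_params):
        # 280 mg is 28x the 10 mg dose; the closed form is dose-proportional
        _, cmax10 = typical_tmax_cmax(typical_params, 10.0)
        grid = default_time_grid()
        prof = conc_profile(typical_params, DoseRegimen.single(280.0), grid)
        assert prof.max() == pytest.approx(28 * cmax10, rel=1e-4)
        assert prof.max() == pytest.approx(3870, rel=2e-3)


class TestTmaxCmax:
    def test_against_dense_grid_argmax(self, typical_params):
        tmax, cmax = typical_tmax_cmax(typical_params, 10.0)
        assert tmax == pytest.approx(0.975, abs=1e-3)
        t = np.arange(0.0, 12.0, 1e-4)
        c = conc_single_dose(typical_params, 10.0, t)
        assert tmax == pytest.approx(t[np.argmax(c)], abs=1e-4)
        assert cmax >= c.max()

    def test_closed_form_special_case(self):
        # tlag=0, ka = 2*ke  ->  tmax = ln2 / ke
        p = StructuralParams(ka=0.5, v=10.0, cl=2.5, tlag=0.0)  # ke=0.25, ka=2ke
        tmax, _ = typical_tmax_cmax(p, 5.0)
        assert tmax == pytest.approx(np.log(2) / 0.25, rel=1e-12)

    def test_dose_scaling(self, typical_params):
        t1, c1 = typical_tmax_cmax(typical_params, 10.0)
        t2, c2 = typical_tmax_cmax(typical_params, 20.0)
        assert t1 == t2
        assert c2 == pytest.approx(2 * c1, rel=1e-12)


class TestOdeOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form_random_params(self, seed):
        rng = np.random.default_rng(seed)
        p = StructuralParams(
            ka=float(np.exp(rng.normal(np.log(5.41), 0.8))),
            v=float(np.exp(rng.normal(np.log(61.7), 0.3))),
            cl=float(np.exp(rng.normal(np.log(16.9), 0.3))),
            tlag=float(rng.uniform(0, 0.8)),
        )
        events = [DoseEvent(float(t), float(rng.uniform(5, 300)))
                  for t in sorted(rng.uniform(0, 6, rng.integers(1, 4)))]
        grid = TimeGrid(np.linspace(0.05, 24, 120))
        closed = conc_profile(p, DoseRegimen(events), grid)
        ode = ode_oracle(p, DoseRegimen(events), grid)
        scale = closed.max()
        np.testing.assert_allclose(ode, closed, rtol=2e-6, atol=1e-6 * scale)

    def test_mass_balance(self, typical_params):
        # independent integration carrying an explicit eliminated-amount state
        p = typical_params
        ke = p.ke
        dose = 50.0

        def rhs(_t, y):
            return [-p.ka * y[0], p.ka * y[0] - ke * y[1], ke * y[1]]

        sol = solve_ivp(rhs, (p.tlag, 24.0), [dose, 0.0, 0.0], rtol=1e-10, atol=1e-12)
        totals = sol.y.sum(axis=0)
        np.testing.assert_allclose(totals, dose, rtol=1e-8)

    def test_analytic_auc_identity(self, typical_params):
        # integral of C dt to infinity equals 1000*dose/CL
        p, dose = typical_params, 10.0
        auc, _ = quad(lambda t: conc_single_dose(p, dose, t), 0, 200, limit=400)
        assert auc == pytest.approx(1000 * dose / p.cl, rel=1e-3)


class TestTimeGridAndRegimen:
    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            DoseRegimen([])
        with pytest.raises(ValueError):
            DoseRegimen([DoseEvent(2.0, 10.0), DoseEvent(1.0, 10.0)])
        with pytest.raises(ValueError):
            DoseEvent(-1.0, 10.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 0.0)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            TimeGrid([1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            TimeGrid([-0.5, 1.0])
        with pytest.raises(ValueError):
            TimeGrid([])
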