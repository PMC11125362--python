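"""FOCE-I estimation stack: objective limits, fits, LRT, bootstrap, diagnostics."""

import numpy as np
import pytest

from zolpitox import (
    ModelConfig,
    PopulationParams,
    StudyDesign,
    bootstrap,
    covariate_sex_test,
    cwres_and_gof,
    fit,
    foce_i_objective,
    generate_study,
    lrt,
    vpc,
)


@pytest.fixture(scope="module")
def study23(ref_pop):
    return generate_study(ref_pop, StudyDesign(), seed=1)


@pytest.fixture(scope="module")
def fit23(study23, ref_pop):
    return fit(study23, ref_pop, compute_se=False)


class TestObjective:
    def test_zero_omega_limit_equals_pooled_least_squares(self, study23, ref_pop):
        # with omega -> 0 every eta collapses to zero and the FOCE-I objective
        # reduces to the pooled proportional-error extended least squares
        tiny = PopulationParams(
            theta=ref_pop.theta, omega=1e-12 * np.eye(3), sigma_prop=ref_pop.sigma_prop
        )
        ofv, etas = foce_i_objective(study23, tiny)
        assert np.abs(etas).max() < 1e-4

        obs = study23.observations()
        from zolpitox import conc_single_dose

        pooled = 0.0
        for _, row in obs.iterrows():
            pred = max(conc_single_dose(ref_pop.theta, 10.0, row["time"]), 1e-6)
            var = (ref_pop.sigma_prop * pred) ** 2
            pooled += (row["dv"] - pred) ** 2 / var + np.log(var)
        assert ofv == pytest.approx(pooled, rel=1e-4)

    def test_invariant_to_relabeling_and_record_order(self, study23, ref_pop):
        ofv_a, _ = foce_i_objective(study23, ref_pop)
        shuffled = study23.resample_subjects(list(reversed(study23.subject_ids)))
        ofv_b, _ = foce_i_objective(shuffled, ref_pop)
        assert ofv_b == pytest.approx(ofv_a, abs=1e-6)

    def test_noiseless_data_identified_at_truth(self, typical_params):
        # zero IIV, zero residual: the objective has a sharp minimum at truth
        clean = PopulationParams(
            theta=typical_params, omega=1e-10 * np.eye(3), sigma_prop=0.05
        )
        gen = PopulationParams(theta=typical_params, omega=np.zeros((3, 3)), sigma_prop=0.0)
        data = generate_study(gen, StudyDesign(n_subjects=4), seed=0)
        ofv0, _ = foce_i_objective(data, clean)
        for bump in ([1.05, 1, 1, 1], [1, 1.05, 1, 1], [1, 1, 1.05, 1], [1, 1, 1, 1.2]):
            from zolpitox import StructuralParams

            th = StructuralParams(
                ka=typical_params.ka * bump[0], v=typical_params.v * bump[1],
                cl=typical_params.cl * bump[2], tlag=typical_params.tlag * bump[3],
            )
            ofv_b, _ = foce_i_objective(
                data, PopulationParams(theta=th, omega=1e-10 * np.eye(3), sigma_prop=0.05)
            )
            assert ofv_b > ofv0


class TestLRT:
    @pytest.mark.parametrize(
        "delta,expected",
        [(3.84, False), (3.85, True), (25.3, True), (0.0, False)],
    )
    def test_single_parameter_threshold(self, delta, expected):
        d, significant = lrt(1000.0, 1000.0 - delta, df_added=1)
        assert d == pytest.approx(delta)
        assert significant is expected

    def test_negative_delta_warns(self):
        with pytest.warns(RuntimeWarning, match="optimization"):
            lrt(100.0, 105.0)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            lrt(10.0, 5.0, df_added=0)


class TestFit:
    def test_fit_from_truth_stays_near_truth(self, study23, fit23, ref_pop):
        th = fit23.estimates.theta
        assert th.v == pytest.approx(ref_pop.theta.v, rel=0.15)
        assert th.cl == pytest.approx(ref_pop.theta.cl, rel=0.15)
        assert th.tlag == pytest.approx(ref_pop.theta.tlag, rel=0.15)
        assert np.isfinite(fit23.ofv)
        assert fit23.converged

    def test_fit_improves_on_initial_objective(self, study23, fit23, ref_pop):
        ofv_init, _ = foce_i_objective(study23, ref_pop)
        assert fit23.ofv <= ofv_init + 1e-6

    def test_nested_model_never_beats_full(self, study23, fit23, ref_pop):
        reduced = fit(study23, ref_pop, ModelConfig(estimate_lag=False),
                      compute_se=False, polish_maxfev=300)
        assert fit23.ofv <= reduced.ofv + 0.1  # optimizer tolerance

    def test_standard_errors_reported_on_small_fit(self, ref_pop):
        data = generate_study(ref_pop, StudyDesign(n_subjects=12), seed=6)
        res = fit(data, ref_pop, compute_se=True, polish_maxfev=200)
        assert np.isfinite(res.se["cl"]) and res.se["cl"] > 0
        assert res.rse_percent["cl"] == pytest.approx(100 * res.se["cl"] / res.params["cl"])


class TestCovariates:
    def test_single_sex_dataset_not_testable(self, ref_pop):
        data = generate_study(ref_pop, StudyDesign(n_subjects=6, n_male=6), seed=2)
        with pytest.raises(ValueError, match="not testable"):
            covariate_sex_test(data, ref_pop)

    def test_strong_sex_effect_detected(self, ref_pop):
        # simulate 40 subjects with a 40% lower clearance in females, then
        # test the covariate: the LRT should flag it
        from zolpitox.dataset import PKDataset

        male = generate_study(ref_pop, StudyDesign(n_subjects=20, n_male=20), seed=31)
        low_cl = PopulationParams(
            theta=type(ref_pop.theta)(
                ka=ref_pop.theta.ka, v=ref_pop.theta.v,
                cl=ref_pop.theta.cl * 0.6, tlag=ref_pop.theta.tlag,
            ),
            omega=ref_pop.omega, sigma_prop=ref_pop.sigma_prop,
        )
        female = generate_study(low_cl, StudyDesign(n_subjects=20, n_male=0), seed=32)
        fem = female.records.copy()
        fem["id"] += 20
        import pandas as pd

        cov = pd.DataFrame(
            {"sex": ["M"] * 20 + ["F"] * 20},
            index=pd.Index(range(1, 41), name="id"),
        )
        data = PKDataset(pd.concat([male.records, fem], ignore_index=True), covariates=cov)
        out = covariate_sex_test(data, ref_pop, on="cl")
        assert out["delta_ofv"] > 3.84
        assert out["significant"]
        assert out["beta_sex"] < 0  # females have lower clearance


class TestBootstrap:
    def test_invariants_and_coverage_smoke(self, study23, fit23, ref_pop):
        bs = bootstrap(study23, 8, seed=4, init=fit23.estimates)
        assert bs.n_converged >= 6
        s = bs.summary
        assert (s["ci_lo"] <= s["median"]).all()
        assert (s["median"] <= s["ci_hi"]).all()
        lo, hi = bs.ci("cl")
        assert lo < fit23.params["cl"] * 1.3 and hi > fit23.params["cl"] * 0.7

    def test_two_subjects_minimum(self, ref_pop):
        data = generate_study(ref_pop, StudyDesign(n_subjects=1), seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap(data, 2, seed=0, init=ref_pop)


class TestDiagnostics:
    def test_cwres_standard_normal_under_correct_model(self, study23, fit23):
        tab = cwres_and_gof(study23, fit23)
        assert abs(tab["cwres"].mean()) < 0.25
        assert tab["cwres"].var() == pytest.approx(1.0, abs=0.3)
        assert np.isfinite(tab["iwres"]).all()

    def test_missing_lag_leaves_early_time_trend(self, study23, ref_pop):
        nolag = fit(study23, ref_pop, ModelConfig(estimate_lag=False),
                    compute_se=False, polish_maxfev=300)
        tab = cwres_and_gof(study23, nolag)
        early = tab[tab["time"] <= 0.5]["cwres"]
        late = tab[tab["time"] >= 4.0]["cwres"]
        # lag-generated data fitted without lag: systematic misfit near onset
        assert abs(early.mean()) > 3 * abs(late.mean())


class TestVPC:
    def test_bands_collapse_without_variability(self, no_iiv_pop):
        gen = no_iiv_pop
        data = generate_study(gen, StudyDesign(n_subjects=5), seed=3)
        res = vpc(data, gen, n_sim=100, seed=0)
        np.testing.assert_allclose(res.sim_lo.to_numpy(), res.sim_hi.to_numpy(), rtol=1e-12)
        assert res.coverage() == 1.0

    def test_self_simulated_data_well_covered(self, study23, ref_pop):
        res = vpc(study23, ref_pop, n_sim=300, seed=7)
        assert res.coverage() >= 0.8
        assert (res.sim_lo.to_numpy() <= res.sim_hi.to_numpy()).all()

    def test_minimum_replicates_enforced(self, study23, ref_pop):
        with pytest.raises(ValueError):
            vpc(study23, ref_pop, n_sim=50, seed=0)
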