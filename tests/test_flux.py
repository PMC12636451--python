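import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from flymet import flux as fx
from flymet import simulate as sim


def _one_factor_plate(seed=0, sigma_well=2.0, sigma_resid=1.0, n_wells=8, n_meas=6):
    spec = sim.FluxSimSpec(sigma_well=sigma_well, sigma_batch=0.0, sigma_resid=sigma_resid,
                           n_wells=n_wells, n_batches=1, measurements_per_phase=n_meas,
                           phase_means={"g": {"baseline": (100.0, 10.0)}}, seed=seed)
    return sim.simulate_flux_plate(spec)


class TestLabelPhases:
    def test_no_injections_all_baseline(self):
        raw = pd.DataFrame({"well": ["w1"] * 3, "batch": "b0", "genotype": "g",
                            "medium": "full", "time_min": [0.0, 6.5, 13.0],
                            "ocr": 1.0, "ecar": 1.0})
        assay = fx.label_phases(raw, [])
        assert set(assay.data["phase"]) == {"baseline"}

    def test_three_injections_expected_counts(self):
        raw = pd.DataFrame({"well": ["w1"] * 12, "batch": "b0", "genotype": "g",
                            "medium": "full", "time_min": np.arange(12) * 6.5,
                            "ocr": 1.0, "ecar": 1.0})
        assay = fx.label_phases(raw, [(19.5, "post_oligo"), (39.0, "post_fccp"),
                                      (58.5, "post_rotAA")])
        counts = assay.data["phase"].value_counts()
        assert counts.to_dict() == {"baseline": 3, "post_oligo": 3,
                                    "post_fccp": 3, "post_rotAA": 3}

    def test_roundtrip_with_generator_labels(self, small_flux_plate):
        df = small_flux_plate.data
        starts = df.groupby("phase")["time_min"].min().sort_values()
        injections = [(t, ph) for ph, t in starts.items() if ph != "baseline"]
        relabeled = fx.label_phases(df.drop(columns="phase"), injections)
        assert (relabeled.data["phase"].to_numpy() == df["phase"].to_numpy()).all()

    def test_unordered_injections_rejected(self):
        raw = pd.DataFrame({"well": ["w1"], "batch": "b0", "genotype": "g",
                            "medium": "full", "time_min": [0.0], "ocr": 1.0, "ecar": 1.0})
        with pytest.raises(ValueError):
            fx.label_phases(raw, [(10.0, "post_oligo"), (5.0, "post_fccp")])


class TestRandomInterceptLMM:
    def test_zero_variance_data_matches_ols(self):
        spec = sim.FluxSimSpec(sigma_well=0.0, sigma_batch=0.0, sigma_resid=1.0,
                               n_wells=6, n_batches=2, measurements_per_phase=4, seed=1)
        df = sim.simulate_flux_plate(spec).subset_phases(["baseline", "post_rotAA"])
        df["phase01"] = (df["phase"] == "post_rotAA").astype(int)
        fit = fx.fit_random_intercept_lmm(df, "ecar ~ phase01 * C(genotype)")
        import patsy
        y, X = patsy.dmatrices("ecar ~ phase01 * C(genotype)", df, return_type="dataframe")
        ols = sm.OLS(y.iloc[:, 0], X).fit()
        np.testing.assert_allclose(fit.fe_params.to_numpy(), ols.params.to_numpy(), atol=1e-6)

    def test_balanced_one_factor_matches_anova_estimators(self):
        """REML variance components equal the expected-mean-squares (ANOVA)
        estimators in a balanced one-random-factor design."""
        plate = _one_factor_plate(seed=2)
        df = plate.data
        fit = fx.fit_random_intercept_lmm(df, "ecar ~ 1", random=("well",))
        m = df.groupby("well")["ecar"].count().iloc[0]
        well_means = df.groupby("well")["ecar"].mean()
        msb = m * well_means.var(ddof=1)
        msw = df.groupby("well")["ecar"].apply(lambda x: x.var(ddof=1)).mean()
        np.testing.assert_allclose(fit.vc["residual"], msw, atol=1e-6)
        np.testing.assert_allclose(fit.vc["well"], (msb - msw) / m, atol=1e-6)
        # and the intercept is the grand mean
        np.testing.assert_allclose(fit.fe_params.iloc[0], df["ecar"].mean(), atol=1e-6)

    def test_variance_component_recovery(self):
        """Well and residual variances recovered within 30% (median over
        replicates) in a 12-well x 2-batch x 20-measurement design.  The
        2-level batch component is only checked for nonnegativity: with one
        degree of freedom its REML estimate routinely collapses to zero
        (lme4 reports the same singular fits)."""
        est = []
        for s in range(40):
            spec = sim.FluxSimSpec(sigma_well=2.0, sigma_batch=1.0, sigma_resid=1.0,
                                   n_wells=12, n_batches=2, measurements_per_phase=20,
                                   phase_means={"a": {"baseline": (100.0, 10.0)}}, seed=s)
            fit = fx.fit_random_intercept_lmm(sim.simulate_flux_plate(spec).data, "ecar ~ 1")
            est.append([fit.vc["well"], fit.vc["batch"], fit.vc["residual"]])
        med = np.median(np.array(est), axis=0)
        assert med[0] == pytest.approx(4.0, rel=0.30)
        assert med[2] == pytest.approx(1.0, rel=0.30)
        assert np.all(np.array(est)[:, 1] >= 0.0)

    def test_single_level_random_factor_dropped_with_warning(self):
        plate = _one_factor_plate(seed=3)
        with pytest.warns(UserWarning, match="single level"):
            fit = fx.fit_random_intercept_lmm(plate.data, "ecar ~ 1", random=("well", "batch"))
        assert "batch" not in fit.vc

    def test_singular_design_rejected(self, small_flux_plate):
        df = small_flux_plate.data.copy()
        df["dup"] = df["ocr"]
        with pytest.raises(ValueError):
            fx.fit_random_intercept_lmm(df, "ecar ~ ocr + dup")

    def test_aggregation_equivalence(self):
        """With no batch component, LMM fixed effects equal OLS on well
        means in a balanced design."""
        spec = sim.FluxSimSpec(sigma_well=2.0, sigma_batch=0.0, sigma_resid=1.0,
                               n_wells=8, n_batches=1, measurements_per_phase=6,
                               phase_means={"a": {"baseline": (100.0, 10.0)},
                                            "b": {"baseline": (100.0, 14.0)}}, seed=4)
        df = sim.simulate_flux_plate(spec).data
        fit = fx.fit_random_intercept_lmm(df, "ecar ~ C(genotype)", random=("well",))
        well_means = df.groupby(["well", "genotype"])["ecar"].mean().reset_index()
        ols = sm.OLS(well_means["ecar"],
                     sm.add_constant((well_means["genotype"] == "b").astype(float))).fit()
        np.testing.assert_allclose(np.sort(fit.fe_params.to_numpy()),
                                   np.sort(ols.params.to_numpy()), atol=1e-6)

    def test_reml_loglik_beats_zero_variance_point(self):
        plate = _one_factor_plate(seed=5)
        model = sm.MixedLM.from_formula("ecar ~ 1", data=plate.data,
                                        groups=np.ones(len(plate.data)),
                                        vc_formula={"well": "0 + C(well)"}, re_formula="0")
        free = model.fit(reml=True)
        from statsmodels.regression.mixed_linear_model import MixedLMParams
        # vcomp ~ 0 (exact zero hits log(0) in the SMW determinant identity)
        at_zero = MixedLMParams.from_components(fe_params=free.fe_params.to_numpy(),
                                                cov_re=np.zeros((0, 0)),
                                                vcomp=np.full(1, 1e-10))
        ll_zero = model.loglike(at_zero, profile_fe=True)
        assert np.isfinite(ll_zero)
        assert free.llf >= ll_zero - 1e-8


class TestMetrics:
    def test_null_simulation_reserve_near_zero(self):
        means = {"a": {"baseline": (100.0, 10.0), "post_rotAA": (10.0, 10.0)},
                 "b": {"baseline": (100.0, 10.0), "post_rotAA": (10.0, 10.0)}}
        spec = sim.FluxSimSpec(phase_means=means, sigma_well=1.0, sigma_batch=0.5,
                               sigma_resid=1.0, seed=6)
        per, con = fx.glycolytic_reserve(sim.simulate_flux_plate(spec))
        assert np.abs(per["estimate"]).max() < 3 * per["se"].max() + 1.0
        assert con["p"].iloc[0] > 0.01

    def test_injected_reserve_difference_recovered(self):
        means = {"a": {"baseline": (100.0, 10.0), "post_rotAA": (10.0, 30.0)},
                 "b": {"baseline": (100.0, 10.0), "post_rotAA": (10.0, 20.0)}}
        spec = sim.FluxSimSpec(phase_means=means, sigma_well=0.5, sigma_batch=0.2,
                               sigma_resid=0.5, n_wells=8, seed=7)
        per, con = fx.glycolytic_reserve(sim.simulate_flux_plate(spec))
        by_g = per.set_index("genotype")["estimate"]
        assert by_g["a"] == pytest.approx(20.0, abs=1.0)
        assert by_g["b"] == pytest.approx(10.0, abs=1.0)
        assert con["estimate"].iloc[0] == pytest.approx(10.0, abs=1.5)
        assert con["p"].iloc[0] < 0.001

    def test_tau_reserve_deficit_contrast_negative(self):
        """Defaults encode tau reserve < control, so the (control - tau)
        ordering makes the tau-minus-control contrast negative."""
        plate = sim.simulate_flux_plate(sim.FluxSimSpec(seed=8))
        per, con = fx.glycolytic_reserve(plate)
        by_g = per.set_index("genotype")["estimate"]
        assert by_g["tau"] < by_g["control"]

    def test_maximal_ecar_shift_recovered(self):
        means = {"a": {"post_rotAA": (10.0, 45.0)}, "b": {"post_rotAA": (10.0, 30.0)}}
        spec = sim.FluxSimSpec(phase_means=means, sigma_well=0.5, sigma_batch=0.2,
                               sigma_resid=0.5, n_wells=8, seed=9)
        emms, con = fx.maximal_ecar(sim.simulate_flux_plate(spec))
        assert con["estimate"].iloc[0] == pytest.approx(15.0, abs=1.5)
        assert con["p"].iloc[0] < 0.001

    def test_maximal_ecar_emm_equals_cell_mean_noiseless(self):
        means = {"a": {"post_rotAA": (10.0, 45.0)}, "b": {"post_rotAA": (10.0, 30.0)}}
        spec = sim.FluxSimSpec(phase_means=means, sigma_well=0.0, sigma_batch=0.0,
                               sigma_resid=1e-6, seed=10)
        plate = sim.simulate_flux_plate(spec)
        emms, _ = fx.maximal_ecar(plate)
        cell = plate.data.groupby("genotype")["ecar"].mean()
        np.testing.assert_allclose(emms.set_index("genotype")["estimate"], cell[emms["genotype"]],
                                   atol=1e-4)

    def test_dg2_slopes(self):
        means = {"a": {"post_2dg": (10.0, 30.0)}, "b": {"post_2dg": (10.0, 30.0)}}
        spec = sim.FluxSimSpec(phase_means=means, sigma_well=0.2, sigma_batch=0.1,
                               sigma_resid=0.2, n_wells=8, measurements_per_phase=5,
                               dg2_slopes={"a": -2.0, "b": -1.0}, seed=11)
        per, con = fx.dg2_slope(sim.simulate_flux_plate(spec))
        by_g = per.set_index("genotype")["slope"]
        assert by_g["a"] == pytest.approx(-2.0, abs=0.1)
        assert by_g["b"] == pytest.approx(-1.0, abs=0.1)
        assert con["estimate"].iloc[0] == pytest.approx(-1.0, abs=0.15)
        assert con["p"].iloc[0] < 0.001

    def test_flat_post_2dg_slope_near_zero(self):
        means = {"a": {"post_2dg": (10.0, 30.0)}}
        spec = sim.FluxSimSpec(phase_means=means, sigma_well=0.2, sigma_batch=0.1,
                               sigma_resid=0.2, measurements_per_phase=5, seed=12)
        per, _ = fx.dg2_slope(sim.simulate_flux_plate(spec))
        assert abs(per["slope"].iloc[0]) < 0.1

    def test_ocr_metrics_construction(self):
        """Baseline 100, post-oligo 40, FCCP 150, rotAA 10 -> ATP-linked 60,
        reserve 50, peak capacity 140."""
        means = {"a": {"baseline": (100.0, 10.0), "post_oligo": (40.0, 10.0),
                       "post_fccp": (150.0, 10.0), "post_rotAA": (10.0, 10.0)}}
        spec = sim.FluxSimSpec(phase_means=means, sigma_well=0.5, sigma_batch=0.2,
                               sigma_resid=0.5, n_wells=8, seed=13)
        out = fx.ocr_metrics(sim.simulate_flux_plate(spec))
        expected = {"atp_linked": 60.0, "respiratory_reserve": 50.0, "peak_capacity": 140.0}
        for name, (per, _) in out.items():
            est, se = per["estimate"].iloc[0], per["se"].iloc[0]
            assert abs(est - expected[name]) < 2 * se + 0.5

    def test_oligo_no_effect_atp_linked_zero(self):
        means = {"a": {"baseline": (100.0, 10.0), "post_oligo": (100.0, 10.0),
                       "post_fccp": (150.0, 10.0), "post_rotAA": (10.0, 10.0)}}
        spec = sim.FluxSimSpec(phase_means=means, sigma_well=0.5, sigma_batch=0.2,
                               sigma_resid=0.5, seed=14)
        per, _ = fx.ocr_metrics(sim.simulate_flux_plate(spec))["atp_linked"]
        assert abs(per["estimate"].iloc[0]) < 3 * per["se"].iloc[0] + 0.5

    def test_constant_offset_absorbed(self, small_flux_plate):
        """Adding a constant to every measurement leaves all difference
        metrics unchanged (random-intercept absorption)."""
        shifted = fx.FluxAssay(small_flux_plate.data.assign(
            ocr=small_flux_plate.data["ocr"] + 25.0,
            ecar=small_flux_plate.data["ecar"] + 25.0))
        per0, _ = fx.glycolytic_reserve(small_flux_plate)
        per1, _ = fx.glycolytic_reserve(shifted)
        np.testing.assert_allclose(per0["estimate"], per1["estimate"], atol=1e-6)
        out0 = fx.ocr_metrics(small_flux_plate)["atp_linked"][0]
        out1 = fx.ocr_metrics(shifted)["atp_linked"][0]
        np.testing.assert_allclose(out0["estimate"], out1["estimate"], atol=1e-6)

    def test_missing_phase_rejected(self):
        means = {"a": {"baseline": (100.0, 10.0)}}
        plate = sim.simulate_flux_plate(sim.FluxSimSpec(phase_means=means, seed=15))
        with pytest.raises(ValueError):
            fx.glycolytic_reserve(plate)


class TestTypeIError:
    def test_genotype_contrast_type_i_error(self):
        """Null simulation: glycolytic-reserve genotype contrast rejects at
        <= 7.5% under a nominal 5% level."""
        means = {"a": {"baseline": (100.0, 10.0), "post_rotAA": (10.0, 25.0)},
                 "b": {"baseline": (100.0, 10.0), "post_rotAA": (10.0, 25.0)}}
        rejections = 0
        n_reps = 400
        for s in range(n_reps):
            spec = sim.FluxSimSpec(phase_means=means, sigma_well=1.0, sigma_batch=0.5,
                                   sigma_resid=1.0, n_wells=4, n_batches=2,
                                   measurements_per_phase=3, seed=10_000 + s)
            _, con = fx.glycolytic_reserve(sim.simulate_flux_plate(spec))
            rejections += con["p"].iloc[0] < 0.05
        assert rejections / n_reps <= 0.075
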