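"""The penalized-smooth mixed-model engine and its diagnostics."""

import numpy as np
import pandas as pd
import pytest

import laywise as lw
from laywise.gamm import (AdditiveMixedModel, ModelDesign, SmoothTermSpec,
                          basis_check, concurvity, default_design,
                          deviance_partition, fit_gamm, predict_order_effect)
from laywise.gamm import test_smooth as smooth_flatness_test


def _single_smooth(response="y", k=6):
    return ModelDesign(response=response,
                       terms=(SmoothTermSpec("s(x)", ("x",), k=k),))


class TestFitCore:
    def test_exact_linear_response_matches_ols(self, rng):
        x = rng.uniform(-1, 1, 150)
        y = 2.0 * x - 0.5
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(150)})
        m = AdditiveMixedModel(design=_single_smooth()).fit(df)
        assert np.abs(m.fitted_ - y).max() < 1e-6
        assert m.edf_["s(x)"] == pytest.approx(1.0, abs=0.05)

    def test_infinite_smoothing_equals_ols_on_linear_design(self, rng):
        x = rng.uniform(-1, 1, 200)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.3, 200)
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(200)})
        m = AdditiveMixedModel(design=_single_smooth(),
                               fixed_smoothing={"s(x)": 1e9}).fit(df)
        A = np.column_stack([np.ones(200), x])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.abs(m.fitted_ - A @ beta).max() < 1e-6

    def test_clutch_intercepts_dominate_when_true(self, rng):
        n_c, per = 40, 6
        b = rng.normal(0, 1.0, n_c)
        cid = np.repeat(np.arange(n_c), per)
        x = rng.uniform(-1, 1, n_c * per)
        y = b[cid] + 0.02 * rng.normal(size=n_c * per)
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": cid})
        des = ModelDesign(response="y", terms=(
            SmoothTermSpec("s(x)", ("x",), k=5),
            SmoothTermSpec("re(clutch)", factor="clutch_id",
                           is_random_intercept=True)))
        part = deviance_partition(des, df, None)
        share = part.set_index("term")["drop_one_share_pct"]
        full = part["full_dev_explained_pct"].iloc[0]
        # one-way ANOVA oracle: between-group share of total variance
        anova_r2 = 1 - (df.groupby("clutch_id")["y"]
                          .transform(lambda g: g - g.mean())**2).sum() / \
                       ((df["y"] - df["y"].mean())**2).sum()
        assert share["re(clutch)"] >= 0.95 * full
        assert full / 100 == pytest.approx(anova_r2, abs=0.02)

    def test_ar_rho_zero_standardized_equals_raw(self, small_frame):
        m = fit_gamm(default_design(), small_frame)
        np.testing.assert_array_equal(m.residuals_, m.std_residuals_)

    def test_ar_whitening_changes_first_rows_only_as_specified(self, small_frame):
        rho = 0.4
        m = fit_gamm(default_design(ar1_rho=rho), small_frame)
        r = m.residuals_
        e = m.std_residuals_
        d = small_frame.data
        first = d["clutch_id"].ne(d["clutch_id"].shift()).to_numpy()
        np.testing.assert_allclose(e[first], r[first])
        idx = np.where(~first)[0]
        np.testing.assert_allclose(
            e[idx], (r[idx] - rho * r[idx - 1]) / np.sqrt(1 - rho**2), atol=1e-12)

    def test_fit_invariants(self, small_frame):
        m = fit_gamm(default_design(), small_frame)
        assert 0.0 <= m.deviance_explained_ <= 1.0
        assert abs(np.mean(m.residuals_)) < 1e-6
        for (spec, _b) in m.bases_:
            dim = m.slices_[spec.name].stop - m.slices_[spec.name].start
            assert -1e-8 <= m.edf_[spec.name] <= dim + 1e-8
        assert m.edf_total_ < m.n_

    def test_determinism_without_seeds(self, small_frame):
        m1 = fit_gamm(default_design(), small_frame)
        m2 = fit_gamm(default_design(), small_frame)
        np.testing.assert_array_equal(m1.coef_, m2.coef_)

    def test_order_effect_recovery_low_noise(self):
        cfg = lw.SyntheticConfig(n_years=2, clutches_per_year=25,
                                 between_clutch_cv=0.02, between_year_sd=0.0,
                                 residual_sd=0.005, seed=17)
        eggs, temps, truth = lw.generate_dataset(cfg)
        frame = lw.build_model_frame(eggs, temps)
        m = fit_gamm(default_design(), frame)
        z = np.linspace(-1.3, 1.3, 41)
        curve = predict_order_effect(m, frame, z)
        truth_pct = 100 * lw.default_order_effect(z)
        zdata = frame.data["position_z"].to_numpy()
        offset = (np.interp(zdata, z, curve["deviation_pct"].to_numpy()).mean()
                  - 100 * lw.default_order_effect(zdata).mean())
        err = curve["deviation_pct"].to_numpy() - offset - truth_pct
        assert np.sqrt(np.mean(err**2)) < 0.5


class TestDesignObjects:
    def test_default_design_structure(self):
        des = default_design()
        names = [t.name for t in des.terms]
        assert names == ["s(position_z)", "s(clutch_size)", "s(tmin3)",
                         "ti(position_z,clutch_size)", "ti(tmin3,clutch_size)",
                         "re(year)", "re(clutch_id)"]
        assert des.terms[0].basis == "cubic_regression_spline"
        assert des.terms[3].basis == "thin_plate"
        assert des.terms[6].basis == "random_intercept"

    def test_optional_terms(self):
        des = default_design(include_order_temp_interaction=True,
                             factor_smooth=True)
        names = [t.name for t in des.terms]
        assert "ti(position_z,tmin3)" in names
        assert "fs(position_z|clutch)" in names

    def test_drop_and_only(self):
        des = default_design()
        assert len(des.drop("s(tmin3)").terms) == 6
        assert len(des.only("s(tmin3)").terms) == 1
        with pytest.raises(KeyError):
            des.drop("nope")

    def test_sklearn_param_interface(self, small_frame):
        m = AdditiveMixedModel(design=default_design())
        params = m.get_params()
        assert "design" in params and "group_col" in params
        m.set_params(group_col="clutch_id")
        from sklearn.base import clone
        clone(m)


class TestSmoothTest:
    def test_strong_signal_detected(self, rng):
        x = rng.uniform(-2, 2, 400)
        y = np.sin(1.5 * x) + rng.normal(0, 0.4, 400)
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(400)})
        m = AdditiveMixedModel(design=_single_smooth(k=8)).fit(df)
        assert smooth_flatness_test(m, "s(x)")["p_value"] < 1e-6

    def test_near_constant_response_nothing_to_explain(self, rng):
        x = rng.uniform(-2, 2, 200)
        y = np.full(200, 3.0) + 1e-9 * rng.normal(size=200)
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(200)})
        m = AdditiveMixedModel(design=_single_smooth()).fit(df)
        assert smooth_flatness_test(m, "s(x)")["p_value"] >= 0.5

    def test_null_term_modest_rejection(self):
        """Quick type-I sanity at n=250 (full calibration is in acceptance)."""
        rej = 0
        for s in range(60):
            r = np.random.default_rng(500 + s)
            x = r.uniform(-2, 2, 250)
            y = r.normal(0, 1, 250)
            df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(250)})
            m = AdditiveMixedModel(design=_single_smooth(k=5)).fit(df)
            rej += smooth_flatness_test(m, "s(x)")["p_value"] < 0.05
        assert rej <= 10  # ~5% expected; binomial(60, .09) upper tail


class TestDiagnostics:
    def test_concurvity_duplicated_covariate(self, rng):
        x = rng.uniform(-1, 1, 200)
        y = np.sin(2 * x) + rng.normal(0, 0.2, 200)
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(200)})
        des = ModelDesign(response="y", terms=(
            SmoothTermSpec("s1(x)", ("x",), k=6),
            SmoothTermSpec("s2(x)", ("x",), k=6)))
        m = AdditiveMixedModel(design=des).fit(df)
        rep = concurvity(m).set_index("term")
        assert rep.loc["s1(x)", "worst_case"] > 0.99

    def test_concurvity_independent_covariates_low(self, rng):
        n = 600
        x1, x2 = rng.uniform(-1, 1, n), rng.uniform(-1, 1, n)
        y = np.sin(2 * x1) + np.cos(2 * x2) + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y, "clutch_id": np.arange(n)})
        des = ModelDesign(response="y", terms=(
            SmoothTermSpec("s(x1)", ("x1",), k=6),
            SmoothTermSpec("s(x2)", ("x2",), k=6)))
        m = AdditiveMixedModel(design=des).fit(df)
        rep = concurvity(m).set_index("term")
        assert rep.loc["s(x1)", "observed"] < 0.1
        assert rep.loc["s(x2)", "observed"] < 0.1

    def test_kindex_white_noise_near_one(self, rng):
        n = 1000
        x = rng.uniform(-1, 1, n)
        y = rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(n)})
        m = AdditiveMixedModel(design=_single_smooth(k=5)).fit(df)
        rep = basis_check(m, df).set_index("term")
        assert rep.loc["s(x)", "k_index"] == pytest.approx(1.0, abs=0.1)

    def test_kindex_detects_unmodelled_signal(self, rng):
        n = 800
        x = np.sort(rng.uniform(-1, 1, n))
        y = np.sin(6 * x) + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(n)})
        # smooth forced flat: residuals keep the sinusoid
        m = AdditiveMixedModel(design=_single_smooth(k=8),
                               fixed_smoothing={"s(x)": 1e14}).fit(df)
        rep = basis_check(m, df).set_index("term")
        assert rep.loc["s(x)", "k_index"] < 0.9

    def test_kindex_saturation_flag(self, rng):
        n = 300
        x = rng.uniform(-1, 1, n)
        y = np.sin(8 * x) + rng.normal(0, 0.05, n)
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(n)})
        m = AdditiveMixedModel(design=_single_smooth(k=5),
                               fixed_smoothing={"s(x)": 1e-12}).fit(df)
        rep = basis_check(m, df).set_index("term")
        assert rep.loc["s(x)", "flag"] == "raise k"


class TestPartitionAndCurve:
    def test_single_term_drop_equals_full(self, rng):
        x = rng.uniform(-1, 1, 200)
        y = np.sin(2 * x) + rng.normal(0, 0.3, 200)
        df = pd.DataFrame({"x": x, "y": y, "clutch_id": np.arange(200)})
        part = deviance_partition(_single_smooth(), df, None, method="both")
        row = part.iloc[0]
        assert row["drop_one_share_pct"] == pytest.approx(
            row["full_dev_explained_pct"], abs=1e-6)
        assert row["add_one_share_pct"] == pytest.approx(
            row["full_dev_explained_pct"], abs=1e-6)

    def test_add_one_nesting_monotone(self, rng):
        n = 300
        x1, x2 = rng.uniform(-1, 1, n), rng.uniform(-1, 1, n)
        y = np.sin(2 * x1) + 0.5 * x2 + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y, "clutch_id": np.arange(n)})
        one = ModelDesign(response="y",
                          terms=(SmoothTermSpec("s(x1)", ("x1",), k=6),))
        two = ModelDesign(response="y", terms=(
            SmoothTermSpec("s(x1)", ("x1",), k=6),
            SmoothTermSpec("s(x2)", ("x2",), k=6)))
        d1 = AdditiveMixedModel(design=one).fit(df).deviance_explained_
        d2 = AdditiveMixedModel(design=two).fit(df).deviance_explained_
        assert d2 >= d1 - 1e-8

    def test_curve_axes_consistent(self, small_frame):
        m = fit_gamm(default_design(), small_frame)
        curve = predict_order_effect(m, small_frame)
        mean_v = small_frame.mean_volume
        np.testing.assert_allclose(
            curve["deviation_pct"] * mean_v / 100.0, curve["deviation_mm3"],
            atol=1e-8)
        np.testing.assert_allclose(
            curve["volume_mm3"] - mean_v, curve["deviation_mm3"], atol=1e-8)
        assert not curve["extrapolated"].any()

    def test_grid_outside_range_flagged(self, small_frame):
        m = fit_gamm(default_design(), small_frame)
        curve = predict_order_effect(m, small_frame, np.array([-5.0, 0.0, 5.0]))
        assert list(curve["extrapolated"]) == [True, False, True]
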