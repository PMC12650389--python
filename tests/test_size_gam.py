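import numpy as np
import pandas as pd
import pytest

from krillstruct import size_gam
from krillstruct.size_gam import (
    RESPONSE,
    build_model_frame,
    fit_gam,
    forward_select,
    latitude_block_cv,
    partial_effects,
    residual_diagnostics,
    vif_prescreen,
)


def _frame(n=800, seed=0, sigma=1.0, fx=None, names=("A", "B")):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({name: rng.uniform(0, 1, n) for name in names})
    y = rng.normal(0, sigma, n)
    if fx:
        for name, f in fx.items():
            y = y + f(df[name].to_numpy())
    df[RESPONSE] = y
    return df


class TestModelFrame:
    def test_log_response_and_row_count(self, paper_fleet):
        hauls, lengths, _ = paper_fleet
        frame = build_model_frame(hauls, lengths)
        assert len(frame) == 811
        means = lengths.groupby("haul_id")["length_mm"].mean()
        hid = frame["haul_id"].iloc[0]
        assert frame[RESPONSE].iloc[0] == pytest.approx(np.log(means[hid]))

    def test_missing_covariate_row_dropped(self, small_fleet):
        hauls, lengths, _ = small_fleet
        hauls = hauls.copy()
        hauls.loc[hauls.index[0], "cluster_temp_c"] = np.nan
        frame = build_model_frame(hauls, lengths)
        assert hauls["haul_id"].iloc[0] not in set(frame["haul_id"])

    def test_density_mode_stamped(self, small_fleet):
        hauls, lengths, _ = small_fleet
        frame = build_model_frame(hauls, lengths, density_mode="unit_consistent")
        assert frame.attrs["density_mode"] == "unit_consistent"


class TestVifPrescreen:
    def test_orthogonalish_predictors_all_retained(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(200, 3)), columns=["Year", "DepKRI", "Density"])
        retained, report = vif_prescreen(frame, predictors=["Year", "DepKRI", "Density"])
        assert retained == ["Year", "DepKRI", "Density"]
        assert not report["excluded"].any()

    def test_constructed_collinear_month_excluded(self):
        # Month built so that R^2 on (Year, Latitude) is 0.8 => VIF = 5
        rng = np.random.default_rng(1)
        n = 5000
        year = rng.normal(0, 1, n)
        lat = rng.normal(0, 1, n)
        signal = (year + lat) / np.sqrt(2)
        month = np.sqrt(0.8) * signal + np.sqrt(0.2) * rng.normal(0, 1, n)
        frame = pd.DataFrame({"Year": year, "Latitude": lat, "Month": month})
        retained, report = vif_prescreen(frame, predictors=["Year", "Latitude", "Month"])
        month_vif = report.set_index("predictor").loc["Month", "vif"]
        assert month_vif == pytest.approx(5.0, rel=0.1)
        assert "Month" not in retained


class TestFitGam:
    def test_linear_truth_recovery(self):
        frame = _frame(fx={"A": lambda x: 2.0 * x}, seed=3)
        fit = fit_gam(frame, ["A"])
        pe = partial_effects(fit, "A")
        assert np.all(np.diff(pe["effect"]) > -1e-9)
        assert fit.edf_by_term["A"] == pytest.approx(1.0, abs=0.35)
        assert fit.term_table["p"].iloc[0] < 1e-6

    def test_pure_noise_not_overfit(self):
        hits = 0
        for s in range(50):
            frame = _frame(n=800, seed=1000 + s, names=("A",))
            fit = fit_gam(frame, ["A"])
            hits += (fit.deviance_explained < 0.05) and (fit.term_table["p"].iloc[0] > 0.05)
        assert hits >= 45

    def test_ridge_penalty_limit_collapses_to_intercept(self):
        frame = _frame(fx={"A": lambda x: np.sin(6 * x)}, seed=5)
        fit = fit_gam(frame, ["A"], penalty="ridge", alphas=1e12)
        assert fit.deviance_explained < 1e-6
        assert fit.edf_total == pytest.approx(1.0, abs=1e-3)

    def test_diff2_penalty_limit_equals_ols(self):
        frame = _frame(fx={"A": lambda x: 2 * x, "B": np.cos}, seed=6, n=400)
        fit = fit_gam(frame, ["A", "B"], penalty="diff2", alphas=1e12)
        X = np.column_stack([np.ones(len(frame)), frame["A"], frame["B"]])
        beta, *_ = np.linalg.lstsq(X, frame[RESPONSE], rcond=None)
        np.testing.assert_allclose(fit.fitted, X @ beta, atol=1e-6)

    def test_rank_deficiency_names_term(self):
        frame = _frame(n=100, seed=7)
        frame["C"] = 1.0
        with pytest.raises(ValueError, match="C"):
            fit_gam(frame, ["A", "C"])

    def test_reml_method_runs(self):
        frame = _frame(fx={"A": lambda x: np.sin(4 * x)}, seed=8, n=300)
        fit = fit_gam(frame, ["A"], method="reml")
        assert 0 < fit.deviance_explained < 1


class TestForwardSelect:
    def test_single_improving_candidate(self):
        frame = _frame(fx={"A": lambda x: 3 * x}, seed=9, names=("A",))
        path, fit = forward_select(frame, ["A"])
        assert len(path) == 1
        assert fit.terms == ["A"]

    def test_aic_strictly_decreasing_along_path(self):
        frame = _frame(
            fx={"A": lambda x: 2 * x, "B": lambda x: np.sin(5 * x)}, seed=10,
            names=("A", "B", "C"),
        )
        path, _ = forward_select(frame, ["A", "B", "C"])
        assert (np.diff(path["aic"]) < 0).all()

    def test_true_terms_selected_before_noise(self):
        frame = _frame(
            fx={"Latitude": lambda x: 1.5 * x, "DepKRI": lambda x: np.sin(3 * x)},
            seed=11, names=("Latitude", "DepKRI", "N1", "N2", "N3"),
        )
        path, _ = forward_select(frame, list(frame.columns[:-1]))
        added = list(path["added"])
        assert set(added[:2]) == {"Latitude", "DepKRI"}

    def test_adding_terms_never_decreases_deviance_explained(self):
        frame = _frame(
            fx={"A": lambda x: 2 * x, "B": lambda x: np.cos(4 * x)}, seed=12)
        path, _ = forward_select(frame, ["A", "B"])
        assert path["deviance_explained_pct"].is_monotonic_increasing


class TestPartialEffects:
    def test_sum_to_zero_over_data(self):
        frame = _frame(fx={"A": lambda x: np.sin(5 * x)}, seed=13)
        fit = fit_gam(frame, ["A"])
        curve_at_data = partial_effects(fit, "A", grid=frame["A"].to_numpy())
        assert abs(curve_at_data["effect"].mean()) < 1e-8

    def test_extrapolation_truncated_and_flagged(self):
        frame = _frame(seed=14)
        fit = fit_gam(frame, ["A"])
        pe = partial_effects(fit, "A", grid=np.linspace(-1, 2, 50))
        assert pe.attrs["truncated"]
        assert pe["x"].min() >= frame["A"].min() - 1e-12

    def test_band_widens_away_from_data_mass(self):
        frame = _frame(fx={"A": lambda x: x}, seed=15)
        fit = fit_gam(frame, ["A"])
        pe = partial_effects(fit, "A")
        assert (pe["upper"] >= pe["lower"]).all()
        assert (pe["se"] > 0).all()


class TestDiagnostics:
    def test_residual_mean_is_numerically_zero(self):
        frame = _frame(fx={"A": lambda x: 2 * x}, seed=16)
        fit = fit_gam(frame, ["A"])
        diag = residual_diagnostics(fit)
        assert abs(diag["residual_mean"]) < 1e-8 * frame[RESPONSE].std()

    def test_homoscedastic_truth_passes_bp_most_seeds(self):
        hits = 0
        for s in range(30):
            frame = _frame(fx={"A": lambda x: 2 * x}, seed=2000 + s)
            diag = residual_diagnostics(fit_gam(frame, ["A"]))
            hits += diag["bp_p"] > 0.05
        assert hits >= 0.9 * 30 - 1e-9

    def test_variance_inflated_tail_detected(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(3000 + s)
            x = rng.uniform(0, 1, 800)
            y = 2 * x + rng.normal(0, 0.5 + 2.0 * x, 800)
            frame = pd.DataFrame({"A": x, RESPONSE: y})
            diag = residual_diagnostics(fit_gam(frame, ["A"]))
            hits += diag["bp_p"] < 0.05
        assert hits >= 0.8 * 20


def test_latitude_block_cv_runs(paper_fleet):
    hauls, lengths, _ = paper_fleet
    frame = build_model_frame(hauls, lengths)
    cv = latitude_block_cv(frame, ["Latitude", "DepKRI"], n_blocks=4)
    assert len(cv) == 4
    assert (cv["rmse"] > 0).all()
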