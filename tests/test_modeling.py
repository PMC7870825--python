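import numpy as np
import pandas as pd
import pytest

import uavbiomass as ub
from uavbiomass.modeling import StandardizedTable

from conftest import MODEL_FEATURES


def _tiny_table():
    return pd.DataFrame(
        {
            "month": ["May"] * 3 + ["July"] * 3,
            "replicate": [1] * 6,
            "x": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
            "biomass": [2.0, 4.0, 6.0, 1.0, 2.0, 3.0],
        }
    )


class TestStandardizeByGroup:
    def test_group_moments_are_zero_and_one(self, field_std_table):
        nat = field_std_table.copy()
        std = ub.standardize_by_group(nat, value_columns=("area", "biomass"))
        for _, sub in std.data.groupby(["month", "replicate"]):
            assert abs(sub["area"].mean()) < 1e-9
            assert abs(sub["area"].std(ddof=1) - 1) < 1e-9

    def test_closed_form_three_values(self):
        std = ub.standardize_by_group(_tiny_table(), value_columns=("x",))
        np.testing.assert_allclose(
            std.data["x"].to_numpy(), [-1, 0, 1, -1, 0, 1], atol=1e-12
        )

    def test_idempotent(self):
        once = ub.standardize_by_group(_tiny_table(), value_columns=("x", "biomass"))
        twice = ub.standardize_by_group(once.data, value_columns=("x", "biomass"))
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_zero_variance_column_named_in_error(self):
        t = _tiny_table()
        t["x"] = 5.0
        with pytest.raises(ValueError, match="zero variance.*'x'"):
            ub.standardize_by_group(t, value_columns=("x",))

    def test_small_group_rejected(self):
        t = _tiny_table().iloc[:2]
        with pytest.raises(ValueError, match="fewer than 3"):
            ub.standardize_by_group(t, value_columns=("x",))


class TestFeatureCorrelations:
    def test_duplicate_and_anticorrelated_columns(self):
        t = _tiny_table()
        t["y"] = t["x"]
        t["z"] = -t["x"]
        std = ub.standardize_by_group(t, value_columns=("x", "y", "z"))
        corr = ub.feature_correlations(std)
        assert corr.loc["x", "y"] == pytest.approx(1.0)
        assert corr.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)

    def test_simulated_loadings_recovered(self, field_std_table):
        corr = field_std_table[list(MODEL_FEATURES)].corr()
        for feat, rho in (("height", 0.5), ("ngrdi", 0.6), ("ndre", 0.3)):
            assert corr.loc["area", feat] == pytest.approx(rho, abs=0.05)


class TestClusterFeatures:
    def test_duplicated_features_merge_at_height_zero(self):
        t = _tiny_table()
        t["y"] = t["x"]
        std = ub.standardize_by_group(t, value_columns=("x", "y", "biomass"))
        clusters = ub.cluster_features(std, columns=("x", "y", "biomass"))
        first_merge = clusters.feature_linkage[0]
        assert first_merge[2] == pytest.approx(0.0, abs=1e-9)
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_rededge_trio_clusters_tightly(self, vi_feature_table):
        std = ub.standardize_by_group(vi_feature_table)
        cols = tuple(c for c in std.value_columns if c != "biomass")
        clusters = ub.cluster_features(std, columns=cols)
        order = clusters.feature_order
        trio = sorted(order.index(n) for n in ("ndre", "sr", "ci_rededge"))
        assert trio[2] - trio[0] == 2  # adjacent leaves in the dendrogram


class TestRSSContributions:
    def test_deltas_nonnegative_and_null_feature_negligible(self, field_std_table):
        t = field_std_table.copy()
        rng = np.random.default_rng(0)
        t["junk"] = rng.standard_normal(len(t))  # true coefficient 0
        std_cols = (*MODEL_FEATURES, "junk")
        report = ub.rss_contributions(
            StandardizedTable(t, ("month", "replicate"), (*std_cols, "biomass"),
                              pd.DataFrame()),
            features=std_cols,
        )
        assert (report["delta_rss"] >= 0).all()
        total_ss = ((t["biomass"] - t["biomass"].mean()) ** 2).sum()
        junk = report.set_index("feature").loc["junk", "delta_rss"]
        assert junk / total_ss < 0.005

    def test_duplicated_informative_features_share_no_credit(self, field_std_table):
        t = field_std_table.copy()
        t["area2"] = t["area"]
        with pytest.warns(UserWarning, match="rank-deficient"):
            report = ub.rss_contributions(
                StandardizedTable(t, ("month", "replicate"),
                                  ("area", "area2", "height", "biomass"), pd.DataFrame()),
                features=("area", "area2", "height"),
            )
        by_feat = report.set_index("feature")["delta_rss"]
        assert by_feat["area"] == pytest.approx(0.0, abs=1e-6)
        assert by_feat["area2"] == pytest.approx(0.0, abs=1e-6)
        assert by_feat["height"] > 1.0  # still jointly informative

    def test_area_dominates_contributions_on_default_simulation(self, vi_feature_table):
        std = ub.standardize_by_group(vi_feature_table)
        report = ub.rss_contributions(std)
        top = report.loc[report["delta_rss"].idxmax(), "feature"]
        assert top == "area"


class TestSelectModelFeatures:
    def test_mirrors_published_selection_logic(self, vi_feature_table):
        std = ub.standardize_by_group(vi_feature_table)
        corr = ub.feature_correlations(std)
        clusters = ub.cluster_features(
            std, columns=tuple(c for c in std.value_columns if c != "biomass")
        )
        selected = ub.select_model_features(std, corr, clusters)
        assert selected[0] == "area"
        assert selected[1] == "height"  # volume was next-best -> height taken
        assert len(selected) == 4
        assert "ngrdi" in selected[2:]
        assert set(selected[2:]) & {"ndre", "sr", "ci_rededge"}

    def test_independent_features_reduce_to_top_by_correlation(self):
        rng = np.random.default_rng(1)
        n = 400
        t = pd.DataFrame({
            "month": "May", "replicate": 1,
            "a": rng.standard_normal(n), "b": rng.standard_normal(n),
            "c": rng.standard_normal(n), "d": rng.standard_normal(n),
            "e": rng.standard_normal(n),
        })
        t["biomass"] = (0.9 * t["a"] + 0.7 * t["b"] + 0.5 * t["c"] + 0.4 * t["d"]
                        + 0.35 * t["e"] + rng.standard_normal(n) * 0.2)
        std = ub.standardize_by_group(t)
        corr = ub.feature_correlations(std)
        selected = ub.select_model_features(
            std, corr, ndvi_feature="none", volume_feature="none",
            height_feature="b", n_remaining_clusters=2,
        )
        ranked = corr["biomass"].drop("biomass").abs().sort_values(ascending=False)
        assert selected[:2] == list(ranked.index[:2])

    def test_empty_candidate_set_rejected(self):
        rng = np.random.default_rng(2)
        n = 50
        t = pd.DataFrame({"month": "May", "replicate": 1,
                          "a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        t["biomass"] = t["a"] + 0.1 * rng.standard_normal(n)
        std = ub.standardize_by_group(t)
        corr = ub.feature_correlations(std)
        with pytest.raises(ValueError, match="no candidate"):
            ub.select_model_features(std, corr, ndvi_feature="none",
                                     volume_feature="none", height_feature="b",
                                     r_min=0.99)


class TestFitPredictMetrics:
    def test_orthogonal_features_recover_marginal_correlations(self):
        rng = np.random.default_rng(3)
        n = 5000
        X = rng.standard_normal((n, 2))
        X = X - X.mean(0)
        # orthogonalize exactly
        X[:, 1] -= X[:, 0] * (X[:, 0] @ X[:, 1]) / (X[:, 0] @ X[:, 0])
        X /= X.std(0, ddof=1)
        y = 0.6 * X[:, 0] + 0.3 * X[:, 1]
        df = pd.DataFrame({"f1": X[:, 0], "f2": X[:, 1], "biomass": y})
        model = ub.fit_ols(df, ("f1", "f2"))
        corr1 = np.corrcoef(X[:, 0], y)[0, 1] * y.std(ddof=1)
        corr2 = np.corrcoef(X[:, 1], y)[0, 1] * y.std(ddof=1)
        np.testing.assert_allclose(model.coefficients, [corr1, corr2], rtol=1e-10)

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8],
                           "biomass": [1.0, 2, 3, 4]})
        with pytest.raises(np.linalg.LinAlgError):
            ub.fit_ols(df, ("a", "b"))

    def test_estimates_within_sampling_error_across_seeds(self):
        hits = 0
        for seed in range(20):
            truth = ub.simulate_field(ub.FieldLayout(), noise_sd=0.5, seed=seed)
            model = ub.fit_ols(ub.truth_to_model_table(truth), MODEL_FEATURES)
            se = 3 * 0.5 / np.sqrt(len(truth))  # conservative 3-sigma band
            if np.all(np.abs(model.coefficients - np.array(ub.EQ1_BETA)) < 3 * se):
                hits += 1
        assert hits >= 19

    def test_predict_linear_combination_and_backtransform(self):
        model = ub.BiomassModel.from_preset("final")
        feats = pd.DataFrame([{"area": 0.0, "height": 0.0, "ngrdi": 0.0, "ndre": 0.0},
                              {"area": 1.0, "height": 0.0, "ngrdi": 0.0, "ndre": 0.0}])
        pred = ub.predict(model, feats)
        np.testing.assert_allclose(pred, [0.0, 0.70])
        stats = pd.DataFrame(
            {"month": ["May"], "replicate": [1], "column": ["biomass"],
             "mean": [4.28], "sd": [0.58]}
        ).set_index(["month", "replicate", "column"])
        groups = pd.DataFrame({"month": ["May", "May"], "replicate": [1, 1]})
        kg = ub.predict(model, feats, group_stats=stats, groups=groups)
        assert kg[0] == pytest.approx(4.28)
        assert kg[1] == pytest.approx(4.28 + 0.58 * 0.70)

    def test_predict_missing_feature_rejected(self):
        model = ub.BiomassModel.from_preset("final")
        with pytest.raises(KeyError):
            ub.predict(model, pd.DataFrame({"area": [0.0]}))

    def test_metrics_contracts(self):
        obs = np.array([1.0, 2.0, 3.0, 5.0])
        perfect = ub.metrics(obs, obs)
        assert perfect["r2"] == pytest.approx(1.0) and perfect["rmse"] == 0.0
        affine = ub.metrics(obs, 2.0 + 3.0 * obs)
        assert affine["r2"] == pytest.approx(1.0)
        assert affine["spearman"] == pytest.approx(1.0)
        assert affine["rmse"] > 0  # RMSE is not affine-invariant
        degenerate = ub.metrics(np.zeros(3), np.ones(3))
        assert np.isnan(degenerate["r2"]) and degenerate["rmse"] == 1.0

    def test_ss_r2_variant_penalizes_offsets(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        shifted = obs + 1.0
        assert ub.metrics(obs, shifted)["r2"] == pytest.approx(1.0)
        assert ub.metrics(obs, shifted, r2_method="ss")["r2"] < 1.0

    def test_model_json_round_trip(self, tmp_path):
        model = ub.BiomassModel.from_preset("full")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ub.BiomassModel.from_json(path)
        assert back.features == model.features
        np.testing.assert_allclose(back.coefficients, model.coefficients)

    def test_excluding_flagged_outlier_group_changes_fit(self, field_std_table):
        full = ub.fit_ols(field_std_table, MODEL_FEATURES)
        reduced = ub.fit_ols(field_std_table, MODEL_FEATURES,
                             exclude_groups=[("September", 2)])
        assert reduced.training_info["n"] == full.training_info["n"] - 270
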