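"""Feature screening, collinearity filtering, ensemble training, raster
inversion and nitrogen-status mapping."""

import numpy as np
import pandas as pd
import pytest

import indicot as ic
from indicot.raster import CLASS_CODES


class TestScreening:
    def test_identical_feature_selected(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        feats = pd.DataFrame({"self": y, "noise": rng.normal(size=50)})
        rep = ic.pearson_screen(feats, y)
        assert "self" in rep.selected
        assert rep.correlations["self"] == pytest.approx(1.0)

    def test_boundary_is_strict(self):
        # construct a feature with |r| exactly 0.6 against the target
        y = np.array([1.0, -1.0] * 20)
        rng = np.random.default_rng(1)
        z = rng.normal(size=40)
        z = z - z.mean()
        z -= y * (z @ y) / (y @ y)  # orthogonalise against y
        r0 = 0.6
        x = r0 * y / np.linalg.norm(y) + np.sqrt(1 - r0**2) * z / np.linalg.norm(z)
        feats = pd.DataFrame({"edge": x})
        rep = ic.pearson_screen(feats, y)
        assert abs(rep.correlations["edge"]) == pytest.approx(0.6, abs=1e-12)
        assert rep.selected == []
        assert "edge" in rep.removed

    def test_independent_noise_excluded(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=200)
        feats = pd.DataFrame({"noise": rng.normal(size=200)})
        rep = ic.pearson_screen(feats, y)
        assert rep.selected == []

    def test_constant_feature_flagged(self):
        y = np.arange(10.0)
        rep = ic.pearson_screen(pd.DataFrame({"const": np.ones(10)}), y)
        assert "undefined" in rep.removed["const"]


class TestVIF:
    def test_orthogonal_features_unit_vif(self):
        n = 32
        t = np.arange(n)
        feats = pd.DataFrame({
            "c1": np.cos(2 * np.pi * t / n),
            "s1": np.sin(2 * np.pi * t / n),
            "c2": np.cos(4 * np.pi * t / n),
        })
        vifs = ic.vif(feats)
        np.testing.assert_allclose(vifs, 1.0, atol=1e-9)

    def test_duplicate_feature_infinite(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        vifs = ic.vif(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)}))
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_matches_correlation_matrix_inverse_oracle(self):
        """VIFs equal the diagonal of the inverse correlation matrix."""
        rng = np.random.default_rng(4)
        base = rng.normal(size=(60, 3))
        base[:, 2] = 0.6 * base[:, 0] + 0.4 * base[:, 1] + 0.5 * rng.normal(size=60)
        feats = pd.DataFrame(base, columns=["a", "b", "c"])
        expected = np.diag(np.linalg.inv(np.corrcoef(base, rowvar=False)))
        np.testing.assert_allclose(ic.vif(feats), expected, atol=1e-10)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            ic.vif(pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)}))


class TestCollinearityFilter:
    def test_duplicated_pair_one_removed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.1, 50)
        feats = pd.DataFrame({"a": x, "a_copy": x.copy(), "b": rng.normal(size=50)})
        rep = ic.collinearity_filter(feats, y)
        assert ("a" in rep.selected) ^ ("a_copy" in rep.selected)
        assert "b" in rep.selected

    def test_orthogonal_features_untouched(self):
        n = 32
        t = np.arange(n)
        feats = pd.DataFrame({
            "c1": np.cos(2 * np.pi * t / n),
            "s1": np.sin(2 * np.pi * t / n),
        })
        y = feats["c1"] + 0.5 * feats["s1"]
        rep = ic.collinearity_filter(feats, y)
        assert sorted(rep.selected) == ["c1", "s1"] and rep.removed == {}

    def test_weaker_pair_member_dropped(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=200)
        strong = y + rng.normal(0, 0.3, 200)
        weak = strong + rng.normal(0, 0.12, 200)  # near-duplicate, weaker vs y
        feats = pd.DataFrame({
            "strong": strong, "weak": weak,
            "o1": rng.normal(size=200), "o2": rng.normal(size=200),
        })
        r_pair = np.corrcoef(strong, weak)[0, 1]
        assert r_pair > 0.9
        assert abs(np.corrcoef(weak, y)[0, 1]) < abs(np.corrcoef(strong, y)[0, 1])
        rep = ic.collinearity_filter(feats, y)
        assert "strong" in rep.selected and "weak" in rep.removed
        assert "pairwise" in rep.removed["weak"]

    def test_idempotent_on_own_output(self, default_table):
        y = default_table["lai"]
        feats = default_table[list(ic.VI_NAMES)]
        first = ic.collinearity_filter(feats, y)
        second = ic.collinearity_filter(default_table[first.selected], y)
        assert second.selected == first.selected and second.removed == {}

    def test_terminates_with_at_least_one_feature(self):
        # even under hostile thresholds the one-at-a-time rule keeps a survivor
        x = np.arange(20.0)
        feats = pd.DataFrame({"a": x, "b": x})
        rep = ic.collinearity_filter(feats, x, r_max=0.5, vif_max=1.0)
        assert len(rep.selected) == 1 and len(rep.removed) == 1


class TestMetrics:
    def test_perfect_prediction(self):
        out = ic.evaluate_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (out.r2, out.rmse, out.re_pct) == (1.0, 0.0, 0.0)

    def test_mean_model_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = ic.evaluate_metrics(y, np.full(4, y.mean()))
        assert out.r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        out = ic.evaluate_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert out.r2 == pytest.approx(0.5)
        assert out.rmse == pytest.approx(0.5773502691896257)
        assert out.re_pct == pytest.approx(100.0 / 9.0)

    def test_zero_observation_flags_re(self):
        out = ic.evaluate_metrics([0.0, 1.0, 2.0], [0.1, 1.0, 2.0])
        assert not out.re_defined and np.isnan(out.re_pct)
        assert np.isfinite(out.r2) and np.isfinite(out.rmse)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.uniform(1, 5, 100)
        yhat = y + rng.normal(0, 0.5, 100)
        out = ic.evaluate_metrics(y, yhat)
        sse = sum((a - b) ** 2 for a, b in zip(y, yhat))
        sst = sum((a - np.mean(y)) ** 2 for a in y)
        assert out.r2 == pytest.approx(1 - sse / sst, abs=1e-12)
        assert out.rmse == pytest.approx(np.sqrt(sse / len(y)), abs=1e-12)
        re = 100.0 * np.mean([abs(b - a) / abs(a) for a, b in zip(y, yhat)])
        assert out.re_pct == pytest.approx(re, abs=1e-12)


class TestTraining:
    def test_target_leakage_sanity(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=80)
        X = pd.DataFrame({"leak": y, "noise": rng.normal(size=80)})
        spec = ic.ModelSpec(family="bagged_trees", n_estimators=(100,),
                            max_depth=(6,), seed=0)
        _, result, _ = ic.train_inversion_model(X, y, spec)
        assert result.r2 > 0.9

    def test_pure_noise_target_low_r2(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(120, 4)), columns=list("abcd"))
        y = rng.normal(size=120)
        spec = ic.ModelSpec(seed=0)
        _, result, _ = ic.train_inversion_model(X, y, spec)
        assert result.r2 <= 0.2

    def test_seeded_training_is_reproducible(self, default_table, default_indi):
        X = default_table[list(ic.DEFAULT_FEATURES["indi"])]
        y = default_indi.indi
        spec = ic.ModelSpec(seed=3)
        out1 = ic.train_inversion_model(X, y, spec, stage_labels=default_table["stage"])
        out2 = ic.train_inversion_model(X, y, spec, stage_labels=default_table["stage"])
        np.testing.assert_array_equal(out1[2]["validation_index"], out2[2]["validation_index"])
        np.testing.assert_allclose(
            out1[2]["validation_predictions"], out2[2]["validation_predictions"]
        )
        assert out1[1] == out2[1]

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ValueError):
            ic.train_inversion_model(X, np.arange(5.0), ic.ModelSpec(seed=0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ic.ModelSpec(family="deep_net")
        with pytest.raises(ValueError):
            ic.ModelSpec(folds=1)
        with pytest.raises(ValueError):
            ic.ModelSpec(train_fraction=1.2)


@pytest.fixture(scope="module")
def fitted_bundle(default_table, default_indi):
    df = default_table.copy()
    df["indi"] = default_indi.indi
    feats = list(ic.DEFAULT_FEATURES["indi"])
    spec = ic.ModelSpec(seed=0, n_estimators=(100,), max_depth=(3,), learning_rate=(0.1,))
    model, _, _ = ic.train_inversion_model(df[feats], df["indi"], spec,
                                           stage_labels=df["stage"])
    return model, feats, df


class TestRasterInversion:
    def test_constant_raster_constant_surface(self, fitted_bundle):
        model, feats, _ = fitted_bundle
        bands = np.broadcast_to(
            np.array([0.05, 0.10, 0.08, 0.25, 0.45])[:, None, None], (5, 6, 6)
        ).copy()
        grid = ic.RasterGrid(bands=bands, band_names=ic.BAND_NAMES)
        out = ic.invert_raster(model, grid, feats)
        assert np.nanstd(out.indi) == pytest.approx(0.0, abs=1e-12)

    def test_pixelwise_equals_looped_prediction(self, fitted_bundle, tiny_raster):
        model, feats, _ = fitted_bundle
        out = ic.invert_raster(model, tiny_raster, feats)
        bands = tiny_raster.band_dict()
        for i in range(10):
            for j in range(10):
                if not tiny_raster.mask[i, j]:
                    assert np.isnan(out.indi[i, j])
                    continue
                pixel = {b: float(bands[b][i, j]) for b in ic.BAND_NAMES}
                vis = ic.compute_all_vis(pixel)
                X = pd.DataFrame([[vis[f] for f in feats]], columns=feats)
                assert out.indi[i, j] == pytest.approx(float(model.predict(X)[0]), abs=1e-9)

    def test_nodata_mask_propagates(self, fitted_bundle, tiny_raster):
        model, feats, _ = fitted_bundle
        out = ic.invert_raster(model, tiny_raster, feats)
        np.testing.assert_array_equal(np.isnan(out.indi), ~tiny_raster.mask)
        np.testing.assert_array_equal(out.mask, tiny_raster.mask)

    def test_missing_band_rejected(self, fitted_bundle):
        model, feats, _ = fitted_bundle
        grid = ic.RasterGrid(bands=np.zeros((4, 3, 3)),
                             band_names=("blue", "green", "red", "nir"))
        with pytest.raises(ValueError, match="red_edge"):
            ic.invert_raster(model, grid, feats)


class TestLinkAndMap:
    def test_exact_line_recovered(self):
        indi = np.linspace(-2, 2, 12)
        nni = 2.0 * indi + 1.0
        links = ic.indi_nni_link(indi, nni, ["s"] * 12)
        fit = links["s"]
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["intercept"] == pytest.approx(1.0)
        assert fit["r2"] == pytest.approx(1.0)

    def test_permuted_pairing_near_zero(self):
        rng = np.random.default_rng(11)
        indi = rng.normal(size=100)
        nni = rng.permutation(2.0 * indi + 1.0)
        links = ic.indi_nni_link(indi, nni, ["s"] * 100)
        assert links["s"]["r2"] < 0.1

    def test_degenerate_indi_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ic.indi_nni_link([1.0, 1.0, 1.0], [0.5, 1.0, 1.5], ["s"] * 3)

    def test_default_synthetic_links_positive(self, default_table, default_indi):
        df = default_table.copy()
        curves = ic.fit_dilution_by_irrigation(df)
        a_resp = ic.fit_quadratic_response(curves["irrigation_mm"], curves["a"], "a")
        b_resp = ic.fit_quadratic_response(curves["irrigation_mm"], curves["b"], "b")
        nni = df["lnc_upper"] / ic.nc_model(
            df["irrigation_mm"].to_numpy(), df["dm"].to_numpy(), a_resp, b_resp
        )
        links = ic.indi_nni_link(default_indi.indi, nni, df["stage"])
        assert set(links) == set(ic.STAGES)
        for stage, fit in links.items():
            assert fit["slope"] > 0 and fit["r2"] > 0

    def test_classify_map_thresholds(self):
        links = {"s": {"slope": 1.0, "intercept": 0.0, "r2": 1.0, "n": 10}}
        surface = np.array([[0.2, 1.0, 1.8], [np.nan, 0.94, 1.06]])
        out = ic.classify_map(surface, "s", links, delta=0.05)
        assert out[0, 0] == CLASS_CODES["deficient"]
        assert out[0, 1] == CLASS_CODES["adequate"]
        assert out[0, 2] == CLASS_CODES["excessive"]
        assert out[1, 0] == CLASS_CODES["nodata"]
        assert out[1, 1] == CLASS_CODES["deficient"]
        assert out[1, 2] == CLASS_CODES["excessive"]

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="link"):
            ic.classify_map(np.zeros((2, 2)), "nope", {})

    def test_zero_n_plots_map_deficient(self, fitted_bundle):
        """End-to-end: rasterise the boll-setting stage, invert and classify;
        zero-N plots must come out deficient and high-N plots must not."""
        model, feats, df = fitted_bundle
        curves = ic.fit_dilution_by_irrigation(df)
        a_resp = ic.fit_quadratic_response(curves["irrigation_mm"], curves["a"], "a")
        b_resp = ic.fit_quadratic_response(curves["irrigation_mm"], curves["b"], "b")
        df = df.assign(nni=df["lnc_upper"] / ic.nc_model(
            df["irrigation_mm"].to_numpy(), df["dm"].to_numpy(), a_resp, b_resp))
        links = ic.indi_nni_link(df["indi"], df["nni"], df["stage"])
        raster, layout, _ = ic.rasterize_stage(df, "boll_setting", pixel_size=1.0,
                                               noise_scale=0.003, seed=1)
        inverted = ic.invert_raster(model, raster, feats)
        classes = ic.classify_map(inverted.indi, "boll_setting", links,
                                  mask=inverted.mask)
        treatments = [pid for pid, _ in layout]
        for k, name in enumerate(treatments):
            pix = classes[raster.plot_ids == k]
            pix = pix[pix > 0]
            frac_deficient = np.mean(pix == CLASS_CODES["deficient"])
            if name.endswith("N0"):
                assert frac_deficient > 0.5, f"{name}: {frac_deficient:.2f}"
            if name.endswith("N350") and not name.startswith("W0.6"):
                assert frac_deficient < 0.5, f"{name}: {frac_deficient:.2f}"
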