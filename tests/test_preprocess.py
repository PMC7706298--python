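"""Plot filters, moisture adjustment, repeatability, binning and indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenosel.datatypes import SpectraMatrix
from phenosel.preprocess import (DEFAULT_VI_REGISTRY, adjust_moisture,
                                 average_plot_reflectance, bin_wavebands,
                                 compute_vi, estimate_band_repeatability,
                                 filter_bands_by_repeatability,
                                 filter_low_emergence, filter_shattered,
                                 normalize_ct_by_pass, repeatability_index)


def _plot_frame(counts, env="E1"):
    return pd.DataFrame({
        "environment": env, "plot_id": [f"P{i}" for i in range(len(counts))],
        "stand_count": counts, "shatter_score": 1,
        "seed_yield": 1000.0, "moisture": 0.13,
    })


class TestEmergenceFilter:
    def test_equal_counts_remove_nothing(self):
        plots = _plot_frame([10] * 8)
        retained, removed = filter_low_emergence(plots)
        assert len(removed) == 0 and len(retained) == 8

    def test_hand_quantile_case(self):
        # counts chosen so Q1 = 9, IQR = 3 under linear interpolation:
        # threshold 9 - 2*3 = 3; count 2 is removed, count 3 is retained
        counts = [2, 9, 9, 9, 10, 11, 12, 12, 12]
        q1, q3 = np.percentile(counts, [25, 75])
        assert q1 == 9 and q3 - q1 == 3
        retained, removed = filter_low_emergence(_plot_frame(counts))
        assert list(removed["stand_count"]) == [2]
        counts[0] = 3
        retained, removed = filter_low_emergence(_plot_frame(counts))
        assert len(removed) == 0          # not strictly below the threshold

    def test_per_environment_thresholds(self):
        a = _plot_frame([2, 9, 9, 9, 10, 11, 12, 12, 12], env="E1")
        b = _plot_frame([2, 2, 2, 2, 3, 3, 3, 3, 3], env="E2")
        plots = pd.concat([a, b], ignore_index=True)
        _, removed = filter_low_emergence(plots)
        assert set(removed["environment"]) == {"E1"}

    def test_all_missing_rejected(self):
        plots = _plot_frame([np.nan] * 5)
        with pytest.raises(ValueError, match="stand counts"):
            filter_low_emergence(plots)


class TestShatterFilter:
    @pytest.mark.parametrize("score,removed", [(1, False), (3, False),
                                               (4, True), (5, True)])
    def test_threshold_boundary(self, score, removed):
        plots = _plot_frame([10, 10])
        plots.loc[1, "shatter_score"] = score
        out, flagged = filter_shattered(plots)
        assert (len(flagged) == 1) == removed
        assert np.isnan(out.loc[1, "seed_yield"]) == removed
        # phenomics rows are always retained
        assert len(out) == 2


class TestMoisture:
    def test_identity_at_basis(self):
        assert adjust_moisture(2000.0, 0.13) == pytest.approx(2000.0)

    @pytest.mark.parametrize("m,expected", [(0.10, 1034.48), (0.20, 919.54)])
    def test_hand_values(self, m, expected):
        assert adjust_moisture(1000.0, m) == pytest.approx(expected, abs=0.01)

    def test_invalid_moisture(self):
        with pytest.raises(ValueError):
            adjust_moisture(1000.0, 1.0)

    @given(y=st.floats(0, 1e4), m=st.floats(0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_dry_matter_preserved(self, y, m):
        adj = adjust_moisture(y, m)
        assert adj * (1 - 0.13) == pytest.approx(y * (1 - m), rel=1e-9)


class TestCTNormalization:
    def test_two_plot_pass(self):
        out = normalize_ct_by_pass(pd.Series([30.0, 32.0]),
                                   pd.Series(["p1", "p1"]))
        np.testing.assert_allclose(out, [-1.0, 1.0])

    def test_drift_removed(self):
        ct = pd.Series([30.0, 32.0, 35.0, 37.0])
        passes = pd.Series(["p1", "p1", "p2", "p2"])
        out = normalize_ct_by_pass(ct, passes)
        np.testing.assert_allclose(out[:2], out[2:])

    def test_singleton_pass_warns_and_centers(self):
        with pytest.warns(UserWarning, match="single plot"):
            out = normalize_ct_by_pass(pd.Series([28.0]), pd.Series(["p1"]))
        assert out.iloc[0] == 0.0


class TestScanAveraging:
    def test_mean_of_two_scans(self):
        idx = pd.MultiIndex.from_tuples(
            [("E1", "P1", 1), ("E1", "P1", 2)],
            names=["environment", "plot_id", "scan"])
        sp = SpectraMatrix("S1", np.array([500.0]),
                           pd.DataFrame({500: [0.2, 0.4]}, index=idx))
        out = average_plot_reflectance(sp)
        assert out.frame.iloc[0, 0] == pytest.approx(0.3)

    def test_missing_scan_uses_other_with_warning(self):
        idx = pd.MultiIndex.from_tuples(
            [("E1", "P1", 1), ("E1", "P1", 2), ("E1", "P2", 1)],
            names=["environment", "plot_id", "scan"])
        sp = SpectraMatrix("S1", np.array([500.0]),
                           pd.DataFrame({500: [0.2, 0.4, 0.5]}, index=idx))
        with pytest.warns(UserWarning, match="missing a reflectance scan"):
            out = average_plot_reflectance(sp)
        assert out.frame.loc[("E1", "P2"), 500] == pytest.approx(0.5)


class TestRepeatability:
    @pytest.mark.parametrize("s2g,s2gxe,s2e,e,r,expected", [
        (2.0, 2.0, 4.0, 2, 2, 0.5),     # 2 / (2 + 1 + 1)
        (3.0, 0.0, 0.0, 4, 2, 1.0),
        (0.0, 1.0, 1.0, 4, 2, 0.0),
        (-1.0, 1.0, 1.0, 4, 2, 0.0),    # negative input truncated
    ])
    def test_index_formula(self, s2g, s2gxe, s2e, e, r, expected):
        assert repeatability_index(s2g, s2gxe, s2e, e, r) == pytest.approx(
            expected)

    def test_monotone_in_environments_and_reps(self):
        base = repeatability_index(1.0, 1.0, 2.0, 2, 2)
        assert repeatability_index(1.0, 1.0, 2.0, 4, 2) > base
        assert repeatability_index(1.0, 1.0, 2.0, 2, 4) > base

    def test_single_environment_rejected(self, tiny_dataset):
        ds = tiny_dataset
        sp = average_plot_reflectance(ds.spectra["S1"])
        single = sp.frame.loc[["E1"]]
        sub = SpectraMatrix("S1", sp.wavelengths, single)
        with pytest.raises(ValueError, match="2 environments"):
            estimate_band_repeatability(sub, ds.plots)

    def test_estimates_track_truth(self, tiny_dataset):
        ds = tiny_dataset
        sp = average_plot_reflectance(ds.spectra["S1"])
        est = estimate_band_repeatability(sp, ds.plots)
        truth = ds.truth.true_band_h2.loc[est.index.astype(float)]
        r = np.corrcoef(est["H2"], truth)[0, 1]
        assert r > 0.8
        assert est["H2"].between(0, 1).all()


class TestBandFilter:
    def test_strict_threshold_boundary(self):
        est = pd.DataFrame({"H2": [0.29, 0.30, 0.31]},
                           index=[500, 510, 520])
        assert filter_bands_by_repeatability(est, 0.3) == [510, 520]

    def test_zero_threshold_keeps_all(self):
        est = pd.DataFrame({"H2": [0.0, 0.1]}, index=[500, 510])
        assert len(filter_bands_by_repeatability(est, 0.0)) == 2


class TestBinning:
    def test_1780_bands_give_178_bins(self):
        lam = np.arange(350, 350 + 1780)
        frame = pd.DataFrame(np.random.default_rng(0).random((2, 1780)),
                             columns=lam)
        binned, bins = bin_wavebands(frame, width=10.0, grid_step=1.0)
        assert binned.shape[1] == 178
        assert len(bins) == 178
        assert (bins["n_bands"] == 10).all()

    def test_constant_spectrum(self):
        lam = np.arange(400, 420)
        frame = pd.DataFrame(np.full((3, 20), 0.37), columns=lam)
        binned, _ = bin_wavebands(frame, width=10.0, grid_step=1.0)
        assert np.allclose(binned.to_numpy(), 0.37)

    def test_hand_means(self):
        lam = np.arange(700, 720)
        frame = pd.DataFrame([np.arange(1, 21, dtype=float)], columns=lam)
        binned, bins = bin_wavebands(frame, width=10.0, grid_step=1.0)
        np.testing.assert_allclose(binned.iloc[0].to_numpy(), [5.5, 15.5])
        # bin label is the rounded average wavelength (700..709 -> 705)
        assert list(binned.columns) == ["R705", "R715"]

    def test_partial_trailing_block_dropped(self):
        lam = np.arange(400, 425)           # 25 bands -> 2 full bins
        frame = pd.DataFrame(np.zeros((1, 25)), columns=lam)
        binned, _ = bin_wavebands(frame, width=10.0, grid_step=1.0)
        assert binned.shape[1] == 2

    def test_noncontiguous_segments_bin_separately(self):
        lam = np.concatenate([np.arange(400, 410), np.arange(500, 510)])
        frame = pd.DataFrame(np.zeros((1, 20)), columns=lam)
        binned, bins = bin_wavebands(frame, width=10.0, grid_step=1.0)
        assert binned.shape[1] == 2
        assert set(bins["center"]) == {405, 505}

    def test_linearity_bin_then_average(self):
        rng = np.random.default_rng(1)
        lam = np.arange(400, 440)
        frame = pd.DataFrame(rng.random((6, 40)), columns=lam)
        b_then_a, _ = bin_wavebands(frame, width=10.0, grid_step=1.0)
        a_then_b, _ = bin_wavebands(frame.mean().to_frame().T,
                                    width=10.0, grid_step=1.0)
        np.testing.assert_allclose(b_then_a.mean().to_numpy(),
                                   a_then_b.iloc[0].to_numpy())

    def test_empty_band_set_rejected(self):
        with pytest.raises(ValueError, match="no retained bands"):
            bin_wavebands(pd.DataFrame(index=[0]))


class TestVegetationIndices:
    def _spectra(self, values: dict):
        lam = np.array(sorted(values))
        frame = pd.DataFrame([np.array([values[w] for w in lam])],
                             columns=lam.astype(int))
        return SpectraMatrix("S1", lam.astype(float), frame)

    def test_ndvi_hand_value(self):
        sp = self._spectra({800: 0.5, 670: 0.1, 734: 0.3, 747: 0.3,
                            715: 0.3, 726: 0.3, 970: 0.3, 900: 0.3,
                            675: 0.3, 650: 0.3, 700: 0.3, 760: 0.3,
                            500: 0.3, 860: 0.3, 1640: 0.3, 2130: 0.3})
        vi = compute_vi(sp)
        assert vi["NDVI"].iloc[0] == pytest.approx((0.5 - 0.1) / 0.6)

    def test_equal_bands_give_zero_ndvi(self):
        sp = self._spectra({w: 0.3 for w in (800, 670, 734, 747, 715, 726,
                                             970, 900, 675, 650, 700, 760,
                                             500, 860, 1640, 2130)})
        vi = compute_vi(sp)
        assert vi["NDVI"].iloc[0] == pytest.approx(0.0)
        assert vi["NWI"].iloc[0] == pytest.approx(0.0)

    def test_zero_denominator_is_nan_with_warning(self):
        vals = {w: 0.3 for w in (800, 670, 734, 747, 715, 726, 970, 900,
                                 675, 650, 700, 760, 500, 860, 1640, 2130)}
        vals[500] = 0.0                      # RARSc divides by R500
        sp = self._spectra(vals)
        with pytest.warns(UserWarning, match="zero denominator"):
            vi = compute_vi(sp)
        assert np.isnan(vi["RARSc"].iloc[0])

    def test_missing_band_names_index_and_band(self):
        # a fine grid that stops at 700 nm: NDVI's 800-nm band is absent
        sp = self._spectra({w: 0.3 for w in range(650, 701)})
        with pytest.raises(KeyError, match="NDVI.*800"):
            compute_vi(sp)

    def test_binned_source_lookup(self):
        lam = np.arange(700, 760)
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.random((4, 60)), columns=lam)
        binned, bins = bin_wavebands(frame, width=10.0, grid_step=1.0)
        from phenosel.preprocess import VIDefinition, _safe_div
        registry = (VIDefinition(
            "VREI2", (734, 747, 715, 726),
            lambda a, b, c, d: _safe_div(a - b, c + d, "VREI2")),)
        vi = compute_vi(binned, bin_table=bins, registry=registry)
        r = {nm: binned[bins.loc[(bins.start <= nm) & (nm <= bins.end),
                                 "label"].iloc[0]] for nm in (734, 747, 715,
                                                              726)}
        expected = (r[734] - r[747]) / (r[715] + r[726])
        np.testing.assert_allclose(vi["VREI2"], expected)
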