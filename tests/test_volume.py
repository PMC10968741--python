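"""Volume-level operations: SNR maps, ROI averaging, voxel fitting, classification."""

import numpy as np
import pytest

import ivimsim as iv
from conftest import one_linear_step, one_log_step


def _b0_volume(values):
    """One-voxel-per-row volume from a (x, y, z, n_b0) array."""
    values = np.asarray(values, dtype=float)
    scheme = iv.AcquisitionScheme(entries=((0.0, values.shape[-1]),))
    return iv.DWIVolume(data=values, scheme=scheme)


class TestSNRMap:
    def test_hand_computed_single_voxel(self):
        vol = _b0_volume(np.array([1.0, 1.0, 1.0, 1.0, 0.9]).reshape(1, 1, 1, 5))
        summary = iv.snr_map(vol)
        assert summary.map[0, 0, 0] == pytest.approx(0.98 / 0.044721, rel=1e-4)
        assert summary.median == pytest.approx(21.913, abs=1e-2)

    def test_requires_two_b0(self):
        with pytest.raises(ValueError, match="b0"):
            iv.snr_map(_b0_volume(np.ones((2, 2, 2, 1))))

    def test_zero_variance_voxels_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            summary = iv.snr_map(_b0_volume(np.ones((3, 3, 3, 5))))
        assert summary.n_voxels == 0
        assert np.isnan(summary.median)
        assert np.all(np.isnan(summary.map))

    def test_invariant_to_global_scaling(self):
        rng = np.random.default_rng(0)
        data = 1.0 + 0.05 * rng.standard_normal((4, 4, 4, 5))
        a = iv.snr_map(_b0_volume(data))
        b = iv.snr_map(_b0_volume(data * 7.5))
        assert b.map == pytest.approx(a.map, rel=1e-12)

    def test_synthetic_series_recovers_construction_snr(self):
        # the 5-sample (n-1) std underestimates sigma (c4(5) ~ 0.94), so the
        # median map value sits ~9% above the construction SNR; a large voxel
        # count makes the median estimate stable
        vol = iv.make_b0_series(n_volumes=5, true_signal=1.0, snr=20.0, shape=(32, 32, 32), seed=11)
        summary = iv.snr_map(vol)
        assert summary.n_voxels >= 10_000
        assert summary.median == pytest.approx(20.0, rel=0.10)


class TestROIAverageSignal:
    def test_identical_voxels_return_normalized_vector(self, ground_truth, scheme):
        sig = iv.ivim_signal(ground_truth, scheme)
        data = np.tile(sig, (2, 2, 1, 1))
        labels = np.ones((2, 2, 1), dtype=int)
        vol = iv.DWIVolume(data=data, scheme=scheme)
        out = iv.roi_average_signal(vol, labels, 1)
        assert out == pytest.approx(sig / sig.max())
        assert out.max() == pytest.approx(1.0)

    def test_per_voxel_scaling_is_absorbed(self, ground_truth, scheme):
        sig = iv.ivim_signal(ground_truth, scheme)
        data = np.stack([3.7 * sig, sig]).reshape(2, 1, 1, -1)
        vol = iv.DWIVolume(data=data, scheme=scheme)
        out = iv.roi_average_signal(vol, np.ones((2, 1, 1), dtype=int), 1)
        assert out == pytest.approx(sig / sig.max())

    def test_empty_roi_names_id(self, ground_truth, scheme):
        sig = iv.ivim_signal(ground_truth, scheme)
        vol = iv.DWIVolume(data=np.tile(sig, (1, 1, 1, 1)), scheme=scheme)
        with pytest.raises(ValueError, match="99"):
            iv.roi_average_signal(vol, np.ones((1, 1, 1), dtype=int), 99)


class TestFitVolume:
    def test_noiseless_phantom_recovers_compartments(self):
        # compartments with clear D*/D scale separation, so the segmented
        # split at b=250 is valid; the default GM value D* = 0.0036 violates
        # that assumption and carries an intrinsic truncation bias instead
        comps = {
            "csf": iv.IVIMParameters(1.0, 0.05, 0.02, 0.0025),
            "gm": iv.IVIMParameters(1.0, 0.09, 0.015, 0.00065),
            "wm": iv.IVIMParameters(1.0, 0.16, 0.012, 0.00079),
        }
        spec = iv.PhantomSpec(shape=(12, 12, 6), snr=None, seed=0, compartments=comps)
        volume, labels = iv.make_phantom(spec)
        maps = iv.fit_volume(volume, method="grid_search")
        grids = iv.GridSpec.default()
        gm = labels == 2
        truth = spec.compartments["gm"]
        assert np.nanmax(np.abs(maps.maps["f"][gm] - truth.f)) <= one_linear_step(grids.s0_fast)
        assert np.nanmax(np.abs(maps.maps["d"][gm] - truth.d)) <= one_linear_step(grids.d)
        assert np.nanmax(np.abs(np.log(maps.maps["d_star"][gm] / truth.d_star))) <= np.log(
            one_log_step(grids.d_star)
        )

    def test_unmasked_voxels_are_sentinel(self, small_phantom):
        _, volume, labels = small_phantom
        maps = iv.fit_volume(volume, method="grid_search")
        background = labels == 0
        for name in ("s0", "f", "d_star", "d"):
            assert np.all(np.isnan(maps.maps[name][background]))
            assert np.all(np.isfinite(maps.maps[name][~background]))

    def test_noisy_gm_f_spread_matches_single_voxel_statistics(self, small_phantom):
        # the per-voxel f error in a constant-parameter region should match the
        # Monte-Carlo single-voxel run at the same SNR within sampling error
        spec, volume, labels = small_phantom
        maps = iv.fit_volume(volume, method="grid_search")
        gm = labels == 2
        f_vals = maps.maps["f"][gm]
        truth = spec.compartments["gm"].f
        rmse_vol = iv.relative_rmse(f_vals, truth)

        cfg = iv.SimulationConfig(
            ground_truth=spec.compartments["gm"],
            snr_levels=[spec.snr],
            n_realizations=1024,
            averaging_factors=[1],
            methods=["grid_search"],
            seed=99,
        )
        rmse_mc = iv.run_study(cfg).get("grid_search", "f", spec.snr)
        assert rmse_vol == pytest.approx(rmse_mc, rel=0.25)

    def test_curve_method_on_tiny_volume(self, scheme, ground_truth):
        sig = iv.ivim_signal(ground_truth, scheme)
        data = np.tile(sig, (2, 1, 1, 1))
        vol = iv.DWIVolume(data=data, scheme=scheme)
        maps = iv.fit_volume(vol, method="one_step")
        assert maps.maps["f"][0, 0, 0] == pytest.approx(ground_truth.f, rel=1e-3)
        assert maps.maps["converged"][0, 0, 0] == 1.0


class TestClassification:
    def test_all_zero_f_map(self):
        report = iv.classify_estimates(np.zeros((4, 4)), np.full((4, 4), 0.01))
        assert report.pct_f_outliers == 100.0
        assert report.pct_f_in_range == 0.0

    def test_closed_interval_for_f(self):
        f = np.array([0.01, 0.02, 0.25, 0.26])
        report = iv.classify_estimates(f, np.full(4, 0.01))
        assert report.pct_f_in_range == 50.0
        assert report.n_f_outliers == 1

    def test_half_open_interval_for_dstar(self):
        ds = np.array([0.005, 0.006, 0.049, 0.05])
        report = iv.classify_estimates(np.full(4, 0.1), ds)
        assert report.pct_dstar_in_range == 50.0

    def test_boundary_dstar_count(self):
        ds = np.array([0.003, 0.01, 0.03, 0.03])
        report = iv.classify_estimates(np.full(4, 0.1), ds, dstar_bounds=(0.003, 0.03))
        assert report.n_boundary_dstar == 3

    def test_known_composition_is_exact(self):
        rng = np.random.default_rng(5)
        f = np.concatenate([
            np.full(30, 0.01),   # outliers
            rng.uniform(0.05, 0.2, 50),  # in range
            np.full(20, 0.5),    # above range
        ])
        ds = np.concatenate([
            rng.uniform(0.007, 0.04, 40),  # in range
            np.full(60, 0.10),             # out of range
        ])
        report = iv.classify_estimates(f, ds)
        assert report.n_total == 100
        assert report.pct_f_outliers == 30.0
        assert report.pct_f_in_range == 50.0
        assert report.pct_dstar_in_range == 40.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            iv.classify_estimates(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="mask"):
            iv.classify_estimates(np.zeros((2, 2)), np.zeros((2, 2)), mask=np.ones((3, 3), bool))
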