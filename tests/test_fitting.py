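"""Per-pixel decay fitting, image aggregation, and rendering."""

import numpy as np
import pytest

from phantomflim.decay import (
    AcquisitionSettings,
    DecayCurve,
    DecayModel,
    expected_bin_counts,
    wrapped_component_bin_integrals,
)
from phantomflim.fitting import (
    FixedTauBiexpFitter,
    FlimImage,
    FlimImageFitter,
    MonoExpFitter,
    PixelFitResult,
    fit_image,
    fit_pixel_biexp_fixed,
    fit_pixel_mono,
    read_flim_image,
    render_flim_image,
    summarize_image,
    write_flim_image,
)
from phantomflim.simulate import PhantomSpec, simulate_flim_image


def _poisson_curve(model, settings, seed):
    expected = expected_bin_counts(model, settings)
    rng = np.random.default_rng(seed)
    return DecayCurve(
        bin_times=expected.bin_times,
        counts=rng.poisson(expected.counts).astype(float),
    )


class TestMonoPixelFit:
    def test_noiseless_self_consistency(self, settings_50mhz, mono_392):
        curve = expected_bin_counts(mono_392, settings_50mhz)
        res = fit_pixel_mono(curve, settings_50mhz)
        assert res.converged
        assert res.tau1 == pytest.approx(3.92, abs=1e-4)
        assert res.a1_pct == 100.0
        assert res.mean_flt == res.tau1

    def test_poisson_recovery_within_scatter(self, settings_50mhz, mono_392):
        """At 1e4 counts a single pixel lands within the expected ~0.04 ns."""
        curve = _poisson_curve(mono_392, settings_50mhz, seed=7)
        res = fit_pixel_mono(curve, settings_50mhz)
        assert res.tau1 == pytest.approx(3.92, abs=0.05)

    def test_all_zero_pixel_excluded(self, settings_50mhz):
        curve = DecayCurve(
            bin_times=settings_50mhz.bin_times,
            counts=np.zeros(settings_50mhz.n_bins),
        )
        res = fit_pixel_mono(curve, settings_50mhz)
        assert res.excluded
        assert not res.converged

    def test_estimator_params_roundtrip(self):
        f = MonoExpFitter(min_counts=50)
        assert f.get_params()["min_counts"] == 50
        f.set_params(min_counts=200)
        assert f.min_counts == 200


class TestBiexpPixelFit:
    def test_noiseless_recovers_truth(self, settings_50mhz, biexp_peg):
        curve = expected_bin_counts(biexp_peg, settings_50mhz)
        res = fit_pixel_biexp_fixed(curve, settings_50mhz, tau2_fixed=3.92)
        assert res.tau1 == pytest.approx(1.15, abs=1e-3)
        assert res.a1_pct == pytest.approx(81.16, abs=0.1)
        assert res.tau2 == 3.92
        # amplitude-weighted mean lifetime of the fitted model
        assert res.mean_flt == pytest.approx(1.672, abs=5e-3)

    def test_pure_fast_component_pushes_a1_to_100(self, settings_50mhz):
        fast = DecayModel(amplitudes=(1.0,), lifetimes=(1.0,))
        curve = _poisson_curve(fast, settings_50mhz, seed=3)
        res = fit_pixel_biexp_fixed(curve, settings_50mhz, tau2_fixed=3.92)
        assert res.a1_pct >= 99.0

    def test_tau_collision_flagged(self, settings_50mhz, mono_392):
        curve = expected_bin_counts(mono_392, settings_50mhz)
        res = fit_pixel_biexp_fixed(curve, settings_50mhz, tau2_fixed=3.92)
        # fast component converges onto the fixed lifetime -> warning flag
        assert res.flag_tau_collision

    def test_invalid_tau2_rejected(self, settings_50mhz, mono_392):
        curve = expected_bin_counts(mono_392, settings_50mhz)
        with pytest.raises(ValueError):
            FixedTauBiexpFitter(tau2_fixed=-1.0).fit(curve, settings_50mhz)


class TestChiSquareCalibration:
    def test_reduced_chi2_near_unity_at_high_counts(self, mono_392):
        """Correctly specified fits at 1e5 counts: mean chi2 in [0.85, 1.15]."""
        settings = AcquisitionSettings(rep_rate=50.0, n_bins=256, counts_target=1e5)
        chi2s = []
        for seed in range(100):
            curve = _poisson_curve(mono_392, settings, seed=seed)
            chi2s.append(fit_pixel_mono(curve, settings).chi2)
        assert 0.85 <= np.mean(chi2s) <= 1.15

    def test_misspecified_mono_fit_inflates_chi2(self, settings_50mhz):
        """Mono fits on two-component data show elevated chi2 flags."""
        biexp = DecayModel(amplitudes=(0.6, 0.4), lifetimes=(0.6, 3.92))
        settings = AcquisitionSettings(rep_rate=50.0, n_bins=256, counts_target=1e5)
        chi2_bad = [
            fit_pixel_mono(_poisson_curve(biexp, settings, s), settings).chi2
            for s in range(10)
        ]
        mono = DecayModel(amplitudes=(1.0,), lifetimes=(2.0,))
        chi2_ok = [
            fit_pixel_mono(_poisson_curve(mono, settings, s), settings).chi2
            for s in range(10)
        ]
        assert np.mean(chi2_bad) > 1.5 > np.mean(chi2_ok)


class TestGridSearchOracle:
    def test_biexp_fit_matches_grid_search_within_one_cell(self, settings_50mhz):
        """Continuous fit vs brute-force (tau1, a1) grid on noiseless curves."""
        w2 = wrapped_component_bin_integrals(3.92, settings_50mhz)
        tau_grid = np.arange(0.3, 3.5, 0.05)
        a1_grid = np.arange(0.40, 1.0, 0.01)
        for truth_f1, truth_tau1 in [(0.8116, 1.15), (0.6613, 2.72), (0.9, 0.7)]:
            model = DecayModel(
                amplitudes=(truth_f1, 1 - truth_f1), lifetimes=(truth_tau1, 3.92)
            )
            curve = expected_bin_counts(model, settings_50mhz)
            # oracle: exhaustive scan, amplitude solved in closed form
            best, best_cost = None, np.inf
            for tau1 in tau_grid:
                w1 = wrapped_component_bin_integrals(tau1, settings_50mhz)
                for f1 in a1_grid:
                    shape = f1 * w1 + (1 - f1) * w2
                    scale = shape @ curve.counts / (shape @ shape)
                    cost = np.sum((scale * shape - curve.counts) ** 2)
                    if cost < best_cost:
                        best, best_cost = (tau1, f1), cost
            res = fit_pixel_biexp_fixed(curve, settings_50mhz, tau2_fixed=3.92)
            # the continuous optimum must beat the discrete one ...
            w1 = wrapped_component_bin_integrals(res.tau1, settings_50mhz)
            f1 = res.a1_pct / 100.0
            shape = f1 * w1 + (1 - f1) * w2
            scale = shape @ curve.counts / (shape @ shape)
            assert np.sum((scale * shape - curve.counts) ** 2) <= best_cost + 1e-3
            # ... and, snapped to the grid, sit at most one cell away
            assert abs(round((res.tau1 - best[0]) / 0.05)) <= 1
            assert abs(round((f1 - best[1]) / 0.01)) <= 1


class TestImageFit:
    def test_homogeneous_image_all_converge(self, settings_50mhz, mono_392):
        spec = PhantomSpec(truth_decay=mono_392, grid=(8, 8), seed=11)
        image = simulate_flim_image(spec, settings_50mhz)
        fitter = FlimImageFitter(mode="mono").fit(image)
        assert fitter.summary_.n_pixels_excluded == 0
        assert fitter.summary_.n_pixels_included == 64
        # spread consistent with counting statistics (a few percent)
        assert fitter.summary_.tau1_std < 0.15
        assert fitter.summary_.tau1_mean == pytest.approx(3.92, abs=0.05)

    def test_dead_pixels_are_excluded(self, settings_50mhz, mono_392):
        spec = PhantomSpec(truth_decay=mono_392, grid=(4, 4), seed=2)
        image = simulate_flim_image(spec, settings_50mhz)
        image.counts[0, 0, :] = 0
        image.counts[3, 2, :] = 0
        grid = fit_image(image, mode="mono")
        summary = summarize_image(grid)
        assert summary.n_pixels_excluded == 2
        assert summary.n_pixels_included == 14

    def test_fit_is_deterministic(self, settings_50mhz, biexp_peg):
        spec = PhantomSpec(truth_decay=biexp_peg, grid=(3, 3), seed=8)
        image = simulate_flim_image(spec, settings_50mhz)
        f1 = FlimImageFitter(mode="biexp_fixed", tau2_fixed=3.92).fit(image)
        f2 = FlimImageFitter(mode="biexp_fixed", tau2_fixed=3.92).fit(image)
        assert f1.frame_.equals(f2.frame_)

    def test_empty_mask_rejected(self, settings_50mhz, mono_392):
        spec = PhantomSpec(truth_decay=mono_392, grid=(2, 2), seed=1)
        image = simulate_flim_image(spec, settings_50mhz)
        image.mask = np.zeros((2, 2), dtype=bool)
        with pytest.raises(ValueError):
            fit_image(image, mode="mono")

    def test_biexp_mode_requires_tau2(self, settings_50mhz, mono_392):
        spec = PhantomSpec(truth_decay=mono_392, grid=(2, 2), seed=1)
        image = simulate_flim_image(spec, settings_50mhz)
        with pytest.raises(ValueError):
            fit_image(image, mode="biexp_fixed")

    def test_lower_counts_do_not_improve_recovery(self, biexp_peg):
        """tau1 RMSE at 1e3 counts/pixel is no better than at 1e4."""
        rmses = {}
        for counts in (1e4, 1e3):
            settings = AcquisitionSettings(
                rep_rate=50.0, n_bins=256, counts_target=counts
            )
            errs = []
            for seed in range(25):
                curve = _poisson_curve(biexp_peg, settings, seed=100 + seed)
                res = fit_pixel_biexp_fixed(curve, settings, tau2_fixed=3.92)
                errs.append(res.tau1 - 1.15)
            rmses[counts] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmses[1e3] >= rmses[1e4]


class TestSummaryAndRendering:
    def _uniform_grid(self, tau=2.0, n=3):
        res = PixelFitResult(
            tau1=tau, tau2=tau, a1_pct=100.0, mean_flt=tau, chi2=1.0,
            converged=True, total_counts=1e4,
        )
        return [[res for _ in range(n)] for _ in range(n)]

    def test_constant_grid_summary(self):
        summary = summarize_image(self._uniform_grid(tau=2.0))
        assert summary.tau1_mean == pytest.approx(2.0)
        assert summary.tau1_std == 0.0
        assert summary.hist_counts.sum() == summary.n_pixels_included == 9

    def test_zero_converged_pixels_raises(self, settings_50mhz):
        bad = PixelFitResult(
            tau1=np.nan, tau2=np.nan, a1_pct=np.nan, mean_flt=np.nan,
            chi2=np.nan, converged=False, total_counts=0.0, excluded=True,
        )
        with pytest.raises(ValueError):
            summarize_image([[bad]])

    def test_histogram_counts_conserved(self, settings_50mhz, mono_392):
        spec = PhantomSpec(truth_decay=mono_392, grid=(6, 6), seed=4)
        image = simulate_flim_image(spec, settings_50mhz)
        summary = FlimImageFitter(mode="mono").fit(image).summary_
        assert summary.hist_counts.sum() == summary.n_pixels_included

    def test_render_uniform_grid(self, tmp_path):
        arr = render_flim_image(self._uniform_grid(), tmp_path / "img.png")
        assert (tmp_path / "img.png").stat().st_size > 0
        assert np.nanstd(arr) == 0.0

    def test_render_marks_excluded_as_nan(self, tmp_path):
        grid = self._uniform_grid()
        grid[1][1] = PixelFitResult(
            tau1=np.nan, tau2=np.nan, a1_pct=np.nan, mean_flt=np.nan,
            chi2=np.nan, converged=False, total_counts=0.0, excluded=True,
        )
        arr = render_flim_image(grid, tmp_path / "img2.png")
        assert np.isnan(arr[1, 1])
        assert np.isfinite(arr[0, 0])

    def test_two_region_boundary_statistically_visible(self, settings_50mhz):
        """Interface image: region means differ by > 5x pooled SE."""
        from phantomflim.simulate import simulate_interface_image

        left = PhantomSpec(
            truth_decay=DecayModel((1.0,), (3.74,)), grid=(8, 8), seed=21
        )
        right = PhantomSpec(
            truth_decay=DecayModel((0.8, 0.2), (0.8, 3.74)), grid=(8, 8), seed=22
        )
        image = simulate_interface_image(left, right, settings_50mhz, seed=5)
        fitter = FlimImageFitter(mode="biexp_fixed", tau2_fixed=3.74).fit(image)
        vals = np.array(
            [[r.mean_flt for r in row] for row in fitter.results_]
        )
        a, b = vals[:, :4].ravel(), vals[:, 4:].ravel()
        pooled_se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(a.mean() - b.mean()) > 5 * pooled_se


class TestImageIO:
    def test_tiff_roundtrip(self, tmp_path, settings_50mhz, mono_392):
        spec = PhantomSpec(truth_decay=mono_392, grid=(4, 5), seed=9)
        image = simulate_flim_image(spec, settings_50mhz)
        image.mask = np.ones((4, 5), dtype=bool)
        image.mask[0, 0] = False
        path = tmp_path / "stack.tif"
        write_flim_image(image, path)
        back = read_flim_image(path)
        np.testing.assert_array_equal(back.counts, image.counts)
        assert back.settings == image.settings
        np.testing.assert_array_equal(back.mask, image.mask)

    def test_shape_validation(self, settings_50mhz):
        with pytest.raises(ValueError):
            FlimImage(
                counts=np.zeros((4, 4, 10), dtype=int), settings=settings_50mhz
            )
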