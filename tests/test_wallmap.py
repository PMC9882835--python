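"""Subresolution thickness mapping: segmentation, peak fits, full maps."""

import numpy as np
import pytest
from scipy.special import erf

from hyphoshell import synthetic_data as sd
from hyphoshell import wallmap as wm

from conftest import brute_force_curve_distance

PX = 65.0


class TestSegmentation:
    def test_radius_within_half_pixel(self):
        g = sd.make_phantom(radius_um=1.0, length_um=4.0, h_nm=80.0)
        spec = sd.ImagingSpec(seed=1)
        img = sd.render_image(g, spec, noise=False)
        m = wm.measure_capsule_fitted(img.channels[0], PX)
        assert abs(m["R_um"] - 1.0) < 0.5 * PX / 1000.0

    def test_pure_noise_fails(self):
        noise = np.random.default_rng(0).normal(10.0, 2.0, (60, 80))
        with pytest.raises(wm.SegmentationError):
            wm.segment_contour(noise, PX)

    def test_flat_image_fails(self):
        with pytest.raises(wm.SegmentationError):
            wm.segment_contour(np.full((50, 50), 7.0), PX)

    def test_bent_midline_arclength(self):
        mid = np.array([[0, 0], [2, 0.3], [4, 0.9], [5.5, 1.8]])
        g = sd.make_phantom(radius_um=1.0, midline=mid, h_nm=80.0)
        img = sd.render_image(g, sd.ImagingSpec(seed=5))
        cont = wm.segment_contour(img.channels[0], PX)
        inner, _, _ = g.inner_contour()
        truth = np.linalg.norm(
            np.diff(np.vstack([inner, inner[:1]]), axis=0), axis=1).sum()
        assert abs(cont.perimeter_um - truth) / truth < 0.02


class TestNormalProfiles:
    def test_constant_image_constant_profile(self, flat_map):
        cont = flat_map.contour
        img = np.full((200, 200), 13.0)
        u, v, inb = wm.sample_normal_profile(img, cont, 10, 400.0, 30.0, PX)
        assert np.allclose(v, 13.0)

    def test_peak_positions_on_phantom(self, rendered_flat):
        img = sd.render_image(rendered_flat.truth,
                              sd.ImagingSpec(seed=3, chromatic_shift=(0, 0)),
                              noise=False)
        cont = wm.segment_contour(img.channels[0], PX)
        i = len(cont) // 2
        u, v1, _ = wm.sample_normal_profile(img.channels[0], cont, i,
                                            800.0, 30.0, PX)
        _, v2, _ = wm.sample_normal_profile(img.channels[1], cont, i,
                                            800.0, 30.0, PX)
        # membrane peak near 0, lectin peak near +h (coarse, argmax level)
        assert abs(u[np.argmax(v1)]) < 100.0
        assert 0.0 < u[np.argmax(v2)] < 250.0

    def test_step_precondition(self, flat_map):
        with pytest.raises(ValueError):
            wm.sample_normal_profile(np.zeros((50, 50)), flat_map.contour, 0,
                                     400.0, PX + 1.0, PX)

    def test_out_of_bounds_flagged(self, flat_map):
        tiny = np.zeros((4, 4))
        _, _, inb = wm.sample_normal_profile(tiny, flat_map.contour, 0,
                                             800.0, 30.0, PX)
        assert inb is False


def gauss_step_profile(u, center, sigma=200.0, A=200.0, b_in=100.0,
                       b_out=10.0):
    g = A * np.exp(-((u - center) ** 2) / (2 * sigma ** 2))
    s = 0.5 * (1 - erf((u - center) / (np.sqrt(2) * sigma)))
    return g + b_out + (b_in - b_out) * s


class TestPeakFit:
    u = np.arange(-800.0, 800.0 + 1e-9, 32.5)

    def test_symmetric_gaussian_exact(self):
        y = 150.0 * np.exp(-((self.u - 40.0) ** 2) / (2 * 200.0 ** 2)) + 5.0
        f = wm.fit_peak(self.u, y, 200.0)
        assert f.center == pytest.approx(40.0, abs=1.0)
        assert f.quality > 0.99

    def test_step_background_unbiased_vs_plain_gaussian(self):
        """On an inside/outside step the Gaussian+erf model stays unbiased
        while a plain Gaussian fit is pulled toward the bright side; the
        expected center is cross-checked with a brute-force grid oracle."""
        y = gauss_step_profile(self.u, 40.0)
        f = wm.fit_peak(self.u, y, 200.0, inside_high=True)
        assert abs(f.center - 40.0) < 2.0

        plain = wm.fit_peak(self.u, y, 200.0, model="gaussian")
        assert abs(plain.center - 40.0) > 10.0

        # oracle: scan the center on a fine grid, solving the linear
        # amplitudes exactly at each candidate, with the width fixed at truth
        centers = np.arange(20.0, 60.0, 0.25)
        sses = []
        for c in centers:
            basis = np.column_stack([
                np.exp(-((self.u - c) ** 2) / (2 * 200.0 ** 2)),
                0.5 * (1 - erf((self.u - c) / (np.sqrt(2) * 200.0))),
                np.ones_like(self.u)])
            coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
            sses.append(((basis @ coef - y) ** 2).sum())
        c_oracle = centers[int(np.argmin(sses))]
        assert abs(f.center - c_oracle) < 1.0

    def test_two_peak_profile_flagged(self):
        y = gauss_step_profile(self.u, 0.0) \
            + 120.0 * np.exp(-((self.u - 500.0) ** 2) / (2 * 150.0 ** 2))
        f = wm.fit_peak(self.u, y, 200.0)
        assert abs(f.center) < 150.0  # dominant peak
        assert f.quality < 0.995

    def test_width_gate(self):
        # far-too-narrow structure: width outside [PSF/2, 3 PSF] -> quality 0
        y = 150.0 * np.exp(-((self.u - 0.0) ** 2) / (2, )[0] / 30.0 ** 2) + 5
        f = wm.fit_peak(self.u, y, 200.0)
        assert f.quality == 0.0


class TestComputeThickness:
    def test_plain_distance(self):
        fi = wm.PeakFit(400.0, 200.0, 100.0, 50.0, 2.0, 0.99)
        fo = wm.PeakFit(465.0, 200.0, 100.0, 2.0, 15.0, 0.99)
        h, ok = wm.compute_thickness(fi, fo, (0.0, 0.0), (0.0, 1.0))
        assert ok and h == pytest.approx(65.0)

    def test_shift_projection(self):
        fi = wm.PeakFit(0.0, 200.0, 100.0, 50.0, 2.0, 0.99)
        fo = wm.PeakFit(95.0, 200.0, 100.0, 2.0, 15.0, 0.99)
        h, ok = wm.compute_thickness(fi, fo, (30.0, 0.0), (1.0, 0.0))
        assert ok and h == pytest.approx(65.0)

    def test_negative_corrected_distance_flagged(self):
        fi = wm.PeakFit(0.0, 200.0, 100.0, 50.0, 2.0, 0.99)
        fo = wm.PeakFit(20.0, 200.0, 100.0, 2.0, 15.0, 0.99)
        h, ok = wm.compute_thickness(fi, fo, (50.0, 0.0), (1.0, 0.0))
        assert not ok

    def test_bad_fit_invalid(self):
        bad = wm.PeakFit(np.nan, np.nan, 0.0, 0.0, 0.0, 0.0)
        good = wm.PeakFit(65.0, 200.0, 100.0, 2.0, 15.0, 0.99)
        _, ok = wm.compute_thickness(bad, good, (0, 0), (1, 0))
        assert not ok


class TestThicknessMap:
    def test_flat_phantom_precision(self, flat_map):
        ok = flat_map.quality_flag
        assert ok.mean() > 0.9
        assert np.nanstd(flat_map.h[ok]) <= 20.0
        assert abs(np.nanmean(flat_map.h[ok]) - 80.0) < 5.0

    def test_tip_thinned_ratio(self):
        """Tip 13% thinner than the sides: the windowed tip/side ratio of
        the recovered map matches the same ratio on the ground truth."""
        g = sd.make_phantom(radius_um=1.2, length_um=5.0,
                            thickness_profile=sd.tip_scaled_profile(90.0, 0.87))
        img = sd.render_image(g, sd.ImagingSpec(seed=11))
        tmap = wm.map_thickness(img)
        ratio = tmap.tip_mean() / tmap.side_mean(inner_um=3.0, outer_um=6.0)
        sp = tmap.s_prime
        truth = g.thickness_at(sp)
        truth_ratio = (truth[sp <= 1.0].mean()
                       / truth[(sp >= 3.0) & (sp <= 6.0)].mean())
        assert ratio == pytest.approx(truth_ratio, abs=0.03)
        assert ratio < 0.95  # thinning is actually detected

    def test_spore_like_phantom(self):
        g = sd.make_phantom(radius_um=2.0, length_um=0.6, h_nm=137.0)
        img = sd.render_image(g, sd.ImagingSpec(seed=21))
        tmap = wm.map_thickness(img)
        assert np.nanmean(tmap.h[tmap.quality_flag]) == pytest.approx(137.0,
                                                                      abs=20.0)

    def test_intensity_rescaling_invariance(self, rendered_flat):
        ch = np.array(rendered_flat.channels)
        scaled = np.stack([3.0 * ch[0], 0.5 * ch[1]])
        t1 = wm.map_thickness(rendered_flat)
        t2 = wm.map_thickness(
            scaled, pixel_size_nm=PX,
            chromatic_shift_nm=rendered_flat.spec.chromatic_shift,
            psf_sigma_nm=rendered_flat.spec.psf_sigma,
            tip_hint_nm=(np.asarray(rendered_flat.truth.tip_position)
                         - np.asarray(rendered_flat.origin_um)) * 1000.0)
        a, b = t1.h[t1.quality_flag], t2.h[t2.quality_flag]
        assert abs(np.nanmean(a) - np.nanmean(b)) < 1.0

    @pytest.mark.parametrize("shift", [(0.0, 0.0), (50.0, 0.0), (-30.0, 40.0)])
    def test_chromatic_shift_invariance(self, flat_phantom, shift):
        """Once the applied shift is supplied for correction the map is
        unchanged (noise-free)."""
        img = sd.render_image(flat_phantom,
                              sd.ImagingSpec(chromatic_shift=shift),
                              noise=False)
        tmap = wm.map_thickness(img)
        assert abs(np.nanmean(tmap.h_raw[tmap.quality_flag]) - 80.0) < 2.0

    @pytest.mark.parametrize("h_true", [50.0, 150.0, 250.0])
    def test_noise_free_bias(self, h_true):
        g = sd.make_phantom(radius_um=1.2, length_um=4.0, h_nm=h_true)
        img = sd.render_image(g, sd.ImagingSpec(seed=1), noise=False)
        tmap = wm.map_thickness(img)
        assert abs(np.nanmean(tmap.h_raw[tmap.quality_flag]) - h_true) < 3.0

    def test_error_grows_with_noise(self):
        g = sd.make_phantom(radius_um=1.2, length_um=4.0, h_nm=100.0)
        stds = []
        for scale in (800.0, 200.0, 50.0):
            img = sd.render_image(g, sd.ImagingSpec(seed=5,
                                                    photon_scale=scale))
            tmap = wm.map_thickness(img)
            stds.append(np.nanstd(tmap.h_raw[tmap.quality_flag]))
        assert stds[0] < stds[1] < stds[2]

    def test_oracle_equivalence_on_truth_curves(self, flat_phantom):
        """Rendering-free route: the geometric normal offset between the
        truth curves equals the brute-force nearest-distance oracle < 1 nm."""
        inner, sp, normals = flat_phantom.inner_contour()
        outer, _ = flat_phantom.outer_contour()
        offsets = np.linalg.norm(outer - inner, axis=1) * 1000.0
        oracle = brute_force_curve_distance(inner, outer, refine=8) * 1000.0
        assert np.max(np.abs(offsets - oracle)) < 1.0


class TestMarkerAnalyses:
    x = np.linspace(-3.0, 3.0, 300)

    def test_fwmh_exact(self):
        y = 5.0 * np.exp(-self.x ** 2 / (2 * 0.2 ** 2))
        w = wm.fwmh(self.x, y)
        assert w == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 0.2, rel=0.01)

    def test_fwmh_baseline_invariant(self):
        y = 5.0 * np.exp(-self.x ** 2 / (2 * 0.2 ** 2))
        assert wm.fwmh(self.x, y + 10.0) == pytest.approx(wm.fwmh(self.x, y),
                                                          rel=0.01)

    def test_fwmh_noisy_monte_carlo(self):
        """SNR-10 profiles over 100 seeds: the mean FWMH stays within 5% of
        2.355 sigma."""
        rng = np.random.default_rng(17)
        vals = []
        for _ in range(100):
            y = 5.0 * np.exp(-self.x ** 2 / (2 * 0.2 ** 2)) \
                + rng.normal(0, 0.5, self.x.size)
            vals.append(wm.fwmh(self.x, y))
        assert np.mean(vals) == pytest.approx(2.355 * 0.2, rel=0.05)

    def test_fwmh_no_peak(self):
        with pytest.raises((ValueError, RuntimeError)):
            wm.fwmh(self.x, np.full_like(self.x, 3.0))

    def test_tip_intensity(self, rendered_flat):
        cont = wm.segment_contour(rendered_flat.channels[0], PX)
        tip = cont.points[cont.tip_index] / 1000.0
        H, W = rendered_flat.channels[0].shape
        yy, xx = np.mgrid[0:H, 0:W] * (PX / 1000.0)
        # absolute spot peak 500 counts over a 50-count background -> 450
        img = 50.0 + 450.0 * np.exp(-((xx - tip[0]) ** 2 + (yy - tip[1]) ** 2)
                                    / (2 * 0.3 ** 2))
        val = wm.tip_intensity(img, cont, pixel_nm=PX)
        assert val == pytest.approx(450.0, abs=10.0)
        # linearity across frames
        val_half = wm.tip_intensity(50.0 + (img - 50.0) / 2, cont, pixel_nm=PX)
        assert val_half / val == pytest.approx(0.5, abs=0.02)

    def test_tip_intensity_uniform(self, rendered_flat):
        cont = wm.segment_contour(rendered_flat.channels[0], PX)
        assert abs(wm.tip_intensity(np.full((100, 140), 20.0), cont,
                                    pixel_nm=PX)) < 1e-9
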