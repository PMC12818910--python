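import numpy as np
import pytest

from tiptrace import (
    AxialProfile,
    Centerline,
    binarize_otsu,
    build_kymograph,
    extract_contour,
    fit_truncated_gaussian,
    make_band_profile,
    profile_along_centerline,
    track_band,
)
from tiptrace.signalprofile import NoBandError


def vertical_centerline(x=50.0, y_top=20.0, y_bot=100.0, pixel_size=1.0, n=81):
    pts = np.column_stack([np.full(n, x), np.linspace(y_bot, y_top, n)])
    c = Centerline(points=pts, pixel_size=pixel_size)
    c.oriented = True
    return c


class TestProfileAlongCenterline:
    def test_uniform_cell_constant_profile(self):
        img = np.full((120, 100), 80.0)
        cl = vertical_centerline()
        p = profile_along_centerline(img, cl, halfwidth=5.0, step=1.0)
        np.testing.assert_allclose(p.intensity, 80.0, rtol=0.01)

    def test_band_argmax_position(self, capsule_factory):
        spec, seq, gt = capsule_factory(n_frames=3, band_center_rel=0.6, seed=4,
                                        growth_rate=0.5, width=6.0,
                                        initial_length=22.0)
        from tiptrace import contour_to_centerline
        t = 0
        c = extract_contour(binarize_otsu(seq.frames[t]))
        cl = contour_to_centerline(c, pixel_size=spec.pixel_size,
                                   anchor=tuple(gt.bottoms[t]))
        step = spec.pixel_size
        p = profile_along_centerline(seq.signal[t], cl, halfwidth=1.2, step=step,
                                     contour=c)
        s_star = gt.band_center_um[t]
        assert abs(p.s[np.argmax(p.intensity)] - s_star) <= 2 * step

    def test_halfwidth_clipped_at_contour(self, capsule_factory):
        """Oversized halfwidth == contour-clipped sampling (exclusion rule)."""
        spec, seq, gt = capsule_factory(n_frames=2, growth_rate=0.0, seed=4,
                                        width=6.0, initial_length=22.0)
        from tiptrace import contour_to_centerline
        c = extract_contour(binarize_otsu(seq.frames[0]))
        cl = contour_to_centerline(c, pixel_size=spec.pixel_size,
                                   anchor=tuple(gt.bottoms[0]))
        big = profile_along_centerline(seq.frames[0], cl, halfwidth=3 * spec.width,
                                       step=spec.pixel_size, contour=c)
        # exclude the cap zones, where normals exit through the soft cap edge
        n_cap = int(np.ceil(spec.width / spec.pixel_size))
        interior = slice(n_cap, -n_cap)
        # independent oracle: interior of the capsule has uniform foreground value
        np.testing.assert_allclose(big.intensity[interior], 200.0, rtol=0.05)

    def test_too_short_centerline_errors(self):
        cl = vertical_centerline(y_top=99.0, y_bot=100.0, n=3)
        with pytest.raises(ValueError, match="short"):
            profile_along_centerline(np.zeros((120, 100)), cl, halfwidth=2.0,
                                     step=5.0)


def gaussian_profile_obj(L=60.0, step=0.5, mu=30.0, sigma=4.0, A=100.0, B=10.0,
                         noise_sd=0.0, seed=0):
    n = int(L / step) + 1
    prof = make_band_profile(n, center=mu / step, sigma=sigma / step, amplitude=A,
                             baseline=B, noise_sd=noise_sd, seed=seed)
    return AxialProfile(s=np.arange(n) * step, intensity=prof)


class TestFitTruncatedGaussian:
    def test_noise_free_recovery_within_1_percent(self):
        p = gaussian_profile_obj()
        fit = fit_truncated_gaussian(p)
        assert fit.amplitude == pytest.approx(100.0, rel=0.01)
        assert fit.mu == pytest.approx(30.0, rel=0.01)
        assert fit.sigma == pytest.approx(4.0, rel=0.01)
        assert fit.baseline == pytest.approx(10.0, rel=0.01)

    def test_band_ends_are_mu_plus_minus_sigma(self):
        fit = fit_truncated_gaussian(gaussian_profile_obj())
        assert fit.lower == pytest.approx(fit.mu - fit.sigma)
        assert fit.upper == pytest.approx(fit.mu + fit.sigma)
        assert (fit.upper - fit.lower) == pytest.approx(2 * fit.sigma)

    def test_end_multiplier(self):
        fit = fit_truncated_gaussian(gaussian_profile_obj(), end_multiplier=2.0)
        assert (fit.upper - fit.lower) == pytest.approx(4 * fit.sigma)

    def test_flat_profile_errors(self):
        p = AxialProfile(s=np.arange(40.0), intensity=np.full(40, 7.0))
        with pytest.raises(NoBandError, match="no band"):
            fit_truncated_gaussian(p)

    def test_tiny_window_errors(self):
        p = gaussian_profile_obj()
        with pytest.raises(NoBandError):
            fit_truncated_gaussian(p, window=(29.0, 30.5))

    def test_noisy_monte_carlo_recovery(self):
        """Median |mu_hat - mu| < 0.5 um, sigma within 15%, mu bias < 0.1 um."""
        mus, sigmas = [], []
        for seed in range(20):
            p = gaussian_profile_obj(noise_sd=5.0, seed=seed)
            fit = fit_truncated_gaussian(p)
            mus.append(fit.mu)
            sigmas.append(fit.sigma)
        mus, sigmas = np.array(mus), np.array(sigmas)
        assert np.median(np.abs(mus - 30.0)) < 0.5
        assert np.median(np.abs(sigmas - 4.0) / 4.0) < 0.15
        assert abs(np.mean(mus) - 30.0) < 0.1


class TestBuildKymograph:
    def _profiles(self, n=4, L=50.0, step=1.0, mu=20.0):
        out = []
        for i in range(n):
            s = np.arange(0.0, L + step / 2, step)
            I = 10 + 90 * np.exp(-((s - mu) ** 2) / 8.0)
            out.append(AxialProfile(s=s, intensity=I, frame_index=i))
        return out

    def test_static_signal_identical_columns(self):
        kymo = build_kymograph(self._profiles(), dt=1.0)
        for j in range(1, kymo.n_frames):
            np.testing.assert_allclose(kymo.matrix[:, j], kymo.matrix[:, 0])

    def test_bins_beyond_L_are_nan(self):
        profs = self._profiles(n=2, L=50.0) + self._profiles(n=1, L=60.0)
        for i, p in enumerate(profs):
            p.frame_index = i
        kymo = build_kymograph(profs, dt=1.0)
        col0 = kymo.matrix[:, 0]
        assert np.isnan(col0[kymo.s_axis > 50.0]).all()
        assert not np.isnan(kymo.matrix[:, 2]).any()

    def test_tip_anchor_reverses(self):
        p = self._profiles(n=1, L=50.0, mu=10.0)
        kb = build_kymograph(p, dt=1.0, anchor="bottom")
        kt = build_kymograph(p, dt=1.0, anchor="tip")
        ib = kb.s_axis[np.nanargmax(kb.matrix[:, 0])]
        it = kt.s_axis[np.nanargmax(kt.matrix[:, 0])]
        assert ib == pytest.approx(10.0, abs=1.0)
        assert it == pytest.approx(40.0, abs=1.0)  # 50 - 10 from the tip

    def test_consistency_with_profiles(self):
        """Kymograph column equals the frame's profile on the common grid."""
        profs = self._profiles(n=3)
        kymo = build_kymograph(profs, dt=1.0)
        for j, p in enumerate(profs):
            expected = np.interp(kymo.s_axis, p.s, p.intensity)
            valid = kymo.s_axis <= p.L
            np.testing.assert_allclose(kymo.matrix[valid, j], expected[valid])


class TestTrackBand:
    def test_moving_band_rate(self):
        profs = []
        for i in range(6):
            profs.append(gaussian_profile_obj(mu=20.0 + 1.5 * i, seed=i))
        table = track_band(profs, dt=1.0)
        slope = np.polyfit(table["time"], table["mu"], 1)[0]
        assert slope == pytest.approx(1.5, rel=0.10)

    def test_corrupted_frame_marked_missing(self):
        profs = [gaussian_profile_obj(seed=i) for i in range(4)]
        profs[2] = AxialProfile(s=profs[2].s, intensity=np.zeros_like(profs[2].s))
        table = track_band(profs, dt=1.0)
        assert np.isnan(table.loc[2, "mu"])
        assert not np.isnan(table.loc[1, "mu"]) and not np.isnan(table.loc[3, "mu"])

    def test_all_frames_fail_errors(self):
        profs = [AxialProfile(s=np.arange(40.0), intensity=np.full(40, 3.0))
                 for _ in range(3)]
        with pytest.raises(NoBandError):
            track_band(profs, dt=1.0)

    def test_band_fixed_from_tip_in_growing_cell(self, capsule_factory):
        """L(t) - mu(t) stays constant when the band rides at fixed tip offset."""
        spec, seq, gt = capsule_factory(n_frames=5, growth_rate=1.0,
                                        band_offset_from_tip=6.0, seed=8,
                                        width=6.0, initial_length=22.0,
                                        frame_shape=(160, 160))
        from tiptrace import contour_to_centerline
        step = spec.pixel_size
        profs = []
        prev = None
        for t in range(5):
            c = extract_contour(binarize_otsu(seq.frames[t]))
            cl = contour_to_centerline(c, pixel_size=spec.pixel_size, prev=prev,
                                       anchor=tuple(gt.bottoms[t]) if prev is None else None)
            prev = cl
            profs.append(profile_along_centerline(seq.signal[t], cl, halfwidth=1.2,
                                                  step=step, contour=c,
                                                  frame_index=t))
        table = track_band(profs, dt=1.0)
        offset = table["L"] - table["mu"]
        assert np.ptp(offset.to_numpy()) <= 2 * step
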