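import numpy as np
import pytest
from scipy import stats

from laminareeg.csd import (
    baseline_correct,
    clip_at_event,
    csd_to_lfp,
    disk_kernel,
    spline_icsd,
    standard_csd,
)
from laminareeg.extracellular import (
    LaminarRecording,
    laminar_electrode_positions,
    lfp_point_source,
    lowpass,
)


def _recording(lfp, spacing=0.1, dt=1.0, sigma=0.33):
    lfp = np.atleast_2d(np.asarray(lfp, float))
    if lfp.shape[1] == lfp.shape[0] and lfp.ndim == 2 and lfp.shape[1] == 1:
        lfp = lfp.T
    depths = spacing * np.arange(lfp.shape[0])
    return LaminarRecording(depths_mm=depths, lfp_mv=lfp, dt_ms=dt, sigma_s_m=sigma)


class TestStandardCSD:
    def test_linear_profile_gives_zero(self):
        rec = _recording([[1.0], [2.0], [3.0]])
        prof = standard_csd(rec)
        assert prof.csd_ua_mm3.shape == (1, 1)
        assert prof.csd_ua_mm3[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # x = (1, 3, 1) mV, z = 0.1 mm, sigma = 0.33 -> -sigma(1+1-6)/z^2 = 132
        rec = _recording([[1.0], [3.0], [1.0]])
        prof = standard_csd(rec)
        assert prof.csd_ua_mm3[0, 0] == pytest.approx(132.0, rel=1e-12)

    def test_uniform_profile_gives_zero(self):
        rec = _recording([[2.0], [2.0], [2.0]])
        assert standard_csd(rec).csd_ua_mm3[0, 0] == 0.0

    def test_linearity_in_lfp(self, rng):
        a = rng.standard_normal((6, 4))
        b = rng.standard_normal((6, 4))
        pa = standard_csd(_recording(a)).csd_ua_mm3
        pb = standard_csd(_recording(b)).csd_ua_mm3
        pab = standard_csd(_recording(2 * a + 3 * b)).csd_ua_mm3
        np.testing.assert_allclose(pab, 2 * pa + 3 * pb, rtol=1e-10, atol=1e-12)

    def test_replicate_padding_keeps_all_channels(self):
        rec = _recording(np.arange(15.0).reshape(5, 3))
        assert standard_csd(rec, pad="replicate").csd_ua_mm3.shape == (5, 3)
        assert standard_csd(rec).csd_ua_mm3.shape == (3, 3)

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError):
            standard_csd(_recording([[1.0], [2.0]]))

    def test_nonuniform_spacing_rejected(self):
        rec = LaminarRecording(
            depths_mm=np.array([0.0, 0.1, 0.35]),
            lfp_mv=np.zeros((3, 2)),
            dt_ms=1.0,
        )
        with pytest.raises(ValueError):
            standard_csd(rec)


class TestSplineICSD:
    def test_zero_lfp_gives_zero_csd(self):
        rec = _recording(np.zeros((8, 3)))
        prof = spline_icsd(rec)
        np.testing.assert_allclose(prof.csd_ua_mm3, 0.0, atol=1e-15)

    def test_fine_grid_at_least_4x(self):
        rec = _recording(np.zeros((8, 2)))
        prof = spline_icsd(rec, grid_factor=4)
        fine_step = np.diff(-prof.z_mm[::-1]).mean()
        assert fine_step <= 0.1 / 4 + 1e-12

    def test_single_disk_source_recovered_at_its_depth(self):
        # forward-generate LFP from a narrow source at a known depth with the
        # analytic disk kernel, then invert: CSD peak within one grid step
        depths = 0.1 * np.arange(16)
        z0 = 0.75
        src_grid = np.linspace(-0.2, 1.7, 2001)
        profile = np.exp(-0.5 * ((src_grid - z0) / 0.02) ** 2)
        K = disk_kernel(depths, src_grid, 3.0, 0.33)
        lfp = (K * np.gradient(src_grid)) @ profile
        rec = _recording(lfp[:, None])
        prof = spline_icsd(rec, diameter_mm=3.0)
        rec_depths = prof.depths_mm[::-1]
        csd = prof.csd_ua_mm3[::-1, 0]
        peak_depth = rec_depths[np.argmax(csd)]
        assert abs(peak_depth - z0) <= np.diff(rec_depths).mean() + 1e-9

    def test_round_trip_reproduces_lfp(self, small_column_currents, rng):
        pos, depths = laminar_electrode_positions()
        rec = lowpass(
            lfp_point_source(small_column_currents, pos, 0.33,
                             electrode_depths_mm=depths), 100.0
        )
        prof = spline_icsd(rec, diameter_mm=3.0)
        lfp2 = csd_to_lfp(prof, depths, 3.0, 0.33)
        rel = np.linalg.norm(lfp2 - rec.lfp_mv) / np.linalg.norm(rec.lfp_mv)
        assert rel < 0.01

    def test_sign_pattern_agrees_with_standard_csd(self, small_column_currents):
        # spline-iCSD and second-derivative CSD must agree in the laminar
        # sink/source pattern at the shared interior depths
        pos, depths = laminar_electrode_positions()
        rec = lowpass(
            lfp_point_source(small_column_currents, pos, 0.33,
                             electrode_depths_mm=depths), 100.0
        )
        std = standard_csd(rec)
        spl = spline_icsd(rec)
        t_peak = np.argmax(np.abs(std.csd_ua_mm3).max(axis=0))
        spl_interp = np.interp(std.z_mm, spl.z_mm, spl.csd_ua_mm3[:, t_peak])
        rho = stats.spearmanr(std.csd_ua_mm3[:, t_peak], spl_interp).statistic
        assert rho > 0.8

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError):
            spline_icsd(_recording(np.zeros((3, 2))))

    def test_bad_diameter_rejected(self):
        with pytest.raises(ValueError):
            spline_icsd(_recording(np.zeros((8, 2))), diameter_mm=0.0)


class TestPreprocessing:
    def _profile(self, csd, dt=1.0):
        csd = np.asarray(csd, float)
        from laminareeg.csd import CSDProfile

        return CSDProfile(
            z_mm=np.arange(csd.shape[0], dtype=float) * 0.1,
            csd_ua_mm3=csd,
            dt_ms=dt,
            method="standard",
        )

    def test_baseline_constant_in_time_zeroed(self):
        prof = self._profile(np.tile([[2.0], [3.0]], (1, 10)))
        out = baseline_correct(prof, (0.0, 9.0))
        np.testing.assert_allclose(out.csd_ua_mm3, 0.0, atol=1e-15)

    def test_baseline_offset_removed(self, rng):
        sig = rng.standard_normal((3, 50))
        sig -= sig[:, :20].mean(axis=1, keepdims=True)
        out = baseline_correct(self._profile(sig + 5.0), (0.0, 19.0))
        np.testing.assert_allclose(out.csd_ua_mm3, sig, atol=1e-12)

    def test_baseline_matches_brute_force_on_ramp(self):
        t = np.arange(30.0)
        csd = np.vstack([t, 2 * t])
        out = baseline_correct(self._profile(csd), (5.0, 14.0))
        brute = csd - csd[:, 5:15].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out.csd_ua_mm3, brute, atol=1e-12)

    def test_baseline_empty_window_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(self._profile(np.zeros((2, 5))), (100.0, 200.0))

    def test_clip_arithmetic(self):
        prof = self._profile(np.zeros((2, 100)))  # dt 1 ms -> 100 ms trace
        out = clip_at_event(prof, 60.0, lead_ms=10.0)
        assert out.csd_ua_mm3.shape[1] == 50  # 50 ms retained

    def test_clip_at_end_with_zero_lead_unchanged(self):
        prof = self._profile(np.zeros((2, 100)))  # spans [0, 100) ms
        out = clip_at_event(prof, 100.0, lead_ms=0.0)
        assert out.csd_ua_mm3.shape[1] == 100

    def test_clip_idempotent(self):
        prof = self._profile(np.random.default_rng(0).normal(size=(2, 100)))
        once = clip_at_event(prof, 60.0)
        twice = clip_at_event(once, 60.0)
        np.testing.assert_array_equal(once.csd_ua_mm3, twice.csd_ua_mm3)

    def test_clip_event_before_start_rejected(self):
        with pytest.raises(ValueError):
            clip_at_event(self._profile(np.zeros((2, 10))), -5.0)
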