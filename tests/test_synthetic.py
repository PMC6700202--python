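"""Phantom generators: geometry, flux, noise models and reproducibility."""

import math

import numpy as np
import pytest

from mitoloc import synthetic
from mitoloc.core import SizingError


def _noise_off(**kw):
    return synthetic.SIMPhantomConfig(
        shot_noise=False, read_noise_sd=0.0, background=0.0, **kw)


class TestSimPair:
    def test_identical_geometry_gives_identical_channels(self):
        cfg = _noise_off(shell_sep_nm=0.0, label_mode_a="omm_shell",
                         label_mode_b="omm_shell")
        ch_a, ch_b, _ = synthetic.generate_sim_pair(cfg, 0)
        np.testing.assert_allclose(ch_a.pixels, ch_b.pixels)

    def test_blur_conserves_flux(self):
        for mode in ("omm_shell", "ibm_shell", "uniform_imm"):
            cfg = _noise_off(label_mode_a=mode)
            ch_a, _, gt = synthetic.generate_sim_pair(cfg, 0)
            assert ch_a.pixels.sum() == pytest.approx(gt.total_flux_a,
                                                      rel=1e-3)

    def test_cross_profile_two_maxima_symmetric(self):
        # brute-force scan of a rendered column perpendicular to the axis
        cfg = _noise_off(label_mode_a="omm_shell")
        ch_a, _, gt = synthetic.generate_sim_pair(cfg, 0)
        (x0, y0), (x1, y1) = gt.tube_axis_px
        col = int(round((x0 + x1) / 2))
        v = ch_a.pixels[:, col]
        interior = np.arange(1, len(v) - 1)
        is_max = (v[interior] > v[interior - 1]) & (v[interior] >= v[interior + 1])
        peaks = interior[is_max]
        peaks = peaks[v[peaks] > 0.05 * v.max()]
        assert len(peaks) == 2
        axis_row = (y0 + y1) / 2
        assert abs((peaks[0] + peaks[1]) / 2 - axis_row) <= 1.0

    def test_peak_separation_converges_to_diameter_at_small_psf(self):
        cfg = _noise_off(psf_fwhm_nm=10.0)
        ch_a, _, gt = synthetic.generate_sim_pair(cfg, 0)
        col = int(round((gt.tube_axis_px[0][0] + gt.tube_axis_px[1][0]) / 2))
        v = ch_a.pixels[:, col]
        mid = len(v) // 2
        top = np.argmax(v[:mid])
        bottom = mid + np.argmax(v[mid:])
        sep_nm = (bottom - top) * cfg.nm_per_px
        assert abs(sep_nm - 2 * cfg.r_outer_nm) <= cfg.nm_per_px

    def test_ground_truth_reflects_config(self):
        cfg = synthetic.SIMPhantomConfig()
        _, _, gt = synthetic.generate_sim_pair(cfg, 0)
        assert gt.true_shell_sep_nm == cfg.shell_sep_nm
        assert gt.true_diameter_a_nm == 2 * cfg.r_outer_nm
        assert gt.true_diameter_b_nm == 2 * (cfg.r_outer_nm - cfg.shell_sep_nm)

    def test_oversized_tube_rejected(self):
        cfg = synthetic.SIMPhantomConfig(tube_length_nm=1e6)
        with pytest.raises(SizingError):
            synthetic.generate_sim_pair(cfg, 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            synthetic.SIMPhantomConfig(r_outer_nm=10.0, shell_sep_nm=20.0)


class TestTemPhantom:
    def test_constant_width_ground_truth(self):
        cfg = synthetic.TEMPhantomConfig(w_junction_nm=20.0,
                                         w_interior_nm=20.0, noise_sd=0.0)
        _, _, gt = synthetic.generate_tem_cristae(cfg, 0)
        np.testing.assert_allclose(gt.profile.w_nm, 20.0)

    def test_control_preset_matches_reported_junction_width(self):
        cfg = synthetic.TEMPhantomConfig.from_preset("control")
        _, _, gt = synthetic.generate_tem_cristae(cfg, 0)
        assert gt.profile.w_nm[0] == pytest.approx(17.1)

    def test_preset_ordering(self):
        w = synthetic.TEM_PRESETS
        assert w["control"] < w["opa1_kd"] < w["micu1_kd"]

    def test_membrane_minima_on_rendered_lines(self):
        # exhaustive search: along orthogonal rows, the intensity minima lie
        # within 1 px of the rendered membrane centerlines
        cfg = synthetic.TEMPhantomConfig(noise_sd=0.0)
        img, path, gt = synthetic.generate_tem_cristae(
            cfg, 0, orientation_deg=0.0)
        x0, y0 = path.vertices_px[0]
        for d in (10.0, 50.0, 100.0):
            col = int(round(x0 + d / cfg.nm_per_px))
            v = img.pixels[:, col]
            w_half_px = cfg.width_at(d) / 2.0 / cfg.nm_per_px
            expected = (y0 - w_half_px, y0 + w_half_px)
            mid = int(round(y0))
            found = (np.argmin(v[:mid]), mid + np.argmin(v[mid:]))
            for e, f in zip(expected, found):
                assert abs(e - f) <= 1.0

    def test_unresolvable_flag(self):
        cfg = synthetic.TEMPhantomConfig(w_junction_nm=3.0, w_interior_nm=3.0,
                                         nm_per_px=2.0)
        _, _, gt = synthetic.generate_tem_cristae(cfg, 0)
        assert gt.unresolvable

    def test_membranes_must_be_dark(self):
        with pytest.raises(ValueError):
            synthetic.TEMPhantomConfig(membrane_contrast=0.5)


class TestBeadField:
    def test_no_distortion_gives_identical_coordinates(self):
        cfg = synthetic.BeadFieldConfig(n_beads=10)
        _, _, gt = synthetic.generate_bead_field(cfg, 0)
        np.testing.assert_allclose(gt.coords_a_px, gt.coords_b_px)

    def test_rigid_translation(self):
        cfg = synthetic.BeadFieldConfig(n_beads=10,
                                        inter_channel_shift_px=(2.0, 0.0))
        _, _, gt = synthetic.generate_bead_field(cfg, 0)
        np.testing.assert_allclose(gt.coords_b_px - gt.coords_a_px,
                                   [[2.0, 0.0]] * 10, atol=1e-12)

    def test_magnification_displacement_closed_form(self):
        scale = 1.001
        cfg = synthetic.BeadFieldConfig(n_beads=12, inter_channel_scale=scale)
        _, _, gt = synthetic.generate_bead_field(cfg, 0)
        c0 = (cfg.field_px - 1) / 2.0
        for a, b in zip(gt.coords_a_px, gt.coords_b_px):
            r = np.hypot(a[0] - c0, a[1] - c0)
            assert np.hypot(*(b - a)) == pytest.approx(0.001 * r, abs=1e-9)

    def test_overlap_rejected(self):
        cfg = synthetic.BeadFieldConfig(n_beads=500, field_px=48)
        with pytest.raises(Exception):
            synthetic.generate_bead_field(cfg, 0)


class TestTracePhantom:
    def test_flat_trace_without_response_or_bleach(self):
        cfg = synthetic.TracePhantomConfig(response_amplitude=0.0,
                                           bleach_tau_s=math.inf,
                                           noise_sd=0.0)
        trace, _ = synthetic.generate_trace(cfg, 0)
        np.testing.assert_allclose(trace.f, cfg.baseline)

    def test_pure_exponential_decay(self):
        cfg = synthetic.TracePhantomConfig(response_amplitude=0.0,
                                           bleach_tau_s=80.0, noise_sd=0.0)
        trace, _ = synthetic.generate_trace(cfg, 0)
        np.testing.assert_allclose(
            trace.f, cfg.baseline * np.exp(-trace.t / 80.0))

    def test_logistic_ground_truth_closed_form(self):
        cfg = synthetic.TracePhantomConfig(baseline=200.0,
                                           response_amplitude=50.0,
                                           response_rate=0.4)
        _, gt = synthetic.generate_trace(cfg, 0)
        assert gt.max_slope_pct_per_s == pytest.approx(
            100.0 * 0.4 * 50.0 / (4.0 * 200.0))
        assert gt.t_at_max_slope_s == cfg.response_onset_s


@pytest.mark.parametrize("gen,cfg", [
    (synthetic.generate_sim_pair, synthetic.SIMPhantomConfig()),
    (synthetic.generate_tem_cristae, synthetic.TEMPhantomConfig()),
    (synthetic.generate_bead_field, synthetic.BeadFieldConfig(n_beads=8)),
    (synthetic.generate_trace, synthetic.TracePhantomConfig()),
])
def test_generators_bit_identical_at_fixed_seed(gen, cfg):
    out1 = gen(cfg, 99)
    out2 = gen(cfg, 99)

    def arrays(obj):
        if hasattr(obj, "pixels"):
            return [obj.pixels]
        if hasattr(obj, "frames"):
            return [obj.frames]
        if hasattr(obj, "f"):
            return [obj.t, obj.f]
        return []

    for a, b in zip(out1, out2):
        for x, y in zip(arrays(a), arrays(b)):
            assert np.array_equal(x, y)
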