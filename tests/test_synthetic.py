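"""Ground-truth generators: determinism, Poisson calibration, geometry."""

import numpy as np
import pytest

from synaptiq import (
    ChannelSim,
    SimEphysConfig,
    SimFieldConfig,
    SimImageConfig,
    make_template,
    simulate_field,
    simulate_mpsc_trace,
    simulate_puncta_stack,
    simulate_section_series,
)


def _cfg(**kw):
    defaults = dict(
        field_size_um=20.0,
        pixel_size_um=0.2,
        n_sections=10,
        z_step_um=0.2,
        channels={"pre": ChannelSim(2.5e8), "post": ChannelSim(2.5e8)},
        colocalization_fraction=0.5,
        gaussian_noise_sd=0.0,
        poisson_noise=False,
        seed=0,
    )
    defaults.update(kw)
    return SimImageConfig(**defaults)


class TestPunctaStack:
    def test_zero_density_gives_pure_background(self):
        cfg = _cfg(channels={"pre": ChannelSim(0.0), "post": ChannelSim(0.0)})
        series, truth = simulate_puncta_stack(cfg)
        assert truth.n_pairs == 0
        for name in ("pre", "post"):
            assert len(truth.centers_um[name]) == 0
            assert np.all(series.channels[name] == cfg.background_level)

    def test_full_colocalization_zero_offset_centers_coincide(self):
        cfg = _cfg(colocalization_fraction=1.0, pair_offset_sd_um=0.0, seed=3)
        _, truth = simulate_puncta_stack(cfg)
        pre = truth.centers_um["pre"]
        post = truth.centers_um["post"]
        assert truth.n_pairs == len(pre) > 0
        for i, j in truth.pairs:
            np.testing.assert_array_equal(pre[i], post[j])

    def test_poisson_count_calibration_over_seeds(self):
        # 2.5e8 / mm^3 in a 20 x 20 x 2 um field -> expected 200 puncta
        counts = []
        for seed in range(100):
            cfg = _cfg(seed=seed)
            _, truth = simulate_puncta_stack(cfg)
            n = len(truth.centers_um["pre"])
            assert abs(n - 200) <= 4 * np.sqrt(200)  # each draw within 4 SD
            counts.append(n)
        # across-seed mean within 4 standard errors
        assert abs(np.mean(counts) - 200) <= 4 * np.sqrt(200) / np.sqrt(100)

    def test_pair_offsets_have_configured_sd(self):
        cfg = _cfg(
            field_size_um=40.0,
            channels={"pre": ChannelSim(4.0e8), "post": ChannelSim(4.0e8)},
            colocalization_fraction=1.0,
            pair_offset_sd_um=0.15,
            seed=2,
        )
        _, truth = simulate_puncta_stack(cfg)
        pre = truth.centers_um["pre"]
        post = truth.centers_um["post"]
        offsets = np.concatenate([post[j] - pre[i] for i, j in truth.pairs]).ravel()
        assert len(offsets) >= 3000
        assert abs(offsets.std() - 0.15) <= 0.15 * 0.15

    def test_truth_inside_field(self):
        cfg = _cfg(seed=9, pair_offset_sd_um=0.5)
        series, truth = simulate_puncta_stack(cfg)
        hi = np.array(truth.field_extent_um)
        for arr in truth.centers_um.values():
            assert np.all(arr >= 0) and np.all(arr <= hi)

    def test_determinism_bitwise(self):
        a, ta = simulate_puncta_stack(_cfg(seed=4, poisson_noise=True, gaussian_noise_sd=2.0))
        b, tb = simulate_puncta_stack(_cfg(seed=4, poisson_noise=True, gaussian_noise_sd=2.0))
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])
        np.testing.assert_array_equal(ta.centers_um["pre"], tb.centers_um["pre"])

    def test_field_too_small_raises(self):
        with pytest.raises(ValueError, match="field too small"):
            simulate_puncta_stack(_cfg(channels={"pre": ChannelSim(1e13), "post": ChannelSim(1e8)}))


class TestSectionSeries:
    def _ribbon_cfg(self, **kw):
        defaults = dict(
            pixel_size_um=0.0587,
            n_sections=30,
            channels={"pre": ChannelSim(3e7, punctum_radius_um=0.1), "post": ChannelSim(0.0)},
            colocalization_fraction=0.0,
            flicker_density_per_mm3=0.0,
            field_size_um=10.0,
        )
        defaults.update(kw)
        return _cfg(**defaults)

    def test_punctum_rendered_on_consecutive_sections(self):
        # a 0.2 um z-extent punctum on 0.07 um sections must appear on >= 2
        cfg = self._ribbon_cfg(seed=1)
        series, truth = simulate_section_series(cfg)
        img = series.channels["pre"]
        px, dz = series.pixel_size_um, series.section_spacing_um
        checked = 0
        for x, y, z in truth.centers_um["pre"]:
            if not (0.15 < z < series.depth_um - 0.15):
                continue
            col = img[:, int(y / px), int(x / px)]
            on = np.flatnonzero(col > cfg.background_level + 1.0)
            assert len(on) >= 2 and np.all(np.diff(on) == 1)
            checked += 1
        assert checked > 0

    def test_flicker_on_exactly_one_section(self):
        cfg = _cfg(
            pixel_size_um=0.0587,
            field_size_um=10.0,
            n_sections=30,
            channels={"pre": ChannelSim(0.0), "post": ChannelSim(0.0)},
            colocalization_fraction=0.0,
            flicker_density_per_mm3=5e7,
            seed=8,
        )
        series, truth = simulate_section_series(cfg)
        img = series.channels["pre"]
        px = series.pixel_size_um
        assert len(truth.flicker_centers_um["pre"]) > 0
        for (x, y), k in zip(truth.flicker_centers_um["pre"], truth.flicker_sections["pre"]):
            col = img[:, int(y / px), int(x / px)]
            on = np.flatnonzero(col > cfg.background_level + 1.0)
            np.testing.assert_array_equal(on, [k])

    def test_single_section_ribbon_rejected(self):
        with pytest.raises(ValueError, match="2 sections"):
            simulate_section_series(self._ribbon_cfg(n_sections=1))

    def test_determinism(self):
        a, _ = simulate_section_series(self._ribbon_cfg(seed=3))
        b, _ = simulate_section_series(self._ribbon_cfg(seed=3))
        np.testing.assert_array_equal(a.channels["pre"], b.channels["pre"])


class TestField:
    def test_cells_count_matches_truth(self):
        from skimage.measure import label

        cfg = SimFieldConfig(n_objects=20, gaussian_noise_sd=0.0, seed=1)
        img, truth = simulate_field(cfg, "cells")
        assert truth.n_objects == 20
        assert len(truth.centers_um["cells"]) == 20
        lab = label(img > cfg.background_level + cfg.peak_intensity / 2)
        assert lab.max() == 20

    def test_vertical_fibers_cross_horizontal_line(self):
        cfg = SimFieldConfig(
            n_objects=3,
            fiber_angles_deg=[90.0, 90.0, 90.0],
            fiber_points_um=[(40.0, 75.0), (75.0, 75.0), (110.0, 75.0)],
            gaussian_noise_sd=0.0,
            seed=0,
        )
        _, truth = simulate_field(cfg, "fibers")
        assert truth.n_crossings == 3

    def test_parallel_fibers_never_cross(self):
        cfg = SimFieldConfig(
            n_objects=3,
            fiber_angles_deg=[0.0],
            fiber_points_um=[(75.0, 30.0), (75.0, 50.0), (75.0, 120.0)],
            gaussian_noise_sd=0.0,
            seed=0,
        )
        _, truth = simulate_field(cfg, "fibers")
        assert truth.n_crossings == 0

    def test_unplaceable_cells_raise(self):
        cfg = SimFieldConfig(n_objects=100, cell_radius_um=20.0, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            simulate_field(cfg, "cells")


class TestMpscTrace:
    def test_zero_rate_gives_flat_noise(self):
        cfg = SimEphysConfig(duration_s=5.0, event_rate_hz=0.0, baseline_noise_sd_pA=0.0, seed=0)
        rec, truth = simulate_mpsc_trace(cfg)
        assert len(truth.event_onsets_s) == 0
        assert np.all(rec.samples == 0.0)

    def test_isolated_event_peak_equals_amplitude(self):
        cfg = SimEphysConfig(
            duration_s=300.0, event_rate_hz=0.02, amplitude_mean_pA=20.0,
            amplitude_sd_pA=0.0, baseline_noise_sd_pA=0.0, seed=3,
        )
        rec, truth = simulate_mpsc_trace(cfg)
        assert len(truth.event_onsets_s) > 0
        assert rec.samples.max() == pytest.approx(20.0, abs=1e-9)

    def test_inward_polarity_flips_sign(self):
        cfg = SimEphysConfig(duration_s=60.0, event_rate_hz=0.1, polarity="inward",
                             baseline_noise_sd_pA=0.0, seed=4)
        rec, truth = simulate_mpsc_trace(cfg)
        assert len(truth.event_onsets_s) > 0
        assert rec.samples.min() < 0 and rec.samples.max() == 0.0
        assert np.all(truth.event_amplitudes_pA > 0)  # truth stores magnitudes

    def test_poisson_event_count_calibration(self):
        counts = []
        for seed in range(100):
            cfg = SimEphysConfig(duration_s=30.0, event_rate_hz=2.0,
                                 baseline_noise_sd_pA=0.0, seed=seed)
            _, truth = simulate_mpsc_trace(cfg)
            counts.append(len(truth.event_onsets_s))
        assert abs(np.mean(counts) - 60) <= 4 * np.sqrt(60) / np.sqrt(100)

    def test_kernel_longer_than_trace_rejected(self):
        cfg = SimEphysConfig(duration_s=0.04, kernel_length_ms=50.0, seed=0)
        with pytest.raises(ValueError, match="longer than the trace"):
            simulate_mpsc_trace(cfg)

    def test_determinism(self):
        a, _ = simulate_mpsc_trace(SimEphysConfig(duration_s=5.0, seed=6))
        b, _ = simulate_mpsc_trace(SimEphysConfig(duration_s=5.0, seed=6))
        np.testing.assert_array_equal(a.samples, b.samples)
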