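import dataclasses
import math

import numpy as np
import pytest

import hexpam as h
from hexpam.forward import _kernel_at, record_length
from hexpam.pipeline import nominal_positions
from hexpam.recon import (WavelengthPair, assemble_volume,
                          demultiplex_wavelengths, depth_correct, envelope,
                          project_mip, stitch_channels)

from conftest import surface_depths_mm


class TestEnvelope:
    def test_zero_signal_zero_envelope(self):
        assert not envelope(np.zeros(256)).any()

    def test_sinusoid_amplitude_recovered(self):
        t = np.arange(1024)
        sig = 3.0 * np.sin(2 * np.pi * 0.12 * t)
        env = envelope(sig)[100:-100]
        assert np.allclose(env, 3.0, rtol=0.01)

    def test_modulated_pulse_peak_at_modulation_center(self, desk_cfg):
        n = 400
        sig = _kernel_at(np.arange(n) - 217.0, desk_cfg)
        assert abs(int(np.argmax(envelope(sig))) - 217) <= 1

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            envelope(np.array([0.0, np.nan]))


class TestDemultiplex:
    def _two_pulse_aline(self, cfg, n=500, centers=(250, 362)):
        sig = np.zeros(n)
        for c in centers:
            sig += _kernel_at(np.arange(n) - float(c), cfg)
        return sig

    def test_constructed_pulses_split_between_gates(self, desk_cfg):
        # 448 ns at 250 MHz -> shift of exactly 112 samples
        cfg = dataclasses.replace(desk_cfg, pulse_delay_ns=448.0)
        sig = self._two_pulse_aline(cfg)
        pair = demultiplex_wavelengths(sig, cfg)
        e1 = np.sum(pair.a532 ** 2)
        e2 = np.sum(pair.a558 ** 2)
        # each gate holds one pulse: equal energies, no cross leakage
        assert e1 == pytest.approx(e2, rel=1e-6)
        p1 = int(np.argmax(pair.a532[0, 0])) + pair.window_start[0, 0]
        p2 = (int(np.argmax(pair.a558[0, 0])) + pair.window_start[0, 0]
              + pair.delay_samples)
        assert p1 == 250 and p2 == 362

    def test_all_zero_aline_flagged_empty(self, desk_cfg):
        pair = demultiplex_wavelengths(np.zeros(500), desk_cfg)
        assert pair.empty.all()
        assert not pair.a532.any() and not pair.a558.any()

    def test_window_never_longer_than_delay(self, desk_cfg):
        pair = demultiplex_wavelengths(np.zeros(500), desk_cfg)
        assert pair.window_len <= round(desk_cfg.delay_samples)

    def test_overrun_past_record_end_rejected(self, desk_cfg):
        n = 300  # too short for surface at 250 plus two gates
        sig = self._two_pulse_aline(desk_cfg, n=n, centers=(250,))
        with pytest.raises(ValueError, match="overrun"):
            demultiplex_wavelengths(sig, desk_cfg)

    def test_amplitudes_match_separate_wavelength_simulations(
            self, geom, table, desk_cfg, single_vessel_scan):
        # separate-simulation oracle: demultiplexing the joint record must
        # reproduce single-wavelength acquisitions to numerical precision
        ph = single_vessel_scan["phantom"]
        raw = single_vessel_scan["raw"]
        only532 = h.simulate_scan(ph, table, desk_cfg, geom, None, seed=1,
                                  wavelengths=(532,))
        only558 = h.simulate_scan(ph, table, desk_cfg, geom, None, seed=1,
                                  wavelengths=(558,))
        pair = demultiplex_wavelengths(raw, desk_cfg, channel=1)
        a532, a558 = pair.amplitudes("l2")
        ref532 = np.sqrt(np.sum(only532.ch1.astype(np.float64) ** 2, axis=-1))
        ref558 = np.sqrt(np.sum(only558.ch1.astype(np.float64) ** 2, axis=-1))
        sel = ~pair.empty
        # gated envelope L2 equals sqrt(2) x raw L2 for an analytic echo
        np.testing.assert_allclose(a532[sel], math.sqrt(2) * ref532[sel],
                                   rtol=1e-9)
        np.testing.assert_allclose(a558[sel], math.sqrt(2) * ref558[sel],
                                   rtol=1e-9)


class TestAssembleVolume:
    def _pair_from(self, win, positions, cfg):
        nb, na, nw = win.shape
        return WavelengthPair(a532=win, a558=win.copy(),
                              window_start=np.zeros((nb, na), dtype=int),
                              window_len=nw, delay_samples=nw,
                              empty=np.zeros((nb, na), dtype=bool))

    def test_bin_center_positions_place_losslessly(self, desk_cfg):
        nx = int(round(desk_cfg.channel_range_mm / (desk_cfg.pixel_um * 1e-3)))
        win = np.arange(nx * 3, dtype=float).reshape(1, nx, 3)
        positions = (np.arange(nx) + 0.5) * desk_cfg.pixel_um * 1e-3
        vol = assemble_volume(self._pair_from(win, positions, desk_cfg),
                              positions, desk_cfg)
        assert np.array_equal(vol.data[0], win[0])
        assert vol.provenance["dropped"] == 0

    def test_collisions_average(self, desk_cfg):
        win = np.array([[[2.0], [4.0]]])  # two A-lines, same bin
        positions = np.array([0.010, 0.012])
        vol = assemble_volume(self._pair_from(win, positions, desk_cfg),
                              positions, desk_cfg)
        assert vol.data[0, 0, 0] == pytest.approx(3.0)

    def test_occupancy_matches_counting_oracle(self, desk_cfg):
        # nonuniform 8.4-um average step onto a 5-um lattice
        cfg = dataclasses.replace(desk_cfg, pixel_um=5.0)
        pitch = 5e-3
        nx = int(round(cfg.channel_range_mm / pitch))
        positions = np.arange(0.0, cfg.channel_range_mm, 8.4e-3)
        na = positions.size
        win = np.ones((1, na, 2))
        vol = assemble_volume(self._pair_from(win, positions, cfg),
                              positions, cfg)
        occupancy = vol.provenance["filled"].mean()
        oracle = len(set(int(p // pitch) for p in positions)) / nx
        assert occupancy == pytest.approx(oracle, rel=0.02)

    def test_out_of_lattice_positions_dropped_and_counted(self, desk_cfg):
        win = np.ones((1, 2, 2))
        positions = np.array([0.5, 9.9])
        vol = assemble_volume(self._pair_from(win, positions, desk_cfg),
                              positions, desk_cfg)
        assert vol.provenance["dropped"] == 1


class TestDepthCorrect:
    def test_flat_target_spread_below_axial_resolution(self, flat_target_scan,
                                                       geom):
        raw = flat_target_scan["raw"]
        cfg = flat_target_scan["config"]
        pair = demultiplex_wavelengths(raw, cfg, channel=1)
        vol = assemble_volume(pair, nominal_positions(cfg), cfg)
        uncorrected = surface_depths_mm(vol)
        corrected = surface_depths_mm(depth_correct(vol, geom, cfg))
        spread_before = (uncorrected.max() - uncorrected.min()) * 1e3
        spread_after = (corrected.max() - corrected.min()) * 1e3
        assert spread_after < 33.0
        assert spread_after < spread_before  # strictly improves

    def test_zero_sag_columns_unchanged(self, geom, desk_cfg, rng):
        # columns at the centre of the facet pass (zero sagitta) must come
        # through the correction bit-identically
        nb, nx, nw = 2, 5, 40
        data = rng.random((nb, nx, nw))
        start = np.full((nb, nx), 30.0)
        centre = desk_cfg.channel_range_mm / 2.0
        vol = h.ImageVolume(
            data=data.copy(), pixel_um=desk_cfg.pixel_um,
            z_pitch_mm=desk_cfg.mm_per_sample, wavelength_nm=532,
            provenance={"gate_start_samples": start,
                        "x_lattice_mm": np.full(nx, centre),
                        "x_source_mm": np.full((nb, nx), centre),
                        "filled": np.ones((nb, nx), dtype=bool),
                        "depth_corrected": False})
        out = depth_correct(vol, geom, desk_cfg)
        assert np.allclose(out.data, data, atol=1e-12)

    def test_idempotent(self, flat_target_scan, geom):
        raw = flat_target_scan["raw"]
        cfg = flat_target_scan["config"]
        pair = demultiplex_wavelengths(raw, cfg, channel=1)
        vol = depth_correct(assemble_volume(pair, nominal_positions(cfg), cfg),
                            geom, cfg)
        again = depth_correct(vol, geom, cfg)
        assert np.array_equal(again.data, vol.data)

    def test_missing_provenance_rejected(self, geom, desk_cfg):
        vol = h.ImageVolume(data=np.zeros((1, 4, 8)), pixel_um=5.0,
                            z_pitch_mm=0.006, wavelength_nm=532)
        with pytest.raises(ValueError, match="provenance"):
            depth_correct(vol, geom, desk_cfg)


class TestProjectMip:
    def test_single_occupied_slice_is_returned(self):
        vol = np.zeros((4, 5, 6))
        vol[:, :, 3] = np.arange(20).reshape(4, 5)
        assert np.array_equal(project_mip(vol), vol[:, :, 3])

    def test_zero_volume_projects_to_zero(self):
        assert not project_mip(np.zeros((3, 3, 3))).any()

    def test_dominates_every_voxel_and_is_idempotent(self, rng):
        vol = rng.random((6, 7, 8))
        mip = project_mip(vol)
        assert np.all(mip[:, :, None] >= vol)
        assert np.array_equal(project_mip(vol[:, :, ::-1]), mip)


class TestStitchChannels:
    def test_constant_images_stay_constant(self):
        cfg = h.ScanConfig(pixel_um=50.0)
        img = np.full((4, 280), 3.25)
        out = stitch_channels(img, img, cfg)
        assert np.allclose(out, 3.25)

    def test_zero_overlap_concatenates_to_28mm(self):
        cfg = h.ScanConfig(overlap_mm=1e-9, fov_fast_mm=28.0 - 1e-9,
                           pixel_um=50.0)
        a = np.ones((2, 280))
        b = 2 * np.ones((2, 280))
        out = stitch_channels(a, b, cfg)
        assert out.shape[1] == 560  # 28 mm at 50 um
        assert np.allclose(out[:, :280], 1) and np.allclose(out[:, 280:], 2)

    def test_four_mm_overlap_gives_24mm(self):
        cfg = h.ScanConfig(pixel_um=50.0)
        out = stitch_channels(np.ones((2, 280)), np.ones((2, 280)), cfg)
        assert out.shape[1] * cfg.pixel_um * 1e-3 == pytest.approx(24.0)

    def test_pixels_outside_overlap_copied_verbatim(self, rng):
        cfg = h.ScanConfig(pixel_um=50.0)
        a = rng.random((3, 280))
        b = rng.random((3, 280))
        out = stitch_channels(a, b, cfg)
        n_ov = 80
        assert np.array_equal(out[:, :280 - n_ov], a[:, :280 - n_ov])
        assert np.array_equal(out[:, 280:], b[:, n_ov:])

    def test_mismatched_rows_rejected(self):
        cfg = h.ScanConfig(pixel_um=50.0)
        with pytest.raises(ValueError, match="slow-axis"):
            stitch_channels(np.ones((2, 280)), np.ones((3, 280)), cfg)
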