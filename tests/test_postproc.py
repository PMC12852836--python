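import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage
from skimage.metrics import structural_similarity

import hexpam as h
from hexpam.pipeline import assemble_image, nominal_positions
from hexpam.postproc import (apply_facet_transforms, estimate_facet_transforms,
                             mean_pairwise_correlation, recombine_facets,
                             region_metric, split_by_facet, stabilize_frames,
                             unmix_so2, upsample_image)
from hexpam.recon import demultiplex_wavelengths


def vessel_mip(seed, ny=240, nx=180):
    spec = h.PhantomSpec(extent_mm=(ny * 0.015, nx * 0.015, 0.6),
                         voxel_um=15.0, n_vessels=7, radius_um=(40.0, 90.0),
                         depth_band_mm=(0.2, 0.4), seed=seed)
    return h.generate_vessel_phantom(spec).total_hb.sum(axis=2).T[:ny, :nx]


class TestSplitByFacet:
    def test_round_robin_partition_counts(self, rng):
        stack = rng.random((60, 10))
        facet_map = np.arange(60) % 6
        stacks, rows = split_by_facet(stack, facet_map)
        assert [s.shape[0] for s in stacks] == [10] * 6
        assert np.array_equal(rows[2], np.arange(2, 60, 6))

    def test_single_facet_is_identity(self, rng):
        stack = rng.random((5, 4))
        stacks, rows = split_by_facet(stack, np.zeros(5, dtype=int))
        assert np.array_equal(stacks[0], stack)

    def test_recombination_restores_acquisition_order(self, rng):
        stack = rng.random((31, 8))
        facet_map = np.arange(31) % 6
        stacks, rows = split_by_facet(stack, facet_map)
        assert np.array_equal(recombine_facets(stacks, rows, 31), stack)

    def test_facet_map_length_must_match(self, rng):
        with pytest.raises(ValueError, match="every row"):
            split_by_facet(rng.random((6, 4)), np.zeros(5, dtype=int))


class TestEstimateFacetTransforms:
    def _stacks(self, img, offsets, rng=None, snr_db=20.0):
        stacks = []
        for f, off in enumerate(offsets):
            shifted = ndimage.shift(img, (0, off), order=3, mode="constant")
            sub = shifted[f::6]
            if rng is not None:
                p = (sub ** 2).mean()
                sub = sub + np.sqrt(p * 10 ** (-snr_db / 10)) \
                    * rng.standard_normal(sub.shape)
            stacks.append(sub)
        return stacks

    def test_zero_misalignment_recovers_identity(self):
        img = vessel_mip(41)
        tr = estimate_facet_transforms(self._stacks(img, np.zeros(6)),
                                       reference_facet=0, max_shift=14)
        assert np.abs(tr.shifts[:, 1]).max() <= 0.1
        assert np.array_equal(tr.shifts[0], [0, 0])

    def test_known_fast_axis_offsets_recovered(self, rng):
        img = vessel_mip(42)
        offsets = np.array([6.0, -4.0, 2.0, 0.0, -2.0, 4.0])
        tr = estimate_facet_transforms(self._stacks(img, offsets, rng),
                                       reference_facet=3, max_shift=14)
        rel = offsets - offsets[3]
        assert np.abs(tr.shifts[:, 1] - rel).max() <= 0.5

    def test_plain_shifted_pair(self, rng):
        # two stacks, one a (3, 0)-px shifted copy of the other
        img = vessel_mip(43)
        shifted = ndimage.shift(img, (3.0, 0.0), order=3, mode="constant")
        tr = estimate_facet_transforms([img, shifted], reference_facet=0,
                                       max_shift=8, row_stretch=1)
        assert tr.shifts[1] == pytest.approx([3.0, 0.0], abs=0.25)

    def test_featureless_stacks_rejected(self):
        flat = [np.ones((60, 80)) for _ in range(3)]
        with pytest.raises(ValueError, match="insufficient structure"):
            estimate_facet_transforms(flat, max_shift=8)

    def test_forward_simulated_offsets_recovered(self, geom, table):
        # end-to-end: inject per-facet trajectory offsets, raster, demultiplex,
        # assemble at nominal positions, and register; the scene appears
        # displaced by the negative of each injected offset
        cfg = h.ScanConfig(channel_range_mm=2.0, overlap_mm=0.5,
                           fov_fast_mm=3.5, prf_kHz=48.0, bscan_rate_Hz=300.0,
                           slow_step_um=25.0, fov_slow_mm=6.0,
                           depth_range_mm=1.2, pixel_um=12.5)
        px = cfg.pixel_um
        pert = h.FacetPerturbation(
            offsets_um=(6 * px, -4 * px, 2 * px, 0.0, -2 * px, 4 * px),
            gains=(1.0,) * 6)
        spec = h.PhantomSpec(extent_mm=(3.8, 6.2, 0.9), voxel_um=15.0,
                             n_vessels=24, radius_um=(35.0, 80.0),
                             depth_band_mm=(0.25, 0.45), seed=7)
        ph = h.generate_vessel_phantom(spec)
        raw = h.simulate_scan(ph, table, cfg, geom, pert, seed=0)
        expected = -(np.asarray(pert.offsets_um) - pert.offsets_um[3]) / px
        for ch in (1, 2):
            pair = demultiplex_wavelengths(raw, cfg, channel=ch)
            a532, _ = pair.amplitudes("l2")
            img = assemble_image(a532, nominal_positions(cfg), cfg)
            stacks, _ = split_by_facet(img, raw.facet_of_bscan)
            tr = estimate_facet_transforms(stacks, reference_facet=3,
                                           max_shift=12)
            assert np.abs(tr.shifts[:, 1] - expected).max() <= 0.5


class TestApplyFacetTransforms:
    def test_identity_transforms_equal_naive_interleave(self, rng):
        img = vessel_mip(44)
        stacks, rows = split_by_facet(img, np.arange(img.shape[0]) % 6)
        identity = h.FacetTransform(shifts=np.zeros((6, 2)),
                                    gains=np.ones(6), reference=0)
        merged = apply_facet_transforms(stacks, identity, rows, img.shape[0])
        assert np.allclose(merged, img)

    def test_zero_images_stay_zero(self):
        stacks = [np.zeros((10, 20)) for _ in range(3)]
        tr = h.FacetTransform(shifts=np.array([[0, 0], [1, 2], [-1, 1.5]]),
                              gains=np.ones(3), reference=0)
        assert not apply_facet_transforms(stacks, tr).any()

    def test_inverse_apply_restores_unperturbed_image(self, rng):
        img = vessel_mip(45)
        offsets = np.array([0.0, 4.0, -3.0, 2.0, -1.0, 3.0])
        stacks = [ndimage.shift(img, (0, off), order=1)[f::6]
                  for f, off in enumerate(offsets)]
        rows = [np.arange(f, img.shape[0], 6) for f in range(6)]
        tr = estimate_facet_transforms(stacks, reference_facet=0,
                                       max_shift=10)
        merged = apply_facet_transforms(stacks, tr, rows, img.shape[0])
        crop = (slice(12, -12), slice(12, -12))
        ssim = structural_similarity(
            img[crop], merged[crop],
            data_range=img[crop].max() - img[crop].min())
        assert ssim >= 0.98

    def test_alignment_does_not_reduce_pairwise_correlation(self, rng):
        img = vessel_mip(46)
        offsets = np.array([0.0, 5.0, -4.0, 3.0, -2.0, 4.0])
        stacks = [ndimage.shift(img, (0, off), order=1)[f::6]
                  for f, off in enumerate(offsets)]
        tr = estimate_facet_transforms(stacks, reference_facet=0,
                                       max_shift=10)
        aligned = [ndimage.shift(s, (-tr.shifts[f][0] / 6, -tr.shifts[f][1]),
                                 order=1) for f, s in enumerate(stacks)]
        assert (mean_pairwise_correlation(aligned)
                >= mean_pairwise_correlation(stacks))

    def test_shape_mismatch_rejected(self):
        tr = h.FacetTransform(shifts=np.zeros((2, 2)), gains=np.ones(2),
                              reference=0)
        with pytest.raises(ValueError, match="width"):
            apply_facet_transforms([np.ones((4, 5)), np.ones((4, 6))], tr)


class TestStabilizeFrames:
    def test_identical_frames_zero_shifts(self):
        img = vessel_mip(47, ny=96, nx=96)
        aligned, shifts, flags = stabilize_frames(np.stack([img] * 4))
        assert not shifts.any()
        assert not flags.any()

    def test_known_translations_recovered(self):
        img = ndimage.gaussian_filter(vessel_mip(48, ny=128, nx=128), 1.0)
        moves = [(0.0, 0.0), (2.5, -1.5), (-3.0, 4.0)]
        frames = np.stack([ndimage.shift(img, m, order=3) for m in moves])
        _, shifts, flags = stabilize_frames(frames)
        for m, s in zip(moves[1:], shifts[1:]):
            assert s == pytest.approx([-m[0], -m[1]], abs=0.5)
        assert not flags.any()

    def test_pure_noise_flagged_low_confidence(self, rng):
        img = vessel_mip(49, ny=96, nx=96)
        frames = np.stack([img, rng.standard_normal((96, 96))])
        _, _, flags = stabilize_frames(frames)
        assert flags[1]

    def test_single_frame_is_identity(self):
        img = vessel_mip(50, ny=64, nx=64)
        aligned, shifts, flags = stabilize_frames(img[None])
        assert np.array_equal(aligned[0], img)
        assert not shifts.any() and not flags.any()


class TestUpsampleImage:
    def test_factor_one_is_identity(self, rng):
        img = rng.random((12, 9))
        assert np.array_equal(upsample_image(img, 1), img)

    def test_constant_stays_constant(self):
        up = upsample_image(np.full((8, 8), 5.5), 4)
        assert np.allclose(up, 5.5)

    def test_linear_ramp_reproduced_exactly(self):
        ramp = np.add.outer(np.arange(10.0), 2 * np.arange(12.0))
        up = upsample_image(ramp, 3)
        expected = np.add.outer(np.arange(up.shape[0]) / 3,
                                2 * np.arange(up.shape[1]) / 3)
        assert np.allclose(up, expected, atol=1e-9)

    def test_original_sites_preserved(self, rng):
        img = rng.random((15, 11))
        up = upsample_image(img, 2)
        assert np.allclose(up[::2, ::2], img, atol=1e-9)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            upsample_image(np.ones((4, 4)), 0.5)


class TestUnmixSO2:
    def test_pure_chromophore_columns(self, table):
        E = table.matrix()
        a532 = np.zeros((3, 3))
        a558 = np.zeros((3, 3))
        a532[0, 0], a558[0, 0] = E[0, 0], E[1, 0]  # pure HbO2
        a532[1, 1], a558[1, 1] = E[0, 1], E[1, 1]  # pure HbR
        m = unmix_so2(a532, a558, table, threshold=1e-9)
        assert m.so2[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert m.so2[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self, table):
        with pytest.raises(ValueError, match="share a shape"):
            unmix_so2(np.ones((2, 2)), np.ones((2, 3)), table)

    @given(seed=st.integers(0, 200))
    def test_outputs_clipped_and_zero_amplitude_masked(self, table, seed):
        r = np.random.default_rng(seed)
        a532 = np.maximum(r.normal(1.0, 1.0, (8, 8)), 0.0)
        a558 = np.maximum(r.normal(1.0, 1.0, (8, 8)), 0.0)
        a532[0, 0] = 0.0
        m = unmix_so2(a532, a558, table, threshold=0.0)
        assert not m.mask[0, 0]
        vals = m.so2[m.mask]
        assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_energy_calibration_rescales_558(self, table):
        E = table.matrix()
        a532 = np.full((2, 2), E[0, 0])
        a558 = np.full((2, 2), E[1, 0] / 2.0)
        m = unmix_so2(a532, a558, table, calibration_558=2.0, threshold=1e-9)
        assert np.allclose(m.so2, 1.0)


class TestRegionMetric:
    def test_constant_image_returns_value(self):
        img = np.full((5, 5), 2.5)
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:3, 1:4] = True
        assert region_metric(img, mask) == pytest.approx(2.5)

    def test_single_pixel_mask(self, rng):
        img = rng.random((6, 6))
        mask = np.zeros((6, 6), dtype=bool)
        mask[4, 2] = True
        assert region_metric(img, mask) == pytest.approx(img[4, 2])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_metric(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))

    def test_amplitude_step_ratio_recovered(self, rng):
        img = vessel_mip(51, ny=120, nx=120)
        mask = img > 0.3 * img.max()
        noise = 0.01 * img.max()
        frames = np.stack([img + noise * rng.standard_normal(img.shape),
                           0.6 * img + noise * rng.standard_normal(img.shape)])
        series = region_metric(frames, mask)
        assert series[1] / series[0] == pytest.approx(0.6, rel=0.01)

    def test_so2_step_recovered(self, table, rng):
        # amplitude pairs consistent with sO2 = 0.85 then 0.75
        E = table.matrix()
        img = vessel_mip(52, ny=100, nx=100)
        mask = img > 0.3 * img.max()
        maps = []
        for so2 in (0.85, 0.75):
            c = np.array([so2, 1 - so2])
            amps = E @ c
            a532 = img * amps[0] * (1 + 0.01 * rng.standard_normal(img.shape))
            a558 = img * amps[1] * (1 + 0.01 * rng.standard_normal(img.shape))
            maps.append(unmix_so2(a532, a558, table,
                                  threshold=1e-6 * img.max()))
        series = region_metric(maps, mask, metric="mean_so2")
        assert series[0] - series[1] == pytest.approx(0.10, abs=0.02)
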