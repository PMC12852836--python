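"""End-to-end convenience chains over the library modules.

These helpers wire the canonical order — demultiplex, assemble, depth
correction, projection, stitching, facet registration, unmixing — for the
common case of a simulated :class:`~hexpam.forward.RawScan`.  Each stage
remains available individually in its own module.
"""

from __future__ import annotations

import numpy as np

from .forward import RawScan
from .geometry import ScanConfig
from .phantom import ExtinctionTable
from .postproc import (SO2Map, apply_facet_transforms, estimate_facet_transforms,
                       split_by_facet, unmix_so2)
from .recon import (assemble_volume, demultiplex_wavelengths, depth_correct,
                    project_mip, stitch_channels)

__all__ = [
    "nominal_positions",
    "assemble_image",
    "reconstruct",
    "register_facets",
    "so2_from_raw",
]


def nominal_positions(config: ScanConfig) -> np.ndarray:
    """Ideal channel-local fast-axis position of every A-line in a B-scan."""
    na = config.n_alines
    return (np.arange(na) + 0.5) / na * config.channel_range_mm


def assemble_image(amplitudes: np.ndarray, positions_mm: np.ndarray,
                   config: ScanConfig) -> np.ndarray:
    """Nearest-bin average of per-A-line amplitudes onto the fast lattice."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    nb, na = amplitudes.shape
    positions = np.asarray(positions_mm, dtype=float)
    if positions.ndim == 1:
        positions = np.broadcast_to(positions, (nb, na))
    pitch_mm = config.pixel_um * 1e-3
    nx = int(round(config.channel_range_mm / pitch_mm))
    bins = np.floor(positions / pitch_mm).astype(int)
    inside = (bins >= 0) & (bins < nx)
    acc = np.zeros((nb, nx))
    cnt = np.zeros((nb, nx))
    rows = np.broadcast_to(np.arange(nb)[:, None], (nb, na))
    np.add.at(acc, (rows[inside], bins[inside]), amplitudes[inside])
    np.add.at(cnt, (rows[inside], bins[inside]), 1.0)
    filled = cnt > 0
    acc[filled] /= cnt[filled]
    return acc


def reconstruct(raw: RawScan, correct_depth: bool = True) -> dict:
    """Demultiplex, assemble, depth-correct, project, and stitch a raw scan.

    Returns a dict with per-channel :class:`WavelengthPair` objects, the
    (optionally depth-corrected) volumes and en-face MIPs keyed by
    ``(channel, wavelength)``, and the stitched en-face image per wavelength.
    """
    config = raw.config
    positions = nominal_positions(config)
    out = {"pairs": {}, "volumes": {}, "mips": {}, "stitched": {}}
    for ch in (1, 2):
        pair = demultiplex_wavelengths(raw, config, channel=ch)
        out["pairs"][ch] = pair
        for wl in (532, 558):
            vol = assemble_volume(pair, positions, config, wavelength_nm=wl)
            if correct_depth:
                vol = depth_correct(vol, raw.geom, config)
            out["volumes"][(ch, wl)] = vol
            out["mips"][(ch, wl)] = project_mip(vol)
    for wl in (532, 558):
        out["stitched"][wl] = stitch_channels(out["mips"][(1, wl)],
                                              out["mips"][(2, wl)], config)
    return out


def register_facets(image: np.ndarray, facet_map: np.ndarray,
                    reference_facet: int = 0, max_shift: int = 12):
    """Split an interleaved en-face image by facet, register, re-merge.

    Returns ``(aligned_image, transforms)``.
    """
    stacks, rows = split_by_facet(image, facet_map)
    transforms = estimate_facet_transforms(stacks, reference_facet,
                                           max_shift=max_shift)
    aligned = apply_facet_transforms(stacks, transforms, row_indices=rows,
                                     n_rows=image.shape[0])
    return aligned, transforms


def so2_from_raw(raw: RawScan, table: ExtinctionTable | None = None,
                 register: bool = False, max_shift: int = 12,
                 **unmix_kwargs) -> dict:
    """Stitched dual-wavelength amplitude images and their sO2 map.

    Amplitudes use the shift-invariant window L2 norm so the 532/558 ratio
    survives the sub-sample timing offset between the two gates.  With
    ``register=True`` both wavelength images of each channel are re-aligned
    with the facet transforms estimated on that channel's 532-nm image.
    """
    table = table or ExtinctionTable.default()
    config = raw.config
    positions = nominal_positions(config)
    imgs = {}
    transforms = {}
    for ch in (1, 2):
        pair = demultiplex_wavelengths(raw, config, channel=ch)
        a532, a558 = pair.amplitudes("l2")
        img532 = assemble_image(a532, positions, config)
        img558 = assemble_image(a558, positions, config)
        if register:
            facet_map = raw.facet_of_bscan
            _, tr = register_facets(img532, facet_map, max_shift=max_shift)
            stacks532, rows = split_by_facet(img532, facet_map)
            stacks558, _ = split_by_facet(img558, facet_map)
            img532 = apply_facet_transforms(stacks532, tr, rows, img532.shape[0])
            img558 = apply_facet_transforms(stacks558, tr, rows, img558.shape[0])
            transforms[ch] = tr
        imgs[(ch, 532)] = img532
        imgs[(ch, 558)] = img558
    s532 = stitch_channels(imgs[(1, 532)], imgs[(2, 532)], config)
    s558 = stitch_channels(imgs[(1, 558)], imgs[(2, 558)], config)
    so2 = unmix_so2(s532, s558, table, **unmix_kwargs)
    return {"a532": s532, "a558": s558, "so2": so2,
            "transforms": transforms or None}
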