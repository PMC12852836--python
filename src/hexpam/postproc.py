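"""Facet registration, frame stabilisation, upsampling, and sO2 mapping.

A water-immersed polygon scanner wobbles and its facets differ slightly in
size, so B-scans acquired by different facets follow displaced trajectories.
The processing chain here mirrors that workflow: split the B-scan stack by
originating facet, register every facet's image to a reference facet
(translation by normalised cross-correlation with parabolic sub-pixel
refinement), resample and re-interleave, stabilise repeated frames by phase
correlation, upsample with interpolating splines, and finally unmix the two
wavelength amplitudes into per-pixel oxygen saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage
from scipy.signal import windows
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation

from .phantom import ExtinctionTable

__all__ = [
    "FacetTransform",
    "SO2Map",
    "split_by_facet",
    "recombine_facets",
    "estimate_facet_transforms",
    "apply_facet_transforms",
    "mean_pairwise_correlation",
    "stabilize_frames",
    "upsample_image",
    "unmix_so2",
    "region_metric",
]


@dataclass
class FacetTransform:
    """Per-facet 2-D translations (slow, fast) in pixels, plus optional gains.

    The reference facet's transform is the identity by construction.
    """

    shifts: np.ndarray  # [n_facets, 2] = (dy, dx)
    gains: np.ndarray
    reference: int

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.gains = np.asarray(self.gains, dtype=float)
        if not np.all(np.isfinite(self.shifts)) or not np.all(np.isfinite(self.gains)):
            raise ValueError("transforms must be finite")
        if np.any(np.abs(self.shifts[self.reference]) > 1e-9):
            raise ValueError("reference facet transform must be the identity")


@dataclass
class SO2Map:
    """Per-pixel oxygen saturation with a validity mask.

    ``so2`` is clipped to [0, 1] and NaN outside ``mask``; ``thb`` is the
    relative total-haemoglobin proxy (sum of unmixed concentrations).
    """

    so2: np.ndarray
    mask: np.ndarray
    thb: np.ndarray


def split_by_facet(stack: np.ndarray, facet_map: np.ndarray):
    """Partition B-scan rows by originating facet.

    ``stack`` is ``[row, ...]`` with one row per B-scan and ``facet_map``
    gives each row's facet index.  Returns ``(facet_stacks, row_indices)``
    where ``facet_stacks[f]`` holds facet ``f``'s rows in acquisition order.
    """
    stack = np.asarray(stack)
    facet_map = np.asarray(facet_map)
    if facet_map.shape[0] != stack.shape[0]:
        raise ValueError(
            f"facet_map must label every row: {facet_map.shape[0]} labels for "
            f"{stack.shape[0]} rows")
    facets = np.unique(facet_map)
    stacks, indices = [], []
    for f in facets:
        rows = np.flatnonzero(facet_map == f)
        stacks.append(stack[rows].copy())
        indices.append(rows)
    return stacks, indices


def recombine_facets(facet_stacks, row_indices, n_rows: int | None = None):
    """Inverse of :func:`split_by_facet` (no transforms applied)."""
    if n_rows is None:
        n_rows = max(int(r.max()) for r in row_indices) + 1
    out = np.zeros((n_rows,) + facet_stacks[0].shape[1:],
                   dtype=facet_stacks[0].dtype)
    for sub, rows in zip(facet_stacks, row_indices):
        out[rows] = sub
    return out


def _paraboloid_peak(patch: np.ndarray) -> np.ndarray:
    """Sub-pixel offset of the maximum of a 3x3 correlation patch.

    Fits a full 2-D quadratic (with cross term) by least squares, so a
    tilted correlation ridge — e.g. from diagonal vessels — does not bias
    the per-axis estimates the way two separable 1-D fits would.
    """
    y, x = np.mgrid[-1:2, -1:2]
    A = np.stack([np.ones(9), y.ravel(), x.ravel(), (y * y).ravel(),
                  (x * x).ravel(), (y * x).ravel()], axis=1)
    _, by, bx, ayy, axx, ayx = np.linalg.lstsq(A, patch.ravel(), rcond=None)[0]
    H = np.array([[2 * ayy, ayx], [ayx, 2 * axx]])
    if np.linalg.det(H) <= 0:  # not a proper maximum; keep the integer peak
        return np.zeros(2)
    offset = -np.linalg.solve(H, np.array([by, bx]))
    return np.clip(offset, -1.0, 1.0)


def _ncc_shift(reference: np.ndarray, moving: np.ndarray, max_shift: int,
               dy_center: float = 0.0, dy_window: float | None = None):
    """Translation of ``moving`` relative to ``reference`` via NCC.

    The central crop of ``moving`` is slid over ``reference``; the NCC peak
    is refined to sub-pixel precision with a 2-D paraboloid fit.  When
    ``dy_window`` is given, the slow-axis peak search is confined to
    ``dy_center +- dy_window``: with elongated structures the correlation
    forms a ridge along the structure direction, and a known acquisition row
    offset between stacks removes that ambiguity.
    """
    m = max_shift
    if moving.shape[0] <= 2 * m + 2 or moving.shape[1] <= 2 * m + 2:
        raise ValueError(
            f"images of shape {moving.shape} too small for max_shift={m}")
    template = moving[m:-m, m:-m]
    if template.std() == 0 or reference.std() == 0:
        raise ValueError("insufficient structure for registration "
                         "(constant image)")
    corr = match_template(reference, template, pad_input=False)
    if dy_window is not None:
        # row p corresponds to dy = m - p
        dy = m - np.arange(corr.shape[0])
        masked = corr.copy()
        masked[np.abs(dy - dy_center) > dy_window, :] = -np.inf
        corr_for_peak = masked
    else:
        corr_for_peak = corr
    peak = np.unravel_index(np.argmax(corr_for_peak), corr.shape)
    if all(0 < p < s - 1 for p, s in zip(peak, corr.shape)):
        patch = corr[peak[0] - 1:peak[0] + 2, peak[1] - 1:peak[1] + 2]
        sub = _paraboloid_peak(patch)
    else:
        sub = np.zeros(2)
    shift = np.array([m - (peak[0] + sub[0]), m - (peak[1] + sub[1])])
    return shift, float(corr[peak])


def estimate_facet_transforms(facet_stacks, reference_facet: int = 0,
                              max_shift: int = 12,
                              estimate_gains: bool = False,
                              row_stretch: int | None = None) -> FacetTransform:
    """Estimate each facet's displacement against a reference facet.

    A facet stack holds every ``n``-th B-scan, so it is heavily decimated
    along the slow axis; before correlation each stack is linearly stretched
    back to full row density (``row_stretch``, default the facet count),
    which removes most of the decimation aliasing.  Returns translations
    ``(dy, dx)`` — dy in full-raster rows, dx in fast-axis pixels — such
    that facet ``f``'s image equals the reference shifted by ``shifts[f]``;
    the reference transform is the identity.
    """
    n = len(facet_stacks)
    if n < 2:
        raise ValueError("need at least two facet stacks to register")
    if row_stretch is None:
        row_stretch = n
    rows = min(s.shape[0] for s in facet_stacks)
    cols = min(s.shape[1] for s in facet_stacks)
    # smooth below the decimation Nyquist so the per-facet sampling phase
    # cannot bias the correlation peak along image gradients
    sigma = 1.0 * row_stretch
    cropped = [ndimage.gaussian_filter(
        _stretch_rows(np.asarray(s[:rows, :cols], dtype=float), row_stretch),
        (sigma, 0.0)) for s in facet_stacks]
    ref = cropped[reference_facet]
    shifts = np.zeros((n, 2))
    gains = np.ones(n)
    for f in range(n):
        if f == reference_facet:
            continue
        # round-robin decimated stacks trail the reference by (f - ref)
        # raster rows; centre the slow-axis search there, allow one facet
        # period of true misalignment, and report misalignment only (the
        # acquisition row offset is removed, so aligned stacks estimate as
        # the identity)
        if row_stretch > 1:
            intrinsic = -(f - reference_facet)
            raw, _ = _ncc_shift(ref, cropped[f], max_shift,
                                dy_center=intrinsic,
                                dy_window=float(row_stretch))
            raw[0] -= intrinsic
        else:
            raw, _ = _ncc_shift(ref, cropped[f], max_shift)
        shifts[f] = raw
        if estimate_gains:
            ref_mean = ref.mean()
            gains[f] = cropped[f].mean() / ref_mean if ref_mean > 0 else 1.0
    return FacetTransform(shifts=shifts, gains=gains, reference=reference_facet)


def _stretch_rows(stack: np.ndarray, factor: int) -> np.ndarray:
    """Linear interpolation of a row-decimated stack to full row density."""
    if factor == 1:
        return stack
    rows = stack.shape[0]
    out_rows = (rows - 1) * factor + 1
    coords_y = np.arange(out_rows) / factor
    cy = np.broadcast_to(coords_y[:, None], (out_rows, stack.shape[1]))
    cx = np.broadcast_to(np.arange(stack.shape[1])[None, :], cy.shape)
    return ndimage.map_coordinates(stack, [cy, cx], order=1, mode="nearest")


def apply_facet_transforms(facet_stacks, transforms: FacetTransform,
                           row_indices=None, n_rows: int | None = None,
                           row_stretch: int | None = None):
    """Undo each facet's displacement and re-interleave into one image.

    Each facet stack is resampled by the inverse of its estimated translation
    (linear interpolation; the slow-axis component is converted from
    full-raster rows to the stack's decimated rows) and divided by its gain,
    then rows are scattered back to their acquisition positions (round-robin
    if ``row_indices`` is omitted).
    """
    n = len(facet_stacks)
    if transforms.shifts.shape[0] != n:
        raise ValueError(
            f"{transforms.shifts.shape[0]} transforms for {n} facet stacks")
    shapes = {s.shape for s in facet_stacks}
    if len({sh[1:] for sh in shapes}) != 1:
        raise ValueError(f"facet stacks disagree in width: {shapes}")
    if row_stretch is None:
        row_stretch = n
    aligned = []
    for f, sub in enumerate(facet_stacks):
        dy, dx = transforms.shifts[f]
        moved = ndimage.shift(np.asarray(sub, dtype=float),
                              (-dy / row_stretch, -dx), order=1,
                              mode="constant")
        aligned.append(moved / transforms.gains[f])
    if row_indices is None:
        total = sum(s.shape[0] for s in facet_stacks)
        row_indices = [np.arange(f, total, n)[:facet_stacks[f].shape[0]]
                       for f in range(n)]
    return recombine_facets(aligned, row_indices, n_rows)


def mean_pairwise_correlation(facet_stacks) -> float:
    """Mean Pearson correlation over all facet pairs (alignment quality)."""
    rows = min(s.shape[0] for s in facet_stacks)
    cols = min(s.shape[1] for s in facet_stacks)
    flat = [np.asarray(s[:rows, :cols], dtype=float).ravel()
            for s in facet_stacks]
    vals = []
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            vals.append(np.corrcoef(flat[i], flat[j])[0, 1])
    return float(np.mean(vals))


def stabilize_frames(frames, upsample_factor: int = 20,
                     confidence_threshold: float = 0.2):
    """Register every frame to the first by phase-correlation translation.

    Returns ``(aligned, shifts, low_confidence)``: the resampled frames, the
    per-frame (dy, dx) shifts, and a flag per frame marking registrations
    whose post-alignment correlation with the reference falls below the
    threshold (e.g. pure-noise frames).  A single frame is returned as is.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a [frame, y, x] stack")
    n = frames.shape[0]
    shifts = np.zeros((n, 2))
    flags = np.zeros(n, dtype=bool)
    aligned = frames.copy()
    ref = frames[0]
    # demean and taper the borders so the cross-correlation is not dominated
    # by the image mean or by circular wrap-around artefacts
    taper = np.outer(windows.tukey(frames.shape[1], 0.3),
                     windows.tukey(frames.shape[2], 0.3))
    ref_w = (ref - ref.mean()) * taper
    for i in range(1, n):
        mov_w = (frames[i] - frames[i].mean()) * taper
        shift, _, _ = phase_cross_correlation(ref_w, mov_w,
                                              upsample_factor=upsample_factor,
                                              normalization=None)
        shifts[i] = shift
        aligned[i] = ndimage.shift(frames[i], shift, order=1, mode="constant")
        # confidence from the interior only: border-fill pixels would
        # otherwise dominate the correlation of low-contrast frames
        my = min(int(np.ceil(abs(shift[0]))) + 1, frames.shape[1] // 4)
        mx = min(int(np.ceil(abs(shift[1]))) + 1, frames.shape[2] // 4)
        a = ref[my:-my, mx:-mx]
        b = aligned[i][my:-my, mx:-mx]
        if a.std() == 0 or b.std() == 0:
            flags[i] = True
        else:
            corr = np.corrcoef(a.ravel(), b.ravel())[0, 1]
            flags[i] = corr < confidence_threshold
    return aligned, shifts, flags


def upsample_image(image: np.ndarray, factor: float) -> np.ndarray:
    """Interpolating-spline upsampling to a ``factor``-times finer grid.

    Values at the original sample sites are preserved exactly.  (A learned
    upsampler can be slotted in behind the same signature.)
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    image = np.asarray(image, dtype=float)
    if factor == 1:
        return image.copy()
    ny, nx = image.shape
    ky = min(3, ny - 1)
    kx = min(3, nx - 1)
    spline = interpolate.RectBivariateSpline(
        np.arange(ny), np.arange(nx), image, kx=kx, ky=ky, s=0)
    new_y = np.arange(int(round((ny - 1) * factor)) + 1) / factor
    new_x = np.arange(int(round((nx - 1) * factor)) + 1) / factor
    return spline(new_y, new_x)


def unmix_so2(a532: np.ndarray, a558: np.ndarray, table: ExtinctionTable,
              calibration_558: float = 1.0, threshold: float | None = None,
              threshold_mads: float = 3.0) -> SO2Map:
    """Linear spectral unmixing of dual-wavelength amplitudes into sO2.

    Per pixel, solve ``[a532; a558] = E [c_HbO2; c_HbR]`` with ``E`` the 2x2
    extinction matrix at (532, 558) nm, then ``sO2 = c_HbO2 / (c_HbO2 +
    c_HbR)`` clipped to [0, 1].  ``calibration_558`` rescales the 558-nm
    amplitude for inter-wavelength pulse-energy imbalance.  Pixels whose
    amplitude falls below the threshold (default ``threshold_mads`` scaled
    MADs of each amplitude image, never below zero amplitude) or whose
    unmixed total haemoglobin is non-positive are masked invalid.
    """
    a532 = np.asarray(a532, dtype=float)
    a558 = np.asarray(a558, dtype=float) * calibration_558
    if a532.shape != a558.shape:
        raise ValueError(
            f"amplitude images must share a shape, got {a532.shape} and "
            f"{a558.shape}")
    E = table.matrix((532.0, 558.0))
    det = np.linalg.det(E)
    if abs(det) < 1e-12 * np.abs(E).max() ** 2:
        raise ValueError("extinction matrix at (532, 558) nm is singular")
    inv = np.linalg.inv(E)
    amps = np.stack([a532.ravel(), a558.ravel()])
    conc = inv @ amps
    c_hbo2 = conc[0].reshape(a532.shape)
    c_hbr = conc[1].reshape(a532.shape)
    thb = c_hbo2 + c_hbr
    if threshold is None:
        thr = []
        for img in (a532, a558):
            med = np.median(img)
            thr.append(threshold_mads * 1.4826 * np.median(np.abs(img - med)))
        thr532, thr558 = thr
    else:
        thr532 = thr558 = threshold
    mask = (a532 > max(thr532, 0.0)) & (a558 > max(thr558, 0.0)) & (thb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        so2 = np.clip(c_hbo2 / thb, 0.0, 1.0)
    so2 = np.where(mask, so2, np.nan)
    return SO2Map(so2=so2, mask=mask, thb=thb)


def region_metric(frames, region_mask: np.ndarray,
                  metric: str = "mean_amplitude"):
    """Masked mean of an image quantity per frame (perfusion / sO2 proxy).

    ``frames`` may be a single 2-D image, a ``[frame, y, x]`` stack, a list
    of images, or (for ``metric='mean_so2'``) a single :class:`SO2Map` or a
    list of them.  Returns a float for a single frame, else an array.
    """
    if metric not in ("mean_amplitude", "mean_so2"):
        raise ValueError(f"unknown metric {metric!r}")
    single = False
    if isinstance(frames, SO2Map):
        frames = [frames]
        single = True
    elif isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = frames[None]
        single = True
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    out = []
    for fr in frames:
        if metric == "mean_so2":
            if not isinstance(fr, SO2Map):
                raise TypeError("metric 'mean_so2' needs SO2Map frames")
            if fr.so2.shape != region_mask.shape:
                raise ValueError("mask shape does not match the frames")
            sel = region_mask & fr.mask
            out.append(float(np.nanmean(fr.so2[sel])) if sel.any() else np.nan)
        else:
            fr = np.asarray(fr, dtype=float)
            if fr.shape != region_mask.shape:
                raise ValueError("mask shape does not match the frames")
            out.append(float(fr[region_mask].mean()))
    return out[0] if single else np.asarray(out)
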