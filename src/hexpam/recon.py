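"""Raw A-lines -> spatially correct per-wavelength images.

Stages: time-gated wavelength demultiplexing (surface-anchored windows no
longer than the inter-wavelength delay), analytic-signal envelope detection,
assembly of A-lines onto a regular lateral lattice, arc depth correction,
en-face maximum-intensity projection, and dual-channel stitching with a
ramped blend across the overlap band.

Coordinate convention: x = fast axis, y = slow axis, z = depth; indices are
0-based, intervals half-open; the lateral lattice pitch defaults to the
configured ``pixel_um``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .geometry import ScanConfig, ScannerGeometry, arc_sag_mm, effective_range_mm
from .forward import RawScan

__all__ = [
    "WavelengthPair",
    "ImageVolume",
    "envelope",
    "demultiplex_wavelengths",
    "assemble_volume",
    "depth_correct",
    "project_mip",
    "stitch_channels",
]


def envelope(signal_in: np.ndarray) -> np.ndarray:
    """Analytic-signal magnitude along the last axis (length preserving)."""
    signal_in = np.asarray(signal_in, dtype=np.float64)
    if not np.all(np.isfinite(signal_in)):
        raise ValueError("signal contains non-finite values")
    return np.abs(sps.hilbert(signal_in, axis=-1))


@dataclass
class WavelengthPair:
    """Demultiplexed envelope windows of the two excitation wavelengths.

    ``a532``/``a558`` are envelope stacks ``[bscan, aline, window_sample]``;
    ``window_start`` holds the detected surface sample per A-line (the gate
    for 532 nm; the 558-nm gate is delayed by ``delay_samples``).  A-lines
    with no supra-threshold sample are flagged in ``empty`` and carry
    all-zero windows.
    """

    a532: np.ndarray
    a558: np.ndarray
    window_start: np.ndarray
    window_len: int
    delay_samples: int
    empty: np.ndarray
    channel: int = 1

    def __post_init__(self) -> None:
        if self.a532.shape != self.a558.shape:
            raise ValueError("a532 and a558 must share a shape")
        if self.window_len > self.delay_samples + 1:
            raise ValueError("gating window must not exceed the pulse delay")

    def amplitudes(self, mode: str = "l2"):
        """Per-A-line amplitude images (A532, A558).

        ``l2`` returns the window root-sum-square, which is invariant to
        sub-sample time shifts of a band-limited echo and therefore preserves
        the inter-wavelength amplitude ratio exactly; ``peak`` returns the
        per-window envelope maximum (the usual display amplitude).
        """
        if mode == "l2":
            return (np.sqrt(np.sum(np.square(self.a532), axis=-1)),
                    np.sqrt(np.sum(np.square(self.a558), axis=-1)))
        if mode == "peak":
            return self.a532.max(axis=-1), self.a558.max(axis=-1)
        raise ValueError(f"mode must be 'l2' or 'peak', got {mode!r}")


def _gate_guard_samples(config: ScanConfig) -> int:
    """Lead added before the detected surface when placing the gates.

    The transducer impulse response rises over several envelope sigmas before
    the threshold crossing; starting each gate this far ahead keeps the
    leading pulse energy inside its own gate for both wavelengths, so the
    532/558 window-energy ratio is unbiased by the gate placement.
    """
    fs = config.digitizer_rate_MHz * 1e6
    sigma = (config.axial_res_um * 1e-6 / config.sound_speed_m_s
             / (2.0 * math.sqrt(2.0 * math.log(2.0))) * fs)
    return int(math.ceil(6.0 * sigma)) + 2


def _noise_threshold(env: np.ndarray, n_mads: float) -> float:
    """Surface-detection threshold: n_mads * MAD with a relative floor."""
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    peak = float(env.max())
    if peak == 0.0:
        return np.inf
    return max(n_mads * 1.4826 * mad, 1e-3 * peak)


def demultiplex_wavelengths(raw, config: ScanConfig,
                            channel: int = 1) -> WavelengthPair:
    """Split each A-line into two surface-anchored time gates.

    The 532-nm gate is ``[t_surf, t_surf + W)`` and the 558-nm gate
    ``[t_surf + delay, t_surf + delay + W)``, where ``t_surf`` is the first
    envelope sample above the noise threshold (``surface_threshold_mads``
    median absolute deviations, with a small relative floor) and
    ``W = floor(delay * fs)`` samples, so the gates can never overlap.
    Accepts a :class:`RawScan` or a raw ``[bscan, aline, sample]`` array.
    """
    stack = raw.channel(channel) if isinstance(raw, RawScan) else np.asarray(raw)
    if stack.ndim == 1:
        stack = stack[None, None, :]
    elif stack.ndim == 2:
        stack = stack[None, :, :]
    nb, na, ns = stack.shape
    delay = int(round(config.delay_samples))
    window = int(math.floor(config.delay_samples))
    env = envelope(stack)
    thresh = _noise_threshold(env, config.surface_threshold_mads)
    above = env > thresh
    t_surf = np.where(above.any(axis=-1), above.argmax(axis=-1), -1)
    empty = t_surf < 0
    guard = _gate_guard_samples(config)
    start = np.where(empty, 0, np.maximum(t_surf - guard, 0))
    overrun = start + delay + window > ns
    if np.any(overrun & ~empty):
        b, a = np.argwhere(overrun & ~empty)[0]
        raise ValueError(
            f"gating window overruns the record for A-line (bscan={b}, "
            f"aline={a}): surface at sample {start[b, a]}, record length {ns}")
    gather = start[..., None] + np.arange(window)[None, None, :]
    rows_b = np.arange(nb)[:, None, None]
    rows_a = np.arange(na)[None, :, None]
    # gate the raw signal first, then envelope each gate separately: the raw
    # echoes have compact support, whereas a full-record analytic envelope
    # has slow tails that would leak between the two wavelength gates and
    # bias the 532/558 amplitude ratio
    a532 = envelope(stack[rows_b, rows_a, gather])
    a558 = envelope(stack[rows_b, rows_a, gather + delay])
    a532[empty] = 0.0
    a558[empty] = 0.0
    return WavelengthPair(a532=a532, a558=a558, window_start=start,
                          window_len=window, delay_samples=delay,
                          empty=empty, channel=channel)


@dataclass
class ImageVolume:
    """Per-wavelength amplitude volume on a regular (x, y, z) lattice.

    ``data`` is indexed ``[iy, ix, iz]`` (slow, fast, depth).  ``provenance``
    carries what depth correction needs: the channel, the per-pixel gate
    start (in samples), the fast-axis lattice in channel-local mm, and
    whether the arc correction has already been applied.
    """

    data: np.ndarray
    pixel_um: float
    z_pitch_mm: float
    wavelength_nm: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_um <= 0 or self.z_pitch_mm <= 0:
            raise ValueError("lattice pitches must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")


def assemble_volume(pair: WavelengthPair, positions_mm: np.ndarray,
                    config: ScanConfig, wavelength_nm: int = 532) -> ImageVolume:
    """Scatter A-line windows onto a regular fast-axis lattice.

    ``positions_mm`` gives one channel-local fast-axis coordinate per A-line
    (``[bscan, aline]`` or ``[aline]`` broadcast across B-scans); assignment
    is nearest-bin with averaging on collisions.  Positions outside the
    lattice are dropped and counted in ``provenance['dropped']``.
    """
    win = pair.a532 if wavelength_nm == 532 else pair.a558
    nb, na, nw = win.shape
    positions = np.asarray(positions_mm, dtype=float)
    if positions.ndim == 1:
        positions = np.broadcast_to(positions, (nb, na))
    if positions.shape != (nb, na):
        raise ValueError(
            f"need one position per A-line: positions {positions.shape}, "
            f"stack {(nb, na)}")
    pitch_mm = config.pixel_um * 1e-3
    nx = int(round(config.channel_range_mm / pitch_mm))
    # half-open bins [k*pitch, (k+1)*pitch): nearest-bin assignment that is
    # stable when positions fall exactly on bin edges
    bins = np.floor(positions / pitch_mm).astype(int)
    inside = (bins >= 0) & (bins < nx) & ~pair.empty
    dropped = int(np.sum((bins < 0) | (bins >= nx)))
    acc = np.zeros((nb, nx, nw))
    cnt = np.zeros((nb, nx))
    starts = np.zeros((nb, nx))
    xmean = np.zeros((nb, nx))
    for b in range(nb):
        sel = inside[b]
        np.add.at(acc[b], bins[b][sel], win[b][sel])
        np.add.at(cnt[b], bins[b][sel], 1.0)
        np.add.at(starts[b], bins[b][sel], pair.window_start[b][sel])
        np.add.at(xmean[b], bins[b][sel], positions[b][sel])
    filled = cnt > 0
    acc[filled] /= cnt[filled][:, None]
    starts[filled] /= cnt[filled]
    lattice = (np.arange(nx) + 0.5) * pitch_mm  # bin centres
    xmean[filled] /= cnt[filled]
    xmean[~filled] = np.broadcast_to(lattice, (nb, nx))[~filled]
    return ImageVolume(
        data=acc, pixel_um=config.pixel_um, z_pitch_mm=config.mm_per_sample,
        wavelength_nm=wavelength_nm,
        provenance={
            "channel": pair.channel,
            "gate_start_samples": starts,
            "filled": filled,
            "x_lattice_mm": lattice,
            "x_source_mm": xmean,  # mean true position of the binned A-lines
            "dropped": dropped,
            "depth_corrected": False,
        })


def depth_correct(volume: ImageVolume, geom: ScannerGeometry,
                  config: ScanConfig) -> ImageVolume:
    """Remove the rotatory-scanning arc distortion from a volume.

    Each column's samples sit at apparent depths
    ``z = (gate_start + k) * c / fs``; the arc sagitta at the column's
    fast-axis position is subtracted and the column is re-binned by linear
    interpolation onto a common absolute-depth lattice.  Columns at the
    centre of the facet pass (zero sagitta) are unchanged up to the common
    re-referencing.  Idempotent: a volume whose provenance already records
    the correction is returned as is.
    """
    prov = volume.provenance
    for key in ("gate_start_samples", "x_lattice_mm"):
        if key not in prov:
            raise ValueError(
                f"volume lacks {key!r} provenance; assemble it from a "
                "demultiplexed scan before depth correction")
    if prov.get("depth_corrected", False):
        return volume
    nb, nx, nw = volume.data.shape
    dz = volume.z_pitch_mm
    # evaluate the sagitta at the true source positions of each column where
    # recorded (bin centres can be half a pixel off the actual trajectory)
    x_src = prov.get("x_source_mm")
    if x_src is None:
        x_src = np.broadcast_to(prov["x_lattice_mm"], (nb, nx))
    sag = arc_sag_mm(x_src, config)  # [nb, nx]
    start = prov["gate_start_samples"]  # [nb, nx] samples
    # apparent depth of window sample 0, corrected for the arc
    z0 = start * dz - sag
    filled = prov.get("filled", np.ones_like(z0, dtype=bool))
    z_lo = float(z0[filled].min()) if filled.any() else 0.0
    # snap the common lattice to the sample grid so zero-sagitta columns are
    # re-referenced by an integer number of samples (no interpolation loss)
    z_lo = math.floor(z_lo / dz + 1e-9) * dz
    k = np.arange(nw)
    z_out = z_lo + k * dz
    # for each column, sample index in the window that lands on z_out
    idx = (z_out[None, None, :] - z0[:, :, None]) / dz  # [nb, nx, nw]
    valid = (idx >= -1e-9) & (idx <= nw - 1 + 1e-9)
    idx = np.clip(idx, 0.0, nw - 1)
    lo_c = np.clip(np.floor(idx).astype(int), 0, nw - 2)
    frac = idx - lo_c
    b_i = np.arange(nb)[:, None, None]
    x_i = np.arange(nx)[None, :, None]
    out = ((1 - frac) * volume.data[b_i, x_i, lo_c]
           + frac * volume.data[b_i, x_i, np.minimum(lo_c + 1, nw - 1)])
    out[~valid] = 0.0
    new_prov = dict(prov)
    new_prov.update(depth_corrected=True, z0_mm=z_lo)
    return ImageVolume(data=out, pixel_um=volume.pixel_um, z_pitch_mm=dz,
                       wavelength_nm=volume.wavelength_nm, provenance=new_prov)


def project_mip(volume) -> np.ndarray:
    """En-face maximum-intensity projection (max over depth)."""
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    if data.size == 0:
        raise ValueError("cannot project an empty volume")
    return data.max(axis=-1)


def stitch_channels(img1: np.ndarray, img2: np.ndarray,
                    config: ScanConfig) -> np.ndarray:
    """Merge the two channels' en-face images along the fast axis.

    Inputs are ``[slow, fast]`` images covering one channel range each at the
    configured pixel pitch.  Outside the overlap band pixels are copied
    verbatim; inside it they are blended with a ramp from channel 1 to
    channel 2 (linear by default, raised-cosine via ``config.blend``).  The
    output fast-axis extent is the effective scanning range.
    """
    img1 = np.asarray(img1)
    img2 = np.asarray(img2)
    if img1.shape[0] != img2.shape[0]:
        raise ValueError(
            f"channels must share the slow-axis extent, got {img1.shape[0]} "
            f"and {img2.shape[0]} rows")
    pitch_mm = config.pixel_um * 1e-3
    nx = int(round(config.channel_range_mm / pitch_mm))
    if img1.shape[1] != nx or img2.shape[1] != nx:
        raise ValueError(
            f"each channel image must span channel_range_mm "
            f"({nx} px at {config.pixel_um} um), got {img1.shape[1]} and "
            f"{img2.shape[1]}")
    n_ov = int(round(config.overlap_mm / pitch_mm))
    eff = effective_range_mm(config.channel_range_mm, config.channel_range_mm,
                             config.overlap_mm)
    n_out = int(round(eff / pitch_mm))
    out = np.zeros((img1.shape[0], n_out), dtype=np.result_type(img1, img2))
    out[:, :nx - n_ov] = img1[:, :nx - n_ov]
    out[:, nx:] = img2[:, n_ov:]
    if n_ov > 0:
        t = (np.arange(n_ov) + 0.5) / n_ov
        if config.blend == "cosine":
            w = 0.5 * (1.0 - np.cos(np.pi * t))
        else:
            w = t
        out[:, nx - n_ov:nx] = ((1.0 - w)[None, :] * img1[:, nx - n_ov:]
                                + w[None, :] * img2[:, :n_ov])
    return out
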