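"""Forward acquisition simulator: phantom + scanner config -> raw A-line data.

Signal model
------------
Each laser pulse launches a one-dimensional time-resolved pressure signal.
The depth profile of the absorption coefficient along the beam column
(weighted by a Gaussian lateral aperture matching the stated lateral
resolution) is placed at one-way arrival times ``t = z / c``, convolved with
the transducer axial impulse response (a Gaussian-modulated sinusoid at the
transducer centre frequency, with bandwidth set by the stated axial
resolution), and sampled at the digitiser rate.  The second wavelength's echo
is delayed by the inter-wavelength pulse delay, so both wavelengths share one
recorded A-line without overlapping in time.  Fluence is treated as uniform
at the focal plane and the Grueneisen coefficient is absorbed into the
(relative) amplitude units, which suffices for sO2 ratios.

The rotatory-scanning depth distortion (arc sagitta, see
:func:`hexpam.geometry.arc_sag_mm`) is injected as an extra acoustic path per
A-line, and per-facet fast-axis offsets/gains plus an in-B-scan sinusoidal
wobble emulate the facet-to-facet trajectory misalignment of a
water-immersed polygon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .geometry import ScanConfig, ScannerGeometry, arc_sag_mm
from .phantom import ChromophoreVolume, ExtinctionTable, absorption_coefficient

__all__ = [
    "ALineRecord",
    "FacetPerturbation",
    "RawScan",
    "impulse_response",
    "record_length",
    "simulate_aline",
    "simulate_scan",
    "add_noise",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class FacetPerturbation:
    """Per-facet trajectory errors injected by the simulator.

    ``offsets_um`` shifts each facet's fast-axis trajectory, ``gains``
    stretches it about the pass centre (facet size variation), and
    ``wobble_amplitude_um`` adds a slow sinusoidal fast-axis drift within
    each B-scan (water-damping wobble), with ``wobble_cycles`` periods per
    facet pass.
    """

    offsets_um: tuple
    gains: tuple
    wobble_amplitude_um: float = 0.0
    wobble_cycles: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets_um", tuple(float(v) for v in self.offsets_um))
        object.__setattr__(self, "gains", tuple(float(v) for v in self.gains))
        if len(self.offsets_um) != len(self.gains):
            raise ValueError("offsets_um and gains must have one entry per facet")
        if any(g <= 0 for g in self.gains):
            raise ValueError(f"gains must be positive, got {self.gains}")

    @classmethod
    def zero(cls, n_facets: int = 6) -> "FacetPerturbation":
        return cls(offsets_um=(0.0,) * n_facets, gains=(1.0,) * n_facets)


@dataclass
class ALineRecord:
    """One simulated time-resolved A-line with its acquisition metadata."""

    samples: np.ndarray
    channel: int
    facet_index: int
    bscan_index: int
    fast_position_mm: float
    trigger: float = 0.0


@dataclass
class RawScan:
    """Per-channel stacks of raw A-lines plus the injected ground truth.

    ``ch1``/``ch2`` are float32 arrays ``[bscan, aline, sample]``.  ``truth``
    records everything the simulator injected (per-facet offsets/gains,
    wobble, noise seed, the exact perturbed fast-axis positions and the arc
    sagitta per A-line) so that downstream estimators can be scored against
    it; it is present iff the scan was simulated.
    """

    ch1: np.ndarray
    ch2: np.ndarray
    config: ScanConfig
    geom: ScannerGeometry
    truth: dict | None = None

    def __post_init__(self) -> None:
        if self.ch1.shape != self.ch2.shape:
            raise ValueError("both channels must share a shape")

    @property
    def n_bscans(self) -> int:
        return self.ch1.shape[0]

    @property
    def facet_of_bscan(self) -> np.ndarray:
        return np.arange(self.n_bscans) % self.geom.n_facets

    def channel(self, index: int) -> np.ndarray:
        if index == 1:
            return self.ch1
        if index == 2:
            return self.ch2
        raise ValueError(f"channel must be 1 or 2, got {index}")


def impulse_response(config: ScanConfig) -> np.ndarray:
    """Transducer axial impulse response on the digitiser grid (zero-phase).

    Gaussian-modulated sinusoid whose envelope FWHM maps to the configured
    axial resolution through the speed of sound.
    """
    fs = config.digitizer_rate_MHz * 1e6
    fwhm_t = config.axial_res_um * 1e-6 / config.sound_speed_m_s
    sigma = fwhm_t / _FWHM * fs  # samples
    half = int(math.ceil(6.0 * sigma))
    k = np.arange(-half, half + 1)
    carrier = 2.0 * math.pi * config.transducer_center_MHz * 1e6 / fs
    return np.exp(-0.5 * (k / sigma) ** 2) * np.sin(carrier * k)


def _max_sag_mm(config: ScanConfig) -> float:
    wd = config.working_distance_mm
    half = config.channel_range_mm / 2.0
    return wd - math.sqrt(wd * wd - half * half)


def record_length(config: ScanConfig) -> int:
    """Number of digitiser samples per A-line.

    Covers the configured depth range, the inter-wavelength spatial
    separation, the worst-case arc sagitta, and the impulse-response tails.
    """
    span_mm = config.depth_range_mm + config.pulse_separation_mm + _max_sag_mm(config)
    kernel_half = (impulse_response(config).size - 1) // 2
    return int(math.ceil(span_mm / config.mm_per_sample)) + 2 * (kernel_half + 2) + 8


def _check_beam_inside(phantom: ChromophoreVolume, beam_xy_mm) -> None:
    vox = phantom.voxel_um * 1e-3
    x, y = beam_xy_mm
    nx, ny, _ = phantom.shape
    if not (0 <= x <= (nx - 1) * vox and 0 <= y <= (ny - 1) * vox):
        raise ValueError(
            f"beam position ({x:.3f}, {y:.3f}) mm outside phantom lateral "
            f"extent {((nx - 1) * vox, (ny - 1) * vox)} mm")


def _blur_lateral(mu: np.ndarray, config: ScanConfig, voxel_um: float) -> np.ndarray:
    sigma_vox = (config.lateral_res_um / _FWHM) / voxel_um
    return ndimage.gaussian_filter(mu, sigma=(sigma_vox, sigma_vox, 0.0))


def _sample_profiles(mu_blur: np.ndarray, x_mm: np.ndarray, y_mm: float,
                     voxel_um: float) -> np.ndarray:
    """Bilinear lateral sampling; returns depth profiles [n_alines, nz]."""
    vox = voxel_um * 1e-3
    nz = mu_blur.shape[2]
    cx = np.broadcast_to((np.asarray(x_mm) / vox)[:, None], (len(x_mm), nz))
    cy = np.full_like(cx, y_mm / vox)
    cz = np.broadcast_to(np.arange(nz, dtype=float)[None, :], cx.shape)
    return ndimage.map_coordinates(mu_blur, [cx, cy, cz], order=1, mode="constant")


def _kernel_sigma_samples(config: ScanConfig) -> float:
    fs = config.digitizer_rate_MHz * 1e6
    return config.axial_res_um * 1e-6 / config.sound_speed_m_s / _FWHM * fs


def _kernel_at(x: np.ndarray, config: ScanConfig) -> np.ndarray:
    """Impulse response evaluated at arbitrary (fractional) sample offsets.

    Truncated at six envelope sigmas, so echoes keep compact support and the
    two wavelength gates stay leak-free; the truncation level (~e^-18) is far
    below the sO2 round-trip tolerance.
    """
    sigma = _kernel_sigma_samples(config)
    carrier = (2.0 * math.pi * config.transducer_center_MHz
               / (config.digitizer_rate_MHz))
    out = np.exp(-0.5 * (x / sigma) ** 2) * np.sin(carrier * x)
    out[np.abs(x) > 6.0 * sigma] = 0.0
    return out


def _synthesis_basis(config: ScanConfig, sag_mm: np.ndarray, nz: int,
                     voxel_um: float, n_samples: int, delay_samples: float):
    """Per-voxel echo waveforms ``[aline, voxel, sample]``.

    Voxel ``i`` of A-line ``a`` arrives at ``(z_i + sag_a) / c`` (one-way
    travel; generation is at the absorber) plus the wavelength delay; the
    kernel is evaluated at that exact continuous time so that sub-sample
    delays are rendered faithfully and window energies are shift-invariant.
    """
    c_mm = config.mm_per_sample
    vox = voxel_um * 1e-3
    tau = ((np.arange(nz) * vox)[None, :] + np.asarray(sag_mm)[:, None]) / c_mm
    tau = tau + delay_samples
    k = np.arange(n_samples, dtype=float)
    return _kernel_at(k[None, None, :] - tau[:, :, None], config)


def _time_signal(p532, p558, config: ScanConfig,
                 sag_mm, voxel_um, n_samples, wavelengths=(532, 558),
                 basis: dict | None = None):
    """Superpose per-voxel echoes at t = z/c (558 delayed by the pulse lag)."""
    nz = p532.shape[1]
    na = p532.shape[0]
    sag = np.broadcast_to(np.asarray(sag_mm, dtype=float), (na,))
    acc = np.zeros((na, n_samples))
    shift = config.delay_samples
    for wl, prof, delay in ((532, p532, 0.0), (558, p558, shift)):
        if wl not in wavelengths:
            continue
        if basis is not None and wl in basis:
            B = basis[wl]
        else:
            B = _synthesis_basis(config, sag, nz, voxel_um, n_samples, delay)
        acc += np.einsum("az,azk->ak", prof, B)
    return acc


def simulate_aline(phantom: ChromophoreVolume, table: ExtinctionTable,
                   beam_xy_mm, config: ScanConfig, channel: int = 1,
                   facet_index: int = 0, bscan_index: int = 0,
                   depth_offset_mm: float = 0.0,
                   wavelengths=(532, 558)) -> ALineRecord:
    """Simulate one dual-wavelength A-line at a fixed beam position.

    ``depth_offset_mm`` adds an extra acoustic path (used by the scan
    simulator to inject the rotatory-scanning arc distortion).
    """
    _check_beam_inside(phantom, beam_xy_mm)
    mu = {wl: _blur_lateral(
        absorption_coefficient(phantom.c_hbo2, phantom.c_hbr, wl, table),
        config, phantom.voxel_um) for wl in (532, 558)}
    x, y = beam_xy_mm
    p532 = _sample_profiles(mu[532], np.array([x]), y, phantom.voxel_um)
    p558 = _sample_profiles(mu[558], np.array([x]), y, phantom.voxel_um)
    n = record_length(config)
    sig = _time_signal(p532, p558, config, [depth_offset_mm],
                       phantom.voxel_um, n, wavelengths)
    return ALineRecord(samples=sig[0], channel=channel, facet_index=facet_index,
                       bscan_index=bscan_index, fast_position_mm=float(x))


def simulate_scan(phantom: ChromophoreVolume, table: ExtinctionTable,
                  config: ScanConfig, geom: ScannerGeometry | None = None,
                  perturbation: FacetPerturbation | None = None,
                  noise_snr_db: float = np.inf, seed: int = 0,
                  wavelengths=(532, 558)) -> RawScan:
    """Raster both channels over the phantom and record raw A-line stacks.

    Channel 1 covers fast-axis [0, channel_range]; channel 2 covers
    [channel_range - overlap, effective range], so the two share the
    configured overlap band.  One B-scan per facet pass; facet index cycles
    ``bscan % n_facets``.  White Gaussian noise at ``noise_snr_db`` (np.inf
    keeps the scan noise-free); fully deterministic given ``seed``.
    """
    geom = geom or ScannerGeometry()
    perturbation = perturbation or FacetPerturbation.zero(geom.n_facets)
    if len(perturbation.offsets_um) != geom.n_facets:
        raise ValueError("perturbation must have one entry per facet")
    vox_mm = phantom.voxel_um * 1e-3
    eff = 2 * config.channel_range_mm - config.overlap_mm
    need_x = eff
    need_y = (config.n_bscans - 1) * config.slow_step_um * 1e-3
    have_x = (phantom.shape[0] - 1) * vox_mm
    have_y = (phantom.shape[1] - 1) * vox_mm
    if have_x < need_x - 1e-9 or have_y < need_y - 1e-9:
        raise ValueError(
            f"FOV exceeds phantom: need >= ({need_x:.3f}, {need_y:.3f}) mm "
            f"laterally, phantom spans ({have_x:.3f}, {have_y:.3f}) mm")
    # centre the scan region in the phantom so any spare extent becomes a
    # symmetric margin for the injected trajectory perturbations
    x0 = 0.5 * (have_x - need_x)
    y0 = 0.5 * (have_y - need_y)

    mu = {wl: _blur_lateral(
        absorption_coefficient(phantom.c_hbo2, phantom.c_hbr, wl, table),
        config, phantom.voxel_um) for wl in (532, 558)}

    na, nb = config.n_alines, config.n_bscans
    n_samples = record_length(config)
    x_nom = (np.arange(na) + 0.5) / na * config.channel_range_mm
    sag = arc_sag_mm(x_nom, config)
    offsets = np.asarray(perturbation.offsets_um) * 1e-3
    gains = np.asarray(perturbation.gains)
    wobble = (perturbation.wobble_amplitude_um * 1e-3
              * np.sin(2 * np.pi * perturbation.wobble_cycles
                       * (np.arange(na) + 0.5) / na))
    half_range = config.channel_range_mm / 2.0

    # the echo basis depends only on (aline, voxel depth), not on the B-scan
    # or channel, so build it once per wavelength
    nzv = phantom.shape[2]
    basis = {wl: _synthesis_basis(config, sag, nzv, phantom.voxel_um,
                                  n_samples, 0.0 if wl == 532
                                  else config.delay_samples)
             for wl in wavelengths}

    stacks = {1: np.empty((nb, na, n_samples), dtype=np.float32),
              2: np.empty((nb, na, n_samples), dtype=np.float32)}
    positions = np.empty((nb, na), dtype=np.float64)
    ch2_shift = config.channel_range_mm - config.overlap_mm
    for b in range(nb):
        f = b % geom.n_facets
        x_local = gains[f] * (x_nom - half_range) + half_range + offsets[f] + wobble
        positions[b] = x_local
        y = y0 + b * config.slow_step_um * 1e-3
        for ch, x_global in ((1, x0 + x_local), (2, x0 + x_local + ch2_shift)):
            if x_global.min() < -1e-9 or x_global.max() > have_x + 1e-9:
                raise ValueError(
                    f"perturbed beam positions leave the phantom on channel {ch} "
                    f"(bscan {b}); enlarge the phantom lateral extent")
            p532 = _sample_profiles(mu[532], np.clip(x_global, 0, have_x), y,
                                    phantom.voxel_um)
            p558 = _sample_profiles(mu[558], np.clip(x_global, 0, have_x), y,
                                    phantom.voxel_um)
            stacks[ch][b] = _time_signal(p532, p558, config, sag,
                                         phantom.voxel_um, n_samples,
                                         wavelengths, basis=basis)

    truth = {
        "offsets_um": np.asarray(perturbation.offsets_um),
        "gains": np.asarray(perturbation.gains),
        "wobble_amplitude_um": perturbation.wobble_amplitude_um,
        "wobble_cycles": perturbation.wobble_cycles,
        "noise_snr_db": float(noise_snr_db),
        "seed": int(seed),
        "positions_mm": positions.astype(np.float32),
        "x_nominal_mm": x_nom,
        "sag_mm": sag,
        "slow_step_um": config.slow_step_um,
    }
    if np.isfinite(noise_snr_db):
        # one noise floor for both channels (identical detection electronics),
        # referenced to the combined signal power
        power = 0.5 * (float(np.mean(np.square(stacks[1], dtype=np.float64)))
                       + float(np.mean(np.square(stacks[2], dtype=np.float64))))
        if power == 0.0:
            raise ValueError("cannot scale noise to a zero-power scan")
        sigma = math.sqrt(power * 10.0 ** (-noise_snr_db / 10.0))
        for ch, ss in zip((1, 2), np.random.SeedSequence(seed).spawn(2)):
            rng = np.random.default_rng(ss)
            stacks[ch] = (stacks[ch]
                          + sigma * rng.standard_normal(stacks[ch].shape)
                          ).astype(np.float32)
    return RawScan(ch1=stacks[1], ch2=stacks[2], config=config, geom=geom,
                   truth=truth)


def add_noise(signal_in: np.ndarray, snr_db: float, seed: int) -> np.ndarray:
    """Additive white Gaussian noise at a prescribed signal-to-noise ratio.

    ``snr_db = np.inf`` is the no-noise sentinel.  Raises on a zero-power
    signal with a finite SNR request, since the noise scale is then undefined.
    """
    signal_in = np.asarray(signal_in)
    if np.isinf(snr_db) and snr_db > 0:
        return signal_in.copy()
    if not np.isfinite(snr_db):
        raise ValueError(f"snr_db must be finite or +inf, got {snr_db}")
    power = float(np.mean(np.square(signal_in, dtype=np.float64)))
    if power == 0.0:
        raise ValueError("cannot scale noise to a zero-power signal")
    sigma = math.sqrt(power * 10.0 ** (-snr_db / 10.0))
    rng = np.random.default_rng(seed)
    return signal_in + sigma * rng.standard_normal(signal_in.shape)
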