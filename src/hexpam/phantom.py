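"""Synthetic 3-D chromophore phantoms and optical-absorption bookkeeping.

Real acquisitions image haemoglobin in living vasculature; the desk-scale
stand-ins here are voxelised oxy-/deoxy-haemoglobin concentration maps:
random-walk vessel networks with per-vessel oxygen saturation, uniform flat
slabs (test targets for depth correction), and single point absorbers (test
targets for the time-of-flight arithmetic).  Absorption follows Beer-Lambert
composition of the two chromophores, with molar extinction coefficients read
from a CSV table so that the spectra are configuration, not constants.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

LN10 = math.log(10.0)

__all__ = [
    "ChromophoreVolume",
    "ExtinctionTable",
    "PhantomSpec",
    "generate_vessel_phantom",
    "flat_target_phantom",
    "point_absorber_phantom",
    "generate",
    "absorption_coefficient",
]


@dataclass
class ChromophoreVolume:
    """Voxelised HbO2/HbR concentration maps (mol/L) on an isotropic grid.

    Arrays are indexed ``[ix, iy, iz]`` with x the fast scan axis, y the slow
    axis and z depth; ``origin_mm`` locates voxel (0, 0, 0) in scanner
    coordinates.
    """

    c_hbo2: np.ndarray
    c_hbr: np.ndarray
    voxel_um: float
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.c_hbo2 = np.asarray(self.c_hbo2, dtype=np.float64)
        self.c_hbr = np.asarray(self.c_hbr, dtype=np.float64)
        if self.c_hbo2.shape != self.c_hbr.shape:
            raise ValueError("c_hbo2 and c_hbr must share a shape")
        if self.c_hbo2.ndim != 3:
            raise ValueError("concentration grids must be 3-D")
        if self.voxel_um <= 0:
            raise ValueError(f"voxel_um must be positive, got {self.voxel_um}")
        if np.any(self.c_hbo2 < 0) or np.any(self.c_hbr < 0):
            raise ValueError("concentrations must be non-negative")
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple:
        return self.c_hbo2.shape

    @property
    def extent_mm(self) -> tuple:
        return tuple(n * self.voxel_um * 1e-3 for n in self.shape)

    @property
    def total_hb(self) -> np.ndarray:
        return self.c_hbo2 + self.c_hbr

    def so2(self, eps: float = 0.0) -> np.ndarray:
        """Per-voxel sO2 = c_HbO2 / (c_HbO2 + c_HbR); NaN where empty."""
        thb = self.total_hb
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(thb > eps, self.c_hbo2 / thb, np.nan)
        return out


class ExtinctionTable:
    """Molar extinction coefficients of HbO2 and HbR versus wavelength.

    Units are L mol^-1 cm^-1 (base-10 convention; the ln 10 factor is applied
    explicitly when composing absorption coefficients).  The shipped default
    is an approximate standard tabulated haemoglobin compilation over
    500-600 nm; replace it with your own CSV (header
    ``wavelength_nm,eps_hbo2,eps_hbr``) for quantitative work.
    """

    REQUIRED_NM = (532.0, 558.0)

    def __init__(self, table: pd.DataFrame, required_nm=REQUIRED_NM):
        cols = ["wavelength_nm", "eps_hbo2", "eps_hbr"]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"extinction table lacks columns {missing}")
        df = table[cols].astype(float).sort_values("wavelength_nm")
        if df["wavelength_nm"].duplicated().any():
            raise ValueError("extinction table wavelengths must be unique")
        if (df[["eps_hbo2", "eps_hbr"]] <= 0).any().any():
            raise ValueError("extinction coefficients must be positive")
        self.df = df.reset_index(drop=True)
        for wl in required_nm:
            self.epsilon(wl)
        if required_nm and len(required_nm) == 2:
            if abs(np.linalg.det(self.matrix(required_nm))) < 1e-12:
                raise ValueError(
                    f"extinction matrix at {required_nm} nm is singular")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ExtinctionTable":
        return cls(pd.read_csv(path), **kwargs)

    @classmethod
    def default(cls) -> "ExtinctionTable":
        ref = importlib.resources.files("hexpam") / "data/hemoglobin_extinction.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.df["wavelength_nm"].to_numpy()

    def epsilon(self, wavelength_nm: float) -> tuple:
        """(eps_HbO2, eps_HbR) at an exact tabulated wavelength."""
        hit = self.df[np.isclose(self.df["wavelength_nm"], wavelength_nm,
                                 atol=1e-6)]
        if hit.empty:
            raise KeyError(
                f"wavelength {wavelength_nm} nm not in extinction table; "
                f"available: {list(self.wavelengths_nm)}")
        row = hit.iloc[0]
        return float(row["eps_hbo2"]), float(row["eps_hbr"])

    def matrix(self, wavelengths_nm=REQUIRED_NM) -> np.ndarray:
        """Rows are wavelengths, columns (HbO2, HbR)."""
        return np.array([self.epsilon(wl) for wl in wavelengths_nm])


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a seeded synthetic phantom.

    ``so2_values`` is the per-vessel saturation assignment rule: vessel ``i``
    receives ``so2_values[i % len(so2_values)]``, so the default alternates
    artery-like (0.97) and vein-like (0.70) vessels.  ``total_hb_mol_l`` is
    the intravascular haemoglobin concentration (~2.3 mM in whole blood).
    ``depth_band_mm`` confines vessels to a shallow band compatible with the
    optical depth of focus and the inter-wavelength gating window.
    """

    kind: str = "vessels"
    extent_mm: tuple = (4.0, 2.0, 1.0)
    voxel_um: float = 20.0
    n_vessels: int = 8
    radius_um: tuple = (40.0, 120.0)
    so2_values: tuple = (0.97, 0.70)
    total_hb_mol_l: float = 2.3e-3
    depth_band_mm: tuple = (0.2, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("vessels", "flat_target", "point"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if any(e <= 0 for e in self.extent_mm):
            raise ValueError(f"extent_mm must be positive, got {self.extent_mm}")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if any(not 0.0 <= s <= 1.0 for s in self.so2_values):
            raise ValueError(f"so2 values must lie in [0, 1], got {self.so2_values}")
        if self.total_hb_mol_l < 0:
            raise ValueError("total_hb_mol_l must be >= 0")

    def to_json(self) -> str:
        return json.dumps({k: v for k, v in self.__dict__.items()})


def _grid_shape(extent_mm, voxel_um) -> tuple:
    return tuple(max(1, int(round(e * 1e3 / voxel_um))) for e in extent_mm)


def _walk_vessel(rng, spec: PhantomSpec):
    """Persistent random walk of one vessel centreline; returns points in um."""
    ex, ey, _ = (e * 1e3 for e in spec.extent_mm)
    z_lo, z_hi = (z * 1e3 for z in spec.depth_band_mm)
    step = 2.0 * spec.voxel_um
    # enter from a random edge so vessels cross the field of view
    x = rng.uniform(0, ex)
    y = rng.uniform(0, ey)
    z = rng.uniform(z_lo, z_hi)
    azimuth = rng.uniform(0, 2 * np.pi)
    n_max = int(3 * max(ex, ey) / step)
    pts = [(x, y, z)]
    for _ in range(n_max):
        azimuth += rng.normal(0.0, 0.12)
        z += rng.normal(0.0, 0.1 * step)
        if z < z_lo or z > z_hi:  # reflect back into the band
            z = np.clip(z, z_lo, z_hi)
        x += step * np.cos(azimuth)
        y += step * np.sin(azimuth)
        pts.append((x, y, z))
        if not (0 <= x <= ex and 0 <= y <= ey):
            break
    return np.asarray(pts)


def _rasterize_tube(c_hbo2, c_hbr, pts_um, radius_um, thb, so2, voxel_um):
    """Stamp an anti-aliased tube (hard support beyond its radius)."""
    shape = c_hbo2.shape
    # densify the centreline so marked voxels form a connected path
    seg = np.diff(pts_um, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    dense = [pts_um[0]]
    for p0, s, L in zip(pts_um[:-1], seg, seg_len):
        n = max(1, int(np.ceil(L / (0.5 * voxel_um))))
        for j in range(1, n + 1):
            dense.append(p0 + s * (j / n))
    dense = np.asarray(dense) / voxel_um  # voxel units
    idx = np.round(dense).astype(int)
    margin = int(np.ceil(radius_um / voxel_um)) + 2
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, shape)
    if np.any(hi <= lo):
        return
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    keep = np.all((idx >= lo) & (idx < hi), axis=1)
    idx = idx[keep] - lo
    if idx.size == 0:
        return
    marked = np.zeros(tuple(h - l for l, h in zip(lo, hi)), dtype=bool)
    marked[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~marked) * voxel_um
    w = np.clip((radius_um - dist) / voxel_um + 0.5, 0.0, 1.0)
    w[dist > radius_um] = 0.0
    c_hbo2[box] += thb * so2 * w
    c_hbr[box] += thb * (1.0 - so2) * w


def generate_vessel_phantom(spec: PhantomSpec) -> ChromophoreVolume:
    """Rasterise a seeded random vessel network into concentration maps.

    Each vessel is a persistent-random-walk tube with a radius drawn from
    ``spec.radius_um`` and a per-vessel sO2 from the assignment rule; total
    haemoglobin is uniform inside vessels and zero outside.  Deterministic
    given ``spec`` (the seed is part of the spec).
    """
    if spec.kind != "vessels":
        raise ValueError(f"spec.kind must be 'vessels', got {spec.kind!r}")
    shape = _grid_shape(spec.extent_mm, spec.voxel_um)
    c_hbo2 = np.zeros(shape)
    c_hbr = np.zeros(shape)
    rng = np.random.default_rng(spec.seed)
    for i in range(spec.n_vessels):
        pts = _walk_vessel(rng, spec)
        radius = rng.uniform(*spec.radius_um)
        so2 = spec.so2_values[i % len(spec.so2_values)]
        _rasterize_tube(c_hbo2, c_hbr, pts, radius, spec.total_hb_mol_l,
                        so2, spec.voxel_um)
    return ChromophoreVolume(c_hbo2, c_hbr, spec.voxel_um)


def flat_target_phantom(depth_mm: float, thickness_um: float, extent_mm,
                        voxel_um: float = 10.0,
                        total_hb_mol_l: float = 2.3e-3,
                        so2: float = 1.0) -> ChromophoreVolume:
    """Uniform absorbing slab at a constant physical depth."""
    shape = _grid_shape(extent_mm, voxel_um)
    z0 = int(round(depth_mm * 1e3 / voxel_um))
    nz = max(1, int(round(thickness_um / voxel_um)))
    if z0 < 0 or z0 + nz > shape[2]:
        raise ValueError(
            f"slab [{z0}, {z0 + nz}) lies outside the volume of {shape[2]} "
            f"z-voxels; enlarge extent_mm[2] or reduce depth_mm")
    c_hbo2 = np.zeros(shape)
    c_hbr = np.zeros(shape)
    c_hbo2[:, :, z0:z0 + nz] = total_hb_mol_l * so2
    c_hbr[:, :, z0:z0 + nz] = total_hb_mol_l * (1.0 - so2)
    return ChromophoreVolume(c_hbo2, c_hbr, voxel_um)


def point_absorber_phantom(position_mm, extent_mm, voxel_um: float = 10.0,
                           total_hb_mol_l: float = 2.3e-3,
                           so2: float = 1.0) -> ChromophoreVolume:
    """Single absorbing voxel at ``position_mm`` — time-of-flight test target."""
    shape = _grid_shape(extent_mm, voxel_um)
    idx = tuple(int(round(p * 1e3 / voxel_um)) for p in position_mm)
    if any(i < 0 or i >= n for i, n in zip(idx, shape)):
        raise ValueError(f"position {position_mm} mm outside extent {extent_mm} mm")
    c_hbo2 = np.zeros(shape)
    c_hbr = np.zeros(shape)
    c_hbo2[idx] = total_hb_mol_l * so2
    c_hbr[idx] = total_hb_mol_l * (1.0 - so2)
    return ChromophoreVolume(c_hbo2, c_hbr, voxel_um)


def generate(spec: PhantomSpec) -> ChromophoreVolume:
    """Dispatch on ``spec.kind`` (vessels / flat_target / point)."""
    if spec.kind == "vessels":
        return generate_vessel_phantom(spec)
    if spec.kind == "flat_target":
        return flat_target_phantom(0.4, 3 * spec.voxel_um, spec.extent_mm,
                                   spec.voxel_um, spec.total_hb_mol_l)
    return point_absorber_phantom(tuple(e / 2 for e in spec.extent_mm),
                                  spec.extent_mm, spec.voxel_um,
                                  spec.total_hb_mol_l)


def absorption_coefficient(c_hbo2, c_hbr, wavelength_nm: float,
                           table: ExtinctionTable):
    """Absorption coefficient mu_a in cm^-1 via Beer-Lambert composition.

    ``mu_a = ln(10) * (eps_HbO2(lambda) * c_HbO2 + eps_HbR(lambda) * c_HbR)``
    with concentrations in mol/L and extinction in L mol^-1 cm^-1.
    """
    e1, e2 = table.epsilon(wavelength_nm)
    return LN10 * (e1 * np.asarray(c_hbo2) + e2 * np.asarray(c_hbr))
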