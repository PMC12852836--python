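"""File-format plumbing: HDF5 raw containers, float TIFF images, JSON.

Raw simulated scans live in HDF5 (`/raw/ch1`, `/raw/ch2`, `/truth/*` with
the scan and scanner configuration as JSON attributes); phantoms in HDF5
under `/phantom`; en-face images as 32-bit float TIFF with the pixel pitch
in the resolution tags; manifests and transforms as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import time

import h5py
import numpy as np
import tifffile

from .forward import RawScan
from .geometry import ScanConfig, ScannerGeometry
from .phantom import ChromophoreVolume

__all__ = [
    "save_raw_scan", "load_raw_scan",
    "save_phantom", "load_phantom",
    "write_image_tiff", "read_image_tiff",
    "write_so2_preview",
    "load_region_mask",
    "save_json", "load_json",
    "RunManifest",
]


def _config_json(obj) -> str:
    return json.dumps(dataclasses.asdict(obj))


def save_raw_scan(path, raw: RawScan) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("raw")
        g.create_dataset("ch1", data=raw.ch1, dtype=np.float32)
        g.create_dataset("ch2", data=raw.ch2, dtype=np.float32)
        f.attrs["config"] = _config_json(raw.config)
        f.attrs["geometry"] = _config_json(raw.geom)
        if raw.truth is not None:
            t = f.create_group("truth")
            for key, val in raw.truth.items():
                if isinstance(val, np.ndarray):
                    t.create_dataset(key, data=val)
                else:
                    t.attrs[key] = val


def load_raw_scan(path) -> RawScan:
    with h5py.File(path, "r") as f:
        for name in ("raw/ch1", "raw/ch2"):
            if name not in f:
                raise ValueError(f"{path}: missing dataset /{name}")
        config = ScanConfig(**json.loads(f.attrs["config"]))
        geom = ScannerGeometry(**json.loads(f.attrs["geometry"]))
        truth = None
        if "truth" in f:
            truth = {k: f["truth"][k][()] for k in f["truth"]}
            truth.update(dict(f["truth"].attrs))
        return RawScan(ch1=f["raw/ch1"][()], ch2=f["raw/ch2"][()],
                       config=config, geom=geom, truth=truth)


def save_phantom(path, vol: ChromophoreVolume, spec_json: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("phantom")
        g.create_dataset("c_hbo2", data=vol.c_hbo2)
        g.create_dataset("c_hbr", data=vol.c_hbr)
        g.attrs["voxel_um"] = vol.voxel_um
        g.attrs["origin_mm"] = vol.origin_mm
        if spec_json is not None:
            g.attrs["spec"] = spec_json


def load_phantom(path) -> ChromophoreVolume:
    with h5py.File(path, "r") as f:
        g = f["phantom"]
        return ChromophoreVolume(c_hbo2=g["c_hbo2"][()], c_hbr=g["c_hbr"][()],
                                 voxel_um=float(g.attrs["voxel_um"]),
                                 origin_mm=tuple(g.attrs["origin_mm"]))


def write_image_tiff(path, image: np.ndarray, pixel_um: float) -> None:
    """32-bit float TIFF with the pixel pitch in the resolution tags."""
    px_per_cm = 1e4 / pixel_um
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32),
                     resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER",
                     metadata={"pixel_um": pixel_um})


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_so2_preview(path, so2: np.ndarray, mask: np.ndarray) -> None:
    """8-bit colour preview: blue (0) -> red (1); black where invalid."""
    s = np.nan_to_num(np.asarray(so2, dtype=float), nan=0.0)
    rgb = np.zeros(s.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.clip(s * 255, 0, 255)
    rgb[..., 2] = np.clip((1.0 - s) * 255, 0, 255)
    rgb[~np.asarray(mask, dtype=bool)] = 0
    tifffile.imwrite(path, rgb, photometric="rgb")


def load_region_mask(source, shape=None) -> np.ndarray:
    """Region-of-interest mask from a binary TIFF or a rectangle spec.

    ``source`` is either a path to a TIFF (nonzero pixels are inside) or a
    mapping ``{"x0": ..., "y0": ..., "width": ..., "height": ...}`` in
    pixels, rasterised onto ``shape`` (required for rectangles).
    """
    if isinstance(source, dict):
        if shape is None:
            raise ValueError("rectangle region specs need a target shape")
        mask = np.zeros(shape, dtype=bool)
        y0, x0 = int(source["y0"]), int(source["x0"])
        mask[y0:y0 + int(source["height"]), x0:x0 + int(source["width"])] = True
        if not mask.any():
            raise ValueError(f"rectangle {source} lies outside shape {shape}")
        return mask
    mask = tifffile.imread(source) != 0
    if mask.ndim != 2:
        raise ValueError(f"region mask must be 2-D, got shape {mask.shape}")
    return mask


def save_json(path, obj) -> None:
    def _default(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        raise TypeError(f"not JSON serialisable: {type(v)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


class RunManifest:
    """Reproducibility record of one pipeline run.

    Collects the configuration snapshot, seeds, package versions, per-stage
    wall times, output paths and warnings, and serialises to JSON next to
    the outputs.
    """

    def __init__(self, command: str, config_snapshot: dict, seed: int | None):
        from . import __version__
        self.data = {
            "command": command,
            "config": config_snapshot,
            "seed": seed,
            "versions": {"hexpam": __version__, "numpy": np.__version__},
            "outputs": [],
            "stages": {},
            "warnings": [],
        }
        self._t0 = time.perf_counter()

    def stage(self, name: str) -> None:
        now = time.perf_counter()
        self.data["stages"][name] = round(now - self._t0, 4)
        self._t0 = now

    def output(self, path) -> None:
        self.data["outputs"].append(str(path))

    def warn(self, message: str) -> None:
        self.data["warnings"].append(message)

    def write(self, path) -> None:
        save_json(path, self.data)
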