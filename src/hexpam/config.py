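"""Strict YAML configuration for scanner, acquisition, and simulation.

A config file has three sections — ``scanner`` (polygon geometry),
``acquisition`` (timing/sampling/FOV), and optionally ``simulation``
(phantom recipe, injected facet perturbation, noise level).  Keys carry
their units as suffixes and must match the dataclass fields exactly;
unknown keys are rejected so typos cannot silently fall back to defaults.

Two configs ship with the package: ``invivo`` mirrors the full in vivo
operating point (for timing arithmetic and reports), and ``desk`` is the
scaled-down simulation default.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .forward import FacetPerturbation
from .geometry import ScanConfig, ScannerGeometry
from .phantom import PhantomSpec

__all__ = ["RunSetup", "load_config", "save_config", "builtin_config_path"]


@dataclass
class RunSetup:
    """Everything a pipeline run needs, parsed from one YAML file."""

    geom: ScannerGeometry
    config: ScanConfig
    phantom_spec: PhantomSpec | None = None
    perturbation: FacetPerturbation | None = None
    noise_snr_db: float = np.inf

    def snapshot(self) -> dict:
        out = {
            "scanner": dataclasses.asdict(self.geom),
            "acquisition": dataclasses.asdict(self.config),
        }
        if self.phantom_spec is not None:
            sim: dict = {"phantom": dataclasses.asdict(self.phantom_spec)}
            if self.perturbation is not None:
                sim["perturbation"] = dataclasses.asdict(self.perturbation)
            sim["noise_snr_db"] = (None if np.isinf(self.noise_snr_db)
                                   else self.noise_snr_db)
            out["simulation"] = sim
        return out


def _build(cls, section: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {where!r}; "
            f"allowed: {sorted(known)}")
    section = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in section.items()}
    return cls(**section)


def load_config(path) -> RunSetup:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    allowed_top = {"scanner", "acquisition", "simulation"}
    unknown = set(doc) - allowed_top
    if unknown:
        raise ValueError(
            f"unknown top-level section(s) {sorted(unknown)}; "
            f"allowed: {sorted(allowed_top)}")
    geom = _build(ScannerGeometry, doc.get("scanner", {}) or {}, "scanner")
    config = _build(ScanConfig, doc.get("acquisition", {}) or {}, "acquisition")
    setup = RunSetup(geom=geom, config=config)
    sim = doc.get("simulation")
    if sim:
        allowed_sim = {"phantom", "perturbation", "noise_snr_db"}
        unknown = set(sim) - allowed_sim
        if unknown:
            raise ValueError(
                f"unknown key(s) {sorted(unknown)} in config section "
                f"'simulation'; allowed: {sorted(allowed_sim)}")
        if "phantom" in sim:
            setup.phantom_spec = _build(PhantomSpec, sim["phantom"] or {},
                                        "simulation.phantom")
        if "perturbation" in sim:
            setup.perturbation = _build(FacetPerturbation,
                                        sim["perturbation"] or {},
                                        "simulation.perturbation")
        snr = sim.get("noise_snr_db")
        setup.noise_snr_db = np.inf if snr is None else float(snr)
    return setup


def save_config(path, setup: RunSetup) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(setup.snapshot(), fh, sort_keys=False)


def builtin_config_path(name: str):
    """Path to a shipped configuration (``desk`` or ``invivo``)."""
    ref = importlib.resources.files("hexpam") / f"data/{name}.yaml"
    with importlib.resources.as_file(ref) as path:
        return path
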