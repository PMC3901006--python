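"""Structured run configuration (YAML) for the command-line workflow.

Schema version 1.  Top-level keys: ``paths`` (session_dir, output_dir),
``seed``, ``synth`` (session-generator parameters), ``shape_intervals``
(per-parameter [min, max, n_steps]), ``noise`` (estimation settings and
overrides) and ``pipeline`` (flags: centered, leave_one_out, dw_bounds,
end_window, L, energy, binning factors).  Every key is optional; defaults
reproduce the package's reference synthetic-session conditions.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Any

import yaml

from vsdikit.model_builder import ShapeIntervals, ShapeParams
from vsdikit.synth import SynthConfig

__all__ = ["RunConfig", "load_config", "write_provenance", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class RunConfig:
    """Parsed configuration with typed accessors for each section."""

    def __init__(self, raw: dict[str, Any] | None = None):
        self.raw = raw or {}
        version = self.raw.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema version {version} "
                f"(expected {SCHEMA_VERSION})"
            )

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def session_dir(self) -> Path:
        return Path(self.raw.get("paths", {}).get("session_dir", "session"))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw.get("paths", {}).get("output_dir", "output"))

    def synth_config(self) -> SynthConfig:
        section = dict(self.raw.get("synth", {}))
        if "shape_params" in section:
            section["shape_params"] = ShapeParams(**section["shape_params"])
        if "extra_oscillations" in section:
            section["extra_oscillations"] = tuple(
                tuple(x) for x in section["extra_oscillations"])
        if "response_amplitudes" in section:
            section["response_amplitudes"] = tuple(section["response_amplitudes"])
        if "roi_center" in section:
            section["roi_center"] = tuple(section["roi_center"])
        section.setdefault("seed", self.seed)
        return SynthConfig(**section)

    def shape_intervals(self) -> ShapeIntervals:
        section = self.raw.get("shape_intervals", {})
        kwargs = {k: tuple(v) if k != "cap" else int(v)
                  for k, v in section.items()}
        return ShapeIntervals(**kwargs)

    @property
    def noise_options(self) -> dict[str, Any]:
        section = dict(self.raw.get("noise", {}))
        section.setdefault("heart_band", (1.0, 15.0))
        section["heart_band"] = tuple(section["heart_band"])
        section.setdefault("n_harmonics", 2)
        return section

    @property
    def pipeline_options(self) -> dict[str, Any]:
        section = dict(self.raw.get("pipeline", {}))
        section.setdefault("centered", True)
        section.setdefault("leave_one_out", False)
        section.setdefault("dw_bounds", (1.5, 2.5))
        section["dw_bounds"] = tuple(section["dw_bounds"])
        section.setdefault("end_window", None)
        section.setdefault("L", None)
        section.setdefault("energy", 0.99)
        return section


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return RunConfig(raw)


def write_provenance(output_dir: str | Path, subcommand: str,
                     config: RunConfig, extra: dict | None = None) -> Path:
    """Write a JSON provenance record (config snapshot, seed, versions)."""
    import numpy
    import scipy
    import nibabel

    from vsdikit import __version__

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = {
        "subcommand": subcommand,
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": config.raw,
        "versions": {
            "vsdikit": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "nibabel": nibabel.__version__,
            "python": platform.python_version(),
        },
    }
    if extra:
        record.update(extra)
    path = out / f"provenance_{subcommand.replace('-', '_')}.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
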