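"""Configuration loading, validation and hashing for the pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .dynamics import TrunkModel
from .errors import ConfigurationError
from .femodel import LumbarGeometryParams, MaterialSpec
from .kinematics import FilterSpec
from .stressstats import ThresholdConfig
from .synthgen import ActionTemplate


def _data_text(name: str) -> str:
    return resources.files("lumbarlift.data").joinpath(name).read_text()


def load_action_templates(path=None) -> dict:
    """Shipped (or user-supplied) action templates keyed by action id."""
    raw = yaml.safe_load(Path(path).read_text() if path else _data_text("actions.yaml"))
    out = {}
    for key, spec in raw.items():
        spec = dict(spec)
        spec["peak_time_fractions"] = tuple(spec["peak_time_fractions"])
        out[key] = ActionTemplate(**spec)
    return out


def load_material_table(path=None) -> list:
    raw = yaml.safe_load(Path(path).read_text() if path else _data_text("materials.yaml"))
    return [MaterialSpec(**row) for row in raw]


def load_literature(path=None) -> tuple[dict, dict]:
    """Literature (mean, sd) pairs and the paired reference simulated values."""
    raw = yaml.safe_load(Path(path).read_text() if path else _data_text("literature.yaml"))
    lit = {k: (float(v[0]), float(v[1])) for k, v in raw["literature"].items()}
    sim = {k: float(v) for k, v in raw["reference_simulated"].items()}
    return lit, sim


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    actions: dict
    kin_filter_order: int
    kin_cutoff_hz: float
    force_filter_order: int
    force_cutoff_hz: float
    marker_hz: float
    force_hz: float
    trunk: TrunkModel
    geometry: LumbarGeometryParams
    materials: list
    vertical_load_N: float
    thresholds: ThresholdConfig
    seed: int = 0
    raw: dict = field(default_factory=dict, compare=False)

    def kin_filter(self) -> FilterSpec:
        return FilterSpec(self.kin_filter_order, self.kin_cutoff_hz, self.marker_hz)

    def force_filter(self) -> FilterSpec:
        return FilterSpec(self.force_filter_order, self.force_cutoff_hz, self.force_hz)

    def hash(self) -> str:
        """Stable hash of the configuration for run manifests."""
        payload = dict(self.raw)
        payload["seed"] = self.seed
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_REQUIRED_SECTIONS = ("filters", "sampling", "trunk", "geometry", "loads", "thresholds")


def load_config(path=None, seed: int = 0, coarse: bool = False) -> PipelineConfig:
    """Load and schema-check a YAML config (package defaults when no path).

    ``coarse`` keeps/forces the desk-scale 5 mm mesh edge regardless of the
    configured value.
    """
    raw = yaml.safe_load(Path(path).read_text() if path else _data_text("defaults.yaml"))
    missing = [s for s in _REQUIRED_SECTIONS if s not in raw]
    if missing:
        raise ConfigurationError(f"config missing section(s): {missing}")
    try:
        geo = dict(raw["geometry"])
        geo["annulus_layer_fractions"] = tuple(geo["annulus_layer_fractions"])
        if coarse:
            geo["target_edge_mm"] = max(5.0, float(geo["target_edge_mm"]))
        cfg = PipelineConfig(
            actions=load_action_templates(),
            kin_filter_order=int(raw["filters"]["kinematics"]["order"]),
            kin_cutoff_hz=float(raw["filters"]["kinematics"]["cutoff_hz"]),
            force_filter_order=int(raw["filters"]["forces"]["order"]),
            force_cutoff_hz=float(raw["filters"]["forces"]["cutoff_hz"]),
            marker_hz=float(raw["sampling"]["marker_hz"]),
            force_hz=float(raw["sampling"]["force_hz"]),
            trunk=TrunkModel(**raw["trunk"]),
            geometry=LumbarGeometryParams(**geo),
            materials=load_material_table(),
            vertical_load_N=float(raw["loads"]["vertical_load_N"]),
            thresholds=ThresholdConfig(**raw["thresholds"]),
            seed=int(seed),
            raw=raw,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid configuration: {exc}") from exc
    # filter specs validate cutoff-vs-Nyquist on construction
    cfg.kin_filter()
    cfg.force_filter()
    return cfg
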