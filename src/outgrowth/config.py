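"""Experiment configuration: defaults, named presets, and YAML/JSON loading.

Default parameter table (all overridable per config file):

==========================  =========  =====================================
parameter                   default    meaning
==========================  =========  =====================================
grid.width x grid.height    400 x 400  lattice size, pixels
grid.pixel_area             175/21     um^2 per pixel (21 px cell = 175 um^2)
dynamics.cycle_hours        26         cell-cycle duration, hours
dynamics.max_area           21         uncrowded footprint, pixels
dynamics.min_area           6          fully compressed footprint, pixels
dynamics.division_limit_*   7 / 40     divisions before senescence (normal /
                                       variant)
passaging.seed_count        1200       cells plated per passage (~20%)
passaging.trigger           0.80       confluence triggering subculture
passaging.replicates        5          independent simulations per condition
seeding.class_mix           0.0025     initial variant fraction (0.25%)
radiation (optional)        2 Gy       acute dose; alpha 0.4 / 0.02 per Gy
==========================  =========  =====================================
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .lattice import (
    DEFAULT_PIXEL_AREA,
    ConfigurationError,
    SeedingSpec,
)
from .dynamics import DynamicsParams
from .passaging import PassageConfig
from .radiation import (
    ALPHA_NORMAL_DEFAULT,
    ALPHA_VARIANT_DEFAULT,
    RadiationEvent,
)


@dataclass
class ExperimentConfig:
    """A named bundle of everything one simulation campaign needs."""

    name: str = "custom"
    grid_width: int = 400
    grid_height: int = 400
    pixel_area: float = DEFAULT_PIXEL_AREA
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    passaging: PassageConfig = field(default_factory=PassageConfig)
    seeding: SeedingSpec = field(
        default_factory=lambda: SeedingSpec(n_agents=1200, class_mix=0.0025))
    radiation: Optional[RadiationEvent] = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "seed": self.seed,
            "grid": {
                "width": self.grid_width,
                "height": self.grid_height,
                "pixel_area": self.pixel_area,
            },
            "dynamics": dataclasses.asdict(self.dynamics),
            "passaging": dataclasses.asdict(self.passaging),
            "seeding": dataclasses.asdict(self.seeding),
        }
        if self.radiation is not None:
            d["radiation"] = {
                "dose_gy": self.radiation.dose_gy,
                "time_hours": self.radiation.time_hours,
                "alphas": dict(self.radiation.alphas),
            }
        return d

    def hash(self) -> str:
        """Stable hash of the full configuration, embedded in every output."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def preset(name: str) -> ExperimentConfig:
    """Named experiment presets.

    ``coculture_validation``
        Sparse co-culture of short-lived normal cells (3-division limit) and
        unlimited variants, one week without passaging; reproduces the
        cessation of normal-cell proliferation by day 4 after an average of
        three divisions.
    ``serial_passage``
        The standard long-term scenario: 1,200 cells at 0.25% variants,
        7/40 division limits, subculture at 80% confluence; produces a
        growth plateau at ~7 cumulative population doublings followed by
        variant-driven resumption.
    ``serial_passage_irradiated``
        As ``serial_passage`` plus an acute 2 Gy exposure at plating with
        the per-class default dose-response coefficients; predicts a
        shortened plateau.
    """
    if name == "coculture_validation":
        return ExperimentConfig(
            name=name,
            dynamics=DynamicsParams(division_limit_normal=3,
                                    division_limit_variant=None),
            passaging=PassageConfig(max_passages=0, max_sim_days=7.0,
                                    replicates=5),
            seeding=SeedingSpec(n_agents=240, class_mix=0.5),
        )
    if name == "serial_passage":
        return ExperimentConfig(
            name=name,
            dynamics=DynamicsParams(division_limit_normal=7,
                                    division_limit_variant=40),
            passaging=PassageConfig(seed_count=1200, trigger_saturation=0.80,
                                    max_sim_days=60.0, replicates=5),
            seeding=SeedingSpec(n_agents=1200, class_mix=0.0025),
        )
    if name == "serial_passage_irradiated":
        cfg = preset("serial_passage")
        cfg.name = name
        cfg.radiation = RadiationEvent(
            dose_gy=2.0, time_hours=0.0,
            alphas={"normal": ALPHA_NORMAL_DEFAULT,
                    "variant": ALPHA_VARIANT_DEFAULT})
        return cfg
    raise ConfigurationError(
        f"unknown preset {name!r}; available: coculture_validation, "
        "serial_passage, serial_passage_irradiated")


PRESETS = ("coculture_validation", "serial_passage", "serial_passage_irradiated")

_SECTION_FIELDS = {
    "grid": {"width", "height", "pixel_area"},
    "dynamics": {f.name for f in dataclasses.fields(DynamicsParams)},
    "passaging": {f.name for f in dataclasses.fields(PassageConfig)},
    "seeding": {f.name for f in dataclasses.fields(SeedingSpec)},
    "radiation": {"dose_gy", "time_hours", "alphas"},
}


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build a validated config from a (possibly partial) nested mapping."""
    raw = dict(raw or {})
    known_top = {"name", "seed", "preset"} | set(_SECTION_FIELDS)
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")

    base = preset(raw["preset"]) if "preset" in raw else ExperimentConfig()

    for section, fields_ in _SECTION_FIELDS.items():
        if section not in raw:
            continue
        sub = raw[section] or {}
        bad = set(sub) - fields_
        if bad:
            raise ConfigurationError(
                f"unknown field(s) in '{section}': {sorted(bad)}")
        if section == "grid":
            base.grid_width = int(sub.get("width", base.grid_width))
            base.grid_height = int(sub.get("height", base.grid_height))
            base.pixel_area = float(sub.get("pixel_area", base.pixel_area))
            if base.grid_width <= 0 or base.grid_height <= 0:
                raise ConfigurationError("grid dimensions must be positive")
        elif section == "radiation":
            base.radiation = RadiationEvent(
                dose_gy=float(sub.get("dose_gy", 2.0)),
                time_hours=float(sub.get("time_hours", 0.0)),
                alphas=dict(sub.get("alphas", {
                    "normal": ALPHA_NORMAL_DEFAULT,
                    "variant": ALPHA_VARIANT_DEFAULT})),
            )
        else:
            current = getattr(base, section if section != "seeding" else "seeding")
            merged = {**dataclasses.asdict(current), **sub}
            cls = type(current)
            try:
                setattr(base, section, cls(**merged))
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"invalid '{section}': {exc}")

    base.name = str(raw.get("name", base.name))
    base.seed = int(raw.get("seed", base.seed))
    return base


def load_config(path) -> ExperimentConfig:
    """Load a YAML (or JSON, a YAML subset) config file; empty file = defaults."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}")
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} must contain a mapping")
    return config_from_dict(raw)
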