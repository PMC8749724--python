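"""Run configuration, the packaged reference tallies, and serialization.

The reference fixture is the published 3 x 3 condition grid of detected /
unusable counts (100 breath episodes per condition, scored with and
without IR fusion). It ships as a versioned CSV whose SHA-256 is pinned
here; a checksum mismatch is a hard failure, the counts are load-bearing
for the whole validation layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .detection import ConditionTally
from .monitor import MonitorConfig
from .synth import BreathingProtocol, NoiseModel, SensorModel

__all__ = [
    "REFERENCE_SHA256",
    "load_reference_fixture",
    "RunConfig",
    "load_config",
    "tallies_to_frame",
    "write_tallies",
    "read_tallies",
    "write_manifest",
]

REFERENCE_SHA256 = "f3479e2467a95f34e05fb268edf8d792215be8e9a226282501a4e600730f3485"

# tally CSV column layout: Angle, Displacement, Detected(no IR),
# Unusable(no IR), Detected, Unusable
_TALLY_COLUMNS = [
    "angle_deg", "displacement_um",
    "detected_no_ir", "unusable_no_ir", "detected_ir", "unusable_ir",
]


def load_reference_fixture() -> list[ConditionTally]:
    """The packaged reference condition grid, checksum-verified."""
    ref = resources.files("apneasim").joinpath("data/reference_counts.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != REFERENCE_SHA256:
        raise RuntimeError(
            f"reference fixture checksum mismatch: {digest} != {REFERENCE_SHA256}"
        )
    df = pd.read_csv(ref)
    tallies = [
        ConditionTally(
            angle_deg=float(r.angle_deg),
            displacement_um=float(r.displacement_um),
            detected_no_ir=int(r.detected_no_ir),
            unusable_no_ir=int(r.unusable_no_ir),
            detected_ir=int(r.detected_ir),
            unusable_ir=int(r.unusable_ir),
        )
        for r in df.itertuples()
    ]
    for t in tallies:
        if t.n_episodes != 100:
            raise RuntimeError("reference rows must tally 100 episodes")
    return tallies


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "protocol": BreathingProtocol,
    "noise": NoiseModel,
    "sensor": SensorModel,
    "monitor": MonitorConfig,
}


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for a reproducible run."""

    protocol: BreathingProtocol = dataclasses.field(default_factory=BreathingProtocol)
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    sensor: SensorModel = dataclasses.field(default_factory=SensorModel)
    monitor: MonitorConfig = dataclasses.field(default_factory=MonitorConfig)
    conditions: dict = dataclasses.field(
        default_factory=lambda: {
            "angles_deg": [45.0, 90.0, 135.0],
            "displacements_um": [500.0, 1000.0, 1500.0],
            "n_apneas": 3,
            "apnea_duration_s": 20.0,
            "ir_fraction": 0.5,
        }
    )
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {"protocol", "noise", "sensor", "monitor", "conditions", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for section, typ in _SECTION_TYPES.items():
            if section in data:
                sec = dict(data[section])
                names = {f.name for f in dataclasses.fields(typ)}
                bad = set(sec) - names
                if bad:
                    raise ValueError(
                        f"unknown keys in [{section}]: {sorted(bad)}"
                    )
                if "apnea_events" in sec:
                    sec["apnea_events"] = [tuple(e) for e in sec["apnea_events"]]
                kwargs[section] = typ(**sec)
        if "conditions" in data:
            base = cls().conditions
            bad = set(data["conditions"]) - set(base)
            if bad:
                raise ValueError(f"unknown keys in [conditions]: {sorted(bad)}")
            base.update(data["conditions"])
            kwargs["conditions"] = base
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load YAML or JSON config; a missing path gives the defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# Tally / report serialization
# ---------------------------------------------------------------------------

def tallies_to_frame(tallies: list[ConditionTally]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in tallies])[_TALLY_COLUMNS]


def write_tallies(tallies: list[ConditionTally], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(
            json.dumps([dataclasses.asdict(t) for t in tallies], indent=1)
        )
    else:
        tallies_to_frame(tallies).to_csv(path, index=False)


def read_tallies(path: str | Path) -> list[ConditionTally]:
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    return [
        ConditionTally(
            angle_deg=float(r["angle_deg"]),
            displacement_um=float(r["displacement_um"]),
            detected_no_ir=int(r["detected_no_ir"]),
            unusable_no_ir=int(r["unusable_no_ir"]),
            detected_ir=int(r["detected_ir"]),
            unusable_ir=int(r["unusable_ir"]),
        )
        for r in rows
    ]


def write_manifest(out_dir: str | Path, config: RunConfig, seed: int) -> Path:
    """Record everything needed to reproduce an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "apneasim",
        "version": __version__,
        "seed": int(seed),
        "config_digest": config.digest(),
        "config": config.to_dict(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
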