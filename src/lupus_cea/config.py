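"""Analysis settings, config files, and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

PACKAGE_VERSION = "0.1.0"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisSettings:
    """Design constants of the analysis.

    Defaults mirror the published design: 15-year horizon on monthly
    cycles, 3% annual discounting, $50,000/QALY willingness-to-pay,
    10,000 PSA simulations, 4-month induction, cohort starting age 41
    with 91.2% female mix, no half-cycle correction.
    """

    horizon_years: float = 15.0
    cycles_per_year: int = 12
    discount_rate: float = 0.03
    wtp: float = 50_000.0
    n_sims: int = 10_000
    seed: int = 20_260
    half_cycle_correction: bool = False
    start_age: float = 41.0
    female_fraction: float = 0.912
    induction_cycles: int = 4

    def __post_init__(self) -> None:
        if self.horizon_years < 0:
            raise ConfigError("horizon_years must be >= 0")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if self.wtp < 0:
            raise ConfigError("wtp must be >= 0")
        if self.n_sims < 1:
            raise ConfigError("n_sims must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0,1]")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years * self.cycles_per_year))


def load_settings(overrides: dict | None = None) -> AnalysisSettings:
    """Settings from a (possibly empty) override mapping."""
    overrides = overrides or {}
    valid = set(AnalysisSettings.__dataclass_fields__)
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(f"unknown settings keys: {sorted(unknown)}")
    return AnalysisSettings(**overrides)


@dataclass
class RunConfig:
    """Resolved run configuration: input paths plus settings."""

    ledger: str = "synthetic"       # path or the builtin synthetic ledger
    life_table: str = "synthetic"   # path or the builtin synthetic table
    calibrate: bool = True          # calibrate synthetic ledger to base case
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)


def load_config(path) -> RunConfig:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    cfg = RunConfig(
        ledger=raw.get("ledger", "synthetic"),
        life_table=raw.get("life_table", "synthetic"),
        calibrate=bool(raw.get("calibrate", True)),
        settings=load_settings(raw.get("settings")),
    )
    for key, label in (("ledger", "ledger"), ("life_table", "life table")):
        value = getattr(cfg, key)
        if value != "synthetic" and not Path(value).exists():
            raise ConfigError(f"{path}: {label} file not found: {value}")
    return cfg


def ledger_hash(ledger) -> str:
    """Content hash of a ledger (stable across processes)."""
    from .parameters import _spec_to_dict
    doc = json.dumps([_spec_to_dict(s) for s in ledger.specs.values()],
                     sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted alongside every run's outputs."""

    settings: dict
    ledger_sha256: str
    code_version: str
    seed: int
    started_utc: str = ""
    finished_utc: str = ""
    outputs: list[str] = field(default_factory=list)

    @classmethod
    def start(cls, settings: AnalysisSettings, ledger) -> "RunManifest":
        return cls(settings=asdict(settings), ledger_sha256=ledger_hash(ledger),
                   code_version=PACKAGE_VERSION, seed=settings.seed,
                   started_utc=datetime.now(timezone.utc).isoformat())

    def finish(self, outputs: list[str]) -> "RunManifest":
        self.finished_utc = datetime.now(timezone.utc).isoformat()
        self.outputs = [str(p) for p in outputs]
        return self

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
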