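"""Parameter ledger: definition, validation, moment-matched distributions, sampling.

Every numeric input of the cost-utility model lives in a :class:`ParameterLedger`
of named :class:`ParameterSpec` entries.  Each entry carries a base value, a
one-way sensitivity range, a sampling distribution for probabilistic
sensitivity analysis, and a free-text provenance note.  Distribution families
follow the standard assignment rule for health-economic models: beta for
probabilities and utilities, log-normal for costs and ratio-type parameters
(odds ratios, standardized mortality ratios), normal for continuous clinical
parameters, and a degenerate ``fixed`` family for design constants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: distribution families allowed per parameter role
ROLE_FAMILIES = {
    "probability": {"beta", "fixed"},
    "utility": {"beta", "fixed"},
    "cost": {"lognormal", "fixed"},
    "odds_ratio": {"lognormal", "fixed"},
    "continuous": {"normal", "fixed"},
}

#: default half-width of the one-way sensitivity range when a published
#: range is unavailable (symmetric on the parameter's natural scale)
DEFAULT_DSA_FRACTION = 0.30


class LedgerError(ValueError):
    """Raised for malformed ledgers or infeasible distribution fits."""


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one parameter.

    ``param_a``/``param_b`` are family specific: beta → (a, b) shapes;
    lognormal → (mu, sigma) on the log scale; normal → (mean, sd);
    fixed → (value, 0).
    """

    family: str
    param_a: float
    param_b: float = 0.0
    derivation: str = "direct"

    def __post_init__(self) -> None:
        if self.family not in {"beta", "lognormal", "normal", "fixed"}:
            raise LedgerError(f"unknown distribution family {self.family!r}")
        if self.family == "beta" and not (self.param_a > 0 and self.param_b > 0):
            raise LedgerError("beta shapes must be positive")
        if self.family == "lognormal" and not self.param_b > 0:
            raise LedgerError("lognormal log-scale sd must be positive")
        if self.family == "normal" and not self.param_b >= 0:
            raise LedgerError("normal sd must be non-negative")

    def mean(self) -> float:
        if self.family == "beta":
            return self.param_a / (self.param_a + self.param_b)
        if self.family == "lognormal":
            return math.exp(self.param_a + self.param_b**2 / 2.0)
        return self.param_a

    def sd(self) -> float:
        if self.family == "beta":
            a, b = self.param_a, self.param_b
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
        if self.family == "lognormal":
            s2 = self.param_b**2
            return self.mean() * math.sqrt(math.expm1(s2))
        if self.family == "normal":
            return self.param_b
        return 0.0

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.param_a, self.param_b, size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.param_a, self.param_b, size=size)
        if self.family == "normal":
            return rng.normal(self.param_a, self.param_b, size=size)
        return self.param_a if size is None else np.full(size, self.param_a)


def fit_beta_from_moments(mean: float, se: float) -> DistributionSpec:
    """Beta spec matching a reported mean and standard error.

    Uses the method of moments: with k = mean(1-mean)/se^2 - 1, the shapes
    are a = mean*k and b = (1-mean)*k.  Infeasible standard errors
    (se^2 >= mean(1-mean)) have no beta representation.
    """
    if not 0.0 < mean < 1.0:
        raise LedgerError(f"beta fit needs mean in (0,1), got {mean}")
    if se <= 0:
        raise LedgerError(f"beta fit needs se > 0, got {se}")
    v = se * se
    if v >= mean * (1.0 - mean):
        raise LedgerError(
            f"se {se} infeasible for beta with mean {mean}: "
            "se^2 must be < mean*(1-mean); widen or clip the reported se"
        )
    k = mean * (1.0 - mean) / v - 1.0
    return DistributionSpec("beta", mean * k, (1.0 - mean) * k,
                            derivation="moment-matched-from-mean-se")


def fit_lognormal_from_moments(mean: float, se: float) -> DistributionSpec:
    """Log-normal spec whose arithmetic mean/sd match the inputs.

    sigma^2 = ln(1 + se^2/mean^2), mu = ln(mean) - sigma^2/2.
    A vanishing se degenerates to a fixed value.
    """
    if mean <= 0:
        raise LedgerError(f"lognormal fit needs mean > 0, got {mean}")
    if se < 0:
        raise LedgerError(f"lognormal fit needs se >= 0, got {se}")
    if se == 0:
        return DistributionSpec("fixed", mean, derivation="moment-matched-from-mean-se")
    s2 = math.log1p((se / mean) ** 2)
    return DistributionSpec("lognormal", math.log(mean) - s2 / 2.0, math.sqrt(s2),
                            derivation="moment-matched-from-mean-se")


def fit_normal_from_moments(mean: float, se: float) -> DistributionSpec:
    if se < 0:
        raise LedgerError("normal fit needs se >= 0")
    return DistributionSpec("normal", mean, se, derivation="moment-matched-from-mean-se")


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input with value, range, distribution and provenance.

    ``time_profile`` is an optional piecewise-constant multiplier path,
    a sequence of ``(year, multiplier)`` anchors applied on top of the
    (possibly sampled) scalar value.
    """

    name: str
    role: str
    base_value: float
    low: float | None = None
    high: float | None = None
    distribution: DistributionSpec | None = None
    units: str = ""
    time_profile: tuple[tuple[float, float], ...] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLE_FAMILIES:
            raise LedgerError(f"{self.name}: unknown role {self.role!r}")
        low, high = self.low, self.high
        if low is None or high is None:
            low, high = default_dsa_range(self.role, self.base_value)
            object.__setattr__(self, "low", low)
            object.__setattr__(self, "high", high)
        if self.distribution is None:
            object.__setattr__(self, "distribution",
                               DistributionSpec("fixed", self.base_value))
        if self.time_profile is not None:
            prof = tuple((float(y), float(m)) for y, m in self.time_profile)
            if any(prof[i][0] >= prof[i + 1][0] for i in range(len(prof) - 1)):
                raise LedgerError(f"{self.name}: time_profile years must increase")
            object.__setattr__(self, "time_profile", prof)

    def violations(self) -> list[str]:
        """Range and role/distribution consistency problems, as messages."""
        out = []
        if not self.low <= self.base_value <= self.high:
            out.append(f"{self.name}: base_value {self.base_value} outside "
                       f"[low, high] = [{self.low}, {self.high}]")
        if self.role == "probability" and not (0.0 <= self.low and self.high <= 1.0):
            out.append(f"{self.name}: probability range must lie in [0,1]")
        if self.role == "probability" and not 0.0 <= self.base_value <= 1.0:
            out.append(f"{self.name}: probability base_value outside [0,1]")
        if self.role == "cost" and self.low < 0:
            out.append(f"{self.name}: cost low must be >= 0")
        if self.distribution.family not in ROLE_FAMILIES[self.role]:
            out.append(f"{self.name}: role {self.role} does not admit a "
                       f"{self.distribution.family} distribution")
        return out

    def multiplier_at(self, year: float) -> float:
        """Piecewise-constant time-profile multiplier at a given model year."""
        if not self.time_profile:
            return 1.0
        mult = self.time_profile[0][1]
        for y, m in self.time_profile:
            if year >= y:
                mult = m
            else:
                break
        return mult


def default_dsa_range(role: str, base: float) -> tuple[float, float]:
    """±30% range on the natural scale, clipped to the role's support."""
    lo = base * (1.0 - DEFAULT_DSA_FRACTION)
    hi = base * (1.0 + DEFAULT_DSA_FRACTION)
    if base < 0:
        lo, hi = hi, lo
    if role in ("probability", "utility"):
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    if role == "cost":
        lo = max(lo, 0.0)
    return lo, hi


@dataclass
class ValidationReport:
    missing: list[str] = field(default_factory=list)
    range_violations: list[str] = field(default_factory=list)
    role_mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing or self.range_violations or self.role_mismatches)

    def __bool__(self) -> bool:
        return self.ok

    def summary(self) -> str:
        if self.ok:
            return "ledger OK"
        lines = []
        for label, items in (("missing", self.missing),
                             ("range", self.range_violations),
                             ("role/distribution", self.role_mismatches)):
            lines += [f"[{label}] {m}" for m in items]
        return "\n".join(lines)


@dataclass
class ParameterLedger:
    """Ordered collection of parameter specs; single source of model numbers."""

    specs: dict[str, ParameterSpec]
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        for name, spec in self.specs.items():
            if name != spec.name:
                raise LedgerError(f"ledger key {name!r} != spec name {spec.name!r}")

    def __len__(self) -> int:
        return len(self.specs)

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def __getitem__(self, name: str) -> ParameterSpec:
        return self.specs[name]

    def names(self) -> list[str]:
        return list(self.specs)

    def with_values(self, updates: dict[str, float]) -> "ParameterLedger":
        """New ledger with selected base values replaced (ranges kept)."""
        specs = dict(self.specs)
        for name, value in updates.items():
            if name not in specs:
                raise LedgerError(f"unknown parameter {name!r}")
            specs[name] = replace(specs[name], base_value=float(value))
        return ParameterLedger(specs, self.schema_version)

    def base_parameter_set(self) -> "ParameterSet":
        values = {n: s.base_value for n, s in self.specs.items()}
        return ParameterSet(values, label="base_case",
                            profiles=_profiles_of(self))


def _profiles_of(ledger: ParameterLedger) -> dict[str, tuple[tuple[float, float], ...]]:
    return {n: s.time_profile for n, s in ledger.specs.items() if s.time_profile}


@dataclass
class ParameterSet:
    """One concrete numeric assignment (base case, PSA draw, or DSA setting)."""

    values: dict[str, float]
    label: str = "base_case"
    draw_index: int | None = None
    profiles: dict[str, tuple[tuple[float, float], ...]] = field(default_factory=dict)
    n_clipped: int = 0

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def at(self, name: str, year: float) -> float:
        """Scalar value times the parameter's time-profile multiplier."""
        v = self.values[name]
        prof = self.profiles.get(name)
        if not prof:
            return v
        mult = prof[0][1]
        for y, m in prof:
            if year >= y:
                mult = m
            else:
                break
        return v * mult


def validate_ledger(ledger: ParameterLedger, required: set[str] | frozenset[str] = frozenset()
                    ) -> ValidationReport:
    """Report missing required names, range violations and role mismatches."""
    report = ValidationReport()
    report.missing = sorted(set(required) - set(ledger.specs))
    for spec in ledger.specs.values():
        for msg in spec.violations():
            if "does not admit" in msg:
                report.role_mismatches.append(msg)
            else:
                report.range_violations.append(msg)
    return report


def draw_parameter_set(ledger: ParameterLedger, rng: np.random.Generator,
                       draw_index: int | None = None) -> ParameterSet:
    """One independent draw of every parameter from its distribution.

    Probability-role draws that land outside [0,1] through floating-point
    effects are clipped and counted on the returned set; fixed-family
    parameters pass through unchanged.  Draw order is ledger order, so the
    result is a pure function of (ledger, rng state).
    """
    values: dict[str, float] = {}
    n_clipped = 0
    for name, spec in ledger.specs.items():
        v = float(spec.distribution.sample(rng))
        if spec.role in ("probability", "utility") and not 0.0 <= v <= 1.0:
            logger.warning("clipping out-of-support draw %s=%r to [0,1]", name, v)
            v = min(max(v, 0.0), 1.0)
            n_clipped += 1
        values[name] = v
    return ParameterSet(values, label="psa_draw", draw_index=draw_index,
                        profiles=_profiles_of(ledger), n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# serialization

def _spec_to_dict(spec: ParameterSpec) -> dict:
    d = {
        "name": spec.name,
        "role": spec.role,
        "base_value": spec.base_value,
        "low": spec.low,
        "high": spec.high,
        "units": spec.units,
        "distribution": {
            "family": spec.distribution.family,
            "param_a": spec.distribution.param_a,
            "param_b": spec.distribution.param_b,
            "derivation": spec.distribution.derivation,
        },
        "provenance": spec.provenance,
    }
    if spec.time_profile:
        d["time_profile"] = [[y, m] for y, m in spec.time_profile]
    return d


def _spec_from_dict(d: dict) -> ParameterSpec:
    try:
        name = d["name"]
    except KeyError:
        raise LedgerError("ledger entry without a name") from None
    dist = None
    dd = d.get("distribution")
    if dd is not None:
        try:
            if "mean" in dd:  # moment-parameterised shorthand
                fit = {"beta": fit_beta_from_moments,
                       "lognormal": fit_lognormal_from_moments,
                       "normal": fit_normal_from_moments}[dd["family"]]
                dist = fit(float(dd["mean"]), float(dd["se"]))
            elif dd["family"] == "fixed":
                dist = DistributionSpec("fixed", float(dd.get("param_a", d["base_value"])))
            else:
                dist = DistributionSpec(dd["family"], float(dd["param_a"]),
                                        float(dd.get("param_b", 0.0)),
                                        dd.get("derivation", "direct"))
        except (KeyError, LedgerError) as exc:
            raise LedgerError(f"{name}: bad distribution block: {exc}") from None
    profile = d.get("time_profile")
    if profile is not None:
        profile = tuple((float(y), float(m)) for y, m in profile)
    try:
        return ParameterSpec(
            name=name,
            role=d["role"],
            base_value=float(d["base_value"]),
            low=None if d.get("low") is None else float(d["low"]),
            high=None if d.get("high") is None else float(d["high"]),
            distribution=dist,
            units=d.get("units", ""),
            time_profile=profile,
            provenance=d.get("provenance", ""),
        )
    except (KeyError, TypeError, LedgerError) as exc:
        raise LedgerError(f"parameter {name!r}: {exc}") from None


def load_ledger(path) -> ParameterLedger:
    """Load a YAML/JSON ledger file; applies range/distribution defaulting."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise LedgerError(f"ledger file not found: {path}") from None
    if not isinstance(raw, dict) or "parameters" not in raw:
        raise LedgerError(f"{path}: expected a mapping with a 'parameters' list")
    specs: dict[str, ParameterSpec] = {}
    for entry in raw["parameters"]:
        spec = _spec_from_dict(entry)
        if spec.name in specs:
            raise LedgerError(f"duplicate parameter name {spec.name!r}")
        specs[spec.name] = spec
    return ParameterLedger(specs, raw.get("schema_version", SCHEMA_VERSION))


def save_ledger(ledger: ParameterLedger, path) -> None:
    doc = {"schema_version": ledger.schema_version,
           "parameters": [_spec_to_dict(s) for s in ledger.specs.values()]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
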