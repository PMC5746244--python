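"""Model-input parameters, their ranges, and the YAML parameter-set dialect.

Every uncertain model input is a :class:`ParameterRange`: a named quantity
with literature-derived ``[low, high]`` bounds, a unit string, and a *kind*
that fixes its physical domain (a probability lives in [0, 1], a rate or a
count is non-negative).  Parameter sets are stored one-per-intervention in
small human-editable YAML files::

    intervention: influenza_seniors
    parameters:
      - name: mortality_rate_65plus
        low: 9.4
        high: 15.6
        units: per 100,000 person-years
        kind: rate_per_100k

A degenerate range with ``low == high`` is legal and encodes a fixed
constant (e.g. a cohort size).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "ParameterKind",
    "DistributionKind",
    "ParameterRange",
    "SimulationConfig",
    "ParameterDraw",
    "ParameterParseError",
    "ParameterValidationError",
    "read_parameter_set",
    "write_parameter_set",
    "validate_parameter_set",
    "missing_parameters",
    "builtin_parameter_set_path",
]


def builtin_parameter_set_path(name: str = "influenza_50plus") -> Path:
    """Path of a parameter-set file shipped with the package."""
    from importlib import resources

    return Path(resources.files("cpbsim").joinpath(f"data/{name}.params.yaml"))  # type: ignore[arg-type]


class ParameterParseError(ValueError):
    """A parameter-set file does not conform to the documented schema."""


class ParameterValidationError(ValueError):
    """A parameter range (or set of ranges) violates a domain invariant."""


class ParameterKind(str, Enum):
    """Physical domain of a model input."""

    PROBABILITY = "probability"
    RATE_PER_100K = "rate_per_100k"
    COUNT = "count"
    QALY_WEIGHT = "qaly_weight"

    @property
    def domain(self) -> tuple[float, float]:
        """Hard bounds any sampled value of this kind must respect."""
        if self in (ParameterKind.PROBABILITY, ParameterKind.QALY_WEIGHT):
            return (0.0, 1.0)
        return (0.0, float("inf"))


class DistributionKind(str, Enum):
    """Sampling distribution placed over a parameter's range.

    ``uniform`` spreads probability evenly over ``[low, high]``.
    ``normal_matched`` is a Gaussian whose mean and variance equal those of
    that uniform distribution (mean ``(low+high)/2``, sd ``(high-low)/sqrt(12)``),
    used as a distributional-sensitivity check.
    """

    UNIFORM = "uniform"
    NORMAL_MATCHED = "normal_matched"


#: One sampled value (or a vector of values, one per Monte Carlo iteration)
#: for every named parameter.
ParameterDraw = Mapping[str, Union[float, np.ndarray]]


@dataclass(frozen=True)
class ParameterRange:
    """A named model input with ``[low, high]`` bounds.

    Raises :class:`ParameterValidationError` on construction if ``low > high``
    or the bounds leave the kind's physical domain.
    """

    name: str
    low: float
    high: float
    units: str = ""
    kind: ParameterKind = ParameterKind.PROBABILITY

    def __post_init__(self) -> None:
        if not self.name:
            raise ParameterValidationError("parameter name must be non-empty")
        object.__setattr__(self, "kind", ParameterKind(self.kind))
        object.__setattr__(self, "low", float(self.low))
        object.__setattr__(self, "high", float(self.high))
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ParameterValidationError(
                f"{self.name}: bounds must be finite, got [{self.low}, {self.high}]"
            )
        if self.low > self.high:
            raise ParameterValidationError(
                f"{self.name}: low ({self.low}) exceeds high ({self.high})"
            )
        lo, hi = self.kind.domain
        if self.low < lo or self.high > hi:
            raise ParameterValidationError(
                f"{self.name}: bounds [{self.low}, {self.high}] leave the "
                f"{self.kind.value} domain [{lo}, {hi}]"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def is_point_mass(self) -> bool:
        return self.low == self.high

    def clamp(self, values):
        """Clip value(s) to this parameter's physical domain (not its range)."""
        lo, hi = self.kind.domain
        return np.clip(values, lo, hi)

    def collapsed(self, value: float | None = None) -> "ParameterRange":
        """A point-mass copy at ``value`` (default: the range midpoint)."""
        v = self.midpoint if value is None else float(value)
        return replace(self, low=v, high=v)


@dataclass(frozen=True)
class SimulationConfig:
    """How a Monte Carlo run is executed and summarised.

    ``n_iterations`` defaults to 10**6, the scale at which estimates of this
    kind are fully converged (they stabilise from ~10**4 draws).
    """

    n_iterations: int = 1_000_000
    seed: int = 0
    input_distribution: DistributionKind = DistributionKind.UNIFORM
    quantile_levels: tuple[float, float] = (0.025, 0.975)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "input_distribution", DistributionKind(self.input_distribution)
        )
        if self.n_iterations < 1:
            raise ParameterValidationError("n_iterations must be positive")
        lo, hi = self.quantile_levels
        if not (0.0 < lo < hi < 1.0):
            raise ParameterValidationError(
                f"quantile levels must satisfy 0 < lo < hi < 1, got ({lo}, {hi})"
            )


_REQUIRED_FIELDS = ("name", "low", "high")


def _parse_entry(entry: object, index: int) -> ParameterRange:
    if not isinstance(entry, Mapping):
        raise ParameterParseError(f"parameter entry #{index} is not a mapping")
    for fld in _REQUIRED_FIELDS:
        if fld not in entry:
            raise ParameterParseError(
                f"parameter entry #{index} is missing required field '{fld}'"
            )
    for fld in ("low", "high"):
        try:
            float(entry[fld])
        except (TypeError, ValueError):
            raise ParameterParseError(
                f"parameter '{entry.get('name', index)}': field '{fld}' "
                f"is not a number ({entry[fld]!r})"
            ) from None
    kind = entry.get("kind", ParameterKind.PROBABILITY.value)
    try:
        kind = ParameterKind(kind)
    except ValueError:
        raise ParameterParseError(
            f"parameter '{entry['name']}': field 'kind' has unknown value "
            f"{kind!r} (expected one of {[k.value for k in ParameterKind]})"
        ) from None
    return ParameterRange(
        name=str(entry["name"]),
        low=float(entry["low"]),
        high=float(entry["high"]),
        units=str(entry.get("units", "")),
        kind=kind,
    )


def read_parameter_set(path: str | Path) -> list[ParameterRange]:
    """Read and validate a parameter-set YAML file.

    Round-trips losslessly through :func:`write_parameter_set`.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "parameters" not in doc:
        raise ParameterParseError(
            f"{path}: expected a mapping with a 'parameters' list"
        )
    entries = doc["parameters"]
    if not isinstance(entries, Sequence):
        raise ParameterParseError(f"{path}: 'parameters' is not a list")
    return [_parse_entry(e, i) for i, e in enumerate(entries)]


def write_parameter_set(
    ranges: Iterable[ParameterRange],
    path: str | Path,
    intervention: str | None = None,
) -> None:
    """Write ranges to the YAML parameter-set dialect."""
    doc: dict = {}
    if intervention is not None:
        doc["intervention"] = intervention
    doc["parameters"] = [
        {
            "name": r.name,
            "low": r.low,
            "high": r.high,
            "units": r.units,
            "kind": r.kind.value,
        }
        for r in ranges
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def missing_parameters(
    ranges: Iterable[ParameterRange], required: Iterable[str]
) -> list[str]:
    """Required names not present in ``ranges`` (order preserved)."""
    have = {r.name for r in ranges}
    return [name for name in required if name not in have]


def validate_parameter_set(
    ranges: Sequence[ParameterRange], required: Iterable[str] = ()
) -> bool:
    """True iff every required name appears exactly once and invariants hold.

    Range invariants are enforced at construction; this adds the set-level
    checks.  Duplicate names raise :class:`ParameterValidationError` listing
    the duplicates; missing required names simply yield ``False`` (use
    :func:`missing_parameters` for the report).  Order-independent.
    """
    names = [r.name for r in ranges]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ParameterValidationError(f"duplicate parameter names: {dupes}")
    return not missing_parameters(ranges, required)
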