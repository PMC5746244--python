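"""Deterministic clinically-preventable-burden (CPB) chain for a birth cohort.

The model follows the standard CPB accounting used for preventive services
such as influenza vaccination.  A hypothetical birth cohort (default four
million persons) is followed over its lifetime; within each age stratum the
chain per event channel (mortality / hospitalization / illness) is:

1. *attributable events*: incidence (per 100,000 person-years) times the
   stratum's person-years gives the current annual burden;
2. *counterfactual burden*: the burden had nobody received the intervention,
   back-calculated as ``current / (1 - coverage * efficacy)`` from the
   population's current uptake;
3. *effectiveness*: offering the intervention to everyone only averts events
   in the fraction that accepts it, so effectiveness = adherence * efficacy;
4. *prevented events*: counterfactual burden times effectiveness;
5. *QALYs saved*: each prevented death counts a full 1 QALY; prevented
   morbidity events are weighted by a health-utility decrement in [0, 1];
6. the cohort total is scaled to QALYs per 10**3 interventions delivered.

Strata are independent (no transmission effects) and are summed.  Every
operation accepts scalars or numpy arrays, so a whole Monte Carlo batch can
flow through the chain at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import yaml

from .params import ParameterDraw

__all__ = [
    "EventChannel",
    "AgeStratum",
    "CohortSpec",
    "CpbResult",
    "CpbDomainError",
    "ModelConfigurationError",
    "attributable_events",
    "counterfactual_burden",
    "effectiveness",
    "prevented_events",
    "qalys_saved",
    "qalys_per_1e3",
    "run_cpb",
    "read_cohort_model",
    "write_cohort_model",
    "builtin_model_path",
]

#: Either a literal constant or the name of a parameter in the draw.
ParamRef = Union[str, float, int]

_CHANNEL_NAMES = ("mortality", "hospitalization", "illness")
_DENOMINATORS = ("delivered", "offered", "cohort")


class CpbDomainError(ValueError):
    """An input left the physical domain of a CPB operation."""


class ModelConfigurationError(KeyError):
    """A cohort model references a parameter absent from the draw."""


# ---------------------------------------------------------------------------
# elementary operations


def attributable_events(rate_per_100k, person_years):
    """Annual events attributable to the condition.

    ``rate_per_100k / 100,000 * person_years``; e.g. a mortality rate of
    12.5 per 100,000 over ~50 million senior person-years gives 6,250 deaths.
    """
    rate_per_100k = np.asarray(rate_per_100k, dtype=float)
    person_years = np.asarray(person_years, dtype=float)
    if np.any(rate_per_100k < 0) or np.any(person_years < 0):
        raise CpbDomainError("rate and person-years must be non-negative")
    out = rate_per_100k / 100_000.0 * person_years
    return out if out.ndim else float(out)


def counterfactual_burden(current_events, coverage, efficacy):
    """Events that would occur if nobody received the intervention.

    Back-calculates ``current / (1 - coverage * efficacy)``: the observed
    burden is what remains after the currently-covered fraction has had its
    preventable share removed.
    """
    current_events = np.asarray(current_events, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    efficacy = np.asarray(efficacy, dtype=float)
    if np.any(current_events < 0):
        raise CpbDomainError("current events must be non-negative")
    averted = coverage * efficacy
    if np.any(averted < 0) or np.any(averted >= 1):
        raise CpbDomainError(
            "coverage * efficacy must lie in [0, 1); the back-calculation "
            "diverges as it approaches 1"
        )
    out = current_events / (1.0 - averted)
    return out if out.ndim else float(out)


def effectiveness(adherence, efficacy):
    """Realised protective fraction when the intervention is offered to all.

    Only adherent recipients are protected, so this is adherence * efficacy.
    """
    adherence = np.asarray(adherence, dtype=float)
    efficacy = np.asarray(efficacy, dtype=float)
    for name, v in (("adherence", adherence), ("efficacy", efficacy)):
        if np.any(v < 0) or np.any(v > 1):
            raise CpbDomainError(f"{name} must lie in [0, 1]")
    out = adherence * efficacy
    return out if out.ndim else float(out)


def prevented_events(counterfactual, eff):
    """Counterfactual events averted by offering the intervention."""
    counterfactual = np.asarray(counterfactual, dtype=float)
    eff = np.asarray(eff, dtype=float)
    if np.any(counterfactual < 0) or np.any(eff < 0) or np.any(eff > 1):
        raise CpbDomainError(
            "counterfactual must be non-negative and effectiveness in [0, 1]"
        )
    out = counterfactual * eff
    return out if out.ndim else float(out)


def qalys_saved(prevented: Mapping[str, object], weights: Mapping[str, object]):
    """Sum channel-wise ``prevented * weight``.

    Mortality carries a full weight of 1 QALY per prevented death; morbidity
    channels use a utility decrement for the time patients would be sick.
    """
    total = 0.0
    for channel, n in prevented.items():
        w = np.asarray(weights[channel], dtype=float)
        if channel == "mortality" and np.any(w != 1.0):
            raise CpbDomainError("mortality QALY weight must be exactly 1")
        if np.any(w < 0):
            raise CpbDomainError(f"{channel}: QALY weight must be non-negative")
        total = total + np.asarray(n, dtype=float) * w
    total = np.asarray(total, dtype=float)
    return total if total.ndim else float(total)


def qalys_per_1e3(total_qalys, n_interventions):
    """Scale cohort QALYs to the reporting unit, QALYs per 10**3 interventions."""
    total_qalys = np.asarray(total_qalys, dtype=float)
    n_interventions = np.asarray(n_interventions, dtype=float)
    if np.any(n_interventions <= 0):
        raise CpbDomainError("n_interventions must be positive")
    out = total_qalys / n_interventions * 1000.0
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# model definition


@dataclass(frozen=True)
class EventChannel:
    """One burden pathway within a stratum.

    ``incidence`` names the rate-per-100,000 parameter; ``efficacy`` the
    channel-specific protective efficacy; ``qaly_weight`` is a parameter name
    or a constant (the mortality channel must use the constant 1).
    """

    name: str
    incidence: ParamRef
    efficacy: ParamRef
    qaly_weight: ParamRef = 1.0

    def __post_init__(self) -> None:
        if self.name not in _CHANNEL_NAMES:
            raise ModelConfigurationError(
                f"unknown channel {self.name!r}; expected one of {_CHANNEL_NAMES}"
            )
        if self.name == "mortality" and self.qaly_weight != 1.0:
            raise CpbDomainError("mortality channel QALY weight must be 1")


@dataclass(frozen=True)
class AgeStratum:
    """An age band of the cohort with its own coverage and burden channels."""

    label: str
    person_years: ParamRef
    coverage: ParamRef
    channels: tuple[EventChannel, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))


@dataclass(frozen=True)
class CohortSpec:
    """A birth-cohort CPB model.

    ``denominator`` fixes what counts as one intervention when scaling to
    QALYs per 10**3 interventions: ``delivered`` (person-years offered times
    adherence — a delivered service; the default), ``offered`` (person-years
    offered), or ``cohort`` (birth-cohort size).
    """

    name: str
    adherence: ParamRef
    strata: tuple[AgeStratum, ...]
    birth_cohort_size: float = 4_000_000.0
    denominator: str = "delivered"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))
        if self.birth_cohort_size <= 0:
            raise CpbDomainError("birth cohort size must be positive")
        if self.denominator not in _DENOMINATORS:
            raise ModelConfigurationError(
                f"unknown denominator {self.denominator!r}; "
                f"expected one of {_DENOMINATORS}"
            )
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise ModelConfigurationError(f"strata labels overlap: {labels}")

    def parameter_names(self) -> set[str]:
        """All parameter names the model consumes from a draw."""
        names: set[str] = set()
        refs: list[ParamRef] = [self.adherence]
        for s in self.strata:
            refs += [s.person_years, s.coverage]
            for c in s.channels:
                refs += [c.incidence, c.efficacy, c.qaly_weight]
        for r in refs:
            if isinstance(r, str):
                names.add(r)
        return names

    def evaluate(self, draw: ParameterDraw):
        """QALYs per 10**3 interventions for one draw (scalar or vectorised)."""
        return run_cpb(self, draw).qalys_per_1e3


@dataclass
class CpbResult:
    """Outcome of one pass through the CPB chain.

    Per-(stratum, channel) event counts plus the cohort totals.  All fields
    are scalars for a scalar draw, or arrays of length n for a vectorised one.
    """

    current_events: dict[tuple[str, str], object]
    counterfactual_events: dict[tuple[str, str], object]
    prevented_events: dict[tuple[str, str], object]
    total_qalys: object
    n_interventions: object
    qalys_per_1e3: object


def _resolve(draw: ParameterDraw, ref: ParamRef, context: str):
    if isinstance(ref, str):
        try:
            return np.asarray(draw[ref], dtype=float)
        except KeyError:
            raise ModelConfigurationError(
                f"{context}: draw is missing parameter {ref!r}"
            ) from None
    return np.asarray(float(ref))


def run_cpb(model: CohortSpec, draw: ParameterDraw) -> CpbResult:
    """Run the full CPB chain for one parameter draw.

    Deterministic for a fixed draw, and exactly the composition of the six
    elementary operations per stratum and channel.
    """
    adherence = _resolve(draw, model.adherence, model.name)
    current: dict[tuple[str, str], object] = {}
    counterfactual: dict[tuple[str, str], object] = {}
    prevented: dict[tuple[str, str], object] = {}
    total_q = 0.0
    offered = 0.0
    for stratum in model.strata:
        ctx = f"{model.name}/{stratum.label}"
        py = _resolve(draw, stratum.person_years, ctx)
        cov = _resolve(draw, stratum.coverage, ctx)
        offered = offered + py
        for ch in stratum.channels:
            key = (stratum.label, ch.name)
            rate = _resolve(draw, ch.incidence, f"{ctx}/{ch.name}")
            eff_c = _resolve(draw, ch.efficacy, f"{ctx}/{ch.name}")
            w = _resolve(draw, ch.qaly_weight, f"{ctx}/{ch.name}")
            cur = attributable_events(rate, py)
            cf = counterfactual_burden(cur, cov, eff_c)
            prev = prevented_events(cf, effectiveness(adherence, eff_c))
            current[key] = cur
            counterfactual[key] = cf
            prevented[key] = prev
            total_q = total_q + qalys_saved({ch.name: prev}, {ch.name: w})
    if model.denominator == "delivered":
        n_int = offered * adherence
    elif model.denominator == "offered":
        n_int = offered * np.ones_like(np.asarray(adherence, dtype=float))
    else:  # cohort
        n_int = model.birth_cohort_size * np.ones_like(
            np.asarray(adherence, dtype=float)
        )
    total_q = np.asarray(total_q, dtype=float)
    n_arr = np.asarray(n_int, dtype=float)
    # zero adherence delivers no interventions and saves no QALYs: the rate
    # is 0 by convention, not a 0/0 domain error
    if np.any((n_arr <= 0) & (total_q > 0)):
        raise CpbDomainError("positive QALYs with no interventions delivered")
    if np.all(n_arr > 0):
        rate_out = qalys_per_1e3(total_q, n_arr)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            rate_out = np.where(n_arr > 0, total_q / np.where(n_arr > 0, n_arr, 1.0) * 1000.0, 0.0)
        rate_out = rate_out if rate_out.ndim else float(rate_out)
    return CpbResult(
        current_events=current,
        counterfactual_events=counterfactual,
        prevented_events=prevented,
        total_qalys=total_q if total_q.ndim else float(total_q),
        n_interventions=n_int if np.asarray(n_int).ndim else float(n_int),
        qalys_per_1e3=rate_out,
    )


# ---------------------------------------------------------------------------
# model file I/O


def builtin_model_path(name: str = "influenza_50plus") -> Path:
    """Path of a cohort-model file shipped with the package."""
    from importlib import resources

    return Path(resources.files("cpbsim").joinpath(f"data/{name}.model.yaml"))  # type: ignore[arg-type]


def _ref_from_yaml(v: object) -> ParamRef:
    return v if isinstance(v, str) else float(v)  # type: ignore[arg-type]


def read_cohort_model(path: str | Path) -> CohortSpec:
    """Read a cohort-model YAML file (strata, channels, parameter wiring)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "strata" not in doc:
        raise ModelConfigurationError(f"{path}: expected a mapping with 'strata'")
    strata = []
    for s in doc["strata"]:
        channels = tuple(
            EventChannel(
                name=c["name"],
                incidence=_ref_from_yaml(c["incidence"]),
                efficacy=_ref_from_yaml(c["efficacy"]),
                qaly_weight=_ref_from_yaml(c.get("qaly_weight", 1.0)),
            )
            for c in s.get("channels", ())
        )
        strata.append(
            AgeStratum(
                label=str(s["label"]),
                person_years=_ref_from_yaml(s["person_years"]),
                coverage=_ref_from_yaml(s["coverage"]),
                channels=channels,
            )
        )
    return CohortSpec(
        name=str(doc.get("name", path.stem)),
        adherence=_ref_from_yaml(doc["adherence"]),
        strata=tuple(strata),
        birth_cohort_size=float(doc.get("birth_cohort_size", 4_000_000)),
        denominator=str(doc.get("denominator", "delivered")),
    )


def write_cohort_model(model: CohortSpec, path: str | Path) -> None:
    doc = {
        "name": model.name,
        "birth_cohort_size": model.birth_cohort_size,
        "adherence": model.adherence,
        "denominator": model.denominator,
        "strata": [
            {
                "label": s.label,
                "person_years": s.person_years,
                "coverage": s.coverage,
                "channels": [
                    {
                        "name": c.name,
                        "incidence": c.incidence,
                        "efficacy": c.efficacy,
                        "qaly_weight": c.qaly_weight,
                    }
                    for c in s.channels
                ],
            }
            for s in model.strata
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
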