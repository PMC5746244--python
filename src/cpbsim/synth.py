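"""Synthetic models and parameter sets with closed-form expected outputs.

Two families:

* **product chains** — the model output is a plain product of n independent
  uniform inputs, for which the output mean and sd have closed forms
  (``E[prod] = prod of midpoints``; the variance follows from
  ``E[U^2] = (low^2 + low*high + high^2) / 3``).  These are the analytic
  oracles for the Monte Carlo machinery.
* **an influenza-like cohort model** — two age strata (50–64, 65+) with
  mortality, hospitalization and illness channels.  Ranges printed in the
  influenza-vaccination burden literature are used where available; the rest
  (the whole 50–64 stratum, hospitalization/illness incidences and the
  hospitalization efficacy, the illness QALY weight) are plausibility-chosen
  placeholders, listed in :data:`PLACEHOLDER_PARAMETERS`.  This model
  exercises the full CPB chain; its absolute output depends on the
  placeholders and is not a published quantity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import AgeStratum, CohortSpec, EventChannel
from .params import ParameterKind, ParameterRange, write_parameter_set

__all__ = [
    "SyntheticModelSpec",
    "ProductChainModel",
    "product_chain_moments",
    "make_product_chain",
    "make_influenza_like",
    "collapse_to_midpoints",
    "write_fixture",
    "PLACEHOLDER_PARAMETERS",
]


@dataclass(frozen=True)
class SyntheticModelSpec:
    """Recipe for a synthetic fixture.

    Ranges are built as ``true_value * (1 +/- range_width / 2)`` and must
    stay inside each parameter kind's domain.
    """

    n_parameters: int
    chain_shape: str  # "product_chain" | "influenza_like"
    true_values: Mapping[str, float] = field(default_factory=dict)
    range_width: float = 0.5

    def __post_init__(self) -> None:
        if self.chain_shape not in ("product_chain", "influenza_like"):
            raise ValueError(f"unknown chain shape {self.chain_shape!r}")
        if self.n_parameters < 1:
            raise ValueError("need at least one parameter")
        if not (0.0 <= self.range_width <= 2.0):
            raise ValueError("range_width must lie in [0, 2]")


@dataclass(frozen=True)
class ProductChainModel:
    """Model whose output is the product of its (independent) inputs."""

    name: str
    factors: tuple[str, ...]

    def parameter_names(self) -> set[str]:
        return set(self.factors)

    def evaluate(self, draw):
        out = 1.0
        for f in self.factors:
            out = out * np.asarray(draw[f], dtype=float)
        out = np.asarray(out, dtype=float)
        return out if out.ndim else float(out)


def product_chain_moments(
    ranges: Sequence[ParameterRange],
) -> tuple[float, float]:
    """Closed-form mean and sd of a product of independent uniforms.

    For U(a, b): E[U] = (a+b)/2 and E[U^2] = (a^2 + ab + b^2)/3, so
    E[prod] = prod E[U_i] and Var = prod E[U_i^2] - (prod E[U_i])^2.
    """
    m1 = 1.0
    m2 = 1.0
    for r in ranges:
        m1 *= r.midpoint
        m2 *= (r.low**2 + r.low * r.high + r.high**2) / 3.0
    var = max(m2 - m1**2, 0.0)
    return (m1, math.sqrt(var))


def make_product_chain(
    n: int,
    seed: int | None = None,
    range_width: float = 0.5,
) -> tuple[ProductChainModel, list[ParameterRange], float, float]:
    """A product-of-n-uniforms fixture with its analytic mean and sd.

    True values are drawn in (0.2, 0.8) so the relative ranges stay inside
    the probability domain.  Returns (model, ranges, mean, sd).
    """
    if n < 1:
        raise ValueError("need at least one factor")
    rng = np.random.default_rng(seed)
    ranges = []
    for i in range(n):
        tv = float(rng.uniform(0.2, 0.8))
        half = tv * range_width / 2.0
        ranges.append(
            ParameterRange(
                name=f"factor_{i}",
                low=tv - half,
                high=tv + half,
                units="dimensionless",
                kind=ParameterKind.PROBABILITY,
            )
        )
    model = ProductChainModel(
        name=f"product_chain_{n}", factors=tuple(r.name for r in ranges)
    )
    mean, sd = product_chain_moments(ranges)
    return model, ranges, mean, sd


# ---------------------------------------------------------------------------
# influenza-like cohort model

#: Parameters whose ranges are plausibility-chosen placeholders, not
#: published values: the influenza literature prints ranges only for the
#: senior mortality rate, mortality/illness efficacies, senior coverage,
#: adherence, and the sickness QALY weight.
PLACEHOLDER_PARAMETERS = frozenset(
    {
        "mortality_rate_50_64",
        "hosp_rate_65plus",
        "hosp_rate_50_64",
        "illness_rate_65plus",
        "illness_rate_50_64",
        "coverage_50_64",
        "efficacy_hospitalization",
        "qaly_weight_illness",
    }
)

_P = ParameterKind.PROBABILITY
_R = ParameterKind.RATE_PER_100K
_W = ParameterKind.QALY_WEIGHT

_INFLUENZA_RANGES: tuple[tuple[str, float, float, str, ParameterKind], ...] = (
    # printed ranges
    ("mortality_rate_65plus", 9.4, 15.6, "per 100,000 person-years", _R),
    ("efficacy_mortality", 0.35, 0.55, "fraction of deaths averted", _P),
    ("efficacy_illness", 0.10, 0.30, "fraction of illnesses averted", _P),
    ("coverage_65plus", 0.43, 0.72, "current vaccination prevalence", _P),
    ("adherence", 0.75, 0.95, "acceptance when offered", _P),
    ("qaly_weight_sickness", 0.20, 0.40, "QALY decrement per event", _W),
    # placeholders (see PLACEHOLDER_PARAMETERS)
    ("mortality_rate_50_64", 1.0, 3.0, "per 100,000 person-years [placeholder]", _R),
    ("hosp_rate_65plus", 90.0, 210.0, "per 100,000 person-years [placeholder]", _R),
    ("hosp_rate_50_64", 20.0, 60.0, "per 100,000 person-years [placeholder]", _R),
    ("illness_rate_65plus", 2000.0, 8000.0, "per 100,000 person-years [placeholder]", _R),
    ("illness_rate_50_64", 2000.0, 8000.0, "per 100,000 person-years [placeholder]", _R),
    ("coverage_50_64", 0.30, 0.50, "current vaccination prevalence [placeholder]", _P),
    ("efficacy_hospitalization", 0.25, 0.45, "fraction of hospitalizations averted [placeholder]", _P),
    ("qaly_weight_illness", 0.02, 0.10, "QALY decrement per event [placeholder]", _W),
)


def make_influenza_like(
    seed: int | None = None,
) -> tuple[CohortSpec, list[ParameterRange]]:
    """Two-stratum, three-channel influenza-vaccination cohort model.

    ``seed`` is accepted for interface symmetry with the other fixture
    makers; the model itself is fixed.
    """
    ranges = [
        ParameterRange(name=n, low=lo, high=hi, units=u, kind=k)
        for n, lo, hi, u, k in _INFLUENZA_RANGES
    ]

    def channels(suffix: str) -> tuple[EventChannel, ...]:
        return (
            EventChannel(
                name="mortality",
                incidence=f"mortality_rate_{suffix}",
                efficacy="efficacy_mortality",
                qaly_weight=1.0,
            ),
            EventChannel(
                name="hospitalization",
                incidence=f"hosp_rate_{suffix}",
                efficacy="efficacy_hospitalization",
                qaly_weight="qaly_weight_sickness",
            ),
            EventChannel(
                name="illness",
                incidence=f"illness_rate_{suffix}",
                efficacy="efficacy_illness",
                qaly_weight="qaly_weight_illness",
            ),
        )

    model = CohortSpec(
        name="influenza_50plus",
        adherence="adherence",
        birth_cohort_size=4_000_000.0,
        denominator="delivered",
        strata=(
            AgeStratum(
                label="50-64",
                person_years=60_000_000.0,  # 4M persons x 15 years in stratum
                coverage="coverage_50_64",
                channels=channels("50_64"),
            ),
            AgeStratum(
                label="65+",
                person_years=50_000_000.0,
                coverage="coverage_65plus",
                channels=channels("65plus"),
            ),
        ),
    )
    return model, ranges


def collapse_to_midpoints(
    ranges: Sequence[ParameterRange],
    overrides: Mapping[str, float] | None = None,
) -> list[ParameterRange]:
    """Point-mass copies of the ranges (optionally pinning some by name)."""
    overrides = overrides or {}
    return [r.collapsed(overrides.get(r.name)) for r in ranges]


def write_fixture(
    out_dir: str | Path,
    n: int = 3,
    seed: int | None = None,
    range_width: float = 0.5,
) -> dict:
    """Write a product-chain fixture plus an oracle sidecar JSON.

    The sidecar records the generating seed and the closed-form mean/sd so a
    fixture can be consumed (and checked) without re-deriving anything.
    Returns the sidecar content.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, ranges, mean, sd = make_product_chain(n, seed=seed, range_width=range_width)
    write_parameter_set(ranges, out_dir / f"{model.name}.params.yaml", model.name)
    sidecar = {
        "model": model.name,
        "factors": list(model.factors),
        "seed": seed,
        "range_width": range_width,
        "analytic_mean": mean,
        "analytic_sd": sd,
    }
    with (out_dir / f"{model.name}.oracle.json").open("w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
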