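"""QALY rates for interventions that cannot be simulated from first principles.

Many preventive services have published burden estimates (mean QALYs per
10**3 interventions) but no step-by-step computation or parameter ranges to
drive a Monte Carlo run.  For these, the standard deviation is approximated
with a fixed coefficient of variation of one third — a conservative choice
sitting inside the 15–40% CV band observed across the simulable
interventions.

The shipped rate table (``data/qaly_rates.yaml``) carries both kinds of row:
simulated rates with their printed SDs and quantile intervals, and
literature-only means.  For literature rows the table stores the published
rounded SD alongside the exact ``mean / 3``; downstream clinic-impact
calculations can use either (``sd="printed"`` reproduces published tables,
``sd="derived"`` keeps full precision).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .montecarlo import QalyRateEstimate

__all__ = [
    "LiteratureRate",
    "cv_estimate",
    "to_rate_estimate",
    "load_rate_table",
    "builtin_rates_path",
]

#: Fixed fallback coefficient of variation (sd / mean) for literature rates.
LITERATURE_CV = 1.0 / 3.0


@dataclass(frozen=True)
class LiteratureRate:
    """A published mean QALY rate without simulable detail."""

    intervention: str
    mean: float
    citation: str = ""

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError(f"{self.intervention}: mean must be non-negative")


def cv_estimate(mean: float) -> float:
    """SD approximated as one third of the mean."""
    if mean < 0:
        raise ValueError("mean must be non-negative")
    return mean * LITERATURE_CV


def to_rate_estimate(lit: LiteratureRate) -> QalyRateEstimate:
    """Promote a literature mean to a full rate estimate via the CV rule.

    No quantile interval is attached: the underlying distribution is unknown.
    """
    return QalyRateEstimate(
        intervention=lit.intervention,
        mean=lit.mean,
        sd=cv_estimate(lit.mean),
        source="literature",
    )


def builtin_rates_path() -> Path:
    """Path of the rate table shipped with the package."""
    return Path(resources.files("cpbsim").joinpath("data/qaly_rates.yaml"))  # type: ignore[arg-type]


def load_rate_table(
    path: str | Path | None = None, sd: str = "printed"
) -> dict[str, QalyRateEstimate]:
    """Load a rate table keyed by intervention name.

    ``sd="printed"`` uses the SDs as published (rounded to two significant
    figures); ``sd="derived"`` replaces literature-row SDs with the exact
    ``mean / 3``.  Simulated rows always use their published SD.
    """
    if sd not in ("printed", "derived"):
        raise ValueError(f"sd must be 'printed' or 'derived', got {sd!r}")
    path = builtin_rates_path() if path is None else Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    rates: dict[str, QalyRateEstimate] = {}
    for row in doc.get("simulated", ()):
        qi = row.get("qi")
        est = QalyRateEstimate(
            intervention=row["intervention"],
            mean=float(row["mean"]),
            sd=float(row["sd"]),
            qi_low=float(qi[0]) if qi else None,
            qi_high=float(qi[1]) if qi else None,
            source="simulated",
        )
        rates[est.intervention] = est
    for row in doc.get("literature", ()):
        lit = LiteratureRate(
            intervention=row["intervention"],
            mean=float(row["mean"]),
            citation=str(row.get("citation", "")),
        )
        if sd == "derived" or "sd" not in row:
            est = to_rate_estimate(lit)
        else:
            est = QalyRateEstimate(
                intervention=lit.intervention,
                mean=lit.mean,
                sd=float(row["sd"]),
                source="literature",
            )
        if est.intervention in rates:
            raise ValueError(f"duplicate intervention {est.intervention!r}")
        rates[est.intervention] = est
    return rates
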