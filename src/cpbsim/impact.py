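"""Annual health and economic impact of a clinic's preventive-service menu.

Per service, annual QALYs saved = (QALYs per 10**3 interventions) x annual
volume / 1000.  Both factors are uncertain — the rate carries its simulated
or CV-approximated SD, and patient volume fluctuates between years (default
20%) — and they are treated as independent, so the variance of the product
uses the exact moment formula

    Var(XY) = mu_x^2 s_y^2 + mu_y^2 s_x^2 + s_x^2 s_y^2.

Dollars saved apply a constant dollar value per QALY (default $132,200 in
2017 dollars, an inflation-adjusted conservative willingness-to-pay figure);
row SDs by default scale the QALY SD by the cost mean (``mode="row"``, which
reproduces published clinic tables), while ``mode="with_cost_variance"``
additionally folds a cost-per-QALY fluctuation into the product variance.
Totals sum means and, by independence, variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .montecarlo import QalyRateEstimate

__all__ = [
    "ClinicService",
    "EconomicAssumptions",
    "ImpactRow",
    "ImpactTable",
    "product_mean_sd",
    "annual_qalys",
    "annual_dollars",
    "impact_row",
    "aggregate",
    "scenario_impact",
    "roi",
    "uninsured_exam_savings",
    "read_service_menu",
    "builtin_menu_path",
]


@dataclass(frozen=True)
class EconomicAssumptions:
    """Dollar-side model constants (2017 US dollars)."""

    cost_per_qaly: float = 132_200.0
    cost_cv: float = 0.20
    annual_budget: float = 50_000.0
    exam_cost: float = 230.0
    uninsured_fraction: float = 0.5

    def __post_init__(self) -> None:
        for f in (
            "cost_per_qaly",
            "cost_cv",
            "annual_budget",
            "exam_cost",
            "uninsured_fraction",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass(frozen=True)
class ClinicService:
    """An intervention offered at the clinic with its annual volume."""

    intervention: str
    rate: QalyRateEstimate
    annual_volume: float
    volume_cv: float = 0.20

    def __post_init__(self) -> None:
        if self.annual_volume < 0:
            raise ValueError(f"{self.intervention}: volume must be non-negative")
        if not (0.0 <= self.volume_cv < 1.0):
            raise ValueError(f"{self.intervention}: volume_cv must lie in [0, 1)")


@dataclass(frozen=True)
class ImpactRow:
    """Annual QALYs/year and thousands of dollars/year for one service."""

    intervention: str
    qalys_mean: float
    qalys_sd: float
    kdollars_mean: float
    kdollars_sd: float

    def __post_init__(self) -> None:
        for f in ("qalys_mean", "qalys_sd", "kdollars_mean", "kdollars_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.intervention}: {f} must be non-negative")


@dataclass(frozen=True)
class ImpactTable:
    rows: tuple[ImpactRow, ...]
    total: ImpactRow

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))


def product_mean_sd(
    mean_x: float, sd_x: float, mean_y: float, sd_y: float
) -> tuple[float, float]:
    """Exact mean and sd of a product of two independent variables."""
    var = mean_x**2 * sd_y**2 + mean_y**2 * sd_x**2 + sd_x**2 * sd_y**2
    return (mean_x * mean_y, math.sqrt(var))


def annual_qalys(
    rate: QalyRateEstimate, volume: float, volume_cv: float = 0.20
) -> tuple[float, float]:
    """Mean and sd of QALYs saved per year for one service.

    Volume sd is ``volume_cv * volume``; rate and volume are independent.
    """
    if volume < 0 or volume_cv < 0:
        raise ValueError("volume and volume_cv must be non-negative")
    mean, sd = product_mean_sd(rate.mean, rate.sd, volume, volume_cv * volume)
    return (mean / 1000.0, sd / 1000.0)


def annual_dollars(
    qalys: tuple[float, float],
    econ: EconomicAssumptions = EconomicAssumptions(),
    mode: str = "row",
) -> tuple[float, float]:
    """Mean and sd of thousands of dollars saved per year.

    ``mode="row"`` scales both moments by the cost mean.
    ``mode="with_cost_variance"`` treats cost per QALY as a third independent
    fluctuating factor (sd ``cost_cv * cost_per_qaly``) via the product
    formula, which widens the SD.
    """
    q_mean, q_sd = qalys
    if mode == "row":
        scale = econ.cost_per_qaly / 1000.0
        return (q_mean * scale, q_sd * scale)
    if mode == "with_cost_variance":
        mean, sd = product_mean_sd(
            q_mean, q_sd, econ.cost_per_qaly, econ.cost_cv * econ.cost_per_qaly
        )
        return (mean / 1000.0, sd / 1000.0)
    raise ValueError(f"unknown mode {mode!r}")


def impact_row(
    service: ClinicService,
    econ: EconomicAssumptions = EconomicAssumptions(),
    mode: str = "row",
) -> ImpactRow:
    q = annual_qalys(service.rate, service.annual_volume, service.volume_cv)
    d = annual_dollars(q, econ, mode=mode)
    return ImpactRow(
        intervention=service.intervention,
        qalys_mean=q[0],
        qalys_sd=q[1],
        kdollars_mean=d[0],
        kdollars_sd=d[1],
    )


def aggregate(rows: Sequence[ImpactRow]) -> ImpactRow:
    """Total row: means sum; variances sum (independent services)."""
    if not rows:
        raise ValueError("cannot aggregate an empty list of rows")
    return ImpactRow(
        intervention="Total",
        qalys_mean=sum(r.qalys_mean for r in rows),
        qalys_sd=math.sqrt(sum(r.qalys_sd**2 for r in rows)),
        kdollars_mean=sum(r.kdollars_mean for r in rows),
        kdollars_sd=math.sqrt(sum(r.kdollars_sd**2 for r in rows)),
    )


def scenario_impact(
    services: Sequence[ClinicService],
    econ: EconomicAssumptions = EconomicAssumptions(),
    mode: str = "row",
) -> ImpactTable:
    """Full impact table (per-service rows plus total) for a service menu."""
    rows = tuple(impact_row(s, econ, mode=mode) for s in services)
    return ImpactTable(rows=rows, total=aggregate(rows))


def roi(total_kdollars: float, budget: float) -> float:
    """Annual return on investment: dollars saved over operating budget."""
    if budget <= 0:
        raise ValueError("budget must be positive")
    return total_kdollars * 1000.0 / budget


def uninsured_exam_savings(
    n_patients: float, uninsured_fraction: float, exam_cost: float
) -> float:
    """Dollars of free physical exams delivered to uninsured patients."""
    if n_patients < 0 or exam_cost < 0 or not (0.0 <= uninsured_fraction <= 1.0):
        raise ValueError(
            "n_patients and exam_cost must be non-negative and the "
            "uninsured fraction in [0, 1]"
        )
    return n_patients * uninsured_fraction * exam_cost


def builtin_menu_path(name: str) -> Path:
    """Path of a service menu shipped with the package.

    Shipped menus: ``ucc_current`` (the clinic's present services) and
    ``ucc_prospective`` (candidate additions).
    """
    return Path(resources.files("cpbsim").joinpath(f"data/menu_{name}.yaml"))  # type: ignore[arg-type]


def read_service_menu(
    path: str | Path, rates: Mapping[str, QalyRateEstimate]
) -> list[ClinicService]:
    """Read a service-menu YAML file, resolving rates by intervention name.

    A menu entry naming an intervention absent from ``rates`` raises
    ``KeyError``.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    default_cv = float(doc.get("volume_cv", 0.20))
    services = []
    for entry in doc.get("services", ()):
        name = entry["intervention"]
        if name not in rates:
            raise KeyError(
                f"{path.name}: no QALY rate known for intervention {name!r}"
            )
        services.append(
            ClinicService(
                intervention=name,
                rate=rates[name],
                annual_volume=float(entry["annual_volume"]),
                volume_cv=float(entry.get("volume_cv", default_cv)),
            )
        )
    return services
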