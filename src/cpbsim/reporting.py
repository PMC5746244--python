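"""Rendering at house precision, KDE export, and run manifests.

Numbers are rendered the way the clinic tables print them: two significant
figures for QALY rates and SDs (``2.9 (1.0)  [1.4, 5.2]``), and thousands
of dollars as integers once they reach 10.  Raw values always keep full
precision; rounding is a rendering concern only.  Rendering is
locale-independent and byte-stable.
"""

from __future__ import annotations

import csv
import io
import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .impact import ImpactTable
from .montecarlo import QalyRateEstimate

__all__ = [
    "format_sig",
    "format_kdollars",
    "render_estimate",
    "render_rate_table",
    "render_impact_table",
    "rate_table_records",
    "impact_table_records",
    "write_csv",
    "kde_export",
    "RunManifest",
]


def format_sig(x: float, sig: int = 2) -> str:
    """Fixed-point rendering at ``sig`` significant figures.

    Keeps trailing zeros (``1.0``, ``0.070``) so printed precision is
    explicit; integers with >= sig digits print without a decimal point.
    """
    if sig < 1:
        raise ValueError("sig must be >= 1")
    if x == 0 or not np.isfinite(x):
        return "0.0" if x == 0 else str(x)
    exponent = int(np.floor(np.log10(abs(x))))
    decimals = sig - 1 - exponent
    rounded = round(x, decimals)
    # rounding can bump the exponent (0.096 -> 0.10 at 2 s.f.)
    if rounded != 0 and int(np.floor(np.log10(abs(rounded)))) > exponent:
        decimals -= 1
    return f"{rounded:.{max(decimals, 0)}f}"


def format_kdollars(x: float) -> str:
    """Thousands of dollars: integers from 10 up, two significant figures below."""
    return f"{x:.0f}" if abs(x) >= 10 else format_sig(x, 2)


def render_estimate(est: QalyRateEstimate, sig: int = 2) -> str:
    """``"mean (sd)  [qi_low, qi_high]"`` at house precision."""
    out = f"{format_sig(est.mean, sig)} ({format_sig(est.sd, sig)})"
    if est.qi_low is not None:
        out += f"  [{format_sig(est.qi_low, sig)}, {format_sig(est.qi_high, sig)}]"
    return out


def rate_table_records(estimates: Iterable[QalyRateEstimate]) -> list[dict]:
    return [
        {
            "intervention": e.intervention,
            "mean": e.mean,
            "sd": e.sd,
            "qi_low": e.qi_low,
            "qi_high": e.qi_high,
            "n_iterations": e.n_iterations,
            "source": e.source,
        }
        for e in estimates
    ]


def render_rate_table(estimates: Sequence[QalyRateEstimate], sig: int = 2) -> str:
    """Aligned text table of QALYs per 10**3 interventions."""
    width = max([len("Intervention")] + [len(e.intervention) for e in estimates])
    lines = [f"{'Intervention':<{width}}  QALYs/10^3-interventions (SD)  [95% QI]"]
    for e in estimates:
        lines.append(f"{e.intervention:<{width}}  {render_estimate(e, sig)}")
    return "\n".join(lines) + "\n"


def impact_table_records(table: ImpactTable) -> list[dict]:
    rows = list(table.rows) + [table.total]
    return [
        {
            "intervention": r.intervention,
            "qalys_per_year": r.qalys_mean,
            "qalys_sd": r.qalys_sd,
            "kdollars_per_year": r.kdollars_mean,
            "kdollars_sd": r.kdollars_sd,
        }
        for r in rows
    ]


def render_impact_table(table: ImpactTable) -> str:
    """Aligned text table of annual QALYs and thousands of dollars saved."""
    rows = list(table.rows) + [table.total]
    width = max(len("Intervention"), max(len(r.intervention) for r in rows))
    lines = [f"{'Intervention':<{width}}  QALYs/year (SD)  $k/year (SD)"]
    for r in rows:
        q = f"{format_sig(r.qalys_mean)} ({format_sig(r.qalys_sd)})"
        d = f"{format_kdollars(r.kdollars_mean)} ({format_kdollars(r.kdollars_sd)})"
        lines.append(f"{r.intervention:<{width}}  {q:<16} {d}")
    return "\n".join(lines) + "\n"


def write_csv(records: Sequence[dict], path: str | Path) -> None:
    """Comma-separated output with a header row."""
    if not records:
        raise ValueError("nothing to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(records[0].keys()))
        writer.writeheader()
        writer.writerows(records)


def kde_export(
    sample: np.ndarray,
    grid_size: int = 256,
    bw_method: str | float = "scott",
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of a simulated sample on an even grid.

    Scott's-rule bandwidth by default.  The grid spans the sample padded by
    three bandwidths each side so the exported curve integrates to ~1
    (trapezoid rule, within 1%).  A constant sample has no density estimate:
    use a histogram (or report the point mass) instead.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 2:
        raise ValueError("need at least two points for a density estimate")
    if np.ptp(sample) == 0:
        raise ValueError(
            "sample is constant; a kernel density estimate is undefined — "
            "use a histogram instead"
        )
    kde = stats.gaussian_kde(sample, bw_method=bw_method)
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(sample.min() - 3 * bw, sample.max() + 3 * bw, grid_size)
    return grid, kde(grid)


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility sidecar written next to every CLI output file."""

    command: str
    arguments: dict
    seed: int | None = None
    software: str = ""
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, out_path: str | Path) -> Path:
        """Write ``<out>.manifest.json`` next to the output it describes."""
        out_path = Path(out_path)
        manifest_path = out_path.with_name(out_path.name + ".manifest.json")
        doc = {
            "command": self.command,
            "arguments": self.arguments,
            "seed": self.seed,
            "software": self.software,
            "created": self.created,
            "output": out_path.name,
            "python": sys.version.split()[0],
        }
        with manifest_path.open("w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
        return manifest_path
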