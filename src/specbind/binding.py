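"""Binding constant and stoichiometry from the double-logarithm plot, and
site-marker competition analysis.

For static quenching through a ground-state complex,
lg((F0 - F)/F) = lg Ka + n lg[Q]: an ordinary least-squares line in
log10-log10 space yields the number of binding sites n (slope) and the
apparent binding constant Ka (10^intercept).

Site competition: the ligand is titrated against protein pre-equilibrated
with a site marker (warfarin for Sudlow Site I, ibuprofen for Site II).  A
large drop in the apparent Ka in the presence of a marker places the ligand
in that marker's site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .quenching import TitrationSeries

__all__ = [
    "BindingFit",
    "CompetitionResult",
    "DEFAULT_SITE_MAP",
    "double_log_fit",
    "competition_analysis",
]

#: Conventional site-marker assignments for serum albumin.
DEFAULT_SITE_MAP: Mapping[str, str] = {
    "warfarin": "Site I",
    "ibuprofen": "Site II",
}


@dataclass(frozen=True)
class BindingFit:
    """Apparent binding constant and stoichiometry at one temperature."""

    ka: float  # L/mol
    n: float  # binding sites
    r: float  # correlation coefficient in log-log space
    ka_sd: float  # L/mol, propagated from the intercept standard error
    temperature_K: float
    label: str = ""
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.ka > 0:
            raise ValueError("Ka must be positive")
        if not self.n > 0:
            raise ValueError("binding-site count n must be positive")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation coefficient must lie in [-1, 1]")


@dataclass(frozen=True)
class CompetitionResult:
    """Outcome of a site-marker competition experiment."""

    ka_blank: float
    marker_ka: Mapping[str, float]
    percent_decrease: Mapping[str, float]
    assigned_site: str  # e.g. "Site I" or "unresolved"
    winning_marker: str | None
    decrease_threshold_percent: float
    site_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SITE_MAP))


def double_log_fit(series: TitrationSeries, label: str = "") -> BindingFit:
    """OLS of log10((F0-F)/F) on log10([Q]).

    Points with F >= F0 (apparent negative quench, noise) have no defined
    logarithm; they are dropped with a warning rather than clamped, so the
    exclusion is auditable.  At least 3 points must survive.
    """
    q = series.concentrations
    f = series.intensities
    usable = (q > 0) & (f < series.f0)
    n_dropped = int(np.sum((q > 0) & (f >= series.f0)))
    if n_dropped:
        warnings.warn(
            f"double_log_fit: dropped {n_dropped} point(s) with F >= F0",
            stacklevel=2,
        )
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable points with F < F0 and [Q] > 0")
    x = np.log10(q[usable])
    y = np.log10((series.f0 - f[usable]) / f[usable])
    res = stats.linregress(x, y)
    ka = float(10.0 ** res.intercept)
    return BindingFit(
        ka=ka,
        n=float(res.slope),
        r=float(res.rvalue),
        ka_sd=ka * np.log(10.0) * float(res.intercept_stderr),
        temperature_K=series.temperature_K,
        label=label or series.label,
        n_points=int(usable.sum()),
    )


def percent_decrease(ka_blank: float, ka_marker: float) -> float:
    """100 * (Ka_blank - Ka_marker) / Ka_blank."""
    return 100.0 * (ka_blank - ka_marker) / ka_blank


def competition_analysis(
    blank_fit: BindingFit,
    marker_fits: Mapping[str, BindingFit],
    decrease_threshold_percent: float = 50.0,
    site_map: Mapping[str, str] | None = None,
) -> CompetitionResult:
    """Assign the binding site from marker-induced drops in apparent Ka.

    The marker with the largest percent decrease wins if it exceeds the
    threshold; equal largest decreases, or no decrease above threshold,
    give "unresolved".
    """
    if blank_fit.ka <= 0:
        raise ValueError("blank Ka must be positive")
    site_map = dict(site_map if site_map is not None else DEFAULT_SITE_MAP)
    decreases = {
        name: percent_decrease(blank_fit.ka, fit.ka)
        for name, fit in marker_fits.items()
    }
    assigned = "unresolved"
    winner: str | None = None
    if decreases:
        best = max(decreases.values())
        winners = [m for m, d in decreases.items() if d == best]
        if best > decrease_threshold_percent:
            if len(winners) == 1:
                winner = winners[0]
                assigned = site_map.get(winner, f"site of {winner}")
            else:
                warnings.warn(
                    "competition_analysis: tie between markers "
                    f"{winners}; site unresolved",
                    stacklevel=2,
                )
    return CompetitionResult(
        ka_blank=blank_fit.ka,
        marker_ka={m: f.ka for m, f in marker_fits.items()},
        percent_decrease=decreases,
        assigned_site=assigned,
        winning_marker=winner,
        decrease_threshold_percent=decrease_threshold_percent,
        site_map=site_map,
    )
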