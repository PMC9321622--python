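"""DPPH radical-scavenging analysis: percent scavenging, IC50 estimation
and free-vs-protein-bound attenuation comparison.

Scavenging is quantified at the 521 nm DPPH absorbance maximum as
100 * (A_control - A_sample) / A_control.  (A historically common misprint
divides by A_sample instead; that literal form is retained behind a flag
for auditing, never as the default.)  The dose-response is summarised by
IC50, the antioxidant concentration neutralising half the radical, from a
two-parameter log-logistic fit (0-100% asymptotes) or by monotone linear
interpolation between the bracketing points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DpphAssay",
    "Ic50Result",
    "AttenuationReport",
    "scavenging_percent",
    "fit_ic50",
    "attenuation_report",
]


@dataclass(frozen=True)
class DpphAssay:
    """One DPPH dose-response series at 521 nm."""

    concentrations_ug_mL: np.ndarray
    a_control: float
    a_sample: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_ug_mL, dtype=float)
        a = np.asarray(self.a_sample, dtype=float)
        if c.size != a.size:
            raise ValueError("concentration and absorbance lengths differ")
        if np.any(np.diff(c) <= 0) or np.any(c < 0):
            raise ValueError("concentrations must be non-negative, ascending")
        if not self.a_control > 0:
            raise ValueError("control absorbance must be positive")
        if np.any(a < 0):
            raise ValueError("absorbances must be non-negative")
        object.__setattr__(self, "concentrations_ug_mL", c)
        object.__setattr__(self, "a_sample", a)

    @property
    def scavenging(self) -> np.ndarray:
        return scavenging_percent(self.a_control, self.a_sample)


@dataclass(frozen=True)
class Ic50Result:
    """Half-maximal scavenging concentration with fit diagnostics."""

    ic50_ug_mL: float
    method: str  # "loglogistic" | "interp"
    parameters: Mapping[str, float] = field(default_factory=dict)
    residual: float = 0.0
    extrapolated: bool = False
    condition: str = ""


@dataclass(frozen=True)
class AttenuationReport:
    """Free vs complexed IC50 comparison."""

    ic50_free: float
    ic50_complexed: float
    ratio: float  # complexed / free
    percent_change: float  # 100 * (complexed - free) / free
    direction: str  # "attenuated" | "enhanced" | "unchanged"


def scavenging_percent(
    a_control: float, a_sample: float | np.ndarray, mode: str = "standard"
) -> float | np.ndarray:
    """Percent radical scavenging from control and sample absorbances.

    "standard": 100 * (A_control - A_sample) / A_control (the default and
    the definition used for all downstream fits).  "literal": the misprint
    form 100 * (A_control - A_sample / A_sample), kept only for audit.
    """
    if not a_control > 0:
        raise ValueError("control absorbance must be positive")
    a = np.asarray(a_sample, dtype=float)
    if mode == "standard":
        out = 100.0 * (a_control - a) / a_control
    elif mode == "literal":
        if np.any(a == 0):
            raise ZeroDivisionError("literal mode divides by A_sample = 0")
        out = 100.0 * (a_control - a / a)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if np.isscalar(a_sample) else out


def _loglogistic(c: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return 100.0 / (1.0 + (ic50 / c) ** hill)


def fit_ic50(assay: DpphAssay, method: str = "loglogistic") -> Ic50Result:
    """Estimate IC50 from a DPPH assay.

    "loglogistic" fits pct(c) = 100 / (1 + (IC50/c)^h) by least squares
    (asymptotes fixed at 0 and 100%).  "interp" linearly interpolates the
    50% crossing between the two bracketing points and requires a
    monotonically increasing response.  Results whose responses do not
    bracket 50%, or whose IC50 falls outside the measured span, carry the
    ``extrapolated`` flag.
    """
    conc = assay.concentrations_ug_mL
    pct = np.asarray(assay.scavenging, dtype=float)
    nz = conc > 0
    conc, pct = conc[nz], pct[nz]
    if conc.size < 2:
        raise ValueError("need at least 2 nonzero concentrations")
    brackets = pct.min() < 50.0 < pct.max()
    if conc.size < 4 and method == "loglogistic":
        brackets = False  # too few points to trust the crossing

    if method == "loglogistic":
        p0 = (float(np.median(conc)), 1.0)
        popt, _ = curve_fit(
            _loglogistic, conc, pct, p0=p0,
            bounds=([1e-12, 0.05], [np.inf, 20.0]), maxfev=20000,
        )
        ic50, hill = float(popt[0]), float(popt[1])
        resid = float(np.sqrt(np.mean((_loglogistic(conc, *popt) - pct) ** 2)))
        params = {"ic50": ic50, "hill": hill}
    elif method == "interp":
        if np.any(np.diff(pct) < 0):
            raise ValueError(
                "non-monotone response; use method='loglogistic' instead"
            )
        if pct[0] >= 50.0:
            ic50 = float(conc[0])
        elif pct[-1] <= 50.0:
            ic50 = float(conc[-1])
        else:
            i = int(np.searchsorted(pct, 50.0))
            c0, c1, p0_, p1 = conc[i - 1], conc[i], pct[i - 1], pct[i]
            ic50 = float(c0 + (50.0 - p0_) * (c1 - c0) / (p1 - p0_))
        resid = 0.0
        params = {"ic50": ic50}
    else:
        raise ValueError(f"unknown method {method!r}")

    extrapolated = (not brackets) or not (conc[0] <= ic50 <= conc[-1])
    return Ic50Result(
        ic50_ug_mL=ic50,
        method=method,
        parameters=params,
        residual=resid,
        extrapolated=extrapolated,
        condition=assay.condition,
    )


def attenuation_report(
    free_result: Ic50Result, complexed_result: Ic50Result, rel_tol: float = 1e-9
) -> AttenuationReport:
    """Compare free vs protein-complexed IC50s.

    "attenuated" when the complexed IC50 exceeds the free one (weaker
    antioxidant), "enhanced" when it is lower, "unchanged" within
    ``rel_tol`` relative tolerance.
    """
    free, comp = free_result.ic50_ug_mL, complexed_result.ic50_ug_mL
    if free <= 0 or comp <= 0:
        raise ValueError("IC50 values must be positive")
    ratio = comp / free
    if abs(ratio - 1.0) <= rel_tol:
        direction = "unchanged"
    elif ratio > 1.0:
        direction = "attenuated"
    else:
        direction = "enhanced"
    return AttenuationReport(
        ic50_free=free,
        ic50_complexed=comp,
        ratio=ratio,
        percent_change=100.0 * (comp - free) / free,
        direction=direction,
    )
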