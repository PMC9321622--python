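"""Stern-Volmer analysis of fluorescence quenching titrations.

For a fluorophore quenched by a ligand, F0/F = 1 + Ksv*[Q] where F0 and F
are the intensities without and with quencher, [Q] the quencher
concentration, and Ksv the Stern-Volmer constant.  The bimolecular
quenching rate constant is Kq = Ksv / tau0 with tau0 the unquenched
fluorescence lifetime (1e-8 s for serum albumin).

The quenching mechanism is classified jointly from the temperature trend of
Ksv and the magnitude of Kq: a ground-state complex (static quenching)
gives Ksv decreasing with temperature and Kq far above the diffusion limit
of ~2e10 L mol^-1 s^-1, while collisional (dynamic) quenching gives the
opposite trend with Kq at or below that limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TitrationSeries",
    "QuenchFit",
    "MechanismCall",
    "HSA_LIFETIME_S",
    "DIFFUSION_LIMIT_KQ",
    "stern_volmer_fit",
    "classify_quenching",
    "inner_filter_correction",
]

#: Unquenched fluorescence lifetime of serum albumin (s).
HSA_LIFETIME_S = 1e-8

#: Maximum diffusion-limited collisional quenching rate constant (L/mol/s).
DIFFUSION_LIMIT_KQ = 2.0e10


@dataclass(frozen=True)
class TitrationSeries:
    """A fluorescence titration at one temperature.

    ``concentrations`` (mol/L, strictly increasing, may start at 0) and
    ``intensities`` (a.u., > 0) at a fixed emission read-out; ``f0`` is the
    intensity at zero quencher.
    """

    concentrations: np.ndarray
    intensities: np.ndarray
    f0: float
    temperature_K: float
    read_out: str = "peak"
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.concentrations, dtype=float)
        f = np.asarray(self.intensities, dtype=float)
        if q.size != f.size:
            raise ValueError("concentration and intensity lengths differ")
        if np.any(q < 0) or np.any(np.diff(q) <= 0):
            raise ValueError("concentrations must be non-negative, strictly increasing")
        if np.any(f <= 0):
            raise ValueError("all intensities must be positive")
        if not self.f0 > 0:
            raise ValueError("F0 must be positive")
        if not self.temperature_K > 0:
            raise ValueError("temperature must be positive (K)")
        object.__setattr__(self, "concentrations", q)
        object.__setattr__(self, "intensities", f)

    @property
    def quenched_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(Q, F) restricted to nonzero quencher concentration."""
        mask = self.concentrations > 0
        return self.concentrations[mask], self.intensities[mask]


@dataclass(frozen=True)
class QuenchFit:
    """Result of a Stern-Volmer regression at one temperature."""

    ksv: float  # L/mol
    kq: float  # L/mol/s
    tau0: float  # s
    intercept: float
    r: float  # Pearson correlation of F0/F vs [Q]
    sd: float  # standard error of the slope (Ksv)
    temperature_K: float

    def __post_init__(self) -> None:
        if abs(self.kq * self.tau0 - self.ksv) > 1e-6 * max(abs(self.ksv), 1.0):
            raise ValueError("Kq must equal Ksv / tau0")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation coefficient must lie in [-1, 1]")


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism verdict with the evidence behind it."""

    label: str  # "static" | "dynamic" | "indeterminate"
    ksv_decreasing_with_T: bool
    ksv_increasing_with_T: bool
    all_kq_above_threshold: bool
    all_kq_at_or_below_threshold: bool
    kq_threshold: float
    temperatures_K: tuple[float, ...] = field(default_factory=tuple)
    ksv_values: tuple[float, ...] = field(default_factory=tuple)


def inner_filter_correction(
    intensities: np.ndarray, a_excitation: np.ndarray, a_emission: np.ndarray
) -> np.ndarray:
    """Inner-filter-effect correction F_corr = F * 10^((A_ex + A_em)/2).

    Optional pre-step; the default analysis applies none.
    """
    f = np.asarray(intensities, dtype=float)
    return f * 10.0 ** ((np.asarray(a_excitation) + np.asarray(a_emission)) / 2.0)


def stern_volmer_fit(series: TitrationSeries, tau0: float = HSA_LIFETIME_S) -> QuenchFit:
    """Fit F0/F = intercept + Ksv*[Q] by ordinary least squares.

    The [Q] = 0 point (F0/F = 1 by definition) is excluded so the origin
    does not over-weight the regression.  The intercept is left free; its
    deviation from 1 is a diagnostic.  ``sd`` is the standard error of the
    slope, i.e. of Ksv.
    """
    if not tau0 > 0:
        raise ValueError("tau0 must be positive")
    q, f = series.quenched_points
    if q.size < 3:
        raise ValueError("need at least 3 nonzero-concentration points")
    if np.ptp(q) == 0:
        raise ValueError("zero variance in quencher concentration")
    ratio = series.f0 / f
    res = stats.linregress(q, ratio)
    ksv = float(res.slope)
    return QuenchFit(
        ksv=ksv,
        kq=ksv / tau0,
        tau0=tau0,
        intercept=float(res.intercept),
        r=float(res.rvalue),
        sd=float(res.stderr),
        temperature_K=series.temperature_K,
    )


def classify_quenching(
    fits: Sequence[QuenchFit], kq_threshold: float = DIFFUSION_LIMIT_KQ
) -> MechanismCall:
    """Classify the quenching mechanism from fits at >= 2 temperatures.

    "static" requires Ksv non-increasing with temperature AND every Kq
    above ``kq_threshold``; "dynamic" requires Ksv non-decreasing AND every
    Kq at or below the threshold; anything else is "indeterminate" (both
    criteria are reported either way).
    """
    if len(fits) < 2:
        raise ValueError("need fits at >= 2 temperatures")
    temps = [f.temperature_K for f in fits]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures in fit set")
    ordered = sorted(fits, key=lambda f: f.temperature_K)
    ksv = np.array([f.ksv for f in ordered])
    kq = np.array([f.kq for f in ordered])
    decreasing = bool(np.all(np.diff(ksv) <= 0))
    increasing = bool(np.all(np.diff(ksv) >= 0))
    above = bool(np.all(kq > kq_threshold))
    below = bool(np.all(kq <= kq_threshold))
    if decreasing and above:
        label = "static"
    elif increasing and below:
        label = "dynamic"
    else:
        label = "indeterminate"
    return MechanismCall(
        label=label,
        ksv_decreasing_with_T=decreasing,
        ksv_increasing_with_T=increasing,
        all_kq_above_threshold=above,
        all_kq_at_or_below_threshold=below,
        kq_threshold=kq_threshold,
        temperatures_K=tuple(f.temperature_K for f in ordered),
        ksv_values=tuple(float(v) for v in ksv),
    )
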