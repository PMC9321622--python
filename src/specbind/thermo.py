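"""Van't Hoff thermodynamics of binding and interaction-force typing.

With a two-parameter Van't Hoff model (temperature-independent enthalpy
over the fitted range), ln Ka = -dH0/(R*T) + dS0/R is linear in 1/T: the
slope gives the standard enthalpy change dH0, the intercept the entropy
change dS0.  The Gibbs energy follows either as dG0 = dH0 - T*dS0 (the
headline route, matching how binding tables are usually computed) or
directly as dG0 = -R*T*ln Ka; both are reported so their discrepancy is
visible.

The sign pattern of (dH0, dS0) maps onto dominant non-covalent force types
(the Ross-Subramanian rules): dH0 < 0 with dS0 > 0 points to electrostatic
interactions (with a hydrophobic contribution from the positive entropy),
both positive to hydrophobic forces, both negative to hydrogen bonding and
van der Waals contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GAS_CONSTANT",
    "CAL_IT_JOULES",
    "ThermoResult",
    "vant_hoff_fit",
    "gibbs",
    "gibbs_from_ka",
    "classify_forces",
    "kcal_to_kj",
    "thermodynamic_analysis",
]

#: Gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: International-Table calorie in joules (used for kcal -> kJ conversion).
CAL_IT_JOULES = 4.1868


@dataclass(frozen=True)
class ThermoResult:
    """Van't Hoff parameters, per-temperature Gibbs energies, force label."""

    dH0_kJ_mol: float
    dS0_J_mol_K: float
    r: float  # correlation of ln Ka vs 1/T
    temperatures_K: tuple[float, ...]
    dG0_kJ_mol: tuple[float, ...]  # dH - T*dS route (headline)
    dG0_from_ka_kJ_mol: tuple[float, ...]  # -RT ln Ka cross-check
    force_label: str

    def __post_init__(self) -> None:
        for T, dg in zip(self.temperatures_K, self.dG0_kJ_mol):
            expected = self.dH0_kJ_mol - T * self.dS0_J_mol_K / 1000.0
            if abs(dg - expected) > 1e-9 * max(1.0, abs(expected)):
                raise ValueError("stored dG0 inconsistent with dH0 - T*dS0")

    @property
    def spontaneous(self) -> tuple[bool, ...]:
        return tuple(dg < 0 for dg in self.dG0_kJ_mol)


def vant_hoff_fit(
    ka_by_temperature: Mapping[float, float] | Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS of ln Ka on 1/T.

    Returns ``(dH0_kJ_mol, dS0_J_mol_K, r)`` with
    dH0 = -slope * R (kJ/mol) and dS0 = intercept * R (J/mol/K).
    """
    pairs = (
        list(ka_by_temperature.items())
        if isinstance(ka_by_temperature, Mapping)
        else list(ka_by_temperature)
    )
    temps = np.array([t for t, _ in pairs], dtype=float)
    kas = np.array([k for _, k in pairs], dtype=float)
    if len(set(temps.tolist())) != temps.size:
        raise ValueError("duplicate temperatures")
    if temps.size < 2:
        raise ValueError("need Ka at >= 2 distinct temperatures")
    if np.any(temps <= 0) or np.any(kas <= 0):
        raise ValueError("temperatures and Ka values must be positive")
    res = stats.linregress(1.0 / temps, np.log(kas))
    dH0 = -float(res.slope) * GAS_CONSTANT / 1000.0  # kJ/mol
    dS0 = float(res.intercept) * GAS_CONSTANT  # J/mol/K
    return dH0, dS0, float(res.rvalue)


def gibbs(dH0_kJ_mol: float, dS0_J_mol_K: float, temperature_K: float) -> float:
    """dG0 = dH0 - T*dS0 in kJ/mol (entropy given in J/mol/K)."""
    if not temperature_K > 0:
        raise ValueError("temperature must be positive")
    return dH0_kJ_mol - temperature_K * dS0_J_mol_K / 1000.0


def gibbs_from_ka(ka: float, temperature_K: float) -> float:
    """dG0 = -R*T*ln Ka in kJ/mol."""
    if not (ka > 0 and temperature_K > 0):
        raise ValueError("Ka and temperature must be positive")
    return -GAS_CONSTANT * temperature_K * np.log(ka) / 1000.0


def classify_forces(dH0_kJ_mol: float, dS0_J_mol_K: float) -> str:
    """Sign-quadrant force typing (Ross-Subramanian style)."""
    if not (np.isfinite(dH0_kJ_mol) and np.isfinite(dS0_J_mol_K)):
        raise ValueError("dH0 and dS0 must be finite")
    if dH0_kJ_mol == 0 or dS0_J_mol_K == 0:
        return "indeterminate"
    if dH0_kJ_mol < 0 and dS0_J_mol_K > 0:
        return "electrostatic (with hydrophobic contribution)"
    if dH0_kJ_mol > 0 and dS0_J_mol_K > 0:
        return "hydrophobic"
    if dH0_kJ_mol < 0 and dS0_J_mol_K < 0:
        return "hydrogen bonding / van der Waals"
    return "indeterminate"  # dH > 0, dS < 0: unfavourable in both terms


def kcal_to_kj(energy_kcal: float, calorie_factor: float = CAL_IT_JOULES) -> float:
    """Convert kcal/mol to kJ/mol (default: IT calorie, 4.1868 J/cal)."""
    if not np.isfinite(energy_kcal):
        raise ValueError("energy must be finite")
    return energy_kcal * calorie_factor


def thermodynamic_analysis(
    ka_by_temperature: Mapping[float, float] | Sequence[tuple[float, float]],
) -> ThermoResult:
    """Full Van't Hoff chain: fit, per-temperature dG0 (both routes), forces."""
    pairs = (
        sorted(ka_by_temperature.items())
        if isinstance(ka_by_temperature, Mapping)
        else sorted(ka_by_temperature)
    )
    dH0, dS0, r = vant_hoff_fit(pairs)
    temps = tuple(t for t, _ in pairs)
    return ThermoResult(
        dH0_kJ_mol=dH0,
        dS0_J_mol_K=dS0,
        r=r,
        temperatures_K=temps,
        dG0_kJ_mol=tuple(gibbs(dH0, dS0, t) for t in temps),
        dG0_from_ka_kJ_mol=tuple(gibbs_from_ka(k, t) for t, k in pairs),
        force_label=classify_forces(dH0, dS0),
    )
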