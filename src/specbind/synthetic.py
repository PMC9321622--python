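"""Ground-truth synthetic data generators.

Every generator is the right-inverse of its analysis stage at zero noise:
a titration built from a binding law is recovered exactly by the
Stern-Volmer and double-logarithm fits, a two-Gaussian donor/acceptor pair
carries a reference overlap integral computed by fine-grid quadrature, a
CD trace hits a requested alpha-helix percentage, an amide-I envelope is a
known sum of Gaussian bands, and a DPPH series follows an exact
log-logistic law.  Defaults mirror a typical serum-albumin/flavonoid
titration: 2.5e-6 M protein, ligand from 0 to 2.5e-5 M in 2.5e-6 M steps,
excitation 280 nm, emission band near 327 nm, binding thermodynamics
dH0 = -14.12 kJ/mol and dS0 = 43.57 J/mol/K with 1:1 stoichiometry.

All randomness flows through a single numpy Generator seeded explicitly;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .antioxidant import DpphAssay
from .conformation import DEFAULT_AMIDE1_BANDS, MRE208_COIL, MRE208_HELIX
from .quenching import TitrationSeries
from .spectra import Spectrum
from .thermo import GAS_CONSTANT

__all__ = [
    "GroundTruth",
    "ka_at",
    "gen_titration",
    "gen_emission_spectra",
    "gen_synchronous",
    "gen_fret_pair",
    "gen_eem",
    "gen_cd",
    "gen_ftir",
    "gen_dpph",
]

#: Default titration grid: 0 to 2.5e-5 M in 2.5e-6 M steps (11 points).
DEFAULT_CONCENTRATIONS = tuple(np.arange(0, 11) * 2.5e-6)


@dataclass(frozen=True)
class GroundTruth:
    """The generating parameters shared by all synthetic datasets."""

    dH0_kJ_mol: float = -14.12
    dS0_J_mol_K: float = 43.57
    n_sites: float = 1.0
    tau0_s: float = 1e-8
    f0: float = 1539.0  # unquenched peak intensity, a.u.
    emission_center_nm: float = 327.0
    emission_sigma_nm: float = 18.0
    excitation_nm: float = 280.0
    red_shift_nm_per_step: float = 0.2
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    temperatures_K: tuple[float, ...] = (288.0, 298.0, 310.0)
    # FRET pair (two Gaussians)
    donor_center_nm: float = 330.0
    donor_sigma_nm: float = 20.0
    donor_amplitude: float = 1000.0
    acceptor_center_nm: float = 340.0
    acceptor_sigma_nm: float = 25.0
    acceptor_peak_eps: float = 1.0e4  # M^-1 cm^-1
    # CD / FTIR
    alpha_helix_percent: float = 59.24
    cp_mol_L: float = 2.5e-6
    n_residues: int = 585
    path_length_cm: float = 0.1
    ftir_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "beta_sheet": 10.60,
            "random_coil": 14.63,
            "alpha_helix": 59.06,
            "beta_turn": 13.86,
            "beta_antiparallel": 1.85,
        }
    )
    # DPPH
    ic50_ug_mL: float = 9.653
    hill: float = 1.2
    dpph_concentrations: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    a_control: float = 0.80
    seed: int = 0


def ka_at(truth: GroundTruth, temperature_K: float) -> float:
    """Binding constant implied by the Van't Hoff law at one temperature."""
    ln_ka = (
        -truth.dH0_kJ_mol * 1000.0 / (GAS_CONSTANT * temperature_K)
        + truth.dS0_J_mol_K / GAS_CONSTANT
    )
    return float(np.exp(ln_ka))


def _quenched_intensities(truth: GroundTruth, ka: float, q: np.ndarray) -> np.ndarray:
    """F from (F0 - F)/F = Ka * [Q]^n  =>  F = F0 / (1 + Ka [Q]^n)."""
    return truth.f0 / (1.0 + ka * q**truth.n_sites)


def gen_titration(
    truth: GroundTruth,
    temperatures: Sequence[float] | None = None,
    noise: float = 0.0,
    seed: int | None = None,
) -> dict[float, TitrationSeries]:
    """Fluorescence titrations, one series per temperature.

    Intensities follow the 1:1 static-quenching binding law at the
    temperature's Van't Hoff Ka; Gaussian noise of standard deviation
    ``noise * F0`` is added to the quenched intensities (never to F0).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    temps = tuple(temperatures) if temperatures is not None else truth.temperatures_K
    q = np.asarray(truth.concentrations, dtype=float)
    out: dict[float, TitrationSeries] = {}
    for t in temps:
        f = _quenched_intensities(truth, ka_at(truth, t), q)
        if noise > 0:
            f = f + rng.normal(0.0, noise * truth.f0, size=f.size)
            f = np.clip(f, 1e-9 * truth.f0, None)
        out[t] = TitrationSeries(
            concentrations=q,
            intensities=f,
            f0=truth.f0,
            temperature_K=t,
            label=f"synthetic T={t:g}K seed={truth.seed if seed is None else seed}",
        )
    return out


def gen_emission_spectra(
    truth: GroundTruth,
    temperature_K: float = 298.0,
    noise: float = 0.0,
    seed: int | None = None,
    grid: np.ndarray | None = None,
) -> tuple[list[Spectrum], TitrationSeries]:
    """Full emission spectra across a titration at one temperature.

    Each spectrum is a Gaussian band whose amplitude follows the binding
    law and whose center red-shifts linearly with the titration step.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if grid is None:
        grid = np.arange(220.0, 500.0 + 1e-9, 1.0)
    q = np.asarray(truth.concentrations, dtype=float)
    amps = _quenched_intensities(truth, ka_at(truth, temperature_K), q)
    spectra = []
    for step, amp in enumerate(amps):
        center = truth.emission_center_nm + truth.red_shift_nm_per_step * step
        signal = amp * np.exp(-((grid - center) ** 2) / (2 * truth.emission_sigma_nm**2))
        if noise > 0:
            signal = signal + rng.normal(0.0, noise * truth.f0, size=grid.size)
        spectra.append(
            Spectrum(grid.copy(), signal, "emission", label=f"step {step} [Q]={q[step]:g}")
        )
    series = TitrationSeries(
        concentrations=q,
        intensities=np.clip(amps, 1e-12, None),
        f0=truth.f0,
        temperature_K=temperature_K,
    )
    return spectra, series


def gen_synchronous(
    truth: GroundTruth,
    delta_lambda_nm: float,
    ksv: float,
    shift_total_nm: float,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[list[Spectrum], np.ndarray]:
    """Synchronous-fluorescence titration with a programmed total shift.

    Peak intensities follow F0/F = 1 + Ksv*[Q]; the peak center moves
    linearly from its initial position to +``shift_total_nm`` at the final
    concentration.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    q = np.asarray(truth.concentrations, dtype=float)
    grid = np.arange(250.0, 400.0 + 1e-9, 0.5)
    n = q.size
    spectra = []
    for i, qi in enumerate(q):
        amp = truth.f0 / (1.0 + ksv * qi)
        center = truth.emission_center_nm + shift_total_nm * (i / (n - 1))
        signal = amp * np.exp(-((grid - center) ** 2) / (2 * truth.emission_sigma_nm**2))
        if noise > 0:
            signal = signal + rng.normal(0.0, noise * truth.f0, size=grid.size)
        spectra.append(Spectrum(grid.copy(), signal, "emission", label=f"sync dl={delta_lambda_nm}"))
    return spectra, q


def gen_fret_pair(
    truth: GroundTruth, grid_step_nm: float = 0.5, oracle_refine: int = 10
) -> tuple[Spectrum, Spectrum, float]:
    """Donor emission / acceptor molar-absorptivity pair with reference J.

    Both spectra are Gaussians on a shared wavelength range; the returned
    reference overlap integral is computed by trapezoid quadrature on a
    grid ``oracle_refine`` times finer (standard convention, nm^4 M^-1 cm^-1).
    """
    lo = min(truth.donor_center_nm - 6 * truth.donor_sigma_nm,
             truth.acceptor_center_nm - 6 * truth.acceptor_sigma_nm)
    hi = max(truth.donor_center_nm + 6 * truth.donor_sigma_nm,
             truth.acceptor_center_nm + 6 * truth.acceptor_sigma_nm)
    grid = np.arange(lo, hi + 1e-9, grid_step_nm)

    def donor(x: np.ndarray) -> np.ndarray:
        return truth.donor_amplitude * np.exp(
            -((x - truth.donor_center_nm) ** 2) / (2 * truth.donor_sigma_nm**2)
        )

    def acceptor(x: np.ndarray) -> np.ndarray:
        return truth.acceptor_peak_eps * np.exp(
            -((x - truth.acceptor_center_nm) ** 2) / (2 * truth.acceptor_sigma_nm**2)
        )

    fine = np.arange(lo, hi + 1e-9, grid_step_nm / oracle_refine)
    j_ref = float(
        np.trapezoid(donor(fine) * acceptor(fine) * fine**4, fine)
        / np.trapezoid(donor(fine), fine)
    )
    d = Spectrum(grid.copy(), donor(grid), "emission", label="synthetic donor")
    a = Spectrum(grid.copy(), acceptor(grid), "molar_absorptivity", label="synthetic acceptor")
    return d, a, j_ref


def gen_eem(
    blobs: Sequence[tuple[float, float, float]],
    ex_grid: np.ndarray | None = None,
    em_grid: np.ndarray | None = None,
    sigma_nm: float = 8.0,
):
    """Excitation-emission matrix as a sum of Gaussian blobs.

    ``blobs`` is a sequence of (excitation center, emission center,
    amplitude); grids default to 5 nm steps over 220-400 / 220-500 nm.
    """
    from .spectra import EEMatrix

    if ex_grid is None:
        ex_grid = np.arange(220.0, 400.0 + 1e-9, 5.0)
    if em_grid is None:
        em_grid = np.arange(220.0, 500.0 + 1e-9, 5.0)
    z = np.zeros((ex_grid.size, em_grid.size))
    for cx, cm, amp in blobs:
        z += amp * np.exp(
            -((ex_grid[:, None] - cx) ** 2 + (em_grid[None, :] - cm) ** 2)
            / (2 * sigma_nm**2)
        )
    return EEMatrix(ex_grid, em_grid, z)


def gen_cd(
    truth: GroundTruth,
    alpha_helix_percent: float | None = None,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[Spectrum, float]:
    """CD trace (200-240 nm, mdeg) hitting a target alpha-helix percent.

    The trace is a sum of two negative Gaussian bands at 208 and 222 nm
    scaled so the 208 nm reading corresponds exactly to the MRE implied by
    the target helix content.  Returns the spectrum and theta_obs at 208 nm.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    target = truth.alpha_helix_percent if alpha_helix_percent is None else alpha_helix_percent
    mre208 = MRE208_COIL + (MRE208_HELIX - MRE208_COIL) * target / 100.0
    theta208 = mre208 * 10.0 * truth.cp_mol_L * truth.n_residues * truth.path_length_cm
    grid = np.arange(200.0, 240.0 + 1e-9, 0.5)
    band1 = np.exp(-((grid - 208.0) ** 2) / (2 * 6.0**2))
    band2 = 0.9 * np.exp(-((grid - 222.0) ** 2) / (2 * 7.0**2))
    shape = band1 + band2
    at208 = shape[np.argmin(np.abs(grid - 208.0))]
    signal = theta208 * shape / at208
    if noise > 0:
        signal = signal + rng.normal(0.0, noise * abs(theta208), size=grid.size)
    return Spectrum(grid, signal, "ellipticity", label="synthetic CD"), float(theta208)


def gen_ftir(
    truth: GroundTruth,
    fractions: Mapping[str, float] | None = None,
    total_area: float = 10.0,
    sigma_cm: float = 7.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[Spectrum, dict[str, float]]:
    """Amide-I envelope from known per-class band areas.

    One Gaussian per class at the default band centers, with areas
    proportional to the requested fractions; noise is Gaussian with
    standard deviation ``noise`` times the envelope maximum.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    fr = dict(truth.ftir_fractions if fractions is None else fractions)
    total = sum(fr.values())
    fr = {k: 100.0 * v / total for k, v in fr.items()}
    centers = {b.name: b.center for b in DEFAULT_AMIDE1_BANDS}
    grid = np.arange(1590.0, 1710.0 + 1e-9, 1.0)
    signal = np.zeros_like(grid)
    for name, pct in fr.items():
        area = total_area * pct / 100.0
        c = centers[name]
        signal += area / (sigma_cm * np.sqrt(2 * np.pi)) * np.exp(
            -((grid - c) ** 2) / (2 * sigma_cm**2)
        )
    if noise > 0:
        signal = signal + rng.normal(0.0, noise * signal.max(), size=grid.size)
        signal = np.clip(signal, 0.0, None)
    return Spectrum(grid, signal, "ftir", label="synthetic amide-I"), fr


def gen_dpph(
    truth: GroundTruth,
    conditions: Mapping[str, float] | None = None,
    noise: float = 0.0,
    seed: int | None = None,
) -> dict[str, DpphAssay]:
    """DPPH assays from an exact log-logistic scavenging law.

    ``conditions`` maps a label to its IC50 (default: the free ligand at
    ``truth.ic50_ug_mL`` and the protein-bound ligand at 10.68 ug/mL).
    Absorbances are A_control * (1 - pct/100) plus Gaussian noise of
    standard deviation ``noise * A_control``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if conditions is None:
        conditions = {"free": truth.ic50_ug_mL, "complexed": 10.68}
    c = np.asarray(truth.dpph_concentrations, dtype=float)
    out: dict[str, DpphAssay] = {}
    for label, ic50 in conditions.items():
        pct = 100.0 / (1.0 + (ic50 / c) ** truth.hill)
        a = truth.a_control * (1.0 - pct / 100.0)
        if noise > 0:
            a = np.clip(a + rng.normal(0.0, noise * truth.a_control, size=a.size), 0.0, None)
        out[label] = DpphAssay(
            concentrations_ug_mL=c,
            a_control=truth.a_control,
            a_sample=a,
            condition=label,
        )
    return out
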