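"""Core spectral containers, delimited-text I/O, and peak/shift metrics.

A :class:`Spectrum` is a single one-dimensional trace: an ordered axis
(wavelength in nm for UV-Vis / fluorescence / CD, wavenumber in cm^-1 for
FTIR) plus a signal of equal length.  An :class:`EEMatrix` is a full
excitation x emission fluorescence landscape.  Every downstream stage
(quenching, FRET, conformation) consumes these containers.

Peak localisation is deliberately grid-based: instruments report peak
positions on their scan grids, so no sub-grid interpolation is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Spectrum",
    "EEMatrix",
    "PeakSummary",
    "read_spectrum",
    "write_spectrum",
    "read_eem",
    "write_eem",
    "peak_of",
    "shift_metrics",
    "find_3d_peaks",
    "peaks_to_json",
]

#: Spectrum kinds whose signal must be non-negative.
_NONNEGATIVE_KINDS = {"absorbance", "molar_absorptivity"}

_KINDS = {"emission", "absorbance", "molar_absorptivity", "ellipticity", "ftir"}


@dataclass(frozen=True)
class Spectrum:
    """One spectral trace.

    Parameters
    ----------
    axis:
        Strictly monotone axis values (nm or cm^-1).  A decreasing axis
        (common for FTIR exports) is normalised to increasing order on
        construction, co-reversing the signal.
    signal:
        Signal values, same length as ``axis``.
    kind:
        One of ``emission``, ``absorbance``, ``molar_absorptivity``,
        ``ellipticity``, ``ftir``.
    label:
        Free-text provenance tag.
    """

    axis: np.ndarray
    signal: np.ndarray
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if axis.ndim != 1 or signal.ndim != 1:
            raise ValueError("axis and signal must be one-dimensional")
        if axis.size != signal.size:
            raise ValueError(
                f"axis and signal lengths differ ({axis.size} != {signal.size})"
            )
        if axis.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if not np.all(np.isfinite(axis)) or not np.all(np.isfinite(signal)):
            raise ValueError("axis and signal must be finite")
        d = np.diff(axis)
        label = self.label
        if np.all(d < 0):  # stored decreasing: normalise
            axis = axis[::-1].copy()
            signal = signal[::-1].copy()
            if "reversed" not in label:
                label = (label + " [reversed]").strip()
        elif not np.all(d > 0):
            raise ValueError("axis must be strictly monotone")
        if self.kind in _NONNEGATIVE_KINDS and np.any(signal < 0):
            raise ValueError(f"{self.kind} signal must be non-negative")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "label", label)

    def __len__(self) -> int:
        return self.axis.size

    def with_signal(self, signal: np.ndarray) -> "Spectrum":
        return replace(self, signal=np.asarray(signal, dtype=float))


@dataclass(frozen=True)
class EEMatrix:
    """Excitation-emission fluorescence matrix.

    ``intensity[i, j]`` is the reading at excitation ``excitation[i]`` and
    emission ``emission[j]`` (both in nm).
    """

    excitation: np.ndarray
    emission: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        if z.shape != (ex.size, em.size):
            raise ValueError(
                f"intensity shape {z.shape} does not match axes "
                f"({ex.size}, {em.size})"
            )
        if not (np.all(np.diff(ex) > 0) and np.all(np.diff(em) > 0)):
            raise ValueError("EEM axes must be strictly increasing")
        if not np.all(np.isfinite(z)):
            raise ValueError("EEM intensities must be finite")
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "emission", em)
        object.__setattr__(self, "intensity", z)


@dataclass(frozen=True)
class PeakSummary:
    """One fluorescence peak of an EEM: position, Stokes shift, intensity."""

    excitation_nm: float
    emission_nm: float
    stokes_shift_nm: float = field(default=None)  # type: ignore[assignment]
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.stokes_shift_nm is None:
            object.__setattr__(
                self, "stokes_shift_nm", self.emission_nm - self.excitation_nm
            )
        elif abs(self.stokes_shift_nm - (self.emission_nm - self.excitation_nm)) > 1e-9:
            raise ValueError("Stokes shift must equal emission - excitation")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")

    def as_dict(self) -> dict:
        return {
            "excitation_nm": self.excitation_nm,
            "emission_nm": self.emission_nm,
            "stokes_shift_nm": self.stokes_shift_nm,
            "intensity": self.intensity,
        }


# ---------------------------------------------------------------------------
# I/O


class SpectrumParseError(ValueError):
    """Raised when a delimited spectrum file contains a malformed row."""


def _split_row(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        # auto: comma first, else any whitespace
        return line.split(",") if "," in line else line.split()
    return line.split(delimiter)


def read_spectrum(
    path: str | Path,
    kind: str,
    *,
    delimiter: str | None = None,
    comment: str = "#",
    label: str | None = None,
) -> Spectrum:
    """Read a two-column delimited text file into a :class:`Spectrum`.

    The first numeric column is the axis, the second the signal.  A single
    non-numeric header line is tolerated; any later non-numeric row raises
    :class:`SpectrumParseError` naming the offending line.  A decreasing
    axis (FTIR convention) is normalised to increasing order.
    """
    path = Path(path)
    axis: list[float] = []
    signal: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (comment and line.startswith(comment)):
                continue
            parts = [p.strip() for p in _split_row(line, delimiter) if p.strip()]
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not axis:
                    continue  # header
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value in {parts[:2]!r}"
                ) from None
            axis.append(x)
            signal.append(y)
    if len(axis) < 2:
        raise ValueError(f"{path}: fewer than 2 data points")
    return Spectrum(
        np.array(axis), np.array(signal), kind, label=label or path.stem
    )


def write_spectrum(spectrum: Spectrum, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a spectrum as two-column delimited text (full precision)."""
    with open(path, "w") as fh:
        fh.write(f"# kind={spectrum.kind} label={spectrum.label}\n")
        for x, y in zip(spectrum.axis, spectrum.signal):
            fh.write(f"{float(x)!r}{delimiter}{float(y)!r}\n")


def read_eem(path: str | Path) -> EEMatrix:
    """Read an EEM from CSV: first row the emission axis (first cell blank
    or a label), first column the excitation axis."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([p.strip() for p in line.split(",")])
    em = np.array([float(v) for v in rows[0][1:]])
    ex = np.array([float(r[0]) for r in rows[1:]])
    z = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return EEMatrix(ex, em, z)


def write_eem(eem: EEMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ex\\em," + ",".join(repr(float(v)) for v in eem.emission) + "\n")
        for x, row in zip(eem.excitation, eem.intensity):
            fh.write(f"{float(x)!r}," + ",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Metrics


def _window_mask(axis: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(axis, dtype=bool)
    lo, hi = min(window), max(window)
    return (axis >= lo) & (axis <= hi)


def peak_of(
    spectrum: Spectrum, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Position and value of the maximum signal inside ``window``.

    Ties are broken toward the smaller axis value.  No interpolation: the
    returned position is a grid point of the spectrum.
    """
    mask = _window_mask(spectrum.axis, window)
    if mask.sum() < 1:
        raise ValueError(f"window {window} contains no axis points")
    if window is not None and mask.sum() < 3:
        raise ValueError(f"window {window} must contain at least 3 points")
    sub_axis = spectrum.axis[mask]
    sub_sig = spectrum.signal[mask]
    i = int(np.argmax(sub_sig))  # argmax returns the first (smallest-axis) max
    return float(sub_axis[i]), float(sub_sig[i])


def shift_metrics(
    reference: Spectrum,
    perturbed: Spectrum,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Peak shift and percent intensity change between two spectra.

    Returns ``(delta_lambda, percent_change)`` where
    ``delta_lambda = peak(perturbed) - peak(reference)`` (positive = red
    shift) and ``percent_change = 100 * (I_ref - I_pert) / I_ref``
    (positive = intensity decrease).
    """
    if reference.kind != perturbed.kind:
        raise ValueError(
            f"spectra kinds differ ({reference.kind} vs {perturbed.kind})"
        )
    lam_ref, i_ref = peak_of(reference, window)
    lam_pert, i_pert = peak_of(perturbed, window)
    if i_ref == 0:
        raise ValueError("reference peak intensity is zero; percent change undefined")
    return lam_pert - lam_ref, 100.0 * (i_ref - i_pert) / i_ref


def find_3d_peaks(
    eem: EEMatrix, scatter_exclusion_halfwidth: float = 15.0
) -> list[PeakSummary]:
    """Local maxima of an EEM outside the Rayleigh-scatter bands.

    Cells with ``|em - ex| <= halfwidth`` (first-order scatter) or
    ``|em - 2*ex| <= halfwidth`` (second-order) are excluded.  Remaining
    local maxima (8-connected neighbourhood) are returned sorted by
    intensity, descending.  An EEM whose cells are all excluded yields an
    empty list.
    """
    if scatter_exclusion_halfwidth < 0:
        raise ValueError("scatter exclusion halfwidth must be >= 0")
    ex = eem.excitation[:, None]
    em = eem.emission[None, :]
    hw = scatter_exclusion_halfwidth
    excluded = (np.abs(em - ex) <= hw) | (np.abs(em - 2.0 * ex) <= hw)

    # locate maxima on the raw data (excluded cells still take part in the
    # neighbour comparison, so a blob centred inside a scatter band does not
    # spawn spurious edge peaks), then drop maxima inside the bands
    z = eem.intensity
    local_max = (z == ndimage.maximum_filter(z, size=3, mode="nearest")) & ~excluded

    peaks = [
        PeakSummary(
            excitation_nm=float(eem.excitation[i]),
            emission_nm=float(eem.emission[j]),
            intensity=float(eem.intensity[i, j]),
        )
        for i, j in zip(*np.nonzero(local_max))
    ]
    peaks.sort(key=lambda p: -p.intensity)
    return peaks


def peaks_to_json(peaks: Sequence[PeakSummary]) -> str:
    return json.dumps([p.as_dict() for p in peaks], indent=2)
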