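"""Pipeline orchestration and consolidated reporting.

``run_pipeline`` executes whichever analysis stages have inputs configured
(quenching -> binding -> thermodynamics from one titration table; site
competition, FRET, CD, FTIR and DPPH independently) and collects the
results into a :class:`Report` that serialises to JSON and to Markdown
tables.  A stage that fails is recorded in the report without aborting the
others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .antioxidant import DpphAssay, attenuation_report, fit_ic50
from .binding import competition_analysis, double_log_fit
from .conformation import CdParams, alpha_helix_fraction, amide1_band_fit, mean_residue_ellipticity
from .fret import FretConfig, fret_chain
from .quenching import HSA_LIFETIME_S, DIFFUSION_LIMIT_KQ, TitrationSeries, classify_quenching, stern_volmer_fit
from .spectra import read_spectrum
from .thermo import thermodynamic_analysis

__all__ = ["Report", "run_pipeline", "load_titration_table", "load_dpph_table"]

log = logging.getLogger("specbind")


@dataclass
class Report:
    """Consolidated per-stage results with provenance."""

    sections: dict[str, Any] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    config_hash: str = ""
    version: str = __version__

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "inputs": self.inputs,
                "sections": self.sections,
                "errors": self.errors,
            },
            indent=indent,
            default=_jsonify,
        )

    def to_markdown(self) -> str:
        lines = [f"# specbind report (v{self.version})", ""]
        lines.append(f"config hash: `{self.config_hash}`")
        lines.append("")
        for name, section in self.sections.items():
            lines.append(f"## {name}")
            lines.append("")
            lines.extend(_markdown_section(section))
            lines.append("")
        if self.errors:
            lines.append("## errors")
            for stage, msg in self.errors.items():
                lines.append(f"- **{stage}**: {msg}")
        return "\n".join(lines)


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _markdown_section(section: Any) -> list[str]:
    if isinstance(section, list) and section and isinstance(section[0], dict):
        keys = list(section[0].keys())
        out = ["| " + " | ".join(keys) + " |", "|" + "---|" * len(keys)]
        for row in section:
            out.append("| " + " | ".join(_fmt(row.get(k)) for k in keys) + " |")
        return out
    if isinstance(section, dict):
        return [f"- **{k}**: {_fmt(v)}" for k, v in section.items()]
    return [str(section)]


def _fmt(v: Any) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


# ---------------------------------------------------------------------------
# table loaders


def load_titration_table(path: str | Path, label: str = "") -> dict[float, TitrationSeries]:
    """Long-format titration table -> one series per temperature.

    Columns: ``temperature_K``, ``quencher_mol_per_L``, ``intensity``.
    F0 is the intensity at zero quencher concentration when present,
    otherwise the maximum intensity in the series.
    """
    df = pd.read_csv(path)
    required = {"temperature_K", "quencher_mol_per_L", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[float, TitrationSeries] = {}
    for t, grp in df.groupby("temperature_K"):
        grp = grp.sort_values("quencher_mol_per_L")
        q = grp["quencher_mol_per_L"].to_numpy(float)
        f = grp["intensity"].to_numpy(float)
        f0 = float(f[q == 0][0]) if np.any(q == 0) else float(f.max())
        out[float(t)] = TitrationSeries(
            concentrations=q, intensities=f, f0=f0, temperature_K=float(t), label=label
        )
    return out


def load_dpph_table(path: str | Path, condition: str = "") -> DpphAssay:
    """DPPH table with columns ``concentration_ug_per_mL``, ``absorbance``.

    The zero-concentration row is the DPPH control.
    """
    df = pd.read_csv(path).sort_values("concentration_ug_per_mL")
    c = df["concentration_ug_per_mL"].to_numpy(float)
    a = df["absorbance"].to_numpy(float)
    if not np.any(c == 0):
        raise ValueError(f"{path}: needs a zero-concentration control row")
    a_control = float(a[c == 0][0])
    mask = c > 0
    return DpphAssay(
        concentrations_ug_mL=c[mask], a_control=a_control, a_sample=a[mask],
        condition=condition or Path(path).stem,
    )


# ---------------------------------------------------------------------------
# pipeline


def _hash_config(config: Mapping[str, Any]) -> str:
    h = hashlib.sha256()
    h.update(json.dumps({k: v for k, v in sorted(config.items())}, default=str).encode())
    for key, value in sorted(config.items()):
        if isinstance(value, str) and Path(value).is_file():
            h.update(Path(value).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any]) -> Report:
    """Run every stage whose inputs are configured; see module docstring.

    Recognised keys (all optional, at least one stage required):
    ``titration``; ``competition_blank`` plus ``competition_<marker>``;
    ``fret_donor``/``fret_acceptor``/``fret_f``/``fret_f0``; ``cd`` plus
    ``cd_cp``/``cd_n_residues``/``cd_path_length``; ``ftir``;
    ``dpph_free``/``dpph_complexed``; constants ``tau0``, ``kq_threshold``,
    ``k2``, ``n_refr``, ``phi``, ``competition_threshold``.
    """
    config = dict(config)
    report = Report(config_hash=_hash_config(config))

    stage_keys = ("titration", "competition_blank", "fret_donor", "cd", "ftir", "dpph_free")
    if not any(config.get(k) for k in stage_keys):
        raise ValueError("empty config: no stage inputs given")
    for key, value in config.items():
        if isinstance(value, str) and (key in stage_keys or key.startswith(("competition_", "fret_", "dpph_"))):
            if key in ("fret_f", "fret_f0"):
                continue
            if not Path(value).is_file():
                raise ValueError(f"input path for {key!r} does not exist: {value}")
            report.inputs[key] = value

    if config.get("titration"):
        _stage(report, "quenching", _run_quench, config)
    if config.get("competition_blank"):
        _stage(report, "competition", _run_competition, config)
    if config.get("fret_donor"):
        _stage(report, "fret", _run_fret, config)
    if config.get("cd"):
        _stage(report, "cd", _run_cd, config)
    if config.get("ftir"):
        _stage(report, "ftir", _run_ftir, config)
    if config.get("dpph_free"):
        _stage(report, "dpph", _run_dpph, config)
    return report


def _stage(report: Report, name: str, fn, config: Mapping[str, Any]) -> None:
    try:
        log.info("stage %s: running", name)
        fn(report, config)
    except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
        log.error("stage %s failed: %s", name, exc)
        report.errors[name] = str(exc)


def _run_quench(report: Report, config: Mapping[str, Any]) -> None:
    series = load_titration_table(config["titration"])
    tau0 = float(config.get("tau0", HSA_LIFETIME_S))
    qfits = {t: stern_volmer_fit(s, tau0) for t, s in series.items()}
    report.sections["stern_volmer"] = [
        {"T_K": t, "Ksv_L_mol": f.ksv, "Kq_L_mol_s": f.kq, "R": f.r, "SD": f.sd}
        for t, f in sorted(qfits.items())
    ]
    if len(qfits) >= 2:
        mech = classify_quenching(
            list(qfits.values()), float(config.get("kq_threshold", DIFFUSION_LIMIT_KQ))
        )
        report.sections["mechanism"] = dataclasses.asdict(mech)
    bfits = {t: double_log_fit(s) for t, s in series.items()}
    report.sections["binding"] = [
        {"T_K": t, "Ka_L_mol": f.ka, "n": f.n, "R": f.r, "Ka_SD": f.ka_sd}
        for t, f in sorted(bfits.items())
    ]
    if len(bfits) >= 2:
        thermo = thermodynamic_analysis({t: f.ka for t, f in bfits.items()})
        report.sections["thermodynamics"] = dataclasses.asdict(thermo)


def _run_competition(report: Report, config: Mapping[str, Any]) -> None:
    blank_series = load_titration_table(config["competition_blank"], label="blank")
    blank_fit = double_log_fit(next(iter(blank_series.values())))
    marker_fits = {}
    for key, value in config.items():
        if key.startswith("competition_") and key not in ("competition_blank", "competition_threshold"):
            marker = key.removeprefix("competition_")
            marker_series = load_titration_table(value, label=marker)
            marker_fits[marker] = double_log_fit(next(iter(marker_series.values())))
    result = competition_analysis(
        blank_fit, marker_fits, float(config.get("competition_threshold", 50.0))
    )
    report.sections["competition"] = dataclasses.asdict(result)


def _run_fret(report: Report, config: Mapping[str, Any]) -> None:
    donor = read_spectrum(config["fret_donor"], "emission")
    acceptor = read_spectrum(config["fret_acceptor"], "molar_absorptivity")
    cfg = FretConfig(
        k2=float(config.get("k2", 2.0 / 3.0)),
        n_refr=float(config.get("n_refr", 1.336)),
        phi=float(config.get("phi", 0.118)),
        convention=str(config.get("fret_convention", "standard")),
    )
    result = fret_chain(
        donor, acceptor, f=float(config["fret_f"]), f0=float(config["fret_f0"]), config=cfg
    )
    report.sections["fret"] = dataclasses.asdict(result)


def _run_cd(report: Report, config: Mapping[str, Any]) -> None:
    spec = read_spectrum(config["cd"], "ellipticity")
    idx = int(np.argmin(np.abs(spec.axis - 208.0)))
    theta208 = float(spec.signal[idx])
    params = CdParams(
        theta_obs_mdeg=theta208,
        cp_mol_L=float(config.get("cd_cp", 2.5e-6)),
        n_residues=int(config.get("cd_n_residues", 585)),
        path_length_cm=float(config.get("cd_path_length", 0.1)),
    )
    mre = mean_residue_ellipticity(params)
    report.sections["cd"] = {
        "theta208_mdeg": theta208,
        "MRE208_deg_cm2_dmol": mre,
        "alpha_helix_percent": alpha_helix_fraction(mre),
    }


def _run_ftir(report: Report, config: Mapping[str, Any]) -> None:
    spec = read_spectrum(config["ftir"], "ftir")
    ss = amide1_band_fit(spec)
    report.sections["ftir"] = {
        "fractions_percent": dict(ss.fractions),
        "band_centers_cm": dict(ss.band_centers),
        "residual": ss.residual,
    }


def _run_dpph(report: Report, config: Mapping[str, Any]) -> None:
    free = fit_ic50(load_dpph_table(config["dpph_free"], "free"))
    section: dict[str, Any] = {"free": dataclasses.asdict(free)}
    if config.get("dpph_complexed"):
        complexed = fit_ic50(load_dpph_table(config["dpph_complexed"], "complexed"))
        section["complexed"] = dataclasses.asdict(complexed)
        section["attenuation"] = dataclasses.asdict(attenuation_report(free, complexed))
    report.sections["dpph"] = section
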