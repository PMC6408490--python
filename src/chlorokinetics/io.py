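"""CSV/YAML I/O, run configuration, and the end-to-end pipeline.

Profile files are plain CSV with a metadata header of ``# key=value`` lines
carrying the experiment condition, followed by long-format columns
``time_ks, species, conc_M``. Time may instead be given as ``time_min`` and
concentration as ``conc_mM``; both are normalized to ks and M on read.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExperimentCondition,
    FormatError,
    KineticProfile,
    RateFit,
    ValidationError,
)
from . import chloride, kinetics, synthetic, thermo

__all__ = [
    "write_profile",
    "read_profile",
    "read_profiles",
    "write_fits_csv",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("chlorokinetics")
if not logger.handlers:  # stderr INFO logging, configured once on import
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

_CONDITION_KEYS = {
    "solvent": str,
    "gvl_massfrac": float,
    "acid_name": str,
    "acid_conc_M": float,
    "salt_name": str,
    "salt_conc_M": float,
    "anion": str,
    "temperature_K": float,
    "isotope": str,
}

#: accepted column aliases -> (canonical, multiplicative factor to internal units)
_TIME_COLS = {"time_ks": 1.0, "time_min": 0.06}  # 1 min = 0.06 ks
_CONC_COLS = {"conc_M": 1.0, "conc_mM": 1e-3}


def _condition_to_header(cond: ExperimentCondition) -> List[str]:
    vals = {
        "solvent": cond.solvent,
        "gvl_massfrac": cond.gvl_massfrac,
        "acid_name": cond.acid_name,
        "acid_conc_M": cond.acid_conc,
        "salt_name": cond.salt_name if cond.salt_name is not None else "",
        "salt_conc_M": cond.salt_conc,
        "anion": cond.anion,
        "temperature_K": cond.temperature,
        "isotope": cond.isotope,
    }
    return [f"# {k}={v}" for k, v in vals.items()]


def _condition_from_header(meta: Dict[str, str], path) -> ExperimentCondition:
    try:
        return ExperimentCondition(
            solvent=meta.get("solvent", "GVL/H2O"),
            gvl_massfrac=float(meta.get("gvl_massfrac", 0.0)),
            acid_name=meta.get("acid_name", ""),
            acid_conc=float(meta.get("acid_conc_M", 0.0)),
            salt_name=meta.get("salt_name") or None,
            salt_conc=float(meta.get("salt_conc_M", 0.0)),
            anion=meta.get("anion", "none"),
            temperature=float(meta.get("temperature_K", 373.0)),
            isotope=meta.get("isotope", "H"),
        )
    except (ValueError, ValidationError) as exc:
        raise FormatError(f"{path}: bad condition header: {exc}") from exc


def write_profile(profile: KineticProfile, path: Union[str, Path]) -> Path:
    """Write one profile in the documented CSV dialect (long format)."""
    path = Path(path)
    lines = _condition_to_header(profile.condition)
    lines.append("time_ks,species,conc_M")
    for species, conc in profile.concentrations.items():
        for t, c in zip(profile.times, conc):
            lines.append(f"{float(t)!r},{species},{float(c)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_profile(path: Union[str, Path]) -> KineticProfile:
    """Read one profile CSV, validating format and units."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty input file")
    meta: Dict[str, str] = {}
    data_lines: List[tuple] = []  # (line_number, line)
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        data_lines.append((lineno, stripped))
    if not data_lines:
        raise FormatError(f"{path}: no data rows")

    header = [h.strip() for h in data_lines[0][1].split(",")]
    time_col = next((c for c in _TIME_COLS if c in header), None)
    conc_col = next((c for c in _CONC_COLS if c in header), None)
    if time_col is None or "species" not in header or conc_col is None:
        raise FormatError(
            f"{path}: required columns missing; need one of {list(_TIME_COLS)}, "
            f"'species', and one of {list(_CONC_COLS)}; got {header}"
        )
    it, isp, ic = header.index(time_col), header.index("species"), header.index(conc_col)

    records = []
    bad: List[int] = []
    for lineno, line in data_lines[1:]:
        parts = [p.strip() for p in line.split(",")]
        try:
            records.append(
                (float(parts[it]) * _TIME_COLS[time_col],
                 parts[isp],
                 float(parts[ic]) * _CONC_COLS[conc_col])
            )
        except (ValueError, IndexError):
            bad.append(lineno)
    if bad:
        raise FormatError(f"{path}: malformed data rows at lines {bad}")
    if not records:
        raise FormatError(f"{path}: header but no data rows")

    df = pd.DataFrame(records, columns=["time_ks", "species", "conc_M"])
    times = np.sort(df["time_ks"].unique())
    concentrations = {}
    for species, group in df.groupby("species"):
        g = group.sort_values("time_ks")
        if len(g) != len(times) or np.any(g["time_ks"].to_numpy() != times):
            raise FormatError(
                f"{path}: species {species!r} not observed on the common time grid"
            )
        concentrations[species] = g["conc_M"].to_numpy()
    return KineticProfile(
        condition=_condition_from_header(meta, path),
        times=times,
        concentrations=concentrations,
    )


def read_profiles(path: Union[str, Path]) -> List[KineticProfile]:
    """Read a profile CSV, or every ``*.csv`` in a directory (sorted)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise FormatError(f"{path}: no profile CSVs found")
        return [read_profile(f) for f in files]
    return [read_profile(path)]


def write_fits_csv(fits: Sequence[RateFit], path: Union[str, Path]) -> Path:
    """One row per fitted condition: condition fields then k, ci, sse, n."""
    rows = []
    for fit in fits:
        cond = fit.condition or ExperimentCondition()
        rows.append({
            "solvent": cond.solvent,
            "gvl_massfrac": cond.gvl_massfrac,
            "acid_name": cond.acid_name,
            "acid_conc_M": cond.acid_conc,
            "salt_name": cond.salt_name or "",
            "salt_conc_M": cond.salt_conc,
            "anion": cond.anion,
            "temperature_K": cond.temperature,
            "isotope": cond.isotope,
            "k_M_per_ks": fit.k,
            "ci_low": fit.ci95[0],
            "ci_high": fit.ci95[1],
            "sse": fit.residual_sse,
            "n": fit.n_points,
            "converged": fit.converged,
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run.

    The simulate stage draws a rate-constant-versus-chloride study from
    the reference five-solvent design unless overridden; the Arrhenius
    stage regresses a synthetic temperature ladder. Every defaulted value
    is echoed to the log when the pipeline runs."""

    outdir: Union[str, Path] = "chlorokinetics_run"
    seed: int = 0
    noise_cv: float = 0.05
    simulate: bool = True
    profiles: Optional[str] = None  # pre-existing profile CSV dir (skips simulate)
    ci_method: str = "wald"
    shared_enhancement: bool = True
    selectivity: float = 0.78
    k_deg: float = 1.0
    acid_conc: float = 0.005  # M, polar aprotic mixtures
    acid_conc_water_rich: float = 0.5  # M, water-rich mixtures (slow baseline)
    temperature: float = 373.0  # K
    n_time_points: int = 10
    design: Optional[dict] = None  # overrides for the chloride design
    arrhenius: Optional[dict] = None  # {"Ea":..., "lnA":..., "temperatures":[...]}

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _chloride_design(config: RunConfig) -> synthetic.ChlorideDesign:
    design = synthetic.reference_chloride_design()
    if config.design:
        fields = {
            "solvent_fractions": design.solvent_fractions,
            "k_o": design.k_o,
            "K_Cl": design.K_Cl,
            "r_enhance": design.r_enhance,
            "cl_grid": design.cl_grid,
        }
        fields.update(config.design)
        design = synthetic.ChlorideDesign(**fields)
    return design


def _simulate_stage(config: RunConfig, outdir: Path) -> List[KineticProfile]:
    """Generate one batch profile per (solvent, chloride) design point with
    the true rate constant given by the saturation-enhancement law."""
    design = _chloride_design(config)
    conditions, true_k = [], {}
    for frac, ko, kcl in zip(design.solvent_fractions, design.k_o, design.K_Cl):
        acid = config.acid_conc if frac >= 0.5 else config.acid_conc_water_rich
        for cl in design.cl_grid:
            cond = ExperimentCondition(
                solvent="GVL/H2O", gvl_massfrac=frac, acid_name="H2SO4",
                acid_conc=acid, salt_name="KCl" if cl > 0 else None,
                salt_conc=cl, anion="Cl-" if cl > 0 else "none",
                temperature=config.temperature,
            )
            conditions.append(cond)
            true_k[cond] = chloride.enhanced_rate(ko, design.r_enhance, kcl, cl)

    profiles = []
    profile_dir = outdir / "profiles"
    profile_dir.mkdir(parents=True, exist_ok=True)
    for i, cond in enumerate(conditions):
        # sample out to ~3 half-lives of this condition's decay
        k_decay = true_k[cond] * cond.acid_conc
        t_end = 3.0 * math.log(2.0) / k_decay
        spec = synthetic.GeneratorSpec(
            conditions=conditions, true_k=true_k,
            selectivity=config.selectivity, k_deg=config.k_deg,
            noise_cv=config.noise_cv,
            sample_times=np.linspace(0.0, t_end, config.n_time_points),
            seed=config.seed,
        )
        profile = synthetic.simulate_profile(spec, cond)
        write_profile(profile, profile_dir / f"profile_{i:03d}.csv")
        profiles.append(profile)
    logger.info("simulate: wrote %d profiles to %s", len(profiles), profile_dir)
    return profiles


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate (optional) -> fit-rate -> fit-chloride -> arrhenius and
    write a machine-readable summary.

    Returns the summary dict; also writes ``summary.json`` (sorted keys, no
    timestamps, so reruns with the same seed are byte-identical) and
    ``fits.csv`` under ``config.outdir``. Stages without applicable data are
    skipped with a logged notice."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for f in dataclasses.fields(config):
        logger.info("config: %s=%r", f.name, getattr(config, f.name))

    if config.profiles:
        profiles = read_profiles(config.profiles)
        logger.info("loaded %d profiles from %s", len(profiles), config.profiles)
    elif config.simulate:
        profiles = _simulate_stage(config, outdir)
    else:
        raise ValidationError("config must enable simulate or point at profiles")

    fits = [
        kinetics.fit_rate_constant(p, ci_method=config.ci_method) for p in profiles
    ]
    fits_path = write_fits_csv(fits, outdir / "fits.csv")
    logger.info("fit-rate: %d rate constants -> %s", len(fits), fits_path)

    summary: dict = {
        "schema_version": 1,
        "seed": config.seed,
        "noise_cv": config.noise_cv,
        "n_profiles": len(profiles),
        "rate_fits_csv": fits_path.name,
    }

    # chloride stage: needs >=2 solvents with >=4 chloride levels each
    rows = [
        {
            "gvl_massfrac": f.condition.gvl_massfrac,
            "cl_M": f.condition.salt_conc,
            "k_obs": f.k,
        }
        for f in fits
        if f.converged and f.condition is not None and f.k > 0
    ]
    table = pd.DataFrame(rows)
    usable = (
        not table.empty
        and table.groupby("gvl_massfrac")["cl_M"].nunique().ge(4).sum() >= 2
        and table["cl_M"].gt(0).any()
    )
    if usable:
        model_fit = chloride.fit_global(table, shared=config.shared_enhancement)
        summary["chloride_model"] = {
            "shared": model_fit.shared,
            "r_enhance_dimensionless": model_fit.r_enhance,
            "r_enhance_ci95": list(model_fit.r_enhance_ci95),
            "sse_relative": model_fit.sse,
            "per_solvent": {
                str(label): {
                    "r_o_M_per_ks": sf.r_o,
                    "K_Cl_per_M": sf.K_Cl,
                    "r_squared": sf.r_squared,
                }
                for label, sf in model_fit.per_solvent.items()
            },
        }
        k_free = {
            label: sf.r_o for label, sf in model_fit.per_solvent.items()
        }
        if len(k_free) >= 3:
            rel = chloride.k_vs_Kcl_relation(model_fit, k_free)
            summary["k_vs_Kcl_relation"] = {
                "slope": rel.slope,
                "intercept_M_per_ks": rel.intercept,
                "r_squared": rel.r_squared,
            }
        logger.info(
            "fit-chloride: shared enhancement %.4g",
            model_fit.r_enhance if model_fit.r_enhance is not None else float("nan"),
        )
    else:
        logger.info("fit-chloride: no chloride series in inputs; stage skipped")
        summary["chloride_model"] = None

    if config.arrhenius:
        arr = dict(config.arrhenius)
        table = synthetic.generate_arrhenius_set(
            Ea=float(arr.get("Ea", 110.0)),
            lnA=float(arr.get("lnA", 38.0)),
            temperatures=arr.get("temperatures", [363.0, 373.0, 383.0, 393.0]),
            noise_cv=float(arr.get("noise_cv", config.noise_cv)),
            seed=config.seed + 1,
        )
        afit = thermo.fit_arrhenius(table)
        summary["arrhenius"] = {
            "Ea_kJ_per_mol": afit.Ea,
            "lnA": afit.lnA,
            "Ea_ci95_kJ_per_mol": list(afit.Ea_ci95),
            "r_squared": afit.r_squared,
        }
        logger.info("arrhenius: Ea = %.4g kJ/mol", afit.Ea)
    else:
        logger.info("arrhenius: no temperature ladder configured; stage skipped")

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    logger.info("report: %s", summary_path)
    return summary
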