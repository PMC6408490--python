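"""Chloride transition-state saturation-enhancement model.

A chloride anion binds the rate-determining transition state R‡ with
equilibrium constant K_Cl (Cl- + R‡ <-> RCl‡). The fraction of transition
states carrying a chloride is the saturation (Langmuir) form
f = K_Cl*[Cl-] / (1 + K_Cl*[Cl-]), and with the chloride-bound channel
faster by a factor r_enhance = r_Cl/r_o the observed rate constant is

    k(cl) = k_o * [1 + r_enhance * f(cl)]

— increasing and concave in [Cl-], rising from the chloride-free k_o to the
plateau k_o*(1 + r_enhance). Fitting is per-solvent or global across
solvent mixtures with a single shared r_enhance; residuals are relative
(divided by the model value) so solvents whose rate constants differ by
orders of magnitude contribute comparably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple, Union

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

__all__ = [
    "saturation_fraction",
    "enhanced_rate",
    "TransitionStateSpeciation",
    "SolventFit",
    "ChlorideModelFit",
    "LinearRelation",
    "fit_single_solvent",
    "fit_global",
    "shared_enhancement_ftest",
    "k_vs_Kcl_relation",
]


def saturation_fraction(K_Cl, cl_conc):
    """Fraction of transition states bound to chloride,
    K_Cl*cl/(1 + K_Cl*cl). Accepts scalars or arrays; inputs must be
    nonnegative."""
    K_Cl = np.asarray(K_Cl, dtype=float)
    cl = np.asarray(cl_conc, dtype=float)
    if np.any(K_Cl < 0) or np.any(cl < 0):
        raise ValidationError("K_Cl and cl_conc must be nonnegative")
    out = K_Cl * cl / (1.0 + K_Cl * cl)
    return float(out) if out.ndim == 0 else out


def enhanced_rate(r_o, r_enhance, K_Cl, cl_conc):
    """Observed rate-constant scale k_o*[1 + r_enhance*f(cl)]."""
    r_o = np.asarray(r_o, dtype=float)
    if np.any(r_o < 0) or np.any(np.asarray(r_enhance, float) < 0):
        raise ValidationError("r_o and r_enhance must be nonnegative")
    f = saturation_fraction(K_Cl, cl_conc)
    out = r_o * (1.0 + np.asarray(r_enhance, float) * f)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class TransitionStateSpeciation:
    """Chloride speciation of the transition-state ensemble at one point."""

    K_Cl: float  # M^-1
    cl_conc: float  # M
    fraction_bound: float

    @classmethod
    def at(cls, K_Cl: float, cl_conc: float) -> "TransitionStateSpeciation":
        return cls(K_Cl, cl_conc, saturation_fraction(K_Cl, cl_conc))


@dataclass
class SolventFit:
    """Per-solvent parameters of the saturation-enhancement fit."""

    r_o: float  # M^-1 ks^-1
    K_Cl: float  # M^-1
    r_o_ci95: Tuple[float, float]
    K_Cl_ci95: Tuple[float, float]
    r_squared: float
    kcl_identifiable: bool = True
    r_enhance: Optional[float] = None  # populated by the free (unshared) fit


@dataclass
class ChlorideModelFit:
    """Result of the (global) saturation-enhancement fit.

    ``r_enhance`` is the shared enhancement factor (None when fit per
    solvent, in which case each SolventFit carries its own). ``sse`` is the
    pooled relative-residual sum of squares."""

    per_solvent: Dict[object, SolventFit]
    r_enhance: Optional[float]
    r_enhance_ci95: Tuple[float, float]
    sse: float
    n_points: int
    shared: bool = True


@dataclass
class LinearRelation:
    """Ordinary least-squares line with its goodness of fit."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float = 0.0
    slope_ci95: Tuple[float, float] = (math.nan, math.nan)


TableLike = Union[pd.DataFrame, Tuple[np.ndarray, np.ndarray]]


def _as_cl_k(table: TableLike) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(table, pd.DataFrame):
        cl = table["cl_M"].to_numpy(dtype=float)
        k = table["k_obs"].to_numpy(dtype=float)
    else:
        cl, k = (np.asarray(a, dtype=float) for a in table)
    if np.any(cl < 0):
        raise ValidationError("chloride concentrations must be nonnegative")
    if np.any(k <= 0):
        raise ValidationError("observed rate constants must be positive")
    return cl, k


def _initial_guess(cl: np.ndarray, k: np.ndarray) -> Tuple[float, float, float]:
    """Heuristic start: baseline from the smallest-cl point, enhancement from
    the plateau/baseline ratio, K_Cl from the half-rise concentration."""
    order = np.argsort(cl)
    cl, k = cl[order], k[order]
    r_o = float(k[0])
    plateau = float(np.max(k))
    r_enh = max(plateau / r_o - 1.0, 1e-3)
    half_level = r_o * (1.0 + 0.5 * r_enh)
    above = cl[k >= half_level]
    cl_half = float(above[0]) if above.size and above[0] > 0 else float(
        np.median(cl[cl > 0]) if np.any(cl > 0) else 1.0
    )
    return r_o, r_enh, 1.0 / cl_half


def _relative_residual(k_obs, model):
    return (k_obs - model) / model


_WIDE = 1e6  # relative-stderr threshold flagging a non-identifiable K_Cl


def _param_ci(result, name: str, dof: int) -> Tuple[Tuple[float, float], float]:
    par = result.params[name]
    stderr = par.stderr
    if stderr is None or not math.isfinite(stderr):
        return ((0.0, math.inf), math.inf)
    tcrit = stats.t.ppf(0.975, max(dof, 1))
    lo = max(par.value - tcrit * stderr, 0.0)
    return ((lo, par.value + tcrit * stderr), float(stderr))


def _r_squared(k_obs: np.ndarray, model: np.ndarray) -> float:
    sst = float(np.sum((k_obs - k_obs.mean()) ** 2))
    sse = float(np.sum((k_obs - model) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else 0.0
    return max(0.0, 1.0 - sse / sst)


def fit_single_solvent(table: TableLike) -> ChlorideModelFit:
    """Fit (r_o, K_Cl, r_enhance) to one solvent's k-versus-chloride table.

    Requires at least 4 distinct chloride levels including one near zero.
    A flat table (no curvature) is returned as a flagged fit with an
    infinite K_Cl confidence interval, not an exception."""
    cl, k = _as_cl_k(table)
    if len(np.unique(cl)) < 4:
        raise ValidationError("need >= 4 distinct chloride levels")
    if np.min(cl) > 0.1 * np.max(cl):
        raise ValidationError("need a chloride level near zero for the baseline")

    r_o0, r_enh0, kcl0 = _initial_guess(cl, k)
    params = lmfit.Parameters()
    params.add("r_o", value=r_o0, min=1e-12)
    params.add("r_enhance", value=r_enh0, min=0.0)
    params.add("K_Cl", value=kcl0, min=0.0)

    def residual(p):
        model = enhanced_rate(
            p["r_o"].value, p["r_enhance"].value, p["K_Cl"].value, cl
        )
        return _relative_residual(k, model)

    mini = lmfit.Minimizer(residual, params)
    result = mini.minimize(method="leastsq")
    dof = len(cl) - result.nvarys

    r_o = float(result.params["r_o"].value)
    r_enh = float(result.params["r_enhance"].value)
    kcl = float(result.params["K_Cl"].value)
    r_o_ci, _ = _param_ci(result, "r_o", dof)
    kcl_ci, kcl_err = _param_ci(result, "K_Cl", dof)
    enh_ci, _ = _param_ci(result, "r_enhance", dof)

    identifiable = math.isfinite(kcl_err) and (
        kcl <= 0 or kcl_err / max(kcl, 1e-300) < _WIDE
    )
    if not identifiable:
        kcl_ci = (0.0, math.inf)

    model = enhanced_rate(r_o, r_enh, kcl, cl)
    fit = SolventFit(
        r_o=r_o, K_Cl=kcl, r_o_ci95=r_o_ci, K_Cl_ci95=kcl_ci,
        r_squared=_r_squared(k, model), kcl_identifiable=identifiable,
        r_enhance=r_enh,
    )
    sse = float(np.sum(result.residual**2))
    return ChlorideModelFit(
        per_solvent={"solvent": fit}, r_enhance=r_enh, r_enhance_ci95=enh_ci,
        sse=sse, n_points=len(cl), shared=True,
    )


def _split_tables(tables) -> Dict[object, Tuple[np.ndarray, np.ndarray]]:
    if isinstance(tables, pd.DataFrame):
        label_col = (
            "gvl_massfrac" if "gvl_massfrac" in tables.columns else "solvent"
        )
        return {
            label: _as_cl_k(group)
            for label, group in tables.groupby(label_col, sort=True)
        }
    return {label: _as_cl_k(tab) for label, tab in tables.items()}


def fit_global(tables, shared: bool = True) -> ChlorideModelFit:
    """Global saturation-enhancement fit across solvent systems.

    ``tables`` is either a DataFrame with columns
    (gvl_massfrac | solvent, cl_M, k_obs) or a mapping label -> table.
    With ``shared=True`` (default) a single enhancement factor is estimated
    jointly with per-solvent (r_o, K_Cl), minimizing the pooled
    relative-residual SSE; with ``shared=False`` each solvent is fit
    independently. A single solvent delegates to ``fit_single_solvent``.
    """
    groups = _split_tables(tables)
    if len(groups) == 0:
        raise ValidationError("no solvent tables provided")
    if len(groups) == 1:
        ((label, (cl, k)),) = groups.items()
        fit = fit_single_solvent((cl, k))
        fit.per_solvent = {label: fit.per_solvent["solvent"]}
        return fit

    if not shared:
        per = {}
        sse = 0.0
        n = 0
        for label, (cl, k) in groups.items():
            single = fit_single_solvent((cl, k))
            per[label] = single.per_solvent["solvent"]
            sse += single.sse
            n += single.n_points
        return ChlorideModelFit(
            per_solvent=per, r_enhance=None, r_enhance_ci95=(math.nan, math.nan),
            sse=sse, n_points=n, shared=False,
        )

    labels = list(groups)
    params = lmfit.Parameters()
    enh0 = []
    for i, label in enumerate(labels):
        cl, k = groups[label]
        if len(np.unique(cl)) < 4:
            raise ValidationError(
                f"solvent {label!r}: need >= 4 distinct chloride levels"
            )
        r_o0, r_e0, kcl0 = _initial_guess(cl, k)
        params.add(f"r_o_{i}", value=r_o0, min=1e-12)
        params.add(f"K_Cl_{i}", value=kcl0, min=0.0)
        enh0.append(r_e0)
    params.add("r_enhance", value=float(np.median(enh0)), min=0.0)

    def residual(p):
        res = []
        for i, label in enumerate(labels):
            cl, k = groups[label]
            model = enhanced_rate(
                p[f"r_o_{i}"].value, p["r_enhance"].value,
                p[f"K_Cl_{i}"].value, cl,
            )
            res.append(_relative_residual(k, model))
        return np.concatenate(res)

    mini = lmfit.Minimizer(residual, params)
    result = mini.minimize(method="leastsq")
    n_total = sum(len(groups[l][0]) for l in labels)
    dof = n_total - result.nvarys

    enh = float(result.params["r_enhance"].value)
    enh_ci, _ = _param_ci(result, "r_enhance", dof)
    per = {}
    for i, label in enumerate(labels):
        cl, k = groups[label]
        r_o = float(result.params[f"r_o_{i}"].value)
        kcl = float(result.params[f"K_Cl_{i}"].value)
        r_o_ci, _ = _param_ci(result, f"r_o_{i}", dof)
        kcl_ci, kcl_err = _param_ci(result, f"K_Cl_{i}", dof)
        identifiable = math.isfinite(kcl_err) and (
            kcl <= 0 or kcl_err / max(kcl, 1e-300) < _WIDE
        )
        if not identifiable:
            kcl_ci = (0.0, math.inf)
        model = enhanced_rate(r_o, enh, kcl, cl)
        per[label] = SolventFit(
            r_o=r_o, K_Cl=kcl, r_o_ci95=r_o_ci, K_Cl_ci95=kcl_ci,
            r_squared=_r_squared(k, model), kcl_identifiable=identifiable,
        )
    return ChlorideModelFit(
        per_solvent=per, r_enhance=enh, r_enhance_ci95=enh_ci,
        sse=float(np.sum(result.residual**2)), n_points=n_total, shared=True,
    )


def shared_enhancement_ftest(tables) -> Dict[str, float]:
    """F-test of the shared-enhancement restriction.

    Compares the pooled SSE of the shared fit (one enhancement factor)
    against the free fit (one per solvent). Returns the F statistic, its
    p-value, and both SSEs. Small p rejects a common enhancement factor."""
    shared_fit = fit_global(tables, shared=True)
    free_fit = fit_global(tables, shared=False)
    n_solv = len(free_fit.per_solvent)
    df_restrict = n_solv - 1
    df_free = free_fit.n_points - 3 * n_solv
    if df_free <= 0 or free_fit.sse <= 0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = ((shared_fit.sse - free_fit.sse) / df_restrict) / (
            free_fit.sse / df_free
        )
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df_restrict, df_free))
    return {
        "f_statistic": float(f_stat),
        "p_value": p,
        "sse_shared": shared_fit.sse,
        "sse_free": free_fit.sse,
    }


def k_vs_Kcl_relation(
    fit: Union[ChlorideModelFit, Mapping[object, float]],
    chloride_free_k: Mapping[object, float],
) -> LinearRelation:
    """Ordinary least squares of the chloride-free rate constant on the
    fitted chloride binding constant across solvent systems (>= 3 points).

    ``fit`` may be a ChlorideModelFit (K_Cl taken per solvent) or a plain
    mapping label -> K_Cl. All-identical responses return slope 0 and
    R^2 = 0 by convention."""
    kcl_map = (
        {lab: sf.K_Cl for lab, sf in fit.per_solvent.items()}
        if isinstance(fit, ChlorideModelFit)
        else dict(fit)
    )
    labels = [lab for lab in kcl_map if lab in chloride_free_k]
    if len(labels) < 3:
        raise ValidationError("need >= 3 solvent systems for the linear relation")
    x = np.array([kcl_map[lab] for lab in labels], dtype=float)
    y = np.array([chloride_free_k[lab] for lab in labels], dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return LinearRelation(
            slope=0.0, intercept=float(y.mean()), r_squared=0.0,
            slope_stderr=math.inf, slope_ci95=(-math.inf, math.inf),
        )
    res = stats.linregress(x, y)
    n = len(x)
    tcrit = stats.t.ppf(0.975, n - 2) if n > 2 else math.inf
    half = tcrit * res.stderr
    return LinearRelation(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), slope_stderr=float(res.stderr),
        slope_ci95=(float(res.slope - half), float(res.slope + half)),
    )
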