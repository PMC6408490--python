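"""Arrhenius regression, free-energy-profile bookkeeping, and an Eyring
bridge for comparing computed barriers with observed rate-constant trends.

The apparent activation barrier of the dehydration is assembled as the sum
of the reaction free energy to form the oxocarbenium-ion intermediate and
the activation free energy of its subsequent deprotonation; differences in
these apparent barriers map onto rate-constant ratios through
exp(-ddG/(R*T)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

__all__ = [
    "R_GAS",
    "ArrheniusFit",
    "FreeEnergyProfile",
    "fit_arrhenius",
    "assemble_profile",
    "barrier_delta",
    "eyring_rate_ratio",
]

#: gas constant, kJ mol^-1 K^-1
R_GAS = 8.314462618e-3


@dataclass
class ArrheniusFit:
    """Apparent activation energy Ea (kJ/mol) and pre-exponential log lnA
    (in the rate constant's units) from k(T) = A*exp(-Ea/(R*T))."""

    Ea: float
    lnA: float
    Ea_ci95: Tuple[float, float]
    lnA_ci95: Tuple[float, float]
    r_squared: float
    n_points: int

    @property
    def A(self) -> float:
        return math.exp(self.lnA)


def fit_arrhenius(table: Union[pd.DataFrame, Tuple], method: str = "ols") -> ArrheniusFit:
    """Arrhenius regression over a (T, k) table.

    ``method='ols'`` (default) is the conventional linearization, ordinary
    least squares of ln k on 1/T with Ea = -slope*R; CIs come from the
    regression covariance (Student-t, n-2 dof). ``method='nonlinear'`` fits
    k(T) directly with relative residuals, for rate constants spanning
    decades with noise proportional to k."""
    if isinstance(table, pd.DataFrame):
        T = table["T_K"].to_numpy(dtype=float)
        k = table["k"].to_numpy(dtype=float)
    else:
        T, k = (np.asarray(a, dtype=float) for a in table)
    if len(T) < 2:
        raise ValidationError("need >= 2 temperatures")
    if np.any(T <= 0):
        raise ValidationError("temperatures must be positive (K)")
    if np.any(k <= 0):
        raise ValidationError("rate constants must be positive")

    x = 1.0 / T
    y = np.log(k)
    if np.ptp(y) == 0:
        # temperature-independent rate: zero barrier, A = k
        return ArrheniusFit(
            Ea=0.0, lnA=float(y[0]), Ea_ci95=(0.0, 0.0),
            lnA_ci95=(float(y[0]), float(y[0])), r_squared=0.0, n_points=len(T),
        )

    res = stats.linregress(x, y)
    Ea = -res.slope * R_GAS
    lnA = float(res.intercept)
    n = len(T)
    if n > 2 and math.isfinite(res.stderr) and res.stderr > 0:
        tcrit = stats.t.ppf(0.975, n - 2)
        Ea_half = tcrit * res.stderr * R_GAS
        lnA_half = tcrit * res.intercept_stderr
    else:
        Ea_half = lnA_half = 0.0  # two points: exact interpolation

    if method == "nonlinear":
        params = lmfit.Parameters()
        params.add("Ea", value=Ea)
        params.add("lnA", value=lnA)

        def residual(p):
            model = np.exp(p["lnA"].value - p["Ea"].value / (R_GAS * T))
            return (k - model) / model

        out = lmfit.Minimizer(residual, params).minimize(method="leastsq")
        Ea = float(out.params["Ea"].value)
        lnA = float(out.params["lnA"].value)
        dof = max(n - 2, 1)
        tcrit = stats.t.ppf(0.975, dof)
        for name, setter in (("Ea", "Ea"), ("lnA", "lnA")):
            err = out.params[name].stderr
            half = tcrit * err if err is not None and n > 2 else 0.0
            if name == "Ea":
                Ea_half = half
            else:
                lnA_half = half
    elif method != "ols":
        raise ValidationError("method must be 'ols' or 'nonlinear'")

    model = lnA - Ea / (R_GAS * T)
    return ArrheniusFit(
        Ea=float(Ea), lnA=float(lnA),
        Ea_ci95=(Ea - Ea_half, Ea + Ea_half),
        lnA_ci95=(lnA - lnA_half, lnA + lnA_half),
        r_squared=float(res.rvalue**2),
        n_points=n,
    )


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Apparent activation barrier of one solvent/anion system (kJ/mol).

    ``dG_formation`` is the reaction free energy for oxocarbenium-ion
    formation (protonation of the C2 hydroxyl with elimination of water),
    ``dG_abstraction`` the activation free energy for deprotonating the ion,
    and ``dG_total`` their exact sum — the apparent barrier. ``note`` stores
    provenance for rows whose components carry a stated correction."""

    system: str
    dG_formation: float
    dG_abstraction: float
    dG_total: float
    note: Optional[str] = None

    def __post_init__(self):
        if not (math.isfinite(self.dG_formation) and math.isfinite(self.dG_abstraction)):
            raise ValidationError("free-energy components must be finite")
        if self.dG_abstraction < 0:
            raise ValidationError("abstraction barrier must be nonnegative")


def assemble_profile(
    dG_formation: float,
    dG_abstraction: float,
    system: str = "",
    note: Optional[str] = None,
) -> FreeEnergyProfile:
    """Assemble the apparent barrier as the exact sum of the oxocarbenium
    formation free energy and the deprotonation activation free energy."""
    return FreeEnergyProfile(
        system=system,
        dG_formation=float(dG_formation),
        dG_abstraction=float(dG_abstraction),
        dG_total=float(dG_formation) + float(dG_abstraction),
        note=note,
    )


def barrier_delta(profile_a: FreeEnergyProfile, profile_b: FreeEnergyProfile) -> float:
    """Apparent-barrier change dG_total(b) - dG_total(a), kJ/mol; negative
    when system b has the lower barrier."""
    return profile_b.dG_total - profile_a.dG_total


def eyring_rate_ratio(dG_a: float, dG_b: float, T: float) -> float:
    """Rate ratio k_a/k_b implied by two apparent barriers at temperature T,
    exp(-(dG_a - dG_b)/(R*T)). A qualitative bridge for trend comparison
    only — transmission coefficients are assumed equal."""
    if T <= 0:
        raise ValidationError("temperature must be positive (K)")
    return math.exp(-(dG_a - dG_b) / (R_GAS * T))
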