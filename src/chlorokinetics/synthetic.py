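"""Synthetic batch-kinetics data generator.

Emulates isothermal closed-batch dehydration experiments: pseudo-first-order
reactant decay at rate k*[H+], a selectivity branch routing reactant flux to
the primary product (the remainder to unobserved condensation byproducts,
"humins"), consecutive degradation of the primary product, and multiplicative
log-normal measurement noise of the kind produced by HPLC quantification.

Rate-constant-versus-chloride tables follow the transition-state saturation
law  k(cl) = k_o * [1 + r_enhance * K_Cl*cl / (1 + K_Cl*cl)]  so that the
chloride-model fitting stage can be exercised with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    PRIMARY,
    REACTANT,
    SECONDARY,
    ExperimentCondition,
    KineticProfile,
    MissingConditionError,
    ValidationError,
)

__all__ = [
    "GeneratorSpec",
    "ChlorideDesign",
    "simulate_profile",
    "generate_chloride_table",
    "generate_arrhenius_set",
    "reference_chloride_design",
    "lognormal_noise",
]

#: gas constant, kJ mol^-1 K^-1
R_GAS = 8.314462618e-3

#: default sampling grid, ks (≈ 0–3.3 h), matching batch sampling cadence
DEFAULT_SAMPLE_TIMES = tuple(np.linspace(0.0, 12.0, 10))


def lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal factors with coefficient of
    variation ``cv``. cv=0 returns exact ones."""
    if cv < 0:
        raise ValidationError("noise_cv must be nonnegative")
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


@dataclass
class GeneratorSpec:
    """Configuration of one batch of simulated experiments.

    ``true_k`` maps each condition to its second-order rate constant
    (M^-1 ks^-1). ``selectivity`` is the fraction of reacted substrate that
    forms the primary product; ``k_deg`` (M^-1 ks^-1) governs the
    acid-catalyzed consecutive degradation of that product.
    """

    conditions: Sequence[ExperimentCondition]
    true_k: Mapping[ExperimentCondition, float]
    selectivity: float = 0.78
    k_deg: float = 1.0
    noise_cv: float = 0.05
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES
    seed: int = 0
    replicates: int = 1

    def __post_init__(self):
        if not 0.0 <= self.selectivity <= 1.0:
            raise ValidationError("selectivity must be in [0, 1]")
        if self.k_deg < 0:
            raise ValidationError("k_deg must be nonnegative")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be nonnegative")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        t = np.asarray(self.sample_times, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError(
                "sample_times must be nonnegative and strictly increasing"
            )
        for cond in self.conditions:
            if cond not in self.true_k:
                raise MissingConditionError(cond)
            if self.true_k[cond] < 0:
                raise ValidationError("rate constants must be nonnegative")


def batch_concentrations(
    t: np.ndarray,
    r0: float,
    k_decay: float,
    selectivity: float,
    k_deg: float,
) -> dict:
    """Closed-form species concentrations for the consecutive scheme
    R -> (selectivity) P -> S, with first-order rate constants ``k_decay``
    and ``k_deg`` (ks^-1); the (1 - selectivity) branch is an unobserved
    loss channel. Exact solution of the linear ODE system."""
    t = np.asarray(t, dtype=float)
    r = r0 * np.exp(-k_decay * t)
    if k_decay == 0.0:
        p = np.zeros_like(t)
        s = np.zeros_like(t)
        return {REACTANT: r, PRIMARY: p, SECONDARY: s}
    if abs(k_deg - k_decay) < 1e-12 * max(k_decay, 1.0):
        # degenerate equal-rate limit of the two-exponential solution
        p = selectivity * r0 * k_decay * t * np.exp(-k_decay * t)
    else:
        p = (
            selectivity
            * r0
            * k_decay
            / (k_deg - k_decay)
            * (np.exp(-k_decay * t) - np.exp(-k_deg * t))
        )
    converted = r0 - r
    s = selectivity * converted - p
    s = np.where(np.abs(s) < 1e-15 * r0, 0.0, s)  # clip roundoff at t≈0
    return {REACTANT: r, PRIMARY: p, SECONDARY: s}


def simulate_profile(
    spec: GeneratorSpec,
    condition: ExperimentCondition,
    r0: float = 0.050,
) -> KineticProfile:
    """Simulate one concentration-time profile (default 50 mM substrate).

    Before noise the reactant follows R(t) = R0*exp(-k*[H+]*t) and the
    primary product the consecutive-reaction closed form. Noise is
    multiplicative log-normal (unit mean, CV = ``noise_cv``), drawn from a
    stream derived from ``spec.seed`` and the condition's position in
    ``spec.conditions`` so each condition is reproducible independently of
    simulation order.
    """
    if condition not in spec.true_k:
        raise MissingConditionError(condition)
    if condition.acid_conc <= 0:
        raise ValidationError("acid concentration must be positive to simulate")
    idx = list(spec.conditions).index(condition)
    t = np.asarray(spec.sample_times, dtype=float)

    k = spec.true_k[condition]
    k_decay = k * condition.acid_conc  # pseudo-first-order, ks^-1
    k_deg1 = spec.k_deg * condition.acid_conc
    clean = batch_concentrations(t, r0, k_decay, spec.selectivity, k_deg1)

    child = np.random.SeedSequence(spec.seed).spawn(len(spec.conditions))[idx]
    rng = np.random.default_rng(child)
    noisy = {
        name: conc * lognormal_noise(rng, spec.noise_cv, conc.shape)
        for name, conc in clean.items()
    }
    # a noisy zero stays zero under multiplicative noise; nothing to clip,
    # but guard against pathological float behaviour anyway
    noisy = {name: np.maximum(conc, 0.0) for name, conc in noisy.items()}
    return KineticProfile(condition=condition, times=t, concentrations=noisy)


@dataclass
class ChlorideDesign:
    """Design of a rate-constant-versus-chloride study over solvent mixtures.

    ``k_o`` and ``K_Cl`` are per-solvent arrays aligned with
    ``solvent_fractions``; ``r_enhance`` is the shared enhancement factor of
    the chloride-bound transition-state channel.
    """

    solvent_fractions: Sequence[float]
    k_o: Sequence[float]  # M^-1 ks^-1, chloride-free rate constant
    K_Cl: Sequence[float]  # M^-1
    r_enhance: float
    cl_grid: Sequence[float]  # M

    def __post_init__(self):
        fr = np.asarray(self.solvent_fractions, float)
        ko = np.asarray(self.k_o, float)
        kc = np.asarray(self.K_Cl, float)
        cl = np.asarray(self.cl_grid, float)
        if not (len(fr) == len(ko) == len(kc)):
            raise ValidationError("solvent_fractions, k_o, K_Cl must align")
        if np.any((fr < 0) | (fr > 1)):
            raise ValidationError("solvent fractions must be in [0, 1]")
        if np.any(ko <= 0):
            raise ValidationError("k_o must be positive")
        if np.any(kc < 0) or self.r_enhance < 0:
            raise ValidationError("K_Cl and r_enhance must be nonnegative")
        if np.any(cl < 0):
            raise ValidationError("chloride concentrations must be nonnegative")


def reference_chloride_design() -> ChlorideDesign:
    """Five GVL/water mixtures (5-90 wt% GVL) with a shared enhancement
    factor of 5 and per-solvent (k_o, K_Cl) lying on the empirical linear
    relation k_o = 0.84*K_Cl - 0.87, spanning the chloride-free rate
    constants observed from water-rich to 90% GVL solvent. The chloride grid
    covers 5 mM - 2.5 M."""
    K_Cl = np.array([1.5, 3.0, 7.0, 14.0, 25.0])
    k_o = 0.84 * K_Cl - 0.87
    return ChlorideDesign(
        solvent_fractions=[0.05, 0.25, 0.50, 0.75, 0.90],
        k_o=k_o,
        K_Cl=K_Cl,
        r_enhance=5.0,
        cl_grid=[0.0, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 1.5, 2.5],
    )


def generate_chloride_table(
    design: ChlorideDesign,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed rate constants over the (solvent, chloride) design grid.

    k_obs = k_o * [1 + r_enhance * f(cl)] * eps, f the saturation fraction
    K_Cl*cl/(1+K_Cl*cl) and eps unit-mean log-normal with CV ``noise_cv``.
    Deterministic given ``seed``. Returns columns
    (gvl_massfrac, cl_M, k_obs).
    """
    rng = np.random.default_rng(seed)
    cl = np.asarray(design.cl_grid, dtype=float)
    rows = []
    for frac, ko, kcl in zip(design.solvent_fractions, design.k_o, design.K_Cl):
        f = kcl * cl / (1.0 + kcl * cl)
        k_true = ko * (1.0 + design.r_enhance * f)
        eps = lognormal_noise(rng, noise_cv, cl.shape)
        for c, k in zip(cl, k_true * eps):
            rows.append({"gvl_massfrac": frac, "cl_M": c, "k_obs": k})
    return pd.DataFrame(rows)


def generate_arrhenius_set(
    Ea: float,
    lnA: float,
    temperatures: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rate constants over a temperature ladder, k(T) = exp(lnA - Ea/(R*T)).

    ``Ea`` in kJ/mol, ``lnA`` in the log of the rate-constant units.
    Returns columns (T_K, k)."""
    T = np.asarray(temperatures, dtype=float)
    if T.size == 0:
        raise ValidationError("temperature list must not be empty")
    if np.any(T <= 0):
        raise ValidationError("temperatures must be positive (K)")
    rng = np.random.default_rng(seed)
    k = np.exp(lnA - Ea / (R_GAS * T)) * lognormal_noise(rng, noise_cv, T.shape)
    return pd.DataFrame({"T_K": T, "k": k})
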