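# Methods

## Kinetic model and assumptions

Batch experiments are treated as isothermal and well mixed from t = 0; the
reactor heat-up transient and any mass-transfer resistance are outside the
model. Acid catalysis is specific-acid only: the rate law is
r = k_H+ [R][H+], and the general-acid rate constant k_HB is fixed at zero
rather than estimated, on the strength of the inverse solvent kinetic
isotope effect (k_D/k_H between roughly 1.7 and 2.7), which indicates a
fast pre-equilibrium protonation. Strong acids are taken as fully
dissociated in every solvent mixture, so [H+] equals the nominal acid
concentration. For salt-only experiments (no Brønsted acid) the same
exponential law is fit with the salt concentration as the catalytic
reference.

The reaction network used by the generator is the minimal scheme that
reproduces yield-at-conversion semantics for the three monitored species:

    fructose --k·[H+]--> (selectivity) HMF + (1-selectivity) humins
    HMF      --k_deg·[H+]--> levulinic acid

Both steps are pseudo-first-order in substrate at fixed acid concentration,
so all species have closed-form solutions (the consecutive-reaction
two-exponential form for HMF, with the series limit when the two rate
constants coincide). Humins are unobserved; mass balance
R + HMF + LA + humins = R0 holds exactly in the noiseless model.

## Chloride transition-state enhancement

Chloride binds the rate-determining transition state, Cl⁻ + R‡ ⇌ RCl‡,
with equilibrium constant K_Cl (M⁻¹). The bound fraction follows the
saturation (Langmuir) form f = K_Cl[Cl⁻]/(1+K_Cl[Cl⁻]), and the observed
rate constant is k(Cl⁻) = r_o·[1 + r_enhance·f] with r_enhance = r_Cl/r_o.
The function is strictly increasing and concave in [Cl⁻], equals r_o at
zero chloride, and plateaus at r_o(1 + r_enhance).

The global fit estimates one shared r_enhance across solvent systems plus
per-solvent (r_o, K_Cl). Sharing the enhancement factor is a model choice,
not a theorem, so `shared_enhancement_ftest` also fits the free
(per-solvent enhancement) model and reports the F-test of the restriction;
the shared form is the default. Whether r_o should be fixed at the
measured chloride-free rate constant or estimated is genuinely open; it is
estimated here, initialized from the smallest-chloride observation, which
absorbs baseline measurement error at the cost of one parameter per
solvent.

## Estimation and uncertainty

All nonlinear fits use Levenberg–Marquardt least squares (lmfit). Residuals
are relative — divided by the model value — in both the rate-constant and
chloride-model fits. This is the correct weighting when measurement error
is proportional to the measured value, which is how chromatographic
concentration data behave and exactly how the synthetic noise is generated;
it is also what lets solvents whose rate constants span three orders of
magnitude contribute comparably to the pooled chloride objective. An
unweighted option (`weighting="absolute"`) is available. In a 500-replicate
Monte-Carlo study at 5% noise the default Wald intervals cover the true
rate constant ~95–96% of the time; with absolute weighting under the same
multiplicative noise, coverage degrades markedly, which is why relative
weighting is the default.

95% confidence intervals are linearized (Jacobian-based) Wald intervals
using Student-t with n − p degrees of freedom; profile-likelihood intervals
via lmfit's F-test machinery are available with `ci_method="profile"`.
R0 is fitted (initialized at the first observation) rather than fixed,
absorbing dilution error. A fit whose implied conversion over the observed
window is below 10⁻⁶ is flagged `converged=False` ("does not decay")
instead of raising. A chloride fit with no curvature (flat table) is
returned with r_enhance ≈ 0, `kcl_identifiable=False`, and an infinite
K_Cl confidence interval rather than an exception.

Arrhenius analysis uses the conventional linearization, OLS of ln k on 1/T
with Ea = −slope·R (R = 8.314462618×10⁻³ kJ mol⁻¹ K⁻¹ throughout); a
direct nonlinear fit with relative residuals is offered for ladders whose
rates span decades. With exactly two temperatures the inversion is exact
and the interval collapses to a point. A temperature-independent ladder
returns Ea = 0 with R² = 0 by convention (no variance to explain); the
solvent-baseline linear relation adopts the same R² = 0 convention for a
constant response.

Free-energy bookkeeping is exact decimal addition: the apparent barrier is
the sum of the oxocarbenium-ion formation free energy and the
deprotonation activation free energy. Rows whose components carry a stated
correction keep a provenance note; the corrections themselves are never
recomputed. The Eyring bridge exp(−ΔΔG‡/RT) is for trend comparison only
(equal transmission coefficients assumed).

## Synthetic-data generator

Defaults mirror the study conditions: 50 mM substrate, 5 mM acid in polar
aprotic mixtures (0.5 M in water-rich mixtures, whose baseline rate
constants are ~100× smaller), 373 K, selectivity 0.78 (the HMF yield
observed at ~90% conversion in 90% GVL with HCl), one observation per time
point, and noise_cv = 0.05 — the experiments report 95% confidence
intervals rather than a noise model, and 5% relative error is typical of
HPLC quantification. Noise is multiplicative log-normal with unit mean
(σ² = ln(1+cv²)), applied independently per species and time point;
streams derive from a seed plus the condition's position in the design, so
any single condition is reproducible in isolation. The reference chloride
design spans 5–90 wt% GVL with K_Cl = 1.5–25 M⁻¹ and baselines on the
empirical line k_o = 0.84·K_Cl − 0.87 (so the 90% GVL baseline is
≈20 M⁻¹ ks⁻¹), a shared enhancement factor of 5, and a chloride grid from
0 to 2.5 M.

What the generator does not emulate: reactor heat-up transients, replicate
scatter beyond the multiplicative term, activity-coefficient effects at
high salt, the GVL/4-hydroxyvaleric acid hydration equilibrium, and any
anion-specific chemistry (bromide/iodide/fluoride conditions are data
labels only). Passing recovery tests therefore demonstrates estimator
correctness under the assumed error structure, not robustness to every
failure mode of real reactor data.

One consequence of observation-level noise: the stoichiometric bound
yield ≤ conversion is a theorem of the noiseless model and is asserted
there; noisy observed yields can exceed noisy observed conversions by a
few percent, and the package reports what the data say rather than
clipping.

## Problem sizes

The shipped analyses are desk-scale: the reference design is 5 solvents ×
11 chloride levels; recovery and calibration studies use 10-point profiles
with 20–500 seeded replicates; the demo pipeline simulates and fits 55
profiles end to end in about a second. All results in the README were
printed by the code shown next to them.

## Known limitations

- The 95% intervals are asymptotic; at very small n (≤4 points) profile
  intervals are the better choice.
- K_Cl and r_enhance are partially collinear when the chloride grid does
  not reach saturation; the initializer uses the half-rise concentration,
  but a grid whose largest K_Cl·[Cl⁻] is below ~1 will show inflated K_Cl
  uncertainty.
- Interpolation for yield-at-conversion is linear in time between
  bracketing samples; with coarse grids and fast degradation this slightly
  biases the interpolated product concentration.
- Units: time in ks and concentration in M internally; readers accept
  minutes and mM columns and convert on input (1 min = 0.06 ks).
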