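# chlorokinetics

Kinetic analysis of chloride-ion promotion of acid-catalyzed fructose
dehydration to 5-hydroxymethylfurfural (HMF) in polar aprotic
solvent/water mixtures — for catalysis researchers who estimate rate
constants from batch concentration–time profiles and want the chloride
transition-state enhancement model fitted globally across solvent systems.

## The model

In a closed batch reactor under specific-acid catalysis the substrate
decays as

    r = k_H+ [R][H+],    R(t) = R0 · exp(−k_H+ [H+] t)

with `k_H+` in M⁻¹ ks⁻¹ (the general-acid channel k_HB is fixed at zero: an
inverse solvent kinetic isotope effect, k_D/k_H > 1, shows the acidic
proton does the catalysis). Chloride promotes the reaction by binding the
rate-determining transition state, Cl⁻ + R‡ ⇌ RCl‡ with equilibrium
constant `K_Cl` (M⁻¹); the fraction of transition states carrying a
chloride is the saturation form

    f = K_Cl[Cl⁻] / (1 + K_Cl[Cl⁻])

and the observed rate constant rises from the chloride-free baseline `r_o`
toward a plateau:

    k(Cl⁻) = r_o · [1 + r_enhance · f],    r_enhance = r_Cl / r_o

The enhancement factor `r_enhance` is shared across GVL/water solvent
mixtures in the global fit, while `r_o` and `K_Cl` are per-solvent. The
package also does Arrhenius regression (ln k vs 1/T, Ea = −slope·R),
assembles apparent activation barriers as the exact sum of the
oxocarbenium-ion formation free energy and the deprotonation barrier, and
bridges barrier differences to rate ratios via exp(−ΔΔG‡/RT).

A synthetic-data module generates batch profiles (pseudo-first-order decay,
selectivity branch to HMF, consecutive degradation to levulinic acid,
multiplicative log-normal noise) and rate-constant-vs-chloride tables with
known ground truth, so every fitting stage is testable end to end.

## Worked example

```python
import chlorokinetics as ck

# five GVL/water mixtures, shared enhancement factor 5, 5% relative noise
table = ck.generate_chloride_table(ck.reference_chloride_design(),
                                   noise_cv=0.05, seed=1)
fit = ck.fit_global(table, shared=True)
print(round(fit.r_enhance, 3))                      # 4.866
print(round(fit.per_solvent[0.9].K_Cl, 2))          # 24.62  (M^-1, 90% GVL)

rel = ck.k_vs_Kcl_relation(fit, {s: f.r_o for s, f in fit.per_solvent.items()})
print(round(rel.slope, 2), round(rel.intercept, 2)) # 0.88 -0.6
```

The recovered shared enhancement (≈5) means chloride binding makes the
rate-determining step about six times faster at saturation; the near-linear
relation between the chloride-free rate constant and `K_Cl` says the same
solvent environments that speed up proton catalysis also strengthen
chloride binding to the transition state.

The same analysis as a shell pipeline (simulate → fit-rate → fit-chloride →
arrhenius → report):

```sh
chlorokinetics report --config examples/demo_config.yaml
chlorokinetics assemble-dg examples/free_energy.csv
# -> "90% GVL / H+/Cl-: 38 + 29 = 67 kJ/mol", etc.
```

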