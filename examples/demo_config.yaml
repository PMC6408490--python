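# End-to-end demo: simulate the five-solvent chloride study, fit every
# profile's rate constant, fit the shared-enhancement chloride model, and
# regress a synthetic Arrhenius ladder.
outdir: scratch/demo_run
seed: 1
noise_cv: 0.05
simulate: true
shared_enhancement: true
arrhenius:
  Ea: 110.0        # kJ/mol
  lnA: 38.0
  temperatures: [363.0, 373.0, 383.0, 393.0]
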