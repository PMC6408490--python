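# computed free-energy components per solvent/anion system (kJ/mol)
system,dG_formation_kJ_per_mol,dG_abstraction_kJ_per_mol,note
"H2O / H+",57,35,
"H2O / H+/Cl-",58,35,
"75% GVL / H+",49,35,
"75% GVL / H+/Cl-",44,30,
"90% GVL / H+",43,33,
"90% GVL / H+/Cl-",38,29,formation term carries a dissociation correction
"90% GVL / H+/TfO-",43,33,anion migrated; values from the anion-free system
"90% GVL / H+/HSO4-",45,33,
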