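# Spanish-flavoured factor set: tier-2 enteric CH4 with a lower methane
# conversion factor (warmer climate, more concentrate in diets) and markedly
# higher embedded factors for purchased concentrate.
name: ES_style
enteric_mode: tier2
ym: 5.5
b0: 0.17
mcf:
  slurry_tank: 18.0          # warmer storage
  solid_storage: 5.0
  pasture_deposition: 1.5
ef3_storage:
  slurry_tank: 0.005
  solid_storage: 0.005
  pasture_deposition: 0.0
ef3_prp: 0.02
ef1: 0.01
frac_gas_fert: 0.10
frac_gas_manure: 0.20
frac_leach: 0.30
ef4: 0.01
ef5: 0.0075
ef_lime: 0.44
ef_fert_manufacture: 6.0
ef_concentrate:              # highest embedded concentrate factors of the sets
  compound_ration: 1.05
  cereal_mix: 0.75
  protein_mix: 1.35
ef_diesel: 2.67
ef_electricity: 0.30
seq_rate_grassland: 500.0
seq_rate_hedgerow: 1.00
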