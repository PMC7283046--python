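# French-flavoured factor set: per-head enteric CH4 table (tier-3 style,
# systematically above the tier-2 gross-energy estimate for the same cohort),
# low-carbon electricity, higher grassland sequestration credit.
name: FR_style
enteric_mode: per_head_table
ym: 6.5                      # retained for reference; unused in per-head mode
per_head_enteric:            # kg CH4/head/yr
  suckler_cow: 92.0
  breeding_bull: 100.0
  weanling: 34.0
  store: 58.0
  finishing_bull: 72.0
  finishing_steer: 70.0
  finishing_heifer: 62.0
  dairy_origin_calf: 32.0
b0: 0.17
mcf:
  slurry_tank: 17.0
  solid_storage: 4.0
  pasture_deposition: 1.0
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
ef_fert_manufacture: 5.5
ef_concentrate:
  compound_ration: 0.70
  cereal_mix: 0.50
  protein_mix: 0.95
ef_diesel: 2.67
ef_electricity: 0.06
seq_rate_grassland: 600.0
seq_rate_hedgerow: 1.50
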