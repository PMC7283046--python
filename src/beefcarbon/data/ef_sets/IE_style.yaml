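# Irish-flavoured factor set: tier-2 enteric CH4 from gross energy intake,
# grass-based concentrate factors, CAN-dominated fertilizer manufacture.
name: IE_style
enteric_mode: tier2
ym: 6.5                      # % of GEI, roughage diets
b0: 0.17                     # m3 CH4/kg VS
mcf:
  slurry_tank: 17.0          # % of B0, cool-climate liquid storage
  solid_storage: 4.0
  pasture_deposition: 1.0
ef3_storage:
  slurry_tank: 0.005         # kg N2O-N/kg N
  solid_storage: 0.005
  pasture_deposition: 0.0
ef3_prp: 0.02
ef1: 0.01
frac_gas_fert: 0.10
frac_gas_manure: 0.20
frac_leach: 0.30
ef4: 0.01
ef5: 0.0075
ef_lime: 0.44                # kg CO2/kg limestone (12/100 * 44/12)
ef_fert_manufacture: 6.0     # kg CO2e/kg N
ef_concentrate:              # kg CO2e/kg fed
  compound_ration: 0.75
  cereal_mix: 0.55
  protein_mix: 1.00
ef_diesel: 2.67              # kg CO2e/L
ef_electricity: 0.45         # kg CO2e/kWh
seq_rate_grassland: 500.0    # kg CO2e/ha/yr, permanent pasture
seq_rate_hedgerow: 1.25      # kg CO2e/m/yr
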