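# Packaged mitigation-measure catalogue.
#
# Four groups, ordered by typical mitigation potential: animal performance &
# diet > soil & land use > manure management > energy.  Per-measure magnitudes
# are package design values drawn from the abatement literature for Western
# European beef systems; measures whose reduction level is highly uncertain
# carry uncertainty_flag.  Overrides replace an engine or farm parameter with
# a new value; deltas scale the named gas of the affected sources by a
# percentage (negative = reduction).
measures:
  - name: improved_genetic_merit
    category: animal_performance_diet
    mechanism: intensity_delta
    deltas: {CH4: -8.0, N2O: -6.0}
    affected_sources: [enteric, manure_storage, manure_spreading, grazing_returns]
    uncertainty_flag: false
  - name: improved_animal_health
    category: animal_performance_diet
    mechanism: intensity_delta
    deltas: {CH4: -6.0, N2O: -4.0}
    affected_sources: [enteric, manure_storage, manure_spreading, grazing_returns]
    uncertainty_flag: false
  - name: ch4_inhibiting_feed_additive
    category: animal_performance_diet
    mechanism: parameter_override
    overrides: {ym: 4.95}          # caps the enteric loss factor below 5% of GEI
    uncertainty_flag: true
  - name: improved_forage_quality
    category: animal_performance_diet
    mechanism: intensity_delta
    deltas: {CH4: -5.0}
    affected_sources: [enteric]
    uncertainty_flag: false
  - name: low_footprint_concentrate_sourcing
    category: animal_performance_diet
    mechanism: intensity_delta
    deltas: {CO2: -15.0}
    affected_sources: [concentrate]
    uncertainty_flag: false
  - name: white_clover_incorporation
    category: soil_land_use
    mechanism: intensity_delta
    deltas: {N2O: -20.0, CO2: -20.0}
    affected_sources: [soil_fertilizer, indirect_n, fert_manufacture]
    uncertainty_flag: true
  - name: urease_inhibitor_fertilizer
    category: soil_land_use
    mechanism: intensity_delta
    deltas: {N2O: -10.0}
    affected_sources: [soil_fertilizer, indirect_n]
    uncertainty_flag: true
  - name: hedgerow_planting
    category: soil_land_use
    mechanism: parameter_override
    overrides: {hedgerow_length: 4000.0}   # m of managed hedgerow after planting
    uncertainty_flag: false
  - name: grassland_preservation
    category: soil_land_use
    mechanism: parameter_override
    overrides: {seq_rate_grassland: 650.0} # kg CO2e/ha/yr maintained on permanent pasture
    uncertainty_flag: true
  - name: slurry_store_cover
    category: manure_management
    mechanism: intensity_delta
    deltas: {CH4: -30.0, N2O: -10.0}
    affected_sources: [manure_storage]
    uncertainty_flag: false
    applicable_systems: [suckler_to_weaning, suckler_to_beef, dairy_calf_to_beef,
                         dairy_calf_to_store, beef_fattening]
  - name: low_emission_slurry_spreading
    category: manure_management
    mechanism: intensity_delta
    deltas: {N2O: -12.0}
    affected_sources: [manure_spreading]
    uncertainty_flag: false
  - name: energy_efficiency_and_renewables
    category: energy
    mechanism: intensity_delta
    deltas: {CO2: -20.0}
    affected_sources: [energy]
    uncertainty_flag: false
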