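# 100-year global warming potentials the framework standardizes on.
gwp_ch4: 25.0
gwp_n2o: 298.0
gwp_co2: 1.0
horizon: 100.0
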