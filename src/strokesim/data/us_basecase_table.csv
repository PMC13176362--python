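scenario,strokes_averted_thousands,stroke_deaths_averted_thousands,incremental_cost_billions,incremental_qalys_thousands,nhb_thousands,icer
hba1c_control,28.2,12.0,251.3,-38,-2552,NA
bp_control,73.1,31.2,-13.9,327,467,Cost Saving
statin_treatment,24.5,7.8,-0.97,1254,1264,Cost Saving
aspirin_treatment,56.6,23.8,-5.5,86,141,Cost Saving
smoking_cessation,9.1,3.4,0.8,37,29,21712
weight_loss,59.8,22.4,54.1,555,14,97393
noac_treatment,84.8,32.0,13.9,99,-39,139453
multiple_preventions_1,151,61.9,-13.4,1418,1552,Cost Saving
multiple_preventions_2,202,81.1,43.0,1940,1511,22156
all_preventions,300,118.2,316.0,1914,-1246,165086
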