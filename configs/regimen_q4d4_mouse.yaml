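# Mouse efficacy regimen: IV bolus Q4d x 4 starting day 0 (dose set per arm).
regimen:
  dose: 1.0
  interval_day: 4
  n_doses: 4
  infusion_h: 0.0
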