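# Clinical regimen: 1 mg/kg IV Q3W x 4, 1-hour infusion.
regimen:
  dose: 1.0
  interval_day: 21
  n_doses: 4
  infusion_h: 1.0
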