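# PF-06804103 two-compartment population PK in cynomolgus monkey (per kg).
pk:
  Vc: 38.1   # mL/kg
  CL: 7.2    # mL/day/kg
  Vp: 20.2   # mL/kg
  Q: 19.2    # mL/day/kg
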