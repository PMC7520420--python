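# PF-06804103 two-compartment PK in mouse (per kg), single 3 mg/kg IV dose.
pk:
  Vc: 61.0   # mL/kg
  CL: 22.8   # mL/day/kg
  Vp: 56.2   # mL/kg
  Q: 35.0    # mL/day/kg
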