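# T-DM1 clinical shed-target TMDD parameters (fitted to Phase 1 PK).
tmdd:
  pk: {Vc: 37.0, CL: 7.2, Vp: 30.0, Q: 12.0}
  KD: 0.1          # nM
  kon: 61.3        # 1/nM/day
  kshed: 6.65      # nM/day
  kdeg: 33.3       # 1/day
  kel_complex: 32.6  # 1/day
translation:
  thresholds: [0.5, 4.0]
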