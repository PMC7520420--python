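# Predicted human shed-target TMDD parameters for PF-06804103: linear PK
# allometrically scaled from monkey (volumes exponent 1, clearances 0.9),
# binding KD measured for PF-06804103, target turnover and complex
# elimination carried over from the T-DM1 clinical fit. ecd0 defaults to
# kshed/kdeg (turnover steady state) when omitted.
tmdd:
  pk: {Vc: 38.1, CL: 5.52, Vp: 20.2, Q: 14.9}
  KD: 0.1          # nM
  kon: 61.3        # 1/nM/day
  kshed: 6.65      # nM/day
  kdeg: 33.3       # 1/day
  kel_complex: 32.6  # 1/day
translation:
  thresholds: [0.5, 4.0]
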