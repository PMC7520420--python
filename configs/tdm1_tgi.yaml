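# T-DM1 fitted TGI parameters for the three responsive CLX models.
# JIMT-1 and 144580 did not respond to T-DM1 (TSC > 50 ug/mL); no
# parameters are available for them.
models:
  N87:
    kgEx: 0.0732
    kg: 37.9
    Vmax: 4220.0
    tau: 1.36
    kkmax: 0.405
    kc50: 131.0
    n: 1.0
    cv_percent: {kgEx: 11, kg: 17, Vmax: 18, tau: 16, kkmax: 38, kc50: 48}
  BT474:
    kgEx: 0.0575
    kg: 77.4
    Vmax: 5280.0
    tau: 2.4
    kkmax: 1.38
    kc50: 311.0
    n: 1.01
    cv_percent: {kgEx: 46, kg: 20, Vmax: 23, tau: 7, kkmax: 91, kc50: 110, n: 4}
  HCC-1954:
    kgEx: 0.0918
    kg: 40.7
    Vmax: 3180.0
    tau: 1.0
    kkmax: 0.319
    kc50: 8.63
    n: 1.5
    cv_percent: {kgEx: 8, kg: 6, Vmax: 27, tau: 8, kkmax: 7, kc50: 10}
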