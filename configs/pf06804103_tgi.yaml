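# PF-06804103 fitted TGI parameters per mouse xenograft model, with CV%
# (parameters reported with '(-)' precision carry cv 0 and are held fixed
# in bootstrap resampling). Units: kgEx 1/day, kg mm3/day, Vmax mm3,
# tau day, kkmax 1/day, kc50 ug/mL.
models:
  JIMT-1:
    kgEx: 0.0883
    kg: 47.5
    Vmax: 4080.0
    tau: 2.23
    kkmax: 0.703
    kc50: 10.6
    n: 2.4
    cv_percent: {kgEx: 8, kg: 23, Vmax: 15, tau: 6, kkmax: 9, kc50: 9, n: 12}
  N87:
    kgEx: 0.068
    kg: 26.8
    Vmax: 4600.0
    tau: 2.54
    kkmax: 0.15
    kc50: 1.24
    n: 1.0
    cv_percent: {kgEx: 8, kg: 14, Vmax: 20, tau: 6, kkmax: 5, kc50: 16}
  BT474:
    kgEx: 0.0442
    kg: 78.5
    Vmax: 5280.0
    tau: 3.04
    kkmax: 0.998
    kc50: 31.5
    n: 1.0
    cv_percent: {kgEx: 65, kg: 23, Vmax: 23, tau: 16, kkmax: 209, kc50: 236}
  "24312":
    kgEx: 0.023
    kg: 24.4
    Vmax: 5000.0
    tau: 1.66
    kkmax: 0.721
    kc50: 15.8
    n: 2.6
    cv_percent: {kgEx: 12, kg: 15, tau: 1, kc50: 5}
  "37622":
    kgEx: 0.0559
    kg: 68.4
    Vmax: 3840.0
    tau: 3.32
    kkmax: 0.362
    kc50: 4.19
    n: 1.3
    cv_percent: {kgEx: 9, kg: 22, Vmax: 13, tau: 5, kkmax: 13, kc50: 19, n: 7}
  "144580":
    kgEx: 0.0461
    kg: 395.0
    Vmax: 5920.0
    tau: 9.0
    kkmax: 0.516
    kc50: 25.8
    n: 2.4
    cv_percent: {kgEx: 8, kg: 65, Vmax: 16, tau: 5, kkmax: 13, kc50: 16, n: 21}
  GA-3109:
    kgEx: 0.115
    kg: 57.2
    Vmax: 7070.0
    tau: 5.81
    kkmax: 1.24
    kc50: 14.7
    n: 2.5
    cv_percent: {kgEx: 6, kg: 9, Vmax: 26, tau: 2, kkmax: 2, kc50: 6, n: 6}
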