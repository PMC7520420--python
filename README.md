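# adcpkpd

Translational PK/PD modeling for HER2 antibody–drug conjugates (ADCs).

Discovery-stage ADC programs routinely ask two questions: *how potent is
the new conjugate relative to the standard of care across tumor models?*
and *what clinical dose should be efficacious?* This package implements
the modeling pipeline that answers both for HER2 ADCs such as
trastuzumab emtansine (T-DM1) and next-generation conjugates
(PF-06804103), for modelers and quantitative pharmacologists:

1. **Mouse PK** — linear two-compartment IV disposition (closed-form
   simulation, macro↔micro constant conversion, allometric scaling to
   human with exponent 1 for volumes and 0.9 for clearances).
2. **Tumor growth inhibition (TGI)** — a modified Simeoni transit model:

       dV1/dt = G(TV)·V1 − k_kill(C)·V1,   k_kill = kkmax·Cⁿ/(kc50ⁿ+Cⁿ)
       dV2/dt = k_kill·V1 − V2/τ,  dV3/dt = (V2−V3)/τ,  dV4/dt = (V3−V4)/τ

   with logistic-capped exponential-to-linear switching growth
   G(TV) = kgEx(1−TV/Vmax)/(1+((kgEx/kg)·TV)^ψ)^(1/ψ), ψ = 20.
3. **Tumor-static concentration (TSC)** — the exposure at which kill
   balances growth, TSC = kc50·(G/(kkmax−G))^(1/n), with 80% CIs by
   log-normal parametric bootstrap. TSC is the potency yardstick that
   lets two ADCs be compared across cell-line and patient-derived
   xenografts.
4. **Clinical PK** — a target-mediated drug disposition (TMDD) model in
   which shed HER2 extracellular domain (ECD) circulating in serum binds
   the ADC and the complex is cleared, producing the non-linear clearance
   seen in patients.
5. **Translation** — mouse-fitted PD parameters driven by predicted human
   exposure to classify projected responses (regression / stasis /
   regrowth) and find stasis doses.

A synthetic-data module generates xenograft studies (log-normal
inter-animal growth variability, additive+proportional noise, Q4d×4
dosing) and clinical PK datasets with the statistical structure the
estimators assume, so the whole pipeline is testable end to end. A
two-stage estimation module (vehicle growth per animal, then pooled
penalized ML for the drug effect) fits the TGI model to tumor-volume
tables and the TMDD turnover to concentration tables.

## Worked example

```python
import numpy as np
from adcpkpd import (fixtures, bootstrap_tsc_ci, DosingRegimen,
                     simulate_tmdd, nca_metrics, predict_clinical)

# Potency in the JIMT-1 xenograft (a trastuzumab-resistant breast model)
p = fixtures.tgi_params("PF-06804103", "JIMT-1")
u = fixtures.tgi_uncertainty("PF-06804103", "JIMT-1")
r = bootstrap_tsc_ci(p, u, n_boot=10_000, seed=1)
print(f"TSC = {r.tsc:.2f} ug/mL, 80% CI [{r.ci80_low:.2f}, {r.ci80_high:.2f}]")

# Predicted human PK: shed-target TMDD makes clearance dose-dependent
human = fixtures.tmdd_pf_human()
times = np.arange(0.0, 21.0001, 0.005)
for dose in (0.15, 3.0):
    reg = DosingRegimen.uniform(dose, 21.0, 1, infusion_h=1.0)
    m = nca_metrics(simulate_tmdd(human, reg, times).profile("free", "ug/mL"),
                    dose=dose)
    print(f"dose {dose} mg/kg: CL = {m['CL']:.1f} mL/day/kg, "
          f"t1/2 = {m['half_life']:.1f} d")

# Projected clinical response at 1 mg/kg every 3 weeks x 4
reg = DosingRegimen.uniform(1.0, 21.0, 4, infusion_h=1.0)
pred = predict_clinical(p, human, reg, thresholds=(0.5, 4.0), model_id="JIMT-1")
print(f"JIMT-1 @ 1 mg/kg Q3Wx4: {pred.outcome} (TV ratio {pred.tv_ratio_end:.3f})")
```

prints

```
TSC = 4.72 ug/mL, 80% CI [3.90, 5.62]
dose 0.15 mg/kg: CL = 33.5 mL/day/kg, t1/2 = 0.9 d
dose 3.0 mg/kg: CL = 7.7 mL/day/kg, t1/2 = 4.3 d
JIMT-1 @ 1 mg/kg Q3Wx4: regression (TV ratio 0.098)
```

The TSC of 4.7 µg/mL is the constant plasma concentration that would hold
a small JIMT-1 tumor static; the CI reflects the fitted parameter
uncertainty. Clearance falling from 33.5 to 7.7 mL/day/kg as the dose
rises is the shed-target signature: at low doses a large fraction of the
ADC is captured by circulating ECD and cleared as complex. The final line
projects tumor regression in this model at the 1 mg/kg Q3W clinical
regimen — 21 days after the last dose the projected tumor volume is about
10% of baseline.

## Command line

Every stage is also a subcommand of the `adcpkpd` CLI, operating on
delimited-text tables and YAML configs (see `configs/` for the shipped
parameter sets): `simulate-pk`, `simulate-tgi`, `simulate-tmdd`, `nca`,
`fit-growth`, `fit-tgi`, `fit-tmdd`, `tsc`, `translate`, and
`generate-data`. For example:

```bash
adcpkpd tsc --params configs/pf06804103_tgi.yaml --n-boot 10000 --seed 1 --out tsc.csv
```

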