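"""Synthetic xenograft efficacy studies and clinical PK datasets.

The xenograft generator emulates the design of the mouse studies the TGI
model is fitted to: animals randomized at 150-300 mm^3, IV Q4d×4 dosing from
day 0, roughly weekly-or-denser caliper measurements, log-normal inter-animal
variability on the two growth rates, and an additive-plus-proportional
residual error on observed volumes. The clinical generator samples the
shed-target TMDD model under Q3W-style IV infusion with proportional
log-normal assay error, optionally varying each subject's baseline shed-target
level.

Per-animal/per-subject random streams are derived from the study seed with
``numpy`` SeedSequence spawn keys, so enlarging a study never perturbs the
data of existing animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .pk_linear import (
    ConcentrationProfile,
    DosingRegimen,
    InvalidParameterError,
    TwoCptParams,
    simulate_2cpt,
)
from .tgi_model import TGIParams, _rk4_tgi_grid
from .tmdd_model import TMDDParams, simulate_tmdd

__all__ = [
    "StudyDesign",
    "TumorStudy",
    "generate_xenograft_study",
    "generate_clinical_pk",
    "IIVSpec",
    "ResidualErrorModel",
]

#: observed volumes are floored here so additive noise cannot produce
#: non-positive measurements (a generator artifact, not a model feature)
VOLUME_FLOOR_MM3 = 1.0


@dataclass(frozen=True)
class IIVSpec:
    """Log-normal inter-animal SDs (omegas) of the growth parameters."""

    omega_kgEx: float
    omega_kg: float

    def __post_init__(self):
        if self.omega_kgEx < 0 or self.omega_kg < 0:
            raise InvalidParameterError("omegas must be >= 0")


@dataclass(frozen=True)
class ResidualErrorModel:
    """Combined residual error: SD(pred) = additive + proportional * pred."""

    additive: float
    proportional: float

    def __post_init__(self):
        if self.additive < 0 or self.proportional < 0:
            raise InvalidParameterError("error components must be >= 0")

    def sd(self, pred):
        return self.additive + self.proportional * np.asarray(pred, dtype=float)


@dataclass(frozen=True)
class StudyDesign:
    """Design of a xenograft efficacy study.

    dose_arms lists mg/kg per arm with 0 meaning vehicle; every dose in
    ``dose_times`` (day) is given to every dosed arm (IV bolus by default,
    infusion_h > 0 for zero-order input). Measurements are taken on
    ``measurement_days``; initial volumes are uniform over ``v0_range``.
    """

    n_animals_per_arm: int = 8
    dose_arms: tuple = (0.0, 0.25, 0.5, 1.0)
    dose_times: tuple = (0.0, 4.0, 8.0, 12.0)  # Q4d x 4
    infusion_h: float = 0.0
    measurement_days: tuple = (0.0, 4.0, 7.0, 11.0, 14.0, 18.0, 21.0, 25.0, 28.0)
    v0_range: tuple = (150.0, 300.0)
    v0_distribution: str = "uniform"  # or "lognormal" (median = geometric mid)

    def __post_init__(self):
        if self.n_animals_per_arm < 1:
            raise InvalidParameterError("need >= 1 animal per arm")
        if not any(d == 0 for d in self.dose_arms):
            raise InvalidParameterError("need >= 1 vehicle (dose 0) arm for growth fitting")
        if min(self.measurement_days) < 0:
            raise InvalidParameterError("measurement days must be >= 0")
        if 0.0 not in self.measurement_days:
            raise InvalidParameterError("each animal needs a day-0 measurement")
        if self.v0_range[0] <= 0 or self.v0_range[1] < self.v0_range[0]:
            raise InvalidParameterError("v0_range must satisfy 0 < lo <= hi")
        if self.v0_distribution not in ("uniform", "lognormal"):
            raise InvalidParameterError("v0_distribution must be uniform or lognormal")

    def regimen_for_dose(self, dose: float) -> DosingRegimen | None:
        if dose == 0:
            return None
        return DosingRegimen.uniform(
            dose,
            interval_day=(self.dose_times[1] - self.dose_times[0])
            if len(self.dose_times) > 1
            else 1.0,
            n_doses=len(self.dose_times),
            infusion_h=self.infusion_h,
            start_day=self.dose_times[0],
        )


@dataclass
class TumorStudy:
    """Animal-level longitudinal tumor volumes plus (for synthetic data) truth.

    ``data`` columns: animal_id, arm_id, dose_mg_per_kg, time_day,
    tumor_volume_mm3. ``truth`` (optional) holds each animal's generating
    parameters for recovery testing; ``dose_times`` records the shared dosing
    schedule.
    """

    data: pd.DataFrame
    truth: pd.DataFrame | None = None
    dose_times: tuple | None = None
    infusion_h: float = 0.0

    REQUIRED = ("animal_id", "arm_id", "dose_mg_per_kg", "time_day", "tumor_volume_mm3")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"TumorStudy missing columns: {missing}")
        if (self.data["tumor_volume_mm3"] <= 0).any():
            raise InvalidParameterError("tumor volumes must be > 0")
        ids_without_day0 = [
            aid
            for aid, g in self.data.groupby("animal_id")
            if (g["time_day"].min() != 0)
        ]
        if ids_without_day0:
            raise InvalidParameterError(
                f"animals missing a day-0 measurement: {ids_without_day0[:5]}"
            )

    def vehicle(self) -> pd.DataFrame:
        return self.data[self.data["dose_mg_per_kg"] == 0]

    def dosed(self) -> pd.DataFrame:
        return self.data[self.data["dose_mg_per_kg"] > 0]

    @property
    def arms(self) -> list:
        return sorted(self.data["dose_mg_per_kg"].unique())


def _grid_for(days: Sequence[float], dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Half-step RK4 grid covering [0, max(days)] and indices of the days."""
    t_end = float(max(days))
    n_steps = max(1, int(round(t_end / dt)))
    dt_eff = t_end / n_steps
    half = np.linspace(0.0, t_end, 2 * n_steps + 1)
    idx = np.array([min(n_steps, int(round(d / dt_eff))) for d in days])
    return half, idx


def generate_xenograft_study(
    design: StudyDesign,
    p: TGIParams,
    iiv: IIVSpec,
    err: ResidualErrorModel,
    pk: TwoCptParams,
    seed: int,
    dt: float = 0.02,
) -> TumorStudy:
    """Simulate a xenograft efficacy study with the stated statistical structure.

    Each animal's kgEx and kg are log-normal with median at the population
    value and log-SD equal to the omegas; v0 is drawn over ``v0_range``;
    trajectories come from the TGI model driven by the closed-form plasma
    concentration of the animal's dose arm; observations add combined
    additive+proportional Gaussian noise and are floored at 1 mm^3.
    """
    days = np.asarray(sorted(design.measurement_days), dtype=float)
    half_grid, day_idx = _grid_for(days, dt)
    n_steps = (len(half_grid) - 1) // 2
    dt_eff = half_grid[-1] / n_steps if n_steps else dt

    rows, truth_rows = [], []
    for arm_idx, dose in enumerate(design.dose_arms):
        regimen = design.regimen_for_dose(dose)
        if regimen is None:
            conc_half = np.zeros_like(half_grid)
            conc_left = conc_half
        else:
            conc_half = simulate_2cpt(pk, regimen, half_grid).values
            # left limits so bolus jumps at grid nodes are not smeared
            conc_left = simulate_2cpt(
                pk, regimen, np.maximum(half_grid - 1e-9, 0.0)
            ).values
        m = design.n_animals_per_arm
        kgEx = np.empty(m)
        kg = np.empty(m)
        v0 = np.empty(m)
        noise = np.empty((len(days), m))
        for j in range(m):
            # independent stream per (arm, animal): adding animals/arms later
            # leaves earlier draws untouched
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(arm_idx, j))
            )
            kgEx[j] = p.kgEx * np.exp(iiv.omega_kgEx * rng.standard_normal())
            kg[j] = p.kg * np.exp(iiv.omega_kg * rng.standard_normal())
            lo, hi = design.v0_range
            if design.v0_distribution == "uniform":
                v0[j] = rng.uniform(lo, hi)
            else:
                med = np.sqrt(lo * hi)
                sd = np.log(hi / lo) / 4.0
                v0[j] = med * np.exp(sd * rng.standard_normal())
            noise[:, j] = rng.standard_normal(len(days))
        tv = _rk4_tgi_grid(
            kgEx, kg, p.Vmax, p.tau, p.kkmax, p.kc50, p.n, p.psi, v0,
            conc_half, dt_eff, conc_half_left=conc_left,
        )
        pred = tv[day_idx, :]
        obs = np.maximum(pred + err.sd(pred) * noise, VOLUME_FLOOR_MM3)
        for j in range(m):
            aid = f"arm{arm_idx}_an{j}"
            truth_rows.append(
                {"animal_id": aid, "arm_id": f"arm{arm_idx}", "dose_mg_per_kg": dose,
                 "kgEx": kgEx[j], "kg": kg[j], "v0": v0[j]}
            )
            for d, day in enumerate(days):
                rows.append(
                    {"animal_id": aid, "arm_id": f"arm{arm_idx}",
                     "dose_mg_per_kg": dose, "time_day": day,
                     "tumor_volume_mm3": obs[d, j]}
                )
    return TumorStudy(
        data=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
        dose_times=design.dose_times,
        infusion_h=design.infusion_h,
    )


def generate_clinical_pk(
    p: TMDDParams,
    doses: Sequence[float],
    sampling_days: Sequence[float],
    prop_error: float,
    n_per_dose: int,
    seed: int,
    regimen_interval_day: float = 21.0,
    n_doses: int = 1,
    infusion_h: float = 1.0,
    ecd0_range: tuple | None = None,
    analyte: str = "free",
) -> list[ConcentrationProfile]:
    """Sample clinical PK profiles from the shed-target TMDD model.

    One profile per subject; ``n_per_dose`` subjects at each dose level,
    dosed by 1-h IV infusion (default single dose; set n_doses for Q3W-style
    repeat dosing). Observations are log-normally perturbed with log-SD
    ``prop_error``. If ``ecd0_range`` (nM) is given, each subject's baseline
    shed-target level is drawn uniformly in it (kshed re-tied).
    """
    days = np.asarray(sorted(sampling_days), dtype=float)
    profiles = []
    for d_idx, dose in enumerate(doses):
        regimen = DosingRegimen.uniform(dose, regimen_interval_day, n_doses,
                                        infusion_h=infusion_h)
        base_traj = None
        for s in range(n_per_dose):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(d_idx, s))
            )
            if ecd0_range is not None:
                ecd0 = rng.uniform(*ecd0_range)
                subj_p = p.with_ecd0(ecd0)
                traj = simulate_tmdd(subj_p, regimen, days)
            else:
                if base_traj is None:
                    base_traj = simulate_tmdd(p, regimen, days)
                traj = base_traj
            clean = traj.profile(analyte=analyte, unit="ug/mL").values
            obs = clean * np.exp(prop_error * rng.standard_normal(len(days)))
            profiles.append(
                ConcentrationProfile(
                    days, obs, unit="ug/mL", analyte=analyte,
                    subject_id=f"dose{d_idx}_s{s}", dose=dose,
                )
            )
    return profiles
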