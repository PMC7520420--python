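"""Target-mediated drug disposition (TMDD) model with a shed soluble target.

Clinical PK of anti-HER2 ADCs is non-linear because the shed HER2
extracellular domain (ECD) circulating in serum binds the antibody and the
complex is cleared. The model couples a linear two-compartment disposition of
free ADC with turnover of the shed target (zero-order shedding kshed,
first-order degradation kdeg) and 1:1 reversible binding (kon, koff = KD*kon),
with first-order elimination of the complex (kel_complex). All concentrations
are in nM; time in days.

    dC_ADC/dt     = In(t) - (CL/Vc) C_ADC - (Q/Vc) C_ADC + (Q/Vp)(Vp/Vc) C_per
                    - kon C_ADC C_ECD + koff C_cplx
    dC_per/dt     = (Q/Vc)(Vc/Vp) C_ADC - (Q/Vp) C_per
    dC_ECD/dt     = kshed - kdeg C_ECD - kon C_ADC C_ECD + koff C_cplx
    dC_cplx/dt    = kon C_ADC C_ECD - koff C_cplx - kel_complex C_cplx

Initial state: drug-free with C_ECD(0) = ECD0 (default kshed/kdeg, the
turnover steady state). A "free" assay observes C_ADC; a "total" assay
observes C_ADC + C_cplx.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from .pk_linear import (
    NMOL_PER_MG_ADC,
    ConcentrationProfile,
    DosingRegimen,
    InvalidParameterError,
    TwoCptParams,
    nm_to_ugml,
)
from .tgi_model import IntegrationError

__all__ = [
    "TMDDParams",
    "TMDDState",
    "TMDDTrajectory",
    "simulate_tmdd",
    "nca_metrics",
    "fit_ecd_to_profile",
]


@dataclass(frozen=True)
class TMDDParams:
    """Linear PK plus shed-target binding/turnover parameters.

    linear : two-compartment disposition of the free ADC (per kg)
    KD : ADC-target binding affinity (nM); koff = KD * kon
    kon : association rate (1/nM/day)
    kshed : zero-order target shedding rate (nM/day)
    kdeg : first-order target degradation rate (1/day)
    kel_complex : elimination rate of the ADC-target complex (1/day)
    ecd0 : baseline shed-target concentration (nM); default kshed/kdeg so the
        target starts at its turnover steady state. Supplying an inconsistent
        ecd0 requires ``allow_inconsistent_baseline=True``.
    """

    linear: TwoCptParams
    KD: float
    kon: float
    kshed: float
    kdeg: float
    kel_complex: float
    ecd0: float | None = None
    allow_inconsistent_baseline: bool = False

    def __post_init__(self):
        bad = [
            k
            for k in ("KD", "kshed", "kdeg", "kel_complex")
            if getattr(self, k) <= 0
        ]
        if self.kon < 0:
            bad.append("kon")
        if bad:
            raise InvalidParameterError(
                f"TMDDParams requires positive values; invalid: {bad}"
            )
        if self.ecd0 is None:
            object.__setattr__(self, "ecd0", self.kshed / self.kdeg)
        elif self.ecd0 <= 0:
            raise InvalidParameterError("ecd0 must be > 0")
        else:
            consistent = abs(self.kshed - self.kdeg * self.ecd0) <= 1e-6 * self.kshed
            if not consistent and not self.allow_inconsistent_baseline:
                raise InvalidParameterError(
                    f"kshed ({self.kshed}) != kdeg*ecd0 ({self.kdeg * self.ecd0:.6g}); "
                    "pass allow_inconsistent_baseline=True to start off steady state"
                )

    @property
    def koff(self) -> float:
        return self.KD * self.kon

    def with_ecd0(self, ecd0: float) -> "TMDDParams":
        """Re-tie the baseline: set ecd0 and kshed = kdeg * ecd0."""
        return replace(self, ecd0=ecd0, kshed=self.kdeg * ecd0,
                       allow_inconsistent_baseline=False)


@dataclass(frozen=True)
class TMDDState:
    """Concentrations (nM): free ADC central/peripheral, free target, complex."""

    C_ADC: float
    C_ADC_per: float
    C_ECD: float
    C_ADC_ECD: float


@dataclass
class TMDDTrajectory:
    """Solution of the TMDD system on a time grid (all nM)."""

    times: np.ndarray
    C_ADC: np.ndarray
    C_ADC_per: np.ndarray
    C_ECD: np.ndarray
    C_ADC_ECD: np.ndarray

    def states(self) -> list[TMDDState]:
        return [
            TMDDState(self.C_ADC[i], self.C_ADC_per[i], self.C_ECD[i], self.C_ADC_ECD[i])
            for i in range(len(self.times))
        ]

    def profile(self, analyte: str = "free", unit: str = "ug/mL") -> ConcentrationProfile:
        """Observable concentration trace: free ADC or total (free + complex)."""
        if analyte == "free":
            vals = self.C_ADC
        elif analyte == "total":
            vals = self.C_ADC + self.C_ADC_ECD
        else:
            raise InvalidParameterError("analyte must be 'free' or 'total'")
        prof = ConcentrationProfile(self.times, np.maximum(vals, 0.0), unit="nM",
                                    analyte=analyte)
        return prof.as_unit(unit)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_day": self.times,
                "C_ADC_nM": self.C_ADC,
                "C_ADC_per_nM": self.C_ADC_per,
                "C_ECD_nM": self.C_ECD,
                "C_ADC_ECD_nM": self.C_ADC_ECD,
            }
        )


def _dose_to_nM(dose_mg_per_kg: float, Vc_mL_per_kg: float) -> float:
    """Concentration (nM) added to central by a dose, = nmol/kg over L/kg."""
    return dose_mg_per_kg * NMOL_PER_MG_ADC / (Vc_mL_per_kg / 1000.0)


def simulate_tmdd(
    p: TMDDParams,
    regimen: DosingRegimen,
    times: Sequence[float],
    rtol: float = 1e-9,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> TMDDTrajectory:
    """Integrate the shed-target TMDD system for an IV regimen.

    Infusions enter the central compartment at a constant zero-order rate over
    their stated duration; bolus events add dose/Vc instantaneously. The
    integrator restarts at every infusion start/end so the piecewise-constant
    input never sits inside a solver step.
    """
    t_req = np.asarray(times, dtype=float)
    if np.any(t_req < 0) or np.any(np.diff(t_req) < 0):
        raise InvalidParameterError("times must be >= 0 and non-decreasing")
    lin = p.linear
    kel = lin.CL / lin.Vc
    k12 = lin.Q / lin.Vc
    k21 = lin.Q / lin.Vp
    kon, koff = p.kon, p.koff

    # piecewise-constant infusion rate in nM/day
    infusions = []  # (start, end, rate_nM_per_day)
    boluses = []  # (time, delta_nM)
    for e in regimen.events:
        if e.dose == 0:
            continue
        amt = _dose_to_nM(e.dose, lin.Vc)
        if e.infusion_duration == 0:
            boluses.append((e.start_time, amt))
        else:
            infusions.append(
                (e.start_time, e.start_time + e.infusion_duration, amt / e.infusion_duration)
            )

    def rate_in(t: float) -> float:
        return sum(r for a, b, r in infusions if a <= t < b)

    def rhs(t, y, r_in):
        c, cp, e, x = y
        bind = kon * c * e - koff * x
        return [
            r_in - kel * c - k12 * c + k21 * cp * (lin.Vp / lin.Vc) - bind,
            k12 * c * (lin.Vc / lin.Vp) - k21 * cp,
            p.kshed - p.kdeg * e - bind,
            bind - p.kel_complex * x,
        ]

    t_end = float(t_req[-1]) if t_req.size else 0.0
    bp = set()
    for a, b, _ in infusions:
        bp.update((a, b))
    for t0, _ in boluses:
        bp.add(t0)
    knots = np.unique(np.array([0.0, t_end] + [x for x in bp if 0 < x < t_end]))
    bolus_map = {}
    for t0, amt in boluses:
        bolus_map[t0] = bolus_map.get(t0, 0.0) + amt

    y = np.array([0.0, 0.0, p.ecd0, 0.0])
    if 0.0 in bolus_map:
        y[0] += bolus_map[0.0]
    out_t, out_y = [], []
    if t_req.size and t_req[0] == 0.0:
        out_t.append(np.array([0.0]))
        out_y.append(y[:, None].copy())
    for a, b in zip(knots[:-1], knots[1:]):
        r_in = rate_in((a + b) / 2.0)
        mask = (t_req > a) & (t_req <= b)
        t_eval = np.union1d(t_req[mask], [b])
        sol = solve_ivp(
            rhs, (a, b), y, args=(r_in,), method=method, t_eval=t_eval,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"TMDD integration failed on [{a}, {b}]: {sol.message}")
        keep = np.isin(sol.t, t_req[mask])
        if keep.any():
            out_t.append(sol.t[keep])
            out_y.append(sol.y[:, keep])
        y = sol.y[:, -1].copy()
        if b in bolus_map:
            y[0] += bolus_map[b]
    tt = np.concatenate(out_t) if out_t else np.array([])
    yy = np.concatenate(out_y, axis=1) if out_y else np.zeros((4, 0))
    yy = np.maximum(yy, 0.0)
    return TMDDTrajectory(times=tt, C_ADC=yy[0], C_ADC_per=yy[1], C_ECD=yy[2],
                          C_ADC_ECD=yy[3])


def nca_metrics(
    profile: ConcentrationProfile,
    dose: float,
    terminal_window: tuple[float, float] | None = None,
) -> dict:
    """Non-compartmental PK metrics from a concentration-time profile.

    AUC(0->inf) is the trapezoid over the sampled grid plus the log-linear
    tail C_last/lambda_z; lambda_z comes from regressing ln(conc) on time over
    ``terminal_window``. The default window spans the post-distribution phase
    — from 10% of the sampled span through the last sample — rather than only
    the final samples: with a shed-target sink the very late decline is
    target-accelerated, and a last-points-only window would measure that
    accelerated tail instead of the elimination phase. Clearance is dose/AUC
    with dose in mg/kg and concentrations in µg/mL, giving mL/day/kg;
    half-life is ln2/lambda_z in days.
    """
    prof = profile.as_unit("ug/mL")
    t, c = prof.times, prof.values
    if terminal_window is None:
        span = t[-1] - t[0]
        terminal_window = (t[0] + 0.10 * span, t[-1])
    lo, hi = terminal_window
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 3:
        raise InvalidParameterError("terminal window must contain >= 3 samples")
    tw, cw = t[sel], c[sel]
    if np.any(cw <= 0):
        raise InvalidParameterError("profile must be strictly positive in the terminal window")
    if np.any(np.diff(cw) > 1e-9 * cw[:-1]):
        raise InvalidParameterError(
            "non-monotone terminal phase in the window; choose a later terminal_window"
        )
    fit = linregress(tw, np.log(cw))
    lambda_z = -fit.slope
    if lambda_z <= 0:
        raise InvalidParameterError("terminal slope is non-negative; choose a later window")
    auc_grid = float(np.trapezoid(c, t))
    auc = auc_grid + float(c[-1]) / lambda_z
    cl = dose * 1000.0 / auc  # (µg/kg) / (µg·day/mL) = mL/day/kg
    return {"CL": cl, "half_life": float(np.log(2) / lambda_z), "AUC": auc,
            "lambda_z": float(lambda_z), "AUC_grid": auc_grid}


def fit_ecd_to_profile(
    observed: ConcentrationProfile,
    p: TMDDParams,
    regimen: DosingRegimen,
    ecd_bounds: tuple[float, float] = (0.16, 0.28),
) -> float:
    """One-dimensional least-squares fit of the baseline shed-target level.

    Re-ties kshed = kdeg * ECD0 at every trial value and minimizes the sum of
    squared log-scale residuals of the observed analyte against the simulated
    profile. Returns the optimal ECD0 (nM); warns when the optimum sits at a
    bound.
    """
    lo, hi = ecd_bounds
    if lo <= 0 or hi <= lo:
        raise InvalidParameterError("ecd_bounds must satisfy 0 < lo < hi")
    obs = observed.as_unit("nM")
    mask = obs.values > 0
    t_obs, v_obs = obs.times[mask], obs.values[mask]
    log_obs = np.log(v_obs)

    def sse(ecd0: float) -> float:
        traj = simulate_tmdd(p.with_ecd0(ecd0), regimen, t_obs, rtol=1e-8, atol=1e-10)
        pred = traj.profile(analyte=observed.analyte, unit="nM").values
        pred = np.maximum(pred, 1e-12)
        return float(np.sum((np.log(pred) - log_obs) ** 2))

    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6 * (hi - lo)})
    x = float(res.x)
    if min(x - lo, hi - x) < 1e-3 * (hi - lo):
        warnings.warn(
            f"fitted ECD0 = {x:.4g} nM lies at a bound of {ecd_bounds}; "
            "consider widening the bounds",
            stacklevel=2,
        )
    return x
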