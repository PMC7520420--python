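"""Mouse-to-human efficacy translation for HER2 ADCs.

Clinical tumor response is projected by driving the mouse-fitted TGI model
with the predicted human free-ADC concentration from the shed-target TMDD
model. Mouse PD parameters (including the initial tumor volume) are carried
over unchanged; plasma concentration is assumed a valid surrogate for the
concentration at the tumor. Because xenografts grow much faster than
clinical tumors, predicted stasis under mouse growth rates is interpreted as
at least stable disease in patients — the predictions are conservative, which
the output labels note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pk_linear import (
    UGML_PER_NM_ADC,
    DosingRegimen,
    InvalidParameterError,
)
from .tgi_model import TGIParams, simulate_tgi
from .tmdd_model import TMDDParams, simulate_tmdd

__all__ = [
    "OUTCOME_THRESHOLDS",
    "ClinicalPrediction",
    "predict_clinical",
    "dose_for_stasis",
]

#: default tumor-volume-ratio thresholds: < lower -> regression,
#: [lower, upper] -> stasis, > upper -> regrowth
OUTCOME_THRESHOLDS = (0.8, 1.2)

#: the mouse-stasis ≈ human better-than-stable-disease caveat, attached to
#: every prediction rather than modeled
TRANSLATION_NOTE = (
    "mouse growth rates exceed clinical ones; predicted stasis corresponds to "
    "at least stable disease in patients"
)


@dataclass
class ClinicalPrediction:
    """Projected clinical tumor trajectory and its outcome class."""

    model_id: str
    regimen: DosingRegimen
    times: np.ndarray
    tv: np.ndarray
    outcome: str  # regression | stasis | regrowth
    tv_ratio_end: float
    note: str = TRANSLATION_NOTE


def _classify(ratio: float, thresholds: tuple[float, float]) -> str:
    lo, hi = thresholds
    if ratio < lo:
        return "regression"
    if ratio <= hi:
        return "stasis"
    return "regrowth"


def predict_clinical(
    pd_params: TGIParams,
    human_pk: TMDDParams,
    regimen: DosingRegimen,
    horizon: float | None = None,
    thresholds: tuple[float, float] = OUTCOME_THRESHOLDS,
    v0: float | None = None,
    model_id: str = "",
    pk_dt: float = 0.01,
) -> ClinicalPrediction:
    """Simulate a clinical regimen and classify the tumor response.

    The free-ADC plasma concentration from the TMDD model (nM) is converted
    to µg/mL and drives the TGI model with the mouse-fitted PD parameters.
    The outcome is classified from TV(horizon)/v0 against ``thresholds``;
    the default horizon is one dosing interval past the last dose.
    """
    last = regimen.events[-1].start_time
    if horizon is None:
        interval = (
            regimen.events[1].start_time - regimen.events[0].start_time
            if len(regimen.events) > 1
            else 21.0
        )
        horizon = last + interval
    if horizon < last:
        raise InvalidParameterError("horizon must extend past the last dose")
    v0 = pd_params.v0 if v0 is None else v0
    if v0 != pd_params.v0:
        pd_params = TGIParams(
            kgEx=pd_params.kgEx, kg=pd_params.kg, Vmax=pd_params.Vmax,
            tau=pd_params.tau, kkmax=pd_params.kkmax, kc50=pd_params.kc50,
            n=pd_params.n, psi=pd_params.psi, v0=v0,
        )

    pk_times = np.arange(0.0, horizon + pk_dt / 2, pk_dt)
    traj = simulate_tmdd(human_pk, regimen, pk_times)
    conc = traj.profile(analyte="free", unit="ug/mL")

    out_times = np.linspace(0.0, horizon, int(round(horizon)) * 4 + 1)
    tgi = simulate_tgi(
        pd_params, conc, out_times, breakpoints=regimen.breakpoints
    )
    ratio = float(tgi.tv[-1] / v0)
    return ClinicalPrediction(
        model_id=model_id,
        regimen=regimen,
        times=tgi.times,
        tv=tgi.tv,
        outcome=_classify(ratio, thresholds),
        tv_ratio_end=ratio,
    )


def dose_for_stasis(
    pd_params: TGIParams,
    human_pk: TMDDParams,
    interval: float = 21.0,
    n_doses: int = 4,
    bracket: tuple[float, float] = (0.05, 10.0),
    infusion_h: float = 1.0,
    tol: float = 0.01,
    max_iter: int = 60,
    **predict_kwargs,
) -> float:
    """Bisect on dose until the end-of-horizon volume ratio crosses 1.

    Returns the dose (mg/kg) at which TV(horizon) = v0 within ``tol`` on the
    ratio. Raises if the bracket does not straddle the stasis boundary (e.g.
    kkmax below the growth rate, where no dose achieves stasis).
    """

    def ratio(dose: float) -> float:
        regimen = DosingRegimen.uniform(dose, interval, n_doses, infusion_h=infusion_h)
        return predict_clinical(
            pd_params, human_pk, regimen, **predict_kwargs
        ).tv_ratio_end - 1.0

    lo, hi = bracket
    f_lo, f_hi = ratio(lo), ratio(hi)
    if f_lo * f_hi > 0:
        raise InvalidParameterError(
            f"bracket {bracket} does not straddle the stasis boundary "
            f"(ratio-1 at ends: {f_lo:.3g}, {f_hi:.3g}); no dose in the bracket "
            "achieves stasis" if f_lo > 0 else
            f"bracket {bracket} does not straddle the stasis boundary "
            f"(ratio-1 at ends: {f_lo:.3g}, {f_hi:.3g})"
        )
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # bisect in log-dose
        f_mid = ratio(mid)
        if abs(f_mid) < tol:
            return float(mid)
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return float(np.sqrt(lo * hi))
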