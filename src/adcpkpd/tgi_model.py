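"""Tumor growth inhibition ODE model for ADC xenograft efficacy.

A modified Simeoni transit-compartment model: proliferating volume V1 grows
with a logistic cap (Vmax) and a smooth switch between exponential and linear
growth regimes, while a concentration-driven Hill kill rate moves volume into
a chain of three transduction (death-signaling) compartments V2-V4 that drain
with mean transit time tau.

    dV1/dt = G(TV) * V1 - k_kill(C) * V1
    dV2/dt = k_kill(C) * V1 - V2/tau
    dV3/dt = (V2 - V3)/tau
    dV4/dt = (V3 - V4)/tau
    TV     = V1 + V2 + V3 + V4

with G(TV) = kgEx (1 - TV/Vmax) / (1 + ((kgEx/kg) TV)^psi)^(1/psi) and
k_kill(C) = kkmax C^n / (kc50^n + C^n). Initial condition: V1(0)=v0, rest 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .pk_linear import (
    ConcentrationProfile,
    DosingRegimen,
    InvalidParameterError,
    TwoCptParams,
    concentration_fn,
)

__all__ = [
    "TGIParams",
    "TGIState",
    "TGITrajectory",
    "kill_rate",
    "growth_rate",
    "simulate_tgi",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """ODE solver failed; message carries solver diagnostics."""


@dataclass(frozen=True)
class TGIParams:
    """Parameters of the tumor growth inhibition model.

    kgEx : exponential growth rate (1/day)
    kg : linear growth rate (mm^3/day)
    Vmax : maximum tumor volume (mm^3)
    tau : transduction (transit) time per death compartment (day)
    kkmax : maximum kill rate (1/day)
    kc50 : plasma concentration at half-maximal kill (µg/mL)
    n : Hill coefficient
    psi : exponential-to-linear switching exponent (fixed at 20 in the
        reference analyses; override only deliberately)
    v0 : initial tumor volume (mm^3)
    """

    kgEx: float
    kg: float
    Vmax: float
    tau: float
    kkmax: float
    kc50: float
    n: float
    psi: float = 20.0
    v0: float = 200.0

    def __post_init__(self):
        bad = [
            k
            for k in ("kgEx", "kg", "Vmax", "tau", "kkmax", "kc50", "n", "psi", "v0")
            if getattr(self, k) <= 0
        ]
        if bad:
            raise InvalidParameterError(
                f"TGIParams requires strictly positive values; non-positive: {bad}"
            )


@dataclass(frozen=True)
class TGIState:
    """Model state at one time: compartment volumes, total, and kill rate."""

    V1: float
    V2: float
    V3: float
    V4: float
    TV: float
    kkill: float


@dataclass
class TGITrajectory:
    """Solution of the TGI system on a time grid."""

    times: np.ndarray  # (m,)
    V: np.ndarray  # (m, 4)
    kkill: np.ndarray  # (m,)

    @property
    def tv(self) -> np.ndarray:
        return self.V.sum(axis=1)

    def states(self) -> list[TGIState]:
        tv = self.tv
        return [
            TGIState(*self.V[i], tv[i], self.kkill[i]) for i in range(len(self.times))
        ]

    def to_frame(self, animal_id: str | None = None):
        import pandas as pd

        d = {
            "time_day": self.times,
            "V1": self.V[:, 0],
            "V2": self.V[:, 1],
            "V3": self.V[:, 2],
            "V4": self.V[:, 3],
            "TV": self.tv,
        }
        df = pd.DataFrame(d)
        if animal_id is not None:
            df.insert(0, "animal_id", animal_id)
        return df


def kill_rate(c, p: TGIParams):
    """Hill kill rate k_kill(C) = kkmax C^n / (kc50^n + C^n), in 1/day.

    Zero at C=0, half-maximal at C=kc50, saturating at kkmax.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise InvalidParameterError("concentration must be >= 0")
    # evaluated as kkmax / (1 + (kc50/c)^n): overflow-safe for large n
    with np.errstate(divide="ignore", over="ignore"):
        out = np.where(c > 0, p.kkmax / (1.0 + (p.kc50 / np.where(c > 0, c, 1.0)) ** p.n), 0.0)
    return float(out) if out.ndim == 0 else out


def _switch_denominator(x, psi):
    """(1 + x^psi)^(1/psi) computed in log space to avoid overflow for x^20."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    posmask = x > 0
    out[posmask] = np.exp(np.logaddexp(0.0, psi * np.log(x[posmask])) / psi)
    return out


def growth_rate(tv, p: TGIParams):
    """Per-volume net growth factor G(TV), in 1/day.

    G(TV) = kgEx (1 - TV/Vmax) / (1 + ((kgEx/kg) TV)^psi)^(1/psi).
    Tends to kgEx as TV->0 (exponential regime); for TV large relative to
    kg/kgEx the product G*V1 approaches the linear rate kg; G(Vmax)=0.
    """
    tv = np.asarray(tv, dtype=float)
    if np.any(tv < 0):
        raise InvalidParameterError("tumor volume must be >= 0")
    denom = _switch_denominator((p.kgEx / p.kg) * tv, p.psi)
    out = p.kgEx * (1.0 - tv / p.Vmax) / denom
    return float(out) if out.ndim == 0 else out


def _resolve_conc(conc) -> tuple[Callable, np.ndarray]:
    """Normalize the driving concentration into (callable c(t), breakpoints)."""
    if conc is None:
        return (lambda t: np.zeros_like(np.asarray(t, dtype=float))), np.array([])
    if isinstance(conc, ConcentrationProfile):
        prof = conc.as_unit("ug/mL")
        f = prof.interpolator()
        return f, np.array([])
    if isinstance(conc, tuple) and len(conc) == 2 and isinstance(conc[0], TwoCptParams):
        p, regimen = conc
        return concentration_fn(p, regimen), regimen.breakpoints
    if callable(conc):
        return conc, np.array([])
    raise TypeError(
        "conc must be None, a ConcentrationProfile, a callable c(t), or a "
        "(TwoCptParams, DosingRegimen) pair"
    )


def simulate_tgi(
    p: TGIParams,
    conc,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    breakpoints: Sequence[float] | None = None,
) -> TGITrajectory:
    """Integrate the TGI system driven by a plasma concentration input.

    ``conc`` may be None (vehicle), a ConcentrationProfile (interpolated), a
    callable c(t) in µg/mL, or a (TwoCptParams, DosingRegimen) pair simulated
    analytically. Integration restarts at dose-event breakpoints so that
    concentration discontinuities never sit inside a solver step.
    """
    t_req = np.asarray(times, dtype=float)
    if np.any(t_req < 0) or np.any(np.diff(t_req) < 0):
        raise InvalidParameterError("times must be >= 0 and non-decreasing")
    cfun, bp = _resolve_conc(conc)
    if breakpoints is not None:
        bp = np.union1d(bp, np.asarray(breakpoints, dtype=float))

    def rhs(t, y):
        v1 = y[0]
        tv = max(y.sum(), 0.0)
        g = growth_rate(tv, p)
        kk = kill_rate(max(float(np.asarray(cfun(t)).item()), 0.0), p)
        return [
            g * v1 - kk * v1,
            kk * v1 - y[1] / p.tau,
            (y[1] - y[2]) / p.tau,
            (y[2] - y[3]) / p.tau,
        ]

    t_end = float(t_req[-1]) if len(t_req) else 0.0
    knots = np.unique(
        np.concatenate([[0.0, t_end], bp[(bp > 0) & (bp < t_end)]])
    )
    y = np.array([p.v0, 0.0, 0.0, 0.0])
    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    if t_req.size and t_req[0] == 0.0:
        out_t.append(np.array([0.0]))
        out_y.append(y[:, None].copy())
    for a, b in zip(knots[:-1], knots[1:]):
        mask = (t_req > a) & (t_req <= b)
        t_eval = np.union1d(t_req[mask], [b])  # always land on the breakpoint
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"TGI integration failed on [{a}, {b}]: {sol.message}"
            )
        keep = np.isin(sol.t, t_req[mask])
        if keep.any():
            out_t.append(sol.t[keep])
            out_y.append(sol.y[:, keep])
        y = sol.y[:, -1]
    tt = np.concatenate(out_t) if out_t else np.array([])
    yy = np.concatenate(out_y, axis=1).T if out_y else np.zeros((0, 4))
    yy = np.maximum(yy, 0.0)
    cvals = np.maximum(np.asarray(cfun(tt), dtype=float), 0.0) if tt.size else np.array([])
    kk = kill_rate(cvals, p) if tt.size else np.array([])
    return TGITrajectory(times=tt, V=yy, kkill=np.atleast_1d(kk))


# --- fast vectorized grid integrator (internal) ------------------------------
#
# Fixed-step RK4 on a regular grid, compiled with numba. This is the bulk
# simulation path used by the estimation and synthetic-data modules, where the
# same smooth system is integrated thousands of times; the public solver
# remains the adaptive stiff-capable simulate_tgi above, and the two are
# cross-checked in the test suite.

from numba import njit


@njit(cache=True)
def _growth_factor_scalar(kgEx, kg, Vmax, psi, tv):
    if tv <= 0.0:
        return kgEx
    x = kgEx / kg * tv
    if x < 1.0:
        denom = math.exp(math.log1p(x**psi) / psi)
    else:
        denom = x * math.exp(math.log1p(x**-psi) / psi)
    return kgEx * (1.0 - tv / Vmax) / denom


@njit(cache=True)
def _rk4_tgi_kernel(kgEx, kg, Vmax, tau, psi, kk_half, kk_left, v0, dt):
    """RK4 over (2*n_steps+1, m) half-grid kill rates; returns TV (n_steps+1, m).

    ``kk_left`` holds the left-limit kill rate at each node: the final RK
    stage of the step ending on a dose event must see the pre-dose
    concentration, while the first stage of the step starting there sees the
    post-dose value — otherwise the bolus discontinuity is smeared across one
    step and the local error degrades to O(dt).
    """
    n_half, m = kk_half.shape
    n_steps = (n_half - 1) // 2
    y = np.zeros((4, m))
    for j in range(m):
        y[0, j] = v0[j]
    tv_out = np.empty((n_steps + 1, m))
    for j in range(m):
        tv_out[0, j] = v0[j]
    f = np.empty((4, 4, m))  # RK stage derivatives
    yt = np.empty((4, m))
    for i in range(n_steps):
        for stage in range(4):
            if stage == 0:
                kk_row = kk_half[2 * i]
                for s in range(4):
                    yt[s] = y[s]
            elif stage == 1:
                kk_row = kk_half[2 * i + 1]
                for s in range(4):
                    yt[s] = y[s] + 0.5 * dt * f[0, s]
            elif stage == 2:
                kk_row = kk_half[2 * i + 1]
                for s in range(4):
                    yt[s] = y[s] + 0.5 * dt * f[1, s]
            else:
                kk_row = kk_left[2 * i + 2]
                for s in range(4):
                    yt[s] = y[s] + dt * f[2, s]
            for j in range(m):
                tv = yt[0, j] + yt[1, j] + yt[2, j] + yt[3, j]
                if tv < 0.0:
                    tv = 0.0
                g = _growth_factor_scalar(kgEx[j], kg[j], Vmax[j], psi, tv)
                kk = kk_row[j]
                v1 = yt[0, j]
                f[stage, 0, j] = g * v1 - kk * v1
                f[stage, 1, j] = kk * v1 - yt[1, j] / tau
                f[stage, 2, j] = (yt[1, j] - yt[2, j]) / tau
                f[stage, 3, j] = (yt[2, j] - yt[3, j]) / tau
        for s in range(4):
            for j in range(m):
                v = y[s, j] + (dt / 6.0) * (
                    f[0, s, j] + 2.0 * f[1, s, j] + 2.0 * f[2, s, j] + f[3, s, j]
                )
                y[s, j] = v if v > 0.0 else 0.0
        for j in range(m):
            tv_out[i + 1, j] = y[0, j] + y[1, j] + y[2, j] + y[3, j]
    return tv_out


def _rk4_tgi_grid(
    kgEx,
    kg,
    Vmax,
    tau: float,
    kkmax: float,
    kc50: float,
    n: float,
    psi: float,
    v0,
    conc_half_grid: np.ndarray,
    dt: float,
    conc_half_left: np.ndarray | None = None,
) -> np.ndarray:
    """Fixed-step RK4 for many animals at once.

    Growth parameters and v0 are per-animal arrays of shape (m,); kill
    parameters are shared scalars. ``conc_half_grid`` holds the driving
    concentration (µg/mL) on the half-step grid, shape (2*n_steps+1, m) or
    (2*n_steps+1,) broadcast to all animals; ``conc_half_left`` optionally
    holds its left limits (differing only at bolus-event nodes). Returns TV
    of shape (n_steps+1, m).
    """

    def hill(arr, m):
        cpos = np.maximum(np.asarray(arr, dtype=float), 0.0)
        if cpos.ndim == 1:
            cpos = cpos[:, None]
        with np.errstate(divide="ignore", over="ignore"):
            kk = np.where(
                cpos > 0,
                kkmax / (1.0 + (kc50 / np.where(cpos > 0, cpos, 1.0)) ** n),
                0.0,
            )
        if kk.shape[1] != m:
            kk = np.broadcast_to(kk, (kk.shape[0], m))
        return np.ascontiguousarray(kk)

    v0 = np.atleast_1d(np.asarray(v0, dtype=float))
    m = v0.shape[0]
    kgEx = np.ascontiguousarray(np.broadcast_to(np.asarray(kgEx, float), (m,)))
    kg = np.ascontiguousarray(np.broadcast_to(np.asarray(kg, float), (m,)))
    Vmax = np.ascontiguousarray(np.broadcast_to(np.asarray(Vmax, float), (m,)))
    kk = hill(conc_half_grid, m)
    kk_left = kk if conc_half_left is None else hill(conc_half_left, m)
    return _rk4_tgi_kernel(
        kgEx, kg, Vmax, float(tau), float(psi), kk, kk_left, v0, float(dt)
    )


@njit(cache=True)
def _vehicle_growth_kernel(kgEx, kg, Vmax, psi, v0, n_steps, dt):
    """RK4 for the drug-free 1-D growth ODE, per-animal parameters."""
    m = v0.shape[0]
    v = v0.copy()
    out = np.empty((n_steps + 1, m))
    for j in range(m):
        out[0, j] = v[j]
    for i in range(n_steps):
        for j in range(m):
            x = v[j]
            f1 = _growth_factor_scalar(kgEx[j], kg[j], Vmax[j], psi, x) * x
            x2 = x + 0.5 * dt * f1
            f2 = _growth_factor_scalar(kgEx[j], kg[j], Vmax[j], psi, x2) * x2
            x3 = x + 0.5 * dt * f2
            f3 = _growth_factor_scalar(kgEx[j], kg[j], Vmax[j], psi, x3) * x3
            x4 = x + dt * f3
            f4 = _growth_factor_scalar(kgEx[j], kg[j], Vmax[j], psi, x4) * x4
            nv = x + (dt / 6.0) * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
            v[j] = nv if nv > 0.0 else 0.0
            out[i + 1, j] = v[j]
    return out


def _vehicle_growth_grid(kgEx, kg, Vmax, psi, v0, n_steps, dt):
    """Drug-free growth trajectories V(t) of shape (n_steps+1, m)."""
    v0 = np.atleast_1d(np.asarray(v0, dtype=float))
    m = v0.shape[0]
    kgEx = np.ascontiguousarray(np.broadcast_to(np.asarray(kgEx, float), (m,)))
    kg = np.ascontiguousarray(np.broadcast_to(np.asarray(kg, float), (m,)))
    Vmax = np.ascontiguousarray(np.broadcast_to(np.asarray(Vmax, float), (m,)))
    return _vehicle_growth_kernel(kgEx, kg, Vmax, float(psi), v0, int(n_steps), float(dt))
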