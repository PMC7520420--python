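"""Tumor-static concentration (TSC) and its parametric-bootstrap confidence interval.

TSC is the constant plasma concentration at which the drug-induced kill rate
exactly balances the net per-volume growth rate, so tumor volume neither grows
nor shrinks. Setting kill_rate(TSC) = G(v0) in the Hill model and solving for
concentration gives the closed form

    TSC = kc50 * ( G / (kkmax - G) )^(1/n),     G = G(v0),

finite only when kkmax > G(v0) (otherwise no concentration achieves stasis).
The reported point estimates use the v0 -> 0 limit, where G = kgEx.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .pk_linear import InvalidParameterError
from .tgi_model import TGIParams, growth_rate

__all__ = [
    "StasisUnreachableError",
    "TSCResult",
    "ParamUncertainty",
    "compute_tsc",
    "bootstrap_tsc_ci",
]

# Parameters that may be resampled in the bootstrap, in a fixed order.
_BOOT_PARAMS = ("kgEx", "kg", "Vmax", "tau", "kkmax", "kc50", "n")


class StasisUnreachableError(ValueError):
    """kkmax <= G(v0): the drug cannot hold the tumor static at any concentration."""


@dataclass(frozen=True)
class TSCResult:
    """Point estimate and bootstrap CI of the tumor-static concentration (µg/mL)."""

    tsc: float
    ci80_low: float | None
    ci80_high: float | None
    n_boot: int
    seed: int | None
    level: float = 0.80
    n_unreachable: int = 0


@dataclass(frozen=True)
class ParamUncertainty:
    """Per-parameter relative standard errors (CV %) for resampling.

    Keys are TGIParams field names; parameters absent from the mapping (or
    with CV 0, e.g. those reported with a '(-)' precision) are held fixed.
    An optional correlation matrix over ``order`` induces correlated
    log-normal draws; by default draws are independent.
    """

    cv_percent: Mapping[str, float]
    correlation: np.ndarray | None = None
    order: Sequence[str] | None = None

    def __post_init__(self):
        for k, v in self.cv_percent.items():
            if k not in _BOOT_PARAMS:
                raise InvalidParameterError(
                    f"unknown parameter {k!r}; resamplable: {_BOOT_PARAMS}"
                )
            if v < 0:
                raise InvalidParameterError(f"CV% for {k!r} must be >= 0")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if self.order is None or c.shape != (len(self.order), len(self.order)):
                raise InvalidParameterError(
                    "correlation requires a matching 'order' of parameter names"
                )
            eig = np.linalg.eigvalsh((c + c.T) / 2)
            if eig.min() < -1e-10:
                raise InvalidParameterError("correlation matrix must be PSD")


def compute_tsc(p: TGIParams, v0_for_tsc: float = 0.0) -> float:
    """Closed-form tumor-static concentration (µg/mL).

    ``v0_for_tsc`` is the tumor volume at which the stasis balance is
    evaluated; 0 gives the small-tumor limit G = kgEx used for the reported
    values. Raises :class:`StasisUnreachableError` when kkmax <= G(v0).
    """
    if v0_for_tsc < 0:
        raise InvalidParameterError("v0_for_tsc must be >= 0")
    g = p.kgEx if v0_for_tsc == 0.0 else float(growth_rate(v0_for_tsc, p))
    if p.kkmax <= g:
        raise StasisUnreachableError(
            f"kkmax ({p.kkmax}) must exceed the growth rate at v0 ({g}) "
            "for a finite tumor-static concentration"
        )
    return p.kc50 * (g / (p.kkmax - g)) ** (1.0 / p.n)


def _tsc_vectorized(
    kgEx: np.ndarray,
    kg: np.ndarray,
    Vmax: np.ndarray,
    kkmax: np.ndarray,
    kc50: np.ndarray,
    n: np.ndarray,
    psi: float,
    v0: float,
) -> np.ndarray:
    """TSC for arrays of parameter draws; NaN where stasis is unreachable."""
    if v0 == 0.0:
        g = kgEx
    else:
        x = (kgEx / kg) * v0
        denom = np.exp(np.logaddexp(0.0, psi * np.log(np.maximum(x, 1e-300))) / psi)
        g = kgEx * (1.0 - v0 / Vmax) / denom
    with np.errstate(invalid="ignore", divide="ignore"):
        out = kc50 * np.power(g / (kkmax - g), 1.0 / n)
    out = np.where(kkmax > g, out, np.nan)
    return out


def bootstrap_tsc_ci(
    p: TGIParams,
    u: ParamUncertainty,
    n_boot: int = 10_000,
    seed: int | None = None,
    level: float = 0.80,
    v0_for_tsc: float = 0.0,
) -> TSCResult:
    """Parametric-bootstrap CI on TSC by log-normal resampling of the estimates.

    Each uncertain parameter is drawn log-normally with median at its point
    estimate and log-scale SD sqrt(ln(1 + CV^2)); TSC is recomputed per draw.
    Draws where stasis is unreachable are discarded (their count is reported).
    The CI is the empirical ((1-level)/2, (1+level)/2) percentile interval —
    the (10th, 90th) percentiles for the default 80% level.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise InvalidParameterError("level must be in (0, 1)")
    point = compute_tsc(p, v0_for_tsc)
    rng = np.random.default_rng(seed)

    names = [k for k in _BOOT_PARAMS if u.cv_percent.get(k, 0.0) > 0]
    sigmas = np.array(
        [np.sqrt(np.log1p((u.cv_percent[k] / 100.0) ** 2)) for k in names]
    )
    if names:
        if u.correlation is not None:
            full = {k: i for i, k in enumerate(u.order)}
            idx = [full[k] for k in names if k in full]
            sub = np.asarray(u.correlation, dtype=float)[np.ix_(idx, idx)]
            z = rng.multivariate_normal(np.zeros(len(names)), sub, size=n_boot)
        else:
            z = rng.standard_normal((n_boot, len(names)))
        draws = {
            k: getattr(p, k) * np.exp(sigmas[j] * z[:, j]) for j, k in enumerate(names)
        }
    else:
        draws = {}

    def col(k):
        if k in draws:
            return draws[k]
        return np.full(n_boot, getattr(p, k))

    tscs = _tsc_vectorized(
        col("kgEx"), col("kg"), col("Vmax"), col("kkmax"), col("kc50"), col("n"),
        p.psi, v0_for_tsc,
    )
    ok = np.isfinite(tscs)
    n_unreachable = int(n_boot - ok.sum())
    if not ok.any():
        raise StasisUnreachableError("all bootstrap draws had kkmax <= growth rate")
    q = np.percentile(tscs[ok], [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return TSCResult(
        tsc=point,
        ci80_low=float(q[0]),
        ci80_high=float(q[1]),
        n_boot=n_boot,
        seed=seed,
        level=level,
        n_unreachable=n_unreachable,
    )
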