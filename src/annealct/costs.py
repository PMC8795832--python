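"""The seven per-view cost functions and their aggregation.

Each cost compares a measured projection vector ``P_M`` with a
postulated one ``P_P`` for a single view:

* ``MAE``   -- mean absolute difference.
* ``RMSE``  -- root-mean-squared difference.
* ``RSE``   -- squared error relative to the measured view's variation
  about its mean, ``sum(d^2) / sum((mean(P_M) - P_M)^2)``.
* ``RAE``   -- absolute analogue of RSE.
* ``RMSLE`` -- RMSE of ``log(1 + P)`` differences (defined for all
  non-negative data, unlike a naive log of the raw difference).
* ``UIQI``  -- Wang-Bovik universal image quality index, the product of
  correlation, luminance and contrast comparison factors (similarity,
  bounded above by 1).
* ``SSIM``  -- structural similarity l*c*s with the standard C1/C2/C3
  stabilizers, window = the whole vector (similarity, bounded by 1).

:func:`aggregate_cost` averages the per-view statistic over all views
and wraps similarity indices as ``1 - mean(index)`` so that a single
minimizer serves every cost.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .forward_model import GeometryError, Sinogram

__all__ = [
    "CostFunctionId",
    "CostDomainError",
    "DegenerateProjectionError",
    "SIMILARITY_IDS",
    "is_similarity",
    "view_cost",
    "per_view_costs",
    "aggregate_cost",
    "aggregate_from_arrays",
]


class CostFunctionId(str, Enum):
    UIQI = "uiqi"
    RSE = "rse"
    SSIM = "ssim"
    MAE = "mae"
    RAE = "rae"
    RMSE = "rmse"
    RMSLE = "rmsle"

    @classmethod
    def parse(cls, token: str) -> "CostFunctionId":
        try:
            return cls(token.strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown cost function {token!r}; valid ids: {valid}"
            ) from None


SIMILARITY_IDS = frozenset({CostFunctionId.UIQI, CostFunctionId.SSIM})


def is_similarity(cost_id: CostFunctionId) -> bool:
    return cost_id in SIMILARITY_IDS


class CostDomainError(ValueError):
    """Input outside a cost function's domain (e.g. negative for RMSLE)."""


class DegenerateProjectionError(ValueError):
    """A cost's denominator vanishes (e.g. constant measured view)."""


def _as_columns(pm, pp) -> tuple[np.ndarray, np.ndarray]:
    pm = np.asarray(pm, dtype=float)
    pp = np.asarray(pp, dtype=float)
    if pm.shape != pp.shape:
        raise ValueError("projection arrays must have identical shapes")
    if pm.ndim == 1:
        pm, pp = pm[:, None], pp[:, None]
    if pm.shape[0] < 2:
        raise ValueError("projections need at least 2 detector bins")
    if not (np.all(np.isfinite(pm)) and np.all(np.isfinite(pp))):
        raise ValueError("projections must be finite")
    return pm, pp


def _moments(pm, pp):
    """Per-column means, sample variances (ddof=1) and covariance."""
    n = pm.shape[0]
    mm = pm.mean(axis=0)
    mp = pp.mean(axis=0)
    vm = pm.var(axis=0, ddof=1)
    vp = pp.var(axis=0, ddof=1)
    cov = ((pm - mm) * (pp - mp)).sum(axis=0) / (n - 1)
    return mm, mp, vm, vp, cov


def _uiqi_three_factor(pm, pp) -> np.ndarray:
    mm, mp, vm, vp, cov = _moments(pm, pp)
    sm, sp = np.sqrt(vm), np.sqrt(vp)
    if np.any(sm * sp == 0.0):
        raise DegenerateProjectionError(
            "UIQI is undefined for a constant projection vector"
        )
    corr = cov / (sm * sp)
    lum = 2.0 * mm * mp / (mm**2 + mp**2)
    con = 2.0 * sm * sp / (vm + vp)
    return corr * lum * con


def _uiqi_single_factor(pm, pp) -> np.ndarray:
    # algebraically identical to the three-factor product on
    # non-degenerate input, but finite whenever either vector varies
    mm, mp, vm, vp, cov = _moments(pm, pp)
    num = 4.0 * cov * mm * mp
    den = (vm + vp) * (mm**2 + mp**2)
    safe = np.where(den == 0.0, 1.0, den)
    return np.where(den == 0.0, 0.0, num / safe)


def _ssim(pm, pp) -> np.ndarray:
    mm, mp, vm, vp, cov = _moments(pm, pp)
    span = pm.max(axis=0) - pm.min(axis=0)
    dyn = np.where(span > 0.0, span, 1.0)  # dynamic range of the measured view
    c1 = (0.01 * dyn) ** 2
    c2 = (0.03 * dyn) ** 2
    c3 = c2 / 2.0
    sm, sp = np.sqrt(vm), np.sqrt(vp)
    lum = (2.0 * mm * mp + c1) / (mm**2 + mp**2 + c1)
    con = (2.0 * sm * sp + c2) / (vm + vp + c2)
    struct = (cov + c3) / (sm * sp + c3)
    return lum * con * struct


def per_view_costs(
    cost_id: CostFunctionId, pm: np.ndarray, pp: np.ndarray
) -> np.ndarray:
    """Vectorized per-view statistic; columns of ``pm``/``pp`` are views.

    Similarity ids return the raw index (higher is better); error ids
    return the error (lower is better).
    """
    cost_id = CostFunctionId(cost_id)
    pm, pp = _as_columns(pm, pp)
    n = pm.shape[0]
    d = pm - pp
    if cost_id is CostFunctionId.MAE:
        return np.abs(d).mean(axis=0)
    if cost_id is CostFunctionId.RMSE:
        return np.sqrt((d**2).mean(axis=0))
    if cost_id is CostFunctionId.RMSLE:
        if np.any(pm < 0.0) or np.any(pp < 0.0):
            raise CostDomainError("RMSLE requires non-negative projections")
        g = np.log1p(pm) - np.log1p(pp)
        return np.sqrt((g**2).mean(axis=0))
    if cost_id in (CostFunctionId.RSE, CostFunctionId.RAE):
        dev = pm.mean(axis=0) - pm
        if cost_id is CostFunctionId.RSE:
            den = (dev**2).sum(axis=0)
            num = (d**2).sum(axis=0)
        else:
            den = np.abs(dev).sum(axis=0)
            num = np.abs(d).sum(axis=0)
        if np.any(den == 0.0):
            raise DegenerateProjectionError(
                f"{cost_id.value.upper()} is undefined when a measured view "
                "is constant"
            )
        return num / den
    if cost_id is CostFunctionId.UIQI:
        return _uiqi_three_factor(pm, pp)
    if cost_id is CostFunctionId.SSIM:
        return _ssim(pm, pp)
    raise AssertionError(f"unhandled cost id {cost_id}")  # pragma: no cover


def view_cost(cost_id: CostFunctionId, pm: np.ndarray, pp: np.ndarray) -> float:
    """Single-view statistic for two equal-length projection vectors."""
    pm = np.asarray(pm, dtype=float)
    pp = np.asarray(pp, dtype=float)
    if pm.ndim != 1 or pp.ndim != 1:
        raise ValueError("view_cost expects 1-D projection vectors")
    return float(per_view_costs(cost_id, pm, pp)[0])


def uiqi_closed_form(pm: np.ndarray, pp: np.ndarray) -> float:
    """Equivalent single-factor UIQI, 4*cov*mx*my / ((vx+vy)(mx^2+my^2))."""
    pm, pp = _as_columns(pm, pp)
    return float(_uiqi_single_factor(pm, pp)[0])


def aggregate_from_arrays(
    cost_id: CostFunctionId, pm: np.ndarray, pp: np.ndarray
) -> float:
    """Aggregate objective from raw bins-x-views arrays (lower is better)."""
    cost_id = CostFunctionId(cost_id)
    if cost_id is CostFunctionId.UIQI:
        pm2, pp2 = _as_columns(pm, pp)
        values = _uiqi_single_factor(pm2, pp2)
    else:
        values = per_view_costs(cost_id, pm, pp)
    mean = float(np.mean(values))
    return 1.0 - mean if is_similarity(cost_id) else mean


def aggregate_cost(cost_id: CostFunctionId, pm: Sinogram, pp: Sinogram) -> float:
    """SA objective ``C_k``: mean view cost, minimization-oriented."""
    if (
        pm.geometry.n_bins != pp.geometry.n_bins
        or pm.geometry.n_views != pp.geometry.n_views
        or not np.allclose(pm.geometry.angles, pp.geometry.angles)
    ):
        raise GeometryError("sinograms have mismatched geometries")
    return aggregate_from_arrays(cost_id, pm.values, pp.values)
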