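"""Simulated-annealing reconstruction engine.

The estimate ``f_k`` lives on a quantized intensity lattice in [0, 1].
Each iteration proposes a uniformly random pixel and a uniformly random
lattice level; because the forward model assigns every pixel to exactly
one detector bin per view, the postulated sinogram is updated
incrementally -- one bin per view receives the intensity increment --
and no backward projection is ever needed.  The candidate is accepted
when it lowers the objective, otherwise with Metropolis probability
``h_k = exp(-dC / T_k)`` under the cosh cooling profile

    T_k = (T0 - TN) / cosh(10 k / N) + TN,

held constant over slabs of ``slab`` iterations so the intensity
distribution can equilibrate.  The best estimate seen so far is
returned together with the per-slab best-cost trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import costs as _costs
from .costs import CostFunctionId
from .forward_model import Sinogram, bin_map, radon_forward
from .phantom import quantize

__all__ = [
    "AnnealConfig",
    "AnnealState",
    "Move",
    "MoveOutcome",
    "temperature_at",
    "propose_move",
    "apply_move",
    "commit_move",
    "metropolis_accept",
    "run_sa",
]


@dataclass(frozen=True)
class AnnealConfig:
    """Generic SA parameters plus the CT-specific ones.

    ``n_iter=None`` resolves to ``3125 * side**2`` proposals, i.e.
    2e5 for 8x8 and 8e5 for 16x16 grids.  ``stop_tolerance`` is the
    relative slab-over-slab best-cost change below which an error-type
    cost stops early; 0 disables early stopping (pure iteration-count
    rule).
    """

    side: int
    cost: CostFunctionId = CostFunctionId.RMSLE
    t_initial: float = 0.1
    t_final: float = 1.5e-3
    n_iter: int | None = None
    slab: int = 1000
    intensity_levels: int = 256
    seed: int = 0
    stop_tolerance: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "cost", CostFunctionId(self.cost))
        if self.side < 2:
            raise ValueError("side must be at least 2")
        if not 0.0 < self.t_final < self.t_initial:
            raise ValueError("need 0 < t_final < t_initial")
        if self.slab < 1:
            raise ValueError("slab must be >= 1")
        if self.resolved_iters() < self.slab:
            raise ValueError("iteration budget must be >= slab")
        if self.intensity_levels < 2:
            raise ValueError("intensity_levels must be >= 2")
        if self.stop_tolerance < 0.0:
            raise ValueError("stop_tolerance must be >= 0")

    def resolved_iters(self) -> int:
        if self.n_iter is not None:
            return int(self.n_iter)
        return 3125 * self.side**2


def temperature_at(k: int, cfg: AnnealConfig) -> float:
    """Cooling profile, constant within each temperature slab."""
    n = cfg.resolved_iters()
    if not 0 <= k <= n:
        raise ValueError(f"iteration {k} outside [0, {n}]")
    k_eff = (k // cfg.slab) * cfg.slab
    return (cfg.t_initial - cfg.t_final) / math.cosh(10.0 * k_eff / n) + cfg.t_final


def metropolis_accept(delta_c: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept improving moves always, worsening ones with exp(-dC/T)."""
    if temperature <= 0.0:
        raise ValueError("temperature must be positive")
    if delta_c < 0.0:
        return True
    return bool(rng.random() < math.exp(-delta_c / temperature))


class Move(NamedTuple):
    row: int
    col: int
    level: float  # new intensity on the quantization lattice


class MoveOutcome(NamedTuple):
    pp: np.ndarray     # candidate postulated sinogram (bins x views)
    cost: float        # candidate objective
    delta_c: float


@dataclass
class AnnealState:
    """The evolving estimate with its incrementally maintained sinogram."""

    config: AnnealConfig
    measured: Sinogram
    estimate: np.ndarray
    pp: np.ndarray
    cost: float
    k: int = 0
    best_estimate: np.ndarray | None = None
    best_cost: float = math.inf
    accepted: int = 0
    trace: np.ndarray = field(default_factory=lambda: np.zeros(0))
    _bin_map: np.ndarray | None = None

    @classmethod
    def initialize(
        cls,
        measured: Sinogram,
        cfg: AnnealConfig,
        template: np.ndarray | None = None,
    ) -> "AnnealState":
        if template is None:
            from .wavelet_init import build_template

            template = build_template(
                measured, cfg.side, intensity_levels=cfg.intensity_levels
            ).image
        template = np.asarray(template, dtype=float)
        if template.shape != (cfg.side, cfg.side):
            raise ValueError("template side does not match configuration")
        _check_degenerate(cfg.cost, measured)
        est = quantize(np.clip(template, 0.0, 1.0), cfg.intensity_levels)
        pp = radon_forward(est, measured.geometry).values
        cost = _costs.aggregate_from_arrays(cfg.cost, measured.values, pp)
        return cls(
            config=cfg,
            measured=measured,
            estimate=est,
            pp=pp,
            cost=cost,
            best_estimate=est.copy(),
            best_cost=cost,
            _bin_map=bin_map(cfg.side, measured.geometry),
        )


def _check_degenerate(cost_id: CostFunctionId, measured: Sinogram) -> None:
    pm = measured.values
    if cost_id in (CostFunctionId.RSE, CostFunctionId.RAE):
        if np.any(np.ptp(pm, axis=0) == 0.0):
            raise _costs.DegenerateProjectionError(
                f"{cost_id.value.upper()} cannot anneal against a sinogram "
                "with a constant view"
            )
    if cost_id is CostFunctionId.RMSLE and np.any(pm < 0.0):
        raise _costs.CostDomainError("RMSLE requires non-negative projections")


def propose_move(state: AnnealState, rng: np.random.Generator) -> Move:
    """Uniform pixel and uniform quantized level, per the sampling rule."""
    side = state.config.side
    levels = state.config.intensity_levels
    p = int(rng.integers(0, side * side))
    level = int(rng.integers(0, levels)) / (levels - 1)
    return Move(row=p // side, col=p % side, level=level)


def apply_move(state: AnnealState, move: Move) -> MoveOutcome:
    """Candidate sinogram and cost change for a move (not committed).

    One detector bin per view receives the intensity increment; the
    candidate cost is evaluated on the updated arrays.
    """
    delta = move.level - state.estimate[move.row, move.col]
    pp_new = state.pp.copy()
    bins = state._bin_map[move.row, move.col]
    pp_new[bins, np.arange(state.measured.n_views)] += delta
    cost = _costs.aggregate_from_arrays(
        state.config.cost, state.measured.values, pp_new
    )
    return MoveOutcome(pp=pp_new, cost=cost, delta_c=cost - state.cost)


def commit_move(state: AnnealState, move: Move, outcome: MoveOutcome) -> None:
    """Adopt an evaluated move; rejected candidates simply drop out."""
    state.estimate[move.row, move.col] = move.level
    state.pp = outcome.pp
    state.cost = outcome.cost
    state.k += 1
    state.accepted += 1
    if outcome.cost < state.best_cost:
        state.best_cost = outcome.cost
        state.best_estimate = state.estimate.copy()


# ---------------------------------------------------------------------------
# incremental objective bookkeeping for the fast annealing loop


class _CostTracker:
    """Per-view accumulators of the SA objective, updated in O(M) per move.

    For error costs the running absolute/squared/log-squared error sums
    are maintained; for UIQI/SSIM the sufficient statistics of the
    postulated views (sum, sum of squares, cross sum with the measured
    view).  ``refresh`` recomputes everything from the arrays to bound
    floating-point drift; the annealing loop calls it once per slab.
    """

    def __init__(self, cost_id: CostFunctionId, pm: np.ndarray, pp: np.ndarray):
        self.id = CostFunctionId(cost_id)
        self.pm = np.asarray(pm, dtype=float)
        self.pp = np.asarray(pp, dtype=float).copy()
        self.n, self.m = self.pm.shape
        self._ar = np.arange(self.m)
        n = self.n
        cid = self.id
        if cid in (CostFunctionId.RAE,):
            self.den = np.abs(self.pm.mean(0) - self.pm).sum(0)
        if cid in (CostFunctionId.RSE,):
            self.den = ((self.pm.mean(0) - self.pm) ** 2).sum(0)
        if cid is CostFunctionId.RMSLE:
            self.log_pm = np.log1p(self.pm)
        if cid in (CostFunctionId.UIQI, CostFunctionId.SSIM):
            self.mm = self.pm.mean(0)
            self.vm = self.pm.var(0, ddof=1)
            self.sm = np.sqrt(self.vm)
            span = self.pm.max(0) - self.pm.min(0)
            dyn = np.where(span > 0.0, span, 1.0)
            self.c1 = (0.01 * dyn) ** 2
            self.c2 = (0.03 * dyn) ** 2
            self.c3 = self.c2 / 2.0
        self._stash = None
        self.refresh()

    # -- accumulator -> objective -------------------------------------
    def _objective(self, acc) -> float:
        n, cid = self.n, self.id
        if cid is CostFunctionId.MAE:
            return float(acc.mean()) / n
        if cid is CostFunctionId.RMSE:
            return float(np.sqrt(np.maximum(acc, 0.0) / n).mean())
        if cid is CostFunctionId.RMSLE:
            return float(np.sqrt(np.maximum(acc, 0.0) / n).mean())
        if cid is CostFunctionId.RAE:
            return float((acc / self.den).mean())
        if cid is CostFunctionId.RSE:
            return float((np.maximum(acc, 0.0) / self.den).mean())
        sp, sp2, spm = acc
        mp = sp / n
        vp = np.maximum((sp2 - n * mp**2) / (n - 1), 0.0)
        cov = (spm - n * self.mm * mp) / (n - 1)
        if cid is CostFunctionId.UIQI:
            num = 4.0 * cov * self.mm * mp
            den = (self.vm + vp) * (self.mm**2 + mp**2)
            q = np.where(den == 0.0, 0.0, num / np.where(den == 0.0, 1.0, den))
            return 1.0 - float(q.mean())
        sp_std = np.sqrt(vp)
        lum = (2.0 * self.mm * mp + self.c1) / (self.mm**2 + mp**2 + self.c1)
        con = (2.0 * self.sm * sp_std + self.c2) / (self.vm + vp + self.c2)
        struct = (cov + self.c3) / (self.sm * sp_std + self.c3)
        return 1.0 - float((lum * con * struct).mean())

    def refresh(self) -> float:
        """Recompute accumulators exactly from the current arrays."""
        pm, pp, cid = self.pm, self.pp, self.id
        d = pm - pp
        if cid in (CostFunctionId.MAE, CostFunctionId.RAE):
            self.acc = np.abs(d).sum(0)
        elif cid in (CostFunctionId.RMSE, CostFunctionId.RSE):
            self.acc = (d**2).sum(0)
        elif cid is CostFunctionId.RMSLE:
            self.acc = ((self.log_pm - np.log1p(pp)) ** 2).sum(0)
        else:
            self.acc = (pp.sum(0), (pp**2).sum(0), (pm * pp).sum(0))
        self.cost = self._objective(self.acc)
        return self.cost

    def evaluate(self, bins: np.ndarray, delta: float) -> float:
        """Candidate objective after adding ``delta`` at one bin per view."""
        ar = self._ar
        ppo = self.pp[bins, ar]
        ppn = ppo + delta
        cid = self.id
        if cid in (CostFunctionId.MAE, CostFunctionId.RAE):
            pmb = self.pm[bins, ar]
            acc = self.acc - np.abs(pmb - ppo) + np.abs(pmb - ppn)
        elif cid in (CostFunctionId.RMSE, CostFunctionId.RSE):
            pmb = self.pm[bins, ar]
            acc = self.acc - (pmb - ppo) ** 2 + (pmb - ppn) ** 2
        elif cid is CostFunctionId.RMSLE:
            lg = self.log_pm[bins, ar]
            acc = self.acc - (lg - np.log1p(ppo)) ** 2 + (lg - np.log1p(ppn)) ** 2
        else:
            sp, sp2, spm = self.acc
            pmb = self.pm[bins, ar]
            acc = (sp + delta, sp2 + ppn**2 - ppo**2, spm + pmb * delta)
        self._stash = (bins, ppn, acc)
        return self._objective(acc)

    def commit(self) -> None:
        bins, ppn, acc = self._stash
        self.pp[bins, self._ar] = ppn
        self.acc = acc


def run_sa(
    measured: Sinogram,
    cfg: AnnealConfig,
    template: np.ndarray | None = None,
) -> AnnealState:
    """Full annealing run; returns the final state with best-so-far fields.

    ``trace`` holds the best cost at initialization and after every
    temperature slab, for convergence analysis.
    """
    state = AnnealState.initialize(measured, cfg, template)
    n_total = cfg.resolved_iters()
    slab = cfg.slab
    side = cfg.side
    levels = cfg.intensity_levels
    scale = 1.0 / (levels - 1)
    bm_flat = state._bin_map.reshape(side * side, measured.n_views)
    est_flat = state.estimate.ravel()

    tracker = _CostTracker(cfg.cost, measured.values, state.pp)
    cost = tracker.cost
    best = cost
    best_img = state.estimate.copy()
    trace = [cost]
    accepted = 0
    rng = np.random.default_rng(cfg.seed)
    error_cost = not _costs.is_similarity(cfg.cost)

    k = 0
    while k < n_total:
        m = min(slab, n_total - k)
        temp = temperature_at(k, cfg)
        pix = rng.integers(0, side * side, m)
        lev = rng.integers(0, levels, m)
        unif = rng.random(m)
        for i in range(m):
            p = pix[i]
            new_level = lev[i] * scale
            delta = new_level - est_flat[p]
            cand = tracker.evaluate(bm_flat[p], delta)
            d_c = cand - cost
            if d_c < 0.0 or unif[i] < math.exp(-d_c / temp):
                tracker.commit()
                est_flat[p] = new_level
                cost = cand
                accepted += 1
                if cost < best:
                    best = cost
                    best_img = state.estimate.copy()
        k += m
        cost = tracker.refresh()  # bound accumulator drift once per slab
        if cost < best:
            best = cost
            best_img = state.estimate.copy()
        prev_best = trace[-1]
        trace.append(best)
        if error_cost and cfg.stop_tolerance > 0.0:
            if prev_best - best < cfg.stop_tolerance * best:
                break

    state.pp = tracker.pp
    state.cost = cost
    state.k = k
    state.accepted = accepted
    state.best_cost = best
    state.best_estimate = best_img
    state.trace = np.asarray(trace)
    return state
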