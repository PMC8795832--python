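"""Cost-function benchmark: repeated SA runs with quality bookkeeping.

Reproduces the sensitivity-analysis protocol: a fixed phantom is
forward-projected once, the wavelet template is built once, and every
cost function is annealed for a number of seeded repetitions under the
same schedule.  Reported per cost: mean and sample standard deviation
(n-1) of PSNR / EuE / WPSNR against the phantom, plus wall-clock run
time (informational only -- hardware dependent) and the per-run
best-cost traces.  A master seed fully determines every run seed.

The benchmark always runs the full iteration budget (the early-stop
tolerance is forced to zero) so that all costs experience the same
annealing schedule and traces span the whole cooling profile.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annealer import AnnealConfig, run_sa
from .costs import CostFunctionId
from .forward_model import ProjectionGeometry, Sinogram, radon_forward
from .metrics import quality_report
from .wavelet_init import build_template

__all__ = ["BenchmarkResult", "benchmark_costs", "convergence_trace"]


@dataclass
class BenchmarkResult:
    """Aggregate table, per-run records and convergence traces."""

    table: pd.DataFrame                     # one row per cost function
    runs: pd.DataFrame                      # one row per (cost, repetition)
    traces: dict[str, list[np.ndarray]]     # raw best-cost traces per cost
    measured: Sinogram
    template: np.ndarray


def benchmark_costs(
    phantom_img: np.ndarray,
    cfg: AnnealConfig,
    cost_ids: Sequence[CostFunctionId],
    repetitions: int,
    n_views: int = 18,
) -> BenchmarkResult:
    """Run ``repetitions`` seeded SA runs for every cost id."""
    if repetitions < 2:
        raise ValueError("need at least 2 repetitions for a std estimate")
    cost_ids = [CostFunctionId(c) for c in cost_ids]
    if not cost_ids:
        raise ValueError("cost id list must not be empty")
    phantom_img = np.asarray(phantom_img, dtype=float)
    side = phantom_img.shape[0]
    if side != cfg.side:
        raise ValueError("phantom side does not match configuration")

    geom = ProjectionGeometry.uniform(n_views, side=side)
    measured = radon_forward(phantom_img, geom)
    template = build_template(
        measured, side, intensity_levels=cfg.intensity_levels
    ).image

    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=(len(cost_ids), repetitions))

    records = []
    traces: dict[str, list[np.ndarray]] = {c.value: [] for c in cost_ids}
    for i, cost_id in enumerate(cost_ids):
        for r in range(repetitions):
            run_cfg = replace(
                cfg, cost=cost_id, seed=int(seeds[i, r]), stop_tolerance=0.0
            )
            tic = time.perf_counter()
            state = run_sa(measured, run_cfg, template=template)
            elapsed = time.perf_counter() - tic
            q = quality_report(phantom_img, state.best_estimate)
            traces[cost_id.value].append(state.trace)
            records.append(
                {
                    "cost": cost_id.value,
                    "repetition": r,
                    "seed": int(seeds[i, r]),
                    "psnr_db": q.psnr,
                    "eue": q.eue,
                    "wpsnr_db": q.wpsnr,
                    "final_cost": state.best_cost,
                    "accepted": state.accepted,
                    "runtime_s": elapsed,
                }
            )
    runs = pd.DataFrame.from_records(records)
    table = (
        runs.groupby("cost", sort=False)
        .agg(
            psnr_mean=("psnr_db", "mean"),
            psnr_std=("psnr_db", lambda s: s.std(ddof=1)),
            eue_mean=("eue", "mean"),
            eue_std=("eue", lambda s: s.std(ddof=1)),
            wpsnr_mean=("wpsnr_db", "mean"),
            wpsnr_std=("wpsnr_db", lambda s: s.std(ddof=1)),
            runtime_mean_s=("runtime_s", "mean"),
        )
        .reset_index()
    )
    return BenchmarkResult(
        table=table,
        runs=runs,
        traces=traces,
        measured=measured,
        template=template,
    )


def convergence_trace(trace: np.ndarray) -> np.ndarray:
    """Best-so-far cost normalized by the initial cost, per slab.

    The first value is always 1 and the series is non-increasing.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty cost trace")
    best = np.minimum.accumulate(trace)
    if best[0] == 0.0:
        return np.ones_like(best)
    return best / best[0]
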