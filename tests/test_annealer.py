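import math

import numpy as np
import pytest

from annealct.annealer import (
    AnnealConfig,
    AnnealState,
    Move,
    _CostTracker,
    apply_move,
    commit_move,
    metropolis_accept,
    propose_move,
    run_sa,
    temperature_at,
)
from annealct.costs import (
    CostFunctionId,
    DegenerateProjectionError,
    aggregate_from_arrays,
)
from annealct.forward_model import ProjectionGeometry, Sinogram, radon_forward
from annealct.metrics import psnr
from annealct.wavelet_init import build_template


class TestTemperature:
    def test_starts_at_initial_temperature(self):
        cfg = AnnealConfig(side=8, t_initial=0.1)
        assert temperature_at(0, cfg) == pytest.approx(0.1)

    def test_final_temperature_approached_within_cosh_tail(self):
        cfg = AnnealConfig(side=8, t_initial=0.1, t_final=1e-6, n_iter=200_000)
        t_end = temperature_at(200_000, cfg)
        # (T0 - TN)/cosh(10) ~ 9.08e-6
        assert t_end == pytest.approx(1e-6 + 0.0999990 / math.cosh(10.0), rel=1e-3)
        assert abs(t_end - 1e-6) < 1.1e-5

    def test_constant_within_slab_decreasing_across_slabs(self):
        cfg = AnnealConfig(side=8, n_iter=10_000, slab=1000)
        assert temperature_at(1500, cfg) == temperature_at(1999, cfg)
        slab_temps = [temperature_at(k, cfg) for k in range(0, 10_001, 1000)]
        assert np.all(np.diff(slab_temps) < 0.0)

    def test_iteration_beyond_budget_rejected(self):
        cfg = AnnealConfig(side=8, n_iter=1000)
        with pytest.raises(ValueError):
            temperature_at(1001, cfg)


class TestMetropolis:
    def test_improvements_always_accepted(self, rng):
        assert all(
            metropolis_accept(-0.5, t, rng) for t in (1e-9, 1.0, 100.0)
        )

    def test_zero_change_always_accepted(self, rng):
        assert all(metropolis_accept(0.0, 0.1, rng) for _ in range(100))

    def test_acceptance_frequency_matches_boltzmann_factor(self):
        rng = np.random.default_rng(5)
        trials = 20_000
        hits = sum(metropolis_accept(0.05, 0.05, rng) for _ in range(trials))
        assert hits / trials == pytest.approx(math.exp(-1.0), abs=0.01)

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(0.1, 0.0, rng)


@pytest.fixture()
def state8(sino8):
    cfg = AnnealConfig(side=8, cost=CostFunctionId.RMSE, seed=3)
    return AnnealState.initialize(sino8, cfg)


class TestMoves:
    def test_proposals_uniform_over_pixels_and_on_lattice(self, state8):
        rng = np.random.default_rng(0)
        hits = np.zeros(64)
        for _ in range(10_000):
            mv = propose_move(state8, rng)
            hits[mv.row * 8 + mv.col] += 1
            assert (mv.level * 255) == pytest.approx(round(mv.level * 255))
        p = 1.0 / 64
        sigma = math.sqrt(10_000 * p * (1 - p))
        assert np.all(np.abs(hits - 10_000 * p) < 5 * sigma)

    def test_same_seed_same_proposal_stream(self, state8):
        rng_a, rng_b = np.random.default_rng(9), np.random.default_rng(9)
        a = [propose_move(state8, rng_a) for _ in range(50)]
        b = [propose_move(state8, rng_b) for _ in range(50)]
        assert a == b

    def test_zero_change_move_is_neutral(self, state8):
        mv = Move(row=2, col=3, level=state8.estimate[2, 3])
        out = apply_move(state8, mv)
        assert out.delta_c == 0.0
        assert np.array_equal(out.pp, state8.pp)

    def test_incremental_pp_matches_full_recomputation(self, state8):
        rng = np.random.default_rng(1)
        for _ in range(300):
            mv = propose_move(state8, rng)
            commit_move(state8, mv, apply_move(state8, mv))
        recomputed = radon_forward(state8.estimate, state8.measured.geometry).values
        assert np.abs(state8.pp - recomputed).max() < 1e-10

    def test_moves_on_same_pixel_compose_last_wins(self, state8):
        for level in (0.5, 1.0):
            mv = Move(row=4, col=4, level=level)
            commit_move(state8, mv, apply_move(state8, mv))
        assert state8.estimate[4, 4] == 1.0
        recomputed = radon_forward(state8.estimate, state8.measured.geometry).values
        assert np.allclose(state8.pp, recomputed)


class TestCostTracker:
    @pytest.mark.parametrize("cid", list(CostFunctionId))
    def test_tracker_matches_reference_objective(self, cid, rng):
        pm = rng.random((13, 6)) + 0.2
        pp = rng.random((13, 6)) + 0.2
        tracker = _CostTracker(cid, pm, pp)
        assert tracker.cost == pytest.approx(
            aggregate_from_arrays(cid, pm, pp), abs=1e-12
        )
        # a handful of incremental updates stays consistent
        for step in range(20):
            bins = rng.integers(0, 13, 6)
            delta = float(rng.normal(0.0, 0.1))
            cand = tracker.evaluate(bins, delta)
            pp_ref = tracker.pp.copy()
            pp_ref[bins, np.arange(6)] += delta
            assert cand == pytest.approx(
                aggregate_from_arrays(cid, pm, pp_ref), abs=1e-9
            )
            if step % 2 == 0:
                tracker.commit()


class TestRunSA:
    def test_same_seed_reproduces_estimate(self, sino8):
        cfg = AnnealConfig(side=8, cost="rmse", n_iter=5000, seed=11)
        a = run_sa(sino8, cfg)
        b = run_sa(sino8, cfg)
        assert np.array_equal(a.best_estimate, b.best_estimate)
        assert a.best_cost == b.best_cost

    def test_best_cost_never_exceeds_template_cost(self, sino8):
        cfg = AnnealConfig(side=8, cost="rmse", n_iter=20_000, seed=2,
                           stop_tolerance=0.0)
        state = run_sa(sino8, cfg)
        assert state.best_cost <= state.trace[0]
        assert np.all(np.diff(state.trace) <= 1e-15)

    def test_final_pp_consistent_with_estimate(self, sino8):
        cfg = AnnealConfig(side=8, cost="rmsle", n_iter=10_000, seed=4)
        state = run_sa(sino8, cfg)
        recomputed = radon_forward(state.estimate, sino8.geometry).values
        assert np.abs(state.pp - recomputed).max() < 1e-10

    def test_full_run_improves_psnr_over_template(self, phantom8, sino8):
        template = build_template(sino8, 8).image
        cfg = AnnealConfig(side=8, cost="rmse", n_iter=200_000, seed=1,
                           stop_tolerance=0.0)
        state = run_sa(sino8, cfg, template=template)
        assert psnr(phantom8, state.best_estimate) >= psnr(phantom8, template) + 5.0

    def test_loose_tolerance_stops_after_first_slab(self, sino8):
        cfg = AnnealConfig(side=8, cost="rmse", n_iter=50_000, slab=1000,
                           seed=6, stop_tolerance=1e9)
        state = run_sa(sino8, cfg)
        assert state.k == 1000

    def test_degenerate_cost_rejected_at_start(self):
        geom = ProjectionGeometry.uniform(4, side=4)
        constant = Sinogram(np.full((geom.n_bins, 4), 2.0), geom)
        cfg = AnnealConfig(side=4, cost="rse", n_iter=1000, slab=100)
        with pytest.raises(DegenerateProjectionError):
            run_sa(constant, cfg, template=np.full((4, 4), 0.5))


def test_config_validation():
    with pytest.raises(ValueError):
        AnnealConfig(side=8, t_initial=0.1, t_final=0.2)
    with pytest.raises(ValueError):
        AnnealConfig(side=8, n_iter=10, slab=100)
    assert AnnealConfig(side=8).resolved_iters() == 200_000
    assert AnnealConfig(side=16).resolved_iters() == 800_000
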