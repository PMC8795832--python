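import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annealct.costs import (
    CostDomainError,
    CostFunctionId,
    DegenerateProjectionError,
    aggregate_cost,
    per_view_costs,
    uiqi_closed_form,
    view_cost,
)
from annealct.forward_model import GeometryError, ProjectionGeometry, Sinogram


class TestViewCost:
    @pytest.mark.parametrize(
        "cid,pm,pp,expected",
        [
            (CostFunctionId.MAE, [1, 3], [2, 5], 1.5),
            (CostFunctionId.RMSE, [0, 0], [3, 4], np.sqrt(12.5)),
            (CostFunctionId.RSE, [1, 3], [2, 5], 2.5),
            (CostFunctionId.RAE, [1, 3], [2, 5], 1.5),
        ],
    )
    def test_hand_computed_error_values(self, cid, pm, pp, expected):
        assert view_cost(cid, np.array(pm, float), np.array(pp, float)) == (
            pytest.approx(expected)
        )

    @pytest.mark.parametrize("cid", [CostFunctionId.UIQI, CostFunctionId.SSIM])
    def test_similarity_is_one_on_perfect_match(self, cid, rng):
        p = rng.random(16)
        assert view_cost(cid, p, p) == pytest.approx(1.0, abs=1e-9)

    def test_rmsle_zero_on_perfect_match(self, rng):
        p = rng.random(16)
        assert view_cost(CostFunctionId.RMSLE, p, p) == 0.0

    def test_uiqi_matches_single_factor_closed_form(self):
        rng = np.random.default_rng(321)
        pm = rng.random(32)
        pp = rng.random(32)
        assert view_cost(CostFunctionId.UIQI, pm, pp) == pytest.approx(
            uiqi_closed_form(pm, pp), abs=1e-10
        )

    @pytest.mark.parametrize("cid", [CostFunctionId.RSE, CostFunctionId.RAE])
    def test_constant_measured_view_is_degenerate(self, cid):
        with pytest.raises(DegenerateProjectionError):
            view_cost(cid, np.full(8, 2.0), np.arange(8.0))

    def test_rmsle_rejects_negative_values(self):
        with pytest.raises(CostDomainError):
            view_cost(CostFunctionId.RMSLE, np.array([-1.0, 2.0]), np.array([0.0, 1.0]))

    @pytest.mark.parametrize(
        "cid", [CostFunctionId.MAE, CostFunctionId.RMSE, CostFunctionId.RMSLE]
    )
    def test_symmetric_costs(self, cid, rng):
        pm, pp = rng.random(16), rng.random(16)
        assert view_cost(cid, pm, pp) == pytest.approx(view_cost(cid, pp, pm))

    @pytest.mark.parametrize(
        "cid",
        [CostFunctionId.RSE, CostFunctionId.RAE, CostFunctionId.SSIM],
    )
    def test_reference_vector_matters(self, cid):
        # the measured projection enters denominators / stabilizers, so
        # swapping arguments must change the value for generic input
        rng = np.random.default_rng(9)
        pm, pp = rng.random(16), 2.0 * rng.random(16)
        assert view_cost(cid, pm, pp) != pytest.approx(
            view_cost(cid, pp, pm), abs=1e-12
        )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(0.0, 100.0), min_size=2, max_size=32),
    st.integers(0, 2**31 - 1),
)
def test_rmse_dominates_mae(pm_list, seed):
    pm = np.asarray(pm_list)
    pp = pm + np.random.default_rng(seed).normal(size=pm.size)
    mae = view_cost(CostFunctionId.MAE, pm, pp)
    rmse = view_cost(CostFunctionId.RMSE, pm, pp)
    assert rmse >= mae - 1e-12


class TestAggregate:
    def test_identical_sinograms_cost_zero(self, sino8):
        for cid in (CostFunctionId.RMSE, CostFunctionId.SSIM, CostFunctionId.MAE):
            assert aggregate_cost(cid, sino8, sino8) == pytest.approx(0.0, abs=1e-12)

    def test_single_view_aggregate_reduces_to_view_cost(self, rng):
        geom = ProjectionGeometry(angles=np.array([0.3]), n_bins=9)
        pm = Sinogram(rng.random((9, 1)), geom)
        pp = Sinogram(rng.random((9, 1)), geom)
        for cid in (CostFunctionId.MAE, CostFunctionId.RMSE, CostFunctionId.RMSLE):
            assert aggregate_cost(cid, pm, pp) == pytest.approx(
                view_cost(cid, pm.values[:, 0], pp.values[:, 0])
            )

    def test_nonnegative_and_zero_only_at_equality(self, rng, sino8):
        other = Sinogram(sino8.values + rng.random(sino8.values.shape), sino8.geometry)
        for cid in CostFunctionId:
            cost = aggregate_cost(cid, sino8, other)
            assert cost > 0.0
            assert aggregate_cost(cid, sino8, sino8) == pytest.approx(0.0, abs=1e-12)

    def test_geometry_mismatch_rejected(self, sino8, rng):
        other_geom = ProjectionGeometry.uniform(9, n_bins=sino8.n_bins)
        other = Sinogram(rng.random((sino8.n_bins, 9)), other_geom)
        with pytest.raises(GeometryError):
            aggregate_cost(CostFunctionId.RMSE, sino8, other)

    def test_per_view_vectorization_matches_scalar_path(self, rng):
        pm = rng.random((13, 6)) + 0.1
        pp = rng.random((13, 6)) + 0.1
        for cid in CostFunctionId:
            vec = per_view_costs(cid, pm, pp)
            scalar = [view_cost(cid, pm[:, j], pp[:, j]) for j in range(6)]
            assert np.allclose(vec, scalar, atol=1e-12)


def test_unknown_token_lists_valid_ids():
    with pytest.raises(ValueError, match="rmsle"):
        CostFunctionId.parse("nope")
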