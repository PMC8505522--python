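"""Gravity-model diffusion: probabilities, shares, candidates, flows."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vrank_cascade import (
    joint_prob,
    logistic_prob,
    migration_candidates,
    normalize_shares,
    trade_candidates,
)
from vrank_cascade.config import DiffusionParams
from vrank_cascade.diffusion import (
    apply_flows,
    distance_penalty,
    gain_probability,
    migration_flow_matrix,
    trade_flow_matrix,
)
from vrank_cascade.errors import ConsistencyError

from .conftest import make_pair_net
from .oracles import logistic_bruteforce, shares_bruteforce


class TestLogistic:
    @pytest.mark.parametrize("z, expected", [(0.0, 0.5), (2.0, 0.8807970779778823)])
    def test_standard_values(self, z, expected):
        assert logistic_prob(z) == pytest.approx(expected, abs=1e-12)
        assert logistic_prob(z) == pytest.approx(logistic_bruteforce(z), abs=1e-12)

    def test_saturates_at_one_over_a(self):
        assert logistic_prob(1e4, a=2.0, b=1.0) == pytest.approx(0.5)
        assert logistic_prob(-1e4) == pytest.approx(0.0, abs=1e-12)

    @given(z1=st.floats(-50, 50), z2=st.floats(-50, 50))
    def test_monotone_and_bounded(self, z1, z2):
        p1, p2 = logistic_prob(z1), logistic_prob(z2)
        assert 0.0 <= p1 <= 1.0
        if z1 < z2:
            assert p1 <= p2

    def test_gain_probability_small_gains_near_zero(self):
        """A small net gain maps to a probability close to zero, the
        center gain to one half, high gains close to one."""
        params = DiffusionParams()
        assert gain_probability(0.0, params) < 0.2
        assert gain_probability(params.gain_center, params) == pytest.approx(0.5)
        assert gain_probability(2.0, params) > 0.95


class TestJointProb:
    def test_no_distance_penalty_passes_gain_through(self):
        assert joint_prob(0.7, 0.0) == pytest.approx(0.7)

    def test_zero_gain_kills_flow_regardless_of_distance(self):
        assert joint_prob(0.0, 0.9) == 0.0

    def test_nearer_node_wins_at_equal_gain(self):
        params = DiffusionParams()
        near = joint_prob(0.6, distance_penalty(0.2, params))
        far = joint_prob(0.6, distance_penalty(0.9, params))
        assert near > far


class TestNormalizeShares:
    def test_worked_example_two_dp(self):
        """Probability vector {0.2, 0.5, 0.7, 0.7} (sum 2.1) splits into
        shares {0.10, 0.24, 0.33, 0.33}: the first location gets 10%,
        the two most desirable ones 33% each."""
        probs = [0.2, 0.5, 0.7, 0.7]
        shares = normalize_shares(probs)
        assert np.round(shares, 2).tolist() == [0.10, 0.24, 0.33, 0.33]
        assert shares.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(shares, shares_bruteforce(probs))

    def test_single_destination_gets_everything(self):
        assert normalize_shares([0.42]).tolist() == [1.0]

    def test_symmetric_split(self):
        assert normalize_shares([0.3, 0.3]).tolist() == [0.5, 0.5]

    def test_all_zero_is_the_no_flow_signal(self):
        assert normalize_shares([0.0, 0.0]).sum() == 0.0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12).filter(lambda v: sum(v) > 0))
    def test_shares_sum_to_one(self, probs):
        assert normalize_shares(probs).sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_probabilities_rejected(self):
        with pytest.raises(ConsistencyError):
            normalize_shares([0.5, -0.1])


class TestCandidates:
    def test_identical_neighbors_yield_no_migration(self):
        net = make_pair_net()
        w = np.array([0.82, 0.82])
        p = np.array([2.0, 2.0])
        assert migration_candidates(net, w, p, 0) == {}

    def test_double_real_wage_gives_unit_gain(self):
        net = make_pair_net()
        w = np.array([1.0, 2.0])
        p = np.array([1.0, 1.0])
        assert migration_candidates(net, w, p, 0) == {1: pytest.approx(1.0)}

    def test_only_positive_gains_retained(self):
        net = make_pair_net()
        w = np.array([2.0, 1.0])
        p = np.array([1.0, 1.0])
        assert migration_candidates(net, w, p, 0) == {}
        assert 0 in migration_candidates(net, w, p, 1)

    def test_trade_excludes_markets_below_cost(self):
        net = make_pair_net()
        assert trade_candidates(net, np.array([0.5, 0.9]), 0, rho=1.0) == {}

    def test_trade_retains_market_at_the_margin(self):
        """A market pricing exactly at unit cost stays in the destination
        set with zero margin (the producer just covers cost)."""
        net = make_pair_net()
        cands = trade_candidates(net, np.array([0.5, 1.0]), 0, rho=1.0)
        assert cands == {1: 0.0}

    def test_trade_margin_values(self):
        net = make_pair_net()
        cands = trade_candidates(net, np.array([2.0, 1.5]), 0, rho=1.0)
        assert cands[0] == pytest.approx(1.0)  # home market, p = 2*rho
        assert cands[1] == pytest.approx(0.5)


class TestFlowMatrices:
    def test_symmetric_pair_no_net_migration(self):
        net = make_pair_net(both_food=True)
        params = DiffusionParams()
        flows = migration_flow_matrix(
            net, np.array([0.82, 0.82]), np.array([2.0, 2.0]), np.array([100.0, 100.0]), params
        )
        assert flows.sum() == 0.0

    def test_migration_respects_mu_cap(self):
        net = make_pair_net()
        params = DiffusionParams()
        L = np.array([100.0, 100.0])
        flows = migration_flow_matrix(
            net, np.array([1.0, 9.0]), np.array([1.0, 1.0]), L, params
        )
        out = flows.sum(axis=1) - flows.diagonal()
        assert np.all(out <= params.mu * L + 1e-12)
        assert out[0] > 0  # poorer node emits

    def test_trade_conserves_goods(self):
        net = make_pair_net()
        params = DiffusionParams()
        x = np.array([90.0, 10.0])
        flows = trade_flow_matrix(net, np.array([0.5, 4.0]), x, params, rho=1.0, layer="food")
        # everything mobile is accounted for: shipped away or retained home
        assert np.allclose(flows.sum(axis=1), params.mu * x)
        marketed = (1 - params.mu) * x + flows.sum(axis=0)
        assert marketed.sum() == pytest.approx(x.sum())

    def test_no_admissible_market_keeps_goods_home(self):
        net = make_pair_net()
        params = DiffusionParams()
        x = np.array([90.0, 10.0])
        flows = trade_flow_matrix(net, np.array([0.5, 0.6]), x, params, rho=1.0, layer="food")
        assert np.allclose(flows.diagonal(), params.mu * x)
        assert flows[0, 1] == flows[1, 0] == 0.0

    def test_sampled_mode_conserves_and_differs(self):
        net = make_pair_net()
        params = DiffusionParams()
        L = np.array([100.0, 100.0])
        rng = np.random.default_rng(5)
        flows = migration_flow_matrix(
            net, np.array([1.0, 9.0]), np.array([1.0, 1.0]), L, params, rng=rng
        )
        out = flows.sum(axis=1) - flows.diagonal()
        assert np.all(out <= params.mu * L + 1e-9)


class TestApplyFlows:
    def test_zero_flows_leave_stocks_unchanged(self):
        stocks = np.array([10.0, 20.0])
        assert np.array_equal(apply_flows(stocks, np.zeros((2, 2))), stocks)

    def test_transfer_conserves_total(self):
        stocks = np.array([100.0, 50.0])
        flows = np.array([[0.0, 10.0], [0.0, 0.0]])
        moved = apply_flows(stocks, flows)
        assert moved.tolist() == [90.0, 60.0]
        assert moved.sum() == stocks.sum()

    def test_opposing_equal_flows_cancel(self):
        stocks = np.array([100.0, 100.0])
        flows = np.array([[0.0, 7.0], [7.0, 0.0]])
        assert np.allclose(apply_flows(stocks, flows), stocks)

    def test_overdraw_is_a_bug_trap(self):
        with pytest.raises(ConsistencyError):
            apply_flows(np.array([5.0, 5.0]), np.array([[0.0, 6.0], [0.0, 0.0]]))
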