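"""Regulatory drive, integration and Monte-Carlo steady-state sampling."""

import numpy as np
import pandas as pd
import pytest

from netdasc.dynamics import (
    ActivitySimulator,
    hill,
    integrate,
    monte_carlo_activities,
    read_activities,
    regulatory_drive,
    write_activities,
)
from netdasc.network import ACTIVATION, INHIBITION

from .conftest import make_params, net_from_edges, random_dag, random_signed_network

# ---------------------------------------------------------------- oracles


def hill_ref(x: float, n: float = 3.0, k: float = 0.5) -> float:
    """Plain-python Hill reference, independent of the vectorized path."""
    return x**n * (1 + k**n) / (x**n + k**n)


def closed_form_steady(net, caps: dict, n: float = 3.0, k: float = 0.5) -> dict:
    """Topologically ordered fixed-point propagation x_i* = e_i * F_i(x*).

    Valid on acyclic networks only; written with plain loops as an
    independent oracle for the integrator.
    """
    import networkx as nx

    incoming: dict = {node: [] for node in net.nodes}
    for l in net.links:
        incoming[l.target].append(l)
    order = list(nx.topological_sort(nx.DiGraph([(l.source, l.target) for l in net.links])))
    order += [node for node in net.nodes if node not in order]
    x: dict = {}
    for node in order:
        acts = [l for l in incoming[node] if l.sign == ACTIVATION]
        inhs = [l for l in incoming[node] if l.sign == INHIBITION]
        a = sum(l.weight * hill_ref(x[l.source], n, k) for l in acts) / sum(
            l.weight for l in acts
        ) if acts else 1.0
        p = 1.0
        for l in inhs:
            p *= 1.0 - hill_ref(x[l.source], n, k)
        x[node] = caps[node] * a * p
    return x


# ---------------------------------------------------------------- hill & drive


def test_hill_normalization_endpoints():
    assert hill(0.0) == 0.0
    assert hill(1.0) == 1.0
    assert hill(0.5) == pytest.approx(0.5625)  # 0.5^3 (1+0.5^3)/(2*0.5^3)
    x = np.linspace(0, 1, 50)
    assert (np.diff(hill(x)) > 0).all()


class TestRegulatoryDrive:
    def test_single_activator_saturated(self):
        net = net_from_edges("A->B")
        params = make_params(net)
        assert regulatory_drive("B", [1.0, 0.0], params) == pytest.approx(1.0)

    def test_single_inhibitor_silent(self):
        net = net_from_edges("A-|B")
        params = make_params(net)
        assert regulatory_drive("B", [0.0, 0.3], params) == pytest.approx(1.0)

    def test_half_activation(self):
        net = net_from_edges("A->B")
        params = make_params(net)
        state = [0.5, 0.0]
        assert regulatory_drive("B", state, params) == pytest.approx(0.5625)

    def test_input_free_node_drive_is_one(self):
        net = net_from_edges("A->B")
        params = make_params(net)
        assert regulatory_drive("A", [0.2, 0.9], params) == 1.0

    def test_out_of_range_state_rejected(self):
        net = net_from_edges("A->B")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            regulatory_drive("B", [1.2, 0.0], make_params(net))

    def test_drive_bounded_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            net = random_signed_network(rng)
            params = make_params(net, capacities=float(rng.uniform(0, 1)))
            state = rng.uniform(0, 1, net.n_nodes)
            for node in net.nodes:
                f = regulatory_drive(node, state, params)
                assert 0.0 <= f <= 1.0

    def test_drive_monotone_in_regulators(self):
        """Raising an activator never lowers F; raising an inhibitor never raises it."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 300:
            net = random_signed_network(rng, n=6, p=0.35)
            params = make_params(net)
            idx = net.node_index()
            state = rng.uniform(0, 1, net.n_nodes)
            for l in net.links:
                lo = state.copy()
                hi = state.copy()
                lo[idx[l.source]] = min(lo[idx[l.source]], rng.uniform(0, 1))
                hi[idx[l.source]] = max(state[idx[l.source]], rng.uniform(0, 1))
                f_lo = regulatory_drive(l.target, lo, params)
                f_hi = regulatory_drive(l.target, hi, params)
                if l.sign == ACTIVATION:
                    assert f_hi >= f_lo - 1e-12
                else:
                    assert f_hi <= f_lo + 1e-12
                checked += 1


# ---------------------------------------------------------------- integration


class TestIntegrate:
    def test_input_free_relaxes_to_capacity(self):
        net = net_from_edges("A->B")
        params = make_params(net, capacities={"A": 0.7, "B": 0.0})
        for x0 in ([0.0, 0.0], [1.0, 1.0], [0.42, 0.9]):
            res = integrate(params, x0, tol=1e-9, t_max=300)
            assert res.converged
            assert res.state[0] == pytest.approx(0.7, abs=1e-8)

    def test_activation_chain_fixed_point(self):
        net = net_from_edges("A->B")
        params = make_params(net, capacities={"A": 1.0, "B": 0.8})
        res = integrate(params, [0.1, 0.1], tol=1e-9, t_max=300)
        assert res.state == pytest.approx([1.0, 0.8], abs=1e-8)

    def test_full_inhibition_shuts_node_off(self):
        net = net_from_edges("A-|B")
        params = make_params(net, capacities={"A": 1.0, "B": 0.9})
        res = integrate(params, [0.5, 0.5], tol=1e-9, t_max=300)
        assert res.state[0] == pytest.approx(1.0, abs=1e-8)
        assert res.state[1] == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("bad", [{"dt": 0}, {"t_max": -1}, {"tol": 0}])
    def test_bad_arguments_rejected(self, bad):
        net = net_from_edges("A->B")
        with pytest.raises(ValueError):
            integrate(make_params(net), [0.5, 0.5], **bad)

    def test_zero_capacity_kills_all_activity(self):
        rng = np.random.default_rng(5)
        net = random_signed_network(rng)
        params = make_params(net, capacities=0.0)
        res = integrate(params, rng.uniform(0, 1, net.n_nodes), tol=1e-9, t_max=300)
        assert np.all(res.state < 1e-8)

    def test_closed_form_agreement_on_acyclic_networks(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            net = random_dag(rng, n=rng.integers(4, 10))
            caps = {node: float(rng.uniform(0, 1)) for node in net.nodes}
            params = make_params(net, capacities=caps)
            expected = closed_form_steady(net, caps)
            res = integrate(params, rng.uniform(0, 1, net.n_nodes), tol=1e-8, t_max=500)
            assert res.converged
            got = dict(zip(net.nodes, res.state))
            for node in net.nodes:
                assert got[node] == pytest.approx(expected[node], abs=1e-6)

    def test_boundedness_on_random_networks(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            net = random_signed_network(rng)
            params = make_params(net, capacities=float(rng.uniform(0, 1)))
            res = integrate(params, rng.uniform(0, 1, net.n_nodes))
            assert np.all((res.state >= 0) & (res.state <= 1))


# ---------------------------------------------------------------- Monte Carlo


class TestMonteCarlo:
    def test_same_seed_bit_identical(self, toggle_net):
        params = make_params(toggle_net)
        d1 = monte_carlo_activities(params, n_init=50, seed=4)
        d2 = monte_carlo_activities(params, n_init=50, seed=4)
        assert np.array_equal(d1.activities, d2.activities)
        assert np.array_equal(d1.converged, d2.converged)

    def test_batch_size_does_not_change_results(self, toggle_net):
        params = make_params(toggle_net)
        d1 = monte_carlo_activities(params, n_init=64, seed=4, batch_size=64)
        d2 = monte_carlo_activities(params, n_init=64, seed=4, batch_size=7)
        assert np.array_equal(d1.activities, d2.activities)

    def test_monostable_network_collapses_to_point(self):
        net = net_from_edges("A->B", "B->C")
        params = make_params(net, capacities={"A": 0.9, "B": 0.7, "C": 0.6})
        d = monte_carlo_activities(params, n_init=100, seed=0, tol=1e-9, t_max=300)
        assert d.convergence_rate == 1.0
        assert (d.activities.std(axis=0) < 1e-6).all()

    def test_toggle_switch_bimodal_and_balanced(self, toggle_net):
        params = make_params(toggle_net)
        d = monte_carlo_activities(params, n_init=2000, seed=7)
        a = d.node_activities("A")
        frac_high = float(np.mean(a > 0.5))
        # symmetric circuit: equal basins; 0.5 +/- 3*SE at n=2000
        assert frac_high == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(2000))
        assert np.median(a[a > 0.5]) > 0.99
        assert np.median(a[a < 0.5]) < 0.01

    def test_activities_stay_in_unit_interval(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            net = random_signed_network(rng)
            params = make_params(net, capacities=float(rng.uniform(0.2, 1.0)))
            d = monte_carlo_activities(params, n_init=40, seed=3)
            assert ((d.activities >= 0) & (d.activities <= 1)).all()

    def test_clamp_never_triggers_at_default_step(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            net = random_signed_network(rng)
            params = make_params(net, capacities=float(rng.uniform(0.2, 1.0)))
            d = monte_carlo_activities(params, n_init=40, seed=8)
            assert d.clamp_events == 0

    def test_standard_error_scales_with_sqrt_n(self, toggle_net):
        """SE of the mean activity on the bistable switch shrinks as 1/sqrt(n)."""
        params = make_params(toggle_net)
        sizes = [500, 2000, 8000]
        reps = 8
        se = []
        for n in sizes:
            means = [
                monte_carlo_activities(params, n_init=n, seed=100 * r + n).activities[:, 0].mean()
                for r in range(reps)
            ]
            se.append(np.std(means, ddof=1))
        slope = np.polyfit(np.log(sizes), np.log(se), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.22)

    def test_low_convergence_warns_not_errors(self, toggle_net):
        params = make_params(toggle_net)
        with pytest.warns(RuntimeWarning, match="converged"):
            monte_carlo_activities(params, n_init=20, seed=1, t_max=0.2)

    def test_n_init_validated(self, toggle_net):
        with pytest.raises(ValueError, match="n_init"):
            monte_carlo_activities(make_params(toggle_net), n_init=0)


# ---------------------------------------------------------------- simulator & IO


class TestActivitySimulator:
    def test_transform_returns_mean_activity_matrix(self):
        net = net_from_edges("A->B")
        X = pd.DataFrame({"A": [1.0, 0.2], "B": [0.8, 0.8]}, index=["s1", "s2"])
        sim = ActivitySimulator(network=net, n_init=20, random_state=0, tol=1e-8).fit(X)
        out = sim.transform(X)
        assert out.shape == (2, 2)
        assert out.loc["s1", "A"] == pytest.approx(1.0, abs=1e-6)
        assert out.loc["s1", "B"] == pytest.approx(0.8, abs=1e-5)
        assert out.loc["s2", "B"] == pytest.approx(0.8 * hill_ref(0.2), abs=1e-4)

    def test_sklearn_param_round_trip(self):
        sim = ActivitySimulator(n_init=5)
        params = sim.get_params()
        assert params["n_init"] == 5
        sim.set_params(n_init=9)
        assert sim.n_init == 9

    def test_unfitted_simulate_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            ActivitySimulator().simulate(pd.DataFrame({"A": [0.5]}))


def test_activities_tsv_round_trip(tmp_path, toggle_net):
    params = make_params(toggle_net)
    dists = [
        monte_carlo_activities(params, n_init=10, seed=s, sample=f"s{s}") for s in (1, 2)
    ]
    p = tmp_path / "act.tsv"
    write_activities(dists, p)
    back = read_activities(p)
    assert [d.sample for d in back] == ["s1", "s2"]
    for orig, rec in zip(dists, back):
        assert rec.nodes == orig.nodes
        np.testing.assert_allclose(rec.activities, orig.activities, atol=1e-12)
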