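"""Sensitivity analysis: the doubling transform, virtual-evidence
interventions against enumeration, and the influence/CPT scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import PUBLISHED_ARCS, chain_network
from oracles import brute_marginal, random_network
from surveybbn.bbn import BayesianNetwork, DAGStructure, fit_cpts
from surveybbn.sensitivity import (
    InterventionSpec,
    baseline_marginals,
    cpt_sensitivity,
    double_state,
    influence_scan,
    intervene,
    net_effect,
)


def _published_topology_network(seed=0):
    """Random CPTs on the published arc set (S1, S7 isolated)."""
    nodes = tuple(f"S{i}" for i in range(1, 9))
    structure = DAGStructure.from_arcs(nodes, PUBLISHED_ARCS)
    rng = np.random.default_rng(seed)
    states = {n: ["low", "high"] for n in nodes}
    cpts = {}
    for n in nodes:
        pa = structure.parents[n]
        shape = tuple(2 for _ in pa) + (2,)
        raw = rng.dirichlet([2.0, 2.0], size=int(np.prod(shape[:-1]) or 1))
        cpts[n] = raw.reshape(shape)
    return BayesianNetwork(structure=structure, states=states, cpts=cpts)


class TestDoubleState:
    def test_published_three_state_example(self):
        # doubling the top state of (0.18, 0.67, 0.15) gives 0.30 and
        # rescales the rest by 0.70/0.85
        q = double_state(np.array([0.18, 0.67, 0.15]), state=2)
        assert q == pytest.approx([0.18 * 70 / 85, 0.67 * 70 / 85, 0.30],
                                  abs=1e-12)

    def test_cap_applies_when_doubling_overshoots(self):
        eps = 1e-6
        q = double_state(np.array([0.36, 0.64]), state=1, eps=eps)
        assert q == pytest.approx([eps, 1 - eps], abs=1e-15)

    def test_result_is_distribution_and_ratios_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.full(4, 0.8))
            s = int(rng.integers(4))
            q = double_state(p, s)
            assert q.sum() == pytest.approx(1.0, abs=1e-12)
            assert (q >= 0).all()
            others = [i for i in range(4) if i != s and p[i] > 1e-12]
            ratios = {q[i] / p[i] for i in others}
            assert max(ratios) - min(ratios) < 1e-9  # common scale factor

    @given(st.floats(0.001, 0.45))
    @settings(deadline=None)
    def test_doubles_exactly_below_the_cap(self, p0):
        q = double_state(np.array([p0, 1 - p0]), state=0)
        assert q[0] == pytest.approx(2 * p0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            double_state(np.array([0.5, 0.6]), 0)   # not normalized
        with pytest.raises(ValueError):
            double_state(np.array([0.0, 1.0]), 1)   # already certain


class TestIntervene:
    def test_source_posterior_equals_doubled_marginal(self):
        net = chain_network(0.2)
        spec = InterventionSpec(source="Y", state=1)
        post = intervene(net, spec)
        base = baseline_marginals(net)["Y"]
        assert np.allclose(post["Y"], double_state(base, 1), atol=1e-9)

    def test_disconnected_node_unaffected(self):
        structure = DAGStructure(nodes=("A", "B"), parents={"A": (), "B": ()})
        net = BayesianNetwork(
            structure=structure,
            states={"A": ["low", "high"], "B": ["low", "high"]},
            cpts={"A": np.array([0.3, 0.7]), "B": np.array([0.6, 0.4])})
        post = intervene(net, InterventionSpec(source="A"))
        assert np.allclose(post["B"], [0.6, 0.4], atol=1e-12)

    def test_matches_enumeration_with_replaced_prior_on_roots(self):
        # for a root source, virtual evidence q/p is exactly a prior swap:
        # cross-check every posterior against enumeration of the edited net
        for seed in range(10):
            net = random_network(np.random.default_rng(seed), 5)
            root = next(n for n in net.nodes if not net.structure.parents[n])
            base = baseline_marginals(net)[root]
            state = net.card(root) - 1
            q = double_state(base, state)
            post = intervene(net, InterventionSpec(source=root, state=state))
            edited_cpts = dict(net.cpts) | {root: q}
            edited = BayesianNetwork(structure=net.structure,
                                     states=net.states, cpts=edited_cpts)
            for n in net.nodes:
                want = brute_marginal(edited, n)
                assert np.allclose(post[n], want, atol=1e-9), (seed, n)

    def test_do_mode_agrees_with_evidence_mode_on_roots(self):
        net = random_network(np.random.default_rng(42), 5)
        root = next(n for n in net.nodes if not net.structure.parents[n])
        spec = InterventionSpec(source=root)
        ev = intervene(net, spec, mode="evidence")
        do = intervene(net, spec, mode="do")
        for n in net.nodes:
            assert np.allclose(ev[n], do[n], atol=1e-9)

    def test_evidence_mode_propagates_against_arcs(self):
        # boosting a child updates its parent's posterior (unlike "do")
        net = chain_network(0.1)
        base = baseline_marginals(net)
        ev = intervene(net, InterventionSpec(source="Z", state=1))
        do = intervene(net, InterventionSpec(source="Z", state=1), mode="do")
        assert not np.allclose(ev["X"], base["X"], atol=1e-6)
        assert np.allclose(do["X"], base["X"], atol=1e-12)

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            intervene(chain_network(), InterventionSpec(source="Q"))


class TestNetEffect:
    def test_sixty_percent_increase(self):
        base = {"T": np.array([0.75, 0.25])}
        after = {"T": np.array([0.60, 0.40])}
        assert net_effect(base, after, "T") == pytest.approx(60.0)

    def test_no_change_is_zero(self):
        m = {"T": np.array([0.3, 0.7])}
        assert net_effect(m, {"T": m["T"].copy()}, "T") == 0.0

    def test_zero_baseline_rejected(self):
        base = {"T": np.array([1.0, 0.0])}
        with pytest.raises(ValueError):
            net_effect(base, base, "T")


class TestInfluenceScan:
    def test_disconnected_network_all_zero(self):
        structure = DAGStructure(nodes=("A", "B", "C"),
                                 parents={n: () for n in "ABC"})
        rng = np.random.default_rng(1)
        cpts = {n: rng.dirichlet([2, 2]) for n in "ABC"}
        net = BayesianNetwork(structure=structure,
                              states={n: ["low", "high"] for n in "ABC"},
                              cpts=cpts)
        table = influence_scan(net)
        off = table.effects.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.array_equal(off, np.zeros(6))

    def test_published_topology_zero_pattern(self):
        net = _published_topology_network(seed=3)
        table = influence_scan(net)
        eff = table.effects
        # isolated sections influence nothing and nothing influences them
        for isolated in ("S1", "S7"):
            row = eff.loc[isolated].drop(isolated)
            col = eff[isolated].drop(isolated)
            assert (row == 0).all() and (col == 0).all()
        # the hub's row is nonzero at every connected section
        for tgt in ("S2", "S3", "S4", "S6", "S8"):
            assert eff.loc["S5", tgt] != 0

    def test_ranking_sums_absolute_effects(self):
        net = _published_topology_network(seed=4)
        table = influence_scan(net)
        manual = table.effects.abs().sum(axis=1, skipna=True)
        assert np.allclose(table.ranking.sort_index(), manual.sort_index(),
                           atol=1e-12)
        assert (table.ranking.values[:-1] >= table.ranking.values[1:]).all()

    def test_deterministic(self):
        net = _published_topology_network(seed=5)
        a = influence_scan(net).effects
        b = influence_scan(net).effects
        assert a.equals(b)

    def test_diagonal_is_nan(self):
        net = _published_topology_network(seed=6)
        eff = influence_scan(net).effects
        assert np.isnan(np.diag(eff.to_numpy())).all()


class TestCptSensitivity:
    def test_d_separated_node_has_no_influence(self):
        net = _published_topology_network(seed=7)
        table = cpt_sensitivity(net, focus="S5").set_index("node")
        assert table.loc["S1", "max_abs_change"] == 0.0
        assert table.loc["S1", "category"] == "none"

    def test_focus_own_cpt_is_influential(self):
        net = chain_network(0.2)
        table = cpt_sensitivity(net, focus="Z").set_index("node")
        assert table.loc["Z", "max_abs_change"] > 0
        assert table.loc["Z", "category"] in ("mild", "high")
        # a stronger perturbation pushes every chain node over the threshold
        strong = cpt_sensitivity(net, focus="Z", delta=0.3).set_index("node")
        assert (strong["category"] == "high").all()

    def test_max_shift_matches_direct_perturbation(self):
        net = chain_network(0.2)
        table = cpt_sensitivity(net, focus="Z", delta=0.10).set_index("node")
        base = baseline_marginals(net)["Z"]
        best = 0.0
        for i in range(2):          # parent state of Y's CPT
            for j in range(2):      # child state
                for sign in (+1, -1):
                    cpt = net.cpts["Y"].copy()
                    cpt[i, j] *= 1 + sign * 0.10
                    cpt[i] /= cpt[i].sum()
                    edited = BayesianNetwork(
                        structure=net.structure, states=net.states,
                        cpts=dict(net.cpts) | {"Y": cpt})
                    shift = np.abs(brute_marginal(edited, "Z") - base).max()
                    best = max(best, shift)
        assert table.loc["Y", "max_abs_change"] == pytest.approx(best, abs=1e-12)

    def test_unknown_focus_rejected(self):
        with pytest.raises(ValueError):
            cpt_sensitivity(chain_network(), focus="Q")
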