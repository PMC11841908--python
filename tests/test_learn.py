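"""Structure learning: score-based searches against the exhaustive-DAG
oracle, the G-squared CI test, and PC skeleton/orientation behaviour."""

import numpy as np
import pandas as pd
import pytest

from conftest import chain_network, make_discrete
from oracles import all_dags
from surveybbn.bbn import DAGStructure, check_acyclic, sample
from surveybbn.discretize import DiscreteDataset
from surveybbn.learn import (
    CPDAG,
    LearnConfig,
    arcs_to_text,
    bayesian_search,
    ci_test_g2,
    extend_to_dag,
    greedy_thick_thinning,
    learn_grid,
    learn_structure,
    pc_algorithm,
    _Scorer,
)
from surveybbn.preprocess import impute_mean
from surveybbn.synth import GeneratorConfig, generate_survey


def _independent_data(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    return make_discrete(
        pd.DataFrame({c: rng.integers(0, 2, n) for c in "ABC"}),
        {c: 2 for c in "ABC"})


def _copy_data(n=2000, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    flip = rng.random(n) < 0.05
    return make_discrete(pd.DataFrame({"A": x, "B": np.where(flip, 1 - x, x)}),
                         {"A": 2, "B": 2})


def _exhaustive_best(data, ess=1.0):
    """Highest-BDeu structure over all DAGs on the data's (<=3) columns."""
    scorer = _Scorer(data, ess)
    best, best_score = None, -np.inf
    for dag in all_dags(sorted(data.columns)):
        parents = {n: dag.parents[n] for n in dag.nodes}
        s = scorer.total(parents)
        if s > best_score:
            best, best_score = parents, s
    return best, best_score


class TestBayesianSearch:
    def test_independent_columns_give_empty_graph(self):
        s = bayesian_search(_independent_data(), LearnConfig(algorithm="BS"))
        assert s.arcs == []

    def test_noisy_copy_gives_single_arc(self):
        s = bayesian_search(_copy_data(), LearnConfig(algorithm="BS"))
        assert len(s.arcs) == 1
        assert set(s.arcs[0]) == {"A", "B"}

    def test_matches_exhaustive_optimum_on_three_nodes(self):
        codes = sample(chain_network(0.15), 3000, seed=7)
        data = make_discrete(codes, {c: 2 for c in codes.columns})
        best_parents, best_score = _exhaustive_best(data)
        s = bayesian_search(data, LearnConfig(algorithm="BS", seed=0))
        got = _Scorer(data).total({n: s.parents[n] for n in s.nodes})
        assert got == pytest.approx(best_score, abs=1e-9)

    def test_deterministic_given_seed(self):
        data = _copy_data(500, seed=9)
        cfg = LearnConfig(algorithm="BS", seed=4)
        assert (bayesian_search(data, cfg).arcs
                == bayesian_search(data, cfg).arcs)

    def test_single_column_rejected(self):
        data = make_discrete(pd.DataFrame({"A": [0, 1, 0, 1]}), {"A": 2})
        with pytest.raises(ValueError):
            bayesian_search(data, LearnConfig(algorithm="BS"))


class TestGreedyThickThinning:
    def test_independent_columns_give_empty_graph(self):
        s = greedy_thick_thinning(_independent_data(seed=2), LearnConfig())
        assert s.arcs == []

    def test_chain_recovers_skeleton(self):
        codes = sample(chain_network(0.1), 5000, seed=11)
        data = make_discrete(codes, {c: 2 for c in codes.columns})
        s = greedy_thick_thinning(data, LearnConfig())
        skeleton = {frozenset(a) for a in s.arcs}
        assert skeleton == {frozenset(("X", "Y")), frozenset(("Y", "Z"))}

    def test_matches_exhaustive_optimum_on_three_nodes(self):
        codes = sample(chain_network(0.15), 3000, seed=7)
        data = make_discrete(codes, {c: 2 for c in codes.columns})
        _, best_score = _exhaustive_best(data)
        s = greedy_thick_thinning(data, LearnConfig())
        got = _Scorer(data).total({n: s.parents[n] for n in s.nodes})
        assert got == pytest.approx(best_score, abs=1e-9)

    def test_never_below_empty_graph_score(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({c: rng.integers(0, 3, 300) for c in "ABCD"})
            data = make_discrete(df, {c: 3 for c in "ABCD"})
            s = greedy_thick_thinning(data, LearnConfig())
            scorer = _Scorer(data)
            assert (scorer.total({n: s.parents[n] for n in s.nodes})
                    >= scorer.total({n: () for n in s.nodes}) - 1e-9)


class TestCiTestG2:
    def test_independent_uniform_p_value(self):
        data = _independent_data(5000, seed=3)
        assert ci_test_g2(data, "A", "B") > 0.001

    def test_strong_dependence_rejected(self):
        data = _copy_data(2000)
        assert ci_test_g2(data, "A", "B") < 1e-10

    def test_chain_conditional_independence(self):
        codes = sample(chain_network(0.1), 10_000, seed=5)
        data = make_discrete(codes, {c: 2 for c in codes.columns})
        assert ci_test_g2(data, "X", "Z") < 1e-6          # marginally coupled
        assert ci_test_g2(data, "X", "Z", ("Y",)) > 0.001  # screened off by Y

    def test_p_value_in_unit_interval(self):
        data = _independent_data(200, seed=8)
        for cond in [(), ("C",)]:
            p = ci_test_g2(data, "A", "B", cond)
            assert 0.0 <= p <= 1.0


class TestPcAlgorithm:
    def test_independent_columns_no_edges(self):
        cp = pc_algorithm(_independent_data(seed=13), LearnConfig(algorithm="PC"))
        assert not cp.directed and not cp.undirected

    def test_collider_orientation(self):
        # A -> C <- B: the unshielded collider must be directed into C
        rng = np.random.default_rng(17)
        a = rng.integers(0, 2, 20_000)
        b = rng.integers(0, 2, 20_000)
        noise = rng.random(20_000) < 0.05
        c = np.where(noise, rng.integers(0, 2, 20_000), (a | b))
        data = make_discrete(pd.DataFrame({"A": a, "B": b, "C": c}),
                             {x: 2 for x in "ABC"})
        cp = pc_algorithm(data, LearnConfig(algorithm="PC"))
        assert ("A", "C") in cp.directed and ("B", "C") in cp.directed

    def test_chain_leaves_compelled_class_undirected(self):
        # X - Y - Z is a Markov-equivalence class with no compelled arcs
        codes = sample(chain_network(0.1), 20_000, seed=19)
        data = make_discrete(codes, {c: 2 for c in codes.columns})
        cp = pc_algorithm(data, LearnConfig(algorithm="PC"))
        assert cp.undirected == {frozenset(("X", "Y")), frozenset(("Y", "Z"))}
        assert not cp.directed


class TestExtendToDag:
    def test_fully_directed_passthrough(self):
        cp = CPDAG(nodes=("A", "B"), directed={("A", "B")}, undirected=set())
        s = extend_to_dag(cp)
        assert s.arcs == [("A", "B")]

    def test_undirected_edge_oriented_lexicographically(self):
        cp = CPDAG(nodes=("A", "B"), directed=set(),
                   undirected={frozenset(("A", "B"))})
        assert extend_to_dag(cp).arcs == [("A", "B")]

    def test_avoids_creating_new_v_structure(self):
        # B -> C directed, A - C undirected and A,B non-adjacent:
        # orienting A -> C would create a new collider at C, so use C -> A
        cp = CPDAG(nodes=("A", "B", "C"), directed={("B", "C")},
                   undirected={frozenset(("A", "C"))})
        s = extend_to_dag(cp)
        assert ("C", "A") in s.arcs

    def test_extension_is_acyclic_and_preserves_skeleton(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            nodes = tuple(f"N{i}" for i in range(5))
            undirected = {frozenset((nodes[i], nodes[j]))
                          for i in range(5) for j in range(i + 1, 5)
                          if rng.random() < 0.4}
            cp = CPDAG(nodes=nodes, directed=set(), undirected=set(undirected))
            s = extend_to_dag(cp)
            assert check_acyclic(s)
            assert {frozenset(a) for a in s.arcs} == undirected

    def test_directed_cycle_rejected(self):
        cp = CPDAG(nodes=("A", "B", "C"),
                   directed={("A", "B"), ("B", "C"), ("C", "A")},
                   undirected=set())
        with pytest.raises(ValueError):
            extend_to_dag(cp)


class TestLearnStructureDispatch:
    @pytest.mark.parametrize("algorithm", ["BS", "GTT", "PC"])
    def test_all_algorithms_return_acyclic_dags(self, algorithm):
        codes = sample(chain_network(0.1), 2000, seed=29)
        data = make_discrete(codes, {c: 2 for c in codes.columns})
        s = learn_structure(data, LearnConfig(algorithm=algorithm))
        assert isinstance(s, DAGStructure)
        assert check_acyclic(s)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            LearnConfig(algorithm="TABU")

    def test_arcs_to_text_format(self):
        s = DAGStructure.from_arcs(("A", "B", "C"), [("A", "B"), ("B", "C")])
        assert arcs_to_text(s) == "A->B\nB->C\n"


@pytest.fixture(scope="module")
def grid():
    clean = impute_mean(generate_survey(GeneratorConfig(seed=31)))
    return learn_grid(clean)


class TestLearnGrid:
    def test_nine_models_with_expected_cells(self, grid):
        assert len(grid) == 9
        cells = {(m.scheme, m.algorithm) for m in grid}
        assert cells == {(s, a)
                         for s in ("two_state", "three_state", "mixed")
                         for a in ("BS", "PC", "GTT")}

    def test_networks_are_valid(self, grid):
        for m in grid:
            assert check_acyclic(m.network.structure)
            for n in m.network.nodes:
                assert np.allclose(m.network.cpts[n].sum(axis=-1), 1.0,
                                   atol=1e-9)

    def test_state_counts_follow_scheme(self, grid):
        for m in grid:
            cards = {m.network.card(n) for n in m.network.nodes}
            if m.scheme == "two_state":
                assert cards == {2}
            elif m.scheme == "three_state":
                assert cards == {3}
            else:
                assert cards <= {2, 3}

    def test_score_matches_recomputation(self, grid):
        clean = impute_mean(generate_survey(GeneratorConfig(seed=31)))
        from surveybbn.discretize import apply_scheme

        m = grid[0]
        data = apply_scheme(clean, m.scheme, "equal_width")
        scorer = _Scorer(data)
        parents = {n: m.network.structure.parents[n] for n in m.network.nodes}
        assert m.score == pytest.approx(scorer.total(parents), abs=1e-9)
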