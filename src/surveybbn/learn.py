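"""Structure learning: score-based hill climbing (Bayesian Search), Greedy
Thick Thinning, and the constraint-based PC algorithm.

The two score-based learners maximize the decomposable BDeu score; PC prunes
a complete undirected graph with G-squared conditional-independence tests,
orients v-structures from separating sets and closes under the Meek rules,
then the resulting CPDAG is extended to a concrete DAG for parameter
fitting.  All tie-breaks are lexicographic in node ids so runs are
reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.stats import chi2

from .bbn import (DAGStructure, BayesianNetwork, check_acyclic, family_score,
                  fit_cpts)
from .discretize import DiscreteDataset, SCHEMES, apply_scheme
from .synth import SurveyDataset

ALGORITHMS = ("BS", "PC", "GTT")


@dataclass
class LearnConfig:
    algorithm: str = "GTT"
    max_parents: int = 4
    restarts: int = 20
    seed: int = 0
    ci_alpha: float = 0.05
    ess: float = 1.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if not 0 < self.ci_alpha < 1:
            raise ValueError("ci_alpha must lie in (0, 1)")


@dataclass
class CPDAG:
    """Partially directed graph: PC's native output."""

    nodes: tuple[str, ...]
    directed: set[tuple[str, str]]
    undirected: set[frozenset[str]]


class _Scorer:
    """Memoized BDeu family scores over one dataset."""

    def __init__(self, data: DiscreteDataset, ess: float = 1.0):
        self.data = data
        self.ess = ess
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, node: str, parents: tuple[str, ...]) -> float:
        key = (node, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = family_score(node, key[1], self.data, self.ess)
        return self._cache[key]

    def total(self, parents: dict[str, tuple[str, ...]]) -> float:
        return sum(self.family(n, p) for n, p in parents.items())


def _would_cycle(parents: dict[str, tuple[str, ...]], src: str, dst: str) -> bool:
    """True if adding src->dst creates a cycle (src reachable from dst)."""
    stack, seen = [dst], set()
    while stack:
        v = stack.pop()
        if v == src:
            return True
        if v in seen:
            continue
        seen.add(v)
        stack.extend(child for child, pa in parents.items() if v in pa)
    return False


def _hill_climb(parents: dict[str, tuple[str, ...]], scorer: _Scorer,
                max_parents: int) -> dict[str, tuple[str, ...]]:
    """Greedy add/delete/reverse moves until no move improves the score."""
    nodes = sorted(parents)
    while True:
        best_gain, best_apply = 1e-9, None
        for src, dst in itertools.permutations(nodes, 2):
            pa = parents[dst]
            if src not in pa:
                if len(pa) >= max_parents or _would_cycle(parents, src, dst):
                    continue
                gain = (scorer.family(dst, pa + (src,)) - scorer.family(dst, pa))
                if gain > best_gain:
                    best_gain = gain
                    best_apply = ("add", src, dst)
            else:
                # delete
                new_pa = tuple(p for p in pa if p != src)
                gain = scorer.family(dst, new_pa) - scorer.family(dst, pa)
                if gain > best_gain:
                    best_gain, best_apply = gain, ("del", src, dst)
                # reverse
                pa_src = parents[src]
                if len(pa_src) < max_parents:
                    trimmed = {**parents, dst: new_pa}
                    if not _would_cycle(trimmed, dst, src):
                        gain = (scorer.family(dst, new_pa) - scorer.family(dst, pa)
                                + scorer.family(src, pa_src + (dst,))
                                - scorer.family(src, pa_src))
                        if gain > best_gain:
                            best_gain, best_apply = gain, ("rev", src, dst)
        if best_apply is None:
            return parents
        op, src, dst = best_apply
        if op == "add":
            parents = {**parents, dst: tuple(sorted(parents[dst] + (src,)))}
        elif op == "del":
            parents = {**parents, dst: tuple(p for p in parents[dst] if p != src)}
        else:
            parents = {**parents,
                       dst: tuple(p for p in parents[dst] if p != src),
                       src: tuple(sorted(parents[src] + (dst,)))}


def _random_dag(nodes: list[str], rng: np.random.Generator,
                max_parents: int) -> dict[str, tuple[str, ...]]:
    order = list(rng.permutation(nodes))
    parents: dict[str, tuple[str, ...]] = {n: () for n in nodes}
    for i, n in enumerate(order[1:], start=1):
        k = int(rng.integers(0, min(i, max_parents) + 1))
        if k:
            pa = rng.choice(order[:i], size=k, replace=False)
            parents[n] = tuple(sorted(str(p) for p in pa))
    return parents


def bayesian_search(data: DiscreteDataset, cfg: LearnConfig) -> DAGStructure:
    """Score-based search: hill climbing with seeded random restarts."""
    nodes = sorted(data.columns)
    if len(nodes) < 2:
        raise ValueError("need at least two variables")
    scorer = _Scorer(data, cfg.ess)
    rng = np.random.default_rng(cfg.seed)
    best_parents = _hill_climb({n: () for n in nodes}, scorer, cfg.max_parents)
    best_score = scorer.total(best_parents)
    for _ in range(cfg.restarts):
        start = _random_dag(nodes, rng, cfg.max_parents)
        result = _hill_climb(start, scorer, cfg.max_parents)
        score = scorer.total(result)
        if score > best_score + 1e-9:
            best_parents, best_score = result, score
    return DAGStructure(nodes=tuple(nodes), parents=best_parents)


def greedy_thick_thinning(data: DiscreteDataset, cfg: LearnConfig) -> DAGStructure:
    """Two-phase greedy search from the empty graph.

    Thickening adds the acyclicity-preserving arc with the largest positive
    score gain until none helps; thinning then deletes the arc whose removal
    most increases the score until no deletion helps.
    """
    nodes = sorted(data.columns)
    if len(nodes) < 2:
        raise ValueError("need at least two variables")
    scorer = _Scorer(data, cfg.ess)
    parents: dict[str, tuple[str, ...]] = {n: () for n in nodes}
    # phase 1: thickening
    while True:
        best_gain, best_arc = 1e-9, None
        for src, dst in itertools.permutations(nodes, 2):
            pa = parents[dst]
            if src in pa or len(pa) >= cfg.max_parents:
                continue
            if _would_cycle(parents, src, dst):
                continue
            gain = scorer.family(dst, pa + (src,)) - scorer.family(dst, pa)
            if gain > best_gain:
                best_gain, best_arc = gain, (src, dst)
        if best_arc is None:
            break
        src, dst = best_arc
        parents[dst] = tuple(sorted(parents[dst] + (src,)))
    # phase 2: thinning
    while True:
        best_gain, best_arc = 1e-9, None
        for dst in nodes:
            for src in parents[dst]:
                new_pa = tuple(p for p in parents[dst] if p != src)
                gain = scorer.family(dst, new_pa) - scorer.family(dst, parents[dst])
                if gain > best_gain:
                    best_gain, best_arc = gain, (src, dst)
        if best_arc is None:
            break
        src, dst = best_arc
        parents[dst] = tuple(p for p in parents[dst] if p != src)
    return DAGStructure(nodes=tuple(nodes), parents=parents)


# ---------------------------------------------------------------------------
# PC algorithm


def ci_test_g2(data: DiscreteDataset, x: str, y: str,
               cond: tuple[str, ...] = ()) -> float:
    """G-squared conditional-independence test p-value.

    The statistic is summed over the strata of the conditioning variables;
    empty strata contribute nothing and reduce the degrees of freedom.
    """
    rx, ry = data.n_states(x), data.n_states(y)
    cz = [data.n_states(z) for z in cond]
    shape = tuple(cz) + (rx, ry)
    counts = np.zeros(shape)
    cols = [data.codes[z].to_numpy() for z in cond] + \
           [data.codes[x].to_numpy(), data.codes[y].to_numpy()]
    np.add.at(counts, tuple(cols), 1.0)
    tables = counts.reshape(-1, rx, ry)
    g2, dof = 0.0, 0
    for t in tables:
        n = t.sum()
        if n == 0:
            continue
        row = t.sum(axis=1, keepdims=True)
        col = t.sum(axis=0, keepdims=True)
        expected = row * col / n
        mask = t > 0
        g2 += 2.0 * (t[mask] * np.log(t[mask] / expected[mask])).sum()
        dof += (rx - 1) * (ry - 1)
    dof = max(dof, 1)
    return float(chi2.sf(g2, dof))


def pc_algorithm(data: DiscreteDataset, cfg: LearnConfig) -> CPDAG:
    """Constraint-based skeleton discovery + v-structure and Meek orientation."""
    nodes = sorted(data.columns)
    if len(nodes) < 2:
        raise ValueError("need at least two variables")
    adj = {n: set(m for m in nodes if m != n) for n in nodes}
    sepset: dict[frozenset[str], tuple[str, ...]] = {}
    level = 0
    while level <= cfg.max_parents:
        if all(len(adj[x]) - 1 < level for x in nodes):
            break
        for x in nodes:
            for y in sorted(adj[x]):
                if x >= y:
                    continue
                removed = False
                for base in (sorted(adj[x] - {y}), sorted(adj[y] - {x})):
                    if len(base) < level:
                        continue
                    for S in itertools.combinations(base, level):
                        if ci_test_g2(data, x, y, S) > cfg.ci_alpha:
                            adj[x].discard(y)
                            adj[y].discard(x)
                            sepset[frozenset((x, y))] = S
                            removed = True
                            break
                    if removed:
                        break
        level += 1
    undirected = {frozenset((x, y)) for x in nodes for y in adj[x] if x < y}
    directed: set[tuple[str, str]] = set()
    # v-structures: x - z - y with x,y nonadjacent and z outside sepset(x,y)
    for z in nodes:
        nbrs = sorted(adj[z])
        for x, y in itertools.combinations(nbrs, 2):
            if y in adj[x]:
                continue
            if z not in sepset.get(frozenset((x, y)), ()):
                for a in (x, y):
                    e = frozenset((a, z))
                    if e in undirected:
                        undirected.discard(e)
                        directed.add((a, z))
                    # already directed the other way by an earlier v-structure:
                    # keep the first orientation (deterministic node order)
    _meek_closure(nodes, directed, undirected)
    return CPDAG(nodes=tuple(nodes), directed=directed, undirected=undirected)


def _meek_closure(nodes, directed: set, undirected: set) -> None:
    """Apply Meek rules R1-R4 until fixpoint (in place)."""

    def orient(a, b):
        undirected.discard(frozenset((a, b)))
        directed.add((a, b))

    def is_adj(a, b):
        return frozenset((a, b)) in undirected or (a, b) in directed or (b, a) in directed

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, z not adjacent y  =>  x -> y
                if any((z, x) in directed and not is_adj(z, y)
                       for z in nodes if z not in (x, y)):
                    orient(x, y)
                    changed = True
                    break
                # R2: x -> z -> y  =>  x -> y
                if any((x, z) in directed and (z, y) in directed
                       for z in nodes if z not in (x, y)):
                    orient(x, y)
                    changed = True
                    break
                # R3: x - z1 -> y, x - z2 -> y, z1,z2 nonadjacent => x -> y
                zs = [z for z in nodes if z not in (x, y)
                      and frozenset((x, z)) in undirected and (z, y) in directed]
                if any(not is_adj(z1, z2)
                       for z1, z2 in itertools.combinations(zs, 2)):
                    orient(x, y)
                    changed = True
                    break
                # R4: x - z1, z1 -> z2, z2 -> y, z1,y nonadj... (chordal case)
                zs2 = [(z1, z2) for z1 in nodes for z2 in nodes
                       if z1 not in (x, y) and z2 not in (x, y) and z1 != z2
                       and frozenset((x, z1)) in undirected
                       and (z1, z2) in directed and (z2, y) in directed
                       and not is_adj(z1, y) and is_adj(x, z2)]
                if zs2:
                    orient(x, y)
                    changed = True
                    break
            if changed:
                break


def extend_to_dag(cpdag: CPDAG) -> DAGStructure:
    """Deterministic order-based extension of a CPDAG to a DAG.

    Undirected edges are oriented from the lexicographically earlier to the
    later node unless that creates a cycle or a new v-structure, in which
    case the reverse direction is used; if both directions cycle, the CPDAG
    is inextensible.
    """
    directed = set(cpdag.directed)
    if not check_acyclic(DAGStructure.from_arcs(cpdag.nodes, sorted(directed))):
        raise ValueError("directed part of the CPDAG already contains a cycle")
    parents_of = lambda v: {a for a, b in directed if b == v}

    def creates_cycle(a, b):
        trial = directed | {(a, b)}
        g = {n: set() for n in cpdag.nodes}
        for s, t in trial:
            g[s].add(t)
        # DFS cycle check
        color = {n: 0 for n in cpdag.nodes}

        def dfs(v):
            color[v] = 1
            for w in g[v]:
                if color[w] == 1 or (color[w] == 0 and dfs(w)):
                    return True
            color[v] = 2
            return False

        return any(color[n] == 0 and dfs(n) for n in cpdag.nodes)

    def new_vstructure(a, b):
        # a->b creates a new collider at b if b has a parent c nonadjacent to a
        for c in parents_of(b):
            if c == a:
                continue
            adj = (frozenset((a, c)) in cpdag.undirected or (a, c) in directed
                   or (c, a) in directed)
            if not adj:
                return True
        return False

    for e in sorted(cpdag.undirected, key=sorted):
        a, b = sorted(e)
        if not creates_cycle(a, b) and not new_vstructure(a, b):
            directed.add((a, b))
        elif not creates_cycle(b, a):
            directed.add((b, a))
        elif not creates_cycle(a, b):
            directed.add((a, b))
        else:
            raise ValueError("CPDAG is not extensible to a DAG")
    return DAGStructure.from_arcs(cpdag.nodes, sorted(directed))


def learn_structure(data: DiscreteDataset, cfg: LearnConfig) -> DAGStructure:
    """Dispatch on cfg.algorithm; PC output is DAG-extended."""
    if cfg.algorithm == "BS":
        return bayesian_search(data, cfg)
    if cfg.algorithm == "GTT":
        return greedy_thick_thinning(data, cfg)
    return extend_to_dag(pc_algorithm(data, cfg))


def arcs_to_text(structure: DAGStructure) -> str:
    """One 'source->target' per line, for diffing learned structures."""
    return "\n".join(f"{s}->{t}" for s, t in structure.arcs) + "\n"


@dataclass
class LearnedModel:
    scheme: str
    algorithm: str
    seed: int
    network: BayesianNetwork
    score: float


def learn_grid(data: SurveyDataset, method: str = "equal_width",
               schemes: tuple[str, ...] = SCHEMES,
               algorithms: tuple[str, ...] = ALGORITHMS,
               base_cfg: LearnConfig | None = None,
               pseudocount: float = 1.0) -> list[LearnedModel]:
    """The scheme x algorithm model grid (3 x 3 = nine models by default).

    Each cell discretizes the clean data under its scheme with the given
    binning method, learns a structure, and fits smoothed CPTs.
    """
    if base_cfg is None:
        base_cfg = LearnConfig()
    models = []
    for scheme in schemes:
        disc = apply_scheme(data, scheme, method, seed=base_cfg.seed)
        for alg in algorithms:
            cfg = dc_replace(base_cfg, algorithm=alg)
            structure = learn_structure(disc, cfg)
            net = fit_cpts(structure, disc, pseudocount=pseudocount)
            from .bbn import total_score
            models.append(LearnedModel(scheme=scheme, algorithm=alg, seed=cfg.seed,
                                       network=net,
                                       score=total_score(structure, disc, cfg.ess)))
    return models
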