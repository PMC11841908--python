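"""Independent brute-force oracles used to check the package's fast paths.

Everything here works by direct enumeration or closed form and never calls
the implementation routines it is used to verify.
"""

from __future__ import annotations

import itertools

import numpy as np

from surveybbn.bbn import BayesianNetwork, DAGStructure


def enumerate_joint(net: BayesianNetwork) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Full joint table by multiplying CPT entries assignment by assignment."""
    cards = [net.card(n) for n in net.nodes]
    combos = list(itertools.product(*(range(c) for c in cards)))
    probs = np.empty(len(combos))
    for i, combo in enumerate(combos):
        idx = dict(zip(net.nodes, combo))
        p = 1.0
        for n in net.nodes:
            key = tuple(idx[q] for q in net.structure.parents[n]) + (idx[n],)
            p *= float(net.cpts[n][key])
        probs[i] = p
    return combos, probs


def brute_marginal(net: BayesianNetwork, query: str,
                   hard: dict[str, int] | None = None,
                   virtual: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Posterior marginal by summation over the enumerated joint."""
    hard = hard or {}
    virtual = virtual or {}
    combos, probs = enumerate_joint(net)
    qi = net.nodes.index(query)
    out = np.zeros(net.card(query))
    for combo, p in zip(combos, probs):
        if any(combo[net.nodes.index(n)] != s for n, s in hard.items()):
            continue
        for n, lik in virtual.items():
            p *= lik[combo[net.nodes.index(n)]]
        out[combo[qi]] += p
    if out.sum() <= 0:
        raise ValueError("zero-probability evidence")
    return out / out.sum()


def random_network(rng: np.random.Generator, n_nodes: int = 8,
                   max_card: int = 3, edge_prob: float = 0.35) -> BayesianNetwork:
    """Random DAG (edges respect node order) with Dirichlet CPTs."""
    nodes = tuple(f"N{i}" for i in range(n_nodes))
    cards = {n: int(rng.integers(2, max_card + 1)) for n in nodes}
    parents = {}
    for i, n in enumerate(nodes):
        pool = [nodes[j] for j in range(i) if rng.random() < edge_prob]
        parents[n] = tuple(sorted(pool[:3]))
    structure = DAGStructure(nodes=nodes, parents=parents)
    cpts = {}
    for n in nodes:
        shape = tuple(cards[p] for p in parents[n]) + (cards[n],)
        flat = rng.dirichlet(np.ones(cards[n]), size=int(np.prod(shape[:-1], dtype=int)))
        cpts[n] = flat.reshape(shape)
    states = {n: [f"C{i}" for i in range(cards[n])] for n in nodes}
    return BayesianNetwork(structure=structure, states=states, cpts=cpts)


def mean_silhouette_1d(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette by the direct definition (Euclidean, 1-D)."""
    x = np.asarray(x, dtype=float)
    vals = []
    for i in range(len(x)):
        own = labels == labels[i]
        a = np.abs(x[own] - x[i]).sum() / max(own.sum() - 1, 1)
        b = min(np.abs(x[labels == c] - x[i]).mean()
                for c in np.unique(labels) if c != labels[i])
        vals.append(0.0 if own.sum() == 1 else (b - a) / max(a, b))
    return float(np.mean(vals))


def optimal_1d_partition_ss(x: np.ndarray, k: int) -> float:
    """Minimal within-cluster sum of squares over all contiguous partitions.

    For 1-D squared-error clustering the optimum is contiguous in sorted
    order, so dynamic programming over split points is exhaustive.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    pre = np.concatenate([[0.0], np.cumsum(xs)])
    pre2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def ss(i, j):  # within-SS of xs[i:j]
        m = j - i
        s = pre[j] - pre[i]
        return (pre2[j] - pre2[i]) - s * s / m

    dp = np.full((k + 1, n + 1), np.inf)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(1, n + 1):
            for i in range(c - 1, j):
                cand = dp[c - 1, i] + ss(i, j)
                if cand < dp[c, j]:
                    dp[c, j] = cand
    return float(dp[k, n])


def all_dags(nodes: tuple[str, ...]):
    """Every DAG over the given nodes (use only for <= 3 nodes: 25 DAGs)."""
    pairs = list(itertools.combinations(nodes, 2))
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        arcs = []
        for (a, b), c in zip(pairs, choice):
            if c == 1:
                arcs.append((a, b))
            elif c == 2:
                arcs.append((b, a))
        g = {n: set() for n in nodes}
        for s, t in arcs:
            g[s].add(t)
        # cycle check by DFS
        color = {n: 0 for n in nodes}

        def dfs(v):
            color[v] = 1
            for w in g[v]:
                if color[w] == 1 or (color[w] == 0 and dfs(w)):
                    return True
            color[v] = 2
            return False

        if any(color[n] == 0 and dfs(n) for n in nodes):
            continue
        yield DAGStructure.from_arcs(nodes, arcs)


def cronbach_alpha_reference(x: np.ndarray) -> float:
    """Alpha from the covariance-matrix identity (independent route)."""
    c = np.cov(np.asarray(x, dtype=float), rowvar=False, ddof=1)
    m = c.shape[0]
    return m / (m - 1) * (1 - np.trace(c) / c.sum())
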