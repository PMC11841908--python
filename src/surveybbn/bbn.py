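"""Discrete Bayesian belief network: representation, fitting, scoring, inference.

A network is a DAG over discrete variables plus one conditional probability
table (CPT) per node; the joint factorizes as the product of the per-node
conditionals given their parents.  Everything downstream (structure search,
cross-validated prediction, sensitivity interventions) runs on this
representation.

Inference is exact variable elimination with a min-degree ordering; at the
scale this package targets (eight nodes, two or three states each) exactness
is cheap and no approximation is ever needed.  Parameter fitting uses
Laplace-style pseudocounts so sparse parent configurations at small n never
produce zero probabilities, and structure scoring is the BDeu log marginal
likelihood (uniform structure prior) that drives the score-based learners.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .discretize import DiscreteDataset


# ---------------------------------------------------------------------------
# structure


@dataclass(frozen=True)
class DAGStructure:
    """Directed acyclic graph given by per-node parent sets."""

    nodes: tuple[str, ...]
    parents: dict[str, tuple[str, ...]]

    @classmethod
    def from_arcs(cls, nodes, arcs) -> "DAGStructure":
        nodes = tuple(nodes)
        parents: dict[str, list[str]] = {n: [] for n in nodes}
        for src, dst in arcs:
            if src == dst:
                raise ValueError("self-arcs are not allowed")
            if src in parents[dst]:
                raise ValueError(f"duplicate arc {src}->{dst}")
            parents[dst].append(src)
        return cls(nodes=nodes, parents={n: tuple(sorted(p)) for n, p in parents.items()})

    @property
    def arcs(self) -> list[tuple[str, str]]:
        return sorted((p, n) for n in self.nodes for p in self.parents[n])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.to_networkx()))


def check_acyclic(structure: DAGStructure) -> bool:
    """True iff a topological order exists."""
    return nx.is_directed_acyclic_graph(structure.to_networkx())


# ---------------------------------------------------------------------------
# network and evidence


@dataclass
class BayesianNetwork:
    """DAG + state spaces + CPTs.

    ``cpts[n]`` has one axis per parent of n (in the stored parent order)
    followed by the axis of n itself; every row over the last axis sums to 1.
    """

    structure: DAGStructure
    states: dict[str, list[str]]
    cpts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not check_acyclic(self.structure):
            raise ValueError("structure must be acyclic")
        for n in self.structure.nodes:
            expect = tuple(len(self.states[p]) for p in self.structure.parents[n])
            expect += (len(self.states[n]),)
            if self.cpts[n].shape != expect:
                raise ValueError(f"CPT shape mismatch for {n}")
            if not np.allclose(self.cpts[n].sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {n} must sum to 1")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.structure.nodes

    def card(self, node: str) -> int:
        return len(self.states[node])

    def state_index(self, node: str, state) -> int:
        if isinstance(state, (int, np.integer)):
            if not 0 <= state < self.card(node):
                raise ValueError(f"state {state} out of range for {node}")
            return int(state)
        try:
            return self.states[node].index(state)
        except ValueError:
            raise ValueError(f"unknown state {state!r} for node {node}") from None


@dataclass
class Evidence:
    """Hard assignments and/or virtual (likelihood) evidence.

    A node carries either a hard state or a likelihood vector, never both;
    likelihood vectors must have at least one positive entry.
    """

    hard: dict[str, object] = field(default_factory=dict)
    virtual: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        both = set(self.hard) & set(self.virtual)
        if both:
            raise ValueError(f"nodes with both hard and virtual evidence: {sorted(both)}")
        for n, lik in self.virtual.items():
            lik = np.asarray(lik, dtype=float)
            if np.any(lik < 0) or not np.any(lik > 0):
                raise ValueError(f"likelihood for {n} needs nonnegative entries, one positive")
            self.virtual[n] = lik


# ---------------------------------------------------------------------------
# joint probability and fitting


def joint_probability(net: BayesianNetwork, assignment: dict[str, object]) -> float:
    """Probability of a full assignment: product of CPT entries."""
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment must cover all nodes, missing {sorted(missing)}")
    idx = {n: net.state_index(n, assignment[n]) for n in net.nodes}
    p = 1.0
    for n in net.nodes:
        key = tuple(idx[q] for q in net.structure.parents[n]) + (idx[n],)
        p *= float(net.cpts[n][key])
    return p


def fit_cpts(structure: DAGStructure, data: DiscreteDataset,
             pseudocount: float = 1.0) -> BayesianNetwork:
    """Smoothed maximum-likelihood CPTs from discrete data.

    P(x | pa) = (count(x, pa) + c) / (count(pa) + c * |states(x)|); with
    pseudocount c = 0 an unseen parent configuration falls back to a
    uniform row.  State spaces come from the dataset's BinningSpec, so
    states absent from the sample still exist in the network.
    """
    if data.n_rows == 0:
        raise ValueError("empty data")
    if set(structure.nodes) - set(data.columns):
        raise ValueError("data columns must cover all nodes")
    states = {n: data.spec.states(n) for n in structure.nodes}
    cards = {n: len(states[n]) for n in structure.nodes}
    cpts: dict[str, np.ndarray] = {}
    for n in structure.nodes:
        pa = structure.parents[n]
        shape = tuple(cards[p] for p in pa) + (cards[n],)
        counts = np.zeros(shape)
        cols = [data.codes[p].to_numpy() for p in pa] + [data.codes[n].to_numpy()]
        np.add.at(counts, tuple(cols), 1.0)
        counts += pseudocount
        totals = counts.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore"):
            cpt = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0),
                           1.0 / cards[n])
        cpts[n] = cpt
    return BayesianNetwork(structure=structure, states=states, cpts=cpts)


# ---------------------------------------------------------------------------
# BDeu scoring


def family_score(node: str, parents: tuple[str, ...], data: DiscreteDataset,
                 ess: float = 1.0) -> float:
    """BDeu log marginal likelihood of one node-family.

    Dirichlet hyperparameters ess / (q r) per CPT cell and ess / q per parent
    configuration, with r the node cardinality and q the number of parent
    configurations; decomposable, so the total structure score is the sum of
    family scores.
    """
    if ess <= 0:
        raise ValueError("ess must be positive")
    r = data.n_states(node)
    q = int(np.prod([data.n_states(p) for p in parents])) if parents else 1
    shape = tuple(data.n_states(p) for p in parents) + (r,)
    counts = np.zeros(shape)
    cols = [data.codes[p].to_numpy() for p in parents] + [data.codes[node].to_numpy()]
    np.add.at(counts, tuple(cols), 1.0)
    counts = counts.reshape(q, r)
    a_jk = ess / (q * r)
    a_j = ess / q
    nj = counts.sum(axis=1)
    score = (gammaln(a_j) - gammaln(a_j + nj)).sum()
    score += (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
    return float(score)


def total_score(structure: DAGStructure, data: DiscreteDataset,
                ess: float = 1.0) -> float:
    return sum(family_score(n, structure.parents[n], data, ess)
               for n in structure.nodes)


# ---------------------------------------------------------------------------
# exact inference: variable elimination


def _multiply(f1, f2):
    vars1, a1 = f1
    vars2, a2 = f2
    out_vars = list(vars1) + [v for v in vars2 if v not in vars1]
    sh1 = [a1.shape[vars1.index(v)] if v in vars1 else 1 for v in out_vars]
    sh2 = [a2.shape[vars2.index(v)] if v in vars2 else 1 for v in out_vars]
    b1 = np.transpose(a1, [vars1.index(v) for v in out_vars if v in vars1]).reshape(sh1)
    b2 = np.transpose(a2, [vars2.index(v) for v in out_vars if v in vars2]).reshape(sh2)
    return tuple(out_vars), b1 * b2


def _sum_out(factor, var):
    fvars, arr = factor
    ax = fvars.index(var)
    return tuple(v for v in fvars if v != var), arr.sum(axis=ax)


def infer(net: BayesianNetwork, evidence: Evidence | None,
          query: list[str] | str) -> dict[str, np.ndarray]:
    """Exact posterior marginals of the query nodes given evidence.

    Hard evidence slices factors, virtual evidence multiplies in its
    likelihood vector; elimination follows a min-degree ordering.  Raises
    if the evidence has zero total probability.
    """
    if evidence is None:
        evidence = Evidence()
    if isinstance(query, str):
        query = [query]
    hard_idx = {n: net.state_index(n, s) for n, s in evidence.hard.items()}
    for n, lik in evidence.virtual.items():
        if len(lik) != net.card(n):
            raise ValueError(f"likelihood length mismatch for {n}")

    base_factors = []
    for n in net.nodes:
        fvars = tuple(net.structure.parents[n]) + (n,)
        base_factors.append((fvars, net.cpts[n]))
    for n, lik in evidence.virtual.items():
        base_factors.append(((n,), np.asarray(lik, dtype=float)))

    # slice in hard evidence
    factors = []
    for fvars, arr in base_factors:
        for v in fvars:
            if v in hard_idx:
                arr = np.take(arr, hard_idx[v], axis=fvars.index(v))
                fvars = tuple(u for u in fvars if u != v)
        factors.append((fvars, np.asarray(arr, dtype=float)))

    out: dict[str, np.ndarray] = {}
    for qn in query:
        if qn in hard_idx:
            point = np.zeros(net.card(qn))
            point[hard_idx[qn]] = 1.0
            out[qn] = point
            continue
        out[qn] = _eliminate_to(factors, qn)
    return out


def _eliminate_to(factors, target: str) -> np.ndarray:
    work = list(factors)
    hidden = sorted({v for fvars, _ in work for v in fvars} - {target})
    # min-degree: repeatedly eliminate the variable appearing with the
    # fewest distinct neighbors in the current factor graph
    while hidden:
        neigh = {v: set() for v in hidden}
        for fvars, _ in work:
            for v in fvars:
                if v in neigh:
                    neigh[v].update(u for u in fvars if u != v)
        var = min(hidden, key=lambda v: (len(neigh[v]), v))
        hidden.remove(var)
        related = [f for f in work if var in f[0]]
        work = [f for f in work if var not in f[0]]
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        work.append(_sum_out(prod, var))
    prod = ((), np.array(1.0))
    for f in work:
        prod = _multiply(prod, f)
    fvars, arr = prod
    if fvars != (target,):
        arr = np.transpose(arr, [fvars.index(target)]) if target in fvars else arr
    z = arr.sum()
    if z <= 0:
        raise ValueError("evidence has zero total probability")
    return np.asarray(arr, dtype=float).reshape(-1) / z


# ---------------------------------------------------------------------------
# serialization


def to_text(net: BayesianNetwork) -> str:
    """Human-readable structured-text serialization (round-trips)."""
    lines = ["# surveybbn network"]
    for n in net.nodes:
        lines.append(f"node {n} states {' '.join(net.states[n])}")
    for src, dst in net.structure.arcs:
        lines.append(f"arc {src} -> {dst}")
    for n in net.nodes:
        pa = net.structure.parents[n]
        lines.append(f"cpt {n} given {' '.join(pa) if pa else '-'}")
        table = net.cpts[n].reshape(-1, net.card(n))
        cards = [net.card(p) for p in pa]
        for j, row in enumerate(table):
            cfg = np.unravel_index(j, cards) if pa else ()
            key = ",".join(str(c) for c in cfg) if pa else "-"
            lines.append("  " + key + " : " + " ".join(f"{v:.12g}" for v in row))
    return "\n".join(lines) + "\n"


def from_text(text: str) -> BayesianNetwork:
    states: dict[str, list[str]] = {}
    arcs: list[tuple[str, str]] = []
    rows: dict[str, list[np.ndarray]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("node "):
            parts = line.split()
            states[parts[1]] = parts[3:]
        elif line.startswith("arc "):
            _, src, _, dst = line.split()
            arcs.append((src, dst))
        elif line.startswith("cpt "):
            current = line.split()[1]
            rows[current] = []
        else:
            _, vals = line.split(":")
            rows[current].append(np.array([float(v) for v in vals.split()]))
    structure = DAGStructure.from_arcs(tuple(states), arcs)
    cpts = {}
    for n in structure.nodes:
        shape = tuple(len(states[p]) for p in structure.parents[n]) + (len(states[n]),)
        cpts[n] = np.vstack(rows[n]).reshape(shape)
    return BayesianNetwork(structure=structure, states=states, cpts=cpts)


def to_bif(net: BayesianNetwork) -> str:
    """Export in the Bayesian-network interchange format (BIF)."""
    out = ["network surveybbn {", "}"]
    for n in net.nodes:
        out.append(f"variable {n} {{")
        out.append(f"  type discrete [ {net.card(n)} ] {{ {', '.join(net.states[n])} }};")
        out.append("}")
    for n in net.nodes:
        pa = net.structure.parents[n]
        head = f"probability ( {n}" + (f" | {', '.join(pa)}" if pa else "") + " ) {"
        out.append(head)
        if not pa:
            out.append("  table " + ", ".join(f"{v:.10g}" for v in net.cpts[n]) + ";")
        else:
            cards = [net.card(p) for p in pa]
            table = net.cpts[n].reshape(-1, net.card(n))
            for j, row in enumerate(table):
                cfg = np.unravel_index(j, cards)
                labels = ", ".join(net.states[p][c] for p, c in zip(pa, cfg))
                out.append(f"  ({labels}) " + ", ".join(f"{v:.10g}" for v in row) + ";")
        out.append("}")
    return "\n".join(out) + "\n"


_BIF_VAR = re.compile(
    r"variable\s+(\w+)\s*\{[^}]*type\s+discrete\s*\[\s*\d+\s*\]\s*\{([^}]*)\}",
    re.S,
)
_BIF_PROB = re.compile(
    r"probability\s*\(\s*(\w+)\s*(?:\|\s*([^)]*))?\)\s*\{([^}]*)\}", re.S
)


def from_bif(text: str) -> BayesianNetwork:
    """Parse the subset of BIF written by :func:`to_bif`."""
    states = {m.group(1): [s.strip() for s in m.group(2).split(",")]
              for m in _BIF_VAR.finditer(text)}
    parents: dict[str, tuple[str, ...]] = {}
    raw_cpts: dict[str, np.ndarray] = {}
    for m in _BIF_PROB.finditer(text):
        node = m.group(1)
        pa = tuple(p.strip() for p in m.group(2).split(",")) if m.group(2) else ()
        body = m.group(3)
        card = len(states[node])
        if not pa:
            nums = re.findall(r"[-+0-9.eE]+", body.split("table", 1)[1])
            raw_cpts[node] = np.array([float(v) for v in nums])
        else:
            cards = [len(states[p]) for p in pa]
            table = np.zeros((int(np.prod(cards)), card))
            for line in body.strip().splitlines():
                line = line.strip().rstrip(";")
                if not line:
                    continue
                cfg_part, vals_part = line.split(")", 1)
                cfg_labels = [s.strip() for s in cfg_part.lstrip("(").split(",")]
                cfg = tuple(states[p].index(lbl) for p, lbl in zip(pa, cfg_labels))
                j = int(np.ravel_multi_index(cfg, cards))
                table[j] = [float(v) for v in vals_part.split(",")]
            raw_cpts[node] = table.reshape(tuple(cards) + (card,))
        parents[node] = pa
    structure = DAGStructure(nodes=tuple(states), parents=parents)
    return BayesianNetwork(structure=structure, states=states, cpts=raw_cpts)


def sample(net: BayesianNetwork, n: int, seed: int = 0):
    """Forward (ancestral) sampling: n rows of integer state codes."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    order = net.structure.topological_order()
    out = {node: np.empty(n, dtype=int) for node in net.nodes}
    for node in order:
        pa = net.structure.parents[node]
        cpt = net.cpts[node]
        if not pa:
            out[node] = rng.choice(net.card(node), size=n, p=cpt)
        else:
            u = rng.random(n)
            rows = cpt[tuple(out[p] for p in pa)]
            out[node] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return pd.DataFrame({node: out[node] for node in net.nodes})


def all_assignments(net: BayesianNetwork):
    """Iterate every full node->state-index assignment (small nets only)."""
    cards = [net.card(n) for n in net.nodes]
    for combo in itertools.product(*(range(c) for c in cards)):
        yield dict(zip(net.nodes, combo))
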