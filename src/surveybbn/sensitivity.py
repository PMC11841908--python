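"""Sensitivity analyses on a fitted network.

Two complementary views of "which factor matters most":

* a one-at-a-time CPT-perturbation scan (the style of a modelling tool's
  built-in sensitivity view), ranking nodes by how much a +/-10% nudge of
  any of their CPT entries can move a chosen focus node's marginal; and

* a doubling intervention: the probability of a source node's top state is
  doubled (capped just below 1), the remaining states are rescaled so their
  mutual ratios are preserved, and the new marginal is imposed through
  virtual evidence (a Jeffrey-style update).  The net effect on every other
  node is the relative percent change of its top-state probability, and the
  full source x target matrix ranks the factors by total influence.

The update deliberately conditions rather than severs arcs, matching what
adjusting a node's probability does in evidence-propagation software;
information therefore flows both along and against arc directions.  A
graph-surgery ("do") mode is available behind a flag.  Sources that are
d-separated from a target given no evidence have exactly zero effect and
are zeroed structurally rather than numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import networkx as nx
import numpy as np
import pandas as pd

from .bbn import BayesianNetwork, DAGStructure, Evidence, infer


@dataclass
class InterventionSpec:
    source: str
    state: int | None = None      # None -> the source's highest-valued state
    multiplier: float = 2.0
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.multiplier <= 1:
            raise ValueError("multiplier must exceed 1")
        if not 0 < self.eps < 0.01:
            raise ValueError("eps must lie in (0, 0.01)")


@dataclass
class SensitivityTable:
    """Source x target net-effect matrix plus baseline marginals."""

    effects: pd.DataFrame          # percent changes; NaN on the diagonal
    baseline: dict[str, np.ndarray]
    ranking: pd.Series             # summed |effect| per source, descending

    def to_csv(self, path) -> None:
        self.effects.to_csv(path, na_rep="")


def baseline_marginals(net: BayesianNetwork) -> dict[str, np.ndarray]:
    """No-evidence posterior marginal of every node."""
    return infer(net, None, list(net.nodes))


def double_state(marginal: np.ndarray, state: int, multiplier: float = 2.0,
                 eps: float = 1e-6) -> np.ndarray:
    """Boost one state's probability, preserving the others' mutual ratios.

    p' = min(multiplier * p, 1 - eps) for the chosen state; the remaining
    states are scaled by (1 - p') / (1 - p).  The cap keeps the result a
    proper distribution when the boosted state already exceeds 1/multiplier.
    """
    p = np.asarray(marginal, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9) or np.any(p < 0):
        raise ValueError("input must be a probability vector")
    p0 = p[state]
    if p0 >= 1.0:
        raise ValueError("state already has probability 1; nothing to rescale")
    boosted = min(multiplier * p0, 1.0 - eps)
    out = p * (1.0 - boosted) / (1.0 - p0)
    out[state] = boosted
    return out


def intervene(net: BayesianNetwork, spec: InterventionSpec,
              mode: str = "evidence") -> dict[str, np.ndarray]:
    """Impose the doubled marginal on the source and return all posteriors.

    ``evidence`` mode (default) applies virtual evidence with likelihood
    q(x)/p(x), so the source's posterior equals the doubled marginal q and
    the update propagates in both arc directions.  ``do`` mode severs the
    source's incoming arcs and replaces its CPT with q (interventional
    semantics).
    """
    if spec.source not in net.nodes:
        raise ValueError(f"unknown source node {spec.source!r}")
    p = baseline_marginals(net)[spec.source]
    state = spec.state if spec.state is not None else net.card(spec.source) - 1
    if p[state] <= 0:
        raise ValueError("boosted state has zero baseline probability")
    q = double_state(p, state, spec.multiplier, spec.eps)
    if mode == "evidence":
        lik = q / p
        ev = Evidence(virtual={spec.source: lik})
        return infer(net, ev, list(net.nodes))
    if mode == "do":
        parents = dict(net.structure.parents)
        parents[spec.source] = ()
        structure = DAGStructure(nodes=net.structure.nodes, parents=parents)
        cpts = dict(net.cpts)
        cpts[spec.source] = q
        cut = BayesianNetwork(structure=structure, states=net.states, cpts=cpts)
        return infer(cut, None, list(cut.nodes))
    raise ValueError("mode must be 'evidence' or 'do'")


def net_effect(baseline: dict[str, np.ndarray], intervened: dict[str, np.ndarray],
               target: str) -> float:
    """Relative percent change of the target's top-state probability."""
    p = baseline[target][-1]
    if p <= 0:
        raise ValueError("zero baseline top-state probability")
    return float(100.0 * (intervened[target][-1] - p) / p)


def _marginally_coupled(net: BayesianNetwork, source: str, target: str) -> bool:
    """False iff source and target are d-separated given no evidence."""
    g = net.structure.to_networkx()
    return not nx.is_d_separator(g, {source}, {target}, set())


def influence_scan(net: BayesianNetwork,
                   multiplier: float = 2.0, eps: float = 1e-6,
                   mode: str = "evidence") -> SensitivityTable:
    """Doubling intervention at every node; net effects on all others.

    Sources are ranked by the sum of absolute net effects across targets
    (the "most critical factor" criterion).  Entries whose source-target
    pair is d-separated given no evidence are exactly zero by construction.
    """
    nodes = list(net.nodes)
    base = baseline_marginals(net)
    effects = pd.DataFrame(np.nan, index=nodes, columns=nodes)
    for src in nodes:
        post = intervene(net, InterventionSpec(source=src, multiplier=multiplier,
                                               eps=eps), mode=mode)
        for tgt in nodes:
            if tgt == src:
                continue
            if not _marginally_coupled(net, src, tgt):
                effects.loc[src, tgt] = 0.0
            else:
                effects.loc[src, tgt] = net_effect(base, post, tgt)
    ranking = effects.abs().sum(axis=1).sort_values(ascending=False)
    return SensitivityTable(effects=effects, baseline=base, ranking=ranking)


def cpt_sensitivity(net: BayesianNetwork, focus: str,
                    delta: float = 0.10,
                    high_threshold: float = 0.01,
                    mild_threshold: float = 1e-6) -> pd.DataFrame:
    """One-at-a-time CPT perturbation scan toward a focus node.

    Every CPT entry is scaled by (1 +/- delta) with its row renormalized,
    and the largest absolute change in the focus node's marginal is
    recorded per node, then thresholded into high / mild / none.
    """
    if focus not in net.nodes:
        raise ValueError(f"unknown focus node {focus!r}")
    base = baseline_marginals(net)[focus]
    rows = []
    for n in net.nodes:
        cpt = net.cpts[n]
        flat = cpt.reshape(-1, net.card(n))
        max_change = 0.0
        for j in range(flat.shape[0]):
            for s in range(flat.shape[1]):
                for factor in (1.0 + delta, 1.0 - delta):
                    row = flat[j].copy()
                    row[s] *= factor
                    row /= row.sum()
                    new_flat = flat.copy()
                    new_flat[j] = row
                    cpts = dict(net.cpts)
                    cpts[n] = new_flat.reshape(cpt.shape)
                    perturbed = dc_replace(net, cpts=cpts)
                    m = infer(perturbed, None, focus)[focus]
                    max_change = max(max_change, float(np.abs(m - base).max()))
        category = ("high" if max_change >= high_threshold
                    else "mild" if max_change >= mild_threshold else "none")
        rows.append({"node": n, "max_abs_change": max_change, "category": category})
    out = pd.DataFrame(rows).sort_values("max_abs_change", ascending=False)
    return out.reset_index(drop=True)
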