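"""Exact inference on the pathway network via the junction-tree algorithm.

The learned DAG is moralized, triangulated with the minimum-fill heuristic,
and its maximal cliques assembled into a clique tree satisfying the running
intersection property.  Marginals given (hard) evidence are computed with
two-pass sum-product message passing (Shafer-Shenoy: collect to a root,
then distribute), which makes the result independent of the chosen root.
Perturbation scenarios clamp one or more pathways to a state and report how
the posterior state probabilities of every other pathway move relative to
the no-evidence baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._factors import Factor, product
from .bayesnet import BayesianNetworkModel, STATES, _STATE_INDEX
from .errors import ImpossibleEvidenceError

Evidence = Mapping[str, int]  # node -> observed state in {-1, 0, +1}
MarginalTable = dict[str, np.ndarray]  # node -> P over (-1, 0, +1)


@dataclass
class JunctionTree:
    """Clique tree with separators and clique potentials."""

    cliques: list[tuple[str, ...]]
    tree_edges: list[tuple[int, int]]
    separators: dict[tuple[int, int], tuple[str, ...]]
    potentials: list[Factor] = field(repr=False)
    nodes: list[str] = field(default_factory=list)

    def containing_clique(self, node: str) -> int:
        for i, c in enumerate(self.cliques):
            if node in c:
                return i
        raise KeyError(node)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.tree_edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)


def _min_fill_cliques(nodes: Sequence[str], adj: dict[str, set[str]]) -> list[tuple[str, ...]]:
    """Triangulate by min-fill elimination (lexicographic ties); return maximal cliques."""
    adj = {n: set(adj[n]) for n in nodes}
    remaining = set(nodes)
    cliques: list[set[str]] = []
    while remaining:
        def fill(n: str) -> int:
            nbrs = sorted(adj[n] & remaining)
            return sum(
                1
                for i, a in enumerate(nbrs)
                for b in nbrs[i + 1:]
                if b not in adj[a]
            )

        v = min(sorted(remaining), key=fill)
        nbrs = adj[v] & remaining
        clique = {v} | nbrs
        cliques.append(clique)
        for a in nbrs:
            for b in nbrs:
                if a != b:
                    adj[a].add(b)
        remaining.discard(v)
    # drop non-maximal cliques, deterministic order
    cliques.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    maximal: list[set[str]] = []
    for c in cliques:
        if not any(c <= m for m in maximal):
            maximal.append(c)
    maximal.sort(key=lambda c: tuple(sorted(c)))
    return [tuple(sorted(c)) for c in maximal]


def build_junction_tree(model: BayesianNetworkModel) -> JunctionTree:
    """Moralize, triangulate (min-fill), and assemble a calibratable clique tree.

    Cliques are connected by a maximum-weight spanning forest on separator
    sizes (Kruskal, deterministic edge order); disconnected components are
    then joined with empty separators so the result is a single tree.  Each
    CPT is multiplied into exactly one clique containing its family.
    """
    nodes = list(model.dag.nodes)
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for p, c in model.dag.edges:
        adj[p].add(c)
        adj[c].add(p)
    for c in nodes:  # moral edges between co-parents
        ps = model.parents[c]
        for i, a in enumerate(ps):
            for b in ps[i + 1:]:
                adj[a].add(b)
                adj[b].add(a)
    cliques = _min_fill_cliques(nodes, adj)
    n = len(cliques)
    # Kruskal maximum spanning forest on separator size
    cand = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (-len(set(cliques[e[0]]) & set(cliques[e[1]])), e),
    )
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree_edges: list[tuple[int, int]] = []
    for i, j in cand:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree_edges.append((i, j))
    tree_edges.sort()
    separators = {
        (i, j): tuple(sorted(set(cliques[i]) & set(cliques[j]))) for i, j in tree_edges
    }
    potentials = [Factor.ones(c) for c in cliques]
    for node in nodes:
        family = {node, *model.parents[node]}
        home = next(i for i, c in enumerate(cliques) if family <= set(c))
        potentials[home] = potentials[home].multiply(
            Factor((node, *model.parents[node]), model.cpts[node])
        )
    return JunctionTree(
        cliques=cliques,
        tree_edges=tree_edges,
        separators=separators,
        potentials=potentials,
        nodes=nodes,
    )


def _validate_evidence(tree: JunctionTree, evidence: Evidence) -> dict[str, int]:
    out = {}
    for node, state in evidence.items():
        if node not in tree.nodes:
            raise KeyError(f"evidence node {node!r} not in model")
        if state not in STATES:
            raise ValueError(f"evidence state for {node!r} must be one of {STATES}")
        out[node] = _STATE_INDEX[state]
    return out


def propagate(tree: JunctionTree, evidence: Evidence | None = None, root: int = 0) -> MarginalTable:
    """Posterior node marginals given hard evidence.

    Two-pass sum-product (collect to ``root``, then distribute); marginals
    are read from the first clique containing each node and normalized.
    Raises :class:`ImpossibleEvidenceError` when the evidence has
    probability zero under the model.
    """
    ev = _validate_evidence(tree, evidence or {})
    pots = list(tree.potentials)
    for node, idx in ev.items():
        i = tree.containing_clique(node)
        pots[i] = pots[i].reduce(node, idx)
    # message schedule: BFS tree from root
    order: list[int] = [root]
    parent_of: dict[int, int | None] = {root: None}
    for i in order:
        for j in tree.neighbors(i):
            if j not in parent_of:
                parent_of[j] = i
                order.append(j)
    if len(order) != len(tree.cliques):
        raise ValueError("junction tree is not connected")

    messages: dict[tuple[int, int], Factor] = {}

    def sep(i: int, j: int) -> tuple[str, ...]:
        if (i, j) in tree.separators:
            return tree.separators[(i, j)]
        return tree.separators[(j, i)]

    def message(i: int, j: int) -> Factor:
        incoming = [messages[(k, i)] for k in tree.neighbors(i) if k != j]
        return product([pots[i]] + incoming).marginalize(sep(i, j))

    for i in reversed(order):  # collect: leaves towards root
        p = parent_of[i]
        if p is not None:
            messages[(i, p)] = message(i, p)
    for i in order:  # distribute: root towards leaves
        for j in tree.neighbors(i):
            if parent_of.get(j) == i:
                messages[(i, j)] = message(i, j)

    marginals: MarginalTable = {}
    for node in tree.nodes:
        i = tree.containing_clique(node)
        belief = product([pots[i]] + [messages[(k, i)] for k in tree.neighbors(i)])
        vec = belief.marginalize((node,)).table
        z = float(vec.sum())
        if z <= 0.0:
            raise ImpossibleEvidenceError(
                f"evidence {dict(evidence or {})} has probability zero under the model"
            )
        marginals[node] = vec / z
    return marginals


@dataclass
class ScenarioResult:
    """Posterior and baseline marginals for one perturbation scenario."""

    name: str
    evidence: dict[str, int]
    posterior: MarginalTable
    baseline: MarginalTable

    @property
    def delta(self) -> MarginalTable:
        return {n: self.posterior[n] - self.baseline[n] for n in self.posterior}


def scenario_inference(
    model: BayesianNetworkModel,
    scenarios: Mapping[str, Evidence],
) -> dict[str, ScenarioResult]:
    """Run named evidence scenarios and report signed probability changes.

    Each scenario clamps some pathways to states; the result carries the
    posterior marginals, the shared no-evidence baseline, and (via
    ``.delta``) the per-node change in each state's probability.
    """
    tree = build_junction_tree(model)
    baseline = propagate(tree, {})
    out = {}
    for name, ev in scenarios.items():
        posterior = propagate(tree, ev)
        out[name] = ScenarioResult(
            name=name,
            evidence=dict(ev),
            posterior=posterior,
            baseline=baseline,
        )
    return out
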