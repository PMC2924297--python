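"""Discrete Bayesian networks over pathway states: BIC, GES, CPTs, link strength.

The structure score is the Bayesian Information Criterion in its standard
(Schwarz) form on the natural-log scale,

    BIC(S) = sum_nodes LL_hat(node | parents) - (d/2) * ln M,

with ``d`` the number of free multinomial parameters and ``M`` the number of
observations (experiments).  BIC decomposes over (node, parent-set)
families and is likelihood-equivalent, the two properties Greedy
Equivalence Search (GES) relies on.  GES searches over Markov equivalence
classes (CPDAGs): a forward phase greedily applies the best positive
single-edge insertion, then a backward phase the best deletion, using
Chickering's validity conditions for both operators.

Edge influence is quantified as the "true link strength percentage": the
relative reduction in entropy of the child given knowledge of the parent,
100 * (H(child) - H(child | parent)) / H(child), with entropies in bits
computed from the model-implied joint distribution.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._factors import CARD, Factor, eliminate
from .errors import NotExtendableError
from .io import DiscreteStateMatrix

STATES = (-1, 0, 1)
_STATE_INDEX = {-1: 0, 0: 1, 1: 2}


# ---------------------------------------------------------------------------
# Graph types
# ---------------------------------------------------------------------------

@dataclass
class Dag:
    """Directed acyclic graph with an explicit node order."""

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate nodes")
        for p, c in self.edges:
            if p == c:
                raise ValueError(f"self-loop on {p!r}")
            if p not in node_set or c not in node_set:
                raise ValueError(f"edge ({p!r}, {c!r}) uses undeclared node")
        self.topological_order()  # raises on cycles

    def parents(self, node: str) -> tuple[str, ...]:
        pos = {n: i for i, n in enumerate(self.nodes)}
        return tuple(sorted((p for p, c in self.edges if c == node), key=pos.__getitem__))

    def topological_order(self) -> list[str]:
        indeg = {n: 0 for n in self.nodes}
        for _, c in self.edges:
            indeg[c] += 1
        ready = [n for n in self.nodes if indeg[n] == 0]
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for p, c in sorted(self.edges):
                if p == n:
                    indeg[c] -= 1
                    if indeg[c] == 0:
                        ready.append(c)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order


@dataclass
class Cpdag:
    """Completed partially directed acyclic graph (Markov equivalence class)."""

    nodes: list[str]
    directed_edges: set[tuple[str, str]] = field(default_factory=set)
    undirected_edges: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for e in self.directed_edges:
            if frozenset(e) in self.undirected_edges:
                raise ValueError(f"edge {e} both directed and undirected")

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.directed_edges} | set(self.undirected_edges)

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Colliders x -> z <- y with x, y non-adjacent, as (x, z, y), x < y."""
        skel = self.skeleton()
        out = set()
        for (a, z1), (b, z2) in itertools.combinations(sorted(self.directed_edges), 2):
            if z1 == z2 and frozenset((a, b)) not in skel:
                x, y = sorted((a, b))
                out.add((x, z1, y))
        return out


# ---------------------------------------------------------------------------
# Data encoding and scoring
# ---------------------------------------------------------------------------

def to_observations(matrix: DiscreteStateMatrix) -> pd.DataFrame:
    """Transpose a pathways x experiments state matrix to observations x nodes."""
    frame = matrix.frame.T
    if frame.isna().to_numpy().any():
        raise ValueError("network data must have no missing cells")
    return frame


def _encode(data: pd.DataFrame) -> np.ndarray:
    arr = data.to_numpy(dtype=float)
    if not np.isin(arr, (-1.0, 0.0, 1.0)).all():
        raise ValueError("network data must be trinary (-1, 0, +1)")
    return (arr + 1).astype(np.int64)  # states -1,0,+1 -> codes 0,1,2


class BicScorer:
    """Cached per-family BIC scores for trinary data (natural-log scale)."""

    def __init__(self, data: pd.DataFrame):
        self.nodes = list(data.columns)
        self._col = {n: i for i, n in enumerate(self.nodes)}
        self.codes = _encode(data)
        self.m = self.codes.shape[0]
        if self.m < 1:
            raise ValueError("need at least one observation")
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local_score(self, node: str, parents: Iterable[str]) -> float:
        """Penalized family score: max log-likelihood - ((r-1)q/2) ln M."""
        ni = self._col[node]
        pis = tuple(sorted(self._col[p] for p in parents))
        key = (ni, pis)
        if key in self._cache:
            return self._cache[key]
        k = len(pis)
        q = CARD ** k
        config = np.zeros(self.m, dtype=np.int64)
        for pi in pis:
            config = config * CARD + self.codes[:, pi]
        joint = config * CARD + self.codes[:, ni]
        counts = np.bincount(joint, minlength=q * CARD).reshape(q, CARD)
        nij = counts.sum(axis=1, keepdims=True)
        nz = counts > 0
        ll = float((counts[nz] * np.log(counts[nz] / np.broadcast_to(nij, counts.shape)[nz])).sum())
        score = ll - 0.5 * (CARD - 1) * q * math.log(self.m)
        self._cache[key] = score
        return score


def bic_score(dag: Dag, data: pd.DataFrame | DiscreteStateMatrix) -> float:
    """Total BIC of a DAG on observations x nodes data (decomposable over families)."""
    if isinstance(data, DiscreteStateMatrix):
        data = to_observations(data)
    if set(dag.nodes) != set(data.columns):
        raise ValueError("DAG nodes and data columns differ")
    scorer = BicScorer(data)
    return sum(scorer.local_score(n, dag.parents(n)) for n in dag.nodes)


# ---------------------------------------------------------------------------
# PDAG utilities
# ---------------------------------------------------------------------------

def _pdag_to_dag(
    nodes: Sequence[str],
    pa: Mapping[str, set[str]],
    und: Mapping[str, set[str]],
) -> dict[str, set[str]]:
    """Consistent DAG extension of a PDAG (Dor & Tarsi).

    Eligible nodes are consumed in reverse-lexicographic order, so of an
    undirected pair the later node becomes the sink (A—B becomes A→B).
    Raises :class:`NotExtendableError` when no extension exists.
    """
    pa = {n: set(pa[n]) for n in nodes}
    und = {n: set(und[n]) for n in nodes}
    ch: dict[str, set[str]] = {n: set() for n in nodes}
    for c, ps in pa.items():
        for p in ps:
            ch[p].add(c)
    out_pa = {n: set(pa[n]) for n in nodes}
    remaining = set(nodes)
    while remaining:
        chosen = None
        for x in sorted(remaining, reverse=True):
            if ch[x] & remaining:
                continue
            adj_x = (pa[x] | und[x]) & remaining
            ok = True
            for y in und[x] & remaining:
                adj_y = pa[y] | ch[y] | und[y]
                if not (adj_x - {y} <= adj_y):
                    ok = False
                    break
            if ok:
                chosen = x
                break
        if chosen is None:
            raise NotExtendableError("PDAG admits no consistent extension")
        for y in und[chosen] & remaining:
            out_pa[chosen].add(y)
            und[y].discard(chosen)
        for p in pa[chosen] & remaining:
            ch[p].discard(chosen)
        und[chosen] = set()
        remaining.discard(chosen)
    return out_pa


def _dag_to_cpdag(
    nodes: Sequence[str], pa: Mapping[str, set[str]]
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """CPDAG of a DAG: keep v-structure edges directed, close under Meek rules."""
    directed: set[tuple[str, str]] = set()
    skel: set[frozenset[str]] = set()
    for c, ps in pa.items():
        for p in ps:
            skel.add(frozenset((p, c)))
    for c in nodes:
        for x, y in itertools.combinations(sorted(pa[c]), 2):
            if frozenset((x, y)) not in skel:
                directed.add((x, c))
                directed.add((y, c))
    und = {e for e in skel if not _covered(e, directed)}
    return _meek_closure(nodes, directed, und)


def _covered(edge: frozenset[str], directed: set[tuple[str, str]]) -> bool:
    a, b = tuple(edge)
    return (a, b) in directed or (b, a) in directed


def _meek_closure(
    nodes: Sequence[str],
    directed: set[tuple[str, str]],
    und: set[frozenset[str]],
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    directed = set(directed)
    und = set(und)

    def adjacent(a: str, b: str) -> bool:
        return (a, b) in directed or (b, a) in directed or frozenset((a, b)) in und

    changed = True
    while changed:
        changed = False
        for e in sorted(und, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # R1: w -> x, x - y, w and y non-adjacent  =>  x -> y
                if any((w, x) in directed and not adjacent(w, y) for w in nodes if w != y):
                    directed.add((x, y))
                    und.discard(e)
                    changed = True
                    break
                # R2: x -> w -> y and x - y  =>  x -> y
                if any((x, w) in directed and (w, y) in directed for w in nodes):
                    directed.add((x, y))
                    und.discard(e)
                    changed = True
                    break
                # R3: x - c, x - d, c -> y, d -> y, c and d non-adjacent  =>  x -> y
                r3 = False
                for c, d in itertools.combinations(sorted(nodes), 2):
                    if (
                        frozenset((x, c)) in und
                        and frozenset((x, d)) in und
                        and (c, y) in directed
                        and (d, y) in directed
                        and not adjacent(c, d)
                    ):
                        r3 = True
                        break
                if r3:
                    directed.add((x, y))
                    und.discard(e)
                    changed = True
                    break
            if changed:
                break
    pa: dict[str, set[str]] = {n: set() for n in nodes}
    und_adj: dict[str, set[str]] = {n: set() for n in nodes}
    for p, c in directed:
        pa[c].add(p)
    for e in und:
        a, b = tuple(e)
        und_adj[a].add(b)
        und_adj[b].add(a)
    return pa, und_adj


def cpdag_to_dag(cpdag: Cpdag) -> Dag:
    """A consistent DAG extension of a CPDAG (deterministic; see `_pdag_to_dag`)."""
    pa: dict[str, set[str]] = {n: set() for n in cpdag.nodes}
    und: dict[str, set[str]] = {n: set() for n in cpdag.nodes}
    for p, c in cpdag.directed_edges:
        pa[c].add(p)
    for e in cpdag.undirected_edges:
        a, b = tuple(e)
        und[a].add(b)
        und[b].add(a)
    out_pa = _pdag_to_dag(cpdag.nodes, pa, und)
    edges = {(p, c) for c, ps in out_pa.items() for p in ps}
    return Dag(list(cpdag.nodes), edges)


# ---------------------------------------------------------------------------
# Greedy Equivalence Search
# ---------------------------------------------------------------------------

_GAIN_EPS = 1e-10


class _GesState:
    def __init__(self, nodes: Sequence[str], scorer: BicScorer, max_parents: int | None):
        self.nodes = list(nodes)
        self.scorer = scorer
        self.max_parents = max_parents if max_parents is not None else len(nodes)
        self.pa: dict[str, set[str]] = {n: set() for n in nodes}
        self.und: dict[str, set[str]] = {n: set() for n in nodes}

    # --- structural helpers -------------------------------------------------
    def ch(self, x: str) -> set[str]:
        return {c for c, ps in self.pa.items() if x in ps}

    def adj(self, x: str) -> set[str]:
        return self.pa[x] | self.ch(x) | self.und[x]

    def na(self, y: str, x: str) -> set[str]:
        """Undirected neighbours of y that are adjacent to x."""
        return {t for t in self.und[y] if t in self.adj(x)}

    def is_clique(self, s: set[str]) -> bool:
        return all(b in self.adj(a) for a, b in itertools.combinations(s, 2))

    def blocked_semi_directed(self, y: str, x: str, block: set[str]) -> bool:
        """True when every semi-directed path y ~> x passes through ``block``."""
        seen = {y} | block
        frontier = [y] if y not in block else []
        while frontier:
            u = frontier.pop()
            for v in self.ch(u) | self.und[u]:
                if v == x:
                    return False
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        return True

    # --- operator enumeration ----------------------------------------------
    def best_insert(self) -> tuple[float, tuple] | None:
        best: tuple[float, tuple] | None = None
        for y in sorted(self.nodes):
            for x in sorted(self.nodes):
                if x == y or x in self.adj(y):
                    continue
                na = self.na(y, x)
                t0 = sorted(self.und[y] - self.adj(x))
                for size in range(len(t0) + 1):
                    for t in itertools.combinations(t0, size):
                        s = na | set(t)
                        new_parents = self.pa[y] | s
                        if len(new_parents) + 1 > self.max_parents:
                            continue
                        if not self.is_clique(s):
                            continue
                        if not self.blocked_semi_directed(y, x, s):
                            continue
                        gain = self.scorer.local_score(y, new_parents | {x}) - \
                            self.scorer.local_score(y, new_parents)
                        cand = (gain, (x, y, t))
                        if best is None or _better(cand, best):
                            best = cand
        return best

    def apply_insert(self, x: str, y: str, t: tuple[str, ...]) -> None:
        self.pa[y].add(x)
        for u in t:
            self.und[y].discard(u)
            self.und[u].discard(y)
            self.pa[y].add(u)
        self._rebuild_cpdag()

    def best_delete(self) -> tuple[float, tuple] | None:
        best: tuple[float, tuple] | None = None
        for y in sorted(self.nodes):
            for x in sorted(self.pa[y] | self.und[y]):
                na = self.na(y, x)
                h0 = sorted(na)
                for size in range(len(h0) + 1):
                    for h in itertools.combinations(h0, size):
                        if not self.is_clique(na - set(h)):
                            continue
                        pa_plus = self.pa[y] | {x}
                        keep = (na - set(h))
                        gain = self.scorer.local_score(y, keep | (pa_plus - {x})) - \
                            self.scorer.local_score(y, keep | pa_plus)
                        cand = (gain, (x, y, h))
                        if best is None or _better(cand, best):
                            best = cand
        return best

    def apply_delete(self, x: str, y: str, h: tuple[str, ...]) -> None:
        self.pa[y].discard(x)
        self.und[y].discard(x)
        self.und[x].discard(y)
        for u in h:
            self.und[y].discard(u)
            self.und[u].discard(y)
            self.pa[u].add(y)
            if u in self.und[x]:
                self.und[x].discard(u)
                self.und[u].discard(x)
                self.pa[u].add(x)
        self._rebuild_cpdag()

    def _rebuild_cpdag(self) -> None:
        dag_pa = _pdag_to_dag(self.nodes, self.pa, self.und)
        self.pa, self.und = _dag_to_cpdag(self.nodes, dag_pa)

    def to_cpdag(self) -> Cpdag:
        directed = {(p, c) for c, ps in self.pa.items() for p in ps}
        und = {frozenset((a, b)) for a, nbrs in self.und.items() for b in nbrs}
        return Cpdag(list(self.nodes), directed, und)


def _better(cand: tuple[float, tuple], best: tuple[float, tuple]) -> bool:
    if cand[0] > best[0] + _GAIN_EPS:
        return True
    if cand[0] < best[0] - _GAIN_EPS:
        return False
    return cand[1] < best[1]  # lexicographic (x, y, set) tie rule


def ges(
    data: pd.DataFrame | DiscreteStateMatrix,
    max_parents: int | None = 4,
) -> Cpdag:
    """Greedy Equivalence Search over trinary data (observations x nodes).

    Forward phase: repeatedly apply the valid single-edge insertion with the
    largest positive BIC gain.  Backward phase: repeatedly apply the best
    score-improving deletion.  Deterministic: ties go to the
    lexicographically smallest (parent, child, subset) move.  ``max_parents``
    caps family sizes (with 3-state nodes, five parents already exceed one
    free parameter per pathway-scale observation).
    """
    if isinstance(data, DiscreteStateMatrix):
        data = to_observations(data)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    scorer = BicScorer(data)
    state = _GesState(list(data.columns), scorer, max_parents)
    while True:
        best = state.best_insert()
        if best is None or best[0] <= _GAIN_EPS:
            break
        state.apply_insert(*best[1])
    while True:
        best = state.best_delete()
        if best is None or best[0] <= _GAIN_EPS:
            break
        state.apply_delete(*best[1])
    return state.to_cpdag()


# ---------------------------------------------------------------------------
# Parameter fitting and link strength
# ---------------------------------------------------------------------------

@dataclass
class BayesianNetworkModel:
    """DAG plus conditional probability tables over trinary nodes.

    ``cpts[node]`` has axes ``(node, parent_1, ..., parent_k)`` with parents
    in ``parents[node]`` order and states ordered (-1, 0, +1) on every axis.
    """

    dag: Dag
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    states: tuple[int, int, int] = STATES

    def __post_init__(self) -> None:
        for n in self.dag.nodes:
            t = self.cpts[n]
            if t.shape != (CARD,) * (1 + len(self.parents[n])):
                raise ValueError(f"CPT shape mismatch for {n!r}")
            col_sums = t.sum(axis=0)
            if not np.allclose(col_sums, 1.0, atol=1e-12):
                raise ValueError(f"CPT columns of {n!r} do not sum to 1")
            if (t < -1e-15).any() or (t > 1 + 1e-15).any():
                raise ValueError(f"CPT of {n!r} outside [0, 1]")

    def factors(self) -> list[Factor]:
        return [Factor((n, *self.parents[n]), self.cpts[n]) for n in self.dag.nodes]

    def joint_marginal(self, keep: Sequence[str]) -> Factor:
        """Exact joint marginal over ``keep`` by variable elimination."""
        f = eliminate(self.factors(), keep)
        out_order = tuple(k for k in keep if k in f.variables)
        perm = [f.variables.index(v) for v in out_order]
        return Factor(out_order, np.transpose(f.table, perm)).normalize()


@dataclass(frozen=True)
class LinkStrength:
    parent: str
    child: str
    percent: float


def fit_cpts(
    dag: Dag,
    data: pd.DataFrame | DiscreteStateMatrix,
    pseudocount: float = 1.0,
) -> BayesianNetworkModel:
    """Fit CPTs by (Laplace-smoothed) relative frequencies.

    Entry = (count + pseudocount) / (config_total + 3 * pseudocount); with
    ``pseudocount=0`` unseen parent configurations fall back to uniform.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if isinstance(data, DiscreteStateMatrix):
        data = to_observations(data)
    codes = _encode(data[list(dag.nodes)])
    col = {n: i for i, n in enumerate(dag.nodes)}
    parents = {n: dag.parents(n) for n in dag.nodes}
    cpts: dict[str, np.ndarray] = {}
    for n in dag.nodes:
        ps = parents[n]
        k = len(ps)
        config = np.zeros(codes.shape[0], dtype=np.int64)
        for p in ps:
            config = config * CARD + codes[:, col[p]]
        joint = config * CARD + codes[:, col[n]]
        counts = np.bincount(joint, minlength=CARD ** (k + 1)).astype(float)
        counts = counts.reshape((CARD,) * k + (CARD,))
        counts = np.moveaxis(counts, -1, 0)  # child axis first
        totals = counts.sum(axis=0)
        denom = totals + CARD * pseudocount
        with np.errstate(invalid="ignore", divide="ignore"):
            cpt = (counts + pseudocount) / denom
        cpt = np.where(denom > 0, cpt, 1.0 / CARD)  # unseen config, no smoothing
        cpts[n] = cpt
    return BayesianNetworkModel(dag=dag, parents=parents, cpts=cpts)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def link_strength(
    model: BayesianNetworkModel,
    parent: str,
    child: str,
    mode: str = "marginal",
) -> LinkStrength:
    """Entropy-reduction strength of a DAG edge, as a percentage.

    ``mode="marginal"`` (default) uses the pairwise model-implied joint of
    (parent, child), other variables marginalized out.  ``mode="conditional"``
    conditions on the child's co-parents instead (average over their joint).
    By convention the strength is 0 when the child's (conditional) entropy
    is 0.
    """
    if (parent, child) not in model.dag.edges:
        raise ValueError(f"({parent!r}, {child!r}) is not an edge of the model")
    if mode == "marginal":
        joint = model.joint_marginal((parent, child)).table
        h_child = _entropy_bits(joint.sum(axis=0))
        if h_child == 0:
            return LinkStrength(parent, child, 0.0)
        h_joint = _entropy_bits(joint.ravel())
        h_parent = _entropy_bits(joint.sum(axis=1))
        h_cond = h_joint - h_parent
        pct = 100.0 * (h_child - h_cond) / h_child
    elif mode == "conditional":
        co = tuple(p for p in model.parents[child] if p != parent)
        order = (child, parent) + co
        joint = model.joint_marginal(order).table
        h_all = _entropy_bits(joint.ravel())
        h_pc = _entropy_bits(joint.sum(axis=0).ravel())          # H(parent, co)
        h_c_co = _entropy_bits(joint.sum(axis=1).ravel())        # H(child, co)
        h_co = _entropy_bits(joint.sum(axis=(0, 1)).ravel())     # H(co)
        h_child_given_co = h_c_co - h_co
        if h_child_given_co == 0:
            return LinkStrength(parent, child, 0.0)
        h_child_given_pc = h_all - h_pc
        pct = 100.0 * (h_child_given_co - h_child_given_pc) / h_child_given_co
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return LinkStrength(parent, child, float(min(100.0, max(0.0, pct))))


def all_link_strengths(model: BayesianNetworkModel, mode: str = "marginal") -> list[LinkStrength]:
    return [link_strength(model, p, c, mode=mode) for p, c in sorted(model.dag.edges)]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_model(model: BayesianNetworkModel, path: str | Path) -> None:
    doc = {
        "nodes": model.dag.nodes,
        "states": list(model.states),
        "edges": sorted(model.dag.edges),
        "cpts": {
            n: {
                "parents": list(model.parents[n]),
                "table": model.cpts[n].ravel().tolist(),
            }
            for n in model.dag.nodes
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_model(path: str | Path) -> BayesianNetworkModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    dag = Dag(doc["nodes"], {tuple(e) for e in doc["edges"]})
    parents = {}
    cpts = {}
    for n, entry in doc["cpts"].items():
        ps = tuple(entry["parents"])
        parents[n] = ps
        cpts[n] = np.array(entry["table"], float).reshape((CARD,) * (1 + len(ps)))
    return BayesianNetworkModel(dag=dag, parents=parents, cpts=cpts)
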