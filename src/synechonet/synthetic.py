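"""Synthetic compendia with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a multi-laboratory
expression compendium: experiments with 2-8 replicates, a planted set of
"core" genes shifted (random sign) in most experiments, condition-specific
background genes shifted in few, regulator-target pairs whose trinary
patterns agree at a stated rate, and pathway member genes whose shifts
follow pathway states sampled from a known ground-truth Bayesian network.
Replicate noise is Gaussian by default; a heavy-tailed mode (scaled t with
3 df) exists to stress the discretizer.  Every generator is a pure
function of its seed and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import io as cio
from ._factors import CARD
from .bayesnet import BayesianNetworkModel, Dag, write_model
from .io import DiscreteStateMatrix, ExpressionCompendium, GeneAnnotation

_STATE_OF_CODE = np.array([-1, 0, 1])


@dataclass
class GroundTruthLedger:
    """Everything needed to score recovery of the planted structure."""

    planted_core_genes: set[str]
    core_active_fraction: float
    background_active_fraction: float
    regulator_pairs: list[tuple[str, str, float]]  # (regulator, target, agreement)
    true_network: BayesianNetworkModel
    planted_pathway_states: DiscreteStateMatrix
    planted_gene_states: DiscreteStateMatrix
    effect_size: float
    noise_sd: float
    seed: int
    annotations: dict[str, GeneAnnotation] = field(default_factory=dict)
    membership: dict[str, set[str]] = field(default_factory=dict)


def random_network(
    n_nodes: int,
    edge_prob: float = 0.3,
    coupling: float = 0.85,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> BayesianNetworkModel:
    """A random trinary Bayesian network with parent-agreement CPTs.

    Nodes are ordered and each forward pair is an edge with ``edge_prob``.
    Root priors are uniform; a child matches the majority state of its
    parents with probability ``coupling`` (remaining mass split evenly over
    the other two states).  Ties in the parent majority resolve toward 0,
    then -1, then +1.
    """
    if not (0 <= edge_prob <= 1):
        raise ValueError("edge_prob must be in [0, 1]")
    if not (0 < coupling < 1 or coupling == 1.0):
        raise ValueError("coupling must be in (0, 1]")
    rng = np.random.default_rng(seed)
    nodes = list(names) if names is not None else [f"P{i + 1:02d}" for i in range(n_nodes)]
    edges = {
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    }
    dag = Dag(nodes, edges)
    parents = {n: dag.parents(n) for n in nodes}
    cpts: dict[str, np.ndarray] = {}
    for n in nodes:
        k = len(parents[n])
        if k == 0:
            cpts[n] = np.full((CARD,), 1.0 / CARD)
            continue
        table = np.empty((CARD,) + (CARD,) * k)
        for config in np.ndindex(*(CARD,) * k):
            maj = _majority_state(config)
            col = np.full(CARD, (1.0 - coupling) / 2.0)
            col[maj] = coupling
            table[(slice(None),) + config] = col
        cpts[n] = table
    return BayesianNetworkModel(dag=dag, parents=parents, cpts=cpts)


def _majority_state(config: tuple[int, ...]) -> int:
    counts = np.bincount(config, minlength=CARD)
    best = counts.max()
    for idx in (1, 0, 2):  # prefer 0, then -1, then +1 on ties
        if counts[idx] == best:
            return idx
    raise AssertionError


def sample_pathway_states(
    model: BayesianNetworkModel,
    n_experiments: int,
    seed: int = 0,
) -> DiscreteStateMatrix:
    """Ancestral samples from the network; one column per experiment."""
    rng = np.random.default_rng(seed)
    order = model.dag.topological_order()
    codes: dict[str, np.ndarray] = {}
    for node in order:
        ps = model.parents[node]
        cpt = model.cpts[node]
        if not ps:
            probs = np.broadcast_to(cpt, (n_experiments, CARD))
        else:
            idx = tuple(codes[p] for p in ps)
            probs = np.moveaxis(cpt, 0, -1)[idx]
        u = rng.random(n_experiments)
        cum = probs.cumsum(axis=1)
        codes[node] = (u[:, None] > cum).sum(axis=1)
    experiments = [f"e{j + 1:03d}" for j in range(n_experiments)]
    arr = np.vstack([_STATE_OF_CODE[codes[n]] for n in model.dag.nodes]).astype(float)
    return DiscreteStateMatrix(
        pd.DataFrame(arr, index=list(model.dag.nodes), columns=experiments)
    )


def generate_compendium(
    n_genes: int = 3000,
    n_experiments: int = 60,
    n_core: int = 150,
    core_active_fraction: float = 0.7,
    background_active_fraction: float = 0.1,
    n_regulators: int = 5,
    targets_per_regulator: int = 4,
    regulator_agreement: float = 0.8,
    regulator_active_fraction: float = 0.5,
    network: BayesianNetworkModel | None = None,
    n_pathways: int = 12,
    genes_per_pathway: int = 8,
    membership: Mapping[str, set[str]] | None = None,
    effect_size: float = 2.0,
    noise_sd: float = 0.3,
    replicate_range: tuple[int, int] = (2, 8),
    plasmid_fraction: float = 0.05,
    heavy_tails: bool = False,
    seed: int = 0,
) -> tuple[ExpressionCompendium, GroundTruthLedger]:
    """Generate a compendium with planted core, regulator and pathway structure.

    Gene roles are disjoint blocks: pathway members first, then regulators
    and their targets, then core genes; the remainder is background, a
    ``plasmid_fraction`` of which is annotated as plasmid-encoded.  Each
    (gene, experiment) cell's replicates are drawn around
    ``effect_size * planted_state`` with scale ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    experiments = [f"e{j + 1:03d}" for j in range(n_experiments)]

    if network is None:
        network = random_network(n_pathways, edge_prob=0.3, coupling=0.85,
                                 seed=int(rng.integers(2 ** 31)))
    pathway_states = sample_pathway_states(
        network, n_experiments, seed=int(rng.integers(2 ** 31))
    )
    pathway_states.frame.columns = experiments

    if membership is None:
        membership = {}
        gi = 0
        for pw in network.dag.nodes:
            membership[pw] = {genes[gi + k] for k in range(genes_per_pathway)}
            gi += genes_per_pathway
    member_genes = sorted({g for ms in membership.values() for g in ms})
    if not set(member_genes) <= set(genes):
        raise ValueError("membership references genes outside the compendium")
    n_member = len(member_genes)
    n_targets = n_regulators * targets_per_regulator
    if n_member + n_regulators + n_targets + n_core > n_genes:
        raise ValueError("gene roles overlap: too few genes for the requested structure")
    pool = [g for g in genes if g not in set(member_genes)]
    regulators = pool[:n_regulators]
    targets = pool[n_regulators:n_regulators + n_targets]
    core = pool[n_regulators + n_targets:n_regulators + n_targets + n_core]
    background = pool[n_regulators + n_targets + n_core:]
    regulator_pairs = [
        (regulators[r], targets[r * targets_per_regulator + t], regulator_agreement)
        for r in range(n_regulators)
        for t in range(targets_per_regulator)
    ]
    gene_pathway = {}
    for pw in membership:
        for g in membership[pw]:
            gene_pathway.setdefault(g, pw)  # first listed pathway generates the signal

    # planted trinary state per (gene, experiment)
    E = n_experiments
    planted = np.zeros((n_genes, E))
    gidx = {g: i for i, g in enumerate(genes)}
    pw_arr = pathway_states.frame.to_numpy(float)
    pw_row = {pw: i for i, pw in enumerate(pathway_states.rows)}
    for g in member_genes:
        planted[gidx[g]] = pw_arr[pw_row[gene_pathway[g]]]
    for g in core:
        active = rng.random(E) < core_active_fraction
        signs = rng.choice((-1.0, 1.0), size=E)
        planted[gidx[g]] = np.where(active, signs, 0.0)
    reg_profile: dict[str, np.ndarray] = {}
    for g in regulators:
        active = rng.random(E) < regulator_active_fraction
        signs = rng.choice((-1.0, 1.0), size=E)
        reg_profile[g] = np.where(active, signs, 0.0)
        planted[gidx[g]] = reg_profile[g]
    for reg, tgt, agree in regulator_pairs:
        copy = rng.random(E) < agree
        other = np.array([
            rng.choice([s for s in (-1.0, 0.0, 1.0) if s != v]) for v in reg_profile[reg]
        ])
        planted[gidx[tgt]] = np.where(copy, reg_profile[reg], other)
    for g in background:
        active = rng.random(E) < background_active_fraction
        signs = rng.choice((-1.0, 1.0), size=E)
        planted[gidx[g]] = np.where(active, signs, 0.0)

    lo, hi = replicate_range
    reps_per_exp = rng.integers(lo, hi + 1, size=E)
    values: dict[tuple[str, str], tuple[float, ...]] = {}
    for j, e in enumerate(experiments):
        r = int(reps_per_exp[j])
        if heavy_tails:
            noise = rng.standard_t(3, size=(n_genes, r)) * (noise_sd / np.sqrt(3.0))
        else:
            noise = rng.normal(0.0, noise_sd, size=(n_genes, r))
        block = effect_size * planted[:, j:j + 1] + noise
        for i, g in enumerate(genes):
            values[(g, e)] = tuple(float(v) for v in block[i])
    compendium = ExpressionCompendium(genes, experiments, values)

    n_plasmid = int(round(plasmid_fraction * n_genes))
    plasmid = set(background[-n_plasmid:]) if n_plasmid else set()
    annotations = {}
    for g in genes:
        if g in gene_pathway:
            category = gene_pathway[g]
        elif g in set(core):
            category = "core"
        else:
            category = "unknown"
        annotations[g] = GeneAnnotation(
            gene=g,
            replicon="plasmid" if g in plasmid else "chromosome",
            category=category,
            is_regulatory=g in set(regulators),
        )

    ledger = GroundTruthLedger(
        planted_core_genes=set(core),
        core_active_fraction=core_active_fraction,
        background_active_fraction=background_active_fraction,
        regulator_pairs=regulator_pairs,
        true_network=network,
        planted_pathway_states=pathway_states,
        planted_gene_states=DiscreteStateMatrix(
            pd.DataFrame(planted, index=genes, columns=experiments)
        ),
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
        annotations=annotations,
        membership={pw: set(ms) for pw, ms in membership.items()},
    )
    return compendium, ledger


def generate_upstream_fasta(
    genes: Sequence[str],
    motif: str = "TTATAATNATTATAA",
    carrier_genes: Sequence[str] = (),
    length: int = 300,
    seed: int = 0,
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Random upstream sequences, with the motif embedded in carrier genes.

    Returns the records and a map of carrier gene -> 0-based offset of the
    planted instance (ambiguity codes resolved uniformly at random).
    """
    if length < len(motif):
        raise ValueError("sequence length shorter than the motif")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    carriers = set(carrier_genes)
    if not carriers <= set(genes):
        raise ValueError("carrier genes must be a subset of genes")
    from .core_response import IUPAC

    records: list[SeqRecord] = []
    offsets: dict[str, int] = {}
    for g in genes:
        seq = rng.choice(bases, size=length)
        if g in carriers:
            off = int(rng.integers(0, length - len(motif) + 1))
            instance = [
                ch if ch in "ACGT" else str(rng.choice(list(IUPAC[ch])))
                for ch in motif.upper()
            ]
            seq[off:off + len(motif)] = instance
            offsets[g] = off
        records.append(SeqRecord(Seq("".join(seq)), id=g, description=""))
    return records, offsets


def write_dataset(outdir: str | Path, compendium: ExpressionCompendium,
                  ledger: GroundTruthLedger) -> Path:
    """Emit the generated dataset in the pipeline's input formats.

    Writes compendium.tsv, annotations.tsv, membership.tsv, the planted
    pathway/gene state matrices, the true network, and a ledger.json of the
    scalar parameters.  Byte-identical for identical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_compendium(compendium, outdir / "compendium.tsv")
    cio.write_annotations(ledger.annotations, outdir / "annotations.tsv")
    cio.write_membership(ledger.membership, outdir / "membership.tsv")
    cio.write_state_matrix(ledger.planted_pathway_states, outdir / "planted_pathway_states.tsv")
    cio.write_state_matrix(ledger.planted_gene_states, outdir / "planted_gene_states.tsv")
    write_model(ledger.true_network, outdir / "true_network.json")
    scalars = {
        "planted_core_genes": sorted(ledger.planted_core_genes),
        "core_active_fraction": ledger.core_active_fraction,
        "background_active_fraction": ledger.background_active_fraction,
        "regulator_pairs": ledger.regulator_pairs,
        "effect_size": ledger.effect_size,
        "noise_sd": ledger.noise_sd,
        "seed": ledger.seed,
    }
    (outdir / "ledger.json").write_text(json.dumps(scalars, indent=1), encoding="utf-8")
    return outdir
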