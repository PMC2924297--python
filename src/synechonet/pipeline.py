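"""End-to-end orchestration of the integrative transcriptome analysis.

Stages: discretize -> core transcriptional response -> coregulation network
-> pathway states -> pathway selection -> structure learning (GES) -> CPT
fitting -> link strengths -> perturbation scenarios (optional) -> motif
survey (optional).  Every intermediate artifact is written as TSV/JSON
under the run directory together with a manifest; re-running an identical
config on identical inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import __version__
from . import io as cio
from .bayesnet import all_link_strengths, cpdag_to_dag, fit_cpts, ges, to_observations, write_model
from .config import PipelineConfig
from .core_response import (
    coregulation_network,
    greedy_regulator_cover,
    identify_ctr,
    regulation_frequency,
    scan_consensus,
    summarize_ctr,
)
from .discretize import discretize_compendium
from .errors import SynechonetError
from .pathway_state import build_pathway_state_matrix, select_pathways

log = logging.getLogger("synechonet")


class StageError(SynechonetError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    counts: dict[str, int] = {}

    def stage(name: str):
        log.info("stage %s", name)
        return name

    try:
        name = stage("read_inputs")
        compendium = cio.read_compendium(config.compendium)
        annotations = cio.read_annotations(config.annotations)
        membership = cio.read_membership(config.membership)
        counts["genes_total"] = len(compendium.genes)
        counts["experiments"] = len(compendium.experiments)

        name = stage("filter_chromosomal")
        chromosomal = cio.filter_chromosomal(compendium, annotations)
        counts["genes_chromosomal"] = len(chromosomal.genes)

        name = stage("discretize")
        disc = discretize_compendium(
            chromosomal,
            alpha=config.alpha,
            min_replicates=config.min_replicates,
            scale_strategy=config.scale_strategy,  # type: ignore[arg-type]
        )
        cio.write_state_matrix(disc.states, outdir / "gene_states.tsv")
        (outdir / "under_replicated.txt").write_text(
            "\n".join(disc.under_replicated) + ("\n" if disc.under_replicated else ""),
            encoding="utf-8",
        )
        gene_level = disc.states.drop_columns(disc.under_replicated)
        counts["experiments_gene_level"] = len(gene_level.columns)

        name = stage("ctr")
        freqs = regulation_frequency(gene_level)
        ctr = identify_ctr(gene_level, threshold=config.ctr_threshold, strict=config.ctr_strict)
        summary = summarize_ctr(len(ctr), len(chromosomal.genes))
        lines = ["gene\tn_regulated\tn_observed\tfraction\tin_ctr"]
        ctr_set = set(ctr)
        for rf in freqs:
            f = "" if rf.fraction is None else f"{rf.fraction:.6f}"
            lines.append(
                f"{rf.gene}\t{rf.n_regulated}\t{rf.n_observed}\t{f}\t{str(rf.gene in ctr_set).lower()}"
            )
        (outdir / "ctr.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        (outdir / "ctr_summary.json").write_text(
            json.dumps(
                {"n_ctr": summary.n_ctr, "n_chromosomal": summary.n_chromosomal,
                 "percent": summary.percent},
                indent=1,
            ),
            encoding="utf-8",
        )
        counts["ctr_genes"] = len(ctr)

        name = stage("coregulation")
        regulators = [g for g in gene_level.rows if annotations[g].is_regulatory]
        edges = coregulation_network(
            gene_level, regulators, ctr, cutoff=config.coregulation_cutoff
        ) if regulators and ctr else []
        lines = ["regulator\ttarget\tagreement\tn_compared"]
        for e in edges:
            lines.append(f"{e.regulator}\t{e.target}\t{e.agreement:.6f}\t{e.n_compared}")
        (outdir / "coregulation_edges.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        cover, cover_frac = greedy_regulator_cover(edges, ctr) if edges else ([], 0.0)
        (outdir / "regulator_cover.json").write_text(
            json.dumps({"regulators": cover, "covered_fraction": cover_frac}, indent=1),
            encoding="utf-8",
        )
        counts["coregulation_edges"] = len(edges)

        name = stage("pathway_states")
        pw_matrix = build_pathway_state_matrix(
            chromosomal, membership, alpha=config.alpha,
            pooling=config.pooling,  # type: ignore[arg-type]
        )
        cio.write_state_matrix(pw_matrix, outdir / "pathway_states.tsv")
        counts["pathways"] = len(pw_matrix.rows)

        name = stage("select_pathways")
        reports = select_pathways(
            pw_matrix, membership, min_genes=config.min_genes, min_frac=config.min_frac
        )
        lines = ["pathway\tn_genes\tfrac_regulated\tselected"]
        for r in reports:
            lines.append(
                f"{r.pathway}\t{r.n_genes}\t{r.frac_regulated:.6f}\t{str(r.selected).lower()}"
            )
        (outdir / "pathway_selection.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        selected = [r.pathway for r in reports if r.selected]
        counts["pathways_selected"] = len(selected)

        name = stage("learn_structure")
        if len(selected) < 2:
            raise ValueError(
                f"need at least 2 selected pathways to learn a network, got {len(selected)}"
            )
        sub = cio.DiscreteStateMatrix(pw_matrix.frame.loc[selected])
        data = to_observations(sub)
        cpdag = ges(data, max_parents=config.max_parents)
        lines = ["source\ttarget\tkind"]
        for p, c in sorted(cpdag.directed_edges):
            lines.append(f"{p}\t{c}\tdirected")
        for e in sorted(cpdag.undirected_edges, key=sorted):
            a, b = sorted(e)
            lines.append(f"{a}\t{b}\tundirected")
        (outdir / "cpdag.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        dag = cpdag_to_dag(cpdag)
        counts["network_edges"] = len(dag.edges)

        name = stage("fit_cpts")
        model = fit_cpts(dag, data, pseudocount=config.pseudocount)
        write_model(model, outdir / "model.json")

        name = stage("link_strength")
        strengths = all_link_strengths(model, mode=config.link_strength_mode)
        lines = ["parent\tchild\tpercent"]
        for s in strengths:
            lines.append(f"{s.parent}\t{s.child}\t{s.percent:.4f}")
        (outdir / "link_strengths.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

        name = stage("scenarios")
        if config.scenarios:
            from .inference import scenario_inference

            scen = yaml.safe_load(Path(config.scenarios).read_text(encoding="utf-8")) or {}
            results = scenario_inference(model, scen)
            lines = [
                "scenario\tnode\tP(-1)\tP(0)\tP(+1)\tdP(-1)\tdP(0)\tdP(+1)"
            ]
            for sname in results:
                res = results[sname]
                for node in model.dag.nodes:
                    p = res.posterior[node]
                    d = res.delta[node]
                    lines.append(
                        f"{sname}\t{node}\t" + "\t".join(f"{v:.6f}" for v in (*p, *d))
                    )
            (outdir / "scenarios.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
            counts["scenarios"] = len(results)

        name = stage("motif_survey")
        if config.upstream_fasta:
            from Bio import SeqIO

            records = list(SeqIO.parse(config.upstream_fasta, "fasta"))
            hits = scan_consensus(records)
            lines = ["gene\toffset\tmatched\tstrand"]
            for h in hits:
                lines.append(f"{h.gene}\t{h.offset}\t{h.matched}\t{h.strand}")
            (outdir / "motif_hits.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
            counts["motif_hits"] = len(hits)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(name, exc) from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return outdir


def _setup_logging(outdir: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        log.addHandler(logging.StreamHandler())
    # a run-local log file; replaced per run
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)
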