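"""Pathway-level trinary states from pooled gene-level expression.

For one pathway in one experiment, the per-gene summarized log-ratios of
its member genes are treated as a population and tested against the
zero-mean reference with the same one-sample KS construction used at the
gene level; the sign of the population mean sets the direction.  Pooling
per-gene replicate means (rather than raw replicates) prevents highly
replicated genes from dominating the call; raw pooling is available as a
sensitivity analysis.  Pathway calls use every experiment — a single
replicate still contributes its value to the pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .discretize import ks_state
from .io import DiscreteStateMatrix, ExpressionCompendium


@dataclass(frozen=True)
class PathwaySelectionReport:
    pathway: str
    n_genes: int
    frac_regulated: float
    selected: bool


def pathway_state(member_values: Sequence[float], alpha: float = 0.05) -> int:
    """Trinary state of one pathway in one experiment from pooled member values."""
    vals = [v for v in member_values]
    if len(vals) == 0:
        raise ValueError("empty member-value population")
    return ks_state(vals, alpha=alpha, min_replicates=1).state


def build_pathway_state_matrix(
    compendium: ExpressionCompendium,
    membership: Mapping[str, set[str]],
    alpha: float = 0.05,
    pooling: Literal["means", "raw"] = "means",
) -> DiscreteStateMatrix:
    """Pathways x experiments state matrix from pooled member expression.

    Genes belonging to several pathways contribute to each.  Pathways with
    no member measured anywhere in the compendium are excluded with a
    warning.  Experiments where a pathway has no measured member yield
    state 0 (no evidence of regulation); the result has no missing cells.
    """
    gene_set = set(compendium.genes)
    means = compendium.means_frame() if pooling == "means" else None
    rows: list[str] = []
    arr_rows: list[list[float]] = []
    for pw in membership:
        members = sorted(membership[pw] & gene_set)
        if not members or not any(
            compendium.replicates(g, e) for g in members for e in compendium.experiments
        ):
            warnings.warn(f"pathway {pw!r} has no measured member genes; excluded", stacklevel=2)
            continue
        states = []
        for e in compendium.experiments:
            if pooling == "means":
                pool = means.loc[members, e].dropna().tolist()
            else:
                pool = [v for g in members for v in compendium.replicates(g, e)]
            states.append(float(pathway_state(pool, alpha=alpha)) if pool else 0.0)
        rows.append(pw)
        arr_rows.append(states)
    frame = pd.DataFrame(
        np.array(arr_rows, float).reshape(len(rows), len(compendium.experiments)),
        index=rows,
        columns=list(compendium.experiments),
    )
    return DiscreteStateMatrix(frame)


def select_pathways(
    matrix: DiscreteStateMatrix,
    membership: Mapping[str, set[str]],
    min_genes: int = 3,
    min_frac: float = 0.10,
) -> list[PathwaySelectionReport]:
    """Select pathways for network modelling.

    A pathway is selected when it has at least ``min_genes`` member genes
    and is regulated (state != 0) in at least ``min_frac`` of experiments.
    The report covers every pathway of the matrix, sorted by identifier.
    """
    arr = matrix.frame.to_numpy(float)
    reports = []
    for i, pw in enumerate(matrix.rows):
        n_genes = len(membership.get(pw, ()))
        frac = float((arr[i] != 0).mean()) if arr.shape[1] else 0.0
        reports.append(
            PathwaySelectionReport(
                pathway=pw,
                n_genes=n_genes,
                frac_regulated=frac,
                selected=n_genes >= min_genes and frac >= min_frac,
            )
        )
    return sorted(reports, key=lambda r: r.pathway)
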