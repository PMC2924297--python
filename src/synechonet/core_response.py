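"""Core transcriptional response, regulator coregulation and motif survey.

The core transcriptional response (CTR) is the set of genes called
differentially regulated in more than half of the usable experiments — a
meta-analysis notion of a general stress response that is independent of
any single perturbation.  Coregulation between a regulatory gene and a
target is scored as Hamming agreement between their trinary profiles: the
fraction of experiments (where both are observed) carrying identical
states.  Profiles agreeing in more than 60% of experiments are connected,
a cutoff anchored by the divergently transcribed perR/aphC pair whose
profiles agree in 61% of experiments.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import UndefinedAgreementError
from .io import DiscreteStateMatrix

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

PERR_CONSENSUS = "TTATAATNATTATAA"


@dataclass(frozen=True)
class RegulationFrequency:
    gene: str
    n_regulated: int
    n_observed: int

    @property
    def fraction(self) -> float | None:
        return None if self.n_observed == 0 else self.n_regulated / self.n_observed


@dataclass(frozen=True)
class CoregulationEdge:
    regulator: str
    target: str
    agreement: float
    n_compared: int


@dataclass(frozen=True)
class MotifHit:
    gene: str
    offset: int
    matched: str
    strand: str = "+"


@dataclass(frozen=True)
class CtrSummary:
    n_ctr: int
    n_chromosomal: int
    percent: int


def regulation_frequency(matrix: DiscreteStateMatrix) -> list[RegulationFrequency]:
    """Per-gene regulation counts over non-missing cells."""
    if not matrix.rows or not matrix.columns:
        raise ValueError("state matrix is empty")
    arr = matrix.frame.to_numpy(float)
    observed = ~np.isnan(arr)
    regulated = observed & (arr != 0)
    return [
        RegulationFrequency(g, int(regulated[i].sum()), int(observed[i].sum()))
        for i, g in enumerate(matrix.rows)
    ]


def identify_ctr(
    matrix: DiscreteStateMatrix,
    threshold: float = 0.5,
    strict: bool = True,
) -> list[str]:
    """Genes regulated in more than (or at least) ``threshold`` of observed experiments.

    ``strict=True`` uses a strict inequality ("more than 50%"); genes with no
    observed experiment are never included.
    """
    out = []
    for rf in regulation_frequency(matrix):
        f = rf.fraction
        if f is None:
            continue
        if (f > threshold) if strict else (f >= threshold):
            out.append(rf.gene)
    return out


def summarize_ctr(ctr: int | Iterable[str], n_chromosomal: int) -> CtrSummary:
    """CTR size as a rounded percentage of the chromosomal gene complement."""
    if n_chromosomal <= 0:
        raise ValueError("n_chromosomal must be positive")
    n = ctr if isinstance(ctr, int) else len(list(ctr))
    percent = int(math.floor(100 * n / n_chromosomal + 0.5))
    return CtrSummary(n_ctr=n, n_chromosomal=n_chromosomal, percent=percent)


def agreement(
    profile_a: Sequence[float | int | None],
    profile_b: Sequence[float | int | None],
) -> tuple[float, int]:
    """Hamming agreement between two trinary profiles.

    Positions where either state is missing (None or NaN) are excluded from
    numerator and denominator.  Returns ``(agreement, n_compared)``; equals
    1 - HammingDistance/n_compared.  Symmetric in its arguments.
    """
    a = np.array([np.nan if v is None else float(v) for v in profile_a])
    b = np.array([np.nan if v is None else float(v) for v in profile_b])
    if a.size != b.size:
        raise ValueError("profiles must have equal length")
    both = ~np.isnan(a) & ~np.isnan(b)
    n = int(both.sum())
    if n == 0:
        raise UndefinedAgreementError("profiles share no observed experiment")
    matches = int((a[both] == b[both]).sum())
    return matches / n, n


def coregulation_network(
    matrix: DiscreteStateMatrix,
    regulatory_genes: Iterable[str],
    targets: Iterable[str],
    cutoff: float = 0.6,
) -> list[CoregulationEdge]:
    """All regulator-target pairs whose profiles agree in more than ``cutoff``.

    Self pairs (a regulatory gene that is itself a target) are skipped.
    Pairs with no jointly observed experiment are skipped.  Edges come out
    in matrix row order (regulators outer, targets inner).
    """
    row_pos = {g: i for i, g in enumerate(matrix.rows)}
    regs = _in_matrix_order(regulatory_genes, row_pos, "regulatory genes")
    tgts = _in_matrix_order(targets, row_pos, "targets")
    arr = matrix.frame.to_numpy(float)
    r = arr[[row_pos[g] for g in regs]]
    t = arr[[row_pos[g] for g in tgts]]
    both = ~np.isnan(r)[:, None, :] & ~np.isnan(t)[None, :, :]
    match = (r[:, None, :] == t[None, :, :]) & both
    n_cmp = both.sum(axis=2)
    n_match = match.sum(axis=2)
    edges = []
    for i, rg in enumerate(regs):
        for j, tg in enumerate(tgts):
            if rg == tg or n_cmp[i, j] == 0:
                continue
            agr = n_match[i, j] / n_cmp[i, j]
            if agr > cutoff:
                edges.append(CoregulationEdge(rg, tg, float(agr), int(n_cmp[i, j])))
    return edges


def _in_matrix_order(genes: Iterable[str], row_pos: dict[str, int], what: str) -> list[str]:
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in row_pos]
    if missing:
        raise KeyError(f"{what} absent from state matrix: {', '.join(sorted(missing)[:10])}")
    return sorted(genes, key=row_pos.__getitem__)


def greedy_regulator_cover(
    edges: Iterable[CoregulationEdge],
    targets: Iterable[str],
    coverage: float = 0.85,
) -> tuple[list[str], float]:
    """Greedy set cover: regulators chosen by marginal target coverage.

    Returns the selected regulators (ties broken lexicographically) and the
    fraction of ``targets`` their edges cover; stops once ``coverage`` is
    reached or no regulator adds a new target.
    """
    targets = list(dict.fromkeys(targets))
    by_reg: dict[str, set[str]] = {}
    tset = set(targets)
    for e in edges:
        if e.target in tset:
            by_reg.setdefault(e.regulator, set()).add(e.target)
    covered: set[str] = set()
    chosen: list[str] = []
    while by_reg and targets and len(covered) / len(targets) < coverage:
        # largest marginal gain; ties broken lexicographically
        best = min(sorted(by_reg), key=lambda r: -len(by_reg[r] - covered))
        if not (by_reg[best] - covered):
            break
        covered |= by_reg[best]
        chosen.append(best)
        del by_reg[best]
    frac = len(covered) / len(targets) if targets else 0.0
    return chosen, frac


def _consensus_regex(consensus: str) -> re.Pattern[str]:
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in consensus")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_consensus(
    upstream_sequences: Iterable,
    consensus: str = PERR_CONSENSUS,
    both_strands: bool = False,
) -> list[MotifHit]:
    """Exact IUPAC matches of a consensus in upstream sequences.

    ``upstream_sequences`` is an iterable of Bio.SeqRecord objects or
    ``(gene, sequence)`` pairs.  The scan is forward-strand by default: the
    PerR consensus is its own reverse complement, so a one-strand scan
    already sees both orientations.  ``both_strands=True`` additionally
    scans the reverse complement (for non-palindromic consensi); such hits
    carry ``strand="-"`` with the offset still on the forward coordinate
    of the match start.
    """
    pattern = _consensus_regex(consensus)
    width = len(consensus)
    hits: list[MotifHit] = []
    for rec in upstream_sequences:
        if hasattr(rec, "seq"):
            gene, seq = rec.id, str(rec.seq)
        else:
            gene, seq = rec
        seq = seq.upper()
        if not set(seq) <= set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"{gene}: non-nucleotide characters {bad}")
        for m in pattern.finditer(seq):
            hits.append(MotifHit(gene, m.start(), m.group(1)))
        if both_strands:
            rc = str(Seq(seq).reverse_complement())
            for m in pattern.finditer(rc):
                fwd_off = len(seq) - m.start() - width
                hits.append(MotifHit(gene, fwd_off, m.group(1), strand="-"))
    return hits
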