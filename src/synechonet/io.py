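"""Data model and file formats for expression compendia and derived matrices.

The compendium holds per-gene, per-experiment collections of replicate
log2(treatment/control) ratios.  All on-disk formats are UTF-8,
tab-separated, with "." as decimal separator and the empty string encoding a
missing value.  Replicate columns are grouped per experiment through headers
of the form ``<experiment>.rep<k>``; the replicate index only groups columns
and carries no further meaning.  Gene and experiment order is preserved from
file order so that every derived output is deterministic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

_REP_RE = re.compile(r"^(?P<exp>.+)\.rep(?P<k>\d+)$")

STATES = (-1, 0, 1)


@dataclass
class ExpressionCompendium:
    """Replicate log2-ratio values indexed by (gene, experiment).

    Parameters
    ----------
    genes, experiments
        Ordered unique identifiers.
    values
        Mapping ``(gene, experiment) -> tuple of finite floats``; absent keys
        (or empty tuples) mean the gene was not measured in that experiment.
    """

    genes: list[str]
    experiments: list[str]
    values: dict[tuple[str, str], tuple[float, ...]]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.experiments)) != len(self.experiments):
            raise ValueError("duplicate experiment identifiers")
        gene_set, exp_set = set(self.genes), set(self.experiments)
        for (g, e), reps in self.values.items():
            if g not in gene_set or e not in exp_set:
                raise ValueError(f"value key ({g!r}, {e!r}) not in declared identifiers")
            if not all(math.isfinite(v) for v in reps):
                raise ValueError(f"non-finite replicate for ({g!r}, {e!r})")

    def replicates(self, gene: str, experiment: str) -> tuple[float, ...]:
        return self.values.get((gene, experiment), ())

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionCompendium":
        keep = [g for g in self.genes if g in set(genes)]
        keep_set = set(keep)
        vals = {k: v for k, v in self.values.items() if k[0] in keep_set}
        return ExpressionCompendium(keep, list(self.experiments), vals)

    def means_frame(self) -> pd.DataFrame:
        """Per-gene replicate means as a genes x experiments frame (NaN = unmeasured)."""
        arr = np.full((len(self.genes), len(self.experiments)), np.nan)
        gi = {g: i for i, g in enumerate(self.genes)}
        ei = {e: j for j, e in enumerate(self.experiments)}
        for (g, e), reps in self.values.items():
            if reps:
                arr[gi[g], ei[e]] = float(np.mean(reps))
        return pd.DataFrame(arr, index=list(self.genes), columns=list(self.experiments))


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    replicon: str  # "chromosome" | "plasmid"
    category: str = ""
    is_regulatory: bool = False

    def __post_init__(self) -> None:
        if self.replicon not in ("chromosome", "plasmid"):
            raise ValueError(f"replicon must be chromosome or plasmid, got {self.replicon!r}")


@dataclass
class DiscreteStateMatrix:
    """Entities x experiments trinary states with missing cells allowed.

    Backed by a float DataFrame holding -1.0, 0.0, +1.0 or NaN (missing).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"state outside {{-1,0,+1}} at row {self.frame.index[bad[0]]!r}, "
                f"column {self.frame.columns[bad[1]]!r}"
            )
        if self.frame.index.has_duplicates or self.frame.columns.has_duplicates:
            raise ValueError("duplicate row or column identifiers")

    @property
    def rows(self) -> list[str]:
        return list(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def state(self, row: str, column: str) -> int | None:
        v = self.frame.at[row, column]
        return None if pd.isna(v) else int(v)

    @classmethod
    def from_dict(
        cls,
        states: Mapping[tuple[str, str], int],
        rows: Sequence[str],
        columns: Sequence[str],
    ) -> "DiscreteStateMatrix":
        arr = np.full((len(rows), len(columns)), np.nan)
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: j for j, c in enumerate(columns)}
        for (r, c), s in states.items():
            arr[ri[r], ci[c]] = float(s)
        return cls(pd.DataFrame(arr, index=list(rows), columns=list(columns)))

    def drop_columns(self, columns: Iterable[str]) -> "DiscreteStateMatrix":
        drop = set(columns)
        keep = [c for c in self.columns if c not in drop]
        return DiscreteStateMatrix(self.frame[keep].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiscreteStateMatrix):
            return NotImplemented
        if self.rows != other.rows or self.columns != other.columns:
            return False
        a, b = self.frame.to_numpy(float), other.frame.to_numpy(float)
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_rows(path: Path) -> list[list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.split("\n") if ln != ""]
    return [ln.split("\t") for ln in lines]


def read_compendium(path: str | Path) -> ExpressionCompendium:
    """Read a replicate-level compendium TSV.

    Header: first column is the gene-id column; every other column must be
    named ``<experiment>.rep<k>``.  Empty cells are missing replicates.
    """
    rows = _read_rows(Path(path))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    experiments: list[str] = []
    col_exp: list[str] = []
    for j, name in enumerate(header[1:], start=1):
        m = _REP_RE.match(name.strip())
        if not m:
            raise ParseError(
                f"{path}: header column {j + 1} ({name!r}) does not match '<experiment>.rep<k>'"
            )
        exp = m.group("exp")
        if exp not in experiments:
            experiments.append(exp)
        col_exp.append(exp)
    genes: list[str] = []
    values: dict[tuple[str, str], tuple[float, ...]] = {}
    seen = set()
    for i, row in enumerate(rows[1:], start=2):
        gene = row[0].strip()
        if not gene:
            raise ParseError(f"{path}: line {i}: empty gene identifier")
        if gene in seen:
            raise ParseError(f"{path}: line {i}: duplicate gene id {gene!r}")
        seen.add(gene)
        genes.append(gene)
        per_exp: dict[str, list[float]] = {}
        for j, cell in enumerate(row[1:]):
            if j >= len(col_exp):
                raise ParseError(f"{path}: line {i}: more cells than header columns")
            cell = cell.strip()
            if cell == "":
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {i}, column {header[j + 1]!r}: non-numeric cell {cell!r}"
                ) from None
            if not math.isfinite(v):
                raise ParseError(
                    f"{path}: line {i}, column {header[j + 1]!r}: non-finite value"
                )
            per_exp.setdefault(col_exp[j], []).append(v)
        for exp, reps in per_exp.items():
            values[(gene, exp)] = tuple(reps)
    return ExpressionCompendium(genes, experiments, values)


def write_compendium(compendium: ExpressionCompendium, path: str | Path) -> None:
    """Write a compendium in the TSV dialect accepted by :func:`read_compendium`.

    Column counts per experiment equal the maximum replicate count observed
    for that experiment; shorter replicate tuples are right-padded with
    empty (missing) cells.
    """
    n_rep = {e: 1 for e in compendium.experiments}
    for (g, e), reps in compendium.values.items():
        n_rep[e] = max(n_rep[e], len(reps))
    header = ["gene"]
    for e in compendium.experiments:
        header += [f"{e}.rep{k + 1}" for k in range(n_rep[e])]
    lines = ["\t".join(header)]
    for g in compendium.genes:
        cells = [g]
        for e in compendium.experiments:
            reps = compendium.replicates(g, e)
            cells += [repr(v) for v in reps]
            cells += [""] * (n_rep[e] - len(reps))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_state_matrix(matrix: DiscreteStateMatrix, path: str | Path) -> None:
    lines = ["\t".join(["id"] + matrix.columns)]
    arr = matrix.frame.to_numpy(float)
    for i, r in enumerate(matrix.rows):
        cells = [r] + ["" if np.isnan(v) else str(int(v)) for v in arr[i]]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_state_matrix(path: str | Path) -> DiscreteStateMatrix:
    rows = _read_rows(Path(path))
    if not rows:
        raise ParseError(f"{path}: empty file")
    columns = [c.strip() for c in rows[0][1:]]
    ids: list[str] = []
    arr = np.full((len(rows) - 1, len(columns)), np.nan)
    for i, row in enumerate(rows[1:], start=2):
        ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "":
                continue
            if cell not in ("-1", "0", "1", "+1"):
                raise ParseError(
                    f"{path}: line {i}, column {columns[j]!r}: invalid state {cell!r}"
                )
            arr[i - 2, j] = float(int(cell))
    return DiscreteStateMatrix(pd.DataFrame(arr, index=ids, columns=columns))


def read_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read the annotation TSV (gene, replicon, category, is_regulatory)."""
    rows = _read_rows(Path(path))
    if not rows or [c.strip() for c in rows[0][:2]] != ["gene", "replicon"]:
        raise ParseError(f"{path}: expected header starting 'gene<TAB>replicon'")
    out: dict[str, GeneAnnotation] = {}
    for i, row in enumerate(rows[1:], start=2):
        gene = row[0].strip()
        if gene in out:
            raise ParseError(f"{path}: line {i}: duplicate annotation for {gene!r}")
        flag = row[3].strip().lower() if len(row) > 3 else "false"
        if flag not in ("true", "false", "1", "0"):
            raise ParseError(f"{path}: line {i}: invalid is_regulatory flag {flag!r}")
        try:
            out[gene] = GeneAnnotation(
                gene=gene,
                replicon=row[1].strip(),
                category=row[2].strip() if len(row) > 2 else "",
                is_regulatory=flag in ("true", "1"),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from None
    return out


def write_annotations(annotations: Mapping[str, GeneAnnotation], path: str | Path) -> None:
    lines = ["gene\treplicon\tcategory\tis_regulatory"]
    for g, a in annotations.items():
        lines.append(f"{a.gene}\t{a.replicon}\t{a.category}\t{str(a.is_regulatory).lower()}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_membership(path: str | Path) -> dict[str, set[str]]:
    """Read the two-column (gene, pathway) membership TSV into pathway -> genes."""
    rows = _read_rows(Path(path))
    if not rows or [c.strip() for c in rows[0][:2]] != ["gene", "pathway"]:
        raise ParseError(f"{path}: expected header 'gene<TAB>pathway'")
    out: dict[str, set[str]] = {}
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise ParseError(f"{path}: line {i}: need non-empty gene and pathway")
        out.setdefault(row[1].strip(), set()).add(row[0].strip())
    return out


def write_membership(membership: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = ["gene\tpathway"]
    for pw in membership:
        for g in sorted(membership[pw]):
            lines.append(f"{g}\t{pw}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def filter_chromosomal(
    compendium: ExpressionCompendium,
    annotations: Mapping[str, GeneAnnotation] | Iterable[GeneAnnotation],
) -> ExpressionCompendium:
    """Restrict a compendium to chromosomal genes.

    Plasmid-encoded genes are dropped; the experiment list is unchanged.
    Raises ``KeyError`` listing any compendium gene without an annotation.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.gene: a for a in annotations}
    missing = [g for g in compendium.genes if g not in annotations]
    if missing:
        raise KeyError(f"unannotated genes: {', '.join(missing[:10])}"
                       + (" ..." if len(missing) > 10 else ""))
    keep = [g for g in compendium.genes if annotations[g].replicon == "chromosome"]
    return compendium.subset_genes(keep)
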