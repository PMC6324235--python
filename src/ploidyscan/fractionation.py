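"""Reference-anchored multi-genome alignment tables and fractionation statistics.

Rows are the reference genome's genes in order; each target genome
contributes as many columns as its orthology depth (e.g. three durian and
five cotton columns on a grape reference), and each orthologous block is
phased into a column so that blocks from the same post-event subgenome
share a column.  From the table come the fraction of reference genes with
no surviving colinear gene in any column of a target (fractionation), and
the column-overlap similarity used to test whether two targets' subgenomes
descend from a shared or from independent polyploidies.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .colinearity import ColinearBlock
from .genome import GenomeTable
from .ploidy import ORTHOLOG


@dataclasses.dataclass
class AlignmentTable:
    """Reference-gene-indexed table of homologous target regions."""

    reference: str
    frame: pd.DataFrame            # index: reference gene ids in order
    columns_by_target: dict[str, list[str]]

    def fill_pattern(self, column: str) -> np.ndarray:
        return self.frame[column].notna().to_numpy()


def _assign_columns(blocks: list[ColinearBlock], n_columns: int | None
                    ) -> tuple[dict[int, int], int]:
    """Greedy interval-graph coloring of ortholog blocks on the reference.

    Longest blocks first; overlapping reference intervals get different
    columns.  Returns column index per block plus the column count actually
    needed; blocks beyond ``n_columns`` go to an overflow column (the last
    one) with a warning.
    """
    order = sorted(range(len(blocks)),
                   key=lambda i: (-blocks[i].length, blocks[i].span_a, blocks[i].chrom_a))
    assigned: dict[int, int] = {}
    col_intervals: list[list[tuple[str, int, int]]] = []
    overflow = False
    for i in order:
        b = blocks[i]
        s, e = b.span_a
        col = None
        for c, ivals in enumerate(col_intervals):
            if all(not (b.chrom_a == ch and s < ie and e > is_) for ch, is_, ie in ivals):
                col = c
                break
        if col is None:
            if n_columns is not None and len(col_intervals) >= n_columns:
                overflow = True
                col = n_columns - 1
            else:
                col_intervals.append([])
                col = len(col_intervals) - 1
        col_intervals[col].append((b.chrom_a, s, e))
        assigned[i] = col
    if overflow:
        warnings.warn("more overlapping orthologous blocks than columns; "
                      "extra blocks placed in the overflow column")
    return assigned, len(col_intervals)


def build_alignment_table(reference: GenomeTable,
                          targets: Mapping[str, Sequence[ColinearBlock]],
                          n_columns: Mapping[str, int] | None = None) -> AlignmentTable:
    """Phase ortholog-labeled blocks into subgenome columns per target.

    ``targets`` maps target taxon -> labeled blocks detected with the
    reference on the A side; only orthologous blocks are used.  Cells hold
    the target gene colinear to the row's reference gene; a target gene
    appears in at most one cell (first placement wins).
    """
    index = [g.gene_id for g in reference.genes]
    data: dict[str, list] = {}
    columns_by_target: dict[str, list[str]] = {}
    row_of = {gid: i for i, gid in enumerate(index)}

    for target, blocks in targets.items():
        ortho = [b for b in blocks if b.label == ORTHOLOG]
        want = None if n_columns is None else n_columns.get(target)
        assigned, n_used = _assign_columns(ortho, want)
        n_cols = want if want is not None else n_used
        cols = [f"{target}_{c + 1}" for c in range(max(n_cols, 1))]
        columns_by_target[target] = cols
        cells: list[list] = [[None] * len(index) for _ in cols]
        placed: set[str] = set()
        for i, b in enumerate(ortho):
            c = assigned[i]
            for ref_gene, tgt_gene in b.pairs:
                if tgt_gene in placed:
                    continue
                row = row_of.get(ref_gene)
                if row is None:
                    continue
                if cells[c][row] is None:
                    cells[c][row] = tgt_gene
                    placed.add(tgt_gene)
        for col_name, col_cells in zip(cols, cells):
            data[col_name] = col_cells

    frame = pd.DataFrame(data, index=pd.Index(index, name="ref_gene"))
    return AlignmentTable(reference=reference.taxon, frame=frame,
                          columns_by_target=columns_by_target)


def count_missing(table: AlignmentTable, target: str) -> float:
    """Fraction of reference genes absent from every column of a target."""
    cols = table.columns_by_target[target]
    if table.frame.empty:
        raise ValueError("empty alignment table")
    present = table.frame[cols].notna().any(axis=1)
    return float(1.0 - present.mean())


def region_similarity(fill_a: np.ndarray, fill_b: np.ndarray) -> float:
    """Shared-fill similarity of two columns over the same reference genes.

    ``|filled in both| / |filled in b|`` — near 1 when the two columns
    descend from a common subgenome that fractionated before they split,
    low and uniform when their polyploidies were independent.
    """
    fill_a = np.asarray(fill_a, bool)
    fill_b = np.asarray(fill_b, bool)
    if fill_a.shape != fill_b.shape:
        raise ValueError("fill patterns must cover the same reference gene set")
    denom = int(fill_b.sum())
    if denom == 0:
        raise ValueError("reference column has no filled positions")
    return float((fill_a & fill_b).sum() / denom)


@dataclasses.dataclass
class SimilaritySummary:
    matrix: pd.DataFrame          # rows: columns of target A; cols: columns of target B
    best_match_mean: float        # mean over A columns of their best similarity
    margin_mean: float            # mean best-minus-secondary margin


def similarity_matrix(table: AlignmentTable, target_a: str, target_b: str,
                      chromosome: str | None = None,
                      reference_table: GenomeTable | None = None) -> SimilaritySummary:
    """All-pairs column similarity between two targets (e.g. 3 x 5 grid).

    With ``chromosome`` given (and the reference :class:`GenomeTable` to
    locate genes), similarity is restricted to reference genes on that
    chromosome — the per-chromosome granularity; otherwise genome-wide.
    """
    cols_a = table.columns_by_target[target_a]
    cols_b = table.columns_by_target[target_b]
    mask = np.ones(len(table.frame), bool)
    if chromosome is not None:
        if reference_table is None:
            raise ValueError("per-chromosome similarity needs the reference GenomeTable")
        mask = np.array([reference_table[g].chromosome == chromosome
                         for g in table.frame.index])
    mat = np.zeros((len(cols_a), len(cols_b)))
    for i, ca in enumerate(cols_a):
        fa = table.fill_pattern(ca) & mask
        for j, cb in enumerate(cols_b):
            fb = table.fill_pattern(cb) & mask
            mat[i, j] = region_similarity(fa, fb) if fb.any() else np.nan
    frame = pd.DataFrame(mat, index=cols_a, columns=cols_b)
    bests, margins = [], []
    for i in range(len(cols_a)):
        row = np.sort(mat[i][~np.isnan(mat[i])])[::-1]
        if row.size:
            bests.append(row[0])
            margins.append(row[0] - row[1] if row.size > 1 else np.nan)
    finite_margins = [m for m in margins if not np.isnan(m)]
    return SimilaritySummary(
        matrix=frame,
        best_match_mean=float(np.mean(bests)) if bests else float("nan"),
        margin_mean=float(np.mean(finite_margins)) if finite_margins else float("nan"),
    )


def write_alignment_tsv(table: AlignmentTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", na_rep=".")
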