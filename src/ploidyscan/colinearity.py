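"""Colinear (syntenic) block detection from homolog hits and gene orders.

Blocks are maximal chains of homologous gene pairs whose ranks are strictly
monotonic on both chromosomes (parallel: both increasing; antiparallel:
one increasing, one decreasing), with neighboring pairs separated by at most
``max_gap`` gene ranks on each chromosome and at least ``min_pairs`` pairs.
Chains are extracted greedily per chromosome pair, best-scoring first, each
hit consumed by at most one block; a gene may still take part in blocks on
other chromosome pairs, which is what makes outparalogy depth visible.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeTable

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclasses.dataclass(frozen=True)
class HomologHit:
    """One pairwise homology observation (a BLAST tabular row)."""

    query: str
    subject: str
    identity: float
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclasses.dataclass
class ColinearBlock:
    """A chained run of colinear gene pairs between two chromosomes."""

    chrom_a: str
    chrom_b: str
    pairs: list[tuple[str, str]]
    orientation: str  # "parallel" | "antiparallel"
    ranks_a: list[int]
    ranks_b: list[int]
    p_value: float | None = None
    median_ks: float | None = None
    label: str | None = None  # filled by Ks classification

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def span_a(self) -> tuple[int, int]:
        """Half-open rank interval covered on chromosome A."""
        return min(self.ranks_a), max(self.ranks_a) + 1

    @property
    def span_b(self) -> tuple[int, int]:
        return min(self.ranks_b), max(self.ranks_b) + 1


def read_blast_tab(path: str | Path) -> list[HomologHit]:
    """Read a 12-column BLAST tabular (outfmt 6 dialect) hit table."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS, comment="#")
    return [
        HomologHit(r.qseqid, r.sseqid, float(r.pident), float(r.evalue), float(r.bitscore))
        for r in df.itertuples()
    ]


def _chain_dp(ra: np.ndarray, rb: np.ndarray, max_gap: int) -> list[int]:
    """Best monotone-increasing chain over points (ra, rb).

    Maximizes pair count; ties broken by smaller total rank span, then by
    lexicographically smallest (ra, rb) of the first pair.  Points must be
    unique.  O(n^2) sparse dynamic programming.
    """
    n = ra.size
    order = np.lexsort((rb, ra))
    ra, rb = ra[order], rb[order]
    score = np.ones(n, dtype=int)
    span = np.zeros(n, dtype=int)
    start = np.arange(n)
    prev = np.full(n, -1)
    for i in range(n):
        for j in range(i):
            da = ra[i] - ra[j]
            db = rb[i] - rb[j]
            if not (0 < da <= max_gap and 0 < db <= max_gap):
                continue
            cand = (score[j] + 1, -(span[j] + da + db), -ra[start[j]], -rb[start[j]])
            cur = (score[i], -span[i], -ra[start[i]], -rb[start[i]])
            if cand > cur:
                score[i] = score[j] + 1
                span[i] = span[j] + da + db
                start[i] = start[j]
                prev[i] = j
    best = max(range(n), key=lambda i: (score[i], -span[i], -ra[start[i]], -rb[start[i]],
                                        -ra[i], -rb[i]))
    chain = []
    i = best
    while i >= 0:
        chain.append(i)
        i = prev[i]
    chain.reverse()
    return [int(order[i]) for i in chain]


def _extract_blocks_for_pair(hits_idx: list[int], qa: np.ndarray, qb: np.ndarray,
                             max_gap: int, min_pairs: int) -> list[tuple[list[int], str]]:
    """Greedy best-chain-first extraction on one chromosome pair.

    Returns (hit index list, orientation) per block.  Antiparallel chains are
    found by negating the B ranks.
    """
    available = list(range(qa.size))
    out = []
    while available:
        sub_a = qa[available]
        sub_b = qb[available]
        cand = []
        if sub_a.size:
            par = _chain_dp(sub_a, sub_b, max_gap)
            cand.append((par, "parallel"))
            anti = _chain_dp(sub_a, -sub_b, max_gap)
            cand.append((anti, "antiparallel"))
        # prefer more pairs; ties parallel-first for determinism
        cand.sort(key=lambda c: (-len(c[0]), c[1] != "parallel"))
        chain, orient = cand[0]
        if len(chain) < min_pairs:
            break
        picked = [available[i] for i in chain]
        out.append(([hits_idx[i] for i in picked], orient))
        picked_set = set(picked)
        available = [i for i in available if i not in picked_set]
    return out


def detect_blocks(hits: Sequence[HomologHit], table_a: GenomeTable, table_b: GenomeTable,
                  max_gap: int = 50, min_pairs: int = 4,
                  evalue_max: float = 1e-5) -> list[ColinearBlock]:
    """Detect all colinear blocks between two genomes (or within one).

    When ``table_a is table_b`` (paralogy mode) self pairs are excluded and
    each block is emitted once, with the lexicographically smaller
    (chromosome, rank) end as the A side.
    """
    self_mode = table_a is table_b or (
        table_a.taxon == table_b.taxon and len(table_a) == len(table_b)
    )
    usable: list[tuple[int, str, str, int, int]] = []  # (hit idx, ca, cb, ra, rb)
    seen_pairs: set[tuple[str, str]] = set()
    for i, h in enumerate(hits):
        if h.evalue > evalue_max:
            continue
        if h.query == h.subject:
            continue
        if h.query not in table_a:
            raise KeyError(f"hit query gene {h.query!r} not in genome {table_a.taxon!r}")
        if h.subject not in table_b:
            raise KeyError(f"hit subject gene {h.subject!r} not in genome {table_b.taxon!r}")
        ga, gb = table_a[h.query], table_b[h.subject]
        ca, ra = ga.chromosome, ga.rank
        cb, rb = gb.chromosome, gb.rank
        q, s = h.query, h.subject
        if self_mode and (ca, ra) > (cb, rb):
            ca, ra, cb, rb = cb, rb, ca, ra
            q, s = s, q
        if self_mode:
            key = (q, s)
            if key in seen_pairs:  # both hit directions present in input
                continue
            seen_pairs.add(key)
        usable.append((i, q, s, ca, cb, ra, rb))

    by_chrom_pair: dict[tuple[str, str], list[tuple]] = {}
    for rec in usable:
        by_chrom_pair.setdefault((rec[3], rec[4]), []).append(rec)

    blocks: list[ColinearBlock] = []
    for (ca, cb) in sorted(by_chrom_pair):
        recs = by_chrom_pair[(ca, cb)]
        # drop duplicate rank coordinates (multiple hits between the same
        # gene pair): keep first occurrence
        seen_xy = set()
        uniq = []
        for rec in recs:
            xy = (rec[5], rec[6])
            if xy in seen_xy:
                continue
            seen_xy.add(xy)
            uniq.append(rec)
        qa = np.array([r[5] for r in uniq])
        qb = np.array([r[6] for r in uniq])
        for idx_list, orient in _extract_blocks_for_pair(
                list(range(len(uniq))), qa, qb, max_gap, min_pairs):
            chosen = [uniq[i] for i in idx_list]
            blocks.append(ColinearBlock(
                chrom_a=ca, chrom_b=cb,
                pairs=[(r[1], r[2]) for r in chosen],
                orientation=orient,
                ranks_a=[r[5] for r in chosen],
                ranks_b=[r[6] for r in chosen],
            ))
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.span_a[0], b.span_b[0]))
    return blocks


def score_block_significance(block: ColinearBlock, table_a: GenomeTable,
                             table_b: GenomeTable, n_hits: int,
                             max_gap: int = 50) -> float:
    """Poisson-approximation p-value for a block given background hit density.

    With ``n_hits`` homolog hits spread over the chromosome pair (lengths
    ``la x lb`` gene ranks), the chance that a given hit extends into a
    further chained pair within the gap window is
    ``q = 1 - exp(-density * max_gap^2)``.  Below the percolation point
    (``density * max_gap^2 < 1``) the expected number of maximal chains of
    at least the observed length, allowing either orientation, any starting
    hit, and requiring the start to have no predecessor, is
    ``E = 2 n (1 - q) q^(k-1)`` and the p-value is ``1 - exp(-E)``.  Above
    the percolation point long chains exist almost surely and the
    maximality factor is dropped, driving p to 1 for any modest block.
    Decreasing in block length at fixed density.
    """
    la = table_a.chromosome_length(block.chrom_a)
    lb = table_b.chromosome_length(block.chrom_b)
    if la == 0 or lb == 0:
        raise ValueError("empty chromosome in significance model")
    density = n_hits / float(la * lb)
    if density == 0.0:
        warnings.warn("zero-density background: block significance is degenerate")
        return 0.0
    crowding = density * max_gap * max_gap
    q = -np.expm1(-crowding)
    if q <= 0:
        return 0.0
    log_e = np.log(2.0 * n_hits) + (block.length - 1) * np.log(q)
    if crowding < 1.0:
        log_e += np.log1p(-q)
    expected = np.exp(min(log_e, 700.0))
    return float(-np.expm1(-expected))


def score_all_blocks(blocks: Iterable[ColinearBlock], table_a: GenomeTable,
                     table_b: GenomeTable, hits: Sequence[HomologHit],
                     max_gap: int = 50) -> None:
    """Attach significance p-values in place, per chromosome pair."""
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        if h.query in table_a and h.subject in table_b:
            key = (table_a[h.query].chromosome, table_b[h.subject].chromosome)
            counts[key] = counts.get(key, 0) + 1
    for b in blocks:
        n = counts.get((b.chrom_a, b.chrom_b), b.length)
        b.p_value = score_block_significance(b, table_a, table_b, n, max_gap)


def blocks_to_frame(blocks: Sequence[ColinearBlock]) -> pd.DataFrame:
    rows = []
    for i, b in enumerate(blocks):
        rows.append({
            "block_id": i,
            "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
            "orientation": b.orientation, "n_pairs": b.length,
            "start_a": b.span_a[0], "end_a": b.span_a[1],
            "start_b": b.span_b[0], "end_b": b.span_b[1],
            "p_value": b.p_value, "median_ks": b.median_ks, "label": b.label,
            "gene_pairs": ";".join(f"{q}|{s}" for q, s in b.pairs),
        })
    return pd.DataFrame(rows)


def write_blocks_tsv(blocks: Sequence[ColinearBlock], path: str | Path) -> None:
    blocks_to_frame(blocks).to_csv(path, sep="\t", index=False)
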