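"""Dotplot-based ploidy profiling: ortholog/outparalog depth per region.

Blocks between a reference and a target genome are labeled orthologous or
outparalogous by their median Ks (orthologs diverged at speciation, so
their Ks is small; outparalogs descend from the shared ancient
hexaploidization and carry its larger Ks).  The reference genome is then
cut into fixed windows of consecutive genes and, per window, the number of
distinct target regions whose orthologous (resp. outparalogous) blocks
overlap it is counted; the mode over windows is the orthology (resp.
outparalogy) ratio, which reads out the target's post-divergence ploidy.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .colinearity import ColinearBlock, HomologHit
from .genome import GenomeTable

ORTHOLOG = "ortholog"
OUTPARALOG = "outparalog"
AMBIGUOUS = "ambiguous"


def classify_blocks_by_ks(blocks: Sequence[ColinearBlock], ortholog_max: float,
                          outparalog_min: float) -> list[ColinearBlock]:
    """Label blocks by median Ks: below ``ortholog_max`` orthologous, above
    ``outparalog_min`` outparalogous, between (or exactly at a threshold, or
    saturated) ambiguous and excluded from ratio counting."""
    if ortholog_max > outparalog_min:
        raise ValueError("ortholog_max must not exceed outparalog_min")
    for b in blocks:
        if b.median_ks is None:
            b.label = AMBIGUOUS
        elif b.median_ks < ortholog_max:
            b.label = ORTHOLOG
        elif b.median_ks > outparalog_min:
            b.label = OUTPARALOG
        else:
            b.label = AMBIGUOUS
    return list(blocks)


def _merge_regions(blocks: list[ColinearBlock], merge_gap: int) -> dict[int, int]:
    """Region id per block index, merging chromosome-breakage complements.

    Two blocks are complements of one broken region when they lie on the
    same target chromosome, their reference intervals are adjacent (gap at
    most ``merge_gap`` ranks, not overlapping by more than ``merge_gap``),
    and their orientations agree.
    """
    order = sorted(range(len(blocks)), key=lambda i: blocks[i].span_a)
    region_of: dict[int, int] = {}
    last_by_target: dict[tuple[str, str], tuple[int, int]] = {}  # (chrom, orient) -> (region, end)
    next_region = 0
    for i in order:
        b = blocks[i]
        key = (b.chrom_a, b.chrom_b, b.orientation)
        start, end = b.span_a
        if key in last_by_target:
            region, prev_end = last_by_target[key]
            if abs(start - prev_end) <= merge_gap:
                region_of[i] = region
                last_by_target[key] = (region, max(prev_end, end))
                continue
        region_of[i] = next_region
        last_by_target[key] = (next_region, end)
        next_region += 1
    return region_of


@dataclasses.dataclass
class DepthProfile:
    """Per-window homologous-region depth of a target genome on a reference."""

    reference: str
    target: str
    window: int
    table: pd.DataFrame  # chrom, window_start, n_ortho_regions, n_outpara_regions
    modal_orthology: int
    modal_outparalogy: int

    @property
    def orthology_ratio(self) -> str:
        return f"1:{self.modal_orthology}"

    @property
    def outparalogy_ratio(self) -> str:
        return f"1:{self.modal_outparalogy}"


def _modal(counts: Sequence[int]) -> int:
    positive = [c for c in counts if c > 0]
    if not positive:
        return 0
    vals, freq = np.unique(positive, return_counts=True)
    return int(vals[np.argmax(freq)])  # ties -> smallest count, deterministic


def depth_profile(reference: GenomeTable, blocks: Sequence[ColinearBlock],
                  target_name: str, window: int = 20,
                  merge_gap: int = 25) -> DepthProfile:
    """Count distinct orthologous/outparalogous target regions per window.

    ``blocks`` must be labeled (``classify_blocks_by_ks``) and detected with
    the reference genome on the A side.
    """
    labeled = [b for b in blocks if b.label in (ORTHOLOG, OUTPARALOG)]
    rows = []
    per_class_regions: dict[str, dict[int, int]] = {}
    by_class: dict[str, list[ColinearBlock]] = {ORTHOLOG: [], OUTPARALOG: []}
    for b in labeled:
        by_class[b.label].append(b)
    for cls, cls_blocks in by_class.items():
        per_class_regions[cls] = _merge_regions(cls_blocks, merge_gap)

    for chrom, genes in reference.chromosomes.items():
        n = len(genes)
        for w0 in range(0, n, window):
            w1 = min(w0 + window, n)
            counts = {}
            for cls, cls_blocks in by_class.items():
                regions = set()
                for i, b in enumerate(cls_blocks):
                    if b.chrom_a != chrom:
                        continue
                    s, e = b.span_a
                    if s < w1 and e > w0:
                        regions.add(per_class_regions[cls][i])
                counts[cls] = len(regions)
            rows.append({"chrom": chrom, "window_start": w0, "window_end": w1,
                         "n_ortholog_regions": counts[ORTHOLOG],
                         "n_outparalog_regions": counts[OUTPARALOG]})
    table = pd.DataFrame(rows)
    if table.empty:
        return DepthProfile(reference.taxon, target_name, window, table, 0, 0)
    return DepthProfile(
        reference=reference.taxon, target=target_name, window=window, table=table,
        modal_orthology=_modal(table["n_ortholog_regions"]),
        modal_outparalogy=_modal(table["n_outparalog_regions"]),
    )


# --------------------------------------------------------------------------
# dotplot rendering


def classify_hits(hits: Sequence[HomologHit], n_secondary: int = 2
                  ) -> dict[tuple[str, str], str]:
    """Best / secondary / other category per hit, ranked within each query.

    The best hit has the highest bit score (ties by identity, then subject
    id); the next ``n_secondary`` are secondary.
    """
    by_query: dict[str, list[HomologHit]] = {}
    for h in hits:
        by_query.setdefault(h.query, []).append(h)
    cats: dict[tuple[str, str], str] = {}
    for q, hs in by_query.items():
        hs.sort(key=lambda h: (-h.bitscore, -h.identity, h.subject))
        for i, h in enumerate(hs):
            cats[(q, h.subject)] = ("best" if i == 0
                                    else "secondary" if i <= n_secondary else "other")
    return cats


def render_dotplot(hits: Sequence[HomologHit], table_a: GenomeTable,
                   table_b: GenomeTable, blocks: Sequence[ColinearBlock],
                   path: str | Path, n_secondary: int = 2) -> list[Path]:
    """Homologous-gene dotplot with block overlays annotated by median Ks.

    Genes are placed at cumulative rank coordinates; best hits red,
    secondary blue, others gray; each block is drawn as a line over its
    span with its median Ks printed at the midpoint.  Writes both SVG and
    PNG next to ``path`` (extension replaced).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def offsets(table: GenomeTable) -> dict[str, int]:
        out, cum = {}, 0
        for chrom, genes in table.chromosomes.items():
            out[chrom] = cum
            cum += len(genes)
        return out, cum

    off_a, tot_a = offsets(table_a)
    off_b, tot_b = offsets(table_b)
    cats = classify_hits(hits, n_secondary)

    fig, ax = plt.subplots(figsize=(7, 7))
    colors = {"best": "#d62728", "secondary": "#1f77b4", "other": "#bbbbbb"}
    pts: dict[str, tuple[list, list]] = {c: ([], []) for c in colors}
    for h in hits:
        if h.query not in table_a or h.subject not in table_b:
            continue
        ga, gb = table_a[h.query], table_b[h.subject]
        cat = cats.get((h.query, h.subject), "other")
        pts[cat][0].append(off_a[ga.chromosome] + ga.rank)
        pts[cat][1].append(off_b[gb.chromosome] + gb.rank)
    for cat in ("other", "secondary", "best"):
        xs, ys = pts[cat]
        ax.scatter(xs, ys, s=3, c=colors[cat], label=cat, linewidths=0)

    for b in blocks:
        xa = [off_a[b.chrom_a] + r for r in (b.span_a[0], b.span_a[1] - 1)]
        if b.orientation == "parallel":
            yb = [off_b[b.chrom_b] + r for r in (b.span_b[0], b.span_b[1] - 1)]
        else:
            yb = [off_b[b.chrom_b] + r for r in (b.span_b[1] - 1, b.span_b[0])]
        ax.plot(xa, yb, lw=1.2, alpha=0.7, color="black")
        if b.median_ks is not None:
            ax.annotate(f"Ks={b.median_ks:.2f}", (np.mean(xa), np.mean(yb)),
                        fontsize=6, color="darkgreen")
    for x in list(off_a.values())[1:]:
        ax.axvline(x, lw=0.3, color="gray")
    for y in list(off_b.values())[1:]:
        ax.axhline(y, lw=0.3, color="gray")
    ax.set_xlim(0, max(tot_a, 1))
    ax.set_ylim(0, max(tot_b, 1))
    ax.set_xlabel(f"{table_a.taxon} gene rank")
    ax.set_ylabel(f"{table_b.taxon} gene rank")
    ax.legend(loc="upper right", fontsize=7)

    base = Path(path)
    written = []
    for ext in (".svg", ".png"):
        out = base.with_suffix(ext)
        fig.savefig(out, dpi=150)
        written.append(out)
    plt.close(fig)
    return written
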