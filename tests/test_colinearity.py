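"""Colinear block detection: chaining, constraints, significance."""

import numpy as np
import pytest

from ploidyscan import colinearity as col
from ploidyscan.genome import GenomeTable


def make_tables(n, m=None):
    ga = GenomeTable.from_ranked("A", {"cA": [(f"a{i}", "+") for i in range(n)]})
    gb = GenomeTable.from_ranked("B", {"cB": [(f"b{i}", "+") for i in range(m or n)]})
    return ga, gb


def hits_at(points):
    return [col.HomologHit(f"a{i}", f"b{j}", 90.0, 1e-10, 100.0) for i, j in points]


def test_simple_parallel_block():
    ga, gb = make_tables(10, 20)
    blocks = col.detect_blocks(hits_at([(i, 10 + i) for i in range(5)]), ga, gb)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.length == 5 and b.orientation == "parallel"
    assert b.pairs[0] == ("a0", "b10") and b.ranks_b == [10, 11, 12, 13, 14]


def test_gap_splits_chain_and_short_fragments_drop():
    # a second matched run jumps by 58 ranks: both fragments (3 and 2 pairs)
    # fall below the 4-pair minimum and are discarded
    ga, gb = make_tables(70, 100)
    pts = [(i, 10 + i) for i in range(5)]                       # survives (5 pairs)
    # far down the query axis (query gap 56 > 50 isolates the runs): a subject
    # jump of 58 splits the second run into 3- and 2-pair fragments
    pts += [(60, 20), (61, 21), (62, 22), (63, 80), (64, 81)]
    blocks = col.detect_blocks(hits_at(pts), ga, gb, max_gap=50, min_pairs=4)
    assert len(blocks) == 1 and blocks[0].length == 5
    assert blocks[0].ranks_a == [0, 1, 2, 3, 4]


def test_antiparallel_block():
    ga, gb = make_tables(10, 20)
    blocks = col.detect_blocks(hits_at([(i, 15 - i) for i in range(6)]), ga, gb)
    assert len(blocks) == 1
    assert blocks[0].orientation == "antiparallel"
    assert blocks[0].length == 6


def test_unknown_gene_and_empty_inputs():
    ga, gb = make_tables(5)
    assert col.detect_blocks([], ga, gb) == []
    with pytest.raises(KeyError, match="zz9"):
        col.detect_blocks([col.HomologHit("zz9", "b0", 90, 1e-9, 50)], ga, gb)


def test_evalue_filter_and_self_hits():
    ga, gb = make_tables(10)
    weak = [col.HomologHit(f"a{i}", f"b{i}", 90.0, 1e-3, 50.0) for i in range(6)]
    assert col.detect_blocks(weak, ga, gb) == []


def test_symmetry_between_genomes():
    """detect_blocks(B, A) is detect_blocks(A, B) with pair roles swapped.

    Exact block-for-block equality on an instance with unambiguous chains;
    on a saturated random instance (where equally-scoring tie choices may
    legitimately differ between orientations of the comparison) the block
    count and chain lengths are still identical.
    """
    ga, gb = make_tables(60)
    pts = [(i, 5 + i) for i in range(8)] + [(30 + i, 50 - i) for i in range(5)]
    pts += [(2, 40), (50, 3), (25, 25)]  # isolated at max_gap 10
    rev_pts = [(j, i) for i, j in pts]
    fwd = col.detect_blocks(hits_at(pts), ga, gb, max_gap=10)
    rev_hits = [col.HomologHit(f"b{i}", f"a{j}", 90.0, 1e-10, 100.0)
                for i, j in rev_pts]
    rev = col.detect_blocks(rev_hits, gb, ga, max_gap=10)
    fwd_sets = sorted(sorted(b.pairs) for b in fwd)
    rev_sets = sorted(sorted((s, q) for q, s in b.pairs) for b in rev)
    assert fwd_sets == rev_sets

    rng = np.random.default_rng(0)
    rpts = {(int(rng.integers(40)), int(rng.integers(40))) for _ in range(60)}
    ga, gb = make_tables(40)
    fwd = col.detect_blocks(hits_at(rpts), ga, gb)
    rev_hits = [col.HomologHit(f"b{i}", f"a{j}", 90.0, 1e-10, 100.0)
                for j, i in rpts]
    rev = col.detect_blocks(rev_hits, gb, ga)
    assert sorted(b.length for b in fwd) == sorted(b.length for b in rev)


# ------------------------------------------------------------------ oracle


def brute_force_blocks(points, max_gap, min_pairs):
    """Independent maximal-chain extraction by recursive exhaustive search.

    Enumerates every maximal monotone gap-bounded chain (both orientations)
    and applies the same greedy best-first consumption as the detector:
    most pairs, ties by smaller span then lexicographic first pair.
    """
    def chains_from(start, pts, flip):
        sx, sy = start
        nexts = [p for p in pts
                 if 0 < p[0] - sx <= max_gap
                 and 0 < (p[1] - sy) * flip <= max_gap]
        if not nexts:
            return [[start]]
        out = []
        for n in nexts:
            out.extend([[start] + c for c in chains_from(n, pts, flip)])
        return out

    def best_chain_oriented(pts, flip):
        best = None
        for start in pts:
            # maximal chains must start at an unextendable point
            has_pred = any(0 < start[0] - p[0] <= max_gap
                           and 0 < (start[1] - p[1]) * flip <= max_gap
                           for p in pts)
            if has_pred:
                continue
            for chain in chains_from(start, pts, flip):
                span = (chain[-1][0] - chain[0][0]
                        + abs(chain[-1][1] - chain[0][1]))
                key = (-len(chain), span, chain[0])
                if best is None or key < best[0]:
                    best = (key, chain)
        return best[1] if best else []

    pts = sorted(points)
    blocks = []
    while pts:
        # longer chain wins; length ties prefer the parallel orientation
        par = best_chain_oriented(pts, 1)
        anti = best_chain_oriented(pts, -1)
        chain = par if len(par) >= len(anti) else anti
        if len(chain) < min_pairs:
            break
        blocks.append(chain)
        pts = [p for p in pts if p not in set(chain)]
    return blocks


@pytest.mark.parametrize("seed", range(12))
def test_matches_brute_force_enumeration(seed):
    """Block count and chain lengths equal an independent exhaustive
    maximal-chain search (equally-scoring tie choices may differ)."""
    rng = np.random.default_rng(seed)
    n_genes, n_hits = 60, 25
    pts = set()
    while len(pts) < n_hits:
        pts.add((int(rng.integers(n_genes)), int(rng.integers(n_genes))))
    ga, gb = make_tables(n_genes)
    got = col.detect_blocks(hits_at(pts), ga, gb, max_gap=12, min_pairs=3)
    expected = brute_force_blocks(pts, max_gap=12, min_pairs=3)
    assert len(got) == len(expected)
    assert sorted(b.length for b in got) == sorted(len(c) for c in expected)


def test_truth_segments_recovered_no_loss(ech_dsh_run):
    """Every true syntenic chromosome pair appears as one full-length block."""
    blocks = ech_dsh_run["blocks"]
    genomes = ech_dsh_run["genomes"]
    # 2 ancestral chromosomes x 3 grape copies x 9 durian copies, 100 genes each
    assert len(blocks) == 54
    assert all(b.length == 100 for b in blocks)
    assert sum(b.length for b in blocks) == 3 * len(genomes["grape"]) * 9 // 3


def test_self_comparison_emits_each_block_once():
    ga = GenomeTable.from_ranked("A", {
        "c1": [(f"x{i}", "+") for i in range(8)],
        "c2": [(f"y{i}", "+") for i in range(8)],
    })
    hits = [col.HomologHit(f"x{i}", f"y{i}", 90.0, 1e-9, 80.0) for i in range(6)]
    hits += [col.HomologHit(f"y{i}", f"x{i}", 90.0, 1e-9, 80.0) for i in range(6)]
    blocks = col.detect_blocks(hits, ga, ga)
    assert len(blocks) == 1 and blocks[0].length == 6
    assert blocks[0].chrom_a == "c1" and blocks[0].chrom_b == "c2"


# ------------------------------------------------------------- significance


def _block_of(k):
    return col.ColinearBlock("cA", "cB", [("x", "y")] * k, "parallel",
                             list(range(k)), list(range(k)))


def test_long_sparse_block_highly_significant():
    ga, gb = make_tables(500)
    p = col.score_block_significance(_block_of(20), ga, gb, n_hits=40, max_gap=50)
    assert p < 1e-6
    # permutation sanity: nothing approaching a 20-chain in 500 shuffles
    rng = np.random.default_rng(2)
    longest = 0
    for _ in range(500):
        pts = set()
        while len(pts) < 30:
            pts.add((int(rng.integers(100)), int(rng.integers(100))))
        blocks = col.detect_blocks(hits_at(pts), *make_tables(100),
                                   max_gap=10, min_pairs=1)
        longest = max(longest, max((b.length for b in blocks), default=0))
    assert longest < 15


def test_saturated_background_not_significant():
    ga, gb = make_tables(50)
    p = col.score_block_significance(_block_of(4), ga, gb, n_hits=2500, max_gap=50)
    assert p > 0.99


def test_zero_density_background_warns():
    ga, gb = make_tables(50)
    with pytest.warns(UserWarning, match="zero-density"):
        assert col.score_block_significance(_block_of(5), ga, gb, 0) == 0.0


def test_pvalue_decreases_with_block_length():
    ga, gb = make_tables(300)
    ps = [col.score_block_significance(_block_of(k), ga, gb, 200, 50)
          for k in range(4, 15)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_analytic_model_within_factor_three_of_permutation():
    """Analytic p-values track permutation p-values within a factor of 3."""
    rng = np.random.default_rng(7)
    checked = 0
    for n_genes, n_hits, g in [(150, 60, 10), (200, 80, 12), (120, 50, 8),
                               (180, 70, 10), (160, 55, 9)]:
        maxlens = []
        for _ in range(300):
            pts = set()
            while len(pts) < n_hits:
                pts.add((int(rng.integers(n_genes)), int(rng.integers(n_genes))))
            blocks = col.detect_blocks(hits_at(pts), *make_tables(n_genes),
                                       max_gap=g, min_pairs=1)
            maxlens.append(max((b.length for b in blocks), default=0))
        maxlens = np.asarray(maxlens)
        ga, gb = make_tables(n_genes)
        for k in range(3, 7):
            p_perm = float((maxlens >= k).mean())
            if not 0.05 <= p_perm <= 0.95:
                continue
            p_ana = col.score_block_significance(_block_of(k), ga, gb, n_hits, g)
            assert p_ana / p_perm < 3.0 and p_perm / p_ana < 3.0
            checked += 1
    assert checked >= 6  # enough informative comparisons
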