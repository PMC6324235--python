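"""Gene-tree building, topology typing, and cluster patterns."""

import itertools

import numpy as np
import pytest

from ploidyscan import simulate, trees
from ploidyscan.trees import Clade, HomologGroup


def seqs_for(names, length=90, seed=0, diverge=None):
    """Random equal-length DNA sequences; ``diverge[name]`` mutates a copy."""
    rng = np.random.default_rng(seed)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    out = {}
    for n in names:
        k = (diverge or {}).get(n, 5)
        seq = list(base)
        for _ in range(k):
            i = int(rng.integers(length))
            seq[i] = "ACGT"[int(rng.integers(4))]
        out[n] = "".join(seq)
    return out


def group_names():
    return (["grape_g1", "cacao_g1", "cotton_g1", "cotton_g2", "cotton_g3",
             "durian_g1", "durian_g2"])


def make_group(seed=0, diverge=None):
    names = group_names()
    return HomologGroup("g", names[0], names[1], names[2:5], names[5:],
                        seqs_for(names, seed=seed, diverge=diverge))


# ------------------------------------------------------------------ NJ/UPGMA


def test_nj_recovers_additive_tree():
    # distances additive on ((a,b),(c,d)) with internal branch 3
    names = ["a", "b", "c", "d"]
    d = np.array([[0, 5, 9, 10],
                  [5, 0, 10, 11],
                  [9, 10, 0, 7],
                  [10, 11, 7, 0]], float)
    tree = trees.neighbor_joining(d, names)
    rooted = trees.root_on_leaf(tree, "a")
    clades = {c.leaf_names() for c in rooted.iter_clades() if not c.is_leaf}
    assert frozenset({"c", "d"}) in clades


def test_upgma_ultrametric_clustering():
    names = ["a", "b", "c"]
    d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float)
    tree = trees.upgma(d, names)
    clades = {c.leaf_names() for c in tree.iter_clades() if not c.is_leaf}
    assert frozenset({"a", "b"}) in clades


def test_build_tree_deterministic():
    g = make_group(seed=1)
    r1 = trees.build_tree(g, bootstrap_n=25, seed=3)
    r2 = trees.build_tree(g, bootstrap_n=25, seed=3)
    assert r1.newick == r2.newick
    assert r1.tree.children[0].name == "grape_g1" or \
        r1.tree.children[1].name == "grape_g1"


def test_bootstrap_supports_sane():
    g = make_group(seed=2, diverge={"durian_g1": 1, "durian_g2": 1,
                                    "cotton_g1": 30, "cotton_g2": 30,
                                    "cotton_g3": 30})
    res = trees.build_tree(g, bootstrap_n=50, seed=0)
    sups = [c.support for c in res.tree.iter_clades()
            if not c.is_leaf and c is not res.tree]
    assert sups and all(0.0 <= s <= 100.0 for s in sups)


def test_degenerate_alignment_errors():
    names = group_names()
    seqs = {n: "---" for n in names}
    g = HomologGroup("g", names[0], names[1], names[2:5], names[5:], seqs)
    with pytest.raises(ValueError, match="no comparable columns"):
        trees.build_tree(g, bootstrap_n=0)


def _has_q_tie(dist):
    """True when some agglomeration step has two equally minimal Q pairs
    (any join choice is then a valid neighbor-joining run)."""
    d = dist.copy()
    active = list(range(d.shape[0]))
    # at m == 3 all Q values coincide by algebra and the join choice cannot
    # change the topology, so only m > 3 steps are checked
    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        vals = sorted(((m - 2) * d[i, j] - sums[i] - sums[j], i, j)
                      for i, j in itertools.combinations(active, 2))
        tied = [v for v in vals if abs(v[0] - vals[0][0]) < 1e-12]
        # at m == 4 the complementary pair always ties exactly and joining
        # either yields the same unrooted topology: benign unless the tie
        # involves overlapping pairs
        for a in range(len(tied)):
            for b in range(a + 1, len(tied)):
                if {tied[a][1], tied[a][2]} & {tied[b][1], tied[b][2]}:
                    return True
        if m > 4 and len(tied) > 1:
            return True
        _, i, j = vals[0]
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x not in (i, j):
                d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        active = [x for x in active if x not in (i, j)] + [k]
    return False


def test_nj_matches_reference_implementation():
    """Unrooted NJ splits equal Bio.Phylo's NJ on simulated groups whenever
    the Q criterion has a unique minimizer at every step."""
    from Bio.Phylo.TreeConstruction import (DistanceMatrix as BPDM,
                                            DistanceTreeConstructor)

    names = group_names()
    full = frozenset(names)

    def canon(sides):
        out = set()
        for s in sides:
            s = frozenset(s)
            if 1 < len(s) < len(names) - 1:
                out.add(min(s, full - s, key=lambda x: (len(x), sorted(x))))
        return out

    tie_free = 0
    for seed in range(30):
        rng = np.random.default_rng(100 + seed)
        div = {n: int(rng.integers(1, 80)) for n in names}
        seqs = seqs_for(names, length=400, seed=200 + seed, diverge=div)
        dist = trees.p_distance_matrix(names, seqs)
        if _has_q_tie(dist):
            continue  # any join order is valid; implementations may differ
        tie_free += 1
        rooted = trees.root_on_leaf(trees.neighbor_joining(dist, names), names[0])
        my_splits = canon(c.leaf_names() for c in rooted.iter_clades()
                          if not c.is_leaf)
        lower = [[float(dist[i][j]) for j in range(i + 1)]
                 for i in range(len(names))]
        ref = DistanceTreeConstructor().nj(BPDM(names=names, matrix=lower))
        ref_splits = canon(frozenset(t.name for t in cl.get_terminals())
                           for cl in ref.get_nonterminals())
        assert my_splits == ref_splits
    assert tie_free >= 12


# ----------------------------------------------------------------- typing


def classify_newick(nwk):
    return trees.classify_topology(Clade.from_newick(nwk))


def test_classify_definition_cases():
    a = "(grape_g,(cacao_g,((cotton_1,cotton_2,cotton_3),(durian_1,durian_2))));"
    assert classify_newick(a) == "A"
    b = "(grape_g,((cacao_g,(durian_1,durian_2)),(cotton_1,cotton_2,cotton_3)));"
    assert classify_newick(b) == "B"
    c = "(grape_g,((cacao_g,(cotton_1,cotton_2,cotton_3)),(durian_1,durian_2)));"
    assert classify_newick(c) == "C"
    d = "(grape_g,((cotton_1,(cacao_g,cotton_2)),(cotton_3,(durian_1,durian_2))));"
    assert classify_newick(d) == "D"


def test_classify_requires_all_species():
    with pytest.raises(ValueError, match="lacks any durian"):
        classify_newick("(grape_g,(cacao_g,(cotton_1,cotton_2)));")


def all_rooted_binary_trees(leaves):
    """Enumerate rooted binary tree shapes over the given leaves."""
    if len(leaves) == 1:
        yield Clade(name=leaves[0])
        return
    first, rest = leaves[0], leaves[1:]
    # choose the subset accompanying the first leaf on the left side
    for r in range(0, len(rest)):
        for combo in itertools.combinations(rest, r):
            left = [first, *combo]
            right = [x for x in rest if x not in combo]
            if not right:
                continue
            for lt in all_rooted_binary_trees(left):
                for rt in all_rooted_binary_trees(right):
                    yield Clade(children=[lt, rt])


def test_classifier_total_by_enumeration():
    """Every rooted tree on 1 cacao + 3 cotton + 2 durian ingroup leaves gets
    exactly one type, and each type is realized."""
    ingroup = ["cacao_g", "cotton_1", "cotton_2", "cotton_3",
               "durian_1", "durian_2"]
    counts = {"A": 0, "B": 0, "C": 0, "D": 0}
    n = 0
    for sub in all_rooted_binary_trees(ingroup):
        tree = Clade(children=[Clade(name="grape_g"), sub])
        t = trees.classify_topology(tree)
        counts[t] += 1
        n += 1
    assert n == 945  # (2*6-3)!! rooted binary shapes on 6 leaves
    assert sum(counts.values()) == n
    assert all(v > 0 for v in counts.values())
    # type A requires cacao sister to the whole cotton+durian clade: the
    # number of such trees is the number of rooted shapes on those 5 leaves
    assert counts["A"] == 105


# ------------------------------------------------------------ cluster pattern


def supported(nwk):
    t = Clade.from_newick(nwk)
    return t


def test_cluster_pattern_cases():
    full = ("(grape_g,(cacao_g,((cotton_1,cotton_2,cotton_3)100,"
            "(durian_1,durian_2)100)100)100);")
    assert trees.cluster_pattern(supported(full)) == "separate_clusters"
    weak = ("(grape_g,(cacao_g,((cotton_1,cotton_2,cotton_3)50,"
            "(durian_1,durian_2)60)40)30);")
    assert trees.cluster_pattern(supported(weak)) == "other"
    pairs = ("(grape_g,(cacao_g,((cotton_1,durian_1)95,"
             "((cotton_2,durian_2)90,cotton_3)20)40)50);")
    assert trees.cluster_pattern(supported(pairs)) == "one_to_one"


def test_separate_clusters_beats_one_to_one_in_precedence():
    t = supported("(grape_g,(cacao_g,((cotton_1,cotton_2,cotton_3)100,"
                  "(durian_1,durian_2)100)100)100);")
    assert trees.cluster_pattern(t, support_min=70) == "separate_clusters"


# ------------------------------------------------- distortion & end-to-end


def groups_from_truth(config, n_groups, jitter=0):
    """Colinearity-anchored homolog groups straight from the truth set."""
    genomes, truth, seqs = simulate.simulate_all(config)
    by_key = {}
    for gid, prov in truth.gene_provenance.items():
        taxon = truth.gene_taxon[gid]
        locus = truth.gene_lineage[gid]
        ech = next((c for n, c in prov if n == "ECH"), None)
        by_key.setdefault((locus, ech), {}).setdefault(taxon, []).append(gid)
    groups = []
    for (locus, ech), members in sorted(by_key.items()):
        if not all(members.get(t) for t in ("grape", "cacao", "durian", "cotton")):
            continue
        if len(members["cotton"]) < 3 or len(members["durian"]) < 2:
            continue
        groups.append(HomologGroup(
            f"{locus}.{ech}", members["grape"][0], members["cacao"][0],
            sorted(members["cotton"])[:5], sorted(members["durian"])[:3],
            {g: seqs[g] for tax in members.values() for g in tax}))
        if len(groups) >= n_groups:
            break
    return groups


def type_fractions(rate_durian, rate_cotton, n_seeds=3, n_groups=60):
    calls = []
    for seed in range(n_seeds):
        cfg = simulate.scenario(
            "ech_dsh_gsd", n_ancestral_genes=20, codon_length=80, seed=seed,
            rate_multipliers={"durian": rate_durian, "cotton": rate_cotton})
        groups = groups_from_truth(cfg, n_groups)
        assert len(groups) >= 40
        calls += [trees.classify_topology(
            trees.build_tree(g, bootstrap_n=0).tree) for g in groups]
    return sum(1 for c in calls if c != "A") / len(calls)


def test_distortion_grows_with_duplicate_era_rates():
    """Equal rates give mostly the expected topology; raising the
    post-duplication rates (durian modestly, cotton strongly, as between
    the real lineages) makes distorted non-A trees increasingly common —
    the long-branch mechanism behind the misplaced outgroup."""
    f1 = type_fractions(1.0, 1.0)
    f2 = type_fractions(1.5, 3.0)
    f3 = type_fractions(2.0, 5.0)
    assert f1 < 0.5          # expected topology dominates at equal rates
    assert f1 < f2 <= f3 + 1e-9   # distortion rises with rate elevation
    assert f3 > 0.4


def test_independent_events_cluster_by_species():
    """With independent polyploidies and elevated cotton rates, supported
    branches cluster genes by species rather than pairing one-to-one."""
    cfg = simulate.scenario("ech_dsh_gsd", n_ancestral_genes=8,
                            codon_length=150, seed=4,
                            rate_multipliers={"cotton": 1.64})
    groups = groups_from_truth(cfg, 16)
    patterns = []
    for i, g in enumerate(groups):
        res = trees.build_tree(g, bootstrap_n=50, seed=i)
        patterns.append(trees.cluster_pattern(res.tree, 70.0))
    sep = patterns.count("separate_clusters")
    one = patterns.count("one_to_one")
    assert sep > one
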