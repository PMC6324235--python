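"""Gene trees of colinearity-anchored homolog groups and topology typing.

Each homolog group holds one grape gene (the outgroup), one cacao gene, at
least three cotton genes and at least two durian genes, all descending from
one ancestral locus.  Distance trees (neighbor-joining or UPGMA on
p-distances, optionally Jukes-Cantor corrected) are rooted on the grape
leaf and classified by where the cacao gene attaches:

* ``A`` — expected history: cacao is sister to the clade of all cotton and
  durian genes;
* ``B`` — cacao is sister to the complete durian cluster;
* ``C`` — cacao is sister to the complete cotton cluster;
* ``D`` — cacao sits inside the ingroup in any other position.

Elevated post-polyploidy substitution rates in cotton and durian pull the
slow cacao gene into the ingroup (a long-branch effect), which is why
almost no real tree is type A.  Bootstrap supports come from alignment
column resampling; the cluster-pattern statistic asks whether, among
well-supported branches, cotton/durian genes form species clusters
(independent polyploidies) or mixed one-to-one pairs (a shared one).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Callable, Mapping, Sequence

import numpy as np


def default_species_of(name: str) -> str:
    return name.split("_", 1)[0]


@dataclasses.dataclass
class Clade:
    """A rooted tree node; leaves carry ``name``, internal nodes ``support``."""

    name: str | None = None
    children: list["Clade"] = dataclasses.field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def iter_clades(self):
        yield self
        for c in self.children:
            yield from c.iter_clades()

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, newick: str) -> "Clade":
        """Parse a Newick string (internal labels read as supports)."""
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(node) -> "Clade":
            if node.is_leaf():
                return cls(name=node.taxon.label.replace(" ", "_"),
                           length=node.edge.length or 0.0)
            support = None
            if node.label is not None:
                try:
                    support = float(node.label)
                except ValueError:
                    pass
            return cls(children=[convert(c) for c in node.child_nodes()],
                       length=node.edge.length or 0.0, support=support)

        return convert(tree.seed_node)


@dataclasses.dataclass
class HomologGroup:
    """One grape + one cacao + >=3 cotton + >=2 durian genes of one locus."""

    group_id: str
    grape: str
    cacao: str
    cotton: list[str]
    durian: list[str]
    sequences: dict[str, str]

    def __post_init__(self):
        if len(self.cotton) < 3 or len(self.durian) < 2:
            raise ValueError(
                f"group {self.group_id}: need >=3 cotton and >=2 durian genes"
            )
        members = self.members()
        missing = [m for m in members if m not in self.sequences]
        if missing:
            raise ValueError(f"group {self.group_id}: missing sequences {missing}")
        lengths = {len(self.sequences[m]) for m in members}
        if len(lengths) != 1:
            raise ValueError(
                f"group {self.group_id}: sequences must be aligned (equal length)"
            )

    def members(self) -> list[str]:
        return [self.grape, self.cacao, *self.cotton, *self.durian]


# --------------------------------------------------------------------------
# distances


def p_distance_matrix(names: Sequence[str], seqs: Mapping[str, str],
                      jukes_cantor: bool = False,
                      columns: np.ndarray | None = None) -> np.ndarray:
    """Pairwise p-distances over non-gap columns, optionally JC corrected.

    ``columns`` selects (possibly resampled) alignment columns for
    bootstrap replicates.
    """
    arrs = []
    for n in names:
        a = np.frombuffer(seqs[n].encode(), dtype="S1")
        arrs.append(a if columns is None else a[columns])
    mat = np.zeros((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        a, b = arrs[i], arrs[j]
        ok = (a != b"-") & (b != b"-")
        n_ok = int(ok.sum())
        if n_ok == 0:
            raise ValueError(f"no comparable columns between {names[i]} and {names[j]}")
        p = float((a[ok] != b[ok]).sum() / n_ok)
        if jukes_cantor:
            if p >= 0.75:
                p = 0.7499  # cap saturated distances
            d = -0.75 * math.log1p(-4.0 * p / 3.0)
        else:
            d = p
        mat[i, j] = mat[j, i] = d
    return mat


# --------------------------------------------------------------------------
# native NJ / UPGMA


def neighbor_joining(dist: np.ndarray, names: Sequence[str]) -> Clade:
    """Saitou-Nei neighbor joining; returns a tree rooted at the final join."""
    nodes = [Clade(name=n) for n in names]
    d = dist.astype(float).copy()
    active = list(range(len(names)))
    while len(active) > 2:
        m = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[i, j] - sums[i] - sums[j]
            key = (q, d[i, j], i, j)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = Clade(children=[nodes[i], nodes[j]])
        # grow matrix with the new node
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]
    i, j = active
    nodes[i].length = max(d[i, j], 0.0)
    nodes[j].length = 0.0
    return Clade(children=[nodes[j], nodes[i]])


def upgma(dist: np.ndarray, names: Sequence[str]) -> Clade:
    """Average-linkage (UPGMA) clustering tree."""
    nodes = [Clade(name=n) for n in names]
    sizes = {i: 1 for i in range(len(names))}
    heights = {i: 0.0 for i in range(len(names))}
    d = dist.astype(float).copy()
    active = list(range(len(names)))
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(active, 2):
            key = (d[i, j], i, j)
            if best is None or key < best:
                best = key
        dij, i, j = best
        h = dij / 2.0
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        parent = Clade(children=[nodes[i], nodes[j]])
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = (sizes[i] * d[i, x] + sizes[j] * d[j, x]) / (
                sizes[i] + sizes[j])
        nodes.append(parent)
        sizes[k] = sizes[i] + sizes[j]
        heights[k] = h
        active = [x for x in active if x not in (i, j)] + [k]
    return nodes[active[0]]


def root_on_leaf(tree: Clade, leaf_name: str) -> Clade:
    """Reroot so the named leaf is one child of the root (outgroup rooting)."""
    # build undirected adjacency, then orient away from the leaf
    adj: dict[int, list[tuple[int, float]]] = {}
    leaves: dict[int, str] = {}
    supports: dict[int, float | None] = {}
    counter = itertools.count()

    def index(node: Clade) -> int:
        i = next(counter)
        supports[i] = node.support
        if node.is_leaf:
            leaves[i] = node.name
        for c in node.children:
            j = index(c)
            adj.setdefault(i, []).append((j, c.length))
            adj.setdefault(j, []).append((i, c.length))
        return i

    index(tree)
    target = next((i for i, n in leaves.items() if n == leaf_name), None)
    if target is None:
        raise ValueError(f"leaf {leaf_name!r} not in tree")

    def orient(i: int, parent: int) -> Clade:
        kids = [(j, ln) for j, ln in adj.get(i, []) if j != parent]
        if i in leaves and not kids:
            return Clade(name=leaves[i])
        node = Clade(support=supports.get(i))
        for j, ln in kids:
            child = orient(j, i)
            child.length = ln
            node.children.append(child)
        if len(node.children) == 1:  # collapse degree-2 passthrough nodes
            only = node.children[0]
            only.length += node.length
            return only
        return node

    (anchor, ln) = adj[target][0]
    ingroup = orient(anchor, target)
    ingroup.length = ln / 2.0
    out_leaf = Clade(name=leaf_name, length=ln / 2.0)
    return Clade(children=[out_leaf, ingroup])


# --------------------------------------------------------------------------
# tree building with bootstrap


@dataclasses.dataclass
class TreeResult:
    tree: Clade           # rooted on the grape leaf, supports attached
    newick: str
    method: str
    bootstrap_n: int


def _clades_of(tree: Clade) -> set[frozenset[str]]:
    out = set()
    for node in tree.iter_clades():
        if not node.is_leaf and node is not tree:
            out.add(node.leaf_names())
    return out


def build_tree(group: HomologGroup, method: str = "nj", bootstrap_n: int = 100,
               seed: int = 0, jukes_cantor: bool = False) -> TreeResult:
    """Distance tree of a homolog group, rooted on grape, with bootstrap.

    Bootstrap resamples alignment columns; each internal branch's support is
    the percentage of replicates containing the same leaf set under the same
    rooting.
    """
    if method not in ("nj", "upgma"):
        raise ValueError(f"unknown tree method {method!r}")
    build = neighbor_joining if method == "nj" else upgma
    names = group.members()
    seqs = group.sequences
    aln_len = len(seqs[names[0]])

    dist = p_distance_matrix(names, seqs, jukes_cantor)
    main = root_on_leaf(build(dist, names), group.grape)

    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset[str], int] = {}
        for _ in range(bootstrap_n):
            cols = rng.integers(0, aln_len, size=aln_len)
            bd = p_distance_matrix(names, seqs, jukes_cantor, columns=cols)
            rep = root_on_leaf(build(bd, names), group.grape)
            for clade in _clades_of(rep):
                counts[clade] = counts.get(clade, 0) + 1
        for node in main.iter_clades():
            if not node.is_leaf and node is not main:
                node.support = 100.0 * counts.get(node.leaf_names(), 0) / bootstrap_n
    return TreeResult(tree=main, newick=main.newick(), method=method,
                      bootstrap_n=bootstrap_n)


# --------------------------------------------------------------------------
# topology typing


def classify_topology(tree: Clade,
                      species_of: Callable[[str], str] = default_species_of) -> str:
    """Type A-D by the cacao gene's attachment in the grape-rooted tree.

    A: cacao sister to all cotton+durian genes; B: cacao sister to the
    complete durian cluster; C: to the complete cotton cluster; D: cacao
    inside the ingroup but none of the above (grouped with, yet not
    outgroup to, cotton and durian genes).
    """
    by_species: dict[str, set[str]] = {}
    for leaf in tree.leaf_names():
        by_species.setdefault(species_of(leaf), set()).add(leaf)
    for sp in ("grape", "cacao", "cotton", "durian"):
        if sp not in by_species:
            raise ValueError(f"tree lacks any {sp} gene")
    (cacao_leaf,) = by_species["cacao"]

    parent = None
    for node in tree.iter_clades():
        if any(c.is_leaf and c.name == cacao_leaf for c in node.children):
            parent = node
            break
    assert parent is not None
    sister = frozenset().union(*[
        c.leaf_names() for c in parent.children
        if not (c.is_leaf and c.name == cacao_leaf)
    ])
    if sister == by_species["cotton"] | by_species["durian"]:
        return "A"
    if sister == by_species["durian"]:
        return "B"
    if sister == by_species["cotton"]:
        return "C"
    return "D"


def cluster_pattern(tree: Clade, support_min: float = 70.0,
                    species_of: Callable[[str], str] = default_species_of) -> str:
    """Supported-branch clustering of cotton/durian genes.

    ``separate_clusters`` when a supported clade holds exactly all durian
    (or all cotton) genes; ``one_to_one`` when durian and cotton genes pair
    off into supported two-leaf mixed clades; ``other`` otherwise.
    """
    by_species: dict[str, set[str]] = {}
    for leaf in tree.leaf_names():
        by_species.setdefault(species_of(leaf), set()).add(leaf)
    durian = frozenset(by_species.get("durian", set()))
    cotton = frozenset(by_species.get("cotton", set()))

    supported = [
        node for node in tree.iter_clades()
        if not node.is_leaf and node is not tree
        and node.support is not None and node.support >= support_min
    ]
    for node in supported:
        ln = node.leaf_names()
        if ln == durian or ln == cotton:
            return "separate_clusters"
    pairs = 0
    for node in supported:
        ln = node.leaf_names()
        if len(ln) == 2 and len(ln & durian) == 1 and len(ln & cotton) == 1:
            pairs += 1
    if pairs >= min(len(durian), len(cotton)):
        return "one_to_one"
    return "other"


# --------------------------------------------------------------------------
# group extraction from alignment tables


def extract_groups(alignment_frame, sequences: Mapping[str, str],
                   cacao_cols: Sequence[str], cotton_cols: Sequence[str],
                   durian_cols: Sequence[str],
                   min_cotton: int = 3, min_durian: int = 2) -> list[HomologGroup]:
    """Build homolog groups from a grape-referenced alignment table.

    One group per reference (grape) gene whose row has a cacao ortholog,
    at least ``min_cotton`` cotton and ``min_durian`` durian orthologs,
    provided all members' sequences are present and of equal length.
    """
    groups = []
    for ref_gene, row in alignment_frame.iterrows():
        cacao = [row[c] for c in cacao_cols if isinstance(row[c], str)]
        cotton = [row[c] for c in cotton_cols if isinstance(row[c], str)]
        durian = [row[c] for c in durian_cols if isinstance(row[c], str)]
        if len(cacao) != 1 or len(cotton) < min_cotton or len(durian) < min_durian:
            continue
        members = [ref_gene, cacao[0], *cotton, *durian]
        if any(m not in sequences for m in members):
            continue
        if len({len(sequences[m]) for m in members}) != 1:
            continue
        groups.append(HomologGroup(
            group_id=str(ref_gene), grape=str(ref_gene), cacao=cacao[0],
            cotton=cotton, durian=durian,
            sequences={m: sequences[m] for m in members},
        ))
    return groups
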