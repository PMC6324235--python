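"""Synthetic polyploid-genome simulator.

Generates genomes with the statistical structure the inference pipeline
assumes: a fixed 4-taxon phylogeny ``(grape,(cacao,(durian,cotton)))``,
recursive whole-genome multiplications placed on its branches, per-duplicate
gene loss (fractionation), tandem duplication, segmental inversion, and
codon sequences whose synonymous divergence tracks the rate-scaled path
length separating any two genes.

Branch lengths are parameterized directly in expected-Ks units (one-way
synonymous substitutions per synonymous site at rate multiplier 1), so an
event placed at Ks-position *t* above a tip produces duplicate pairs with
expected pairwise Ks ``2 t`` on a rate-1 lineage.  Per-branch rate
multipliers scale the realized substitutions on that branch, which is how
the elevated post-polyploidy rate of the cotton lineage is emulated.

Sequences are built from the six fourfold-degenerate codon families whose
first two positions are fully nonsynonymous (Val GTN, Ser TCN, Pro CCN,
Thr ACN, Ala GCN, Gly GGN).  Third positions evolve under a Jukes-Cantor
process at the branch's realized Ks rate; first/second positions accept
occasional nonsynonymous changes at a fraction ``omega`` of that rate,
constrained to stay inside the six families (so no stop codons ever arise
and synonymous site counts stay exact).  This two-rate scheme is all the
pipeline consumes: it makes the expected Nei-Gojobori Ks of a gene pair
equal to the true rate-scaled divergence separating them.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

from .genome import GeneRecord, GenomeTable, write_fasta

# Fixed species tree: edge name -> (child edges); leaves are taxon names.
TREE_CHILDREN: dict[str, tuple[str, str]] = {
    "stem": ("grape", "malvales"),
    "malvales": ("cacao", "malvaceae"),
    "malvaceae": ("durian", "cotton"),
}
TAXA = ("grape", "cacao", "durian", "cotton")
EDGES = ("stem", "grape", "malvales", "cacao", "malvaceae", "durian", "cotton")

# Six codon families with fully nonsynonymous positions 1-2 and a fourfold
# degenerate position 3; no single-nucleotide neighbor is a stop codon path
# we would follow, and S per codon is exactly 1 under Nei-Gojobori counting.
FAMILIES = ("GT", "TC", "CC", "AC", "GC", "GG")
NUCS = "ACGT"
CODONS = tuple(f + n for f in FAMILIES for n in NUCS)
# Single-nucleotide moves between families that stay inside the family set.
FAMILY_MOVES: dict[str, tuple[str, ...]] = {
    "GT": ("GC", "GG"),
    "TC": ("AC", "CC", "GC"),
    "CC": ("AC", "GC", "TC"),
    "AC": ("CC", "GC", "TC"),
    "GC": ("AC", "CC", "TC", "GT", "GG"),
    "GG": ("GT", "GC"),
}


@dataclasses.dataclass(frozen=True)
class PolyploidyEvent:
    """A whole-genome multiplication on one branch of the species tree.

    ``multiplicity`` is the number of genome copies after the event
    (3 = hexaploidization/triplication, 2 = WGD, 5 = decaploidization).
    ``time`` is the event's position on the branch, measured in nominal Ks
    units *above* the branch's lower (more recent) node.
    """

    name: str
    branch: str
    multiplicity: int
    time: float


@dataclasses.dataclass
class SimulationConfig:
    n_ancestral_genes: int = 200
    n_chromosomes: int = 2
    branch_lengths: dict[str, float] = dataclasses.field(default_factory=dict)
    events: list[PolyploidyEvent] = dataclasses.field(default_factory=list)
    retention_prob: float = 1.0
    terminal_loss_prob: float = 0.0
    tandem_rate: float = 0.0
    inversion_rate: float = 0.0
    rate_multipliers: dict[str, float] = dataclasses.field(default_factory=dict)
    codon_length: int = 200
    omega: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in (0, 1]")
        if not 0.0 <= self.terminal_loss_prob < 1.0:
            raise ValueError("terminal_loss_prob must be in [0, 1)")
        for edge in self.branch_lengths:
            if edge not in EDGES:
                raise ValueError(f"unknown branch {edge!r}")
        for edge, length in self.branch_lengths.items():
            if length < 0:
                raise ValueError(f"branch {edge!r} has negative length")
        for ev in self.events:
            if ev.branch not in EDGES:
                raise ValueError(f"event {ev.name!r} on absent branch {ev.branch!r}")
            if ev.multiplicity < 2:
                raise ValueError(f"event {ev.name!r} multiplicity must be >= 2")
            if not 0 <= ev.time <= self.branch_lengths.get(ev.branch, 0.0):
                raise ValueError(
                    f"event {ev.name!r} time {ev.time} outside branch {ev.branch!r}"
                )
        names = [ev.name for ev in self.events]
        if len(names) != len(set(names)):
            raise ValueError("event names must be unique")

    def rate(self, edge: str) -> float:
        return self.rate_multipliers.get(edge, 1.0)

    @property
    def root_events(self) -> set[str]:
        """Names of events on the root edge (shared by all four taxa)."""
        return {ev.name for ev in self.events if ev.branch == "stem"}


class _SimGene:
    """A gene lineage during the tree walk."""

    __slots__ = ("locus", "provenance", "history", "strand")

    def __init__(self, locus: int, provenance: tuple, history: tuple, strand: str):
        self.locus = locus
        self.provenance = provenance  # ((event_name, copy_index), ...)
        self.history = history        # ((segment_key, realized_length), ...)
        self.strand = strand

    def clone(self) -> "_SimGene":
        return _SimGene(self.locus, self.provenance, self.history, self.strand)


class TruthSet:
    """Ground truth of a simulation.

    Maps every extant gene to its ancestral locus and to the ordered list of
    duplication events it passed through (with the copy index it descends
    from at each).  Homology relation labels are derived from provenance, so
    ``relation`` is by construction consistent with ``gene_provenance``.
    """

    def __init__(self, root_events: set[str]):
        self.gene_lineage: dict[str, str] = {}
        self.gene_provenance: dict[str, tuple] = {}
        self.gene_history: dict[str, tuple] = {}
        self.gene_taxon: dict[str, str] = {}
        self._root_events = set(root_events)
        self._locus_members: dict[str, list[str]] = {}

    def _add(self, gene_id: str, taxon: str, gene: _SimGene) -> None:
        locus = f"anc{gene.locus:05d}"
        self.gene_lineage[gene_id] = locus
        self.gene_provenance[gene_id] = gene.provenance
        self.gene_history[gene_id] = gene.history
        self.gene_taxon[gene_id] = taxon
        self._locus_members.setdefault(locus, []).append(gene_id)

    def relation(self, a: str, b: str) -> str | None:
        """Homology relation of an unordered gene pair.

        ``ortholog`` if the pair diverged at a speciation, ``tandem`` if at a
        tandem duplication, otherwise the polyploidy event at which it
        diverged, labeled ``<event>-outparalog`` for root-edge (pre-split)
        events and ``<event>-paralog`` for lineage-specific ones.  ``None``
        if the genes descend from different ancestral loci.
        """
        if self.gene_lineage[a] != self.gene_lineage[b]:
            return None
        pa, pb = self.gene_provenance[a], self.gene_provenance[b]
        for ea, eb in itertools.zip_longest(pa, pb):
            if ea == eb:
                continue
            if ea is None or eb is None:
                # one lineage saw an extra event after the other stopped
                # sharing: the divergence is the older boundary
                extra = ea or eb
                if extra[0].startswith("tandem"):
                    return "tandem"
                return "ortholog"
            if ea[0] != eb[0]:
                if ea[0].startswith("tandem") or eb[0].startswith("tandem"):
                    return "tandem"
                return "ortholog"  # diverged at the speciation separating the events
            name = ea[0]
            if name.startswith("tandem"):
                return "tandem"
            suffix = "outparalog" if name in self._root_events else "paralog"
            return f"{name}-{suffix}"
        if self.gene_taxon[a] != self.gene_taxon[b]:
            return "ortholog"  # no post-split event on either side
        raise AssertionError(f"genes {a!r} and {b!r} have identical provenance")

    def divergence(self, a: str, b: str) -> float:
        """True rate-scaled Ks-path length separating two genes."""
        ha, hb = self.gene_history[a], self.gene_history[b]
        shared = 0
        for xa, xb in zip(ha, hb):
            if xa != xb:
                break
            shared += 1
        return sum(x[1] for x in ha[shared:]) + sum(x[1] for x in hb[shared:])

    def true_pairs(self, taxon_a: str | None = None, taxon_b: str | None = None
                   ) -> Iterator[tuple[str, str, str]]:
        """Yield (gene_a, gene_b, relation) for homologous pairs.

        Restricted to pairs with one gene in ``taxon_a`` and one in
        ``taxon_b`` when given (same-taxon pairs if the two are equal).
        """
        for members in self._locus_members.values():
            for a, b in itertools.combinations(members, 2):
                ta, tb = self.gene_taxon[a], self.gene_taxon[b]
                if taxon_a is not None:
                    want = {taxon_a, taxon_b or taxon_a}
                    if {ta, tb} != want:
                        continue
                yield a, b, self.relation(a, b)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\ttaxon\tlocus\tprovenance\n")
            for gid in sorted(self.gene_lineage):
                prov = ";".join(f"{n}:{c}" for n, c in self.gene_provenance[gid])
                fh.write(f"{gid}\t{self.gene_taxon[gid]}\t{self.gene_lineage[gid]}\t{prov}\n")


# --------------------------------------------------------------------------
# history walk


def _advance(genome: dict[str, list[_SimGene]], key: str, length: float) -> None:
    if length <= 0:
        return
    seg = (key, length)
    for genes in genome.values():
        for g in genes:
            g.history = g.history + (seg,)


def _apply_event(genome: dict[str, list[_SimGene]], ev: PolyploidyEvent,
                 retention_prob: float, rng: np.random.Generator
                 ) -> dict[str, list[_SimGene]]:
    new: dict[str, list[_SimGene]] = {}
    for chrom, genes in genome.items():
        for copy in range(ev.multiplicity):
            name = chrom if copy == 0 else f"{chrom}-{ev.name}{copy}"
            kept: list[_SimGene] = []
            for g in genes:
                # the parental copy (copy 0) is always retained so that no
                # ancestral locus vanishes entirely
                if copy > 0 and rng.random() > retention_prob:
                    continue
                ng = g.clone()
                ng.provenance = ng.provenance + ((ev.name, copy),)
                ng.history = ng.history + ((f"{ev.name}:{copy}", 0.0),)
                kept.append(ng)
            new[name] = kept
    return new


def _apply_tandem(genome: dict[str, list[_SimGene]], edge: str, rate: float,
                  rng: np.random.Generator, counter: itertools.count) -> None:
    if rate <= 0:
        return
    for chrom in list(genome):
        genes = genome[chrom]
        out: list[_SimGene] = []
        for g in genes:
            out.append(g)
            if rng.random() < rate:
                dup = g.clone()
                uid = next(counter)
                dup.provenance = dup.provenance + ((f"tandem-{edge}-{uid}", 1),)
                dup.history = dup.history + ((f"tandem:{uid}", 0.0),)
                out.append(dup)
        genome[chrom] = out


def _apply_inversions(genome: dict[str, list[_SimGene]], n_events: int,
                      rng: np.random.Generator) -> None:
    chroms = sorted(genome)
    for _ in range(n_events):
        chrom = chroms[rng.integers(len(chroms))]
        genes = genome[chrom]
        if len(genes) < 2:
            continue
        i, j = sorted(rng.integers(0, len(genes), size=2))
        if i == j:
            continue
        segment = genes[i:j + 1][::-1]
        for g in segment:
            g.strand = "-" if g.strand == "+" else "+"
        genome[chrom] = genes[:i] + segment + genes[j + 1:]


def simulate_history(config: SimulationConfig) -> tuple[dict[str, GenomeTable], TruthSet]:
    """Walk the species tree, applying polyploidies, loss, tandems, inversions.

    Returns per-taxon :class:`GenomeTable` objects plus the :class:`TruthSet`
    needed to evolve sequences and to score inference results.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    tandem_counter = itertools.count()

    per_chrom = -(-config.n_ancestral_genes // config.n_chromosomes)
    genome0: dict[str, list[_SimGene]] = {}
    for c in range(config.n_chromosomes):
        lo = c * per_chrom
        hi = min(lo + per_chrom, config.n_ancestral_genes)
        genome0[f"chr{c:02d}"] = [_SimGene(i, (), (), "+") for i in range(lo, hi)]

    tables: dict[str, GenomeTable] = {}
    truth = TruthSet(config.root_events)

    def walk(edge: str, genome: dict[str, list[_SimGene]]) -> None:
        length = config.branch_lengths.get(edge, 0.0)
        rate = config.rate(edge)
        events = sorted((e for e in config.events if e.branch == edge),
                        key=lambda e: -e.time)  # oldest (largest time-above-node) first
        pos = length
        for ev in events:
            _advance(genome, f"{edge}:{pos:.6f}", (pos - ev.time) * rate)
            genome = _apply_event(genome, ev, config.retention_prob, rng)
            pos = ev.time
        # tandem duplications act at the branch midpoint of the remaining
        # span so tandem pairs accumulate divergence before the next node
        _advance(genome, f"{edge}:{pos:.6f}", pos * rate / 2.0)
        _apply_tandem(genome, edge, config.tandem_rate, rng, tandem_counter)
        _advance(genome, f"{edge}:mid", pos * rate / 2.0)
        _apply_inversions(genome, rng.poisson(config.inversion_rate), rng)

        if edge in TREE_CHILDREN:
            left, right = TREE_CHILDREN[edge]
            walk(left, {c: [g.clone() for g in gs] for c, gs in genome.items()})
            walk(right, {c: [g.clone() for g in gs] for c, gs in genome.items()})
        else:
            taxon = edge
            if config.terminal_loss_prob > 0:
                # ongoing lineage-specific fractionation: each duplicate may
                # be lost, but never the last copy of a locus in this genome
                survivors: dict[int, int] = {}
                for chrom in sorted(genome):
                    for g in genome[chrom]:
                        survivors[g.locus] = survivors.get(g.locus, 0) + 1
                for chrom in sorted(genome):
                    kept = []
                    for g in genome[chrom]:
                        if (survivors[g.locus] > 1
                                and rng.random() < config.terminal_loss_prob):
                            survivors[g.locus] -= 1
                            continue
                        kept.append(g)
                    genome[chrom] = kept
            ordered: dict[str, list[tuple[str, str]]] = {}
            i = 0
            for chrom in sorted(genome):
                items = []
                for g in genome[chrom]:
                    gid = f"{taxon}_g{i:05d}"
                    i += 1
                    truth._add(gid, taxon, g)
                    items.append((gid, g.strand))
                ordered[f"{taxon}_{chrom}"] = items
            tables[taxon] = GenomeTable.from_ranked(taxon, ordered)

    walk("stem", genome0)
    return tables, truth


# --------------------------------------------------------------------------
# sequence evolution


def _jc_evolve_third(third: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor transition of third-position nucleotide indices (0..3)."""
    if t <= 0:
        return third.copy()
    p_stay = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    change = rng.random(third.size) >= p_stay
    out = third.copy()
    if change.any():
        shift = rng.integers(1, 4, size=int(change.sum()))
        out[change] = (out[change] + shift) % 4
    return out


def _evolve_families(fams: np.ndarray, t_ns: float, rng: np.random.Generator) -> np.ndarray:
    """Nonsynonymous moves between codon families at total rate ``2*t_ns``
    per codon (two nonsynonymous positions), restricted to the family set."""
    out = fams.copy()
    if t_ns <= 0:
        return out
    n_events = rng.poisson(2.0 * t_ns, size=fams.size)
    for idx in np.nonzero(n_events)[0]:
        fam = FAMILIES[out[idx]]
        for _ in range(n_events[idx]):
            moves = FAMILY_MOVES[fam]
            fam = moves[rng.integers(len(moves))]
        out[idx] = FAMILIES.index(fam)
    return out


class _TrieNode:
    __slots__ = ("children",)

    def __init__(self):
        self.children: dict[tuple, "_TrieNode | str"] = {}


def evolve_sequences(genomes: Mapping[str, GenomeTable], truth: TruthSet,
                     config: SimulationConfig) -> dict[str, str]:
    """Evolve a codon sequence for every extant gene along its true lineage.

    Genes sharing history prefixes share the corresponding evolution, so the
    realized substitution process is a proper gene tree: synonymous
    divergence between any two genes is, in expectation, the rate-scaled
    path length separating them (``TruthSet.divergence``).
    """
    if config.codon_length < 50:
        raise ValueError("codon_length must be >= 50 for stable Ks estimation")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    # group genes by locus; build a history trie per locus
    by_locus: dict[str, list[str]] = {}
    for gid, locus in sorted(truth.gene_lineage.items()):
        by_locus.setdefault(locus, []).append(gid)

    sequences: dict[str, str] = {}
    third_choices = np.arange(4)

    for locus in sorted(by_locus):
        root = _TrieNode()
        for gid in by_locus[locus]:
            node = root
            for seg in truth.gene_history[gid]:
                nxt = node.children.get(seg)
                if not isinstance(nxt, _TrieNode):
                    nxt = _TrieNode()
                    node.children[seg] = nxt
                node = nxt
            node.children[("leaf", gid)] = gid

        fams0 = rng.integers(0, len(FAMILIES), size=config.codon_length)
        third0 = rng.choice(third_choices, size=config.codon_length)

        stack: list[tuple[_TrieNode, np.ndarray, np.ndarray]] = [(root, fams0, third0)]
        while stack:
            node, fams, third = stack.pop()
            for key in sorted(node.children, key=repr):
                child = node.children[key]
                if isinstance(child, str):
                    seq = "".join(FAMILIES[f] + NUCS[t] for f, t in zip(fams, third))
                    sequences[child] = seq
                    continue
                t = key[1] if isinstance(key[1], float) else 0.0
                f2 = _evolve_families(fams, config.omega * t, rng) if t else fams
                t2 = _jc_evolve_third(third, t, rng) if t else third
                stack.append((child, f2, t2))
    return sequences


# --------------------------------------------------------------------------
# output emission


def _simulated_hit(pid: float, length_nt: int, evalue: float, bits: float,
                   q: str, s: str) -> str:
    mism = round(length_nt * (1.0 - pid / 100.0))
    return (f"{q}\t{s}\t{pid:.1f}\t{length_nt}\t{mism}\t0\t1\t{length_nt}"
            f"\t1\t{length_nt}\t{evalue:.2e}\t{bits:.1f}")


def hit_rows(truth: TruthSet, config: SimulationConfig, taxon_a: str, taxon_b: str,
             rng: np.random.Generator) -> list[tuple]:
    """Simulated 12-column tabular hits for every true homolog pair.

    Percent identity decays with true divergence d as
    ``100 * (0.45 + 0.55 exp(-d))`` plus Gaussian noise (sd 0.5); the
    E-value is a deterministic decreasing function of identity bounded at
    1e-6 so every emitted hit passes the 1e-5 screen.
    """
    rows = []
    length_nt = config.codon_length * 3
    for a, b, _rel in truth.true_pairs(taxon_a, taxon_b):
        if truth.gene_taxon[a] != taxon_a:
            a, b = b, a
        d = truth.divergence(a, b)
        pid = 100.0 * (0.45 + 0.55 * np.exp(-d)) + rng.normal(0.0, 0.5)
        pid = float(np.clip(pid, 30.0, 100.0))
        evalue = 10.0 ** -(6.0 + 174.0 * np.exp(-d))
        bits = 2.0 * config.codon_length * pid / 100.0
        rows.append((a, b, pid, length_nt, evalue, bits))
    return rows


def emit_outputs(genomes: Mapping[str, GenomeTable], sequences: Mapping[str, str],
                 truth: TruthSet, config: SimulationConfig, outdir: str | Path) -> dict:
    """Write per-taxon CDS FASTA + BED, pairwise hit tables, and truth TSV.

    Hit files ``hits.<A>-<B>.tsv`` (12-column BLAST tabular dialect) are
    written for every unordered taxon pair including self-comparisons, with
    queries drawn from taxon A.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    manifest: dict[str, str] = {}

    taxa = sorted(genomes)
    for taxon in taxa:
        table = genomes[taxon]
        bed = outdir / f"{taxon}.bed"
        table.write_bed(bed)
        fasta = outdir / f"{taxon}.cds.fasta"
        write_fasta({g.gene_id: sequences[g.gene_id] for g in table.genes}, fasta)
        manifest[f"bed:{taxon}"] = str(bed)
        manifest[f"cds:{taxon}"] = str(fasta)

    for a, b in itertools.combinations_with_replacement(taxa, 2):
        path = outdir / f"hits.{a}-{b}.tsv"
        with open(path, "w") as fh:
            for q, s, pid, ln, ev, bits in hit_rows(truth, config, a, b, rng):
                fh.write(_simulated_hit(pid, ln, ev, bits, q, s) + "\n")
        manifest[f"hits:{a}-{b}"] = str(path)

    tpath = outdir / "truth.tsv"
    truth.write_tsv(tpath)
    manifest["truth"] = str(tpath)
    return manifest


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None):
    """Convenience: history + sequences (+ files when ``outdir`` given)."""
    genomes, truth = simulate_history(config)
    sequences = evolve_sequences(genomes, truth, config)
    if outdir is not None:
        emit_outputs(genomes, sequences, truth, config, outdir)
    return genomes, truth, sequences


# --------------------------------------------------------------------------
# scenario presets


def _base_lengths() -> dict[str, float]:
    # node depths (one-way Ks, rate 1): root 0.25, cacao split 0.15,
    # durian-cotton split 0.12; the shared hexaploidization sits at depth
    # 0.60 (0.35 above the root on the stem).
    return {
        "stem": 0.45,
        "grape": 0.25,
        "malvales": 0.10,
        "cacao": 0.15,
        "malvaceae": 0.03,
        "durian": 0.12,
        "cotton": 0.12,
    }


def scenario(name: str, n_ancestral_genes: int = 200, n_chromosomes: int = 2,
             retention_prob: float = 1.0, seed: int = 0, codon_length: int = 200,
             **overrides) -> SimulationConfig:
    """Named polyploidy scenarios on the fixed 4-taxon phylogeny.

    ``ech_only``      shared hexaploidization only (expected grape:durian
                      orthology 1:1, outparalogy 1:2)
    ``ech_wgd``       shared hexaploidization + durian-lineage WGD (1:2, 1:4)
    ``ech_dsh``       shared hexaploidization + durian-lineage triplication
                      (1:3, 1:6)
    ``ech_dsh_gsd``   full model: + cotton-lineage decaploidization
    ``shared_trip``   alternative hypothesis: a single post-ECH triplication
                      on the durian+cotton stem (shared, not independent)
    ``rate_recovery`` full model with equal durian/cotton split depths and a
                      uniformly elevated cotton lineage (x1.64 from the cacao
                      split), the geometry used to exercise the two-step rate
                      correction: shared event at one-way depth 0.52 (peak
                      1.04), splits at 0.125, durian event at 0.085 (true
                      corrected peak 0.17), cotton event at 0.06 (true 0.12)
    ``study``         full model with gene loss, tandems, inversions and an
                      elevated cotton rate — the realistic default
    """
    ech = PolyploidyEvent("ECH", "stem", 3, 0.35)
    dsh = PolyploidyEvent("DSH", "durian", 3, 0.08)
    wgd = PolyploidyEvent("WGD", "durian", 2, 0.08)
    gsd = PolyploidyEvent("GSD", "cotton", 5, 0.05)
    shared = PolyploidyEvent("MST", "malvaceae", 3, 0.015)  # on durian+cotton stem

    events = {
        "ech_only": [ech],
        "ech_wgd": [ech, wgd],
        "ech_dsh": [ech, dsh],
        "ech_dsh_gsd": [ech, dsh, gsd],
        "shared_trip": [ech, shared],
        "rate_recovery": None,  # filled below
        "study": [ech, dsh, gsd],
    }
    if name not in events:
        raise ValueError(f"unknown scenario {name!r}")

    lengths = _base_lengths()
    if name == "rate_recovery":
        lengths = {"stem": 0.35, "grape": 0.25, "malvales": 0.125,
                   "cacao": 0.125, "malvaceae": 0.0, "durian": 0.125,
                   "cotton": 0.125}
        events[name] = [
            PolyploidyEvent("ECH", "stem", 3, 0.27),     # one-way depth 0.52
            PolyploidyEvent("DSH", "durian", 3, 0.085),  # true peak 0.17
            PolyploidyEvent("GSD", "cotton", 5, 0.06),   # true peak 0.12
        ]

    kwargs = dict(
        n_ancestral_genes=n_ancestral_genes,
        n_chromosomes=n_chromosomes,
        branch_lengths=lengths,
        events=events[name],
        retention_prob=retention_prob,
        seed=seed,
        codon_length=codon_length,
    )
    if name == "rate_recovery":
        kwargs.update(rate_multipliers={"cotton": 1.64})
    if name == "study":
        # realistic conditions: heavy fractionation, occasional tandems and
        # rearrangement, cotton lineage ~3x the grape clock after its
        # decaploidization (raises cotton-cacao orthologs ~64% above
        # durian-cacao, as observed between the real genomes)
        kwargs.update(
            retention_prob=0.5,
            tandem_rate=0.01,
            inversion_rate=1.0,
            rate_multipliers={"malvales": 1.25, "malvaceae": 1.3,
                              "durian": 1.4, "cotton": 3.0},
        )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# Ks thresholds separating ortholog from outparalog block medians in the
# synthetic scenarios (true ortholog Ks ~0.5 between grape and the ingroup
# taxa, ~0.24 durian-cotton; ECH outparalog Ks ~1.2).
SCENARIO_KS_THRESHOLDS = (0.85, 0.95)
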