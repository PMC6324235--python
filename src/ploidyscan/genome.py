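"""Gene-order containers and standard-format readers/writers.

A :class:`GenomeTable` is the ordered list of gene models of one genome:
every gene knows its chromosome, its rank (0-based position in gene order
along that chromosome), its strand and its bp interval.  All colinearity
chaining downstream works on ranks, never on bp coordinates.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """One gene model: id, chromosome, rank in gene order, strand, bp span."""

    gene_id: str
    chromosome: str
    rank: int
    strand: str = "+"
    start: int = 0
    end: int = 0


class GenomeTable:
    """Ordered gene models of one genome.

    Invariants: gene ids are unique; within each chromosome, ranks are the
    consecutive integers 0..n-1 in list order.
    """

    def __init__(self, taxon: str, genes: Iterable[GeneRecord]):
        self.taxon = taxon
        self.genes: list[GeneRecord] = list(genes)
        self._by_id: dict[str, GeneRecord] = {}
        self._chromosomes: "OrderedDict[str, list[GeneRecord]]" = OrderedDict()
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r} in {taxon}")
            self._by_id[g.gene_id] = g
            self._chromosomes.setdefault(g.chromosome, []).append(g)
        for chrom, recs in self._chromosomes.items():
            ranks = [g.rank for g in recs]
            if ranks != list(range(len(recs))):
                raise ValueError(
                    f"{taxon}/{chrom}: ranks must be consecutive from 0, got {ranks[:5]}..."
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def chromosomes(self) -> Mapping[str, list[GeneRecord]]:
        return self._chromosomes

    def chromosome_length(self, chrom: str) -> int:
        """Number of genes on a chromosome."""
        return len(self._chromosomes[chrom])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(g) for g in self.genes])

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_ranked(cls, taxon: str, ordered: Mapping[str, list[tuple[str, str]]],
                    gene_span: int = 1000) -> "GenomeTable":
        """Build from {chromosome: [(gene_id, strand), ...]} in gene order."""
        genes = []
        for chrom, items in ordered.items():
            for rank, (gid, strand) in enumerate(items):
                start = rank * gene_span
                genes.append(GeneRecord(gid, chrom, rank, strand, start, start + gene_span - 1))
        return cls(taxon, genes)

    def write_bed(self, path: str | Path) -> None:
        """BED6 (0-based half-open): chrom, start, end, gene_id, score, strand."""
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chromosome}\t{g.start}\t{g.end + 1}\t{g.gene_id}\t0\t{g.strand}\n")

    @classmethod
    def read_bed(cls, taxon: str, path: str | Path) -> "GenomeTable":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            usecols=range(6),
            dtype={"chrom": str, "start": int, "end": int, "gene_id": str, "strand": str},
        )
        return cls._from_coords(taxon, df)

    @classmethod
    def read_gff3(cls, taxon: str, path: str | Path, feature: str = "gene",
                  id_attr: str = "ID") -> "GenomeTable":
        """Read gene features from GFF3; gene id from the given attribute."""
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
        rows = []
        for feat in db.features_of_type(feature):
            if id_attr not in feat.attributes:
                raise ValueError(f"GFF3 {feature} feature without {id_attr}: {feat.id}")
            rows.append(
                {"chrom": feat.seqid, "start": feat.start - 1,  # GFF3 is 1-based
                 "end": feat.end, "gene_id": feat.attributes[id_attr][0],
                 "strand": feat.strand if feat.strand in "+-" else "+"}
            )
        return cls._from_coords(taxon, pd.DataFrame(rows))

    @classmethod
    def _from_coords(cls, taxon: str, df: pd.DataFrame) -> "GenomeTable":
        genes = []
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values(["start", "gene_id"], kind="stable")
            for rank, row in enumerate(sub.itertuples()):
                genes.append(GeneRecord(row.gene_id, str(chrom), rank,
                                        row.strand, int(row.start), int(row.end) - 1))
        return cls(taxon, genes)


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
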