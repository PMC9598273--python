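"""Shared containers for the ceRNA pipeline.

Coordinates are BED-style throughout: 0-based, half-open.  GFF3 is
converted to this convention on read and back on write.  Sequences are
stored in DNA space; ``U`` is normalised to ``T`` at ingest.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

# Sample-group vocabulary of the study design this pipeline targets:
# four tissues x three sexes, sample columns named <GROUP><replicate>,
# e.g. FB1..FB3 for female brain.
DEFAULT_TISSUES = ("B", "G", "L", "M")  # brain, gonad, liver, muscle
DEFAULT_SEXES = ("F", "M", "PM")  # female, male, pseudo-male

CIRC_CLASSES = ("annot_exon", "exon_intron", "antisense", "intergenic", "other")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def normalize_rna(seq: str) -> str:
    """Uppercase and map U->T so all matching happens in DNA space."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class InvalidArgumentError(ValueError):
    """Raised when an operation's preconditions are violated."""


class UndefinedCorrelationError(ValueError):
    """Correlation of a constant vector is undefined."""


@dataclass(frozen=True)
class StudyDesign:
    """Grouped study layout: |tissues| x |sexes| groups, equal replication.

    The default mirrors a 4-tissue x 3-sex x 3-replicate layout
    (36 samples).  Group labels are ``<sex><tissue>`` (``FB`` = female
    brain) and sample labels append the replicate number (``FB1``).
    """

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    sexes: tuple[str, ...] = DEFAULT_SEXES
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise InvalidArgumentError("replicates_per_group must be >= 2")
        if not self.tissues or not self.sexes:
            raise InvalidArgumentError("tissues and sexes must be non-empty")

    @property
    def n_groups(self) -> int:
        return len(self.tissues) * len(self.sexes)

    def groups(self) -> list[str]:
        # sex-major ordering: FB, FG, FL, FM, MB, ... PMM
        return [s + t for s in self.sexes for t in self.tissues]

    def samples(self) -> list[str]:
        return [g + str(r + 1) for g in self.groups() for r in range(self.replicates)]

    def group_of_sample(self, sample: str) -> str:
        return sample.rstrip("0123456789")

    def comparisons(self) -> list["Comparison"]:
        """All within-tissue sex-pair comparisons (12 for the default design)."""
        out = []
        for t in self.tissues:
            for a, b in itertools.combinations(self.sexes, 2):
                out.append(Comparison(tissue=t, group_a=a, group_b=b))
        return out


@dataclass(frozen=True)
class Comparison:
    """One pairwise comparison: sex ``group_a`` vs ``group_b`` within a tissue."""

    tissue: str
    group_a: str
    group_b: str

    @property
    def key(self) -> str:
        return f"{self.tissue}:{self.group_a}_vs_{self.group_b}"

    def columns(self, design: StudyDesign) -> tuple[list[str], list[str]]:
        cols_a = [self.group_a + self.tissue + str(r + 1) for r in range(design.replicates)]
        cols_b = [self.group_b + self.tissue + str(r + 1) for r in range(design.replicates)]
        return cols_a, cols_b


class ExpressionMatrix:
    """Features x samples non-negative count matrix with its design.

    Thin wrapper around a pandas DataFrame (rows = feature ids, columns =
    sample labels ``<GROUP><rep>``) carrying the :class:`StudyDesign` so
    group means and comparison columns can be derived without re-parsing
    column names.
    """

    def __init__(self, counts: pd.DataFrame, design: StudyDesign):
        expected = set(design.samples())
        if set(counts.columns) != expected:
            raise InvalidArgumentError(
                "count matrix columns do not match the design's sample labels"
            )
        if (counts.values < 0).any():
            raise InvalidArgumentError("counts must be non-negative")
        # canonical column order
        self.counts = counts.loc[:, design.samples()].copy()
        self.design = design

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def group_means(self) -> pd.DataFrame:
        """Features x groups mean expression (the 12 group-level profiles)."""
        groups = self.design.groups()
        cols = {g: [g + str(r + 1) for r in range(self.design.replicates)] for g in groups}
        return pd.DataFrame(
            {g: self.counts[c].mean(axis=1) for g, c in cols.items()},
            index=self.counts.index,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path, design: StudyDesign) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(df, design)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.counts.equals(other.counts)
            and self.design == other.design
        )


@dataclass(frozen=True)
class Gene:
    """A gene model: sorted, non-overlapping exons on one strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]


class GenomeAnnotation:
    """Gene models plus chromosome sizes, with GFF3 round-trip."""

    def __init__(self, genes: Sequence[Gene], chrom_sizes: Mapping[str, int]):
        self.genes = {g.gene_id: g for g in genes}
        self.chrom_sizes = dict(chrom_sizes)
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.start)

    def genes_on(self, chrom: str) -> list[Gene]:
        if chrom not in self.chrom_sizes:
            raise LookupError(f"unknown chromosome: {chrom}")
        return self._by_chrom.get(chrom, [])

    def overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        return [g for g in self.genes_on(chrom) if g.start < end and g.end > start]

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(self.chrom_sizes):
                fh.write(f"##sequence-region {chrom} 1 {self.chrom_sizes[chrom]}\n")
            for gid in sorted(self.genes):
                g = self.genes[gid]
                fh.write(
                    f"{g.chrom}\tcernaforge\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\tcernaforge\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GenomeAnnotation":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        chrom_sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _start, end = line.split()
                    chrom_sizes[chrom] = int(end)
        genes = []
        for feat in db.features_of_type("gene"):
            exons = tuple(
                sorted(
                    (e.start - 1, e.end)
                    for e in db.children(feat, featuretype="exon")
                )
            )
            genes.append(
                Gene(gene_id=feat.id, chrom=feat.seqid, strand=feat.strand, exons=exons)
            )
        for g in genes:
            chrom_sizes.setdefault(g.chrom, g.end + 1)
        return cls(genes, chrom_sizes)


@dataclass
class CircRecord:
    """One circRNA call.

    ``blocks`` are absolute 0-based half-open exon blocks for multi-exon
    (back-spliced exonic) circles; ``None`` means an unblocked interval.
    ``circ_class`` is assigned by the classifier, never supplied as input.
    """

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    blocks: tuple[tuple[int, int], ...] | None = None
    circ_class: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidArgumentError("require 0 <= start < end")
        if self.strand not in "+-":
            raise InvalidArgumentError("strand must be '+' or '-'")
        # canonical form: a single block spanning the interval is unblocked
        if self.blocks == ((self.start, self.end),):
            self.blocks = None

    @property
    def spliced_length(self) -> int:
        if self.blocks:
            return sum(e - s for s, e in self.blocks)
        return self.end - self.start


def write_bed12(records: Iterable[CircRecord], path: str | Path) -> None:
    """Write circRNA records as BED12 (0-based half-open, block-encoded)."""
    with open(path, "w") as fh:
        for r in records:
            blocks = r.blocks or ((r.start, r.end),)
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - r.start) for s, _ in blocks)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id}\t0\t{r.strand}\t"
                f"{r.start}\t{r.end}\t0\t{len(blocks)}\t{sizes},\t{starts},\n"
            )


def read_bed12(path: str | Path) -> list[CircRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            blocks = None
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                blocks = tuple(
                    (start + o, start + o + sz) for o, sz in zip(starts, sizes)
                )
            records.append(
                CircRecord(
                    circ_id=name, chrom=chrom, start=start, end=end,
                    strand=strand, blocks=blocks,
                )
            )
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA, normalising U->T."""
    from Bio import SeqIO

    return {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
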