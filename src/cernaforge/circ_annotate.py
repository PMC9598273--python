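"""Classify circRNA calls against a genome annotation and summarise them.

Classes are mutually exclusive, assigned by precedence:

1. ``annot_exon`` — same strand as a gene, both back-splice ends within
   ``tolerance`` nt of annotated exon boundaries of that gene, and the
   body covered by its exons (a circle of whole exons);
2. ``exon_intron`` — same-strand overlap of one gene touching both
   exonic and intronic sequence;
3. ``antisense`` — overlaps a gene only on the opposite strand;
4. ``intergenic`` — overlaps no gene;
5. ``other`` — anything else (e.g. sub-exonic intervals off the
   boundaries, or intron-only circles).

The boundary tolerance (default 2 nt) absorbs off-by-one dialect
differences between callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    CIRC_CLASSES,
    CircRecord,
    Gene,
    GenomeAnnotation,
    InvalidArgumentError,
)

# length histogram bins (inclusive edges)
LENGTH_BINS = (("100-2500", 100, 2500), ("2501-10000", 2501, 10000))

BOUNDARY_TOLERANCE = 2


def _segments(rec: CircRecord) -> tuple[tuple[int, int], ...]:
    """The transcribed body: exon blocks if present, else the whole span."""
    return rec.blocks or ((rec.start, rec.end),)


def _covered_by_exons(rec: CircRecord, gene: Gene, tol: int) -> bool:
    """True if every body segment lies within the exon union expanded by tol."""
    for seg_s, seg_e in _segments(rec):
        pos = seg_s
        for s, e in gene.exons:
            if s - tol <= pos < e + tol:
                pos = e + tol
                if pos >= seg_e:
                    break
        if pos < seg_e:
            return False
    return True


def _near_exon_boundaries(rec: CircRecord, gene: Gene, tol: int) -> bool:
    starts = {s for s, _ in gene.exons}
    ends = {e for _, e in gene.exons}
    return any(abs(rec.start - s) <= tol for s in starts) and any(
        abs(rec.end - e) <= tol for e in ends
    )


def _touches_exon_and_intron(rec: CircRecord, gene: Gene) -> bool:
    segs = _segments(rec)
    hits_exon = any(
        s < seg_e and e > seg_s for s, e in gene.exons for seg_s, seg_e in segs
    )
    hits_intron = any(
        s < seg_e and e > seg_s for s, e in gene.introns() for seg_s, seg_e in segs
    )
    return hits_exon and hits_intron


def classify_circ(
    record: CircRecord,
    annotation: GenomeAnnotation,
    tolerance: int = BOUNDARY_TOLERANCE,
) -> str:
    """Assign exactly one origin class to a circRNA record."""
    overlapping = annotation.overlapping(record.chrom, record.start, record.end)
    same = [g for g in overlapping if g.strand == record.strand]
    for g in same:
        if _near_exon_boundaries(record, g, tolerance) and _covered_by_exons(
            record, g, tolerance
        ):
            return "annot_exon"
    for g in same:
        if _touches_exon_and_intron(record, g):
            return "exon_intron"
    if any(g.strand != record.strand for g in overlapping):
        return "antisense"
    if not overlapping:
        return "intergenic"
    return "other"


def classify_all(
    records: Iterable[CircRecord],
    annotation: GenomeAnnotation,
    tolerance: int = BOUNDARY_TOLERANCE,
) -> list[CircRecord]:
    """Classify records in place and return them."""
    out = []
    for r in records:
        r.circ_class = classify_circ(r, annotation, tolerance)
        out.append(r)
    return out


@dataclass
class CircSummary:
    """Fig-1-style panels: class mix, length histogram, chromosome counts."""

    type_fractions: dict[str, float]
    length_histogram: dict[str, int]
    chrom_counts: dict[str, int]
    region_read_fractions: dict[str, float] | None = None

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for k, v in sorted(self.type_fractions.items()):
            rows.append(("type_fraction", k, v))
        for k, v in self.length_histogram.items():
            rows.append(("length_bin", k, v))
        for k, v in sorted(self.chrom_counts.items()):
            rows.append(("chrom_count", k, v))
        if self.region_read_fractions:
            for k, v in sorted(self.region_read_fractions.items()):
                rows.append(("region_read_fraction", k, v))
        pd.DataFrame(rows, columns=["panel", "key", "value"]).to_csv(
            path, sep="\t", index=False
        )


def length_bin(length: int) -> str:
    for name, lo, hi in LENGTH_BINS:
        if lo <= length <= hi:
            return name
    return "other"


def summarize(
    records: Sequence[CircRecord],
    annotation: GenomeAnnotation,
    read_region_counts: dict[str, float] | None = None,
    tolerance: int = BOUNDARY_TOLERANCE,
) -> CircSummary:
    """Classify and summarise a set of circRNA records.

    ``read_region_counts`` is an optional externally supplied
    exon/intron/intergenic read tally; it is reported as fractions and
    not derived from the records (read-level alignment is upstream of
    this tool).
    """
    if not records:
        raise InvalidArgumentError("record list must be non-empty")
    n = len(records)
    type_counts = {c: 0 for c in CIRC_CLASSES}
    hist = {name: 0 for name, _, _ in LENGTH_BINS}
    hist["other"] = 0
    chrom_counts: dict[str, int] = {}
    for r in records:
        cls = r.circ_class or classify_circ(r, annotation, tolerance)
        r.circ_class = cls
        type_counts[cls] += 1
        hist[length_bin(r.spliced_length)] += 1
        chrom_counts[r.chrom] = chrom_counts.get(r.chrom, 0) + 1
    region = None
    if read_region_counts:
        tot = sum(read_region_counts.values())
        region = {k: v / tot for k, v in read_region_counts.items()}
    return CircSummary(
        type_fractions={c: type_counts[c] / n for c in CIRC_CLASSES},
        length_histogram=hist,
        chrom_counts=chrom_counts,
        region_read_fractions=region,
    )


def plot_summary(summary: CircSummary, outdir: str | Path) -> list[Path]:
    """Optional bar/histogram plots of the summary panels (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, data in (
        ("type_fractions", summary.type_fractions),
        ("length_histogram", summary.length_histogram),
        ("chrom_counts", summary.chrom_counts),
    ):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        keys = list(data)
        ax.bar(range(len(keys)), [data[k] for k in keys])
        ax.set_xticks(range(len(keys)), keys, rotation=45, ha="right", fontsize=7)
        ax.set_title(name.replace("_", " "))
        fig.tight_layout()
        p = outdir / f"{name}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths
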