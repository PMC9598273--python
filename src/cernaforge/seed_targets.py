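"""Canonical miRNA seed-match target prediction.

Sites are defined by complementarity to the miRNA seed (nucleotides 2-8
of the mature miRNA, 5'->3'), in the four canonical classes:

- ``8mer``    — match to positions 2-8 plus an A opposite position 1;
- ``7mer-m8`` — match to positions 2-8;
- ``7mer-A1`` — match to positions 2-7 plus an A opposite position 1;
- ``6mer``    — match to positions 2-7 only.

Matching is single-strand, in DNA space (U normalised to T at ingest).
Overlapping candidates at one seed position collapse to the strongest
class.  No context scoring, conservation filtering or non-canonical
site types are applied: seed classes are the reproducible core of
canonical target prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .core import InvalidArgumentError, normalize_rna, revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_RANK = {t: i for i, t in enumerate(SITE_TYPES)}  # lower = stronger


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based start of the matched site on the transcript
    site_type: str


@dataclass(frozen=True)
class TargetPair:
    mirna_id: str
    transcript_id: str
    site_counts: tuple[tuple[str, int], ...]  # per-class counts, hierarchy order
    best_site_type: str

    @property
    def n_sites(self) -> int:
        return sum(c for _, c in self.site_counts)


def extract_seed(mirna_seq: str) -> str:
    """Seed heptamer: mature miRNA nucleotides 2-8 (1-based, 5'->3')."""
    seq = normalize_rna(mirna_seq)
    if len(seq) < 8:
        raise InvalidArgumentError("mature miRNA must be >= 8 nt")
    if set(seq) - set("ACGT"):
        raise InvalidArgumentError("miRNA sequence must be over {A,C,G,U/T}")
    return seq[1:8]


def scan_sites(
    transcript_seq: str, mirna_seq: str, mirna_id: str = "mirna", transcript_id: str = "tx"
) -> list[SeedSite]:
    """All canonical seed sites of one miRNA on one transcript.

    The scanner anchors on the 6mer core (reverse complement of seed
    positions 2-7), then upgrades by checking the m8 match one base 5'
    on the transcript and the A anchor one base 3'; each core position
    yields at most one site, of the strongest satisfied class.  Reported
    ``start`` is the first transcript base of the full matched pattern.
    """
    tseq = normalize_rna(transcript_seq)
    if not tseq:
        raise InvalidArgumentError("transcript sequence must be non-empty")
    if len(tseq) < 8:
        raise InvalidArgumentError("transcript must be >= 8 nt")
    seed7 = extract_seed(mirna_seq)  # positions 2-8
    core = revcomp(seed7[:6])  # RC of positions 2-7 (6 nt)
    m8 = revcomp(seed7[6])  # base pairing miRNA position 8
    sites = []
    pos = tseq.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and tseq[pos - 1] == m8
        has_a1 = pos + 6 < len(tseq) and tseq[pos + 6] == "A"
        if has_m8 and has_a1:
            stype, start = "8mer", pos - 1
        elif has_m8:
            stype, start = "7mer-m8", pos - 1
        elif has_a1:
            stype, start = "7mer-A1", pos
        else:
            stype, start = "6mer", pos
        sites.append(SeedSite(mirna_id, transcript_id, start, stype))
        pos = tseq.find(core, pos + 1)
    return sites


def scan_all(
    transcripts: Mapping[str, str], mirnas: Mapping[str, str]
) -> list[SeedSite]:
    out = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            out.extend(scan_sites(transcripts[tid], mirnas[mid], mid, tid))
    return out


def build_target_pairs(sites: Iterable[SeedSite]) -> list[TargetPair]:
    """Aggregate sites into miRNA->transcript relations.

    Deterministically ordered by (mirna_id, transcript_id); per-class
    counts follow the site hierarchy, best type is the strongest class
    present.
    """
    grouped: dict[tuple[str, str], dict[str, int]] = {}
    for s in sites:
        key = (s.mirna_id, s.transcript_id)
        grouped.setdefault(key, {t: 0 for t in SITE_TYPES})[s.site_type] += 1
    pairs = []
    for (mid, tid) in sorted(grouped):
        counts = grouped[(mid, tid)]
        best = min((t for t in SITE_TYPES if counts[t] > 0), key=_RANK.get)
        pairs.append(
            TargetPair(mid, tid, tuple((t, counts[t]) for t in SITE_TYPES), best)
        )
    return pairs


def sites_table(sites: Iterable[SeedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.mirna_id, s.transcript_id, s.start, s.site_type) for s in sites],
        columns=["mirna_id", "transcript_id", "start", "site_type"],
    )


def pairs_table(pairs: Iterable[TargetPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        counts = dict(p.site_counts)
        rows.append(
            (p.mirna_id, p.transcript_id, p.best_site_type, p.n_sites)
            + tuple(counts[t] for t in SITE_TYPES)
        )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "transcript_id", "best_site_type", "n_sites"]
        + [f"n_{t}" for t in SITE_TYPES],
    )
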