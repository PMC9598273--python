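"""Synthetic inputs with planted ground truth.

Every downstream stage of the pipeline (classification, differential
expression, target prediction, network assembly, qPCR concordance) has a
recoverable answer key: the generator plants circRNA origin classes,
negative-binomial differential expression, miRNA seed sites, and full
ceRNA triplets with the correlation structure the network filters are
designed to detect, and records all of it in a :class:`PlantedTruth`
ledger.

The generative model for counts is negative binomial with a single
user-set dispersion per matrix: mean = library factor x relative
abundance x multiplicative group effect, variance = mu + phi * mu^2.
Correlation structure for ceRNA triplets is planted on the group-level
(12-group) mean profiles, matching where the network module measures it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CIRC_CLASSES,
    CircRecord,
    Comparison,
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    InvalidArgumentError,
    StudyDesign,
    read_bed12,
    read_fasta,
    revcomp,
    write_bed12,
    write_fasta,
)

# Default circRNA class mix: the annot_exon / exon_intron fractions follow
# the empirical breakdown typical of vertebrate back-splice calls (about
# two-thirds exonic, one-sixth exon-intron); the remainder is split over
# antisense, intergenic and a catch-all class.
DEFAULT_TYPE_MIX = {
    "annot_exon": 0.67,
    "exon_intron": 0.16,
    "antisense": 0.06,
    "intergenic": 0.04,
    "other": 0.07,
}
DEFAULT_LENGTH_RANGE = (100, 2500)


@dataclass
class CountSimSpec:
    """Parameters of the NB count simulator.

    fraction_de : fraction of features given a multiplicative effect in one
        randomly chosen (sex, tissue) group.
    lfc : magnitude of the planted log2 effect (sign random); must be >= 1
        so planted features satisfy the |log2FC| >= 1 truth definition.
    dispersion : NB dispersion phi (variance = mu + phi mu^2).
    lib_size_range : relative library-size factors drawn uniformly per sample.
    mean_log : lognormal parameters of baseline per-feature abundance.
    """

    fraction_de: float = 0.1
    lfc: float = 2.0
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    mean_log: tuple[float, float] = (math.log(50.0), 1.0)

    def validate(self) -> None:
        if self.dispersion < 0:
            raise InvalidArgumentError("dispersion must be >= 0")
        if self.lib_size_range[0] <= 0:
            raise InvalidArgumentError("library sizes must be positive")
        if not 0 <= self.fraction_de <= 1:
            raise InvalidArgumentError("fraction_de must be in [0, 1]")
        if self.fraction_de > 0 and self.lfc < 1:
            raise InvalidArgumentError("planted |log2FC| must be >= 1")


@dataclass
class PlantedTruth:
    """Ground-truth ledger written alongside every synthetic bundle."""

    de_features: dict[str, set[str]] = field(default_factory=dict)
    null_features: set[str] = field(default_factory=set)
    triplets: list[tuple[str, str, str]] = field(default_factory=list)
    seed_sites: dict[tuple[str, str], list[tuple[int, str]]] = field(default_factory=dict)
    circ_classes: dict[str, str] = field(default_factory=dict)

    def merge(self, other: "PlantedTruth") -> None:
        for k, v in other.de_features.items():
            self.de_features.setdefault(k, set()).update(v)
        self.null_features |= other.null_features
        self.null_features -= {f for s in self.de_features.values() for f in s}
        self.triplets.extend(other.triplets)
        for k, v in other.seed_sites.items():
            self.seed_sites.setdefault(k, []).extend(v)
        self.circ_classes.update(other.circ_classes)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for comp, feats in sorted(self.de_features.items()):
            for f in sorted(feats):
                rows.append(("de", comp, f, "", ""))
        for f in sorted(self.null_features):
            rows.append(("null", "", f, "", ""))
        for c, m, g in self.triplets:
            rows.append(("triplet", c, m, g, ""))
        for (m, t), sites in sorted(self.seed_sites.items()):
            for pos, stype in sites:
                rows.append(("seed_site", m, t, str(pos), stype))
        for cid, cls in sorted(self.circ_classes.items()):
            rows.append(("circ_class", cid, cls, "", ""))
        pd.DataFrame(rows, columns=["kind", "a", "b", "c", "d"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlantedTruth":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
        t = cls()
        for kind, a, b, c, d in df.itertuples(index=False):
            if kind == "de":
                t.de_features.setdefault(a, set()).add(b)
            elif kind == "null":
                t.null_features.add(b)
            elif kind == "triplet":
                t.triplets.append((a, b, c))
            elif kind == "seed_site":
                t.seed_sites.setdefault((a, b), []).append((int(c), d))
            elif kind == "circ_class":
                t.circ_classes[a] = b
        return t


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    n_chrom: int, n_genes: int, seed: int
) -> GenomeAnnotation:
    """Random multi-exon gene models on ``n_chrom`` chromosomes.

    The last chromosome is labelled ``W`` and is deliberately gene-poor
    (< 25% of the mean genes per chromosome), emulating a degenerate
    female-specific sex chromosome.  Genes never overlap, on either
    strand, so planted circRNA classes stay unambiguous.
    """
    if n_chrom < 2 or n_genes < n_chrom:
        raise InvalidArgumentError("need n_chrom >= 2 and n_genes >= n_chrom")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chrom - 1)] + ["W"]
    mean_per_chrom = n_genes / n_chrom
    w_genes = int(0.1 * mean_per_chrom)  # strictly below the 25% bound
    remaining = n_genes - w_genes
    per_chrom = {c: remaining // (n_chrom - 1) for c in chroms[:-1]}
    for i in range(remaining - sum(per_chrom.values())):
        per_chrom[chroms[i % (n_chrom - 1)]] += 1
    per_chrom["W"] = w_genes

    genes: list[Gene] = []
    chrom_sizes: dict[str, int] = {}
    gidx = 0
    for chrom in chroms:
        cursor = int(rng.integers(1000, 3000))
        for _ in range(per_chrom[chrom]):
            n_exons = int(rng.integers(2, 7))
            exons = []
            pos = cursor
            for j in range(n_exons):
                elen = int(rng.integers(120, 401))
                exons.append((pos, pos + elen))
                pos += elen
                if j < n_exons - 1:
                    pos += int(rng.integers(200, 1501))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(
                    gene_id=f"gene_{gidx:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            gidx += 1
            cursor = pos + int(rng.integers(3000, 6001))
        chrom_sizes[chrom] = cursor + 5000
    return GenomeAnnotation(genes, chrom_sizes)


# ---------------------------------------------------------------------------
# circRNA planting
# ---------------------------------------------------------------------------

def _class_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so realised fractions track the mix."""
    items = sorted(mix.items())
    counts = {k: int(np.floor(v * n)) for k, v in items}
    rema = sorted(items, key=lambda kv: -(kv[1] * n - np.floor(kv[1] * n)))
    i = 0
    while sum(counts.values()) < n:
        counts[rema[i % len(rema)][0]] += 1
        i += 1
    return counts


def plant_circrnas(
    annotation: GenomeAnnotation,
    n_circ: int,
    type_mix: Mapping[str, float] | None = None,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    seed: int = 0,
) -> tuple[list[CircRecord], PlantedTruth]:
    """Plant circRNA records of known origin class against the annotation.

    Classes are constructed to satisfy the classifier's definitions
    exactly: annot_exon circles are unions of whole exons of one gene
    (same strand); exon_intron circles start on an exon boundary and end
    inside the following intron; antisense circles sit inside a gene on
    the opposite strand; intergenic circles overlap no gene; ``other``
    circles sit strictly inside a single exon away from its boundaries.
    """
    mix = dict(type_mix) if type_mix is not None else dict(DEFAULT_TYPE_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise InvalidArgumentError("type_mix fractions must sum to 1")
    if set(mix) - set(CIRC_CLASSES):
        raise InvalidArgumentError(f"unknown circRNA class in mix: {set(mix) - set(CIRC_CLASSES)}")
    lo, hi = length_range
    if lo < 100:
        raise InvalidArgumentError("minimum circRNA length is 100 nt")
    rng = np.random.default_rng(seed)
    counts = _class_counts(n_circ, mix)
    all_genes = sorted(annotation.genes.values(), key=lambda g: g.gene_id)
    records: list[CircRecord] = []
    truth = PlantedTruth()
    idx = 0

    def emit(rec: CircRecord, cls: str) -> None:
        nonlocal idx
        truth.circ_classes[rec.circ_id] = cls
        records.append(rec)
        idx += 1

    for cls in sorted(counts):
        for _ in range(counts[cls]):
            cid = f"circ_{idx:05d}"
            for _attempt in range(200):
                g = all_genes[int(rng.integers(len(all_genes)))]
                if cls == "annot_exon":
                    runs = []
                    for i in range(len(g.exons)):
                        total = 0
                        for j in range(i, len(g.exons)):
                            total += g.exons[j][1] - g.exons[j][0]
                            if lo <= total <= hi:
                                runs.append((i, j))
                            elif total > hi:
                                break
                    if not runs:
                        continue
                    i, j = runs[int(rng.integers(len(runs)))]
                    blocks = g.exons[i : j + 1]
                    rec = CircRecord(cid, g.chrom, blocks[0][0], blocks[-1][1],
                                     g.strand, blocks=tuple(blocks))
                elif cls == "exon_intron":
                    introns = g.introns()
                    if not introns:
                        continue
                    k = int(rng.integers(len(introns)))
                    ex_s, ex_e = g.exons[k]
                    in_s, in_e = introns[k]
                    max_into = min(in_e - in_s - 10, hi - (ex_e - ex_s))
                    if max_into < 50:
                        continue
                    end = ex_e + int(rng.integers(50, max_into + 1))
                    if not lo <= end - ex_s <= hi:
                        continue
                    rec = CircRecord(cid, g.chrom, ex_s, end, g.strand)
                elif cls == "antisense":
                    span = g.end - g.start
                    L = int(rng.integers(lo, min(hi, span) + 1)) if span > lo else span
                    if L < lo:
                        continue
                    s = g.start + int(rng.integers(0, span - L + 1))
                    rec = CircRecord(cid, g.chrom, s, s + L,
                                     "-" if g.strand == "+" else "+")
                elif cls == "intergenic":
                    chrom_genes = annotation.genes_on(g.chrom)
                    gi = chrom_genes.index(g)
                    gap_s = g.end + 10
                    gap_e = (
                        chrom_genes[gi + 1].start - 10
                        if gi + 1 < len(chrom_genes)
                        else annotation.chrom_sizes[g.chrom] - 10
                    )
                    if gap_e - gap_s < lo:
                        continue
                    L = int(rng.integers(lo, min(hi, gap_e - gap_s) + 1))
                    s = gap_s + int(rng.integers(0, gap_e - gap_s - L + 1))
                    rec = CircRecord(cid, g.chrom, s, s + L,
                                     "+" if rng.random() < 0.5 else "-")
                else:  # other: strictly inside one exon, clear of boundaries
                    wide = [e for e in g.exons if e[1] - e[0] >= lo + 10]
                    if not wide:
                        continue
                    ex_s, ex_e = wide[int(rng.integers(len(wide)))]
                    avail = ex_e - ex_s - 10
                    L = int(rng.integers(lo, min(hi, avail) + 1))
                    s = ex_s + 5 + int(rng.integers(0, avail - L + 1))
                    rec = CircRecord(cid, g.chrom, s, s + L, g.strand)
                emit(rec, cls)
                break
            else:
                raise RuntimeError(f"could not place a {cls} circRNA; annotation too small")
    return records, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 1e-12:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(
    design: StudyDesign,
    features: Sequence[str],
    spec: CountSimSpec | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """NB counts over the grouped design with planted DE features.

    Each DE feature gets a multiplicative ``2**(+/-lfc)`` effect in one
    randomly chosen (sex, tissue) group; the truth ledger records it
    under the two within-tissue comparisons that involve that sex.
    """
    if not features:
        raise InvalidArgumentError("feature list must be non-empty")
    spec = spec or CountSimSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    n = len(features)
    groups = design.groups()
    samples = design.samples()
    base = np.exp(rng.normal(spec.mean_log[0], spec.mean_log[1], size=n))
    lib = rng.uniform(*spec.lib_size_range, size=len(samples))

    effect = np.ones((n, len(groups)))
    truth = PlantedTruth()
    n_de = int(round(spec.fraction_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    de_set = set(de_idx.tolist())
    for fi in de_idx:
        sex = design.sexes[int(rng.integers(len(design.sexes)))]
        tissue = design.tissues[int(rng.integers(len(design.tissues)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        effect[fi, groups.index(sex + tissue)] = 2.0 ** (sign * spec.lfc)
        for comp in design.comparisons():
            if comp.tissue == tissue and sex in (comp.group_a, comp.group_b):
                truth.de_features.setdefault(comp.key, set()).add(features[fi])
    truth.null_features = {f for i, f in enumerate(features) if i not in de_set}

    group_idx = np.array([groups.index(design.group_of_sample(s)) for s in samples])
    mu = base[:, None] * effect[:, group_idx] * lib[None, :]
    counts = _nb_draw(rng, mu, spec.dispersion)
    df = pd.DataFrame(counts, index=list(features), columns=samples)
    mat = ExpressionMatrix(df, design)
    mat.lib_factors = dict(zip(samples, lib))  # kept for later re-draws
    return mat, truth


# ---------------------------------------------------------------------------
# ceRNA structure
# ---------------------------------------------------------------------------

def _seed_site_8mer(mirna_seq: str) -> str:
    """Target-strand 8mer site for a miRNA: RC of positions 2-8 plus an A
    opposite position 1 at the site's 3' end."""
    return revcomp(mirna_seq[1:8]) + "A"


def plant_cerna_structure(
    counts: Mapping[str, ExpressionMatrix],
    sequences: Mapping[str, str],
    n_triplets: int,
    scc_target: float = -0.8,
    pcc_target: float = 0.95,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, ExpressionMatrix], dict[str, str], PlantedTruth]:
    """Plant ceRNA triplets into existing count matrices and sequences.

    Triplets are planted in (circRNA, mRNA) pairs that share two sponge
    miRNAs, so the shared-miRNA hypergeometric test can reach
    significance in small universes.  Each pair gets a geometric ladder
    of group means (adjacent groups differ two-fold): circRNA and mRNA
    share the ladder (Pearson ~ +1 on true means) while its miRNAs get
    the reversed ladder (Spearman = -1 on true means).  Counts for the
    chosen rows are re-drawn from these means; the result is checked
    against ``scc_target`` / ``pcc_target`` on the realised group means
    and re-drawn (bounded retries) until the planted structure holds.

    An 8mer seed site for each sponge miRNA is written into both its
    circRNA and its mRNA 3'UTR sequence.
    """
    if scc_target > -0.7 or pcc_target < 0.9:
        raise InvalidArgumentError(
            "targets must be at least as strict as the network thresholds "
            "(scc_target <= -0.7, pcc_target >= 0.9)"
        )
    circ_m, mir_m, mrna_m = counts["circ"], counts["mirna"], counts["mrna"]
    if n_triplets > min(len(circ_m.features), len(mir_m.features), len(mrna_m.features)):
        raise InvalidArgumentError("n_triplets exceeds available features")
    from scipy.stats import pearsonr, spearmanr

    rng = np.random.default_rng(seed)
    design = circ_m.design
    samples = design.samples()
    groups = design.groups()
    group_idx = np.array([groups.index(design.group_of_sample(s)) for s in samples])

    counts_out = {k: ExpressionMatrix(v.counts.copy(), v.design) for k, v in counts.items()}
    for k in counts_out:
        if hasattr(counts[k], "lib_factors"):
            counts_out[k].lib_factors = counts[k].lib_factors
    seqs_out = dict(sequences)
    truth = PlantedTruth()

    # assign 2 miRNAs per (circ, mRNA) pair, plus one singleton if n is odd
    pair_sizes: list[int] = [2] * (n_triplets // 2) + ([1] if n_triplets % 2 else [])
    circ_ids = list(circ_m.features)[: len(pair_sizes)]
    mrna_ids = list(mrna_m.features)[: len(pair_sizes)]
    mir_pool = list(mir_m.features)
    mir_cursor = 0

    def redraw(mat: ExpressionMatrix, fid: str, means: np.ndarray) -> None:
        lib = np.array(
            [getattr(mat, "lib_factors", {}).get(s, 1.0) for s in samples]
        )
        mu = means[group_idx] * lib
        mat.counts.loc[fid, :] = _nb_draw(rng, mu, dispersion)

    for (cid, gid, size) in zip(circ_ids, mrna_ids, pair_sizes):
        mids = mir_pool[mir_cursor : mir_cursor + size]
        mir_cursor += size
        for _attempt in range(100):
            perm = rng.permutation(12 if len(groups) == 12 else len(groups))
            circ_means = 20.0 * 2.0 ** perm.astype(float)
            mrna_means = 15.0 * 2.0 ** perm.astype(float)
            mir_means = 20.0 * 2.0 ** (len(groups) - 1 - perm).astype(float)
            redraw(counts_out["circ"], cid, circ_means)
            redraw(counts_out["mrna"], gid, mrna_means)
            for mid in mids:
                redraw(counts_out["mirna"], mid, mir_means)
            gm = {k: counts_out[k].group_means() for k in ("circ", "mirna", "mrna")}
            c, g = gm["circ"].loc[cid].values, gm["mrna"].loc[gid].values
            ok = pearsonr(c, g).statistic >= pcc_target
            for mid in mids:
                m = gm["mirna"].loc[mid].values
                ok = ok and spearmanr(m, g).statistic <= scc_target
                ok = ok and spearmanr(m, c).statistic <= scc_target
            if ok:
                break
        else:
            raise RuntimeError("failed to realise planted correlation structure")
        reserved: dict[str, list[tuple[int, int]]] = {cid: [], gid: []}
        for mid in mids:
            site = _seed_site_8mer(seqs_out[mid])
            for tid in (cid, gid):
                tseq = seqs_out[tid]
                # keep planted sites disjoint so later insertions cannot
                # overwrite earlier ones
                for _try in range(200):
                    pos = int(rng.integers(0, len(tseq) - len(site) + 1))
                    if all(
                        pos + len(site) <= s or pos >= e for s, e in reserved[tid]
                    ):
                        break
                else:
                    raise RuntimeError("no room left for planted seed sites")
                reserved[tid].append((pos, pos + len(site)))
                seqs_out[tid] = tseq[:pos] + site + tseq[pos + len(site):]
                truth.seed_sites.setdefault((mid, tid), []).append((pos, "8mer"))
            truth.triplets.append((cid, mid, gid))
    return counts_out, seqs_out, truth


# ---------------------------------------------------------------------------
# sequences, terms, qPCR
# ---------------------------------------------------------------------------

def random_sequences(
    ids: Sequence[str], lengths: Mapping[str, int] | int, seed: int
) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    out = {}
    for i in ids:
        L = lengths if isinstance(lengths, int) else lengths[i]
        out[i] = "".join(rng.choice(list("ACGT"), size=L))
    return out


def random_term_map(
    genes: Sequence[str], n_terms: int, term_size_range: tuple[int, int], seed: int
) -> dict[str, set[str]]:
    rng = np.random.default_rng(seed)
    out = {}
    for t in range(n_terms):
        k = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        k = min(k, len(genes))
        members = rng.choice(len(genes), size=k, replace=False)
        out[f"TERM:{t:04d}"] = {genes[i] for i in members}
    return out


def simulate_ct_table(
    fold_changes: Mapping[str, Mapping[str, float]],
    calibrator: str,
    reference_ct: float = 18.0,
    base_dct: float = 5.0,
    noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct rows consistent with planted fold changes under the Livak model.

    ``fold_changes[target][group]`` is the intended 2^-ddCt fold relative
    to ``calibrator``; replicate Ct values get N(0, noise_sd) cycle noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for target, per_group in fold_changes.items():
        for group, fold in {**per_group, calibrator: 1.0}.items():
            ddct = -np.log2(fold)
            for rep in range(1, replicates + 1):
                ct_ref = reference_ct + rng.normal(0, noise_sd)
                ct_tgt = ct_ref + base_dct + ddct + rng.normal(0, noise_sd)
                rows.append((target, group, rep, round(ct_tgt, 3), round(ct_ref, 3)))
    return pd.DataFrame(
        rows, columns=["target_id", "group", "replicate", "ct_target", "ct_reference"]
    )


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """Sizes and signal settings of a full synthetic bundle.

    Defaults are the strong-signal study conditions used throughout the
    test suite: a modest genome, a few hundred features per matrix, 10%
    planted DE with |log2FC| = 2, and 8 planted ceRNA triplets.
    """

    n_chrom: int = 8
    n_genes: int = 200
    n_circ: int = 200
    n_mirna: int = 60
    n_mrna: int = 150
    n_triplets: int = 8
    type_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
    counts: CountSimSpec = field(default_factory=CountSimSpec)
    planted_dispersion: float = 0.05
    n_terms: int = 20
    term_size_range: tuple[int, int] = (5, 25)


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the truth ledger."""

    design: StudyDesign
    annotation: GenomeAnnotation
    circ_records: list[CircRecord]
    sequences: dict[str, str]  # miRNA mature, mRNA 3'UTR, circRNA
    counts: dict[str, ExpressionMatrix]  # keys: circ, mirna, mrna
    truth: PlantedTruth
    term_map: dict[str, set[str]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.annotation.to_gff3(outdir / "annotation.gff3")
        write_bed12(self.circ_records, outdir / "circrnas.bed")
        for kind in ("circ", "mirna", "mrna"):
            self.counts[kind].to_tsv(outdir / f"counts_{kind}.tsv")
        prefixes = {"circ": "circ_", "mirna": "mir_", "mrna": "mrna_"}
        for kind, pref in prefixes.items():
            write_fasta(
                {k: v for k, v in self.sequences.items() if k.startswith(pref)},
                outdir / f"seq_{kind}.fasta",
            )
        self.truth.to_tsv(outdir / "truth.tsv")
        rows = [
            (t, name, g)
            for t, members in sorted(self.term_map.items())
            for g in sorted(members)
            for name in [t.replace("TERM:", "term ")]
        ]
        pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"]).to_csv(
            outdir / "term_map.tsv", sep="\t", index=False
        )
        with open(outdir / "design.json", "w") as fh:
            json.dump(
                {
                    "tissues": list(self.design.tissues),
                    "sexes": list(self.design.sexes),
                    "replicates": self.design.replicates,
                    "seed": self.design.seed,
                },
                fh,
                indent=0,
                sort_keys=True,
            )

    @classmethod
    def read(cls, indir: str | Path) -> "SyntheticBundle":
        indir = Path(indir)
        with open(indir / "design.json") as fh:
            d = json.load(fh)
        design = StudyDesign(
            tuple(d["tissues"]), tuple(d["sexes"]), d["replicates"], d["seed"]
        )
        annotation = GenomeAnnotation.from_gff3(indir / "annotation.gff3")
        circ_records = read_bed12(indir / "circrnas.bed")
        counts = {
            kind: ExpressionMatrix.from_tsv(indir / f"counts_{kind}.tsv", design)
            for kind in ("circ", "mirna", "mrna")
        }
        sequences: dict[str, str] = {}
        for kind in ("circ", "mirna", "mrna"):
            sequences.update(read_fasta(indir / f"seq_{kind}.fasta"))
        truth = PlantedTruth.from_tsv(indir / "truth.tsv")
        tm_df = pd.read_csv(indir / "term_map.tsv", sep="\t")
        term_map: dict[str, set[str]] = {}
        for t, _n, g in tm_df.itertuples(index=False):
            term_map.setdefault(t, set()).add(g)
        return cls(design, annotation, circ_records, sequences, counts, truth, term_map)


def generate_bundle(
    spec: BundleSpec | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
) -> SyntheticBundle:
    """Generate a complete synthetic bundle with planted truth.

    Deterministic given ``seed``: all per-stage seeds are derived from it.
    """
    spec = spec or BundleSpec()
    design = design or StudyDesign(seed=seed)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2**31)]

    annotation = generate_annotation(spec.n_chrom, spec.n_genes, seeds[0])
    circ_records, circ_truth = plant_circrnas(
        annotation, spec.n_circ, spec.type_mix, spec.length_range, seeds[1]
    )
    circ_ids = [r.circ_id for r in circ_records]
    mir_ids = [f"mir_{i:04d}" for i in range(spec.n_mirna)]
    mrna_ids = [f"mrna_{i:04d}" for i in range(spec.n_mrna)]

    counts = {}
    truth = PlantedTruth()
    truth.merge(circ_truth)
    for kind, ids, s in (
        ("circ", circ_ids, seeds[2]),
        ("mirna", mir_ids, seeds[3]),
        ("mrna", mrna_ids, seeds[4]),
    ):
        mat, t = simulate_counts(design, ids, spec.counts, s)
        counts[kind] = mat
        truth.merge(t)

    seq_lengths: dict[str, int] = {m: 22 for m in mir_ids}
    seq_lengths.update({g: 500 for g in mrna_ids})
    seq_lengths.update(
        {r.circ_id: min(max(r.spliced_length, 100), 2500) for r in circ_records}
    )
    sequences = random_sequences(
        circ_ids + mir_ids + mrna_ids, seq_lengths, seeds[5]
    )

    counts, sequences, cerna_truth = plant_cerna_structure(
        counts,
        sequences,
        spec.n_triplets,
        dispersion=spec.planted_dispersion,
        seed=seeds[6],
    )
    truth.merge(cerna_truth)
    # planted ceRNA features are strongly group-structured, not null
    planted = {f for trip in cerna_truth.triplets for f in trip}
    truth.null_features -= planted

    term_map = random_term_map(mrna_ids, spec.n_terms, spec.term_size_range, seeds[7])
    return SyntheticBundle(design, annotation, circ_records, sequences, counts, truth, term_map)
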