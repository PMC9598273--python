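import dataclasses

import numpy as np
import pytest

from cernaforge.circ_annotate import classify_circ
from cernaforge.core import StudyDesign, InvalidArgumentError
from cernaforge.synthetic_data import (
    CountSimSpec,
    PlantedTruth,
    SyntheticBundle,
    generate_annotation,
    generate_bundle,
    plant_cerna_structure,
    plant_circrnas,
    simulate_counts,
)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def test_minimal_annotation_has_multi_exon_nonoverlapping_genes():
    ann = generate_annotation(2, 2, seed=1)
    assert len(ann.genes) == 2
    for g in ann.genes.values():
        assert len(g.exons) >= 2
    for chrom in ann.chrom_sizes:
        genes = ann.genes_on(chrom)
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start  # no overlap on either strand


def test_w_chromosome_is_gene_poor():
    ann = generate_annotation(22, 400, seed=7)
    w_count = len(ann.genes_on("W"))
    assert w_count < 0.25 * (400 / 22)


def test_annotation_deterministic(tmp_path):
    a1 = generate_annotation(5, 60, seed=7)
    a2 = generate_annotation(5, 60, seed=7)
    a1.to_gff3(tmp_path / "a1.gff3")
    a2.to_gff3(tmp_path / "a2.gff3")
    assert (tmp_path / "a1.gff3").read_bytes() == (tmp_path / "a2.gff3").read_bytes()


def test_annotation_rejects_bad_arguments():
    with pytest.raises(InvalidArgumentError):
        generate_annotation(1, 10, seed=0)
    with pytest.raises(InvalidArgumentError):
        generate_annotation(4, 2, seed=0)


def test_gff3_round_trip(tmp_path):
    ann = generate_annotation(3, 30, seed=2)
    ann.to_gff3(tmp_path / "a.gff3")
    from cernaforge.core import GenomeAnnotation

    back = GenomeAnnotation.from_gff3(tmp_path / "a.gff3")
    assert back.genes == ann.genes
    assert back.chrom_sizes == ann.chrom_sizes


# ---------------------------------------------------------------------------
# circRNA planting
# ---------------------------------------------------------------------------

def test_degenerate_mix_all_annot_exon():
    ann = generate_annotation(3, 50, seed=3)
    recs, truth = plant_circrnas(ann, 10, {"annot_exon": 1.0}, seed=4)
    assert len(recs) == 10
    assert all(classify_circ(r, ann) == "annot_exon" for r in recs)


def test_planted_lengths_stay_in_range():
    ann = generate_annotation(4, 80, seed=5)
    recs, _ = plant_circrnas(ann, 300, length_range=(100, 2500), seed=6)
    assert all(100 <= r.spliced_length <= 2500 for r in recs)


def test_mix_must_sum_to_one():
    ann = generate_annotation(3, 30, seed=1)
    with pytest.raises(InvalidArgumentError):
        plant_circrnas(ann, 10, {"annot_exon": 0.5}, seed=0)


def test_realised_fractions_track_mix():
    ann = generate_annotation(8, 200, seed=1)
    recs, truth = plant_circrnas(ann, 600, seed=2)
    from collections import Counter

    counts = Counter(truth.circ_classes.values())
    assert abs(counts["annot_exon"] / 600 - 0.67) <= 0.05
    assert abs(counts["exon_intron"] / 600 - 0.16) <= 0.05


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def test_no_de_when_fraction_zero(design):
    _, truth = simulate_counts(design, ["a", "b", "c"],
                               CountSimSpec(fraction_de=0.0), seed=1)
    assert truth.de_features == {}
    assert truth.null_features == {"a", "b", "c"}


def test_empty_feature_list_rejected(design):
    with pytest.raises(InvalidArgumentError):
        simulate_counts(design, [], seed=0)


def test_poisson_limit_variance_equals_mean(design):
    spec = CountSimSpec(fraction_de=0.0, dispersion=0.0, lib_size_range=(1.0, 1.0),
                        mean_log=(np.log(100.0), 0.3))
    mat, _ = simulate_counts(design, [f"f{i}" for i in range(10000)], spec, seed=8)
    x = mat.counts.values.astype(float)
    # constant mean across all 36 columns: index of dispersion ~ 1
    ratio = (x.var(axis=1, ddof=1) / x.mean(axis=1)).mean()
    assert abs(ratio - 1.0) < 0.05


def test_planted_lfc_recovered_in_group_means(design):
    """Planted log2FC = 3 shows up in the empirical group-mean ratio."""
    spec = CountSimSpec(fraction_de=1.0, lfc=3.0, dispersion=0.05,
                        lib_size_range=(1.0, 1.0), mean_log=(np.log(300.0), 0.2))
    errs = []
    for s in range(200):
        mat, truth = simulate_counts(design, ["f0"], spec, seed=1000 + s)
        comp_key = sorted(truth.de_features)[0]
        tissue, pair = comp_key.split(":")
        a, b = pair.split("_vs_")
        gm = mat.group_means()
        lfc = np.log2(gm.loc["f0", b + tissue] / gm.loc["f0", a + tissue])
        errs.append(abs(abs(lfc) - 3.0))
    assert np.mean(errs) < 0.5


# ---------------------------------------------------------------------------
# ceRNA planting
# ---------------------------------------------------------------------------

def test_planted_triplet_passes_filters_on_remeasure(design):
    from cernaforge.cerna_network import pearson, spearman
    from cernaforge.synthetic_data import random_sequences

    ids = {k: [f"{k}_{i}" for i in range(4)] for k in ("circ", "mir", "mrna")}
    counts = {}
    for kind, pref in (("circ", "circ"), ("mirna", "mir"), ("mrna", "mrna")):
        counts[kind], _ = simulate_counts(design, ids[pref],
                                          CountSimSpec(fraction_de=0.0), seed=3)
    seqs = random_sequences(ids["circ"] + ids["mrna"], 300, seed=4)
    seqs.update(random_sequences(ids["mir"], 22, seed=5))
    out_counts, out_seqs, truth = plant_cerna_structure(counts, seqs, 1, seed=6)
    assert len(truth.triplets) == 1
    c, m, g = truth.triplets[0]
    gm = {k: out_counts[k].group_means() for k in out_counts}
    assert spearman(gm["mirna"].loc[m], gm["mrna"].loc[g]) <= -0.8
    assert spearman(gm["mirna"].loc[m], gm["circ"].loc[c]) <= -0.8
    assert pearson(gm["circ"].loc[c], gm["mrna"].loc[g]) >= 0.95


def test_planted_site_recovered_by_scanner(bundle):
    from cernaforge import seed_targets

    for (m, t), sites in list(bundle.truth.seed_sites.items())[:4]:
        found = seed_targets.scan_sites(bundle.sequences[t], bundle.sequences[m], m, t)
        found_set = {(s.start, s.site_type) for s in found}
        for pos, stype in sites:
            assert (pos, stype) in found_set


def test_targets_on_wrong_side_of_thresholds_rejected(design):
    counts = {k: simulate_counts(design, ["x"], seed=1)[0]
              for k in ("circ", "mirna", "mrna")}
    with pytest.raises(InvalidArgumentError):
        plant_cerna_structure(counts, {}, 0, scc_target=-0.5)
    with pytest.raises(InvalidArgumentError):
        plant_cerna_structure(counts, {}, 0, pcc_target=0.5)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def test_bundle_truth_is_consistent(bundle):
    # every planted triplet's miRNA has a planted site on both partners
    for c, m, g in bundle.truth.triplets:
        assert (m, c) in bundle.truth.seed_sites
        assert (m, g) in bundle.truth.seed_sites
    # DE and null ledgers are disjoint
    de_all = set().union(*bundle.truth.de_features.values())
    assert not de_all & bundle.truth.null_features


def test_bundle_ids_resolve_and_counts_nonnegative(bundle):
    for kind in ("circ", "mirna", "mrna"):
        mat = bundle.counts[kind]
        assert (mat.counts.values >= 0).all()
        for f in mat.features:
            assert f in bundle.sequences
    assert all(set(s) <= set("ACGT") for s in bundle.sequences.values())


def test_bundle_disk_round_trip(bundle, tmp_path):
    bundle.write(tmp_path / "b")
    back = SyntheticBundle.read(tmp_path / "b")
    # classification state is not serialised; compare the call fields
    strip = lambda recs: [dataclasses.replace(r, circ_class=None) for r in recs]
    assert strip(back.circ_records) == strip(bundle.circ_records)
    assert back.sequences == bundle.sequences
    assert all(back.counts[k] == bundle.counts[k] for k in bundle.counts)
    assert back.truth.triplets == bundle.truth.triplets
    assert back.truth.de_features == bundle.truth.de_features
    assert back.term_map == bundle.term_map
    assert back.annotation.genes == bundle.annotation.genes


def test_bundle_deterministic(tmp_path):
    from cernaforge.synthetic_data import BundleSpec

    spec = BundleSpec(n_chrom=4, n_genes=60, n_circ=40, n_mirna=20, n_mrna=30,
                      n_triplets=2)
    b1 = generate_bundle(spec, seed=9)
    b2 = generate_bundle(spec, seed=9)
    b1.write(tmp_path / "b1")
    b2.write(tmp_path / "b2")
    for p1 in sorted((tmp_path / "b1").iterdir()):
        p2 = tmp_path / "b2" / p1.name
        assert p1.read_bytes() == p2.read_bytes(), p1.name
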