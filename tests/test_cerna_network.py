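import itertools
import math

import numpy as np
import pytest
from scipy import stats

from cernaforge import cerna_network as net
from cernaforge import de_analysis, seed_targets
from cernaforge.core import InvalidArgumentError, UndefinedCorrelationError


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_spearman_perfect_antimonotone():
    assert net.spearman([1, 2, 3], [3, 2, 1]) == -1.0


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    x = np.sort(rng.normal(size=20))
    assert abs(net.spearman(x, np.exp(x)) - 1.0) < 1e-12


def test_pearson_linear_cases():
    x = np.arange(10.0)
    assert abs(net.pearson(x, 2 * x + 1) - 1.0) < 1e-12
    assert abs(net.pearson(x, -x) + 1.0) < 1e-12


def test_correlations_match_oracles():
    """Spearman vs rank-then-Pearson; Pearson vs the covariance formula."""
    rng = np.random.default_rng(2)
    for _ in range(200):
        n = int(rng.integers(3, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if rng.random() < 0.3:  # inject ties
            x = np.round(x, 1)
            y = np.round(y, 1)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        if np.ptp(rx) == 0 or np.ptp(ry) == 0:
            continue
        scc_oracle = np.corrcoef(rx, ry)[0, 1]
        pcc_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std()
        )
        assert abs(net.spearman(x, y) - scc_oracle) < 1e-12
        assert abs(net.pearson(x, y) - pcc_oracle) < 1e-12


def test_constant_vector_is_undefined():
    with pytest.raises(UndefinedCorrelationError):
        net.spearman([1, 1, 1], [1, 2, 3])
    with pytest.raises(UndefinedCorrelationError):
        net.pearson([1, 2, 3], [5, 5, 5])


def test_short_or_unequal_vectors_rejected():
    with pytest.raises(InvalidArgumentError):
        net.spearman([1, 2], [3, 4])
    with pytest.raises(InvalidArgumentError):
        net.pearson([1, 2, 3], [1, 2])


# ---------------------------------------------------------------------------
# shared-sponge test
# ---------------------------------------------------------------------------

def test_disjoint_sets_give_p_one():
    assert net.shared_sponge_test({"a"}, {"b"}, 10) == (0, 1.0)


def test_worked_hypergeometric_case():
    n_shared, p = net.shared_sponge_test({"a", "b", "c"}, {"a", "b", "c"}, 10)
    assert n_shared == 3
    assert abs(p - 1 / 120) < 1e-12


def test_sets_exceeding_universe_rejected():
    with pytest.raises(InvalidArgumentError):
        net.shared_sponge_test({"a", "b"}, {"c"}, 2)


def enumeration_pmf_tail(N, K, n, s):
    """Exhaustive oracle: count n-subsets of an N-universe sharing >= s
    elements with a fixed K-subset (bitmask enumeration)."""
    circ_mask = (1 << K) - 1
    hits = total = 0
    for mask in range(1 << N):
        if mask.bit_count() != n:
            continue
        total += 1
        if (mask & circ_mask).bit_count() >= s:
            hits += 1
    return hits / total


def test_hypergeometric_matches_exhaustive_enumeration():
    for N in range(2, 13):
        for K in range(1, N + 1):
            for n in range(1, N + 1):
                circ = {f"m{i}" for i in range(K)}
                # choose an mrna set with a known overlap
                for shared in {0, min(K, n), max(0, K + n - N)}:
                    mrna = {f"m{i}" for i in range(shared)} | {
                        f"m{K + i}" for i in range(n - shared)
                    }
                    if len(mrna) != n or len(circ | mrna) > N:
                        continue
                    got_shared, p = net.shared_sponge_test(circ, mrna, N)
                    assert got_shared == shared
                    if shared > 0:
                        assert abs(p - enumeration_pmf_tail(N, K, n, shared)) < 1e-9


def test_null_sharing_rarely_significant():
    """Random independent sets of matched sizes: P(p < 0.05) stays near
    or below the nominal level."""
    rng = np.random.default_rng(3)
    N = 30
    hits = 0
    trials = 10000
    for _ in range(trials):
        K, n = 5, 6
        circ = set(rng.choice(N, size=K, replace=False).tolist())
        mrna = set(rng.choice(N, size=n, replace=False).tolist())
        _, p = net.shared_sponge_test(circ, mrna, N)
        hits += p < 0.05
    assert hits / trials <= 0.07


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def _network_inputs(bundle, bundle_de_sets):
    mirnas = {k: v for k, v in bundle.sequences.items() if k.startswith("mir_")}
    txs = {k: v for k, v in bundle.sequences.items()
           if k.startswith(("circ_", "mrna_"))}
    pairs = seed_targets.build_target_pairs(seed_targets.scan_all(txs, mirnas))
    return bundle_de_sets, pairs


def test_unsatisfiable_threshold_empties_network(bundle, bundle_de_sets):
    de_sets, pairs = _network_inputs(bundle, bundle_de_sets)
    nw = net.build_network(de_sets["circ"], de_sets["mirna"], de_sets["mrna"],
                           bundle.counts, pairs, scc_threshold=-1.01)
    assert nw.triplets == [] and nw.nodes == {}


def test_empty_de_sets_give_empty_network(bundle):
    nw = net.build_network(set(), set(), set(), bundle.counts, [])
    assert nw.triplets == [] and nw.edges == []


def test_tightening_thresholds_never_adds_triplets(bundle, bundle_de_sets):
    de_sets, pairs = _network_inputs(bundle, bundle_de_sets)

    def triplet_set(**kw):
        nw = net.build_network(de_sets["circ"], de_sets["mirna"],
                               de_sets["mrna"], bundle.counts, pairs, **kw)
        return {(t.circ_id, t.mirna_id, t.mrna_id) for t in nw.triplets}

    base = triplet_set()
    assert triplet_set(scc_threshold=-0.9) <= base
    assert triplet_set(pcc_threshold=0.97) <= base
    assert triplet_set(alpha=0.01) <= base


def test_network_referential_integrity(bundle, bundle_de_sets):
    de_sets, pairs = _network_inputs(bundle, bundle_de_sets)
    nw = net.build_network(de_sets["circ"], de_sets["mirna"], de_sets["mrna"],
                           bundle.counts, pairs)
    node_ids = set(nw.nodes)
    for e in nw.edges:
        assert e.source in node_ids and e.target in node_ids
    for t in nw.triplets:
        assert {t.circ_id, t.mirna_id, t.mrna_id} <= node_ids
        assert t.significant
        assert t.scc_mir_mrna < -0.7 and t.scc_mir_circ < -0.7
        assert t.pcc_circ_mrna > 0.9 and t.hypergeom_p < 0.05
    nc, nm, ng = nw.node_type_counts()
    assert nc + nm + ng == len(node_ids)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def test_export_round_trip_idempotent(bundle, bundle_de_sets, tmp_path):
    de_sets, pairs = _network_inputs(bundle, bundle_de_sets)
    nw = net.build_network(de_sets["circ"], de_sets["mirna"], de_sets["mrna"],
                           bundle.counts, pairs)
    p1 = net.export_network(nw, tmp_path / "x1", heatmap_profiles=bundle.counts["circ"])
    back = net.import_network(tmp_path / "x1")
    p2 = net.export_network(back, tmp_path / "x2")
    for key in ("nodes", "edges", "triplets", "sankey"):
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
    # Sankey conservation: one link per circ- and mRNA-side edge
    n_mc = sum(e.kind == "miRNA-circRNA" for e in nw.edges)
    n_mg = sum(e.kind == "miRNA-mRNA" for e in nw.edges)
    sankey_lines = (tmp_path / "x1" / "sankey.tsv").read_text().strip().splitlines()
    assert len(sankey_lines) - 1 == n_mc + n_mg


def test_empty_network_exports_headers_only(tmp_path):
    nw = net.CeRNANetwork(nodes={}, edges=[], triplets=[])
    paths = net.export_network(nw, tmp_path)
    for key in ("nodes", "edges", "triplets", "sankey"):
        lines = paths[key].read_text().strip().splitlines()
        assert len(lines) == 1  # header only
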