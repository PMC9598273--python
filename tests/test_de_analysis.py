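import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernaforge import de_analysis as de
from cernaforge.core import Comparison, ExpressionMatrix, InvalidArgumentError, StudyDesign
from cernaforge.synthetic_data import CountSimSpec, simulate_counts


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def test_identical_samples_get_unit_factors():
    df = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
    f = de.normalize_libsize(df)
    np.testing.assert_allclose(f.values, [1.0, 1.0])


def test_doubled_sample_keeps_unit_factor():
    rng = np.random.default_rng(0)
    base = rng.integers(1, 500, size=200)
    df = pd.DataFrame({"a": base, "b": 2 * base})
    f = de.normalize_libsize(df)
    # composition identical -> factors ~1; effective libs stay in ratio 1:2
    np.testing.assert_allclose(f.values, [1.0, 1.0], atol=1e-9)
    eff = df.sum(axis=0).values * f.values
    assert abs(eff[1] / eff[0] - 2.0) < 1e-9


def test_factor_geometric_mean_is_one():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.integers(0, 300, size=(500, 6)),
                      columns=list("abcdef"))
    f = de.normalize_libsize(df)
    assert abs(np.exp(np.log(f.values).mean()) - 1.0) < 1e-9


def test_all_zero_sample_rejected():
    df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(InvalidArgumentError):
        de.normalize_libsize(df)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def test_all_zero_counts_give_p_one():
    p = de.nb_exact_test(np.zeros((1, 3)), np.zeros((1, 3)), 0.1)
    assert p[0] == 1.0


def test_poisson_limit_matches_binomial_oracle():
    """At dispersion 0 with equal replication the conditional test is
    a two-sided binomial test of the group-A sum in the total."""
    p = de.nb_exact_test(np.array([[4, 3, 3]]), np.array([[0, 0, 0]]), 0.0)
    assert abs(p[0] - 2 * 0.5**10) < 1e-12
    # general case against scipy's two-sided binomial test
    for sa, sb in [(7, 2), (12, 5), (3, 3), (0, 6)]:
        ours = de.nb_exact_test(np.array([[sa, 0, 0]]), np.array([[sb, 0, 0]]), 0.0)[0]
        ref = stats.binomtest(sa, sa + sb, 0.5).pvalue
        assert abs(ours - ref) < 1e-10


def test_negative_counts_rejected():
    with pytest.raises(InvalidArgumentError):
        de.nb_exact_test(np.array([[-1, 0, 0]]), np.zeros((1, 3)), 0.1)
    with pytest.raises(InvalidArgumentError):
        de.nb_exact_test(np.zeros((1, 3)), np.zeros((1, 3)), -0.5)


def test_swapping_groups_preserves_p_and_negates_lfc(design):
    mat, _ = simulate_counts(design, [f"f{i}" for i in range(50)],
                             CountSimSpec(fraction_de=0.2), seed=4)
    fwd = de.call_de(mat, Comparison("B", "F", "M"), dispersion=0.1)
    rev = de.call_de(mat, Comparison("B", "M", "F"), dispersion=0.1)
    for a, b in zip(fwd, rev):
        assert abs(a.p_value - b.p_value) < 1e-9
        assert abs(a.log2fc + b.log2fc) < 1e-9


def test_raising_lfc_threshold_never_adds_calls(design):
    mat, _ = simulate_counts(design, [f"f{i}" for i in range(100)],
                             CountSimSpec(fraction_de=0.3, lfc=2.5), seed=5)
    comp = Comparison("G", "F", "PM")
    sig_by_thr = []
    for thr in (0.5, 1.0, 2.0, np.inf):
        res = de.call_de(mat, comp, lfc_threshold=thr)
        sig_by_thr.append({r.feature_id for r in res if r.significant})
    for lo, hi in zip(sig_by_thr, sig_by_thr[1:]):
        assert hi <= lo
    assert sig_by_thr[-1] == set()  # infinite threshold: nothing passes


def test_missing_column_raises(design):
    mat, _ = simulate_counts(design, ["f0"], seed=1)
    small = StudyDesign(tissues=("B",), sexes=("F", "M"))
    with pytest.raises(LookupError):
        de.call_de(mat, Comparison("X", "F", "M"))


def test_significance_rule_is_fold_change_and_p(design):
    mat, _ = simulate_counts(design, [f"f{i}" for i in range(200)],
                             CountSimSpec(fraction_de=0.3, lfc=3.0), seed=6)
    for r in de.call_de(mat, Comparison("L", "M", "PM")):
        assert r.significant == (abs(r.log2fc) >= 1.0 and r.p_value < 0.05)


# ---------------------------------------------------------------------------
# set intersections
# ---------------------------------------------------------------------------

def brute_force_regions(named_sets):
    """Independent oracle: classify every element by its membership pattern."""
    regions = {}
    universe = set().union(*named_sets.values())
    for r in range(1, len(named_sets) + 1):
        for combo in itertools.combinations(sorted(named_sets), r):
            n = 0
            for el in universe:
                membership = frozenset(k for k, v in named_sets.items() if el in v)
                if membership == frozenset(combo):
                    n += 1
            regions[frozenset(combo)] = n
    return regions


def test_two_set_example():
    regions = de.intersect_de_sets({"A": {1, 2}, "B": {2, 3}})
    assert regions[frozenset({"A"})] == 1
    assert regions[frozenset({"B"})] == 1
    assert regions[frozenset({"A", "B"})] == 1


def test_identical_sets_only_fill_full_region():
    s = {1, 2, 3}
    regions = de.intersect_de_sets({"A": set(s), "B": set(s), "C": set(s)})
    assert regions[frozenset({"A", "B", "C"})] == 3
    assert sum(v for k, v in regions.items() if len(k) < 3) == 0


def test_regions_sum_to_union_and_match_oracle():
    rng = np.random.default_rng(7)
    for trial in range(100):
        k = int(rng.integers(2, 6))
        sets = {
            f"S{i}": set(rng.choice(30, size=rng.integers(0, 15), replace=False).tolist())
            for i in range(k)
        }
        regions = de.intersect_de_sets(sets)
        assert regions == brute_force_regions(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))


def test_set_count_out_of_range_rejected():
    with pytest.raises(InvalidArgumentError):
        de.intersect_de_sets({"A": {1}})
    with pytest.raises(InvalidArgumentError):
        de.intersect_de_sets({f"S{i}": {i} for i in range(6)})
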