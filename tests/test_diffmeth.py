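"""Two-group tests, BH step-up, classification rules, and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from epiarray.diffmeth import (
    DiffThresholds,
    bh_adjust,
    classify,
    diff_test,
    hier_cluster,
    summarize_counts,
    two_group_test,
)
from epiarray.errors import ValidationError

GROUPS = np.array(["g1", "g1", "g1", "g2", "g2", "g2"])
ORDER = ("g1", "g2")


def test_identical_group_means_give_zero_log2fc():
    values = np.array([1.0, 2.0, 3.0, 3.0, 1.0, 2.0])
    log2fc, p = two_group_test(values, GROUPS, ORDER)
    assert log2fc == pytest.approx(0.0)
    assert p > 0.9


def test_zero_variance_unequal_means_forced():
    log2fc, p = two_group_test(np.array([5.0, 5, 5, 6, 6, 6]), GROUPS, ORDER)
    assert log2fc == pytest.approx(1.0)
    assert 0 < p < 1e-300  # smallest representable positive, not zero


def test_zero_variance_equal_means_gives_p_one():
    _, p = two_group_test(np.array([5.0] * 6), GROUPS, ORDER)
    assert p == 1.0


def test_too_few_finite_values_gives_missing_p():
    values = np.array([5.0, np.nan, np.nan, 6.0, 6.5, 7.0])
    log2fc, p = two_group_test(values, GROUPS, ORDER)
    assert np.isnan(p)


def test_vectorized_diff_test_matches_scipy_per_transcript(small_profile):
    """The vectorized table agrees with scipy's t-test transcript by transcript."""
    for equal_var in (True, False):
        table = diff_test(small_profile, "m6a", equal_var=equal_var)
        data = small_profile.m6a
        groups = small_profile.samples["group"].to_numpy()
        g1, g2 = small_profile.group_names
        rng = np.random.default_rng(0)
        for tx in rng.choice(data.index, size=40, replace=False):
            row = data.loc[tx].to_numpy()
            a, b = row[groups == g1], row[groups == g2]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size < 2 or b.size < 2:
                assert np.isnan(table.loc[tx, "p"])
                continue
            expected = stats.ttest_ind(b, a, equal_var=equal_var)
            assert table.loc[tx, "log2fc"] == pytest.approx(b.mean() - a.mean())
            assert table.loc[tx, "p"] == pytest.approx(expected.pvalue, rel=1e-9)


def test_swapping_group_labels_negates_fold_changes(small_profile):
    fwd = diff_test(small_profile, "m6a", group_order=small_profile.group_names)
    rev = diff_test(small_profile, "m6a", group_order=small_profile.group_names[::-1])
    assert np.allclose(fwd["log2fc"], -rev["log2fc"], equal_nan=True)
    assert np.allclose(fwd["p"], rev["p"], equal_nan=True)
    swapped = fwd["class"].map({"up": "down", "down": "up", "ns": "ns"})
    assert (swapped == rev["class"]).all()


# ---------------------------------------------------------------------------
# BH correction
# ---------------------------------------------------------------------------

def brute_force_bh(p):
    """Direct transcription of the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        adj[idx] = min(1.0, min(candidates))
    return adj


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.005, 0.04, 0.5], [0.015, 0.06, 0.5]),
    ],
)
def test_bh_known_values(p, expected):
    assert bh_adjust(p) == pytest.approx(expected)


def test_bh_agrees_with_brute_force_and_statsmodels():
    rng = np.random.default_rng(99)
    for _ in range(50):
        p = rng.random(rng.integers(1, 60))
        ours = bh_adjust(p)
        assert ours == pytest.approx(brute_force_bh(p))
        assert ours == pytest.approx(multipletests(p, method="fdr_bh")[1])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
def test_bh_properties(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)  # adjusted never below raw
    assert np.all(adj <= 1.0)
    # monotone: ordering of adjusted p follows ordering of raw p
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def toy_results(rows):
    fc = np.array([r[0] for r in rows], dtype=float)
    return pd.DataFrame(
        {
            "rna_class": "mRNA",
            "measure": "m6a",
            "log2fc": np.log2(fc),
            "fc": fc,
            "p": [r[1] for r in rows],
            "p_adj": [r[1] for r in rows],
        },
        index=[f"t{i}" for i in range(len(rows))],
    )


def test_classify_toy_table():
    rows = [(2.0, 0.01), (0.5, 0.01), (1.6, 0.2), (1.2, 0.01), (0.6, 0.04)]
    out = classify(toy_results(rows), DiffThresholds())
    assert list(out["class"]) == ["up", "down", "ns", "ns", "down"]


@pytest.mark.parametrize(
    "fc, p, expected",
    [
        (1.5, 0.01, "ns"),       # boundary is strict: fold change must exceed 1.5
        (1.0 / 1.5, 0.01, "ns"),
        (2.0, 0.2, "ns"),
        (2.0, 0.05, "ns"),       # p threshold is strict too
        (1.51, 0.049, "up"),
        (0.66, 0.049, "down"),
        (2.0, float("nan"), "ns"),
    ],
)
def test_classify_boundaries(fc, p, expected):
    out = classify(toy_results([(fc, p)]), DiffThresholds())
    assert out["class"].iloc[0] == expected


def test_classify_with_adjusted_p():
    out = classify(toy_results([(2.0, 0.01)]).assign(p_adj=[0.2]),
                   DiffThresholds(use_adjusted=True))
    assert out["class"].iloc[0] == "ns"


def test_summary_counts_pool_small_ncrna_classes():
    df = toy_results([(2.0, 0.01), (0.5, 0.01), (1.0, 0.9), (2.0, 0.01), (2.0, 0.01)])
    df["rna_class"] = ["mRNA", "lncRNA", "mRNA", "snoRNA", "pre-miRNA"]
    table = summarize_counts(classify(df))
    assert table.loc["mRNA", "up"] == 1
    assert table.loc["mRNA", "ns"] == 1
    assert table.loc["lncRNA", "down"] == 1
    assert table.loc["sncRNA", "up"] == 2
    assert table["total"].sum() == 5


def test_invalid_thresholds_rejected():
    with pytest.raises(ValidationError):
        DiffThresholds(fc_cut=1.0)
    with pytest.raises(ValidationError):
        DiffThresholds(p_cut=0.0)


# ---------------------------------------------------------------------------
# Hierarchical clustering of samples
# ---------------------------------------------------------------------------

def test_identical_samples_merge_first():
    rng = np.random.default_rng(5)
    base = rng.normal(size=30)
    mat = pd.DataFrame(
        {"a": base, "b": base, "c": rng.normal(size=30), "d": rng.normal(size=30)}
    )
    res = hier_cluster(mat)
    merged_first = {res.sample_ids[int(res.linkage[0, 0])],
                    res.sample_ids[int(res.linkage[0, 1])]}
    assert merged_first == {"a", "b"}
    assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_cluster_order_equivariance():
    rng = np.random.default_rng(6)
    mat = pd.DataFrame(rng.normal(size=(40, 6)),
                       columns=[f"s{i}" for i in range(6)])
    res = hier_cluster(mat)
    perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
    res_p = hier_cluster(mat[perm])
    # same partition of samples regardless of column order
    part = {frozenset(res.labels.index[res.labels == c]) for c in (1, 2)}
    part_p = {frozenset(res_p.labels.index[res_p.labels == c]) for c in (1, 2)}
    assert part == part_p


def test_constant_sample_vector_handled():
    mat = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0],
                        "c": [1.1, 2.0, 2.9]})
    res = hier_cluster(mat)  # must not raise despite undefined correlations
    assert set(res.labels) == {1, 2}


def test_newick_contains_all_samples(small_profile):
    res = hier_cluster(small_profile.m6a)
    assert res.newick.endswith(";")
    for s in small_profile.samples.index:
        assert s in res.newick


def test_cluster_requires_two_samples():
    with pytest.raises(ValidationError):
        hier_cluster(pd.DataFrame({"a": [1.0, 2.0]}))
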