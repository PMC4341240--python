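"""Normalization, fold-change rules, exact test, screening, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from taprootmir.diffexp import (ac_pvalue, ac_pvalue_reference,
                                cluster_patterns, expression_table,
                                fold_change, normalize_rpm, screen)

LIBSIZES = {"stage1": 16819905, "stage2": 18853348, "stage3": 17082616}


@pytest.mark.parametrize("count,libsize,expected", [
    (50613, 18853348, 2684.56),   # a steeply declining conserved family
    (16238, 17082616, 950.56),
    (0, 10**6, 0.00),
])
def test_rpm_reproduces_printed_normalized_counts(count, libsize, expected):
    assert normalize_rpm(count, libsize, ndigits=2) == expected


def test_rpm_rejects_bad_libsize():
    with pytest.raises(ValueError):
        normalize_rpm(10, 0)


@pytest.mark.parametrize("a,b,expected", [
    (0, 140.03, 13.77),        # zero control substituted by 0.01
    (2834.86, 0, -18.11),      # zero treatment substituted by 0.01
    (1040.43, 643.12, -0.69),
    (2684.56, 950.56, -1.50),
    (7.0, 7.0, 0.00),
])
def test_fold_change_with_zero_substitution(a, b, expected):
    assert fold_change(a, b, ndigits=2) == expected


def test_fold_change_skips_when_both_below_one():
    assert fold_change(0.0, 0.0) is None
    assert fold_change(0.5, 0.9) is None
    assert fold_change(0.5, 2.0) is not None


_rpm_values = st.one_of(st.just(0.0),
                        st.floats(min_value=1e-3, max_value=1e6))


@given(_rpm_values, _rpm_values)
def test_fold_change_antisymmetric(a, b):
    fab = fold_change(a, b)
    fba = fold_change(b, a)
    assert (fab is None) == (fba is None)
    if fab is not None:
        assert fab == pytest.approx(-fba, abs=1e-9)


def test_ac_pvalue_degenerate_cases():
    assert ac_pvalue(0, 10**6, 0, 10**6) == 1.0
    assert ac_pvalue(5, 10**4, 5, 10**4) == 1.0
    assert 0 < ac_pvalue(100, 10**4, 5, 10**4) < 1e-10


def test_ac_pvalue_matches_high_precision_summation_oracle():
    """Two-sided exact-test p agrees with direct summation of the conditional
    count distribution to 1e-10 relative, over a seeded grid spanning counts
    0..1e5 and unequal library sizes."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        x = int(rng.integers(0, 100001))
        y = int(rng.integers(0, 100001))
        n1 = int(rng.integers(10**4, 10**7))
        n2 = int(rng.integers(10**4, 10**7))
        p = ac_pvalue(x, n1, y, n2)
        ref = ac_pvalue_reference(x, n1, y, n2)
        if ref < 1e-290:  # beyond double's normal range: no relative scale
            assert p < 1e-290
        else:
            assert p == pytest.approx(ref, rel=1e-10)


def test_ac_pvalue_swap_symmetry_properties():
    """The conditional count model is exactly symmetric pointwise --
    p(x | y; N2, N1) = (N2/N1) * p(y | x; N1, N2) -- and in the regime that
    drives significance calls (p > 1e-3) swapping the libraries moves the
    two-sided p by less than a factor of two."""
    from scipy import stats

    rng = np.random.default_rng(4)
    for _ in range(100):
        x = int(rng.integers(0, 2000))
        y = int(rng.integers(0, 2000))
        n1 = int(rng.integers(10**4, 10**6))
        n2 = int(rng.integers(10**4, 10**6))
        pmf = stats.nbinom.pmf(y, x + 1, n1 / (n1 + n2)) * (n2 / n1)
        pmf_swapped = stats.nbinom.pmf(x, y + 1, n2 / (n1 + n2))
        if pmf_swapped > 0:
            assert pmf == pytest.approx(pmf_swapped, rel=1e-4)
        a = ac_pvalue(x, n1, y, n2)
        b = ac_pvalue(y, n2, x, n1)
        if min(a, b) > 1e-3:
            assert 0.5 <= a / b <= 2.0


def _records():
    return pd.DataFrame({
        "mirna_id": ["m1", "m2", "m3", "m4"],
        "family": ["f1", "f2", "f3", "f4"],
        "count_stage1": [600, 100, 0, 300],
        "count_stage2": [55, 110, 0, 600],
        "count_stage3": [13, 95, 0, 80],
    })


def test_expression_table_screen_and_clusters():
    table = expression_table(_records(), {s: 20000 for s in LIBSIZES})
    t = table.set_index("mirna_id")
    assert t.loc["m1", "de"] and t.loc["m1", "cluster"] == "down_down"
    assert not t.loc["m2", "de"]
    assert not t.loc["m3", "de"]          # all comparisons skipped
    assert t.loc["m3", "skipped_stage2_stage1"]
    de = screen(table)
    assert set(de["mirna_id"]) == set(table[table["de"]]["mirna_id"])


def test_screen_threshold_is_on_absolute_log2fc():
    df = pd.DataFrame({
        "log2fc_stage2_stage1": [0.5], "pvalue_stage2_stage1": [1e-6],
        "skipped_stage2_stage1": [False],
        "log2fc_stage3_stage1": [-0.5], "pvalue_stage3_stage1": [1e-6],
        "skipped_stage3_stage1": [False],
        "log2fc_stage3_stage2": [-0.9], "pvalue_stage3_stage2": [1e-6],
        "skipped_stage3_stage2": [False],
    })
    assert screen(df).empty


@pytest.mark.parametrize("fc21,fc32,label", [
    (-2.0, -1.5, "down_down"),
    (1.2, -2.1, "up_down"),
    (0.0, 1.1, "flat_up"),
])
def test_cluster_sign_patterns(fc21, fc32, label):
    df = pd.DataFrame({"log2fc_stage2_stage1": [fc21],
                       "log2fc_stage3_stage2": [fc32]})
    assert cluster_patterns(df) == [label]


def test_rpm_sums_to_one_million_over_full_tag_table(full_run):
    tags = full_run.tags
    for stage in ("stage1", "stage2", "stage3"):
        lib = full_run.libsizes[stage]
        rpm = tags[f"count_{stage}"] / lib * 1e6
        assert rpm.sum() == pytest.approx(1e6, rel=1e-6)


def test_simulated_de_recovery_and_null_fpr(full_run):
    """Every planted effect with true |log2FC| >= 2 and adequate counts is
    flagged DE; planted nulls stay below a 2-alpha false-positive rate."""
    truth = full_run.sim.truth.set_index("sequence")
    expr = full_run.expression
    seq_by_id = {m.name: m.sequence for m in full_run.bundle.mature_catalog}
    seq_by_id.update({c.name: c.mature_seq for c in full_run.candidates})
    expr = expr.assign(sequence=[seq_by_id.get(i) for i in expr["mirna_id"]])
    expr = expr[expr["sequence"].notna()].set_index("sequence")

    lfc_cols = ["true_lfc_s2_s1", "true_lfc_s3_s1", "true_lfc_s3_s2"]
    stage_pairs = [("stage2", "stage1"), ("stage3", "stage1"),
                   ("stage3", "stage2")]
    nulls = fps = 0
    for seq, row in truth.iterrows():
        if row["kind"] not in ("known_mirna", "novel_mature"):
            continue
        if seq not in expr.index:
            assert max(row[f"expected_{s}"] for s in
                       ("stage1", "stage2", "stage3")) < 5
            continue
        flagged = bool(expr.loc[seq, "de"])
        must_flag = any(
            abs(row[c]) >= 2 and max(row[f"expected_{b}"],
                                     row[f"expected_{a}"]) >= 50
            for c, (b, a) in zip(lfc_cols, stage_pairs))
        if must_flag:
            assert flagged, f"planted effect not recovered: {row['name']}"
        if not row["true_de"]:
            nulls += 1
            fps += flagged
    assert nulls >= 4
    assert fps / nulls <= 0.10
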