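"""Read cleaning: category order, Table-style accounting, tag collapsing."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from taprootmir import sim_data
from taprootmir.read_clean import (CleaningSummary, FastqFormatError,
                                   assess_read, clean_library,
                                   combine_tag_tables, length_distribution,
                                   summarize_removals)

A3, A5 = sim_data.ADAPTER3, sim_data.ADAPTER5
Q40 = "I"


def _read(insert, pad_to=36):
    seq = (insert + A3)[:pad_to]
    return seq, Q40 * len(seq)


@pytest.mark.parametrize("insert,category", [
    ("ACGTACGTACGTACGTACGTA", "clean"),            # 21 nt
    ("ACGTACGTACGTACGTA", "short_insert"),         # 17 nt
    ("", "insert_null"),
    (A5[:8] + "ACGTACGTACGT", "adapter5_contaminant"),
    ("A" * 20, "poly_a"),
])
def test_assess_read_categories(insert, category):
    seq, qual = _read(insert)
    got, trimmed = assess_read(seq, qual, A3, A5)
    assert got == category
    if got == "clean":
        assert trimmed == insert


def test_poly_a_boundary_is_80_percent():
    # 16 of 20 = 80% -> poly(A); 15 of 20 = 75% -> clean
    at, _ = assess_read(*_read("A" * 16 + "GGGG"), A3, A5)
    below, _ = assess_read(*_read("A" * 15 + "GGGGG"), A3, A5)
    assert at == "poly_a" and below == "clean"


def test_read_with_n_fails_quality_before_any_categorization():
    seq, qual = _read("")  # adapter at position 0 = insert null...
    seq = "N" + seq[1:]    # ...but the N wins first
    assert assess_read(seq, qual, A3, A5)[0] == "low_quality"


def test_quality_thresholds_count_rules():
    insert = "ACGTACGTACGTACGTACGTA"
    seq, _ = _read(insert)
    q9, q12 = chr(33 + 9), chr(33 + 12)
    # 5 bases below Q10 -> fail; 4 -> pass
    assert assess_read(seq, q9 * 5 + Q40 * 31, A3, A5)[0] == "low_quality"
    assert assess_read(seq, q9 * 4 + Q40 * 32, A3, A5)[0] == "clean"
    # 7 bases below Q13 -> fail; 6 -> pass
    assert assess_read(seq, q12 * 7 + Q40 * 29, A3, A5)[0] == "low_quality"
    assert assess_read(seq, q12 * 6 + Q40 * 30, A3, A5)[0] == "clean"


def test_missing_adapter_and_long_insert():
    no_adapter = "ACGT" * 9
    assert assess_read(no_adapter, Q40 * 36, A3, A5)[0] == "adapter3_null"
    # a 31-nt insert with a full adapter behind it (45-nt read)
    insert31 = "ACGTTACGAACGTGACGTTACGATCCGTTGC"
    read = insert31 + A3[:14]
    assert assess_read(read, Q40 * len(read), A3, A5)[0] == "long_insert"


def test_adapter_match_tolerates_one_mismatch():
    insert = "ACGTACGTACGTACGTACGTA"
    a3_tail = A3[:15]
    mutated = a3_tail[:3] + ("G" if a3_tail[3] != "G" else "C") + a3_tail[4:]
    read = insert + mutated
    got, trimmed = assess_read(read, Q40 * len(read), A3, A5)
    assert got == "clean" and trimmed == insert


def test_format_error_on_length_mismatch():
    with pytest.raises(FastqFormatError):
        assess_read("ACGT", "III", A3, A5)


def test_summary_partition_invariant_and_percentages():
    removed = {"adapter3_null": 2578, "insert_null": 2292,
               "adapter5_contaminant": 152282, "short_insert": 104474,
               "poly_a": 6353}
    s = summarize_removals(17087884, removed, raw_reads=17160426)
    assert s.clean_reads == 16819905
    assert s.percentages()["clean_reads"] == 98.43
    with pytest.raises(ValueError):
        CleaningSummary(100, 100, {"poly_a": 10}, clean_reads=100)


def test_clean_library_collapses_tags_and_partitions(small_sim, tmp_path):
    _cfg, _bundle, result = small_sim
    tags, s = clean_library(result.fastq_paths["stage1"], A3, A5)
    assert s.high_quality == s.clean_reads + sum(s.removed.values())
    assert tags["count"].sum() == s.clean_reads
    assert tags["sequence"].is_unique
    assert tags["length"].between(18, 30).all()


def test_empty_fastq_yields_empty_summary(tmp_path):
    path = tmp_path / "empty.fastq"
    path.write_text("")
    tags, s = clean_library(path, A3, A5)
    assert tags.empty
    assert s.raw_reads == s.clean_reads == 0


def test_malformed_fastq_reports_record(tmp_path):
    path = tmp_path / "bad.fastq"
    path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nII\n")
    with pytest.raises(FastqFormatError, match="read 2"):
        clean_library(path, A3, A5)


def test_recleaning_cleaned_output_is_idempotent(small_sim, tmp_path):
    """Re-wrapping every clean insert with the adapter and cleaning again
    reproduces the tag table exactly."""
    _cfg, _bundle, result = small_sim
    tags, _ = clean_library(result.fastq_paths["stage3"], A3, A5)
    rewrapped = tmp_path / "rewrapped.fastq"
    with open(rewrapped, "w") as fh:
        i = 0
        for _, row in tags.iterrows():
            for _ in range(int(row["count"])):
                seq = (row["sequence"] + A3)[:36]
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                i += 1
    tags2, s2 = clean_library(rewrapped, A3, A5)
    merged = tags.merge(tags2, on="sequence", how="outer", suffixes=("_a", "_b"))
    assert (merged["count_a"] == merged["count_b"]).all()
    assert s2.clean_reads == tags["count"].sum()


def test_length_distribution_tallies_reads_not_tags(small_sim):
    import pandas as pd

    tags = pd.DataFrame({"sequence": ["A" * 21, "C" * 21, "G" * 24],
                         "length": [21, 21, 24], "count": [3, 2, 3]})
    dist = length_distribution(tags)
    assert dist[21] == 5 and dist[24] == 3
    assert dist.sum() == 8
    _cfg, _bundle, result = small_sim
    real_tags, s = clean_library(result.fastq_paths["stage2"], A3, A5)
    assert length_distribution(real_tags).sum() == s.clean_reads


def test_combined_tag_table_preserves_per_stage_counts(small_sim):
    _cfg, _bundle, result = small_sim
    per_stage = {}
    totals = {}
    for stage, path in result.fastq_paths.items():
        tags, s = clean_library(path, A3, A5)
        per_stage[stage] = tags
        totals[stage] = s.clean_reads
    combined = combine_tag_tables(per_stage)
    assert combined["sequence"].is_unique
    for stage in per_stage:
        assert combined[f"count_{stage}"].sum() == totals[stage]


@given(st.text(alphabet="ACGT", min_size=1, max_size=40),
       st.integers(min_value=0, max_value=40))
def test_every_read_gets_exactly_one_verdict(seq, qshift):
    qual = chr(33 + min(qshift, 40)) * len(seq)
    cat, insert = assess_read(seq, qual, A3, A5)
    assert cat in ("clean", "low_quality", "adapter3_null", "insert_null",
                   "adapter5_contaminant", "poly_a", "short_insert",
                   "long_insert")
    assert (insert is not None) == (cat == "clean")
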