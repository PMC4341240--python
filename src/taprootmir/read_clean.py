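"""Raw FASTQ -> clean reads and collapsed unique small-RNA tags.

A read is first screened for quality (any 'N', more than 4 bases below Q10,
or more than 6 bases below Q13 disqualify it), then the 3' adapter is located
and the insert examined.  The first failing check wins, in the fixed order:

    quality -> 3' adapter absent -> empty insert -> 5' adapter contaminant
            -> poly(A) insert -> shorter than 18 nt -> longer than 30 nt

Clean inserts (18-30 nt) are collapsed to unique tags with read counts.  The
removal tally partitions the high-quality reads exactly, mirroring the
standard library-QC accounting table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MIN_INSERT = 18
MAX_INSERT = 30

REMOVAL_CATEGORIES = ("adapter3_null", "insert_null", "adapter5_contaminant",
                      "short_insert", "poly_a", "long_insert")

# human-readable labels used in report tables
CATEGORY_LABELS = {
    "adapter3_null": "3' adapter null",
    "insert_null": "Insert null",
    "adapter5_contaminant": "5' adapter contaminants",
    "short_insert": "Smaller than 18 nt",
    "poly_a": "Poly (A)",
    "long_insert": "Longer than 30 nt",
}


class FastqFormatError(ValueError):
    pass


@dataclass
class CleaningSummary:
    raw_reads: int
    high_quality: int
    removed: dict[str, int] = field(default_factory=dict)
    clean_reads: int = 0

    def __post_init__(self):
        for cat in REMOVAL_CATEGORIES:
            self.removed.setdefault(cat, 0)
        if self.high_quality != self.clean_reads + sum(self.removed.values()):
            raise ValueError("summary does not partition: high_quality != "
                             "clean + sum(removed)")
        if self.raw_reads < self.high_quality:
            raise ValueError("raw_reads < high_quality")

    def percentages(self) -> dict[str, float]:
        """Each removal category and clean reads as % of high-quality reads,
        two decimals, round-half-even."""
        if self.high_quality == 0:
            return {c: 0.0 for c in (*REMOVAL_CATEGORIES, "clean_reads")}
        out = {c: round(100.0 * self.removed[c] / self.high_quality, 2)
               for c in REMOVAL_CATEGORIES}
        out["clean_reads"] = round(100.0 * self.clean_reads / self.high_quality, 2)
        return out


def summarize_removals(high_quality: int, removed: dict[str, int],
                       raw_reads: int | None = None) -> CleaningSummary:
    """Build a summary from a high-quality total and per-category removal
    counts; clean reads are whatever remains."""
    clean = high_quality - sum(removed.values())
    return CleaningSummary(raw_reads if raw_reads is not None else high_quality,
                           high_quality, dict(removed), clean)


def find_adapter3(seq: str, adapter: str, min_overlap: int = 6,
                  max_mismatch: int = 1) -> int | None:
    """Earliest position where a prefix of the 3' adapter matches through the
    read end (or the full adapter) with at most ``max_mismatch`` mismatches.
    Returns the insert length, or None when no adapter is found."""
    n = len(seq)
    for p in range(0, n - min_overlap + 1):
        ov = min(len(adapter), n - p)
        mm = 0
        for a, b in zip(seq[p:p + ov], adapter[:ov]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return p
    return None


def _is_high_quality(seq: str, qual: str) -> bool:
    if "N" in seq:
        return False
    below10 = below13 = 0
    for ch in qual:
        q = ord(ch) - 33
        if q < 13:
            below13 += 1
            if q < 10:
                below10 += 1
    return below10 <= 4 and below13 <= 6


def assess_read(seq: str, qual: str, adapter3: str, adapter5: str
                ) -> tuple[str, str | None]:
    """Classify one read; returns (category, insert) where category is
    ``"clean"``, ``"low_quality"`` or a removal category, and insert is the
    trimmed sequence for clean reads."""
    seq = seq.upper()
    if len(seq) != len(qual):
        raise FastqFormatError("quality string length differs from sequence")
    if not seq or not adapter3 or not adapter5:
        raise ValueError("read and adapters must be nonempty")
    if not _is_high_quality(seq, qual):
        return "low_quality", None
    p = find_adapter3(seq, adapter3)
    if p is None:
        return "adapter3_null", None
    insert = seq[:p]
    if not insert:
        return "insert_null", None
    if len(insert) >= 8 and insert[:8] == adapter5[:8]:
        return "adapter5_contaminant", None
    if insert.count("A") / len(insert) >= 0.8:
        return "poly_a", None
    if len(insert) < MIN_INSERT:
        return "short_insert", None
    if len(insert) > MAX_INSERT:
        return "long_insert", None
    return "clean", insert


def clean_library(fastq: str | Path, adapter3: str, adapter5: str
                  ) -> tuple[pd.DataFrame, CleaningSummary]:
    """Clean one FASTQ library and collapse clean inserts to unique tags.

    Returns ``(tags, summary)`` where tags has columns
    ``sequence, length, count`` sorted by descending count.
    """
    raw = hq = 0
    removed = Counter()
    tag_counts: Counter[str] = Counter()
    try:
        with open(fastq) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                cat, insert = assess_read(seq, qual, adapter3, adapter5)
                raw += 1
                if cat == "low_quality":
                    continue
                hq += 1
                if cat == "clean":
                    tag_counts[insert] += 1
                else:
                    removed[cat] += 1
    except ValueError as exc:
        raise FastqFormatError(f"malformed FASTQ record near read {raw + 1} "
                               f"in {fastq}: {exc}") from exc
    tags = pd.DataFrame(
        {"sequence": list(tag_counts), "count": list(tag_counts.values())})
    if tags.empty:
        tags = pd.DataFrame(columns=["sequence", "length", "count"])
    else:
        tags["length"] = tags["sequence"].str.len()
        tags = tags[["sequence", "length", "count"]].sort_values(
            ["count", "sequence"], ascending=[False, True], ignore_index=True)
    summary = CleaningSummary(raw, hq, dict(removed), sum(tag_counts.values()))
    return tags, summary


def length_distribution(tags: pd.DataFrame) -> pd.Series:
    """Clean-read counts per insert length 18..30 (weighted by tag counts)."""
    dist = pd.Series(0, index=range(MIN_INSERT, MAX_INSERT + 1), name="reads")
    if not tags.empty:
        got = tags.groupby("length")["count"].sum()
        dist.loc[got.index] = got
    dist.index.name = "length"
    return dist


def combine_tag_tables(per_stage: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-library tag tables into one table with one count column per
    stage (``count_<stage>``), missing counts as 0."""
    merged: pd.DataFrame | None = None
    for stage, tags in per_stage.items():
        cur = tags[["sequence", "count"]].rename(columns={"count": f"count_{stage}"})
        merged = cur if merged is None else merged.merge(cur, on="sequence", how="outer")
    assert merged is not None
    count_cols = [c for c in merged.columns if c.startswith("count_")]
    merged[count_cols] = merged[count_cols].fillna(0).astype(int)
    merged.insert(1, "length", merged["sequence"].str.len())
    merged["total"] = merged[count_cols].sum(axis=1)
    return merged.sort_values(["total", "sequence"],
                              ascending=[False, True], ignore_index=True)
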