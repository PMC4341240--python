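"""Hierarchical annotation of unique small-RNA tags.

Tags are mapped to the reference by exact matching on both strands, then
classified with strict priority: non-coding RNA first (exact substring of an
rRNA/tRNA/snRNA/snoRNA catalog sequence, sense or antisense), then known
miRNA (at most two mismatches against a mature catalog entry, with the tag
5' end anchored at offsets -2..+2), and finally unannotated.  Each tag gets
exactly one category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .sim_data import Locus, MatureMiRNA, ReferenceBundle, revcomp

log = logging.getLogger(__name__)

CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA", "known_miRNA", "unannotated")
MAX_MISMATCHES = 2
ANCHOR_OFFSETS = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class KnownMatch:
    mature: MatureMiRNA
    mismatches: int
    offset: int


def map_tags(sequences, bundle: ReferenceBundle) -> dict[str, list[Locus]]:
    """All exact occurrences of each tag on both strands of every contig."""
    out: dict[str, list[Locus]] = {}
    for tag in sequences:
        loci: list[Locus] = []
        rc = revcomp(tag)
        for cname in sorted(bundle.contigs):
            contig = bundle.contigs[cname]
            for strand, query in (("+", tag), ("-", rc)):
                pos = contig.find(query)
                while pos != -1:
                    loci.append(Locus(cname, pos, pos + len(tag), strand,
                                      "mapped", tag))
                    pos = contig.find(query, pos + 1)
        out[tag] = loci
    return out


def _anchored_mismatches(tag: str, mature: str, offset: int) -> int:
    """Mismatches over the mature's length with tag[0] anchored at mature
    position ``offset``; mature positions the tag does not cover count as
    mismatches.  No indels inside the comparison window."""
    mm = 0
    for i in range(len(mature)):
        j = i - offset
        if j < 0 or j >= len(tag) or tag[j] != mature[i]:
            mm += 1
            if mm > MAX_MISMATCHES:
                return mm
    return mm


def match_known(tag: str, mature_catalog) -> list[KnownMatch]:
    """All catalog entries at the minimal mismatch count <= 2, best anchoring
    offset per entry; sorted by (mismatches, |offset|, name)."""
    hits: list[KnownMatch] = []
    for mat in mature_catalog:
        best = None
        for off in ANCHOR_OFFSETS:
            mm = _anchored_mismatches(tag, mat.sequence, off)
            if mm <= MAX_MISMATCHES and (best is None or
                                         (mm, abs(off)) < (best.mismatches,
                                                           abs(best.offset))):
                best = KnownMatch(mat, mm, off)
        if best is not None:
            hits.append(best)
    if not hits:
        return []
    lo = min(h.mismatches for h in hits)
    hits = [h for h in hits if h.mismatches == lo]
    return sorted(hits, key=lambda h: (h.mismatches, abs(h.offset), h.mature.name))


def _ncrna_category(tag: str, blobs: dict[str, str]) -> str | None:
    rc = revcomp(tag)
    for kind in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        blob = blobs.get(kind, "")
        if tag in blob or rc in blob:
            return kind
    return None


def classify(tags: pd.DataFrame, bundle: ReferenceBundle) -> pd.DataFrame:
    """Annotate a combined tag table (``sequence`` plus count columns).

    Returns the table with added columns ``category``, ``matched_mirna``,
    ``family``, ``mismatches``, ``n_loci`` and ``loci`` (semicolon-joined
    ``contig:start-end:strand``).  Order-independent: the result is keyed by
    sequence, not input position.
    """
    blobs: dict[str, str] = {}
    for n in bundle.ncrna_catalog:
        blobs[n.kind] = blobs.get(n.kind, "") + "#" + n.sequence
    loci_map = map_tags(tags["sequence"], bundle)

    cats, matched, fams, mms, nloci, locstr = [], [], [], [], [], []
    for seq in tags["sequence"]:
        loci = loci_map[seq]
        nloci.append(len(loci))
        locstr.append(";".join(f"{l.contig}:{l.start}-{l.end}:{l.strand}"
                               for l in loci))
        cat = _ncrna_category(seq, blobs)
        if cat is not None:
            cats.append(cat)
            matched.append("")
            fams.append("")
            mms.append(-1)
            continue
        hits = match_known(seq, bundle.mature_catalog)
        if hits:
            if len(hits) > 1 and len({h.mature.family for h in hits}) > 1:
                log.warning("tag %s ties across families %s; assigned %s",
                            seq, sorted({h.mature.family for h in hits}),
                            hits[0].mature.family)
            cats.append("known_miRNA")
            matched.append(hits[0].mature.name)
            fams.append(hits[0].mature.family)
            mms.append(hits[0].mismatches)
        else:
            cats.append("unannotated")
            matched.append("")
            fams.append("")
            mms.append(-1)
    out = tags.copy()
    out["category"] = cats
    out["matched_mirna"] = matched
    out["family"] = fams
    out["mismatches"] = mms
    out["n_loci"] = nloci
    out["loci"] = locstr
    return out


def category_summary(annot: pd.DataFrame) -> pd.DataFrame:
    """Unique tags and total reads per category (the six-way breakdown)."""
    count_cols = [c for c in annot.columns if c.startswith("count_")]
    rows = []
    for cat in CATEGORIES:
        sub = annot[annot["category"] == cat]
        row = {"category": cat, "unique_tags": len(sub)}
        for c in count_cols:
            row[c] = int(sub[c].sum())
        row["total_reads"] = int(sub[count_cols].sum().sum()) if count_cols else 0
        rows.append(row)
    return pd.DataFrame(rows)
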