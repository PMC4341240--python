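"""Plant miRNA target scanning by complementarity expectation scoring.

A miRNA is aligned antiparallel against every transcript window; each
alignment column is penalized (mismatch +1, G:U wobble +0.5, gap +2) with
penalties doubled inside the 5'-anchored seed region (miRNA positions 2-13).
Windows whose optimal alignment penalty (the "expectation") stays at or
below the cutoff (default 3.0) are reported; overlapping windows collapse to
the best score.  A central defect at miRNA positions 9-11 marks the hit as
translational repression rather than cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CUTOFF = 3.0
MAX_GAPS = 1
SEED_RANGE = (2, 13)      # 1-based inclusive miRNA positions, doubled weight
CENTRAL_RANGE = (9, 11)   # central defect -> translational mode

MISMATCH = 1.0
WOBBLE = 0.5
GAP = 2.0

_COMP = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}


def _column_kind(m: str, t: str) -> str:
    """Pairing of miRNA base m with transcript base t (both 5'->3' symbols,
    aligned antiparallel)."""
    if m == "-" or t == "-":
        return "gap"
    if t == _COMP.get(m, "?"):
        return "match"
    if (m == "G" and t in "TU") or (m in "TU" and t == "G"):
        return "wobble"
    return "mismatch"


def _score_columns(mirna_aln: str, transcript_aln: str):
    """Score aligned strings (miRNA 5'->3' with '-' gaps, transcript already
    reversed to run 3'->5' so columns correspond).  Returns (expectation,
    match line, central_defect)."""
    expectation = 0.0
    match_line = []
    central_defect = False
    pos = 0  # 1-based miRNA position, advances on miRNA bases only
    for m, t in zip(mirna_aln, transcript_aln):
        if m != "-":
            pos += 1
        kind = _column_kind(m, t)
        pen = {"match": 0.0, "wobble": WOBBLE, "mismatch": MISMATCH,
               "gap": GAP}[kind]
        if SEED_RANGE[0] <= pos <= SEED_RANGE[1]:
            pen *= 2.0
        expectation += pen
        match_line.append({"match": "|", "wobble": "o"}.get(kind, " "))
        if kind in ("mismatch", "gap") and CENTRAL_RANGE[0] <= pos <= CENTRAL_RANGE[1]:
            central_defect = True
    return expectation, "".join(match_line), central_defect


def score_alignment(mirna: str, site: str, max_gaps: int = MAX_GAPS):
    """Best gapped alignment of a miRNA against a candidate site.

    ``site`` is the transcript window 5'->3'; the miRNA binds antiparallel,
    so the site is reversed before column-wise comparison.  At most
    ``max_gaps`` gap (in either strand) is considered.  Returns
    ``(expectation, alignment)`` where alignment is the
    (miRNA 5'->3', match line, reversed site) string triple.
    """
    mirna = mirna.upper()
    rsite = site.upper()[::-1]
    L, S = len(mirna), len(rsite)
    if not (L - max_gaps <= S <= L + max_gaps):
        raise ValueError("site length outside miRNA length +- allowed gaps")
    candidates = []
    if S == L:
        candidates.append((mirna, rsite))
    elif S == L + 1 and max_gaps >= 1:   # transcript base bulged: gap in miRNA
        for g in range(L + 1):
            candidates.append((mirna[:g] + "-" + mirna[g:], rsite))
    elif S == L - 1 and max_gaps >= 1:   # miRNA base bulged: gap in transcript
        for g in range(S + 1):
            candidates.append((mirna, rsite[:g] + "-" + rsite[g:]))
    best = None
    for m_aln, t_aln in candidates:
        exp, line, central = _score_columns(m_aln, t_aln)
        if best is None or exp < best[0]:
            best = (exp, (m_aln, line, t_aln), central)
    return best[0], best[1], best[2]


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int
    end: int
    expectation: float
    mode: str                     # "cleavage" | "translation"
    alignment: tuple[str, str, str]


def scan(mirna_id: str, mirna_seq: str, transcripts: dict[str, str],
         cutoff: float = CUTOFF, max_gaps: int = MAX_GAPS) -> list[TargetHit]:
    """All target windows of one miRNA across a transcript set.

    Windows of length ``len(mirna) -+ max_gaps`` are scored at every start;
    overlapping reported windows are deduplicated to the best expectation.
    Results are independent of transcript iteration order.
    """
    if not transcripts:
        raise ValueError("transcripts must be nonempty")
    L = len(mirna_seq)
    hits: list[TargetHit] = []
    for tid in sorted(transcripts):
        seq = transcripts[tid].upper().replace("U", "T")
        found: list[TargetHit] = []
        for start in range(len(seq)):
            for wlen in range(L - max_gaps, L + max_gaps + 1):
                end = start + wlen
                if end > len(seq):
                    continue
                exp, aln, central = score_alignment(mirna_seq, seq[start:end],
                                                    max_gaps)
                if exp <= cutoff:
                    found.append(TargetHit(
                        mirna_id, tid, start, end, exp,
                        "translation" if central else "cleavage", aln))
        found.sort(key=lambda h: (h.expectation, h.start, h.end))
        kept: list[TargetHit] = []
        for h in found:
            if not any(h.start < k.end and k.start < h.end for k in kept):
                kept.append(h)
        hits.extend(sorted(kept, key=lambda h: h.start))
    return hits


def scan_many(mirnas: dict[str, str], transcripts: dict[str, str],
              cutoff: float = CUTOFF, max_gaps: int = MAX_GAPS) -> pd.DataFrame:
    rows = []
    for mid in sorted(mirnas):
        for h in scan(mid, mirnas[mid], transcripts, cutoff, max_gaps):
            rows.append({
                "mirna_id": h.mirna_id, "transcript_id": h.transcript_id,
                "start": h.start, "end": h.end,
                "expectation": h.expectation, "mode": h.mode,
                "mirna_alignment": h.alignment[0],
                "match_line": h.alignment[1],
                "site_alignment": h.alignment[2],
            })
    cols = ["mirna_id", "transcript_id", "start", "end", "expectation",
            "mode", "mirna_alignment", "match_line", "site_alignment"]
    return pd.DataFrame(rows, columns=cols)
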