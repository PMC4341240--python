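"""Novel miRNA prediction from unannotated mapped tags.

For each eligible tag locus two genomic windows are excised (assuming the
tag sits on the 5' or the 3' arm of a precursor), folded, and judged against
stem-loop criteria: the mature must lie in one arm, pair predominantly and
contiguously with the opposite arm (at most 4 unpaired mature bases, no
asymmetric bulge over 2 nt), and the window must fold below an MFE ceiling
(default -18 kcal/mol).  A star tag pairing the opposite arm with 2-nt
3' overhang geometry (+-1 nt slack) upgrades the candidate's evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._fold import FoldResult, fold, structure_pairs
from .sim_data import Locus, ReferenceBundle, revcomp

DEFAULT_FLANK = 160
DEFAULT_SMALL = 15
MIN_MATURE_COUNT = 5          # lowest observed novel-candidate abundance
MFE_CEILING = -18.0           # kcal/mol
MAX_UNPAIRED_MATURE = 4
MAX_BULGE_ASYMMETRY = 2
STAR_SLACK = 1
CRITERIA = ("stem_loop", "mature_in_one_arm", "duplex_mismatches_ok",
            "bulge_ok", "mfe_ok")


@dataclass(frozen=True)
class Window:
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    mature_offset: int   # 0-based offset of the mature within the window
    mature_length: int


@dataclass
class NovelCandidate:
    name: str
    window: Window
    fold: FoldResult
    mature_seq: str
    arm: str                      # "5p" or "3p"
    criteria: dict[str, bool]
    accepted: bool
    counts: dict[str, int] = field(default_factory=dict)
    star_seq: str | None = None
    star_counts: dict[str, int] = field(default_factory=dict)
    star_interval: tuple[int, int] | None = None
    star_similar_abundance: bool = False

    duplex_span: tuple[int, int] | None = None  # contig coords, mature+star extent

    @property
    def hairpin_length(self) -> int:
        return len(self.window.sequence)

    @property
    def mfe(self) -> float:
        return self.fold.mfe


def excise_windows(locus: Locus, bundle: ReferenceBundle,
                   flank: int = DEFAULT_FLANK,
                   small: int = DEFAULT_SMALL) -> list[Window]:
    """Two candidate precursor windows around a mapped tag locus, one per arm
    hypothesis, clipped to contig bounds and strand-adjusted so the mature
    always reads sense within the window."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    contig = bundle.contigs.get(locus.contig)
    if contig is None or not (0 <= locus.start < locus.end <= len(contig)):
        raise ValueError(f"locus outside contig: {locus}")
    spans = [(locus.start - flank, locus.end + small),
             (locus.start - small, locus.end + flank)]
    windows = []
    for a, b in spans:
        a, b = max(0, a), min(len(contig), b)
        seq = contig[a:b]
        if locus.strand == "-":
            seq = revcomp(seq)
            off = b - locus.end
        else:
            off = locus.start - a
        windows.append(Window(locus.contig, a, b, locus.strand, seq,
                              off, locus.end - locus.start))
    return windows


def _duplex_geometry(structure: str, ms: int, me: int):
    """Pairing geometry of the mature span [ms, me) in a dot-bracket string.

    Returns (flags, partners) where partners maps mature positions to their
    pairing partners.
    """
    pairs = structure_pairs(structure)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    mature_chars = {structure[i] for i in range(ms, me) if structure[i] != "."}
    paired = [i for i in range(ms, me) if i in partner]
    unpaired = (me - ms) - len(paired)

    one_arm = len(mature_chars) <= 1  # all '(' or all ')': never spans the loop
    monotone = all(partner[a] > partner[b]
                   for a, b in zip(paired, paired[1:])) if len(paired) > 1 else bool(paired)
    stem_loop = bool(paired) and one_arm and monotone

    bulge_ok = True
    for a, b in zip(paired, paired[1:]):
        gap_m = b - a - 1
        gap_s = abs(partner[a] - partner[b]) - 1
        if abs(gap_m - gap_s) > MAX_BULGE_ASYMMETRY:
            bulge_ok = False
            break
    flags = {
        "stem_loop": stem_loop,
        "mature_in_one_arm": one_arm and bool(paired),
        "duplex_mismatches_ok": unpaired <= MAX_UNPAIRED_MATURE,
        "bulge_ok": bulge_ok,
    }
    return flags, partner, paired


def expected_star_interval(structure: str, ms: int, me: int) -> tuple[int, int] | None:
    """Star span implied by 2-nt 3' overhang duplex geometry: partners of the
    mature minus its last two (overhang) bases, extended 2 nt past the
    partner of the mature 5' end."""
    _flags, partner, paired = _duplex_geometry(structure, ms, me)
    core = [p for p in paired if p < me - 2]
    if not core:
        return None
    q = [partner[p] for p in core]
    return min(q), max(q) + 3


def evaluate(window: Window, tag_loci_in_window=None,
             mfe_ceiling: float = MFE_CEILING,
             fold_result: FoldResult | None = None) -> NovelCandidate:
    """Fold a window and score the stem-loop criteria for its mature tag.

    ``tag_loci_in_window`` is an optional list of ``(sequence, start, end,
    counts)`` tuples in window coordinates used for the star search.
    """
    fr = fold_result or fold(window.sequence)
    ms, me = window.mature_offset, window.mature_offset + window.mature_length
    flags, partner, paired = _duplex_geometry(fr.structure, ms, me)
    flags["mfe_ok"] = fr.mfe <= mfe_ceiling
    arm = "5p"
    for i in range(ms, me):
        if fr.structure[i] == ")":
            arm = "3p"
            break
    cand = NovelCandidate(
        name="", window=window, fold=fr,
        mature_seq=window.sequence[ms:me], arm=arm,
        criteria=flags, accepted=all(flags.values()),
    )
    if paired:
        # duplex extent (mature plus its pairing partners) in contig coords;
        # two windows describe the same hairpin iff these extents overlap
        qs = [partner[p] for p in paired]
        cs, ce = min(ms, min(qs)), max(me, max(qs) + 1)
        if window.strand == "+":
            cand.duplex_span = (window.start + cs, window.start + ce)
        else:
            cand.duplex_span = (window.end - ce, window.end - cs)
    if cand.accepted and tag_loci_in_window:
        star = expected_star_interval(fr.structure, ms, me)
        if star is not None:
            a, b = star
            best = None
            for seq, s, e, counts in tag_loci_in_window:
                if (s, e) == (ms, me):
                    continue
                if abs(s - a) <= STAR_SLACK and abs(e - b) <= STAR_SLACK:
                    tot = sum(counts.values())
                    if best is None or tot > sum(best[3].values()):
                        best = (seq, s, e, counts)
            cand.star_interval = star
            if best is not None:
                cand.star_seq = best[0]
                cand.star_counts = dict(best[3])
    return cand


def _overlaps(a: NovelCandidate, b: NovelCandidate) -> bool:
    """Same genomic hairpin?  Strand-agnostic overlap of the duplex extents
    (whole excised windows overlap merely by flank for nearby loci)."""
    if a.window.contig != b.window.contig:
        return False
    (sa, ea) = a.duplex_span or (a.window.start, a.window.end)
    (sb, eb) = b.duplex_span or (b.window.start, b.window.end)
    return sa < eb and sb < ea


def predict_novel(annot: pd.DataFrame, bundle: ReferenceBundle,
                  flank: int = DEFAULT_FLANK, small: int = DEFAULT_SMALL,
                  min_count: int = MIN_MATURE_COUNT,
                  mfe_ceiling: float = MFE_CEILING,
                  max_loci_per_tag: int = 4) -> list[NovelCandidate]:
    """Run the full prediction over an annotated tag table.

    Eligible mature tags are unannotated, mapped, with at least ``min_count``
    reads summed over libraries.  Overlapping accepted windows are collapsed
    to the lowest-MFE one (ties broken toward the more abundant mature tag).
    """
    count_cols = [c for c in annot.columns if c.startswith("count_")]
    un = annot[annot["category"] == "unannotated"]
    counts_by_seq = {r["sequence"]: {c: int(r[c]) for c in count_cols}
                     for _, r in un.iterrows()}

    # window-local tag loci for the star search, grouped by contig
    tag_loci: dict[str, list[tuple[str, int, int, str, dict]]] = {}
    for _, r in un.iterrows():
        if not r["loci"]:
            continue
        for token in r["loci"].split(";"):
            cpos, strand = token.rsplit(":", 1)
            cname, span = cpos.split(":")
            s, e = (int(x) for x in span.split("-"))
            tag_loci.setdefault(cname, []).append(
                (r["sequence"], s, e, strand, counts_by_seq[r["sequence"]]))

    eligible = un[(un["n_loci"] > 0)
                  & (un[count_cols].sum(axis=1) >= min_count)]
    accepted: list[NovelCandidate] = []
    for _, row in eligible.iterrows():
        seq = row["sequence"]
        for token in row["loci"].split(";")[:max_loci_per_tag]:
            cpos, strand = token.rsplit(":", 1)
            cname, span = cpos.split(":")
            s, e = (int(x) for x in span.split("-"))
            locus = Locus(cname, s, e, strand, "mapped", seq)
            for window in excise_windows(locus, bundle, flank, small):
                local = []
                for tseq, ts, te, tstrand, tcounts in tag_loci.get(cname, []):
                    if tstrand != strand or ts < window.start or te > window.end:
                        continue
                    if strand == "+":
                        local.append((tseq, ts - window.start,
                                      te - window.start, tcounts))
                    else:
                        local.append((tseq, window.end - te,
                                      window.end - ts, tcounts))
                cand = evaluate(window, local, mfe_ceiling)
                if cand.accepted:
                    cand.counts = counts_by_seq[seq]
                    _orient_by_abundance(cand)
                    accepted.append(cand)

    # de-duplicate overlapping windows: lowest MFE wins, then abundance
    accepted.sort(key=lambda c: (round(c.mfe, 6), -sum(c.counts.values())))
    kept: list[NovelCandidate] = []
    for cand in accepted:
        if not any(_overlaps(cand, k) for k in kept):
            kept.append(cand)
    for i, cand in enumerate(sorted(kept, key=lambda c: (c.window.contig,
                                                         c.window.start)), 1):
        cand.name = f"rsa-nmiR{i}-{cand.arm}"
    return sorted(kept, key=lambda c: c.name)


def _orient_by_abundance(cand: NovelCandidate) -> None:
    """Call the more abundant arm of the duplex the mature (field convention);
    near-parity duplexes are flagged, never rejected."""
    if cand.star_seq is None:
        return
    mat, star = sum(cand.counts.values()), sum(cand.star_counts.values())
    if star > mat:
        ms = cand.window.mature_offset
        me = ms + cand.window.mature_length
        a, b = cand.star_interval
        cand.mature_seq, cand.star_seq = cand.star_seq, cand.mature_seq
        cand.counts, cand.star_counts = cand.star_counts, cand.counts
        cand.window = Window(cand.window.contig, cand.window.start,
                             cand.window.end, cand.window.strand,
                             cand.window.sequence, a, b - a)
        cand.star_interval = (ms, me)
        cand.arm = "3p" if cand.arm == "5p" else "5p"
        mat, star = star, mat
    cand.star_similar_abundance = star * 2 >= mat


def candidates_frame(cands: list[NovelCandidate]) -> pd.DataFrame:
    rows = []
    for c in cands:
        row = {
            "name": c.name, "contig": c.window.contig,
            "start": c.window.start, "end": c.window.end,
            "strand": c.window.strand, "hairpin_length": c.hairpin_length,
            "mfe": round(c.mfe, 2), "mature_seq": c.mature_seq, "arm": c.arm,
            "star_seq": c.star_seq or "",
            "star_similar_abundance": c.star_similar_abundance,
            "accepted": c.accepted,
        }
        for k, v in c.counts.items():
            row[k] = v
        for k, v in c.star_counts.items():
            row[f"star_{k}"] = v
        rows.append(row)
    cols = ["name", "contig", "start", "end", "strand", "hairpin_length",
            "mfe", "mature_seq", "arm", "star_seq", "star_similar_abundance",
            "accepted"]
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
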