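"""Synthetic reference bundle and staged small-RNA libraries with known truth.

The generator emulates the study design this package targets: three small-RNA
libraries from successive taproot developmental stages (pre-cortex splitting,
cortex splitting, expanding), each dominated by 21/24-nt inserts, containing
planted mature miRNAs from known families, planted non-coding RNA
contaminants (rRNA/tRNA/snRNA/snoRNA), planted novel-miRNA hairpin loci with
star-strand reads, library-preparation artifacts (5' adapter contaminants,
missing 3' adapter, null inserts, poly(A), short inserts), and a majority of
unannotatable background reads drawn from random genomic positions.

Every planted quantity is recorded in a truth table so each downstream stage
(cleaning, annotation, hairpin prediction, differential expression) can be
validated against ground truth without any external download.  The default
abundance profile plants a miR156a-like decline proportional to the reads
505,759 : 50,613 : 16,238 across stages, at libraries of 20,000 clean reads
(about a 1000-fold scale-down of real library depth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import read_clean as _rc

_ALPH = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

NCRNA_KINDS = ("rRNA", "tRNA", "snRNA", "snoRNA")
ARTIFACT_CLASSES = ("adapter3_null", "insert_null", "adapter5_contaminant",
                    "poly_a", "short_insert")
STAGES = ("stage1", "stage2", "stage3")

# 3'/5' adapters used by the generator and as cleaning defaults (the classic
# small-RNA kit sequences, padded so a 36-nt read is always filled).
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

READ_LENGTH = 36

# insert-length distribution of background reads: 21/24-nt dominated
_BG_LENGTHS = np.arange(18, 27)
_BG_LENGTH_P = np.array([0.03, 0.04, 0.08, 0.33, 0.07, 0.07, 0.24, 0.08, 0.06])


class LayoutError(ValueError):
    """A planted feature does not fit in its contig."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    name: str
    family: str
    sequence: str

    def __post_init__(self):
        if not (18 <= len(self.sequence) <= 26):
            raise ValueError(f"{self.name}: mature length must be in [18, 26]")
        if not self.family:
            raise ValueError(f"{self.name}: empty family")


@dataclass(frozen=True)
class NcRNA:
    name: str
    kind: str
    sequence: str

    def __post_init__(self):
        if self.kind not in NCRNA_KINDS:
            raise ValueError(f"{self.name}: unknown ncRNA kind {self.kind}")


@dataclass(frozen=True)
class Locus:
    contig: str
    start: int
    end: int
    strand: str
    kind: str
    name: str


@dataclass
class ReferenceBundle:
    """Toy genome contigs plus catalogs with fully-known planted truth.

    Coordinates are 0-based half-open; reverse-strand loci emit the reverse
    complement of the contig slice.
    """

    contigs: dict[str, str]
    ncrna_catalog: list[NcRNA]
    mature_catalog: list[MatureMiRNA]
    planted_loci: list[Locus]
    transcripts: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for cat, names in (("contig", self.contigs),
                           ("ncRNA", [n.name for n in self.ncrna_catalog]),
                           ("mature", [m.name for m in self.mature_catalog])):
            names = list(names)
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {cat} names")
        for loc in self.planted_loci:
            if loc.kind == "target_site":
                contig = self.transcripts[loc.contig]
            else:
                contig = self.contigs[loc.contig]
            if not (0 <= loc.start < loc.end <= len(contig)):
                raise LayoutError(f"locus {loc.name} outside contig {loc.contig}")

    def locus_sequence(self, locus: Locus) -> str:
        s = self.contigs[locus.contig][locus.start:locus.end]
        return revcomp(s) if locus.strand == "-" else s

    def loci(self, kind: str) -> list[Locus]:
        return [l for l in self.planted_loci if l.kind == kind]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(outdir / "contigs.fa", self.contigs.items())
        _write_fasta(outdir / "ncrna.fa",
                     ((f"{n.name}|{n.kind}", n.sequence) for n in self.ncrna_catalog))
        _write_fasta(outdir / "mature.fa",
                     ((f"{m.name}|{m.family}", m.sequence) for m in self.mature_catalog))
        if self.transcripts:
            _write_fasta(outdir / "transcripts.fa", self.transcripts.items())
        pd.DataFrame([vars(l) for l in self.planted_loci]).to_csv(
            outdir / "planted_loci.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "ReferenceBundle":
        from Bio import SeqIO

        indir = Path(indir)
        contigs = {r.id: str(r.seq).upper()
                   for r in SeqIO.parse(str(indir / "contigs.fa"), "fasta")}
        ncrna = [NcRNA(r.id.split("|", 1)[0], r.id.split("|", 1)[1],
                       str(r.seq).upper())
                 for r in SeqIO.parse(str(indir / "ncrna.fa"), "fasta")]
        mature = [MatureMiRNA(r.id.split("|", 1)[0], r.id.split("|", 1)[1],
                              str(r.seq).upper())
                  for r in SeqIO.parse(str(indir / "mature.fa"), "fasta")]
        loci = []
        loci_path = indir / "planted_loci.tsv"
        if loci_path.exists():
            for row in pd.read_csv(loci_path, sep="\t").itertuples(index=False):
                loci.append(Locus(row.contig, int(row.start), int(row.end),
                                  row.strand, row.kind, row.name))
        transcripts = {}
        if (indir / "transcripts.fa").exists():
            transcripts = {r.id: str(r.seq).upper()
                           for r in SeqIO.parse(str(indir / "transcripts.fa"), "fasta")}
        bundle = cls(contigs, ncrna, mature, loci, transcripts)
        bundle.validate()
        return bundle


def _write_fasta(path: Path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


@dataclass
class StageProfile:
    """Expected composition of one stage library.

    ``abundance`` maps planted entity names to expected fractions of clean
    reads; the remainder is unannotatable background.  ``artifact_rates`` are
    fractions of *emitted* reads per artifact class.
    """

    stage: str
    target_clean_reads: int
    abundance: dict[str, float]
    artifact_rates: dict[str, float] = field(default_factory=dict)
    quality_error_rate: float = 0.0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage}")
        if self.target_clean_reads < 1000:
            raise ValueError("target_clean_reads must be >= 1000")
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError("negative abundance fraction")
        if sum(self.abundance.values()) > 1 + 1e-9:
            raise ValueError("abundance fractions sum to > 1")
        if any(v < 0 for v in self.artifact_rates.values()) or \
                sum(self.artifact_rates.values()) > 1 - 1e-9:
            raise ValueError("bad artifact rates")


# --- default simulation design ------------------------------------------------

# (name, family, length, per-stage expected clean-read fractions)
_KNOWN_DESIGN = [
    ("rsa-miR156a", "miR156", 21, (0.0300, 0.0027, 0.00095)),  # steep decline
    ("rsa-miR172a", "miR172", 21, (0.0020, 0.0080, 0.0320)),   # steady rise
    ("rsa-miR166a", "miR166", 21, (0.0200, 0.0050, 0.0200)),   # dip and recover
    ("rsa-miR398a", "miR398", 21, (0.0000, 0.0040, 0.0040)),   # stage-specific
    ("rsa-miR168a", "miR168", 22, (0.0800, 0.0800, 0.0800)),   # null
    ("rsa-miR390a", "miR390", 21, (0.0500, 0.0500, 0.0500)),   # null
    ("rsa-miR159a", "miR159", 24, (0.0400, 0.0400, 0.0400)),   # null
    ("rsa-miR397a", "miR397", 21, (0.0100, 0.0150, 0.0100)),   # sub-threshold
]
# catalog-only matures, never planted or expressed
_KNOWN_ABSENT = [("rsa-miR403a", "miR403", 21), ("rsa-miR827a", "miR827", 21)]

# (name, kind, length, flat fraction)
_NCRNA_DESIGN = [
    ("rrna-1", "rRNA", 120, 0.030),
    ("trna-1", "tRNA", 76, 0.030),
    ("snrna-1", "snRNA", 100, 0.030),
    ("snorna-1", "snoRNA", 90, 0.030),
]

# (name, strand, loop length, mature fractions, star fractions)
_HAIRPIN_DESIGN = [
    ("nov1", "+", 12, (0.0200, 0.0200, 0.0200), (0.0040, 0.0040, 0.0040)),
    ("nov2", "+", 14, (0.0120, 0.0030, 0.0010), (0.0024, 0.0006, 0.0002)),
    ("nov3", "-", 12, (0.0080, 0.0080, 0.0080), (0.0016, 0.0016, 0.0016)),
]

# Table-1-inspired default artifact rates (fractions of emitted reads)
_DEFAULT_ARTIFACTS = {
    "adapter3_null": 0.0005, "insert_null": 0.0005,
    "adapter5_contaminant": 0.0090, "poly_a": 0.0010, "short_insert": 0.0060,
}


@dataclass
class SimConfig:
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"contig1": 20000, "contig2": 20000})
    known: list = field(default_factory=lambda: list(_KNOWN_DESIGN))
    known_absent: list = field(default_factory=lambda: list(_KNOWN_ABSENT))
    ncrnas: list = field(default_factory=lambda: list(_NCRNA_DESIGN))
    hairpins: list = field(default_factory=lambda: list(_HAIRPIN_DESIGN))
    mature_len: int = 21
    target_clean_reads: int = 20000
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ARTIFACTS))
    quality_error_rate: float = 0.0005
    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5
    read_length: int = READ_LENGTH

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown simulation config key {key!r}")
            setattr(cfg, key, val)
        return cfg


def default_profiles(config: SimConfig | None = None) -> list[StageProfile]:
    config = config or SimConfig()
    profiles = []
    for si, stage in enumerate(STAGES):
        ab: dict[str, float] = {}
        for name, _fam, _ln, fr in config.known:
            ab[name] = fr[si]
        for name, _kind, _ln, fr in config.ncrnas:
            ab[name] = fr
        for name, _strand, _loop, mf, sf in config.hairpins:
            ab[f"{name}-mature"] = mf[si]
            ab[f"{name}-star"] = sf[si]
        profiles.append(StageProfile(
            stage=stage,
            target_clean_reads=config.target_clean_reads,
            abundance=ab,
            artifact_rates=dict(config.artifact_rates),
            quality_error_rate=config.quality_error_rate,
        ))
    return profiles


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPH[rng.integers(0, 4, n)])


def _hamming_close(a: str, b: str, limit: int) -> bool:
    if abs(len(a) - len(b)) > 2:
        return False
    mm = sum(x != y for x, y in zip(a, b))
    return mm <= limit


def make_reference(config: SimConfig | None = None, seed: int = 0) -> ReferenceBundle:
    """Build a reference bundle with planted known-miRNA, ncRNA, and novel
    hairpin loci; byte-identical output for identical (config, seed)."""
    config = config or SimConfig()
    if not config.contig_lengths:
        raise LayoutError("config must name at least one contig")
    if not (config.known and config.hairpins and config.ncrnas):
        raise LayoutError("config must plant known miRNAs, hairpins and ncRNAs")
    rng = np.random.default_rng(seed)

    contigs = {name: list(_random_seq(rng, n))
               for name, n in config.contig_lengths.items()}

    matures: list[MatureMiRNA] = []
    seqs_used: list[str] = []

    def _fresh_mature(length: int) -> str:
        for _ in range(100):
            s = _random_seq(rng, length)
            if not any(_hamming_close(s, t, 2) for t in seqs_used):
                seqs_used.append(s)
                return s
        raise RuntimeError("could not draw a distinct mature sequence")

    loci: list[Locus] = []
    contig_names = list(contigs)
    cursors = {c: 150 for c in contig_names}

    def _plant(contig: str, seq: str, kind: str, name: str, strand: str = "+") -> Locus:
        start = cursors[contig] + int(rng.integers(100, 300))
        end = start + len(seq)
        if end + 150 > len(contigs[contig]):
            raise LayoutError(f"contig {contig} too short for {name}")
        contigs[contig][start:end] = list(seq if strand == "+" else revcomp(seq))
        cursors[contig] = end
        loc = Locus(contig, start, end, strand, kind, name)
        loci.append(loc)
        return loc

    known_contig = contig_names[0]
    for i, (name, fam, ln, _fr) in enumerate(config.known):
        seq = _fresh_mature(ln)
        matures.append(MatureMiRNA(name, fam, seq))
        strand = "-" if i == len(config.known) - 1 else "+"
        _plant(known_contig, seq, "known_mirna", name, strand)
    for name, fam, ln in config.known_absent:
        matures.append(MatureMiRNA(name, fam, _fresh_mature(ln)))

    ncrnas = []
    for name, kind, ln, _fr in config.ncrnas:
        seq = _random_seq(rng, ln)
        ncrnas.append(NcRNA(name, kind, seq))
        _plant(known_contig, seq, "ncrna", name)

    hp_contig = contig_names[-1]
    for name, strand, loop_len, _mf, _sf in config.hairpins:
        mature = _fresh_mature(config.mature_len)
        loop = _random_seq(rng, loop_len)
        overhang = _random_seq(rng, 2)
        precursor = mature + loop + revcomp(mature) + overhang
        hp = _plant(hp_contig, precursor, "hairpin", name, strand)
        L, M = loop_len, len(mature)
        # sub-loci relative to precursor: mature [0, M); star with 2-nt
        # 3' overhang geometry: [M + L + 2, len(precursor))
        for sub, (a, b) in (("novel_mature", (0, M)),
                            ("novel_star", (M + L + 2, len(precursor)))):
            if strand == "+":
                s, e = hp.start + a, hp.start + b
            else:
                s, e = hp.end - b, hp.end - a
            loci.append(Locus(hp.contig, s, e, strand, sub, f"{name}-{sub.split('_')[1]}"))

    # two target transcripts carrying perfect complementary sites
    transcripts = {}
    site_owners = [config.known[0][0], f"{config.hairpins[1][0]}-mature"]
    entity_seq = _entity_sequences(
        ReferenceBundle({k: "".join(v) for k, v in contigs.items()},
                        ncrnas, matures, loci))
    for t, owner in enumerate(site_owners, start=1):
        site = revcomp(entity_seq[owner])
        up, down = _random_seq(rng, 120), _random_seq(rng, 120)
        transcripts[f"tx{t}"] = up + site + down
        loci.append(Locus(f"tx{t}", 120, 120 + len(site), "+", "target_site", owner))

    bundle = ReferenceBundle({k: "".join(v) for k, v in contigs.items()},
                             ncrnas, matures,
                             [l for l in loci if l.kind != "target_site"] +
                             [l for l in loci if l.kind == "target_site"],
                             transcripts)
    bundle.validate()
    return bundle


def _entity_sequences(bundle: ReferenceBundle) -> dict[str, str]:
    """Read sequence emitted for each planted expressed entity."""
    out = {}
    for loc in bundle.planted_loci:
        if loc.kind in ("known_mirna",):
            out[loc.name] = bundle.locus_sequence(loc)
        elif loc.kind in ("novel_mature", "novel_star"):
            out[loc.name] = bundle.locus_sequence(loc)
    return out


@dataclass
class SimulationResult:
    fastq_paths: dict[str, Path]
    truth: pd.DataFrame
    class_counts: pd.DataFrame  # realized per-stage counts per read class
    libsizes: dict[str, int]    # realized clean (non-artifact) reads per stage


def simulate_libraries(bundle: ReferenceBundle,
                       profiles: list[StageProfile],
                       seed: int,
                       outdir: str | Path) -> SimulationResult:
    """Emit one FASTQ per stage plus a truth table.

    Per library, ``target_clean_reads / (1 - total artifact rate)`` reads
    (rounded) are drawn from a single multinomial over artifact classes,
    planted entities, and background; inserts get the 3' adapter appended and
    are cut to the instrument read length.
    """
    stages = {p.stage for p in profiles}
    if stages != set(STAGES):
        raise ValueError(f"profiles must cover {STAGES}, got {sorted(stages)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    entity_seq = _entity_sequences(bundle)
    ncrna_by_name = {n.name: n for n in bundle.ncrna_catalog}
    contig_names = sorted(bundle.contigs)

    fastq_paths: dict[str, Path] = {}
    class_rows = []
    realized: dict[str, dict[str, int]] = {}
    libsizes: dict[str, int] = {}
    profiles = sorted(profiles, key=lambda p: STAGES.index(p.stage))

    for prof in profiles:
        adapter3, adapter5 = ADAPTER3, ADAPTER5
        art_total = sum(prof.artifact_rates.values())
        n_emit = round(prof.target_clean_reads / (1.0 - art_total))
        entities = sorted(prof.abundance)
        bg_frac = 1.0 - sum(prof.abundance.values())
        classes = (list(ARTIFACT_CLASSES)
                   + [f"entity:{e}" for e in entities] + ["background"])
        probs = np.array([prof.artifact_rates.get(c, 0.0) for c in ARTIFACT_CLASSES]
                         + [(1 - art_total) * prof.abundance[e] for e in entities]
                         + [(1 - art_total) * bg_frac])
        counts = rng.multinomial(n_emit, probs / probs.sum())
        class_counts = dict(zip(classes, (int(c) for c in counts)))

        reads: list[tuple[str, str]] = []  # (class label, sequence)
        for cls, k in class_counts.items():
            for _ in range(k):
                reads.append((cls, _make_read(cls, bundle, entity_seq, ncrna_by_name,
                                              contig_names, rng, adapter3, adapter5)))
        order = rng.permutation(len(reads))

        path = outdir / f"{prof.stage}.fastq"
        with open(path, "w") as fh:
            for ridx, i in enumerate(order):
                cls, seq = reads[i]
                qual = _quality_string(len(seq), prof.quality_error_rate, rng)
                fh.write(f"@{prof.stage}:{ridx} class={cls}\n{seq}\n+\n{qual}\n")
        fastq_paths[prof.stage] = path

        realized[prof.stage] = {e: class_counts[f"entity:{e}"] for e in entities}
        realized[prof.stage]["background"] = class_counts["background"]
        libsizes[prof.stage] = sum(v for c, v in class_counts.items()
                                   if c not in ARTIFACT_CLASSES)
        for cls, k in class_counts.items():
            class_rows.append({"stage": prof.stage, "read_class": cls, "count": k})

    truth = _truth_table(bundle, profiles, entity_seq, realized)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    class_df = pd.DataFrame(class_rows)
    class_df.to_csv(outdir / "class_counts.tsv", sep="\t", index=False)
    return SimulationResult(fastq_paths, truth, class_df, libsizes)


def _make_read(cls, bundle, entity_seq, ncrna_by_name, contig_names, rng,
               adapter3, adapter5) -> str:
    if cls == "adapter3_null":
        while True:
            seq = _random_seq(rng, READ_LENGTH)
            if _rc.find_adapter3(seq, adapter3) is None:
                return seq
    if cls == "insert_null":
        return _fill_read("", adapter3)
    if cls == "adapter5_contaminant":
        insert = adapter5[:10] + _random_seq(rng, int(rng.integers(10, 17)))
        return _fill_read(insert, adapter3)
    if cls == "poly_a":
        n = int(rng.integers(18, 25))
        return _fill_read("A" * n, adapter3)
    if cls == "short_insert":
        return _fill_read(_random_seq(rng, int(rng.integers(10, 18))), adapter3)
    if cls == "background":
        ln = int(rng.choice(_BG_LENGTHS, p=_BG_LENGTH_P))
        contig = contig_names[int(rng.integers(0, len(contig_names)))]
        cseq = bundle.contigs[contig]
        start = int(rng.integers(0, len(cseq) - ln + 1))
        insert = cseq[start:start + ln]
        if rng.random() < 0.5:
            insert = revcomp(insert)
        return _fill_read(insert, adapter3)
    name = cls.split(":", 1)[1]
    if name in ncrna_by_name:
        src = ncrna_by_name[name].sequence
        ln = int(rng.integers(20, 27))
        start = int(rng.integers(0, len(src) - ln + 1))
        return _fill_read(src[start:start + ln], adapter3)
    return _fill_read(entity_seq[name], adapter3)


def _fill_read(insert: str, adapter3: str) -> str:
    read = insert + adapter3
    if len(read) < READ_LENGTH:
        read = read + "A" * (READ_LENGTH - len(read))
    return read[:READ_LENGTH]


def _quality_string(n: int, error_rate: float, rng: np.random.Generator) -> str:
    qual = np.full(n, 40)
    if error_rate > 0:
        low = rng.random(n) < error_rate
        qual[low] = rng.integers(2, 10, int(low.sum()))
    return "".join(chr(33 + q) for q in qual)


def _truth_table(bundle, profiles, entity_seq, realized) -> pd.DataFrame:
    """One row per planted expressed entity with expected/realized counts and
    true per-million log2 fold changes (0 handled by the 0.01 substitution
    rule used downstream)."""
    kind_by_name = {}
    family_by_name = {m.name: m.family for m in bundle.mature_catalog}
    for loc in bundle.planted_loci:
        if loc.kind in ("known_mirna", "novel_mature", "novel_star", "ncrna"):
            kind_by_name[loc.name] = loc.kind
    prof_by_stage = {p.stage: p for p in profiles}
    rows = []
    names = sorted(prof_by_stage[STAGES[0]].abundance)
    for name in names:
        fr = [prof_by_stage[s].abundance.get(name, 0.0) for s in STAGES]
        exp = [f * prof_by_stage[s].target_clean_reads for f, s in zip(fr, STAGES)]
        rpm = [f * 1e6 if f > 0 else 0.01 for f in fr]
        lfc = [math.log2(rpm[1] / rpm[0]), math.log2(rpm[2] / rpm[0]),
               math.log2(rpm[2] / rpm[1])]
        row = {
            "name": name,
            "kind": kind_by_name.get(name, "ncrna"),
            "family": family_by_name.get(name, ""),
            "sequence": entity_seq.get(
                name, next((n.sequence for n in bundle.ncrna_catalog
                            if n.name == name), "")),
        }
        for i, s in enumerate(STAGES):
            row[f"frac_{s}"] = fr[i]
            row[f"expected_{s}"] = exp[i]
            row[f"count_{s}"] = realized[s].get(name, 0)
        row["true_lfc_s2_s1"], row["true_lfc_s3_s1"], row["true_lfc_s3_s2"] = lfc
        row["true_de"] = any(abs(v) >= 1.0 for v in lfc)
        rows.append(row)
    return pd.DataFrame(rows)
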