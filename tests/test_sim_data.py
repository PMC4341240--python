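"""Reference/library generator: determinism, planted truth, artifact rates."""

import filecmp

import numpy as np
import pytest

from taprootmir import sim_data
from taprootmir.sim_data import (LayoutError, SimConfig, StageProfile,
                                 default_profiles, make_reference, revcomp,
                                 simulate_libraries)


def test_reference_is_deterministic_under_fixed_seed():
    a = make_reference(SimConfig(), seed=1)
    b = make_reference(SimConfig(), seed=1)
    assert a.contigs == b.contigs
    assert a.mature_catalog == b.mature_catalog
    assert a.planted_loci == b.planted_loci
    assert make_reference(SimConfig(), seed=2).contigs != a.contigs


def test_planted_sequences_occur_at_their_loci(bundle):
    for loc in bundle.planted_loci:
        if loc.kind == "known_mirna":
            mat = next(m for m in bundle.mature_catalog if m.name == loc.name)
            assert bundle.locus_sequence(loc) == mat.sequence
        elif loc.kind == "ncrna":
            nc = next(n for n in bundle.ncrna_catalog if n.name == loc.name)
            assert bundle.locus_sequence(loc) == nc.sequence


def test_hairpin_lengths_within_observed_precursor_range(bundle):
    lengths = [l.end - l.start for l in bundle.loci("hairpin")]
    assert lengths and all(47 <= n <= 354 for n in lengths)


def test_planted_hairpin_folds_into_mature_star_duplex(bundle):
    from taprootmir._fold import fold, structure_pairs

    hp = bundle.loci("hairpin")[0]
    precursor = bundle.locus_sequence(hp)
    r = fold(precursor)
    assert r.mfe < -18
    partner = dict(structure_pairs(r.structure))
    # the designed 21-nt mature arm pairs base-by-base with the star arm
    m = 21
    paired = [i for i in range(m) if i in partner]
    assert len(paired) >= m - 4


def test_layout_error_when_contig_too_short():
    cfg = SimConfig(contig_lengths={"c1": 500, "c2": 500})
    with pytest.raises(LayoutError):
        make_reference(cfg, seed=1)


def test_duplicate_names_rejected(bundle):
    bad = sim_data.ReferenceBundle(
        dict(bundle.contigs), bundle.ncrna_catalog,
        bundle.mature_catalog + [bundle.mature_catalog[0]],
        bundle.planted_loci)
    with pytest.raises(ValueError, match="duplicate"):
        bad.validate()


def test_stage_profile_validation():
    with pytest.raises(ValueError):
        StageProfile("stage9", 20000, {})
    with pytest.raises(ValueError):
        StageProfile("stage1", 10, {})
    with pytest.raises(ValueError):
        StageProfile("stage1", 20000, {"x": -0.1})


def test_missing_stage_rejected(tmp_path, bundle):
    profiles = default_profiles()[:2]
    with pytest.raises(ValueError, match="stage"):
        simulate_libraries(bundle, profiles, seed=1, outdir=tmp_path)


def test_libraries_byte_identical_under_fixed_seed(tmp_path, bundle):
    profiles = [StageProfile(s, 1000, {"rsa-miR156a": 0.05})
                for s in ("stage1", "stage2", "stage3")]
    r1 = simulate_libraries(bundle, profiles, seed=9, outdir=tmp_path / "a")
    r2 = simulate_libraries(bundle, profiles, seed=9, outdir=tmp_path / "b")
    for stage in r1.fastq_paths:
        assert filecmp.cmp(r1.fastq_paths[stage], r2.fastq_paths[stage],
                           shallow=False)
    assert r1.truth.equals(r2.truth)


def test_emitted_read_count_follows_artifact_inflation(small_sim):
    cfg, _bundle, result = small_sim
    art = sum(cfg.artifact_rates.values())
    expected = round(cfg.target_clean_reads / (1 - art))
    for stage in ("stage1", "stage2", "stage3"):
        total = result.class_counts.query("stage == @stage")["count"].sum()
        assert total == expected


def test_artifact_class_counts_within_binomial_3sigma(small_sim):
    cfg, _bundle, result = small_sim
    art = sum(cfg.artifact_rates.values())
    n = round(cfg.target_clean_reads / (1 - art))
    for cls, rate in cfg.artifact_rates.items():
        got = result.class_counts.query("read_class == @cls")["count"]
        sigma = np.sqrt(n * rate * (1 - rate))
        assert (np.abs(got - n * rate) <= 3 * sigma + 1).all()


def test_no_artifacts_means_every_read_cleans(tmp_path, bundle):
    from taprootmir.read_clean import clean_library

    profiles = [StageProfile(s, 1000, {"rsa-miR156a": 0.10},
                             artifact_rates={}, quality_error_rate=0.0)
                for s in ("stage1", "stage2", "stage3")]
    result = simulate_libraries(bundle, profiles, seed=3, outdir=tmp_path)
    _tags, summary = clean_library(result.fastq_paths["stage1"],
                                   sim_data.ADAPTER3, sim_data.ADAPTER5)
    assert summary.clean_reads == summary.raw_reads == summary.high_quality


def test_planted_decline_counts_within_multinomial_3sigma(tmp_path, bundle):
    """A miR156a-like entity planted proportional to the 505,759 : 50,613 :
    16,238 stage decline at 20k reads/stage lands within 3 sigma of its
    multinomial expectation in every stage."""
    libs = (16819905, 18853348, 17082616)
    reads = (505759, 50613, 16238)
    fracs = [r / n for r, n in zip(reads, libs)]
    profiles = [StageProfile(s, 20000, {"rsa-miR156a": f})
                for s, f in zip(("stage1", "stage2", "stage3"), fracs)]
    result = simulate_libraries(bundle, profiles, seed=7, outdir=tmp_path)
    row = result.truth.set_index("name").loc["rsa-miR156a"]
    for stage, frac in zip(("stage1", "stage2", "stage3"), fracs):
        n_emit = round(20000 / (1 - sum(profiles[0].artifact_rates.values())))
        exp = n_emit * frac
        sigma = np.sqrt(n_emit * frac * (1 - frac))
        assert abs(row[f"count_{stage}"] - exp) <= 3 * sigma


def test_truth_log2fc_zero_for_flat_entity(small_sim):
    _cfg, _bundle, result = small_sim
    row = result.truth.set_index("name").loc["rsa-miR168a"]
    for col in ("true_lfc_s2_s1", "true_lfc_s3_s1", "true_lfc_s3_s2"):
        assert row[col] == pytest.approx(0.0)
    assert not row["true_de"]


def test_nonartifact_inserts_map_to_bundle(small_sim):
    """Every emitted non-artifact insert occurs in the reference (sense or
    antisense), i.e. reads are genuinely genome-derived."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator
    from taprootmir.read_clean import find_adapter3

    _cfg, bundle, result = small_sim
    genome = "#".join(bundle.contigs.values())
    genome_rc = revcomp(genome)
    checked = 0
    with open(result.fastq_paths["stage2"]) as fh:
        for title, seq, _q in FastqGeneralIterator(fh):
            cls = title.split("class=")[1]
            if cls in sim_data.ARTIFACT_CLASSES:
                continue
            p = find_adapter3(seq, sim_data.ADAPTER3)
            insert = seq[:p]
            if cls.startswith("entity:") and not any(
                    cls.endswith(n.name) for n in bundle.ncrna_catalog):
                assert insert in genome or insert in genome_rc
                checked += 1
            if checked > 300:
                break
    assert checked > 100


def test_bundle_roundtrips_through_fasta(tmp_path, bundle):
    bundle.write(tmp_path)
    back = sim_data.ReferenceBundle.read(tmp_path)
    assert back.contigs == bundle.contigs
    assert back.mature_catalog == bundle.mature_catalog
    assert [n.kind for n in back.ncrna_catalog] == \
        [n.kind for n in bundle.ncrna_catalog]
    assert back.transcripts == bundle.transcripts
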