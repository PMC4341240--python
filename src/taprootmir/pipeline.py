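"""End-to-end orchestration: simulate -> clean -> annotate -> novel ->
differential expression -> targets -> reports."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, diffexp, novelmir, read_clean, report_val, sim_data


@dataclass
class RunResult:
    bundle: sim_data.ReferenceBundle
    sim: sim_data.SimulationResult
    summaries: dict[str, read_clean.CleaningSummary]
    tags_per_stage: dict[str, pd.DataFrame]
    tags: pd.DataFrame
    annotation: pd.DataFrame
    candidates: list
    expression: pd.DataFrame
    target_hits: pd.DataFrame | None = None
    libsizes: dict[str, int] = field(default_factory=dict)


def known_mirna_counts(annotation: pd.DataFrame) -> pd.DataFrame:
    """Member-level known-miRNA count table: reads of all tags assigned to
    each mature, per stage."""
    known = annotation[annotation["category"] == "known_miRNA"]
    count_cols = [c for c in annotation.columns if c.startswith("count_")]
    grp = (known.groupby(["matched_mirna", "family"])[count_cols]
           .sum().reset_index()
           .rename(columns={"matched_mirna": "mirna_id"}))
    return grp


def novel_counts(candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {"mirna_id": c.name, "family": c.name.rsplit("-", 1)[0]}
        row.update({k: int(v) for k, v in c.counts.items()})
        rows.append(row)
    cols = ["mirna_id", "family", "count_stage1", "count_stage2", "count_stage3"]
    df = pd.DataFrame(rows, columns=cols)
    return df.fillna(0)


def run_pipeline(outdir: str | Path, seed: int = 1,
                 config: sim_data.SimConfig | None = None,
                 scan_targets: bool = True) -> RunResult:
    """Simulate three stage libraries and push them through every stage of
    the analysis; writes intermediate TSVs and report tables under outdir."""
    outdir = Path(outdir)
    config = config or sim_data.SimConfig()
    bundle = sim_data.make_reference(config, seed)
    bundle.write(outdir / "reference")
    sim = sim_data.simulate_libraries(bundle, sim_data.default_profiles(config),
                                      seed + 1, outdir / "fastq")

    summaries: dict[str, read_clean.CleaningSummary] = {}
    tags_per_stage: dict[str, pd.DataFrame] = {}
    for stage, path in sim.fastq_paths.items():
        tags, summary = read_clean.clean_library(path, config.adapter3,
                                                 config.adapter5)
        summaries[stage] = summary
        tags_per_stage[stage] = tags
    tags = read_clean.combine_tag_tables(tags_per_stage)
    tags.to_csv(outdir / "tags.tsv", sep="\t", index=False)

    annotation = annotate.classify(tags, bundle)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    annotate.category_summary(annotation).to_csv(
        outdir / "category_summary.tsv", sep="\t", index=False)

    candidates = novelmir.predict_novel(annotation, bundle)
    novelmir.candidates_frame(candidates).to_csv(
        outdir / "novel_candidates.tsv", sep="\t", index=False)

    libsizes = {s: summaries[s].clean_reads for s in summaries}
    counts = pd.concat([known_mirna_counts(annotation),
                        novel_counts(candidates)], ignore_index=True)
    expression = diffexp.expression_table(counts, libsizes)
    expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)

    target_hits = None
    if scan_targets and bundle.transcripts:
        de = expression[expression["de"]]
        seq_by_id = {m.name: m.sequence for m in bundle.mature_catalog}
        seq_by_id.update({c.name: c.mature_seq for c in candidates})
        mirnas = {mid: seq_by_id[mid] for mid in de["mirna_id"]
                  if mid in seq_by_id}
        target_hits = targets_scan(mirnas, bundle.transcripts)
        target_hits.to_csv(outdir / "target_hits.tsv", sep="\t", index=False)

    run = RunResult(bundle, sim, summaries, tags_per_stage, tags, annotation,
                    candidates, expression, target_hits, libsizes)
    report_val.build_reports(run, outdir / "reports")
    return run


def targets_scan(mirnas: dict[str, str], transcripts: dict[str, str]):
    from . import targets

    return targets.scan_many(mirnas, transcripts)
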