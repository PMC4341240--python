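"""Summary artifacts and RT-qPCR relative-quantification arithmetic.

Produces the paper-shaped outputs of a full run: the library-QC accounting
table, the insert-length histogram, the per-miRNA expression table with fold
changes and p-values, the DE pattern clusters, and 2^-ddCt relative
expression for qPCR validation panels.  Every number in every report is
recomputed from the upstream tables; no report-only arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from . import read_clean as rc


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        if not (self.ct_target > 0 and self.ct_reference > 0):
            raise ValueError("Ct values must be positive")


def ddct(measurement: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative expression 2^-ddCt against a reference gene and a calibrator
    sample (assumes amplification efficiency 2)."""
    dct = measurement.ct_target - measurement.ct_reference
    dct_cal = calibrator.ct_target - calibrator.ct_reference
    return 2.0 ** (-(dct - dct_cal))


def qpcr_table(ct: pd.DataFrame, calibrator_id: str) -> pd.DataFrame:
    """Relative expression per (gene, sample) from a Ct table with columns
    ``gene, sample_id, ct_target, ct_reference``."""
    rows = []
    for gene, sub in ct.groupby("gene"):
        cal = sub[sub["sample_id"] == calibrator_id]
        if cal.empty:
            raise ValueError(f"calibrator sample {calibrator_id!r} missing "
                             f"for gene {gene}")
        cal_m = QpcrMeasurement(calibrator_id,
                                float(cal.iloc[0]["ct_target"]),
                                float(cal.iloc[0]["ct_reference"]))
        for _, r in sub.iterrows():
            m = QpcrMeasurement(r["sample_id"], float(r["ct_target"]),
                                float(r["ct_reference"]))
            rows.append({"gene": gene, "sample_id": m.sample_id,
                         "relative_expression": ddct(m, cal_m)})
    return pd.DataFrame(rows)


def table1_frame(summaries: dict[str, rc.CleaningSummary]) -> pd.DataFrame:
    """Library-QC accounting table, one column pair per stage; the
    longer-than-30-nt tally is reported as a footnote row."""
    order = ["raw_reads", "high_quality", "adapter3_null", "insert_null",
             "adapter5_contaminant", "short_insert", "poly_a", "clean_reads",
             "long_insert"]
    labels = {"raw_reads": "Raw reads", "high_quality": "High-quality",
              "clean_reads": "Clean reads", **rc.CATEGORY_LABELS}
    rows = []
    for key in order:
        row = {"category": labels[key]}
        for stage, s in summaries.items():
            pct = s.percentages()
            if key == "raw_reads":
                row[f"{stage}_count"], row[f"{stage}_pct"] = s.raw_reads, ""
            elif key == "high_quality":
                row[f"{stage}_count"] = s.high_quality
                row[f"{stage}_pct"] = 100.0 if s.high_quality else 0.0
            elif key == "clean_reads":
                row[f"{stage}_count"] = s.clean_reads
                row[f"{stage}_pct"] = pct["clean_reads"]
            else:
                row[f"{stage}_count"] = s.removed[key]
                row[f"{stage}_pct"] = pct[key]
        rows.append(row)
    return pd.DataFrame(rows)


def length_dist_frame(per_stage_tags: dict[str, pd.DataFrame]) -> pd.DataFrame:
    out = pd.DataFrame({stage: rc.length_distribution(tags)
                        for stage, tags in per_stage_tags.items()})
    out.index.name = "length"
    return out.reset_index()


def table2_frame(expr: pd.DataFrame) -> pd.DataFrame:
    """Expression table with printed two-decimal normalized counts and fold
    changes, mirroring the known-miRNA family summary layout."""
    cols = {"mirna_id": expr["mirna_id"], "family": expr["family"]}
    for s in ("stage1", "stage2", "stage3"):
        cols[f"reads_{s}"] = expr[f"count_{s}"]
    for s in ("stage1", "stage2", "stage3"):
        cols[f"normalized_{s}"] = [
            round(r if c > 0 else 0.01, 2)
            for r, c in zip(expr[f"rpm_{s}"], expr[f"count_{s}"])]
    for key in ("stage2_stage1", "stage3_stage1", "stage3_stage2"):
        cols[f"log2fc_{key}"] = expr[f"log2fc_{key}"].round(2)
        cols[f"pvalue_{key}"] = expr[f"pvalue_{key}"]
    cols["de"] = expr["de"]
    cols["cluster"] = expr["cluster"]
    return pd.DataFrame(cols)


def family_members_frame(annot: pd.DataFrame) -> pd.DataFrame:
    """Distinct matched matures per family in the annotation output."""
    known = annot[annot["category"] == "known_miRNA"]
    grp = known.groupby("family")["matched_mirna"].nunique()
    return (grp.rename("members").reset_index()
            .sort_values("family", ignore_index=True))


def anticorrelation_frame(mirna_expr: pd.DataFrame, target_expr: pd.DataFrame,
                          pairs: list[tuple[str, str]],
                          rho_threshold: float = 0.5) -> pd.DataFrame:
    """Spearman sign summary per miRNA-target pair over the stage profiles:
    'anti' (rho <= -threshold), 'co' (rho >= threshold) or 'none'."""
    stages = ("stage1", "stage2", "stage3")
    rows = []
    mi = mirna_expr.set_index("mirna_id")
    ti = target_expr.set_index("target_id")
    for mirna, target in pairs:
        x = [mi.loc[mirna, f"rpm_{s}"] for s in stages]
        y = [ti.loc[target, f"expr_{s}"] for s in stages]
        rho = stats.spearmanr(x, y).statistic
        call = "none"
        if pd.notna(rho) and rho <= -rho_threshold:
            call = "anti"
        elif pd.notna(rho) and rho >= rho_threshold:
            call = "co"
        rows.append({"mirna_id": mirna, "target_id": target,
                     "spearman_rho": rho, "relationship": call})
    return pd.DataFrame(rows)


def build_reports(run, outdir: str | Path) -> dict[str, Path]:
    """Write the report TSVs for a finished in-memory pipeline run (see
    :func:`taprootmir.pipeline.run_pipeline`)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    def _put(name, frame):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        written[name] = path

    for attr, stage_name in (("summaries", "cleaning summaries"),
                             ("tags_per_stage", "tag tables"),
                             ("expression", "expression table")):
        if getattr(run, attr, None) is None:
            raise FileNotFoundError(
                f"missing upstream output: {stage_name}; rerun that stage")
    _put("summary_table1.tsv", table1_frame(run.summaries))
    _put("length_dist.tsv", length_dist_frame(run.tags_per_stage))
    _put("expression_table2.tsv", table2_frame(run.expression))
    de = run.expression[run.expression["de"]]
    _put("de_clusters.tsv", de[["mirna_id", "family", "cluster"]]
         .sort_values(["cluster", "mirna_id"], ignore_index=True))
    if getattr(run, "annotation", None) is not None:
        _put("family_members.tsv", family_members_frame(run.annotation))
    if getattr(run, "target_hits", None) is not None:
        _put("target_hits.tsv", run.target_hits)
    return written
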