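"""Per-million normalization, exact-test screening and pattern clustering.

Counts from unreplicated count libraries are normalized to reads per million
clean reads (RPM).  Pairwise log2 fold changes between stages substitute
0.01 for a zero normalized value, and a comparison is skipped outright when
both normalized values are below one.  Significance comes from the
Audic-Claverie exact test for two Poisson-sampled libraries:

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

with a two-sided p-value of 2 * min(P(K <= y), P(K >= y)) capped at 1.  A
record is differentially expressed when at least one comparison reaches
|log2FC| >= 1 with p < 0.05.  Expression patterns are the deterministic sign
labels of the stage1->stage2 and stage2->stage3 moves.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

FC_THRESHOLD = 1.0
ALPHA = 0.05
ZERO_SUBSTITUTE = 0.01
SKIP_BELOW = 1.0

COMPARISONS = (("stage2", "stage1"), ("stage3", "stage1"), ("stage3", "stage2"))


def normalize_rpm(count: int, libsize: int, ndigits: int | None = None) -> float:
    """Reads per million clean reads.  Zero substitution is a fold-change
    rule, not a normalization rule, and is deliberately not applied here."""
    if libsize <= 0:
        raise ValueError("libsize must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    rpm = count / libsize * 1e6
    return round(rpm, ndigits) if ndigits is not None else rpm


def fold_change(rpm_control: float, rpm_treatment: float,
                ndigits: int | None = None) -> float | None:
    """log2(treatment / control) after substituting 0 -> 0.01 in either
    operand; None when both substituted values are < 1 (too low to compare)."""
    a = rpm_control if rpm_control > 0 else ZERO_SUBSTITUTE
    b = rpm_treatment if rpm_treatment > 0 else ZERO_SUBSTITUTE
    if a < SKIP_BELOW and b < SKIP_BELOW:
        return None
    lfc = math.log2(b / a)
    return round(lfc, ndigits) if ndigits is not None else lfc


def ac_pvalue(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for count x in a library of n1 reads
    versus count y in a library of n2 reads.

    The conditional distribution of y given x is negative binomial with
    x + 1 successes and success probability n1 / (n1 + n2); the tails are
    evaluated through the regularized incomplete beta function, so counts up
    to 1e7 stay in range.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be >= 0")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p1 = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p1)      # P(K <= y)
    upper = stats.nbinom.sf(y - 1, x + 1, p1)   # P(K >= y)
    return float(min(1.0, 2.0 * min(lower, upper)))


def ac_pvalue_reference(x: int, n1: int, y: int, n2: int) -> float:
    """Brute-force reference for :func:`ac_pvalue`: direct summation of the
    conditional probabilities by exact term recurrence in extended precision
    (80-bit floats).  Independent of the incomplete-beta route used by the
    fast implementation; intended for validation, not production use.
    """
    ld = np.longdouble
    r = ld(n2) / ld(n1)
    logr, log1pr = np.log(r), np.log1p(r)

    def increments(k0: int, k1: int):
        ks = np.arange(k0, k1, dtype=np.int64).astype(ld)
        return logr + np.log(ld(x) + ks + 1) - np.log(ks + 1) - log1pr

    logp0 = -(ld(x) + 1) * log1pr
    lp_lo = logp0 + np.concatenate(([ld(0)], np.cumsum(increments(0, y))))
    lower = np.exp(lp_lo).sum()
    if lower < 0.5:
        # upper tail >= 1 - lower > lower: the minimum tail is the lower one
        return float(min(ld(1), 2 * lower))
    upper = np.exp(lp_lo[-1])
    k0, lp_cur = y, lp_lo[-1]
    while upper > 0:
        lps = lp_cur + np.cumsum(increments(k0, k0 + 8192))
        upper += np.exp(lps).sum()
        lp_cur = lps[-1]
        k0 += 8192
        if lp_cur < np.log(upper) - 50:  # remaining mass < ~1e-20 relative
            break
    return float(min(ld(1), 2 * min(lower, upper)))


def expression_table(counts: pd.DataFrame, libsizes: dict[str, int],
                     threshold: float = FC_THRESHOLD,
                     alpha: float = ALPHA) -> pd.DataFrame:
    """Full expression-record table.

    ``counts`` needs columns ``mirna_id``, ``family`` (may be empty) and
    ``count_stage1..3``; ``libsizes`` maps stage -> clean-read total.
    Adds RPM, pairwise log2 fold changes, exact-test p-values, skip and DE
    flags, and a pattern cluster label for DE records.
    """
    df = counts.copy().reset_index(drop=True)
    for stage in ("stage1", "stage2", "stage3"):
        df[f"rpm_{stage}"] = [normalize_rpm(c, libsizes[stage])
                              for c in df[f"count_{stage}"]]
    for b, a in COMPARISONS:
        key = f"{b}_{a}"
        lfcs, ps, skips = [], [], []
        for _, row in df.iterrows():
            lfc = fold_change(row[f"rpm_{a}"], row[f"rpm_{b}"])
            if lfc is None:
                lfcs.append(np.nan)
                ps.append(np.nan)
                skips.append(True)
            else:
                lfcs.append(lfc)
                ps.append(ac_pvalue(int(row[f"count_{a}"]), libsizes[a],
                                    int(row[f"count_{b}"]), libsizes[b]))
                skips.append(False)
        df[f"log2fc_{key}"] = lfcs
        df[f"pvalue_{key}"] = ps
        df[f"skipped_{key}"] = skips
        df[f"de_{key}"] = [(not s) and abs(l) >= threshold and p < alpha
                           for l, p, s in zip(lfcs, ps, skips)]
    df["de"] = df[[f"de_{b}_{a}" for b, a in COMPARISONS]].any(axis=1)
    df["cluster"] = cluster_patterns(df, threshold)
    return df


def screen(records: pd.DataFrame, threshold: float = FC_THRESHOLD,
           alpha: float = ALPHA) -> pd.DataFrame:
    """DE subset: at least one non-skipped comparison with |log2FC| >=
    threshold and p < alpha."""
    de = pd.Series(False, index=records.index)
    for b, a in COMPARISONS:
        key = f"{b}_{a}"
        ok = (~records[f"skipped_{key}"]
              & (records[f"log2fc_{key}"].abs() >= threshold)
              & (records[f"pvalue_{key}"] < alpha))
        de |= ok.fillna(False)
    return records[de]


def _sign(lfc: float, threshold: float) -> str:
    if pd.isna(lfc) or abs(lfc) < threshold:
        return "flat"
    return "up" if lfc > 0 else "down"


def cluster_patterns(records: pd.DataFrame,
                     threshold: float = FC_THRESHOLD) -> list[str]:
    """Sign-pattern label (stage1->stage2, stage2->stage3) per DE record;
    non-DE records get an empty label."""
    labels = []
    for _, row in records.iterrows():
        if "de" in records.columns and not row["de"]:
            labels.append("")
            continue
        s1 = _sign(row["log2fc_stage2_stage1"], threshold)
        s2 = _sign(row["log2fc_stage3_stage2"], threshold)
        labels.append(f"{s1}_{s2}")
    return labels
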