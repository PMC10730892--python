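"""Differential expression (Welch-t stand-in), BH correction and overlap tests.

The study-scale analysis would use a negative-binomial GLM (DESeq2-style) at
an adjusted-p threshold of 0.1.  Here differential expression is a documented,
deliberately simple stand-in: a per-feature Welch two-sample t-test on
log2(CPM + 1), Benjamini-Hochberg corrected across all tested features, with
the same padj < 0.1 call.  An ingest hook accepts an externally produced
DESeq2-layout table so real results can be dropped in unchanged.

Cross-comparison overlap of DE sets is scored with a one-sided Fisher exact
test (enrichment) on the 2x2 membership table over the jointly tested universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix, cpm_normalize, filter_low_expression

logger = logging.getLogger(__name__)

PADJ_THRESHOLD = 0.1


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving under ties)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    counts: CountMatrix,
    case_samples: list[str],
    control_samples: list[str],
    padj_threshold: float = PADJ_THRESHOLD,
    min_mean: float | None = 5.0,
) -> pd.DataFrame:
    """Welch t-test on log2(CPM+1) per feature, BH-corrected.

    Returns a DataFrame (feature_id, log2_fold_change, p_value, padj,
    significant, direction).  Direction is the sign of the log2 fold change
    ("flat" at exactly zero).  Features are pre-filtered at mean raw count
    > ``min_mean`` unless ``min_mean`` is None.
    """
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("differential_expression: need >=2 replicates per group")
    if min_mean is not None:
        counts = filter_low_expression(counts, min_mean)
    cpm = cpm_normalize(counts)
    log_expr = np.log2(cpm.values + 1.0)
    a = log_expr[case_samples].to_numpy()
    b = log_expr[control_samples].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    # zero variance in both groups: p undefined under Welch; equal means -> no
    # evidence (p = 1), different means -> arbitrarily strong (p = 0)
    degenerate = np.isnan(p)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    p = np.where(degenerate & (lfc != 0), 0.0, p)
    padj = bh_adjust(p)
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "flat"))
    return pd.DataFrame(
        {
            "feature_id": cpm.values.index,
            "log2_fold_change": lfc,
            "p_value": p,
            "padj": padj,
            "significant": padj < padj_threshold,
            "direction": direction,
        }
    ).reset_index(drop=True)


def read_external_de(path: str | Path, padj_threshold: float = PADJ_THRESHOLD) -> pd.DataFrame:
    """Ingest a DESeq2-layout results TSV (baseMean, log2FoldChange, pvalue, padj)."""
    tab = pd.read_csv(path, sep="\t", index_col=0)
    out = pd.DataFrame(
        {
            "feature_id": tab.index,
            "log2_fold_change": tab["log2FoldChange"].to_numpy(),
            "p_value": tab["pvalue"].to_numpy(),
            "padj": tab["padj"].to_numpy(),
        }
    )
    out["significant"] = out["padj"] < padj_threshold
    out["direction"] = np.where(
        out["log2_fold_change"] > 0, "up",
        np.where(out["log2_fold_change"] < 0, "down", "flat"),
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    intersection: int
    universe: int
    odds_ratio: float
    fisher_p: float


def overlap_significance(set_a, set_b, universe_size: int) -> OverlapResult:
    """One-sided Fisher exact test for enrichment of the overlap of two DE sets."""
    a, b = set(set_a), set(set_b)
    k = len(a & b)
    if universe_size < len(a | b):
        raise ValueError("overlap_significance: universe smaller than the union")
    table = [
        [k, len(a) - k],
        [len(b) - k, universe_size - len(a) - len(b) + k],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return OverlapResult(len(a), len(b), k, universe_size, float(odds), float(p))


def de_summary(de_sets: dict[str, pd.DataFrame]) -> dict:
    """Venn-style summary of DE results across comparisons.

    ``de_sets`` maps comparison label -> differential_expression output.
    Returns totals, up/down splits, pairwise and all-way intersections.
    """
    sig = {
        name: set(df.loc[df["significant"], "feature_id"]) for name, df in de_sets.items()
    }
    updown = {
        name: {
            "up": int(((df["significant"]) & (df["direction"] == "up")).sum()),
            "down": int(((df["significant"]) & (df["direction"] == "down")).sum()),
        }
        for name, df in de_sets.items()
    }
    names = sorted(sig)
    pairwise = {
        f"{x}&{y}": len(sig[x] & sig[y])
        for i, x in enumerate(names)
        for y in names[i + 1:]
    }
    allway = len(set.intersection(*sig.values())) if sig else 0
    return {
        "totals": {n: len(sig[n]) for n in names},
        "up_down": updown,
        "pairwise": pairwise,
        "all_way": allway,
    }
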