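"""Per-gene derived ratios and grouped rank-sum comparisons.

Two ratio read-outs of nuclear proximity are supported: the
unspliced/spliced abundance ratio (intron retention, a chromatin-proximity
signature) and the upstream-antisense/sense ratio (uaRNA signature).  Both
are computed per gene and sample with a pseudocount, then compared between
the input and pulldown fractions, or between gene groups (gene classes, ARE
presence, HuR-site bins), with two-sided Wilcoxon rank-sum tests.

Stars follow the usual figure-legend convention: * p<0.05, ** p<0.01,
*** p<0.001, **** p<0.0001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import split_feature_id

logger = logging.getLogger(__name__)

RATIO_KINDS = ("unspliced_spliced", "antisense_sense")


def stars(p: float) -> str:
    """Significance stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if not np.isfinite(p):
        return "na"
    for threshold, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return mark
    return "ns"


@dataclass
class GroupComparison:
    """One two-group rank-sum comparison."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U of group_a
    pvalue: float
    median_diff: float  # median(b) - median(a)

    @property
    def stars(self) -> str:
        return stars(self.pvalue)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact enumeration for tie-free groups of at most 25 each, otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compute_ratios(
    counts: pd.DataFrame,
    kind: str = "unspliced_spliced",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene per-sample ratio records, long format.

    ``unspliced_spliced``: numerator ``<gene>|unspliced``, denominator
    ``<gene>|spliced``.  ``antisense_sense``: numerator ``<gene>|ua``,
    denominator spliced + unspliced.  ratio = (num + pc) / (den + pc);
    with pc = 0 a zero denominator yields an undefined (NaN) record that is
    excluded from downstream tests.
    """
    if kind not in RATIO_KINDS:
        raise ValueError(f"unknown ratio kind {kind!r}")
    by_kind: dict[str, dict[str, str]] = {}
    for fid in counts.index:
        gene, k = split_feature_id(fid)
        by_kind.setdefault(gene, {})[k] = fid

    rows = []
    skipped = 0
    for gene, parts in by_kind.items():
        if kind == "unspliced_spliced":
            if "unspliced" not in parts or "spliced" not in parts:
                skipped += 1
                continue
            num = counts.loc[parts["unspliced"]]
            den = counts.loc[parts["spliced"]]
        else:
            if "ua" not in parts or "spliced" not in parts:
                skipped += 1
                continue
            num = counts.loc[parts["ua"]]
            den = counts.loc[parts["spliced"]]
            if "unspliced" in parts:
                den = den + counts.loc[parts["unspliced"]]
        numer = num.to_numpy(dtype=float)
        denom = den.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (numer + pseudocount) / (denom + pseudocount)
        ratio = np.where(denom + pseudocount > 0, ratio, np.nan)
        for sample, n_, d_, r_ in zip(counts.columns, numer, denom, ratio):
            rows.append((gene, sample, n_, d_, pseudocount, r_, kind))
    if skipped:
        logger.info("compute_ratios(%s): skipped %d genes lacking a member", kind, skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "sample_id", "numerator", "denominator",
            "pseudocount", "ratio", "kind",
        ],
    )


def compare_ratio_distributions(
    ratios: pd.DataFrame,
    design: pd.DataFrame,
    aggregate: str = "mean",
) -> GroupComparison:
    """Input-vs-pulldown comparison of per-gene ratios.

    ``aggregate="mean"`` (default) averages each gene's ratio across the
    replicates of a fraction, then compares the two per-gene vectors across
    genes with a rank-sum test; ``"pool"`` pools all per-sample ratio values
    of each fraction instead.
    """
    if aggregate not in {"mean", "pool"}:
        raise ValueError("aggregate must be 'mean' or 'pool'")
    merged = ratios.merge(design[["sample_id", "fraction"]], on="sample_id")
    merged = merged.dropna(subset=["ratio"])
    groups = {}
    for fraction in ("input", "pulldown"):
        sub = merged[merged["fraction"] == fraction]
        if sub.empty:
            raise ValueError(f"design error: no samples in fraction {fraction!r}")
        if aggregate == "mean":
            groups[fraction] = sub.groupby("gene_id")["ratio"].mean().to_numpy()
        else:
            groups[fraction] = sub["ratio"].to_numpy()
    a, b = groups["input"], groups["pulldown"]
    stat, p = rank_sum_test(a, b)
    return GroupComparison(
        group_a="input",
        group_b="pulldown",
        n_a=len(a),
        n_b=len(b),
        statistic=stat,
        pvalue=p,
        median_diff=float(np.median(b) - np.median(a)),
    )


@dataclass
class TrendSummary:
    """Monotone-trend summary over ordered bins (Spearman of bin vs median)."""

    bins: list
    medians: list[float]
    spearman_rho: float


def grouped_enrichment_comparison(
    enrichments: pd.DataFrame,
    gene_bins,
    value_column: str = "log2FC",
) -> tuple[list[GroupComparison], TrendSummary]:
    """Compare enrichment between adjacent gene bins; summarize the trend.

    ``gene_bins`` maps gene_id to an orderable bin label (e.g. HuR-site
    count bins 0, 1, 2, 3).  Returns pairwise rank-sum comparisons between
    adjacent bins on ``value_column`` plus a Spearman correlation of bin
    index against bin medians.
    """
    gene_bins = dict(gene_bins)
    values = enrichments[value_column].dropna()
    binned: dict = {}
    for gene, v in values.items():
        if gene in gene_bins:
            binned.setdefault(gene_bins[gene], []).append(v)
    labels = sorted(binned)
    labels = [lab for lab in labels if len(binned[lab]) > 0]
    if len(labels) < 2:
        raise ValueError("nothing to compare: fewer than two nonempty bins")
    comparisons = []
    for lab_a, lab_b in zip(labels, labels[1:]):
        a = np.asarray(binned[lab_a], dtype=float)
        b = np.asarray(binned[lab_b], dtype=float)
        stat, p = rank_sum_test(a, b)
        comparisons.append(
            GroupComparison(
                group_a=str(lab_a),
                group_b=str(lab_b),
                n_a=len(a),
                n_b=len(b),
                statistic=stat,
                pvalue=p,
                median_diff=float(np.median(b) - np.median(a)),
            )
        )
    medians = [float(np.median(binned[lab])) for lab in labels]
    if len(labels) > 1:
        rho = float(sps.spearmanr(np.arange(len(labels)), medians).statistic)
    else:  # pragma: no cover
        rho = np.nan
    trend = TrendSummary(bins=list(labels), medians=medians, spearman_rho=rho)
    return comparisons, trend


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "W": c.statistic,
                "p": c.pvalue,
                "median_diff": c.median_diff,
                "stars": c.stars,
            }
            for c in comparisons
        ]
    )
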