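"""Pulldown-versus-input enrichment calls from NB count models.

The analysis mirrors the standard differential-expression recipe for
proximity-labeling data: collapse features to genes, require a minimum count
in every sample, normalize with median-of-ratios size factors, fit a
negative-binomial GLM per gene with a pulldown indicator, test the pulldown
coefficient with a Wald test, and adjust p-values by Benjamini-Hochberg.
A gene is called ``enriched`` when padj < 0.05 and log2FC >= 0.5,
``depleted`` when padj < 0.05 and log2FC <= -0.5, and ``ns`` otherwise
(thresholds configurable).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .glm import fit_nb_glm
from .reference import ANTISENSE_SUFFIX

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)


def split_feature_id(feature_id: str) -> tuple[str, str]:
    """``"G1|unspliced" -> ("G1", "unspliced")``; bare ids are kind ``gene``."""
    if "|" in feature_id:
        gene, kind = feature_id.rsplit("|", 1)
        return gene, kind
    return feature_id, "gene"


def sense_feature_map(feature_ids) -> dict[str, str]:
    """Map spliced/unspliced features to their gene; antisense rows are dropped."""
    fmap: dict[str, str] = {}
    for fid in feature_ids:
        gene, kind = split_feature_id(fid)
        if kind in {"spliced", "unspliced", "gene"}:
            fmap[fid] = gene
    return fmap


def aggregate_to_genes(
    counts: pd.DataFrame, feature_map: Mapping[str, str]
) -> pd.DataFrame:
    """Sum feature counts to gene counts per sample.

    Every feature in ``counts`` must map to exactly one gene; features
    missing from the map raise (annotation mismatch).
    """
    unmapped = [f for f in counts.index if f not in feature_map]
    if unmapped:
        raise KeyError(
            f"annotation mismatch: {len(unmapped)} features not in feature map "
            f"(first: {unmapped[0]!r})"
        )
    genes = pd.Index([feature_map[f] for f in counts.index], name="gene_id")
    out = counts.groupby(genes, sort=False).sum()
    return out


def sense_gene_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Gene-level sense abundance: spliced + unspliced rows, antisense excluded."""
    keep = [f for f in counts.index if not f.endswith(ANTISENSE_SUFFIX)]
    sub = counts.loc[keep]
    return aggregate_to_genes(sub, sense_feature_map(sub.index))


def filter_min_counts(counts: pd.DataFrame, min_count: int = 5) -> pd.DataFrame:
    """Keep genes with at least ``min_count`` in every sample of the analysis."""
    keep = (counts >= min_count).all(axis=1)
    return counts.loc[keep]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled so their median is 1.

    The per-sample factor is the median over all-positive genes of the ratio
    of that sample's count to the gene's geometric mean across samples.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("degenerate matrix: no gene has positive counts in all samples")
    sub = mat[positive]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    sf = np.median(ratios, axis=0)
    sf = sf / np.median(sf)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def align_design(design: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Reorder design rows to match a count matrix's columns."""
    missing = set(sample_ids) - set(design["sample_id"])
    if missing:
        raise ValueError(f"design table lacks samples: {sorted(missing)}")
    aligned = design.set_index("sample_id").loc[list(sample_ids)]
    aligned.index.name = "sample_id"
    return aligned.reset_index()


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through untouched."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def nb_enrichment_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 0.5,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of pulldown vs input.

    ``counts`` must already be gene-level and filtered.  The model per gene
    is ``log mu = log s_j + b0 + b1 * [pulldown]``; ``log2FC = b1 / log 2``.
    Non-converged genes are reported with NA statistics and excluded from
    the BH denominator.
    """
    design = align_design(design, counts.columns)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)

    pulldown = (design["fraction"] == "pulldown").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(pulldown), pulldown])
    Y = counts.to_numpy(dtype=float)
    fit = fit_nb_glm(Y, X, offset=np.log(sf))

    n_failed = int((~fit.converged).sum())
    if n_failed:
        logger.warning("nb_enrichment_test: %d genes failed to converge", n_failed)

    log2fc = fit.beta[:, 1] / LOG2
    se = fit.se[:, 1] / LOG2
    stat = np.divide(
        fit.beta[:, 1], fit.se[:, 1],
        out=np.full(len(Y), np.nan), where=fit.se[:, 1] > 0,
    )
    pvalue = fit.wald_pvalues(1)
    padj = bh_adjust(pvalue)

    call = np.where(
        (padj < alpha) & (log2fc >= lfc_threshold),
        "enriched",
        np.where((padj < alpha) & (log2fc <= -lfc_threshold), "depleted", "ns"),
    )
    call = np.where(np.isfinite(padj), call, "ns")

    base_mean = (Y / sf).mean(axis=1)
    result = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": np.where(fit.converged, log2fc, np.nan),
            "se": np.where(fit.converged, se, np.nan),
            "stat": np.where(fit.converged, stat, np.nan),
            "pvalue": pvalue,
            "padj": padj,
            "call": call,
            "dispersion": fit.alpha,
        },
        index=counts.index,
    )
    result.attrs["size_factors"] = size_factors.to_dict()
    return result
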