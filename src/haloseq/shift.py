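"""Condition-dependent localization-shift tests (e.g. export-inhibitor response).

Given counts from a two-condition experiment with input and pulldown
fractions in each condition, a gene's localization shift is the change in
its pulldown/input enrichment between conditions:

    delta_g = log2FC(pulldown/input | condition B) - log2FC(pulldown/input | condition A)

This is the interaction coefficient of a negative-binomial GLM with
intercept, fraction, condition and fraction-by-condition terms, tested with
a two-sided Wald test and BH-adjusted across genes.  A companion
decomposition fits the condition contrast separately within input-only and
pulldown-only samples, distinguishing a shift driven by pulldown abundance
changes from one driven by input abundance changes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .enrichment import LOG2, align_design, bh_adjust, estimate_size_factors
from .glm import fit_nb_glm

logger = logging.getLogger(__name__)


def _condition_order(design: pd.DataFrame, reference: str | None = None) -> list[str]:
    conditions = list(dict.fromkeys(design["condition"]))
    if reference is not None:
        if reference not in conditions:
            raise ValueError(f"reference condition {reference!r} not in design")
        conditions = [reference] + [c for c in conditions if c != reference]
    return conditions


def _check_cells(design: pd.DataFrame) -> None:
    cells = design.groupby(["fraction", "condition"]).size()
    conditions = design["condition"].nunique()
    if conditions != 2:
        raise ValueError(f"design error: need exactly 2 conditions, got {conditions}")
    if len(cells) != 2 * conditions or (cells < 2).any():
        raise ValueError(
            "design error: all four (fraction x condition) cells need >=2 replicates"
        )


def ratio_change_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    fdr: float = 0.05,
    size_factors: pd.Series | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-gene interaction Wald test of enrichment change between conditions.

    ``counts`` must be gene-level and pre-filtered.  ``reference`` names
    condition A; by default the first condition in design order.  Reports both per-condition
    log2 enrichments from the same fit, their difference ``delta``, and a
    ``sensitive`` flag at the configured FDR.
    """
    _check_cells(design)
    design = align_design(design, counts.columns)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)

    cond_a, cond_b = _condition_order(design, reference)
    pulldown = (design["fraction"] == "pulldown").to_numpy(dtype=float)
    cond = (design["condition"] == cond_b).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(pulldown), pulldown, cond, pulldown * cond])
    Y = counts.to_numpy(dtype=float)
    fit = fit_nb_glm(Y, X, offset=np.log(sf))

    n_failed = int((~fit.converged).sum())
    if n_failed:
        logger.warning("ratio_change_test: %d genes failed to converge", n_failed)

    lfc_a = fit.beta[:, 1] / LOG2
    delta = fit.beta[:, 3] / LOG2
    lfc_b = lfc_a + delta
    se = fit.se[:, 3] / LOG2
    stat = np.divide(
        fit.beta[:, 3], fit.se[:, 3],
        out=np.full(len(Y), np.nan), where=fit.se[:, 3] > 0,
    )
    pvalue = fit.wald_pvalues(3)
    padj = bh_adjust(pvalue)

    ok = fit.converged
    result = pd.DataFrame(
        {
            "lfc_condA": np.where(ok, lfc_a, np.nan),
            "lfc_condB": np.where(ok, lfc_b, np.nan),
            "delta": np.where(ok, delta, np.nan),
            "se": np.where(ok, se, np.nan),
            "stat": np.where(ok, stat, np.nan),
            "pvalue": pvalue,
            "padj": padj,
            "sensitive": np.where(np.isfinite(padj), padj < fdr, False).astype(bool),
        },
        index=counts.index,
    )
    result.attrs["conditions"] = (cond_a, cond_b)
    result.attrs["fdr"] = fdr
    return result


def abundance_change_decomposition(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Condition contrasts fit separately within input and pulldown samples.

    Lets an enrichment change be attributed to the fraction that moved:
    a pure nuclear-retention effect shows a condition log2FC in the pulldown
    samples with none in the input samples.  Size factors are estimated once
    on the full matrix so the two contrasts share a normalization.
    """
    _check_cells(design)
    design = align_design(design, counts.columns)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    cond_a, cond_b = _condition_order(design, reference)

    out = {}
    for fraction in ("input", "pulldown"):
        mask = (design["fraction"] == fraction).to_numpy()
        sub_design = design.loc[mask]
        sub_counts = counts.loc[:, sub_design["sample_id"]]
        sf = size_factors.loc[sub_counts.columns].to_numpy(dtype=float)
        cond = (sub_design["condition"] == cond_b).to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(cond), cond])
        fit = fit_nb_glm(sub_counts.to_numpy(dtype=float), X, offset=np.log(sf))
        pvalue = fit.wald_pvalues(1)
        out[f"{fraction}_lfc"] = np.where(fit.converged, fit.beta[:, 1] / LOG2, np.nan)
        out[f"{fraction}_pvalue"] = pvalue
        out[f"{fraction}_padj"] = bh_adjust(pvalue)
    result = pd.DataFrame(out, index=counts.index)
    result.attrs["conditions"] = (cond_a, cond_b)
    return result
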