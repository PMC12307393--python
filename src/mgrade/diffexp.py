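"""Two-group differential expression between high-grade and low-grade samples.

The test is Welch's t on log-scale expression: log2 intensities for
microarray-like data, or log-CPM (pseudo-count 0.5, library-size normalized)
when raw counts are supplied on the RNA-seq path. Multiple testing is
controlled with Benjamini-Hochberg FDR. The downstream contract is the
filtered signature geneset, to which the per-cancer fold-change and
expression-floor rules are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CancerConfig, ExpressionMatrix, Platform

logger = logging.getLogger(__name__)

__all__ = ["SignatureGeneSets", "de_test", "select_signature_genes", "log_cpm"]


@dataclass(frozen=True)
class SignatureGeneSets:
    """The two disjoint DE-derived gene lists feeding the grade index."""

    up_in_high: tuple[str, ...]
    up_in_low: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.up_in_high) & set(self.up_in_low):
            raise ValueError("up_in_high and up_in_low must be disjoint")

    @property
    def all_genes(self) -> list[str]:
        return list(self.up_in_high) + list(self.up_in_low)


def log_cpm(counts: pd.DataFrame, pseudo_count: float = 0.5) -> pd.DataFrame:
    """Library-size-normalized log2 counts-per-million for a genes x samples table."""
    lib = counts.sum(axis=0)
    return np.log2((counts + pseudo_count) / (lib + 2 * pseudo_count) * 1e6)


def de_test(
    expr: ExpressionMatrix,
    groups: pd.Series,
    counts_input: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch's t-test of high vs low groups.

    Parameters
    ----------
    expr
        Expression on log2 scale (or raw counts with ``counts_input=True``,
        in which case log-CPM is computed first).
    groups
        Per-sample labels drawn from {"high", "low"}; other samples are
        ignored.

    Returns a DataFrame indexed by gene with columns ``logfc`` (high minus
    low, base 2), ``p``, ``q`` (BH-adjusted), ``mean_expr``. Genes with all
    values missing are excluded with a warning; a gene constant in both
    groups gets p = 1 by convention.
    """
    groups = groups.reindex(expr.sample_ids).dropna()
    high_ids = groups[groups == "high"].index
    low_ids = groups[groups == "low"].index
    if len(high_ids) < 2 or len(low_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got high={len(high_ids)}, low={len(low_ids)}"
        )
    values = expr.values
    if counts_input:
        values = log_cpm(values)
    hi = values.loc[:, high_ids].to_numpy()
    lo = values.loc[:, low_ids].to_numpy()

    all_missing = np.isnan(hi).all(axis=1) | np.isnan(lo).all(axis=1)
    if all_missing.any():
        logger.warning("excluding %d all-missing genes from DE", int(all_missing.sum()))

    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(hi, lo, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    mean_hi = np.nanmean(hi, axis=1)
    mean_lo = np.nanmean(lo, axis=1)
    logfc = mean_hi - mean_lo
    # constant-in-both-groups genes have zero variance => t undefined; p = 1
    var0 = (np.nanvar(hi, axis=1) == 0) & (np.nanvar(lo, axis=1) == 0)
    p[var0] = 1.0
    p[np.isnan(p)] = 1.0

    keep = ~all_missing
    res = pd.DataFrame(
        {
            "logfc": logfc[keep],
            "p": p[keep],
            "mean_expr": np.nanmean(np.concatenate([hi, lo], axis=1), axis=1)[keep],
        },
        index=values.index[keep],
    )
    res["q"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
    return res[["logfc", "p", "q", "mean_expr"]]


def select_signature_genes(
    de: pd.DataFrame,
    config: CancerConfig,
    platform: Platform | str = Platform.MICROARRAY,
) -> SignatureGeneSets:
    """Apply the per-cancer significance, fold-change and expression filters.

    Up-in-high genes must satisfy q < q_max, logfc > logfc_up and the
    platform expression floor (minimum log-CPM for RNA-seq, minimum average
    log2 intensity for microarray); up-in-low genes symmetrically with
    logfc < logfc_down. Pure set semantics: row order never matters.
    """
    if de.empty:
        raise ValueError("empty differential-expression table")
    platform = Platform(platform)
    floor = config.de.floor_rnaseq if platform is Platform.RNASEQ else config.de.floor_microarray
    passes_floor = de["mean_expr"] >= floor if platform is Platform.RNASEQ else de["mean_expr"] > floor
    sig = de["q"] < config.de.q_max
    up = de.index[sig & (de["logfc"] > config.de.logfc_up) & passes_floor]
    down = de.index[sig & (de["logfc"] < config.de.logfc_down) & passes_floor]
    if len(up) == 0 and len(down) == 0:
        raise ValueError(
            "no genes pass the signature filters; consider a larger cohort or looser thresholds"
        )
    return SignatureGeneSets(tuple(sorted(up)), tuple(sorted(down)))
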