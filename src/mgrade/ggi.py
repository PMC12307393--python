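"""Unscaled gene-expression grade index (GGI) and survival-driven label generation.

The GGI for a sample is the sum of log2 expression over the genes up in high
grade minus the sum over the genes up in low grade — no rescaling against
pathologist labels. Training labels (mG1 vs mG3/mG4) come from a Cox-regression
threshold scan over the GGI distribution: candidate cutoffs at 1% percentile
steps, each scored by a univariate Cox fit of the binary split, the winner
picked by lowest p-value with concordance and |log HR| as tie-breakers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .datatypes import CancerConfig, ClinicalTable, ExpressionMatrix
from .diffexp import SignatureGeneSets

logger = logging.getLogger(__name__)

__all__ = ["GGILabeling", "compute_ggi", "scan_ggi_threshold", "assign_mgrade_labels"]


@dataclass
class GGILabeling:
    """Result of the threshold scan.

    ``labels`` holds "high"/"low" per sample with high defined by the strict
    rule ggi > threshold. ``scan_table`` records every evaluated candidate
    (cutoff, cox_p, hazard_ratio, concordance, n_high, n_low) for audit.
    """

    ggi: pd.Series
    threshold: float
    scan_table: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        expected = np.where(self.ggi > self.threshold, "high", "low")
        if not (self.labels.to_numpy() == expected).all():
            raise ValueError("labels inconsistent with ggi > threshold rule")
        if self.labels.nunique() < 2:
            raise ValueError("both label groups must be non-empty")


def compute_ggi(expr: ExpressionMatrix, sets: SignatureGeneSets) -> pd.Series:
    """Per-sample unscaled grade index.

    score = sum(expr over up_in_high) - sum(expr over up_in_low), on log2
    values; genes absent from the matrix and missing values are omitted from
    the sums (empty sums contribute 0).
    """
    up = [g for g in sets.up_in_high if g in expr.values.index]
    down = [g for g in sets.up_in_low if g in expr.values.index]
    if not up and not down:
        raise ValueError("no signature gene found in the expression matrix")
    up_sum = expr.values.loc[up].sum(axis=0, skipna=True) if up else 0.0
    down_sum = expr.values.loc[down].sum(axis=0, skipna=True) if down else 0.0
    score = up_sum - down_sum
    score.name = "ggi"
    return score


def _cox_binary(is_high: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Univariate Cox fit of a binary group indicator; (p, HR, concordance)."""
    df = pd.DataFrame({"group": is_high.astype(float), "time": time, "event": event})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return (
        float(cph.summary.loc["group", "p"]),
        float(np.exp(cph.params_.loc["group"])),
        float(cph.concordance_index_),
    )


def scan_ggi_threshold(
    ggi: pd.Series,
    clin: ClinicalTable,
    grid_step: float = 0.01,
    min_group_frac: float = 0.10,
) -> GGILabeling:
    """Scan percentile cutoffs of the GGI distribution for the best survival split.

    Candidates sit at the 1st-99th percentiles in ``grid_step`` increments;
    cutoffs leaving either group under ``min_group_frac`` of the cohort are
    discarded. Each remaining cutoff is scored by a univariate Cox fit of the
    binary high/low indicator; the selected cutoff minimizes the Wald p,
    ties broken by higher concordance, then higher |log HR|.
    """
    ggi = ggi.astype(float)
    clin_sub = clin.subset(ggi.index)
    time = clin_sub.os_time.to_numpy()
    event = clin_sub.os_event.to_numpy()
    if event.sum() < 1:
        raise ValueError("no events in the cohort; cannot scan thresholds")
    if np.nanstd(ggi.to_numpy()) == 0:
        raise ValueError("GGI is constant; no threshold can split the cohort")

    n = len(ggi)
    pct = np.arange(1.0, 99.0 + 1e-9, grid_step * 100.0)
    cutoffs = np.unique(np.percentile(ggi.to_numpy(), pct))

    rows = []
    for cut in cutoffs:
        is_high = ggi.to_numpy() > cut
        n_high = int(is_high.sum())
        n_low = n - n_high
        if min(n_high, n_low) < min_group_frac * n:
            continue
        try:
            p, hr, conc = _cox_binary(is_high, time, event)
        except (ConvergenceError, ValueError) as exc:  # pragma: no cover - rare
            logger.warning("Cox fit failed at cutoff %.4g: %s", cut, exc)
            continue
        rows.append((float(cut), p, hr, conc, n_high, n_low))
    if not rows:
        raise ValueError(
            "no candidate cutoff satisfies the minimum group-size fraction "
            f"({min_group_frac:.0%})"
        )
    scan = pd.DataFrame(
        rows, columns=["cutoff", "cox_p", "hazard_ratio", "concordance", "n_high", "n_low"]
    )
    order = scan.sort_values(
        by=["cox_p", "concordance", "hazard_ratio"],
        key=lambda col: col if col.name == "cox_p" else (
            -col if col.name == "concordance" else -np.abs(np.log(col))
        ),
        kind="mergesort",
    )
    best = order.iloc[0]
    threshold = float(best["cutoff"])
    labels = pd.Series(np.where(ggi > threshold, "high", "low"), index=ggi.index, name="risk_group")
    logger.info(
        "selected GGI threshold %.4g (p=%.3g, HR=%.3g, concordance=%.3f)",
        threshold, best["cox_p"], best["hazard_ratio"], best["concordance"],
    )
    return GGILabeling(ggi=ggi, threshold=threshold, scan_table=scan, labels=labels)


def assign_mgrade_labels(labeling: GGILabeling, config: CancerConfig | None = None,
                         high_name: str | None = None) -> pd.Series:
    """Render the risk split as molecular-grade strings.

    The low-risk group is mG1; the high-risk group is mG3 (mG4 for ccRCC,
    whose aggressive category is grade 4). Intermediate-grade and ungraded
    samples get labels like every other sample.
    """
    if high_name is None:
        high_name = config.high_label if config is not None else "mG3"
    low_name = config.low_label if config is not None else "mG1"
    out = labeling.labels.map({"high": high_name, "low": low_name})
    out.name = "mgrade"
    return out
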