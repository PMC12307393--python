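"""Survival evaluation of molecular vs histological grades.

Cox proportional-hazards fits (lifelines) with optional stage / lymph-node
covariates and cohort strata, Harrell's concordance, IPCW integrated Brier
score over a fixed follow-up window (scikit-survival), scaled-Schoenfeld
proportional-hazards checks, ROC AUC of predicted high-grade probability
against histological G1 vs G3/G4, and the mGrade-by-stage chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sklearn.metrics import roc_auc_score
from sksurv.metrics import integrated_brier_score as _sksurv_ibs
from sksurv.util import Surv

from .datatypes import ClinicalTable

__all__ = [
    "SurvivalFitReport",
    "cox_fit_groups",
    "concordance_index",
    "integrated_brier",
    "ph_assumption_check",
    "auc_vs_histology",
    "stage_association",
    "g2_split_report",
]


@dataclass
class SurvivalFitReport:
    hazard_ratio: float
    ci95: tuple[float, float]
    p: float
    concordance: float
    n: int
    events: int
    covariates: list[str] = field(default_factory=list)
    fitter: CoxPHFitter | None = None
    design: pd.DataFrame | None = None  # the frame the model was fit on

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.hazard_ratio <= hi):
            raise ValueError("95% CI must contain the hazard ratio")


def _design_frame(
    labels: pd.Series, clin: ClinicalTable, covariates: tuple[str, ...] | list[str]
) -> tuple[pd.DataFrame, list[str], bool]:
    clin = clin.subset(labels.index)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {groups}")
    if len(groups) > 2:
        raise ValueError("cox_fit_groups handles a binary group contrast")
    # contrast the high-risk-named group against the other; "m" prefixes sort
    # mG1 < mG3 < mG4, the generic {"high","low"} pair is special-cased
    high_name = "high" if set(groups) == {"high", "low"} else groups[-1]
    df = pd.DataFrame(
        {
            "time": clin.os_time,
            "event": clin.os_event,
            "group": (labels == high_name).astype(float),
        }
    )
    used = []
    stratify_cohort = False
    for cov in covariates:
        if cov == "cohort":
            # cohorts enter as Cox strata: each keeps its own baseline hazard
            df["cohort"] = clin.data["cohort"]
            stratify_cohort = True
            used.append("cohort(strata)")
            continue
        col = clin.data[cov]
        keep = col != "missing"
        dummies = pd.get_dummies(col[keep], prefix=cov, drop_first=True, dtype=float)
        df = df.join(dummies)
        df[dummies.columns] = df[dummies.columns].fillna(0.0)
        used.extend(dummies.columns)
    return df, used, stratify_cohort


def cox_fit_groups(
    labels: pd.Series,
    clin: ClinicalTable,
    covariates: tuple[str, ...] | list[str] = (),
) -> SurvivalFitReport:
    """Cox fit of a binary group contrast with optional covariates.

    ``covariates`` may include "stage" and "lymph_node_status" (entered as
    dummy covariates, "missing" levels dropped) and "cohort" (entered as a
    stratification variable). The reported hazard ratio contrasts the
    lexicographically later group label against the earlier one (e.g. mG3 vs
    mG1). Concordance is Harrell's C on the model's linear predictor.
    """
    if clin.subset(labels.index).os_event.sum() < 1:
        raise ValueError("no events; cannot fit a Cox model")
    df, used, strat = _design_frame(labels, clin, covariates)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event",
                    strata=["cohort"] if strat else None)
        except Exception as exc:
            raise RuntimeError(
                f"Cox fit failed ({exc}); check for complete separation or "
                "degenerate covariates"
            ) from exc
    s = cph.summary.loc["group"]
    return SurvivalFitReport(
        hazard_ratio=float(np.exp(s["coef"])),
        ci95=(float(np.exp(s["coef lower 95%"])), float(np.exp(s["coef upper 95%"]))),
        p=float(s["p"]),
        concordance=float(cph.concordance_index_),
        n=len(df),
        events=int(df["event"].sum()),
        covariates=used,
        fitter=cph,
        design=df,
    )


def concordance_index(risk_scores: pd.Series, clin: ClinicalTable) -> float:
    """Harrell's C of a risk score: higher risk should mean earlier events.

    Censoring-aware (pairs are usable only when the earlier time is an
    event); ties in risk count 0.5.
    """
    clin = clin.subset(risk_scores.index)
    # lifelines' c-index is defined for a *survival* prediction; negate risk
    c = _lifelines_cindex(
        clin.os_time.to_numpy(), -np.asarray(risk_scores, dtype=float), clin.os_event.to_numpy()
    )
    return float(c)


def _km_survival_matrix(
    labels: pd.Series, clin: ClinicalTable, times: np.ndarray
) -> np.ndarray:
    """Per-sample predicted survival curves from within-group Kaplan-Meier."""
    surv = np.empty((len(labels), len(times)))
    for grp in labels.unique():
        ids = labels.index[labels == grp]
        sub = clin.subset(ids)
        km = KaplanMeierFitter()
        km.fit(sub.os_time, sub.os_event)
        curve = km.survival_function_at_times(times).to_numpy()
        surv[np.asarray(labels == grp), :] = curve
    return surv


def integrated_brier(
    predictions: pd.Series | pd.DataFrame,
    clin: ClinicalTable,
    t_start: float = 100.0,
    t_end: float = 1700.0,
    n_grid: int = 100,
) -> float:
    """IPCW integrated Brier score over [t_start, t_end] (days).

    ``predictions`` is either a per-sample group label Series (predicted
    survival = the sample's within-group Kaplan-Meier curve) or a samples x
    times DataFrame of survival probabilities whose columns are times in
    days. Censoring weights come from the Kaplan-Meier of the censoring
    distribution; integration is trapezoidal on a uniform grid inside the
    window.
    """
    clin = clin.subset(predictions.index)
    tmax = clin.os_time.max()
    if t_end >= tmax:
        raise ValueError(
            f"window end {t_end} not covered by follow-up (max observed {tmax:.0f})"
        )
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    y = Surv.from_arrays(clin.os_event.astype(bool).to_numpy(), clin.os_time.to_numpy())
    if isinstance(predictions, pd.DataFrame):
        times = np.asarray(predictions.columns, dtype=float)
        keep = (times >= t_start) & (times <= t_end)
        times = times[keep]
        surv = predictions.to_numpy(dtype=float)[:, keep]
    else:
        times = np.linspace(t_start, t_end, n_grid)
        surv = _km_survival_matrix(predictions, clin, times)
    return float(_sksurv_ibs(y, y, surv, times))


def ph_assumption_check(report: SurvivalFitReport) -> pd.Series:
    """Scaled-Schoenfeld-residual test of proportional hazards, per variable."""
    if report.fitter is None or report.design is None:
        raise ValueError("report carries no fitted Cox model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = proportional_hazard_test(report.fitter, report.design, time_transform="rank")
    out = res.summary["p"].copy()
    out.index = [i[0] if isinstance(i, tuple) else i for i in res.summary.index]
    return out


def auc_vs_histology(probabilities: pd.Series, grades: pd.Series) -> float:
    """ROC AUC of the high-grade probability for histological G3/G4 vs G1.

    G2 and ungraded samples are excluded: the comparison is against the
    unambiguous histological extremes only.
    """
    grades = grades.reindex(probabilities.index)
    is_high = grades.isin(["G3", "G4"])
    is_low = grades == "G1"
    keep = is_high | is_low
    y = is_high[keep].astype(int)
    if y.nunique() < 2:
        raise ValueError("need both G1 and G3/G4 samples for the AUC")
    return float(roc_auc_score(y, probabilities[keep]))


def stage_association(labels: pd.Series, clin: ClinicalTable) -> tuple[float, float, pd.DataFrame]:
    """Chi-square test of the mGrade x clinical-stage contingency table.

    Returns (statistic, p, expected-counts table); the statistic is the
    uncorrected sum((O-E)^2/E). A warning is emitted when any expected count
    falls below 5.
    """
    clin = clin.subset(labels.index)
    stage = clin.data["stage"]
    keep = stage != "missing"
    table = pd.crosstab(labels[keep], stage[keep])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"degenerate contingency table with shape {table.shape}")
    chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    expected = pd.DataFrame(expected, index=table.index, columns=table.columns)
    if (expected.to_numpy() < 5).any():
        warnings.warn("expected count < 5 in the mGrade x stage table", stacklevel=2)
    return float(chi2), float(p), expected


def g2_split_report(
    mgrade_labels: pd.Series, clin: ClinicalTable, covariates=()
) -> SurvivalFitReport:
    """Survival contrast of mG1 vs mG3/mG4 within histological-G2 samples.

    This is the report mode for the intermediate-grade question: does the
    molecular split stratify the samples histology cannot?
    """
    clin_sub = clin.subset(mgrade_labels.index)
    g2_ids = clin_sub.data.index[clin_sub.grade == "G2"]
    if len(g2_ids) == 0:
        raise ValueError("no histological-G2 samples")
    return cox_fit_groups(mgrade_labels.loc[g2_ids], clin, covariates=covariates)
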