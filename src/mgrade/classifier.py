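"""Rank-transformed gradient-boosted-tree grade classifier.

The central idea: replace each sample's geneset expression values by their
within-sample ascending ranks (ties averaged, missing omitted). Ranks depend
only on the ordering of genes inside one sample, so any strictly monotone
per-batch distortion — and the composition of the surrounding cohort — leaves
the features, and therefore the prediction, bit-identical. This is what makes
the classifier a single-sample method.

On top of the rank features sits a LightGBM binary classifier tuned by
stratified cross-validated negative log-loss, and a recursive feature
elimination loop that repeatedly drops the two genes with the smallest mean
|SHAP| attribution until a floor size is reached; the geneset with the best
CV loss along the trace is kept. SHAP attributions come from LightGBM's
native TreeSHAP (``pred_contrib=True``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .datatypes import CancerConfig, ExpressionMatrix, GBMParams

logger = logging.getLogger(__name__)

__all__ = [
    "rank_transform",
    "rank_matrix",
    "cv_train",
    "ShapReport",
    "shap_importance",
    "EliminationStep",
    "EliminationTrace",
    "recursive_elimination",
    "select_best_geneset",
    "TrainedGradeModel",
    "train_final",
    "predict_single_sample",
    "predict_cohort",
    "save_model",
    "load_model",
    "default_param_grid",
]

#: Minimum fraction of the model geneset that must be measured in a sample
#: before prediction is attempted; too many missing genes distort the ranks.
MIN_PRESENT_FRACTION = 0.9

_LGBM_FIXED = dict(
    objective="binary",
    deterministic=True,
    force_row_wise=True,
    n_jobs=1,
    verbose=-1,
)


def rank_transform(values) -> np.ndarray:
    """Within-sample ascending ranks, average ranks for ties, missing omitted.

    ``values`` is a per-gene numeric vector for a single sample; output has
    the same length with NaN where the input was missing. The non-missing
    ranks are a permutation of 1..m (with tie-averaged values), independent
    of the input ordering of genes.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("rank_transform expects a 1-D per-sample vector")
    if np.isnan(arr).all():
        raise ValueError("all values missing; cannot rank")
    return stats.rankdata(arr, method="average", nan_policy="omit")


def rank_matrix(expr: ExpressionMatrix | pd.DataFrame, geneset) -> pd.DataFrame:
    """samples x genes rank-feature matrix over ``geneset``.

    Each row is produced by ranking that sample's geneset values in
    isolation, so the matrix for a cohort equals the stack of single-sample
    transformations.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    geneset = list(geneset)
    missing = [g for g in geneset if g not in values.index]
    sub = values.reindex(geneset).to_numpy(dtype=float)  # genes x samples
    out = np.full_like(sub, np.nan)
    for j in range(sub.shape[1]):
        col = sub[:, j]
        if np.isnan(col).all():
            raise ValueError(f"sample {values.columns[j]!r} has no measured geneset gene")
        out[:, j] = stats.rankdata(col, method="average", nan_policy="omit")
    if missing:
        logger.debug("rank_matrix: %d geneset genes absent from matrix", len(missing))
    return pd.DataFrame(out.T, index=values.columns, columns=geneset)


def default_param_grid(config: CancerConfig) -> list[GBMParams]:
    """Small grid centered on the per-cancer default hyperparameters."""
    grid = []
    for n_est in (100, 200, 500):
        for alpha in (0.0, 0.3):
            grid.append(dataclasses.replace(
                config.gbm, n_estimators=n_est, reg_alpha=alpha,
            ))
    return grid


def _encode_labels(labels: pd.Series, positive: str | None) -> tuple[np.ndarray, tuple[str, str]]:
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {classes}")
    if positive is None:
        positive = classes[-1]  # e.g. mG3 > mG1, "high" > ... lexicographic fallback
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not among labels {classes}")
    negative = [c for c in classes if c != positive][0]
    y = (labels == positive).astype(int).to_numpy()
    return y, (negative, positive)


def _fit_lgbm(X: pd.DataFrame, y: np.ndarray, params: GBMParams, seed: int) -> lgb.LGBMClassifier:
    model = lgb.LGBMClassifier(random_state=seed, **params.as_dict(), **_LGBM_FIXED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def cv_train(
    X: pd.DataFrame,
    labels: pd.Series,
    config: CancerConfig,
    param_grid: list[GBMParams] | None = None,
    seed: int = 0,
    positive: str | None = None,
) -> tuple[GBMParams, float, float]:
    """Stratified k-fold CV over a hyperparameter grid.

    Returns the candidate with the best (lowest) mean held-out negative
    log-loss together with that mean and its across-fold standard deviation.
    ``param_grid=None`` evaluates only the config defaults (grid disabled).
    """
    labels = labels.reindex(X.index)
    y, _ = _encode_labels(labels, positive)
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"each class needs >= cv_folds={config.cv_folds} samples, got {counts.tolist()}"
        )
    candidates = list(param_grid) if param_grid else [config.gbm]
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best: tuple[float, float, GBMParams] | None = None
    for params in candidates:
        losses = []
        for train_idx, test_idx in folds:
            model = _fit_lgbm(X.iloc[train_idx], y[train_idx], params, seed)
            proba = model.predict_proba(X.iloc[test_idx])[:, 1]
            losses.append(log_loss(y[test_idx], proba, labels=[0, 1]))
        mean_loss = float(np.mean(losses))
        sd_loss = float(np.std(losses, ddof=1))
        if best is None or (mean_loss, sd_loss) < (best[0], best[1]):
            best = (mean_loss, sd_loss, params)
    assert best is not None
    return best[2], best[0], best[1]


@dataclass
class ShapReport:
    """Per-feature SHAP summary: mean |attribution| plus the raw matrix."""

    importance: pd.Series          # per-gene mean |SHAP|, non-negative
    attributions: pd.DataFrame     # samples x genes raw attributions (log-odds)
    base_value: float              # expected raw score


def shap_importance(model: lgb.LGBMClassifier | lgb.Booster, X: pd.DataFrame) -> ShapReport:
    """TreeSHAP attributions of the fitted ensemble on ``X``.

    Importance is the mean over samples of the absolute Shapley additive
    attribution per feature. Attributions plus the base value sum exactly to
    the model's raw (log-odds) score for each sample.
    """
    booster = model.booster_ if isinstance(model, lgb.LGBMClassifier) else model
    feat = booster.feature_name()
    if list(X.columns) != feat:
        raise ValueError(f"feature mismatch: model expects {feat}, got {list(X.columns)}")
    contrib = booster.predict(X.to_numpy(dtype=float), pred_contrib=True)
    attributions = pd.DataFrame(contrib[:, :-1], index=X.index, columns=X.columns)
    base = float(contrib[0, -1])
    importance = attributions.abs().mean(axis=0)
    importance.name = "mean_abs_shap"
    return ShapReport(importance=importance, attributions=attributions, base_value=base)


@dataclass
class EliminationStep:
    geneset: tuple[str, ...]
    params: GBMParams
    mean_loss: float
    sd_loss: float
    importance: pd.Series


@dataclass
class EliminationTrace:
    steps: list[EliminationStep]

    def sizes(self) -> list[int]:
        return [len(s.geneset) for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.steps)),
                "n_genes": self.sizes(),
                "mean_cv_logloss": [s.mean_loss for s in self.steps],
                "sd_cv_logloss": [s.sd_loss for s in self.steps],
                "geneset": [",".join(s.geneset) for s in self.steps],
            }
        )


def recursive_elimination(
    expr: ExpressionMatrix,
    labels: pd.Series,
    start_geneset,
    config: CancerConfig,
    seed: int = 0,
    param_grid: list[GBMParams] | None = None,
    positive: str | None = None,
) -> EliminationTrace:
    """SHAP-guided two-at-a-time gene elimination down to ``config.elimination_stop``.

    Each step re-ranks the samples over the current geneset, tunes/fits the
    classifier by CV, computes mean |SHAP| importances on the full labeled
    set, and drops the two least important genes (one when two would
    overshoot the stop size; ties drop the lexicographically smallest gene ID
    first). The trace records every step including the initial geneset.
    """
    genes = list(start_geneset)
    stop = config.elimination_stop
    if len(genes) <= stop:
        logger.warning(
            "start geneset (%d) not larger than stop (%d); single-step trace", len(genes), stop
        )
    steps: list[EliminationStep] = []
    while True:
        X = rank_matrix(expr, genes)
        params, mean_loss, sd_loss = cv_train(
            X, labels, config, param_grid=param_grid, seed=seed, positive=positive
        )
        y, _ = _encode_labels(labels.reindex(X.index), positive)
        model = _fit_lgbm(X, y, params, seed)
        report = shap_importance(model, X)
        steps.append(EliminationStep(tuple(genes), params, mean_loss, sd_loss, report.importance))
        if len(genes) <= stop:
            break
        n_drop = min(2, len(genes) - stop)
        # least important first; ties broken toward the lexicographically
        # smallest gene ID so builds are deterministic
        order = sorted(genes, key=lambda gid: (report.importance[gid], gid))
        dropped = order[:n_drop]
        genes = [gid for gid in genes if gid not in dropped]
        logger.debug("eliminated %s -> %d genes remain", dropped, len(genes))
    return EliminationTrace(steps)


def select_best_geneset(trace: EliminationTrace) -> list[str]:
    """Geneset of the trace step with minimal mean CV log-loss.

    Ties break toward smaller loss sd, then toward the smaller geneset.
    """
    if not trace.steps:
        raise ValueError("empty elimination trace")
    best = min(trace.steps, key=lambda s: (s.mean_loss, s.sd_loss, len(s.geneset)))
    return list(best.geneset)


@dataclass
class TrainedGradeModel:
    """Final fitted classifier with its geneset and provenance."""

    geneset: list[str]
    booster: lgb.Booster
    params: GBMParams
    config: CancerConfig
    label_names: tuple[str, str]  # (low, high)
    trace: EliminationTrace | None = None


def train_final(
    expr: ExpressionMatrix,
    labels: pd.Series,
    geneset,
    config: CancerConfig,
    seed: int = 0,
    param_grid: list[GBMParams] | None = None,
    trace: EliminationTrace | None = None,
    positive: str | None = None,
) -> TrainedGradeModel:
    """Rank-transform over the final geneset, tune by CV, fit on all samples."""
    geneset = list(geneset)
    present = [g for g in geneset if g in expr.values.index]
    if not present:
        raise ValueError("geneset not resolvable in the expression matrix")
    X = rank_matrix(expr, geneset)
    params, mean_loss, sd_loss = cv_train(
        X, labels, config, param_grid=param_grid, seed=seed, positive=positive
    )
    y, names = _encode_labels(labels.reindex(X.index), positive)
    model = _fit_lgbm(X, y, params, seed)
    logger.info("final model: %d genes, CV logloss %.4f +- %.4f", len(geneset), mean_loss, sd_loss)
    return TrainedGradeModel(
        geneset=geneset,
        booster=model.booster_,
        params=params,
        config=config,
        label_names=names,
        trace=trace,
    )


def _predict_ranks(model: TrainedGradeModel, ranks: np.ndarray) -> float:
    proba = model.booster.predict(ranks.reshape(1, -1))
    return float(proba[0])


def predict_single_sample(
    model: TrainedGradeModel,
    sample: pd.Series,
    min_present_fraction: float = MIN_PRESENT_FRACTION,
) -> tuple[float, str]:
    """Classify one sample from its raw per-gene expression values.

    The sample's geneset values are rank-transformed in isolation — no
    cohort, no reference distribution — and fed to the ensemble. Returns the
    probability of the high molecular grade and the 0.5-thresholded label.
    """
    values = sample.reindex(model.geneset).to_numpy(dtype=float)
    missing = [g for g, v in zip(model.geneset, values) if not np.isfinite(v)]
    present_frac = 1.0 - len(missing) / len(model.geneset)
    if present_frac < min_present_fraction:
        raise ValueError(
            f"only {present_frac:.0%} of the model geneset is measured "
            f"(need >= {min_present_fraction:.0%}); missing: {missing}"
        )
    ranks = stats.rankdata(values, method="average", nan_policy="omit")
    prob = _predict_ranks(model, ranks)
    low, high = model.label_names
    return prob, (high if prob > 0.5 else low)


def predict_cohort(model: TrainedGradeModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample probabilities/labels; equals stacking single-sample calls."""
    X = rank_matrix(expr, model.geneset)
    proba = model.booster.predict(X.to_numpy(dtype=float))
    low, high = model.label_names
    return pd.DataFrame(
        {
            "mgrade_probability": proba,
            "mgrade_label": np.where(proba > 0.5, high, low),
        },
        index=X.index,
    )


def save_model(model: TrainedGradeModel, out_dir) -> None:
    """Serialize the model as plain-text artifacts in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "geneset.txt").write_text("\n".join(model.geneset) + "\n")
    meta = {
        "params": model.params.as_dict(),
        "label_names": list(model.label_names),
        "config": {
            "cancer_type": model.config.cancer_type,
            "elimination_stop": model.config.elimination_stop,
            "cv_folds": model.config.cv_folds,
            "test_fraction": model.config.test_fraction,
            "high_label": model.config.high_label,
            "low_label": model.config.low_label,
        },
    }
    (out / "model_meta.json").write_text(json.dumps(meta, indent=2))
    (out / "ensemble.txt").write_text(model.booster.model_to_string())
    if model.trace is not None:
        model.trace.to_frame().to_csv(out / "elimination_trace.tsv", sep="\t", index=False)


def load_model(model_dir) -> TrainedGradeModel:
    """Load a model saved by :func:`save_model`."""
    d = Path(model_dir)
    geneset = [g for g in (d / "geneset.txt").read_text().splitlines() if g]
    meta = json.loads((d / "model_meta.json").read_text())
    booster = lgb.Booster(model_str=(d / "ensemble.txt").read_text())
    cfg_meta = meta["config"]
    config = CancerConfig(
        cancer_type=cfg_meta["cancer_type"],
        gbm=GBMParams(**meta["params"]),
        elimination_stop=cfg_meta["elimination_stop"],
        cv_folds=cfg_meta["cv_folds"],
        test_fraction=cfg_meta["test_fraction"],
        high_label=cfg_meta["high_label"],
        low_label=cfg_meta["low_label"],
    )
    return TrainedGradeModel(
        geneset=geneset,
        booster=booster,
        params=GBMParams(**meta["params"]),
        config=config,
        label_names=tuple(meta["label_names"]),
    )
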