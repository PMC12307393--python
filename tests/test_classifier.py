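import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from mgrade import classifier, simulate
from mgrade.datatypes import ExpressionMatrix, GBMParams, config_for

from conftest import small_spec


def brute_rank(values):
    """Independent oracle: rank = (#smaller) + (#equal + 1)/2, missing omitted."""
    values = list(values)
    obs = [v for v in values if not math.isnan(v)]
    out = []
    for v in values:
        if math.isnan(v):
            out.append(float("nan"))
        else:
            less = sum(1 for u in obs if u < v)
            eq = sum(1 for u in obs if u == v)
            out.append(less + (eq + 1) / 2)
    return np.array(out)


@pytest.mark.parametrize(
    "values,expected",
    [
        ([5.2, 1.1, 3.3], [3, 1, 2]),
        ([2.0, 2.0, 7.0], [1.5, 1.5, 3]),
        ([4.0, float("nan"), 1.0], [2, float("nan"), 1]),
    ],
)
def test_rank_transform_examples(values, expected):
    got = classifier.rank_transform(values)
    np.testing.assert_array_equal(got, np.array(expected, dtype=float))


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    st.lists(
        st.one_of(
            st.integers(min_value=-5, max_value=5).map(float),  # force ties
            st.floats(-100, 100, allow_nan=False),
            st.just(float("nan")),
        ),
        min_size=1,
        max_size=30,
    )
)
def test_rank_transform_matches_brute_oracle(values):
    if all(math.isnan(v) for v in values):
        with pytest.raises(ValueError):
            classifier.rank_transform(values)
        return
    got = classifier.rank_transform(values)
    np.testing.assert_array_equal(got, brute_rank(values))
    obs = got[~np.isnan(got)]
    m = len(obs)
    assert obs.sum() == pytest.approx(m * (m + 1) / 2)  # tie-averaged permutation sum
    # rank conservation: value(A) > value(B) => rank(A) > rank(B)
    arr = np.asarray(values)
    fin = ~np.isnan(arr)
    va, ra = arr[fin], got[fin]
    order = np.argsort(va, kind="mergesort")
    assert (np.diff(ra[order]) >= 0).all()


def test_rank_transform_order_independent():
    rng = np.random.default_rng(0)
    v = rng.normal(size=20)
    perm = rng.permutation(20)
    assert (classifier.rank_transform(v)[perm] == classifier.rank_transform(v[perm])).all()


def test_rank_matrix_stacks_single_sample_transforms(default_cohort):
    genes = default_cohort.expr.gene_ids[:15]
    X = classifier.rank_matrix(default_cohort.expr, genes)
    for s in default_cohort.expr.sample_ids[:5]:
        single = classifier.rank_transform(default_cohort.expr.values.loc[genes, s])
        np.testing.assert_array_equal(X.loc[s].to_numpy(), single)


@pytest.fixture(scope="module")
def separable():
    """Planted signature with effect 3: classes barely overlap in rank space."""
    c = simulate.generate_cohort(
        small_spec(n_samples=200, n_genes=30, n_signal_up=5, n_signal_down=5,
                   effect_size=3.0, noise_sd=0.5, seed=4)
    )
    labels = c.latent_class.map({"high": "mG3", "low": "mG1"})
    X = classifier.rank_matrix(c.expr, c.expr.gene_ids)
    return c, X, labels


def _cv_auc(X, y, params, folds=5, seed=0):
    import lightgbm as lgb

    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    proba = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        m = lgb.LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params.as_dict())
        m.fit(X.iloc[tr], y[tr])
        proba[te] = m.predict_proba(X.iloc[te])[:, 1]
    return roc_auc_score(y, proba)


def test_cv_train_separable_case(separable):
    c, X, labels = separable
    cfg = config_for("custom")
    params, mean_loss, sd_loss = classifier.cv_train(X, labels, cfg, seed=1)
    assert mean_loss < 0.1
    y = (labels == "mG3").astype(int).to_numpy()
    assert _cv_auc(X, y, params, seed=1) > 0.99


def test_cv_train_permutation_null(separable):
    """Randomly permuted labels carry no signal: CV AUC hovers around 0.5."""
    c, X, labels = separable
    cfg = dataclasses.replace(
        config_for("custom"), gbm=GBMParams(n_estimators=50, reg_lambda=0.6)
    )
    rng = np.random.default_rng(7)
    y = (labels == "mG3").astype(int).to_numpy()
    in_band = 0
    n_perm = 50
    for _ in range(n_perm):
        aucs = _cv_auc(X, rng.permutation(y), cfg.gbm, seed=3)
        if 0.4 <= aucs <= 0.6:
            in_band += 1
    assert in_band >= 0.9 * n_perm


def test_cv_train_too_few_samples():
    X = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("wxyz"))
    labels = pd.Series(["mG3", "mG3", "mG1", "mG1"], index=list("abcd"))
    with pytest.raises(ValueError, match="cv_folds"):
        classifier.cv_train(X, labels, config_for("custom"))


def test_cv_train_single_class_rejected(separable):
    c, X, labels = separable
    with pytest.raises(ValueError, match="2 label classes"):
        classifier.cv_train(X, pd.Series("mG3", index=X.index), config_for("custom"))


@pytest.fixture(scope="module")
def fitted(separable):
    c, X, labels = separable
    y = (labels == "mG3").astype(int).to_numpy()
    model = classifier._fit_lgbm(X, y, config_for("custom").gbm, seed=0)
    return model, X


def test_shap_additivity(fitted):
    """Attributions + base value reproduce the raw (log-odds) score exactly."""
    model, X = fitted
    report = classifier.shap_importance(model, X)
    raw = model.booster_.predict(X.to_numpy(), raw_score=True)
    recon = report.attributions.sum(axis=1).to_numpy() + report.base_value
    np.testing.assert_allclose(recon, raw, atol=1e-6)
    assert (report.importance >= 0).all()


def test_shap_unused_feature_has_zero_importance(separable):
    c, X, labels = separable
    X2 = X.copy()
    X2["dead_feature"] = 1.0  # constant: no tree can split on it
    y = (labels == "mG3").astype(int).to_numpy()
    model = classifier._fit_lgbm(X2, y, config_for("custom").gbm, seed=0)
    report = classifier.shap_importance(model, X2)
    assert report.importance["dead_feature"] == 0.0


def test_shap_feature_mismatch_rejected(fitted):
    model, X = fitted
    bad = X.rename(columns={X.columns[0]: "wrong"})
    with pytest.raises(ValueError, match="feature mismatch"):
        classifier.shap_importance(model, bad)


def test_shap_finds_planted_informative_gene():
    """A single informative gene among pure noise tops the importances."""
    rng = np.random.default_rng(0)
    tops = 0
    n_seeds = 20
    for seed in range(n_seeds):
        c = simulate.generate_cohort(
            small_spec(n_samples=150, n_genes=20, n_signal_up=1, n_signal_down=0,
                       effect_size=3.0, noise_sd=0.5, seed=100 + seed)
        )
        X = classifier.rank_matrix(c.expr, c.expr.gene_ids)
        y = (c.latent_class == "high").astype(int).to_numpy()
        model = classifier._fit_lgbm(X, y, GBMParams(n_estimators=100), seed=seed)
        report = classifier.shap_importance(model, X)
        if report.importance.idxmax() == c.signal_up[0]:
            tops += 1
    assert tops >= 0.95 * n_seeds


@pytest.fixture(scope="module")
def elim_cohort():
    c = simulate.generate_cohort(
        small_spec(n_samples=200, n_genes=60, n_signal_up=15, n_signal_down=15,
                   effect_size=2.0, seed=6)
    )
    return c, c.latent_class.map({"high": "mG3", "low": "mG1"})


def test_elimination_sizes_two_at_a_time(elim_cohort):
    c, labels = elim_cohort
    cfg = dataclasses.replace(config_for("custom"), gbm=GBMParams(n_estimators=100))
    trace = classifier.recursive_elimination(
        c.expr, labels, c.expr.gene_ids[:30], cfg, seed=0
    )
    assert trace.sizes() == [30, 28, 26, 24, 22, 20]


def test_elimination_last_step_drops_one_gene_when_two_overshoot(elim_cohort):
    c, labels = elim_cohort
    cfg = dataclasses.replace(config_for("custom"), gbm=GBMParams(n_estimators=50))
    trace = classifier.recursive_elimination(
        c.expr, labels, c.expr.gene_ids[:21], cfg, seed=0
    )
    assert trace.sizes() == [21, 20]


def test_elimination_start_below_stop_single_step(elim_cohort, caplog):
    c, labels = elim_cohort
    cfg = dataclasses.replace(config_for("custom"), gbm=GBMParams(n_estimators=50))
    trace = classifier.recursive_elimination(
        c.expr, labels, c.expr.gene_ids[:12], cfg, seed=0
    )
    assert trace.sizes() == [12]


def _step(genes, loss, sd):
    return classifier.EliminationStep(
        tuple(genes), GBMParams(), loss, sd, pd.Series(1.0, index=list(genes))
    )


def test_select_best_geneset_argmin_and_ties():
    t = classifier.EliminationTrace(
        [_step("abcd", 0.40, 0.1), _step("abc", 0.35, 0.1), _step("ab", 0.38, 0.1)]
    )
    assert classifier.select_best_geneset(t) == list("abc")
    t2 = classifier.EliminationTrace([_step("abcd", 0.35, 0.05), _step("abc", 0.35, 0.02)])
    assert classifier.select_best_geneset(t2) == list("abc")
    t3 = classifier.EliminationTrace([_step("ab", 0.5, 0.1)])
    assert classifier.select_best_geneset(t3) == list("ab")
    t4 = classifier.EliminationTrace([_step("abcd", 0.35, 0.05), _step("abc", 0.35, 0.05)])
    assert classifier.select_best_geneset(t4) == list("abc")  # smaller set wins


def test_final_model_round_trips_through_disk(elim_cohort, tmp_path):
    c, labels = elim_cohort
    cfg = dataclasses.replace(config_for("custom"), gbm=GBMParams(n_estimators=50))
    model = classifier.train_final(c.expr, labels, c.expr.gene_ids[:20], cfg, seed=0)
    preds = classifier.predict_cohort(model, c.expr)
    classifier.save_model(model, tmp_path / "m")
    loaded = classifier.load_model(tmp_path / "m")
    assert loaded.geneset == model.geneset
    assert loaded.label_names == model.label_names
    preds2 = classifier.predict_cohort(loaded, c.expr)
    np.testing.assert_array_equal(
        preds["mgrade_probability"].to_numpy(), preds2["mgrade_probability"].to_numpy()
    )


def test_grid_disabled_keeps_published_hyperparameters(elim_cohort):
    """With the grid off, the per-cancer printed optima are used verbatim."""
    c, labels = elim_cohort
    brca = classifier.train_final(
        c.expr, labels, c.expr.gene_ids[:10], config_for("BRCA"), seed=0, param_grid=None
    )
    assert brca.params.reg_alpha == 0.3 and brca.params.n_estimators == 500
    assert brca.params.reg_lambda == 0.6 and brca.params.max_depth == -1
    assert config_for("ccRCC").gbm.n_estimators == 200
    assert config_for("LUAD").gbm == GBMParams(500, 0.0, 0.6, -1)


@pytest.fixture(scope="module")
def final_model(elim_cohort):
    c, labels = elim_cohort
    cfg = dataclasses.replace(config_for("custom"), gbm=GBMParams(n_estimators=100))
    genes = list(c.signal_up) + list(c.signal_down)
    return classifier.train_final(c.expr, labels, genes, cfg, seed=0), c


def test_single_sample_invariant_under_monotone_maps(final_model):
    model, c = final_model
    s = c.expr.sample_vector(c.expr.sample_ids[0])
    p1, l1 = classifier.predict_single_sample(model, s)
    p2, l2 = classifier.predict_single_sample(model, np.exp(s / 4.0))
    assert p1 == p2 and l1 == l2


def test_single_sample_equals_cohort_prediction(final_model):
    model, c = final_model
    cohort_preds = classifier.predict_cohort(model, c.expr)
    for s in c.expr.sample_ids[:10]:
        p, lab = classifier.predict_single_sample(model, c.expr.sample_vector(s))
        assert p == cohort_preds.loc[s, "mgrade_probability"]
        assert lab == cohort_preds.loc[s, "mgrade_label"]


def test_single_sample_too_many_missing_genes(final_model):
    model, c = final_model
    s = c.expr.sample_vector(c.expr.sample_ids[0]).copy()
    half = model.geneset[: len(model.geneset) // 2]
    s[half] = np.nan
    with pytest.raises(ValueError, match="missing"):
        classifier.predict_single_sample(model, s)


def test_heldout_latent_high_samples_score_high(trained, heldout_cohort):
    """At the canonical fixture, nearly every held-out latent-high sample
    crosses the 0.5 probability cutoff."""
    preds = classifier.predict_cohort(trained.model, heldout_cohort.expr)
    hi = preds.loc[(heldout_cohort.latent_class == "high").to_numpy(), "mgrade_probability"]
    assert (hi > 0.5).mean() >= 0.9
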