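import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from cardiovae.analysis import (
    AnalysisError,
    classify_latent,
    embed_tsne,
    kkt_residual,
    lasso_associations,
    lasso_coordinate_descent,
    pca_contributions,
    pca_contributions_by_group,
)


def _separable(rng, n_per=12, k=4, groups=("A", "B", "C")):
    rows, labels = [], []
    for i, g in enumerate(groups):
        centre = np.zeros(k)
        centre[i % k] = 6.0
        rows.append(centre + rng.normal(scale=0.3, size=(n_per, k)))
        labels += [g] * n_per
    feats = pd.DataFrame(np.vstack(rows),
                         columns=[f"z{j}" for j in range(k)])
    return feats, pd.Series(labels)


def test_classifier_solves_separable_problem(rng):
    feats, labels = _separable(rng)
    rep = classify_latent(feats, labels, n_trees=50, n_folds=4, seed=0)
    assert rep.min_metric == 1.0
    assert rep.overall_accuracy == 1.0
    assert list(rep.metrics.index) == ["A", "B", "C"]
    assert list(rep.metrics.columns) == ["accuracy", "precision",
                                         "recall", "f1"]


def test_classifier_is_column_order_invariant(rng):
    feats, labels = _separable(rng)
    a = classify_latent(feats, labels, n_trees=30, n_folds=3, seed=1)
    b = classify_latent(feats[feats.columns[::-1]], labels,
                        n_trees=30, n_folds=3, seed=1)
    assert a.metrics.equals(b.metrics)


def test_classifier_rejects_tiny_groups(rng):
    feats, labels = _separable(rng, n_per=3)
    with pytest.raises(AnalysisError, match="fewer samples than folds"):
        classify_latent(feats, labels, n_folds=5)


# ---------------------------------------------------------------------------
# t-SNE


def test_tsne_shape_and_determinism(rng):
    feats, labels = _separable(rng, n_per=15)
    with pytest.warns(UserWarning, match="perplexity"):
        a = embed_tsne(feats, seed=3)
        b = embed_tsne(feats, seed=3)
    assert a.coordinates.shape == (45, 2)
    assert list(a.coordinates.columns) == ["tsne1", "tsne2"]
    assert np.array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())


def test_tsne_separates_well_separated_groups(rng):
    feats, labels = _separable(rng, n_per=15)
    with pytest.warns(UserWarning, match="perplexity"):
        emb = embed_tsne(feats, seed=0)
    c = emb.coordinates.to_numpy()
    centroids = np.array([c[labels.to_numpy() == g].mean(axis=0)
                          for g in ("A", "B", "C")])
    spread = max(np.std(c[labels.to_numpy() == g], axis=0).mean()
                 for g in ("A", "B", "C"))
    gaps = [np.linalg.norm(centroids[i] - centroids[j])
            for i in range(3) for j in range(i + 1, 3)]
    assert min(gaps) > 3 * spread


def test_tsne_requires_five_samples(rng):
    feats = pd.DataFrame(rng.normal(size=(4, 3)))
    with pytest.raises(AnalysisError):
        embed_tsne(feats)


# ---------------------------------------------------------------------------
# LASSO


def _lasso_problem(rng, n=120, p=12):
    x = rng.normal(size=(n, p))
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    beta_true = np.zeros(p)
    beta_true[:3] = (1.2, -0.9, 0.7)
    r = 0.5 + x @ beta_true + 0.05 * rng.normal(size=n)
    return x, r


def test_lasso_matches_sklearn(rng):
    x, r = _lasso_problem(rng)
    beta, b0 = lasso_coordinate_descent(x, r, lam=0.05)
    ref = Lasso(alpha=0.05, fit_intercept=True, tol=1e-12,
                max_iter=100_000).fit(x, r)
    assert np.abs(beta - ref.coef_).max() < 1e-6
    assert b0 == pytest.approx(ref.intercept_, abs=1e-8)


def test_lasso_satisfies_kkt(rng):
    x, r = _lasso_problem(rng)
    beta, b0 = lasso_coordinate_descent(x, r, lam=0.05)
    assert kkt_residual(x, r, beta, b0, 0.05) < 1e-6


def test_lasso_high_penalty_zeroes_everything(rng):
    x, r = _lasso_problem(rng)
    beta, b0 = lasso_coordinate_descent(x, r, lam=1e3)
    assert np.all(beta == 0.0)
    assert b0 == pytest.approx(r.mean())


def test_lasso_associations_requires_standardized(rng):
    feats = pd.DataFrame(rng.normal(loc=5.0, size=(30, 4)))
    labels = pd.Series(["A"] * 15 + ["B"] * 15)
    with pytest.raises(AnalysisError, match="standardized"):
        lasso_associations(feats, labels)


def test_lasso_associations_shape(rng):
    x = rng.normal(size=(40, 5))
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    feats = pd.DataFrame(x, columns=[f"f{i}" for i in range(5)])
    labels = pd.Series(["A", "B", "C", "D"] * 10)
    assoc = lasso_associations(feats, labels, regularization=0.01)
    assert assoc.coefficients.shape == (4, 5)
    assert list(assoc.coefficients.index) == ["A", "B", "C", "D"]


# ---------------------------------------------------------------------------
# PCA contributions


def test_pca_contributions_find_dominant_feature(rng):
    n = 50
    base = rng.normal(size=n)
    feats = pd.DataFrame({
        "big": 10.0 * base + 0.1 * rng.normal(size=n),
        "small1": 0.2 * rng.normal(size=n),
        "small2": 0.2 * rng.normal(size=n),
    })
    ranking = pca_contributions(feats, top_n=2)
    assert ranking.top[0] == "big"
    assert ranking.scores.sum() == pytest.approx(1.0)
    assert (ranking.scores >= 0).all()


def test_pca_contributions_validation(rng):
    with pytest.raises(AnalysisError):
        pca_contributions(pd.DataFrame(rng.normal(size=(2, 3))))
    const = pd.DataFrame(np.ones((10, 3)))
    with pytest.raises(AnalysisError, match="constant"):
        pca_contributions(const)


def test_pca_contributions_by_group(rng):
    feats, labels = _separable(rng, n_per=10)
    labels.index = feats.index
    out = pca_contributions_by_group(feats, labels, top_n=2)
    assert set(out) == {"A", "B", "C"}
    for cr in out.values():
        assert len(cr.top) == 2
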