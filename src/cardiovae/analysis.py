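"""Downstream analysis of latent features and standardized omics features.

Four capabilities: random-forest classification of exercise condition
from latent coordinates (scored per group, one-vs-rest, from pooled
out-of-fold predictions), 2-D t-SNE embedding, sparse LASSO association
of each condition with the standardized metabolite/gene features (one
L1-penalised model per condition, solved by coordinate descent with
soft-thresholding), and a PCA-based feature-contribution ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold, cross_val_predict

METRICS = ("accuracy", "precision", "recall", "f1")


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# random-forest classification


@dataclass
class ClassificationReport:
    """Per-group one-vs-rest metrics from pooled out-of-fold predictions."""

    metrics: pd.DataFrame  # index: group, columns: METRICS
    cv_scheme: str
    seed: int
    overall_accuracy: float = float("nan")  # plain multiclass accuracy

    @property
    def min_metric(self) -> float:
        return float(self.metrics.min().min())


def classify_latent(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_trees: int = 500,
    n_folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified K-fold random-forest classification of the condition.

    Feature columns are sorted by name before fitting so the result does
    not depend on column order.  Each group is scored one-vs-rest on the
    pooled out-of-fold predictions.
    """
    y = np.asarray(labels).astype(str)
    x = features[sorted(features.columns)].to_numpy(np.float64)
    counts = pd.Series(y).value_counts()
    if (counts < n_folds).any():
        small = list(counts.index[counts < n_folds])
        raise AnalysisError(
            f"group(s) {small} have fewer samples than folds ({n_folds}); "
            "use more samples per group or fewer folds"
        )
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(rf, x, y, cv=cv)

    rows = []
    for g in sorted(set(y)):
        tp = np.sum((pred == g) & (y == g))
        fp = np.sum((pred == g) & (y != g))
        fn = np.sum((pred != g) & (y == g))
        tn = np.sum((pred != g) & (y != g))
        acc = (tp + tn) / y.size
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        rows.append((g, acc, prec, rec, f1))
    metrics = pd.DataFrame(
        rows, columns=["group", *METRICS]
    ).set_index("group")
    return ClassificationReport(
        metrics=metrics,
        cv_scheme=f"stratified {n_folds}-fold, {n_trees} trees",
        seed=seed,
        overall_accuracy=float(np.mean(pred == y)),
    )


# ---------------------------------------------------------------------------
# t-SNE embedding


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # n x 2, columns tsne1/tsne2
    method: str
    perplexity: float
    iterations: int
    overlay: pd.Series | None = None  # e.g. lactate concentration


def embed_tsne(
    features: pd.DataFrame,
    perplexity: float = 30.0,
    iterations: int = 1000,
    seed: int = 0,
    overlay: pd.Series | None = None,
) -> EmbeddingResult:
    """2-D t-SNE of the latent features; deterministic for a fixed seed.

    If n <= 3 * perplexity the perplexity is lowered (with a warning) to
    keep the neighbourhood size valid for small studies.
    """
    n = features.shape[0]
    if n < 5:
        raise AnalysisError("t-SNE requires at least 5 samples")
    eff = perplexity
    if n <= 3 * perplexity:
        eff = max(5.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for n={n}; lowered to {eff}",
            stacklevel=2,
        )
    ts = TSNE(
        n_components=2, perplexity=eff, max_iter=iterations,
        random_state=seed, init="pca", method="exact",
    )
    coords = ts.fit_transform(features.to_numpy(np.float64))
    coords = pd.DataFrame(coords, index=features.index, columns=["tsne1", "tsne2"])
    if overlay is not None:
        overlay = overlay.loc[features.index]
    return EmbeddingResult(
        coordinates=coords, method="tsne", perplexity=eff,
        iterations=iterations, overlay=overlay,
    )


# ---------------------------------------------------------------------------
# LASSO condition-feature associations (coordinate descent)


@dataclass
class AssociationMatrix:
    """L1-penalised regression coefficients, one row per condition."""

    coefficients: pd.DataFrame  # condition x feature
    intercepts: pd.Series
    regularization: float


def _soft_threshold(rho: float, lam: float) -> float:
    if rho > lam:
        return rho - lam
    if rho < -lam:
        return rho + lam
    return 0.0


def lasso_coordinate_descent(
    x: np.ndarray,
    r: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Minimise (1/2n)||r - b0 - X b||^2 + lam * ||b||_1.

    Predictors are assumed centred, so the intercept is fixed at mean(r)
    and each coordinate update is a closed-form soft-thresholding step.
    Iterates until the largest coefficient change falls below ``tol``.
    """
    n, p = x.shape
    b0 = float(r.mean())
    resid = r - b0
    beta = np.zeros(p)
    col_ss = (x * x).sum(axis=0) / n
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if col_ss[j] == 0:
                continue
            rho = (x[:, j] @ resid) / n + col_ss[j] * beta[j]
            new = _soft_threshold(rho, lam) / col_ss[j]
            delta = new - beta[j]
            if delta != 0.0:
                resid -= x[:, j] * delta
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return beta, b0


def kkt_residual(
    x: np.ndarray, r: np.ndarray, beta: np.ndarray, b0: float, lam: float
) -> float:
    """Maximum violation of the LASSO stationarity conditions."""
    n = x.shape[0]
    grad = -(x.T @ (r - b0 - x @ beta)) / n
    active = beta != 0
    viol = np.zeros_like(beta)
    viol[active] = np.abs(grad[active] + lam * np.sign(beta[active]))
    viol[~active] = np.maximum(np.abs(grad[~active]) - lam, 0.0)
    return float(viol.max(initial=0.0))


def lasso_associations(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    regularization: float = 0.01,
    tol: float = 1e-8,
) -> AssociationMatrix:
    """One sparse one-vs-rest model per condition on standardized features.

    The condition indicator is regressed on the features under an L1
    penalty; the coefficient pattern shows which metabolites and genes
    move with each exercise condition and in which direction.
    Features must arrive standardized (the penalty is not scale
    invariant).
    """
    if regularization < 0:
        raise AnalysisError("regularization must be >= 0")
    x = features.to_numpy(np.float64)
    col_means = x.mean(axis=0)
    col_sds = x.std(axis=0, ddof=1)
    if np.abs(col_means).max() > 1e-6 or np.abs(col_sds - 1).max() > 1e-2:
        raise AnalysisError(
            "features must be standardized (mean 0, sd 1) before LASSO; "
            "the L1 penalty is not scale invariant"
        )
    y = np.asarray(labels).astype(str)
    conditions = sorted(set(y))
    coefs, intercepts = {}, {}
    for g in conditions:
        r = (y == g).astype(np.float64)
        beta, b0 = lasso_coordinate_descent(x, r, regularization, tol=tol)
        coefs[g] = beta
        intercepts[g] = b0
    coef = pd.DataFrame(coefs, index=features.columns).T
    coef.index.name = "condition"
    return AssociationMatrix(
        coefficients=coef,
        intercepts=pd.Series(intercepts, name="intercept"),
        regularization=regularization,
    )


# ---------------------------------------------------------------------------
# PCA feature contributions


@dataclass
class ContributionRanking:
    """Variance-weighted squared-loading contribution per feature."""

    scores: pd.Series  # >= 0, sums to 1
    top: list[str]
    n_components: int


def pca_contributions(features: pd.DataFrame, top_n: int = 10) -> ContributionRanking:
    """Rank features by their share of the retained principal variance.

    Contribution of feature j = sum over retained components c of
    (squared loading of j on c) * (explained-variance ratio of c),
    normalised to sum to 1.  Components are retained until they cover at
    least 90% of the variance.
    """
    if features.shape[0] <= 2:
        raise AnalysisError("PCA contributions require n > 2")
    x = features.to_numpy(np.float64)
    x = x - x.mean(axis=0)
    if not (x.std(axis=0) > 0).any():
        raise AnalysisError("constant feature matrix has no principal directions")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    evr = var / var.sum()
    n_keep = int(np.searchsorted(np.cumsum(evr), 0.90) + 1)
    loadings = vt[:n_keep]  # components x features, rows unit norm
    contrib = (loadings**2 * evr[:n_keep, None]).sum(axis=0)
    contrib = contrib / contrib.sum()
    scores = pd.Series(contrib, index=features.columns, name="contribution")
    top = list(scores.sort_values(ascending=False).index[:top_n])
    return ContributionRanking(scores=scores, top=top, n_components=n_keep)


def pca_contributions_by_group(
    features: pd.DataFrame,
    labels: pd.Series,
    top_n: int = 10,
) -> dict[str, ContributionRanking]:
    """Per-condition contribution rankings (one PCA per group subset)."""
    labels = labels.loc[features.index]
    return {
        g: pca_contributions(features.loc[labels == g], top_n)
        for g in sorted(set(labels))
    }
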