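"""Preprocessing of paired metabolite / expression matrices.

The chain applied before model fitting is, in order:

1. natural-log transform of metabolite concentrations (pseudocount 1),
   z-scoring of gene expression — each modality gets the transform suited
   to its distribution;
2. parametric empirical-Bayes batch correction (ComBat) with the
   biological condition as a preserved covariate, applied per modality;
3. PCA + hierarchical-clustering outlier flagging;
4. per-feature min–max rescaling to [0, 1], the range of the decoder's
   sigmoid output layer.

Every transform stores the parameters needed to invert it, so values can
be mapped back to the corrected raw scale exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind

from .simulate import OmicsDataset

MET_PREFIX = "met:"
GENE_PREFIX = "gene:"


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary transforms


def log_transform(x: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise ln(x + pseudocount); concentrations must be >= 0."""
    if pseudocount <= 0:
        raise PreprocessError("pseudocount must be > 0")
    if (x.values < 0).any():
        raise PreprocessError("negative concentrations are not allowed")
    return np.log(x + pseudocount)


def inverse_log_transform(v: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.exp(v) - pseudocount


def zscore(y: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Per-gene standardisation to mean 0, sd 1 (ddof=1).

    Returns (standardised matrix, means, sds, dropped) where ``dropped``
    lists constant genes removed with a warning.
    """
    means = y.mean(axis=0)
    sds = y.std(axis=0, ddof=1)
    dropped = list(y.columns[(sds == 0) | sds.isna()])
    if dropped:
        warnings.warn(
            f"dropping constant gene(s) with zero variance: {dropped}",
            stacklevel=2,
        )
    keep = [c for c in y.columns if c not in dropped]
    z = (y[keep] - means[keep]) / sds[keep]
    return z, means[keep], sds[keep], dropped


# ---------------------------------------------------------------------------
# ComBat batch correction: parametric empirical-Bayes location/scale model


def _check_combat_design(batch: pd.Series, covariate: pd.Series | None) -> None:
    counts = batch.value_counts()
    singletons = list(counts.index[counts < 2])
    if singletons:
        raise PreprocessError(
            f"batch(es) with fewer than 2 samples: {singletons}"
        )
    if covariate is not None and batch.nunique() > 1:
        bd = pd.get_dummies(batch, drop_first=True, dtype=float)
        gd = pd.get_dummies(covariate, drop_first=True, dtype=float)
        design = np.column_stack([np.ones(len(batch)), bd.to_numpy(), gd.to_numpy()])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise PreprocessError(
                "batch and covariate are confounded (design matrix not full "
                f"rank); aliased columns among batches {list(bd.columns)} and "
                f"groups {list(gd.columns)}"
            )


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def combat_correct(
    v: pd.DataFrame,
    batch: pd.Series,
    covariate: pd.Series | None = None,
    max_iter: int = 100,
    conv: float = 1e-4,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch correction.

    Features are standardised against the covariate-adjusted grand model,
    per-batch additive (gamma) and multiplicative (delta^2) effects are
    estimated, shrunk toward their batch-level priors (normal for gamma,
    inverse-gamma for delta^2) by the standard EB iteration, and removed;
    covariate (biological) effects are preserved.  With a single batch
    the input is returned unchanged.
    """
    batch = batch.loc[v.index].astype(str)
    cov = None if covariate is None else covariate.loc[v.index].astype(str)
    _check_combat_design(batch, cov)
    if batch.nunique() < 2:
        return v.copy()

    y = v.to_numpy(np.float64)
    n, p = y.shape
    batches = sorted(batch.unique())
    bmat = pd.get_dummies(batch, dtype=float)[batches].to_numpy()
    n_b = bmat.sum(axis=0)
    if cov is not None:
        cmat = pd.get_dummies(cov, drop_first=True, dtype=float).to_numpy()
        design = np.column_stack([bmat, cmat])
    else:
        cmat = np.zeros((n, 0))
        design = bmat

    # per-feature OLS of the full batch+covariate model
    beta_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
    grand_mean = (n_b / n) @ beta_hat[: len(batches)]
    stand_mean = grand_mean[None, :] + cmat @ beta_hat[len(batches):]
    resid = y - design @ beta_hat
    var_pooled = (resid**2).sum(axis=0) / n
    var_pooled = np.where(var_pooled == 0, 1e-12, var_pooled)
    z = (y - stand_mean) / np.sqrt(var_pooled)

    z_adj = np.empty_like(z)
    for bi, b in enumerate(batches):
        rows = (batch == b).to_numpy()
        zb = z[rows]
        gamma_hat = zb.mean(axis=0)
        delta_hat = zb.var(axis=0, ddof=1)
        g_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        a_pr, b_pr = _aprior(delta_hat), _bprior(delta_hat)
        nb = rows.sum()
        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        for _ in range(max_iter):
            g_new = (nb * tau2 * gamma_hat + delta_star * g_bar) / (
                nb * tau2 + delta_star
            )
            ss = ((zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (b_pr + 0.5 * ss) / (nb / 2.0 + a_pr - 1.0)
            change = max(
                np.abs(g_new - gamma_star).max(initial=0.0),
                np.abs(d_new - delta_star).max(initial=0.0),
            )
            gamma_star, delta_star = g_new, d_new
            if change < conv:
                break
        z_adj[rows] = (zb - gamma_star[None, :]) / np.sqrt(delta_star)[None, :]

    corrected = z_adj * np.sqrt(var_pooled)[None, :] + stand_mean
    return pd.DataFrame(corrected, index=v.index, columns=v.columns)


# ---------------------------------------------------------------------------
# outlier detection


def detect_outliers(
    v: pd.DataFrame,
    robust_z_threshold: float = 3.0,
    return_details: bool = False,
) -> pd.Series | pd.DataFrame:
    """Flag outlying samples from PC scores and hierarchical clustering.

    A sample is flagged if its score on either of the first two principal
    components lies more than ``robust_z_threshold`` robust standard
    deviations (MAD-scaled) from the component median, or if it is the
    singleton of a 2-cluster average-linkage cut whose merge height
    exceeds 3x the median merge height.  With ``return_details`` the two
    rules are reported separately (columns pc_flag / cluster_flag).
    """
    n = v.shape[0]
    if n < 4:
        raise PreprocessError("outlier detection requires at least 4 samples")
    mat = v.to_numpy(np.float64)
    sd = mat.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    std = (mat - mat.mean(axis=0)) / sd

    # scores on the first two PCs
    u, s, _ = np.linalg.svd(std - std.mean(axis=0), full_matrices=False)
    scores = u[:, :2] * s[:2]
    pc_flags = np.zeros(n, dtype=bool)
    for j in range(min(2, scores.shape[1])):
        col = scores[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        scale = 1.4826 * mad if mad > 0 else col.std(ddof=1)
        if scale > 0:
            pc_flags |= np.abs(col - med) > robust_z_threshold * scale

    # singleton branch in a 2-cluster average-linkage cut
    cluster_flags = np.zeros(n, dtype=bool)
    z = linkage(std, method="average", metric="euclidean")
    labels = fcluster(z, t=2, criterion="maxclust")
    sizes = pd.Series(labels).value_counts()
    if (sizes == 1).any() and z[-1, 2] > 3.0 * np.median(z[:, 2]):
        singleton_label = sizes.index[sizes == 1][0]
        cluster_flags |= labels == singleton_label

    flags = pc_flags | cluster_flags
    if return_details:
        return pd.DataFrame(
            {"outlier": flags, "pc_flag": pc_flags, "cluster_flag": cluster_flags},
            index=v.index,
        )
    return pd.Series(flags, index=v.index, name="outlier")


# ---------------------------------------------------------------------------
# volcano-style differential-expression gene selection


@dataclass
class DESelection:
    """Per-gene differential-expression summary vs. the reference group."""

    table: pd.DataFrame  # columns: log2fc, p_value, neg_log10_p, contrast
    selected: list[str]  # top-N gene names, ranked by minimum p


def select_top_genes(
    y: pd.DataFrame,
    group: pd.Series,
    reference: str = "A",
    n: int = 20,
) -> DESelection:
    """Rank genes by the strongest contrast against the reference group.

    For every gene and every non-reference group: log2 fold change of
    group means and a Welch two-sample t-test on log2(TPM+1).  A gene's
    score is its minimum p across contrasts; the fold change reported is
    the one from that best contrast.  The top ``n`` genes are selected.
    """
    group = group.loc[y.index]
    if reference not in set(group):
        raise PreprocessError(f"reference group {reference!r} not present")
    if n > y.shape[1]:
        raise PreprocessError("cannot select more genes than the panel holds")
    counts = group.value_counts()
    small = list(counts.index[counts < 2])
    if small:
        raise PreprocessError(f"group(s) with fewer than 2 samples: {small}")

    logy = np.log2(y + 1.0)
    ref_rows = group == reference
    records = []
    for gene in y.columns:
        best_p, best_lfc, best_c = 1.0, 0.0, None
        for g in sorted(set(group) - {reference}):
            rows = group == g
            mean_g = y.loc[rows, gene].mean()
            mean_r = y.loc[ref_rows, gene].mean()
            lfc = float(np.log2(mean_g / mean_r)) if mean_r > 0 and mean_g > 0 else 0.0
            t = ttest_ind(logy.loc[rows, gene], logy.loc[ref_rows, gene],
                          equal_var=False)
            p = float(np.clip(t.pvalue, np.finfo(float).tiny, 1.0))
            if best_c is None or p < best_p:
                best_p, best_lfc, best_c = p, lfc, g
        records.append((gene, best_lfc, best_p, -np.log10(best_p), best_c))
    table = pd.DataFrame(
        records, columns=["gene", "log2fc", "p_value", "neg_log10_p", "contrast"]
    ).set_index("gene")
    selected = list(table.sort_values("p_value").index[:n])
    return DESelection(table=table, selected=selected)


# ---------------------------------------------------------------------------
# full preprocessing chain


@dataclass
class ScalingParams:
    """Everything needed to invert the preprocessing transforms."""

    pseudocount: float
    gene_means: pd.Series
    gene_sds: pd.Series
    dropped_genes: list[str]
    feature_min: pd.Series  # over the concatenated, corrected matrix
    feature_max: pd.Series

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pseudocount": self.pseudocount,
            "gene_means": self.gene_means.to_dict(),
            "gene_sds": self.gene_sds.to_dict(),
            "dropped_genes": self.dropped_genes,
            "feature_min": self.feature_min.to_dict(),
            "feature_max": self.feature_max.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingParams":
        d = json.loads(Path(path).read_text())
        return cls(
            pseudocount=d["pseudocount"],
            gene_means=pd.Series(d["gene_means"]),
            gene_sds=pd.Series(d["gene_sds"]),
            dropped_genes=d["dropped_genes"],
            feature_min=pd.Series(d["feature_min"]),
            feature_max=pd.Series(d["feature_max"]),
        )


@dataclass
class PreprocessedData:
    """Transformed, corrected, [0,1]-rescaled matrices ready for the VAE."""

    x_t: pd.DataFrame
    y_t: pd.DataFrame
    scaling: ScalingParams
    outlier_flags: pd.Series
    group: pd.Series
    batch: pd.Series

    @property
    def n_metabolites(self) -> int:
        return self.x_t.shape[1]

    @property
    def n_genes(self) -> int:
        return self.y_t.shape[1]

    def matrix(self, include_outliers: bool = False) -> pd.DataFrame:
        """Concatenated feature matrix with modality-prefixed columns."""
        x = self.x_t.add_prefix(MET_PREFIX)
        y = self.y_t.add_prefix(GENE_PREFIX)
        m = pd.concat([x, y], axis=1)
        if not include_outliers:
            m = m.loc[~self.outlier_flags]
        return m

    def groups(self, include_outliers: bool = False) -> pd.Series:
        g = self.group
        return g if include_outliers else g.loc[~self.outlier_flags]

    def inverse_transform(
        self, x01: pd.DataFrame, y01: pd.DataFrame
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Map [0,1]-scale blocks back to the corrected raw scale."""
        s = self.scaling
        mn_x = s.feature_min[self.x_t.columns]
        mx_x = s.feature_max[self.x_t.columns]
        logx = x01 * (mx_x - mn_x) + mn_x
        x = np.exp(logx) - s.pseudocount
        mn_y = s.feature_min[self.y_t.columns]
        mx_y = s.feature_max[self.y_t.columns]
        zy = y01 * (mx_y - mn_y) + mn_y
        y = zy * s.gene_sds[self.y_t.columns] + s.gene_means[self.y_t.columns]
        return x, y


def _minmax(v: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    mn, mx = v.min(axis=0), v.max(axis=0)
    rng = mx - mn
    degenerate = rng == 0
    rng = rng.mask(degenerate, 1.0)
    out = (v - mn) / rng
    out.loc[:, degenerate] = 0.5
    return out, mn, mx


def preprocess(
    data: OmicsDataset,
    pseudocount: float = 1.0,
    outlier_threshold: float = 3.0,
    flag_outliers: bool = True,
) -> PreprocessedData:
    """Run the full chain: transform, batch-correct, flag outliers, rescale."""
    x_log = log_transform(data.x, pseudocount)
    y_z, gmeans, gsds, dropped = zscore(data.y)

    if data.batch.nunique() > 1:
        x_log = combat_correct(x_log, data.batch, data.group)
        y_z = combat_correct(y_z, data.batch, data.group)

    combined = pd.concat(
        [x_log.add_prefix(MET_PREFIX), y_z.add_prefix(GENE_PREFIX)], axis=1
    )
    if flag_outliers and data.n_samples >= 4:
        # detect on group-centred residuals so well-separated conditions
        # are not themselves mistaken for outlying samples
        centred = combined - combined.groupby(data.group).transform("mean")
        flags = detect_outliers(centred, robust_z_threshold=outlier_threshold)
    else:
        flags = pd.Series(False, index=data.sample_ids, name="outlier")

    x01, mnx, mxx = _minmax(x_log)
    y01, mny, mxy = _minmax(y_z)
    scaling = ScalingParams(
        pseudocount=pseudocount,
        gene_means=gmeans,
        gene_sds=gsds,
        dropped_genes=dropped,
        feature_min=pd.concat([mnx, mny]),
        feature_max=pd.concat([mxx, mxy]),
    )
    return PreprocessedData(
        x_t=x01, y_t=y01, scaling=scaling, outlier_flags=flags,
        group=data.group, batch=data.batch,
    )
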