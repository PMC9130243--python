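"""Differential expression, ROC, embeddings and bi-cluster ordering.

Differential expression uses a two-group linear model with
empirical-Bayes variance moderation: per-gene pooled variances are
shrunk toward a prior estimated across genes by matching the moments of
log sample variances to a scaled F distribution (the standard moderated
t construction), giving t statistics with augmented degrees of freedom.
logFC is tumor mean minus normal mean on the log2 scale, so it equals
the printed AveExpr difference exactly. A plain Welch-t mode is kept
for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, roc_curve
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .snr import _group_masks


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log variances to a scaled F prior -> (prior df, prior var)."""
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    if not np.isfinite(d0):
        return np.inf, float(np.exp(e_mean))
    s02 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


def differential_expression(
    X: pd.DataFrame,
    labels: Sequence,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal differential expression.

    Columns: gene_id, logFC (tumor mean - normal mean), ave_expr_tumor,
    ave_expr_normal, t_statistic, p_value, adj_p (Benjamini-Hochberg),
    direction (up iff logFC > 0).
    """
    if method not in ("moderated", "welch"):
        raise ValueError(f"unknown method {method!r}")
    tumor, normal = _group_masks(labels)
    xt = X.to_numpy()[:, tumor]
    xn = X.to_numpy()[:, normal]
    n1, n2 = xt.shape[1], xn.shape[1]
    mean_t, mean_n = xt.mean(axis=1), xn.mean(axis=1)
    logfc = mean_t - mean_n

    if method == "welch":
        t_stat, p = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
    else:
        v1 = xt.var(axis=1, ddof=1)
        v2 = xn.var(axis=1, ddof=1)
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        d0, s02 = _fit_variance_prior(s2, df)
        if np.isfinite(d0):
            s2_post = (d0 * s02 + df * s2) / (d0 + df)
            df_total = df + d0
        else:
            s2_post = np.full_like(s2, s02)
            df_total = np.inf
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0, np.inf))
        if np.isfinite(df_total):
            p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t_stat))

    out = pd.DataFrame(
        {
            "gene_id": X.index,
            "logFC": logfc,
            "ave_expr_tumor": mean_t,
            "ave_expr_normal": mean_n,
            "t_statistic": t_stat,
            "p_value": p,
            "adj_p": bh_adjust(np.nan_to_num(p, nan=1.0)),
            "direction": np.where(logfc > 0, "up", "down"),
        }
    ).reset_index(drop=True)
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ROCResult:
    auc: float
    sensitivity: float  # percent, at the Youden-optimal cutoff
    specificity: float  # percent
    cutoff: float
    orientation: str  # "up-positive" or "down-positive"


def roc(scores: Sequence[float], labels: Sequence) -> ROCResult:
    """Single-marker ROC: Mann-Whitney AUC and Youden-optimal operating point.

    Orientation is chosen so AUC >= 0.5 (markers down-regulated in
    tumors are scored with their negated expression) and recorded; the
    cutoff is reported on the original score scale.
    """
    s = np.asarray(scores, dtype=float)
    tumor, normal = _group_masks(labels)
    y = tumor.astype(int)
    auc0 = roc_auc_score(y, s)
    if auc0 >= 0.5:
        orientation, use = "up-positive", s
        auc = auc0
    else:
        orientation, use = "down-positive", -s
        auc = 1.0 - auc0
    fpr, tpr, thresholds = roc_curve(y, use, drop_intermediate=False)
    youden = tpr - fpr
    best = int(np.argmax(youden))
    cutoff = thresholds[best]
    if orientation == "down-positive":
        cutoff = -cutoff
    return ROCResult(
        auc=float(auc),
        sensitivity=float(tpr[best] * 100.0),
        specificity=float((1.0 - fpr[best]) * 100.0),
        cutoff=float(cutoff),
        orientation=orientation,
    )


def roc_table(X: pd.DataFrame, labels: Sequence) -> pd.DataFrame:
    """Per-gene ROC of raw expression values (rows of ``X``)."""
    rows = []
    for gene in X.index:
        r = roc(X.loc[gene].to_numpy(), labels)
        rows.append(
            {
                "gene_id": gene,
                "auc": r.auc,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "cutoff": r.cutoff,
                "orientation": r.orientation,
            }
        )
    return pd.DataFrame(rows)


def pca_embed(X: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores of a centered PCA of the genes x samples matrix.

    Sign convention: the largest-magnitude loading of each component is
    made positive. Returns (scores samples x PCs, explained-variance
    fractions).
    """
    mat = X.to_numpy().T  # samples x genes
    n_components = min(n_components, min(mat.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(mat)
    for k in range(n_components):
        lead = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k][lead] < 0:
            scores[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, index=X.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def plsda_embed(X: pd.DataFrame, labels: Sequence, n_components: int = 2) -> pd.DataFrame:
    """PLS-DA sample scores: NIPALS PLS against a one-hot class response."""
    tumor, normal = _group_masks(labels)
    mat = X.to_numpy().T
    if np.allclose(mat.var(axis=0).sum(), 0.0):
        raise FloatingPointError("expression matrix is constant; PLS-DA undefined")
    y = np.column_stack([tumor.astype(float), normal.astype(float)])
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(mat, y)
    scores = pls.transform(mat)
    cols = [f"comp{k + 1}" for k in range(n_components)]
    return pd.DataFrame(scores, index=X.columns, columns=cols)


def bicluster_order(X: pd.DataFrame, zscore: bool = True) -> tuple[list[str], list[str]]:
    """Leaf orders of average-linkage Euclidean clustering of rows and columns.

    Genes are z-scored per row before clustering (heatmap display
    convention); constant genes are left at 0.
    """
    mat = X.to_numpy(dtype=float)
    if zscore:
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        mat = (mat - mu) / sd
    if mat.shape[0] > 1:
        gene_order = [X.index[i] for i in leaves_list(linkage(mat, method="average"))]
    else:
        gene_order = list(X.index)
    if mat.shape[1] > 1:
        sample_order = [X.columns[i] for i in leaves_list(linkage(mat.T, method="average"))]
    else:
        sample_order = list(X.columns)
    return gene_order, sample_order
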