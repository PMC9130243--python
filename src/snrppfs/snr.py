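"""Signal-to-noise-ratio gene ranking and screening.

For gene g with tumor/normal expression vectors, the SNR score is

    SNR(g) = |u+ - u-| / (d+ + d-)

where u+/u- are the group means and d+/d- the group sample standard
deviations (ddof = 1). Genes with the largest between-group mean
difference relative to their within-group spread rank first.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

RANKING_COLUMNS = ["gene_id", "snr", "mean_tumor", "mean_normal", "sd_tumor", "sd_normal", "rank"]


def snr_statistic(x_tumor: Sequence[float], x_normal: Sequence[float]) -> float:
    """SNR of one gene: absolute mean difference over summed group sds.

    Degenerate spreads: if both sds are 0 the score is 0 for equal means
    and ``inf`` (sorts first) for unequal means.
    """
    xt = np.asarray(x_tumor, dtype=float)
    xn = np.asarray(x_normal, dtype=float)
    if xt.size < 2 or xn.size < 2:
        raise ValueError("each group needs at least 2 values")
    num = abs(xt.mean() - xn.mean())
    denom = xt.std(ddof=1) + xn.std(ddof=1)
    if denom == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / denom)


def _group_masks(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels)
    tumor = lab == "tumor"
    normal = lab == "normal"
    if not (tumor | normal).all():
        bad = sorted(set(lab[~(tumor | normal)].tolist()))
        raise ValueError(f"labels must be 'tumor' or 'normal'; got {bad[:5]}")
    if tumor.sum() < 2 or normal.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return tumor, normal


def score_genes(m: pd.DataFrame, labels: Sequence) -> pd.DataFrame:
    """SNR score every gene of a genes x samples matrix (vectorized)."""
    if len(labels) != m.shape[1]:
        raise ValueError("labels must align with the matrix samples")
    tumor, normal = _group_masks(labels)
    xt = m.to_numpy()[:, tumor]
    xn = m.to_numpy()[:, normal]
    mean_t = xt.mean(axis=1)
    mean_n = xn.mean(axis=1)
    sd_t = xt.std(axis=1, ddof=1)
    sd_n = xn.std(axis=1, ddof=1)
    num = np.abs(mean_t - mean_n)
    denom = sd_t + sd_n
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(denom > 0, num / denom, np.where(num == 0, 0.0, np.inf))
    return pd.DataFrame(
        {
            "gene_id": m.index,
            "snr": snr,
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "sd_tumor": sd_t,
            "sd_normal": sd_n,
        }
    )


def rank_and_screen(
    m: pd.DataFrame,
    labels: Sequence,
    k: int | None = 430,
    snr_threshold: float | None = None,
) -> pd.DataFrame:
    """Rank all genes by SNR (descending) and keep the top ``k``.

    Ties are broken by gene id (lexicographic), so the ranking is
    deterministic and independent of input gene order. Pass
    ``k=None, snr_threshold=...`` to screen by score instead of count.
    """
    scored = score_genes(m, labels)
    scored = scored.sort_values(["snr", "gene_id"], ascending=[False, True], kind="mergesort")
    scored["rank"] = np.arange(1, len(scored) + 1)
    scored = scored.reset_index(drop=True)
    if snr_threshold is not None:
        return scored.loc[scored["snr"] >= snr_threshold, RANKING_COLUMNS].reset_index(drop=True)
    if k is None:
        k = len(scored)
    if k > len(scored):
        raise ValueError(f"k={k} exceeds the number of genes ({len(scored)})")
    return scored.loc[: k - 1, RANKING_COLUMNS]
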