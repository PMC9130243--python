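"""Stage correlation, Cox proportional-hazards and Kaplan-Meier analysis.

Stage is always encoded ordinally I-IV -> 1-4; samples with missing
stage are dropped from stage analyses. Cox models maximize the partial
likelihood with Efron tie handling (lifelines); Kaplan-Meier high/low
splits use a maximally selected log-rank cutpoint within the 10-90%
quantile band (median fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats


class DegenerateFitError(ValueError):
    """Raised when a survival model cannot be fit (e.g. no events)."""


def stage_correlation(X: pd.DataFrame, stage: Sequence[float]) -> pd.DataFrame:
    """Pearson correlation of each gene with ordinal tumor stage.

    Missing-stage samples are dropped; two-sided p from the t transform.
    ``stage_positive`` flags r > 0 with p < 0.05. Constant genes (or a
    constant stage vector) yield missing r with a warning.
    """
    stage = np.asarray(stage, dtype=float)
    keep = ~np.isnan(stage)
    if keep.sum() < 3:
        raise ValueError("need >= 3 samples with non-missing stage")
    stage = stage[keep]
    mat = X.to_numpy()[:, keep]
    const_stage = np.allclose(stage.std(), 0.0)
    rows = []
    for gene, vals in zip(X.index, mat):
        if const_stage or np.allclose(vals.std(), 0.0):
            warnings.warn(f"correlation undefined for {gene!r} (constant input)")
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(vals, stage)
        rows.append(
            {
                "gene_id": gene,
                "pearson_r": r,
                "p_value": p,
                "stage_positive": bool(r > 0 and p < 0.05) if np.isfinite(r) else False,
            }
        )
    return pd.DataFrame(rows)


def _check_survival(os_time: np.ndarray, os_event: np.ndarray) -> None:
    if (os_time < 0).any():
        raise ValueError("survival times must be non-negative")
    if os_event.sum() < 1:
        raise DegenerateFitError("no events observed; Cox fit is degenerate")


def cox_fit(
    covariates: pd.DataFrame,
    os_time: Sequence[float],
    os_event: Sequence[int],
    terms: Sequence[str] | None = None,
    model: str = "multivariate",
) -> pd.DataFrame:
    """Cox proportional-hazards fit with Efron ties and Wald 95% CIs.

    ``model="multivariate"`` fits all terms jointly; ``"univariate"``
    loops over the terms one at a time. Returns one row per term:
    term, hazard_ratio, ci_low, ci_high, p_value, model.
    """
    if model not in ("univariate", "multivariate"):
        raise ValueError(f"unknown model {model!r}")
    terms = list(terms) if terms is not None else list(covariates.columns)
    unknown = [t for t in terms if t not in covariates.columns]
    if unknown:
        raise KeyError(f"unknown covariates: {unknown}")
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=float)
    _check_survival(t, e)
    for term in terms:
        if np.allclose(np.asarray(covariates[term], dtype=float).std(), 0.0):
            raise ValueError(f"constant covariate {term!r}")

    def _fit(cols: list[str]) -> pd.DataFrame:
        df = covariates[cols].astype(float).copy()
        df["_time"] = t
        df["_event"] = e
        cph = CoxPHFitter()
        try:
            # tight Newton precision so coefficients are reproducible to ~1e-8
            cph.fit(df, duration_col="_time", event_col="_event", fit_options={"precision": 1e-11})
        except ConvergenceError as exc:
            raise FloatingPointError(f"Cox fit did not converge for {cols}: {exc}") from exc
        summ = cph.summary
        return pd.DataFrame(
            {
                "term": summ.index,
                "hazard_ratio": summ["exp(coef)"].to_numpy(),
                "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
                "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
                "p_value": summ["p"].to_numpy(),
                "coef": summ["coef"].to_numpy(),
            }
        )

    if model == "multivariate":
        out = _fit(terms)
    else:
        out = pd.concat([_fit([term]) for term in terms], ignore_index=True)
    out["model"] = model
    return out.reset_index(drop=True)


@dataclass
class KMCurve:
    label: str
    times: np.ndarray
    survival: np.ndarray  # product-limit estimates, start at 1, non-increasing
    cutpoint: float
    logrank_p: float


def _logrank_stat(time: np.ndarray, event: np.ndarray, high: np.ndarray) -> float:
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    return float(res.test_statistic)


def maxstat_cutpoint(
    score: np.ndarray,
    os_time: np.ndarray,
    os_event: np.ndarray,
    quantile_band: tuple[float, float] = (0.1, 0.9),
) -> float:
    """Cutpoint maximizing the two-group log-rank statistic.

    Candidate splits are the observed score values within the given
    quantile band; falls back to the median when no candidate yields a
    valid two-group split.
    """
    lo, hi = np.quantile(score, quantile_band)
    candidates = np.unique(score[(score >= lo) & (score <= hi)])
    best_cut, best_stat = None, -np.inf
    for c in candidates:
        high = score > c
        if high.sum() < 2 or (~high).sum() < 2:
            continue
        stat = _logrank_stat(os_time, os_event, high)
        if stat > best_stat:
            best_stat, best_cut = stat, c
    if best_cut is None:
        best_cut = float(np.median(score))
    return float(best_cut)


def km_and_logrank(
    score: Sequence[float],
    os_time: Sequence[float],
    os_event: Sequence[int],
    cutpoint_method: str = "maxstat",
) -> tuple[KMCurve, KMCurve]:
    """Kaplan-Meier curves of high vs low marker groups plus log-rank p."""
    if cutpoint_method not in ("median", "maxstat"):
        raise ValueError(f"unknown cutpoint_method {cutpoint_method!r}")
    s = np.asarray(score, dtype=float)
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=float)
    if cutpoint_method == "median":
        cut = float(np.median(s))
    else:
        cut = maxstat_cutpoint(s, t, e)
    high = s > cut
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("cutpoint leaves a group with fewer than 2 samples")
    p = float(logrank_test(t[high], t[~high], e[high], e[~high]).p_value)

    curves = []
    for label, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        sf = kmf.survival_function_
        curves.append(
            KMCurve(
                label=label,
                times=sf.index.to_numpy(dtype=float),
                survival=sf.iloc[:, 0].to_numpy(dtype=float),
                cutpoint=cut,
                logrank_p=p,
            )
        )
    return curves[0], curves[1]


def survival_screen(
    genes: Sequence[str],
    X: pd.DataFrame,
    clinical: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Two-tier survival screen of candidate genes.

    Univariate Cox per gene on samples with survival data; genes are
    flagged ``significant`` (p < 0.05) or ``trend`` (0.05 <= p < 0.1).
    Trend-or-better genes enter a joint multivariate Cox fit. Returns
    (univariate table with flags, multivariate table or None).
    """
    genes = list(genes)
    if not genes:
        return (
            pd.DataFrame(columns=["term", "hazard_ratio", "ci_low", "ci_high", "p_value", "coef", "model", "flag"]),
            None,
        )
    usable = clinical.dropna(subset=["os_time_days", "os_status"])
    ids = usable["sample_id"].tolist()
    t = usable["os_time_days"].to_numpy(dtype=float)
    e = usable["os_status"].to_numpy(dtype=float)
    cov = X.loc[genes, ids].T
    uni = cox_fit(cov, t, e, terms=genes, model="univariate")
    uni["flag"] = np.select(
        [uni["p_value"] < 0.05, uni["p_value"] < 0.1], ["significant", "trend"], default="none"
    )
    hits = uni.loc[uni["flag"] != "none", "term"].tolist()
    multi = cox_fit(cov, t, e, terms=hits, model="multivariate") if len(hits) >= 1 else None
    return uni, multi
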