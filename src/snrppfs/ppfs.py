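"""Predictive permutation feature selection (PPFS) of the class Markov blanket.

PPFS treats Markov-blanket discovery as a sequence of conditional
predictive tests. A candidate gene is judged *given* a context set by
fitting a supervised learner on context + candidate under stratified
k-fold cross-validation and measuring, per fold, how much the validation
score drops when the candidate's column (alone) is permuted. If the
candidate carries information about the class beyond the context, the
drops are systematically positive.

Permutation scheme: the default (``"marginal"``) shuffles the raw
validation column, measuring how much the fitted model relies on the
candidate's actual values. Because shuffling also breaks the
candidate's correlation with the context, redundant-but-correlated
features can register positive drops; when strict conditional semantics
are wanted (e.g. proxy detection), ``permutation_scheme="residual"``
permutes only the residual of an OLS fit of the candidate on the
context (estimated on the training fold), which keeps the permuted
column on the joint candidate/context manifold and isolates the
candidate-specific signal.

Selection runs in two phases over the SNR-ranked candidates:

* ``grow``  — admit candidates (in rank order) whose permutation test
  against the currently admitted set is significant;
* ``prune`` — re-test each admitted gene against all the others and
  remove the non-significant ones, sweeping to a fixed point; survivors
  approximate the minimal Markov blanket.

Significance (``test_level``):

* ``"fisher"`` (default) — within each fold the unpermuted score is
  exchangeable with the permuted scores when the candidate carries no
  information, so its rank yields an exact one-sided p-value; fold
  p-values are combined with Fisher's method. Exact level, no
  distributional assumption on the score drops.
* ``"fold"`` — one-sided one-sample t-test of the per-fold mean drops
  (df = n_folds - 1).
* ``"permutation"`` — t-test over the raw fold x permutation drops;
  anticonservative (drops within a fold share the fold's unpermuted
  score) and kept only for comparison.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .snr import rank_and_screen

_BASE_LEARNERS = {
    "random_forest": RandomForestClassifier,
    "extra_trees": ExtraTreesClassifier,
}


@dataclass(frozen=True)
class PpfsConfig:
    """Settings of the permutation-importance selection.

    ``scorer``: ``"log-loss"`` (default; stays informative once accuracy
    saturates on well-separated cohorts) or ``"accuracy"``.
    ``base_learner``: ``"random_forest"`` or ``"extra_trees"``.
    """

    n_folds: int = 5
    n_permutations: int = 50
    alpha: float = 0.05
    scorer: str = "log-loss"
    base_learner: str = "random_forest"
    n_estimators: int = 40
    # per-split feature subsampling of the ensemble; 1 forces every feature
    # (including the candidate) into play, so the permutation test measures
    # the candidate's information rather than the greedy trees' preferences
    max_split_features: int | str = 1
    max_features: int | None = None
    seed: int = 0
    prune_to_fixed_point: bool = True
    test_level: str = "fisher"  # "fisher", "fold" or "permutation"
    permutation_scheme: str = "marginal"  # "marginal" or "residual" (conditional)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.scorer not in ("accuracy", "log-loss"):
            raise ValueError(f"unknown scorer {self.scorer!r}")
        if self.base_learner not in _BASE_LEARNERS:
            raise ValueError(f"unknown base_learner {self.base_learner!r}")
        if self.test_level not in ("fisher", "fold", "permutation"):
            raise ValueError(f"unknown test_level {self.test_level!r}")
        if self.permutation_scheme not in ("residual", "marginal"):
            raise ValueError(f"unknown permutation_scheme {self.permutation_scheme!r}")


@dataclass
class MarkovBlanketResult:
    """Outcome of SNR-PPFS selection with per-gene provenance."""

    selected: list[str]
    records: pd.DataFrame  # gene, phase, importance_mean, p_value, kept
    rejected_at_prune: list[str]
    config: PpfsConfig

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _encode_labels(y: Sequence) -> np.ndarray:
    lab = np.asarray(y)
    if lab.dtype.kind in "USO":
        enc = (lab == "tumor").astype(int)
        if enc.sum() == 0 and not set(np.unique(lab)) <= {"tumor", "normal"}:
            raise ValueError("labels must be 'tumor'/'normal' or 0/1")
    else:
        enc = lab.astype(int)
    if len(np.unique(enc)) < 2:
        raise ValueError("labels are degenerate (single class)")
    return enc


def _make_learner(cfg: PpfsConfig, seed: int):
    cls = _BASE_LEARNERS[cfg.base_learner]
    return cls(
        n_estimators=cfg.n_estimators,
        max_features=cfg.max_split_features,
        random_state=seed,
        n_jobs=1,
    )


_EPS = 1e-15


def _score_rows(cfg: PpfsConfig, y_true: np.ndarray, proba1: np.ndarray) -> np.ndarray:
    """Higher-is-better score for each row of stacked P(class=1) vectors.

    ``proba1`` has shape (n_blocks, n_samples); returns one score per block.
    """
    if cfg.scorer == "accuracy":
        return ((proba1 >= 0.5).astype(int) == y_true).mean(axis=1)
    p = np.clip(proba1, _EPS, 1 - _EPS)
    return np.where(y_true, np.log(p), np.log1p(-p)).mean(axis=1)


def permutation_importance_test(
    candidate: str,
    context: Sequence[str],
    X: pd.DataFrame,
    y: Sequence,
    cfg: PpfsConfig,
) -> tuple[float, float]:
    """Mean permutation score drop of ``candidate`` given ``context`` and its p-value.

    Fits the base learner on context + candidate under stratified k-fold
    CV; within each validation fold the candidate column is permuted
    ``n_permutations`` times (training untouched) and the score drop
    (original - permuted) recorded. Returns the mean drop and the
    one-sided p-value of the configured t-test of drops > 0.
    """
    context = list(context)
    if candidate in context:
        raise ValueError(f"candidate {candidate!r} already in context")
    features = context + [candidate]
    missing = [g for g in features if g not in X.index]
    if missing:
        raise KeyError(f"genes not in the matrix: {missing[:5]}")
    data = X.loc[features].to_numpy().T  # samples x features
    target = _encode_labels(y)
    cand_col = len(features) - 1

    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed % (2**32))
    # distinct permutation draws per (candidate, context) pair, so a grow-phase
    # admission is re-examined with fresh permutations at prune time
    ctx_digest = zlib.crc32("|".join(sorted(context)).encode())
    rng = np.random.default_rng([cfg.seed % (2**31), zlib.crc32(candidate.encode()), ctx_digest])

    fold_means = []
    all_drops = []
    fold_pvalues = []
    for fold_idx, (tr, va) in enumerate(skf.split(data, target)):
        learner = _make_learner(cfg, seed=(cfg.seed + fold_idx) % (2**32))
        learner.fit(data[tr], target[tr])
        proba = learner.predict_proba(data[va])
        s0 = float(_score_rows(cfg, target[va], proba[None, :, 1])[0])

        n_va = len(va)
        cand_va = data[va][:, cand_col]
        if cfg.permutation_scheme == "residual" and context:
            # conditional permutation: shuffle only the part of the candidate
            # that the context cannot explain (OLS fit on the training fold)
            ctx_tr = np.column_stack([np.ones(len(tr)), data[tr][:, :-1]])
            ctx_va = np.column_stack([np.ones(n_va), data[va][:, :-1]])
            beta = np.linalg.lstsq(ctx_tr, data[tr][:, cand_col], rcond=None)[0]
            fitted = ctx_va @ beta
            resid = cand_va - fitted
        else:
            fitted = np.zeros(n_va)
            resid = cand_va
        stacked = np.tile(data[va], (cfg.n_permutations, 1))
        for p in range(cfg.n_permutations):
            perm = rng.permutation(n_va)
            stacked[p * n_va : (p + 1) * n_va, cand_col] = fitted + resid[perm]
        proba_perm = learner.predict_proba(stacked)[:, 1].reshape(cfg.n_permutations, n_va)
        drops = s0 - _score_rows(cfg, target[va], proba_perm)
        if not np.isfinite(drops).all():
            raise FloatingPointError(f"non-finite validation scores for {candidate!r}")
        fold_means.append(drops.mean())
        all_drops.append(drops)
        # exact one-sided rank p: under the null s0 is exchangeable with the
        # permuted scores, so P(drop of s0 <= permuted) is uniform on the grid
        fold_pvalues.append((1.0 + (drops <= 0).sum()) / (cfg.n_permutations + 1.0))

    mean_drop = float(np.concatenate(all_drops).mean())
    if cfg.test_level == "fisher":
        x2 = -2.0 * np.sum(np.log(fold_pvalues))
        p_value = float(stats.chi2.sf(x2, 2 * cfg.n_folds))
    else:
        values = np.asarray(fold_means if cfg.test_level == "fold" else np.concatenate(all_drops))
        if np.allclose(values.std(ddof=1), 0.0):
            p_value = 0.0 if values.mean() > 0 else 1.0
        else:
            p_value = float(stats.ttest_1samp(values, 0.0, alternative="greater").pvalue)
    return mean_drop, p_value


def grow(
    candidates: Sequence[str] | pd.DataFrame,
    X: pd.DataFrame,
    y: Sequence,
    cfg: PpfsConfig,
) -> tuple[list[str], pd.DataFrame]:
    """Forward phase: admit SNR-ranked candidates that test significant.

    ``candidates`` may be a gene-id sequence or a ranking frame with a
    ``gene_id`` column (rank order is the iteration order).
    """
    if isinstance(candidates, pd.DataFrame):
        candidates = candidates["gene_id"].tolist()
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates to grow from")
    admitted: list[str] = []
    rows = []
    for gene in candidates:
        if cfg.max_features is not None and len(admitted) >= cfg.max_features:
            break
        imp, p = permutation_importance_test(gene, admitted, X, y, cfg)
        keep = p < cfg.alpha
        if keep:
            admitted.append(gene)
        rows.append({"gene": gene, "phase": "grow", "importance_mean": imp, "p_value": p, "kept": keep})
    return admitted, pd.DataFrame(rows)


def prune(
    admitted: Sequence[str],
    X: pd.DataFrame,
    y: Sequence,
    cfg: PpfsConfig,
) -> MarkovBlanketResult:
    """Backward phase: drop genes made redundant by the rest of the set.

    Each retained gene is re-tested with the other retained genes as
    context; non-significant genes are removed. Sweeps repeat until a
    full pass removes nothing (fixed point), or once if
    ``cfg.prune_to_fixed_point`` is off.
    """
    retained = list(admitted)
    if not retained:
        raise ValueError("admitted set is empty")
    rows = []
    rejected: list[str] = []
    while True:
        removed_this_pass = False
        for gene in list(retained):
            context = [g for g in retained if g != gene]
            if not context:  # lone survivor: test against empty context
                imp, p = permutation_importance_test(gene, [], X, y, cfg)
            else:
                imp, p = permutation_importance_test(gene, context, X, y, cfg)
            keep = p < cfg.alpha
            rows.append(
                {"gene": gene, "phase": "prune", "importance_mean": imp, "p_value": p, "kept": keep}
            )
            if not keep:
                retained.remove(gene)
                rejected.append(gene)
                removed_this_pass = True
        if not removed_this_pass or not cfg.prune_to_fixed_point or not retained:
            break
    return MarkovBlanketResult(
        selected=retained,
        records=pd.DataFrame(rows),
        rejected_at_prune=rejected,
        config=cfg,
    )


def snr_ppfs(
    X: pd.DataFrame,
    y: Sequence,
    k_screen: int | None = 430,
    cfg: PpfsConfig | None = None,
) -> MarkovBlanketResult:
    """Full SNR-PPFS selection: screen -> grow -> prune, with provenance."""
    cfg = cfg or PpfsConfig()
    ranking = rank_and_screen(X, y, k=k_screen)
    admitted, grow_records = grow(ranking, X, y, cfg)
    if not admitted:
        return MarkovBlanketResult(
            selected=[], records=grow_records, rejected_at_prune=[], config=cfg
        )
    result = prune(admitted, X, y, cfg)
    result.records = pd.concat([grow_records, result.records], ignore_index=True)
    return result
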