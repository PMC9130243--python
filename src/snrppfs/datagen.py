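"""Synthetic tumor/normal expression cohorts with planted ground truth.

The generator emulates the statistical structure of a combined
tumor + two-source-normal expression cohort (one tumor cohort with
clinical follow-up plus a small matched-normal and a large external
normal subcohort):

* a linear-Gaussian structural equation model over genes with one binary
  class node (tumor vs normal); the Markov blanket of the class node is
  a planted mix of parent genes, child genes and co-parents (spouses);
* many marginally irrelevant noise genes;
* a mild batch offset on a random subset of genes for the second normal
  subcohort, so the two normal subgroups overlap but do not coincide;
* a few zero-inflated noise genes (to exercise the zero filter);
* ordinal tumor stage 1-4 tilted by designated stage genes;
* exponential proportional-hazards survival times driven by designated
  hazard genes and stage, with independent censoring.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import ANNOTATION_COLUMNS, validate_expression

#: Name of the binary class node in the planted DAG.
CLASS_NODE = "class"


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable knobs of the synthetic cohort (log2-expression units).

    Defaults are the package's study conditions: a desk-scale analogue of
    a 289-tumor / 41 + 307-normal colon cohort at roughly 1/50 of its
    dimensionality, with class-conditional shifts in the range reported
    for strong tumor markers and a stage distribution / event rate
    matching a typical stage-I-IV adenocarcinoma cohort.
    """

    # Markov-blanket composition
    frac_parents: float = 0.4
    frac_children: float = 0.4  # remainder are spouses (co-parents)
    effect_low: float = 1.5
    effect_high: float = 3.5
    frac_down: float = 0.2  # fraction of signal genes down-regulated in tumors
    spouse_weight: float = 0.8
    # marginal gene model
    noise_sd: float = 1.0
    baseline_low: float = 2.0
    baseline_high: float = 9.0
    # normal-subcohort-b batch structure
    batch_offset: float = 0.5
    batch_gene_fraction: float = 0.3
    # zero inflation (applied to a designated subset of noise genes)
    zero_inflation_rate: float = 0.8
    zero_inflated_fraction: float = 0.02
    # clinical model
    n_stage_genes: int = 14
    stage_slope_low: float = 0.4
    stage_slope_high: float = 0.9
    hazard_log_hrs: tuple[float, ...] = (0.7, 0.7, -0.7)
    stage_log_hr: float = 0.7885  # log(2.2): one stage step multiplies hazard by 2.2
    baseline_hazard: float = 1.0 / 1500.0  # events per day at covariate means
    censor_rate_multiplier: float = 3.0  # exponential censoring => ~25% event rate
    stage_probs: tuple[float, ...] = (0.159, 0.397, 0.300, 0.144)


@dataclass
class SyntheticTruth:
    """Planted generative model plus designated ground-truth gene sets."""

    dag: nx.DiGraph
    edge_weights: dict[tuple[str, str], float]
    noise_sd: dict[str, float]
    baselines: dict[str, float]
    mb_genes: tuple[str, ...]
    effect_sizes: dict[str, float]
    stage_genes: dict[str, float]
    hazard_genes: dict[str, float]
    batch_genes: tuple[str, ...]
    batch_offset: float
    zero_inflated_genes: tuple[str, ...]
    zero_inflation_rate: float
    config: GeneratorConfig
    seed: int

    @property
    def genes(self) -> list[str]:
        return [n for n in self.dag.nodes if n != CLASS_NODE]

    @property
    def noise_genes(self) -> list[str]:
        mb = set(self.mb_genes)
        return [g for g in self.genes if g not in mb]

    def to_json(self, path: str | Path) -> None:
        """Write a plain-JSON sidecar of the planted truth."""
        payload = {
            "seed": self.seed,
            "edges": [[u, v, self.edge_weights.get((u, v), 1.0)] for u, v in self.dag.edges],
            "mb_genes": list(self.mb_genes),
            "effect_sizes": self.effect_sizes,
            "stage_genes": self.stage_genes,
            "hazard_genes": self.hazard_genes,
            "batch_genes": list(self.batch_genes),
            "batch_offset": self.batch_offset,
            "zero_inflated_genes": list(self.zero_inflated_genes),
            "zero_inflation_rate": self.zero_inflation_rate,
            "baselines": self.baselines,
            "noise_sd": self.noise_sd,
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes x samples
    annotation: pd.DataFrame
    truth: SyntheticTruth


def markov_blanket(dag: nx.DiGraph, node: str) -> set[str]:
    """Parents, children and co-parents of ``node`` in ``dag``."""
    parents = set(dag.predecessors(node))
    children = set(dag.successors(node))
    spouses = {p for c in children for p in dag.predecessors(c)} - {node}
    return parents | children | spouses


def build_truth(
    n_signal: int,
    n_noise: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant a DAG whose class node has a Markov blanket of ``n_signal`` genes.

    The blanket mixes parents, children and co-parents per the config
    fractions (a single signal gene becomes a child); noise genes are
    isolated, hence d-separated from the class node.
    """
    if n_signal < 1:
        raise ValueError("n_signal must be >= 1")
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    n_total = n_signal + n_noise
    width = max(4, len(str(n_total)))
    gene_ids = [f"g{str(i + 1).zfill(width)}" for i in range(n_total)]
    signal = gene_ids[:n_signal]
    noise = gene_ids[n_signal:]

    n_children = max(1, round(cfg.frac_children * n_signal))
    n_parents = min(round(cfg.frac_parents * n_signal), n_signal - n_children)
    n_spouses = n_signal - n_children - n_parents
    children = signal[:n_children]
    parents = signal[n_children : n_children + n_parents]
    spouses = signal[n_children + n_parents :]

    dag = nx.DiGraph()
    dag.add_node(CLASS_NODE)
    dag.add_nodes_from(gene_ids)
    edge_weights: dict[tuple[str, str], float] = {}
    effect_sizes: dict[str, float] = {}

    def draw_effect() -> float:
        mag = rng.uniform(cfg.effect_low, cfg.effect_high)
        return -mag if rng.random() < cfg.frac_down else mag

    for p in parents:
        dag.add_edge(p, CLASS_NODE)
        effect_sizes[p] = draw_effect()
    for c in children:
        dag.add_edge(CLASS_NODE, c)
        effect_sizes[c] = draw_effect()
    for s in spouses:
        child = children[rng.integers(len(children))]
        dag.add_edge(s, child)
        edge_weights[(s, child)] = cfg.spouse_weight

    mb = markov_blanket(dag, CLASS_NODE)
    if mb != set(signal):  # spouse landed on a child with no other co-parent path
        raise AssertionError("planted Markov blanket does not match designated signal genes")

    baselines = {g: float(rng.uniform(cfg.baseline_low, cfg.baseline_high)) for g in gene_ids}
    noise_sd = {g: cfg.noise_sd for g in gene_ids}

    up_signal = [g for g in parents + children if effect_sizes[g] > 0]
    stage_pool = up_signal if up_signal else list(signal)
    n_stage = min(cfg.n_stage_genes, len(stage_pool))
    stage_sel = rng.choice(stage_pool, size=n_stage, replace=False)
    stage_genes = {str(g): float(rng.uniform(cfg.stage_slope_low, cfg.stage_slope_high)) for g in stage_sel}

    n_haz = min(len(cfg.hazard_log_hrs), n_signal)
    haz_sel = rng.choice(signal, size=n_haz, replace=False)
    hazard_genes = {str(g): float(b) for g, b in zip(haz_sel, cfg.hazard_log_hrs)}

    n_batch = round(cfg.batch_gene_fraction * n_total)
    batch_genes = tuple(sorted(str(g) for g in rng.choice(gene_ids, size=n_batch, replace=False)))

    n_zi = round(cfg.zero_inflated_fraction * n_noise)
    zero_inflated = (
        tuple(sorted(str(g) for g in rng.choice(noise, size=n_zi, replace=False))) if n_zi else ()
    )

    return SyntheticTruth(
        dag=dag,
        edge_weights=edge_weights,
        noise_sd=noise_sd,
        baselines=baselines,
        mb_genes=tuple(signal),
        effect_sizes=effect_sizes,
        stage_genes=stage_genes,
        hazard_genes=hazard_genes,
        batch_genes=batch_genes,
        batch_offset=cfg.batch_offset,
        zero_inflated_genes=zero_inflated,
        zero_inflation_rate=cfg.zero_inflation_rate,
        config=cfg,
        seed=seed,
    )


def sample_cohort(
    truth: SyntheticTruth,
    n_tumor: int,
    n_normal_a: int,
    n_normal_b: int,
    seed: int = 0,
) -> SyntheticCohort:
    """Ancestrally sample expression from the planted model.

    Tumor samples get class = 1. The batch offset is added to the
    designated genes of normal-subcohort-b samples; zero-inflated entries
    are set to exact 0; finally values are clipped at 0 (the
    log2(count+1) scale is non-negative).
    """
    for name, n in (("n_tumor", n_tumor), ("n_normal_a", n_normal_a), ("n_normal_b", n_normal_b)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    n_samples = n_tumor + n_normal_a + n_normal_b
    if n_samples < 2:
        raise ValueError("need at least 2 samples in total")
    rng = np.random.default_rng(seed)

    sample_ids = (
        [f"TUM-{i + 1:04d}" for i in range(n_tumor)]
        + [f"NTA-{i + 1:04d}" for i in range(n_normal_a)]
        + [f"NGB-{i + 1:04d}" for i in range(n_normal_b)]
    )
    subcohort = ["tumor"] * n_tumor + ["normal_a"] * n_normal_a + ["normal_b"] * n_normal_b
    group = ["tumor"] * n_tumor + ["normal"] * (n_normal_a + n_normal_b)
    y = np.array([1.0] * n_tumor + [0.0] * (n_normal_a + n_normal_b))

    genes = truth.genes
    x: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(truth.dag):
        if node == CLASS_NODE:
            continue
        val = truth.baselines[node] + rng.normal(0.0, truth.noise_sd[node], size=n_samples)
        if node in truth.effect_sizes:
            val = val + truth.effect_sizes[node] * y
        for pred in truth.dag.predecessors(node):
            if pred == CLASS_NODE:
                continue
            val = val + truth.edge_weights[(pred, node)] * x[pred]
        x[node] = val

    expr = pd.DataFrame(
        np.vstack([x[g] for g in genes]), index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )

    is_b = np.array([s == "normal_b" for s in subcohort])
    if is_b.any() and truth.batch_genes:
        expr.loc[list(truth.batch_genes), is_b] += truth.batch_offset

    for g in truth.zero_inflated_genes:
        mask = rng.random(n_samples) < truth.zero_inflation_rate
        expr.loc[g, mask] = 0.0

    expr = expr.clip(lower=0.0)
    validate_expression(expr)

    ann = pd.DataFrame({"sample_id": sample_ids, "group": group, "subcohort": subcohort})
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            # gender/race are categorical strings, the rest numeric
            ann[col] = pd.Series(np.nan, index=ann.index, dtype=object if col in ("gender", "race") else float)
    ann = ann[ANNOTATION_COLUMNS]
    return SyntheticCohort(expression=expr, annotation=ann, truth=truth)


def sample_clinical(
    cohort: SyntheticCohort,
    seed: int = 0,
    censor_all: bool = False,
) -> pd.DataFrame:
    """Augment the cohort annotation with stage, demographics and survival.

    Tumor samples receive an ordinal stage 1-4 via an ordered-logit model
    whose latent score is a weighted sum of the standardized stage-gene
    expression (cutpoints fixed at the latent quantiles of the target
    stage distribution), plus exponential proportional-hazards survival
    times driven by the hazard genes and stage, independently censored.
    Normal samples keep missing clinical fields. ``censor_all`` forces
    every subject to be censored (for degenerate-fit testing).
    """
    ann = cohort.annotation.copy()
    truth = cohort.truth
    cfg = truth.config
    tumor_mask = (ann["group"] == "tumor").to_numpy()
    n_tumor = int(tumor_mask.sum())
    if n_tumor == 0:
        raise ValueError("cohort contains no tumor samples")
    rng = np.random.default_rng(seed)
    tumor_ids = ann.loc[tumor_mask, "sample_id"].tolist()

    def zscores(gene_set: dict[str, float]) -> np.ndarray:
        lp = np.zeros(n_tumor)
        for g, w in gene_set.items():
            vals = cohort.expression.loc[g, tumor_ids].to_numpy()
            sd = vals.std(ddof=1)
            if sd > 0:
                lp += w * (vals - vals.mean()) / sd
        return lp

    # --- ordinal stage ----------------------------------------------------
    latent = zscores(truth.stage_genes) + rng.logistic(0.0, 1.0, size=n_tumor)
    cum = np.cumsum(cfg.stage_probs)[:-1]
    cutpoints = np.quantile(latent, cum)
    stage = 1 + np.searchsorted(cutpoints, latent)

    # --- survival ---------------------------------------------------------
    lp_surv = zscores(truth.hazard_genes) + cfg.stage_log_hr * (stage - stage.mean())
    rate = cfg.baseline_hazard * np.exp(lp_surv)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.exponential(1.0 / (cfg.baseline_hazard * cfg.censor_rate_multiplier), size=n_tumor)
    if censor_all:
        os_status = np.zeros(n_tumor, dtype=int)
        os_time = censor_time
    else:
        os_status = (event_time <= censor_time).astype(int)
        os_time = np.minimum(event_time, censor_time)

    # --- demographic flavor (shapes only; carried but not modelled) ------
    age = np.clip(rng.normal(67, 12, size=n_tumor), 30, 90).round(1)
    gender = rng.choice(["female", "male"], size=n_tumor, p=[0.46, 0.54])
    race = rng.choice(["asian", "black", "white"], size=n_tumor, p=[0.05, 0.2, 0.75])
    bmi = np.clip(rng.normal(27, 5, size=n_tumor), 16, 45).round(1)

    ann.loc[tumor_mask, "stage"] = stage.astype(float)
    ann.loc[tumor_mask, "age_years"] = age
    ann.loc[tumor_mask, "gender"] = gender
    ann.loc[tumor_mask, "race"] = race
    ann.loc[tumor_mask, "bmi"] = bmi
    ann.loc[tumor_mask, "os_status"] = os_status.astype(float)
    ann.loc[tumor_mask, "os_time_days"] = np.round(os_time, 1)
    return ann


def default_cohort(seed: int = 0, with_clinical: bool = True) -> SyntheticCohort:
    """The package's default desk-scale cohort.

    40 signal + 960 noise genes; 120 tumor / 20 normal-a / 120 normal-b
    samples (the class imbalance and two-source normal structure of a
    tumor-plus-external-normal colon cohort at ~1/50 dimensionality).
    """
    truth = build_truth(n_signal=40, n_noise=960, seed=seed)
    cohort = sample_cohort(truth, n_tumor=120, n_normal_a=20, n_normal_b=120, seed=seed + 1)
    if with_clinical:
        cohort.annotation = sample_clinical(cohort, seed=seed + 2)
    return cohort
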