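"""End-to-end orchestration of the signature-discovery pipeline.

Stages: data loading (or synthetic generation) -> zero filter -> SNR
screening -> PPFS Markov-blanket selection -> PC-stable network ->
differential expression / ROC / embeddings -> stage correlation and
survival modelling. Each stage's counts are logged and recorded in a
JSON run manifest; artifacts are plain TSV/JSON files in the output
directory.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dataio, datagen, expression_stats, network, snr, survival
from .ppfs import PpfsConfig, snr_ppfs

log = logging.getLogger("snrppfs")


@dataclass
class SyntheticSettings:
    n_signal: int = 40
    n_noise: int = 960
    n_tumor: int = 120
    n_normal_a: int = 20
    n_normal_b: int = 120


@dataclass
class PipelineConfig:
    """Validated pipeline settings (real-input paths or synthetic mode)."""

    expression_path: str | None = None
    annotation_path: str | None = None
    synthetic: SyntheticSettings | None = None
    k_screen: int = 430
    ppfs: PpfsConfig = field(default_factory=PpfsConfig)
    bn_alpha: float = 0.05
    bn_max_cond: int = 3
    include_class: bool = False
    cutpoint_method: str = "maxstat"
    out_dir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expression_path is None and self.synthetic is None:
            raise ValueError("config needs either input paths or a synthetic block")
        if self.expression_path is not None and self.annotation_path is None:
            raise ValueError("expression_path requires annotation_path")
        if not 0 < self.bn_alpha < 1:
            raise ValueError("bn_alpha must be in (0, 1)")
        if self.cutpoint_method not in ("median", "maxstat"):
            raise ValueError(f"unknown cutpoint_method {self.cutpoint_method!r}")


def _from_dict(data: dict) -> PipelineConfig:
    def check_keys(d: dict, allowed: list[str], where: str) -> None:
        problems = []
        for key in d:
            if key not in allowed:
                hint = difflib.get_close_matches(key, allowed, n=1)
                suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
                problems.append(f"unknown key {key!r} in {where}{suffix}")
        if problems:
            raise ValueError("; ".join(problems))

    top_allowed = [f.name for f in dataclasses.fields(PipelineConfig)]
    check_keys(data, top_allowed, "config")
    kwargs = dict(data)
    if "synthetic" in kwargs and kwargs["synthetic"] is not None:
        syn = kwargs["synthetic"]
        check_keys(syn, [f.name for f in dataclasses.fields(SyntheticSettings)], "synthetic")
        kwargs["synthetic"] = SyntheticSettings(**syn)
    if "ppfs" in kwargs and kwargs["ppfs"] is not None:
        pp = kwargs["ppfs"]
        check_keys(pp, [f.name for f in dataclasses.fields(PpfsConfig)], "ppfs")
        kwargs["ppfs"] = PpfsConfig(**pp)
    return PipelineConfig(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse + validate a TOML (or YAML) config file into a PipelineConfig."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = tomllib.loads(text)
    if not isinstance(data, dict):
        raise ValueError("config file must define a table/mapping")
    return _from_dict(data)


def _f1(selected: set[str], truth: set[str]) -> float:
    if not selected or not truth:
        return 0.0
    tp = len(selected & truth)
    prec = tp / len(selected)
    rec = tp / len(truth)
    return 0.0 if tp == 0 else 2 * prec * rec / (prec + rec)


def run(config: PipelineConfig) -> dict:
    """Execute every stage and write artifacts + a run manifest.

    Returns the manifest dict. A stage failure is re-raised with the
    stage name; artifacts of earlier stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
    }
    stage = "load"
    try:
        t0 = time.time()
        truth = None
        if config.synthetic is not None:
            syn = config.synthetic
            truth = datagen.build_truth(syn.n_signal, syn.n_noise, seed=config.seed)
            cohort = datagen.sample_cohort(
                truth, syn.n_tumor, syn.n_normal_a, syn.n_normal_b, seed=config.seed + 1
            )
            cohort.annotation = datagen.sample_clinical(cohort, seed=config.seed + 2)
            expr, ann = cohort.expression, cohort.annotation
            truth.to_json(out / "truth.json")
        else:
            expr = dataio.read_expression(config.expression_path)
            ann = dataio.read_annotation(config.annotation_path)
        dataio.write_expression(expr, out / "expression.tsv")
        dataio.write_annotation(ann, out / "annotation.tsv")
        labels = dataio.align_labels(expr, ann)
        manifest["stages"][stage] = {
            "n_genes": int(expr.shape[0]),
            "n_samples": int(expr.shape[1]),
            "elapsed_s": round(time.time() - t0, 2),
        }
        log.info("load: %d genes x %d samples", *expr.shape)

        stage = "zero_filter"
        t0 = time.time()
        filtered = dataio.filter_zero_genes(expr)
        manifest["stages"][stage] = {
            "n_genes": int(filtered.shape[0]),
            "removed": int(expr.shape[0] - filtered.shape[0]),
            "elapsed_s": round(time.time() - t0, 2),
        }
        log.info("zero_filter: %d -> %d genes", expr.shape[0], filtered.shape[0])

        stage = "snr_screen"
        t0 = time.time()
        k = min(config.k_screen, filtered.shape[0])
        ranking = snr.rank_and_screen(filtered, labels, k=k)
        ranking.to_csv(out / "snr_ranking.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_screened": int(len(ranking)), "elapsed_s": round(time.time() - t0, 2)}
        log.info("snr_screen: kept top %d genes", len(ranking))

        stage = "ppfs_select"
        t0 = time.time()
        cfg = dataclasses.replace(config.ppfs, seed=config.seed)
        result = snr_ppfs(filtered, labels, k_screen=k, cfg=cfg)
        result.records.to_csv(out / "ppfs_records.tsv", sep="\t", index=False)
        (out / "selected_genes.txt").write_text("\n".join(result.selected) + "\n")
        manifest["stages"][stage] = {
            "n_selected": len(result.selected),
            "n_rejected_at_prune": len(result.rejected_at_prune),
            "elapsed_s": round(time.time() - t0, 2),
        }
        if truth is not None:
            manifest["stages"][stage]["f1_vs_truth"] = round(
                _f1(set(result.selected), set(truth.mb_genes)), 4
            )
        log.info("ppfs_select: %d genes selected", len(result.selected))
        if not result.selected:
            manifest["stages"]["aborted"] = "no genes selected"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            return manifest
        X_sel = filtered.loc[result.selected]

        stage = "downstream_stats"
        t0 = time.time()
        de = expression_stats.differential_expression(X_sel, labels)
        roc_tab = expression_stats.roc_table(X_sel, labels)
        de_roc = de.merge(roc_tab, on="gene_id")
        de_roc.to_csv(out / "de_roc.tsv", sep="\t", index=False)
        pca_scores, evr = expression_stats.pca_embed(X_sel)
        pca_scores.to_csv(out / "pca_scores.tsv", sep="\t")
        plsda_scores = expression_stats.plsda_embed(X_sel, labels)
        plsda_scores.to_csv(out / "plsda_scores.tsv", sep="\t")
        gene_order, sample_order = expression_stats.bicluster_order(X_sel)
        (out / "heatmap_order.json").write_text(
            json.dumps({"genes": gene_order, "samples": sample_order}, indent=1)
        )
        manifest["stages"][stage] = {
            "n_up": int((de["direction"] == "up").sum()),
            "n_down": int((de["direction"] == "down").sum()),
            "pc1_var": round(float(evr[0]), 4),
            "elapsed_s": round(time.time() - t0, 2),
        }
        log.info("downstream_stats: %d up / %d down", *(manifest["stages"][stage][k] for k in ("n_up", "n_down")))

        stage = "bn_structure"
        t0 = time.time()
        net = network.learn_network(
            X_sel,
            de=de,
            include_class=config.include_class,
            labels=labels,
            alpha=config.bn_alpha,
            max_cond=config.bn_max_cond,
        )
        net.export(out / "network")
        manifest["stages"][stage] = {
            "n_directed": len(net.directed),
            "n_undirected": len(net.undirected),
            "elapsed_s": round(time.time() - t0, 2),
        }
        log.info("bn_structure: %d directed + %d undirected edges", len(net.directed), len(net.undirected))

        stage = "survival_stage"
        t0 = time.time()
        tumor_ann = ann[ann["group"] == "tumor"]
        staged = tumor_ann.dropna(subset=["stage"])
        surv_info: dict = {}
        if len(staged) >= 3:
            stage_tab = survival.stage_correlation(
                X_sel[staged["sample_id"].tolist()], staged["stage"].to_numpy(dtype=float)
            )
            stage_tab.to_csv(out / "stage_correlation.tsv", sep="\t", index=False)
            surv_info["n_stage_positive"] = int(stage_tab["stage_positive"].sum())
        with_surv = tumor_ann.dropna(subset=["os_time_days", "os_status"])
        if len(with_surv) >= 10 and with_surv["os_status"].sum() >= 1:
            uni, multi = survival.survival_screen(result.selected, X_sel, tumor_ann)
            uni.to_csv(out / "cox_univariate.tsv", sep="\t", index=False)
            if multi is not None:
                multi.to_csv(out / "cox_multivariate.tsv", sep="\t", index=False)
            surv_info["n_survival_flagged"] = int((uni["flag"] != "none").sum())
        surv_info["elapsed_s"] = round(time.time() - t0, 2)
        manifest["stages"][stage] = surv_info
        log.info("survival_stage: %s", surv_info)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
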