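#!/usr/bin/env python
"""Clinical associations of the signature: stage correlation and survival.

Pearson correlation of each selected gene with ordinal tumor stage,
two-tier univariate Cox screen (significant p<0.05 / trend p<0.1) with
a joint multivariate fit of the flagged genes, and Kaplan-Meier
high/low curves (maximally selected log-rank cutpoint) for the flagged
genes. Writes the tables under results/survival/.
"""

from pathlib import Path

import pandas as pd

from snrppfs import dataio, survival as sv

IN_COHORT = Path("results/cohort")
IN_SIG = Path("results/signature")
OUT = Path("results/survival")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = dataio.read_expression(IN_COHORT / "expression.tsv")
    ann = dataio.read_annotation(IN_COHORT / "annotation.tsv")
    genes = [g for g in (IN_SIG / "selected_genes.txt").read_text().split() if g]
    tumor = ann[ann.group == "tumor"]

    staged = tumor.dropna(subset=["stage"])
    stage_tab = sv.stage_correlation(
        expr.loc[genes, staged.sample_id.tolist()], staged.stage.to_numpy(float)
    )
    stage_tab.to_csv(OUT / "stage_correlation.tsv", sep="\t", index=False)
    pos = stage_tab[stage_tab.stage_positive]
    print(f"stage correlation: {len(pos)}/{len(genes)} genes positively stage-related (p<0.05)")

    uni, multi = sv.survival_screen(genes, expr, tumor)
    uni.to_csv(OUT / "cox_univariate.tsv", sep="\t", index=False)
    flagged = uni[uni.flag != "none"]
    print(f"univariate Cox: {(uni.flag == 'significant').sum()} significant, "
          f"{(uni.flag == 'trend').sum()} trend genes")
    if multi is not None:
        multi.to_csv(OUT / "cox_multivariate.tsv", sep="\t", index=False)
        sig = multi[multi.p_value < 0.05]
        print(f"multivariate Cox over {len(multi)} flagged genes: "
              f"{len(sig)} independent prognostic (p<0.05)")

    with_surv = tumor.dropna(subset=["os_time_days", "os_status"])
    rows = []
    for gene in flagged.term:
        hi, lo = sv.km_and_logrank(
            expr.loc[gene, with_surv.sample_id.tolist()].to_numpy(),
            with_surv.os_time_days.to_numpy(float),
            with_surv.os_status.to_numpy(float),
        )
        rows.append({"gene": gene, "cutpoint": hi.cutpoint, "logrank_p": hi.logrank_p})
        for curve in (hi, lo):
            pd.DataFrame({"time": curve.times, "survival": curve.survival}).to_csv(
                OUT / f"km_{gene}_{curve.label}.tsv", sep="\t", index=False
            )
    if rows:
        pd.DataFrame(rows).to_csv(OUT / "km_summary.tsv", sep="\t", index=False)
        for r in rows:
            print(f"  KM {r['gene']}: cutpoint {r['cutpoint']:.2f}, log-rank p {r['logrank_p']:.3g}")
    print(f"wrote {OUT}/stage_correlation.tsv, cox_*.tsv, km_*.tsv")


if __name__ == "__main__":
    main()
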