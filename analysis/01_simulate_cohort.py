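#!/usr/bin/env python
"""Generate the study's synthetic tumor/normal cohort.

Desk-scale analogue of a combined tumor + two-source-normal colon
expression cohort: 40 planted Markov-blanket genes (parents, children,
co-parents of the class variable) among 960 noise genes; 120 tumor,
20 platform-matched normal and 120 external normal samples; ordinal
stage, demographics and censored survival for the tumor arm.

Writes expression.tsv, annotation.tsv and the ground-truth sidecar
under results/cohort/.
"""

from pathlib import Path

from snrppfs import dataio, datagen

OUT = Path("results/cohort")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = datagen.default_cohort(seed=SEED)
    dataio.write_expression(cohort.expression, OUT / "expression.tsv")
    dataio.write_annotation(cohort.annotation, OUT / "annotation.tsv")
    cohort.truth.to_json(OUT / "truth.json")

    ann = cohort.annotation
    tumor = ann[ann.group == "tumor"]
    print(f"cohort: {cohort.expression.shape[0]} genes x {cohort.expression.shape[1]} samples")
    print(
        f"  tumor {len(tumor)}, normal_a {(ann.subcohort == 'normal_a').sum()}, "
        f"normal_b {(ann.subcohort == 'normal_b').sum()}"
    )
    print(f"  planted Markov blanket: {len(cohort.truth.mb_genes)} genes")
    print(f"  stage distribution: {tumor.stage.value_counts().sort_index().to_dict()}")
    print(f"  events: {int(tumor.os_status.sum())}/{len(tumor)} "
          f"({tumor.os_status.mean():.0%} event rate)")
    print(f"wrote {OUT}/expression.tsv, annotation.tsv, truth.json")


if __name__ == "__main__":
    main()
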