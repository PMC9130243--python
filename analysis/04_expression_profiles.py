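#!/usr/bin/env python
"""Profile the selected signature: DE, ROC, embeddings, bi-clustering.

Moderated-t differential expression with BH adjustment, per-gene ROC
(Mann-Whitney AUC, Youden cutoff), PCA and PLS-DA sample embeddings,
and average-linkage bi-cluster leaf orders for a heatmap. Writes the
combined DE+ROC table and embedding scores under results/profiles/.
"""

import json
from pathlib import Path

from snrppfs import dataio, expression_stats as es

IN_COHORT = Path("results/cohort")
IN_SIG = Path("results/signature")
OUT = Path("results/profiles")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = dataio.read_expression(IN_COHORT / "expression.tsv")
    ann = dataio.read_annotation(IN_COHORT / "annotation.tsv")
    labels = dataio.align_labels(expr, ann)
    genes = [g for g in (IN_SIG / "selected_genes.txt").read_text().split() if g]
    X = expr.loc[genes]

    de = es.differential_expression(X, labels)
    roc_tab = es.roc_table(X, labels)
    table = de.merge(roc_tab, on="gene_id").sort_values("logFC", ascending=False)
    table.to_csv(OUT / "de_roc.tsv", sep="\t", index=False)
    n_up = (table.direction == "up").sum()
    print(f"differential expression: {n_up} up / {len(table) - n_up} down of {len(table)}")
    print(f"  logFC range {table.logFC.min():.2f} .. {table.logFC.max():.2f}")
    print(f"  per-gene AUC range {table.auc.min():.3f} .. {table.auc.max():.3f}")

    pca_scores, evr = es.pca_embed(X)
    pca_scores.to_csv(OUT / "pca_scores.tsv", sep="\t")
    print(f"PCA: PC1 {evr[0]:.1%}, PC2 {evr[1]:.1%} of variance")

    pls_scores = es.plsda_embed(X, labels)
    pls_scores.to_csv(OUT / "plsda_scores.tsv", sep="\t")
    tum = pls_scores.loc[[l == "tumor" for l in labels], "comp1"]
    nrm = pls_scores.loc[[l == "normal" for l in labels], "comp1"]
    sep = tum.min() > nrm.max() or tum.max() < nrm.min()
    print(f"PLS-DA: classes {'fully separated' if sep else 'overlap'} on component 1")

    gene_order, sample_order = es.bicluster_order(X)
    (OUT / "heatmap_order.json").write_text(
        json.dumps({"genes": gene_order, "samples": sample_order}, indent=1)
    )
    print(f"wrote {OUT}/de_roc.tsv, pca_scores.tsv, plsda_scores.tsv, heatmap_order.json")


if __name__ == "__main__":
    main()
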