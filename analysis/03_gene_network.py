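#!/usr/bin/env python
"""Learn the PC-stable CPDAG over the selected genes.

Fisher-z conditional-independence tests on the selected genes'
expression, PC-stable skeleton, v-structure + Meek orientation; nodes
annotated with their differential-expression direction. Exports edge
list, node annotation, GraphML and DOT under results/network/.
"""

from pathlib import Path

from snrppfs import dataio, expression_stats, network

IN_COHORT = Path("results/cohort")
IN_SIG = Path("results/signature")
OUT = Path("results/network")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = dataio.read_expression(IN_COHORT / "expression.tsv")
    ann = dataio.read_annotation(IN_COHORT / "annotation.tsv")
    labels = dataio.align_labels(expr, ann)
    genes = [g for g in (IN_SIG / "selected_genes.txt").read_text().split() if g]
    X = expr.loc[genes]

    de = expression_stats.differential_expression(X, labels)
    net = network.learn_network(X, de=de, alpha=0.05, max_cond=3)
    net.export(OUT / "network")

    up = sum(1 for a in net.annotations.values() if a == "up")
    down = sum(1 for a in net.annotations.values() if a == "down")
    print(f"network over {len(net.nodes)} genes ({up} up / {down} down):")
    print(f"  {len(net.directed)} directed, {len(net.undirected)} undirected edges")
    if net.conflicts:
        print(f"  {len(net.conflicts)} conflicting v-structure demands (skipped; "
              "edges may still orient during Meek closure)")
    cross = [
        (u, v)
        for u, v in net.edge_table()[["source", "target"]].itertuples(index=False)
        if net.annotations.get(u) != net.annotations.get(v)
    ]
    print(f"  {len(cross)} edges connect up- with down-regulated genes")
    print(f"wrote {OUT}/network.(edges.tsv|nodes.tsv|graphml|dot)")


if __name__ == "__main__":
    main()
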