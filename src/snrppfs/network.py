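"""Constraint-based structure learning over selected genes (PC-stable).

Conditional independence is tested with Fisher's z on partial
correlations, the skeleton is learned with the order-independent
PC-stable rule (neighbor sets frozen at the start of each level), and
the skeleton is oriented into a CPDAG via v-structure detection plus
Meek rules 1-4. A binary class column may be appended as an extra node
(point-biserial approximation inside the same Fisher-z machinery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

CLASS_NODE = "class"


@dataclass
class CITestResult:
    i: str
    j: str
    cond_set: tuple[str, ...]
    r: float
    z: float
    p_value: float
    independent: bool


@dataclass
class GeneNetwork:
    """CPDAG over genes: directed + undirected edges, with provenance."""

    nodes: list[str]
    directed: set[tuple[str, str]]  # (u, v) means u -> v
    undirected: set[frozenset]
    sepsets: dict[frozenset, tuple[str, ...]]
    annotations: dict[str, str] = field(default_factory=dict)  # up / down / class
    conflicts: list[tuple[str, str]] = field(default_factory=list)

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.directed or (v, u) in self.directed or frozenset((u, v)) in self.undirected

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "directed": True}
            for u, v in sorted(self.directed)
        ] + [
            {"source": a, "target": b, "directed": False}
            for a, b in sorted(tuple(sorted(e)) for e in self.undirected)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "directed"])

    def export(self, prefix: str | Path) -> None:
        """Write edge-list TSV, node-annotation TSV, DOT and GraphML files."""
        prefix = Path(prefix)
        self.edge_table().to_csv(prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {"node": self.nodes, "annotation": [self.annotations.get(n, "") for n in self.nodes]}
        ).to_csv(prefix.with_suffix(".nodes.tsv"), sep="\t", index=False)
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n, annotation=self.annotations.get(n, ""))
        for u, v in self.directed:
            g.add_edge(u, v, directed="true")
        for e in self.undirected:
            a, b = sorted(e)
            g.add_edge(a, b, directed="false")
        nx.write_graphml(g, prefix.with_suffix(".graphml"))
        with open(prefix.with_suffix(".dot"), "w") as fh:
            fh.write("digraph cpdag {\n")
            for n in self.nodes:
                fh.write(f'  "{n}";\n')
            for u, v in sorted(self.directed):
                fh.write(f'  "{u}" -> "{v}";\n')
            for e in sorted(tuple(sorted(x)) for x in self.undirected):
                fh.write(f'  "{e[0]}" -> "{e[1]}" [dir=none];\n')
            fh.write("}\n")


def fisher_z_test(
    i: str,
    j: str,
    S: Sequence[str],
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> CITestResult:
    """Fisher-z conditional independence test of rows i, j given S.

    ``data`` is variables x samples. The partial correlation comes from
    the inverse of the correlation submatrix; the z statistic is
    0.5*ln((1+r)/(1-r))*sqrt(n - |S| - 3) with a two-sided normal p.
    """
    S = tuple(S)
    n = data.shape[1]
    if n <= len(S) + 3:
        raise ValueError(f"need n > |S| + 3 (n={n}, |S|={len(S)})")
    sub = data.loc[[i, j, *S]].to_numpy()
    corr = np.corrcoef(sub)
    if np.isnan(corr).any():
        raise FloatingPointError(f"constant variable among {(i, j, *S)}")
    if len(S) == 0:
        r = corr[0, 1]
    else:
        try:
            prec = np.linalg.inv(corr)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(f"singular correlation submatrix for {(i, j, *S)}") from exc
        r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        z, p = np.inf * np.sign(r), 0.0
    else:
        z = 0.5 * np.log((1 + r) / (1 - r)) * np.sqrt(n - len(S) - 3)
        p = 2.0 * stats.norm.sf(abs(z))
    return CITestResult(i=i, j=j, cond_set=S, r=r, z=float(z), p_value=float(p), independent=p > alpha)


def pc_stable_skeleton(
    data: pd.DataFrame,
    alpha: float = 0.05,
    max_cond: int = 3,
) -> tuple[dict[str, set[str]], dict[frozenset, tuple[str, ...]], list[CITestResult]]:
    """Learn the undirected skeleton with the PC-stable rule.

    At each level l the neighbor sets used for conditioning are frozen
    at the start of the level, making the result independent of node
    order. The first separating set found for a pair is recorded.
    Returns (adjacency, sepsets, removal-test log).
    """
    nodes = sorted(data.index)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepsets: dict[frozenset, tuple[str, ...]] = {}
    removals: list[CITestResult] = []

    for level in range(max_cond + 1):
        frozen = {v: sorted(adj[v]) for v in nodes}
        if not any(len(frozen[v]) - 1 >= level for v in nodes):
            break
        for i in nodes:
            for j in frozen[i]:
                if i >= j or j not in adj[i]:
                    continue
                removed = False
                for base in (i, j):
                    other = j if base == i else i
                    pool = [v for v in frozen[base] if v != other]
                    if len(pool) < level:
                        continue
                    for S in combinations(pool, level):
                        res = fisher_z_test(base, other, S, data, alpha=alpha)
                        if res.independent:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            sepsets[frozenset((i, j))] = S
                            removals.append(res)
                            removed = True
                            break
                    if removed:
                        break
    return adj, sepsets, removals


def orient_cpdag(
    adj: Mapping[str, set[str]],
    sepsets: Mapping[frozenset, tuple[str, ...]],
) -> GeneNetwork:
    """Orient a skeleton into a CPDAG: v-structures then Meek rules 1-4.

    Conflicting orientation demands leave the edge undirected and are
    logged in ``conflicts``.
    """
    nodes = sorted(adj)
    undirected: set[frozenset] = set()
    directed: set[tuple[str, str]] = set()
    conflicts: list[tuple[str, str]] = []
    for v in nodes:
        for w in adj[v]:
            undirected.add(frozenset((v, w)))

    def adjacent(a: str, b: str) -> bool:
        return frozenset((a, b)) in undirected or (a, b) in directed or (b, a) in directed

    # v-structures: i - k - j with i, j non-adjacent and k not in sepset(i, j)
    demands: dict[tuple[str, str], int] = {}
    for k in nodes:
        nbrs = sorted(adj[k])
        for i, j in combinations(nbrs, 2):
            if j in adj[i]:
                continue
            if k not in sepsets.get(frozenset((i, j)), ()):
                demands[(i, k)] = demands.get((i, k), 0) + 1
                demands[(j, k)] = demands.get((j, k), 0) + 1
    for (a, b), _ in sorted(demands.items()):
        if (b, a) in demands:  # both directions demanded: conflict, keep undirected
            if (a, b) not in conflicts and (b, a) not in conflicts:
                conflicts.append((a, b))
            continue
        if frozenset((a, b)) in undirected:
            undirected.discard(frozenset((a, b)))
            directed.add((a, b))

    def orient(a: str, b: str) -> bool:
        e = frozenset((a, b))
        if e in undirected:
            undirected.discard(e)
            directed.add((a, b))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in sorted(tuple(sorted(x)) for x in undirected):
            for a, b in (e, e[::-1]):
                # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
                if any((c, a) in directed and not adjacent(c, b) for c in nodes if c not in (a, b)):
                    changed |= orient(a, b)
                    break
                # R2: a -> c -> b and a - b  =>  a -> b
                if any((a, c) in directed and (c, b) in directed for c in nodes if c not in (a, b)):
                    changed |= orient(a, b)
                    break
                # R3: a - c -> b, a - d -> b, c and d non-adjacent  =>  a -> b
                cands = [
                    c
                    for c in nodes
                    if c not in (a, b) and frozenset((a, c)) in undirected and (c, b) in directed
                ]
                if any(not adjacent(c, d) for c, d in combinations(sorted(cands), 2)):
                    changed |= orient(a, b)
                    break
                # R4: a - c, c -> d, d -> b, c and b non-adjacent  =>  a -> b
                if any(
                    adjacent(a, c)
                    and any((c, d) in directed and (d, b) in directed for d in nodes if d not in (a, b, c))
                    and not adjacent(c, b)
                    for c in nodes
                    if c not in (a, b)
                ):
                    changed |= orient(a, b)
                    break
            if changed:
                break

    return GeneNetwork(
        nodes=nodes,
        directed=directed,
        undirected=undirected,
        sepsets=dict(sepsets),
        conflicts=conflicts,
    )


def learn_network(
    X: pd.DataFrame,
    de: pd.DataFrame | None = None,
    include_class: bool = False,
    labels: Sequence | None = None,
    alpha: float = 0.05,
    max_cond: int = 3,
) -> GeneNetwork:
    """PC-stable CPDAG over the genes of ``X`` (vars x samples).

    With ``include_class`` the binary tumor indicator is appended as an
    extra node. Node annotations come from the ``direction`` column of a
    differential-expression table (up/down), the class node is tagged
    ``class``.
    """
    data = X.copy()
    if include_class:
        if labels is None:
            raise ValueError("include_class requires group labels")
        data.loc[CLASS_NODE] = (np.asarray(labels) == "tumor").astype(float)
    adj, sepsets, _ = pc_stable_skeleton(data, alpha=alpha, max_cond=max_cond)
    net = orient_cpdag(adj, sepsets)
    if de is not None:
        direction = de.set_index("gene_id")["direction"]
        for n in net.nodes:
            if n == CLASS_NODE:
                net.annotations[n] = "class"
            elif n in direction.index:
                net.annotations[n] = str(direction[n])
    elif include_class:
        net.annotations[CLASS_NODE] = "class"
    return net


# ---------------------------------------------------------------------------
# DAG <-> CPDAG utilities (used for planted-truth evaluation)
# ---------------------------------------------------------------------------


def dag_to_cpdag(dag: nx.DiGraph) -> GeneNetwork:
    """The CPDAG (Markov equivalence class) of a DAG.

    Skeleton + v-structures of the DAG, closed under Meek rules; exact
    sepsets are taken from the DAG's non-adjacent pairs (any separating
    set works for v-structure detection, we use the parents of the later
    node, which d-separate non-adjacent pairs in the chosen ordering).
    """
    nodes = sorted(dag.nodes)
    adj = {v: {w for w in nodes if dag.has_edge(v, w) or dag.has_edge(w, v)} for v in nodes}
    sepsets: dict[frozenset, tuple[str, ...]] = {}
    order = list(nx.topological_sort(dag))
    pos = {v: k for k, v in enumerate(order)}
    for i, j in combinations(nodes, 2):
        if j in adj[i]:
            continue
        later = i if pos[i] > pos[j] else j
        sepsets[frozenset((i, j))] = tuple(sorted(dag.predecessors(later)))
    return orient_cpdag(adj, sepsets)


def structural_hamming_distance(a: GeneNetwork, b: GeneNetwork) -> int:
    """SHD between two partially directed graphs over the same nodes.

    One point per pair whose edge presence or orientation differs
    (missing vs present, undirected vs directed, or reversed).
    """

    def mark(net: GeneNetwork, u: str, v: str) -> str:
        if (u, v) in net.directed:
            return ">"
        if (v, u) in net.directed:
            return "<"
        if frozenset((u, v)) in net.undirected:
            return "-"
        return "."

    nodes = sorted(set(a.nodes) | set(b.nodes))
    return sum(
        1 for u, v in combinations(nodes, 2) if mark(a, u, v) != mark(b, u, v)
    )
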