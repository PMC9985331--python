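"""Pruned co-expression network around a seed gene.

The network shows the top positively correlated genes of a seed lncRNA.
Construction: take the seed plus its ``n_top`` best positive correlates as
nodes; initialize edges as the union, over nodes, of each node's three
highest-weight incident correlations within the node set; drop edges below a
weight floor; then iteratively prune hub nodes (degree above a threshold) by
removing their lowest-weight edge until the average degree falls below a
target. The seed's few best edges are protected throughout so the query gene
never becomes disconnected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .coexpression import CorrelationMatrix
from .io_formats import GeneAnnotation

__all__ = ["Network", "build_network"]


@dataclass
class Network:
    """Weighted undirected co-expression graph with a flagged seed node."""

    graph: nx.Graph
    seed: str
    warnings: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), float(d["weight"]))
            for u, v, d in self.graph.edges(data=True)
        )

    @property
    def average_degree(self) -> float:
        n = self.graph.number_of_nodes()
        return 2.0 * self.graph.number_of_edges() / n if n else 0.0

    def to_node_link(self) -> dict:
        return {
            "nodes": [
                {
                    "id": n,
                    "chromosome": self.graph.nodes[n].get("chromosome"),
                    "is_seed": bool(self.graph.nodes[n].get("is_seed", False)),
                }
                for n in self.nodes
            ],
            "edges": [
                {"source": u, "target": v, "weight": w} for u, v, w in self.edges
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_node_link(), fh, indent=1, sort_keys=True)

    def save_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in self.edges:
                fh.write(f"{u}\t{v}\t{w:.10g}\n")


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def build_network(
    c: CorrelationMatrix,
    seed: str,
    ann: GeneAnnotation | None = None,
    n_top: int = 100,
    min_weight: float = 0.3,
    init_edges_per_node: int = 3,
    hub_degree: int = 10,
    target_avg_degree: float = 3.0,
    seed_keep: int = 5,
) -> Network:
    """Build and prune the co-expression network around ``seed``.

    Deterministic: all weight ties break lexicographically on the (sorted)
    gene pair. The seed's ``seed_keep`` highest-weight edges within the node
    set are protected — exempt from both the ``min_weight`` cut and pruning.
    Pruning removes, per round, the lowest-weight non-protected edge of every
    node whose degree exceeds ``hub_degree`` (or the single globally weakest
    non-protected edge when no hub exists) until the average degree drops
    below ``target_avg_degree`` or only protected edges remain.
    """
    if seed not in c:
        raise KeyError(f"seed gene {seed!r} not in correlation matrix")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")

    row = c.row(seed).drop(labels=[seed])
    positives = row[row > 0]
    notes: list[str] = []
    g = nx.Graph()
    g.add_node(seed, is_seed=True, chromosome=ann.chromosome(seed) if ann else None)
    if positives.empty:
        notes.append(f"seed {seed!r} has no positive correlates; single-node network")
        warnings.warn(notes[-1])
        return Network(g, seed, notes)

    correlates = sorted(positives.items(), key=lambda kv: (-kv[1], kv[0]))[:n_top]
    nodes = [seed] + [gene for gene, _ in correlates]
    for gene in nodes[1:]:
        g.add_node(gene, is_seed=False, chromosome=ann.chromosome(gene) if ann else None)

    sub = c.data.loc[nodes, nodes]

    # Per-node top incident edges within the node set initialize the graph.
    candidate_edges: dict[tuple[str, str], float] = {}
    for u in nodes:
        incident = sub.loc[u].drop(labels=[u])
        best = sorted(incident.items(), key=lambda kv: (-kv[1], kv[0]))[:init_edges_per_node]
        for v, w in best:
            candidate_edges.setdefault(_edge_key(u, v), float(w))

    # Seed protection: its best seed_keep edges, chosen before any dropping.
    seed_incident = sub.loc[seed].drop(labels=[seed])
    protected = {
        _edge_key(seed, v)
        for v, _ in sorted(seed_incident.items(), key=lambda kv: (-kv[1], kv[0]))[:seed_keep]
    }
    for u, v in protected:
        candidate_edges.setdefault((u, v), float(sub.at[u, v]))

    for (u, v), w in candidate_edges.items():
        if w >= min_weight or (u, v) in protected:
            g.add_edge(u, v, weight=w)

    def avg_degree() -> float:
        return 2.0 * g.number_of_edges() / g.number_of_nodes()

    def removable(node: str | None = None):
        edges = g.edges(node, data=True) if node else g.edges(data=True)
        pool = [
            (float(d["weight"]), _edge_key(u, v))
            for u, v, d in edges
            if _edge_key(u, v) not in protected
        ]
        return min(pool) if pool else None

    while avg_degree() >= target_avg_degree:
        hubs = sorted(n for n in g.nodes if g.degree(n) > hub_degree)
        to_remove: set[tuple[str, str]] = set()
        if hubs:
            for h in hubs:
                worst = removable(h)
                if worst is not None:
                    to_remove.add(worst[1])
        else:
            worst = removable()
            if worst is not None:
                to_remove.add(worst[1])
        if not to_remove:
            notes.append("only protected edges remain; stopping above target degree")
            break
        for u, v in to_remove:
            if g.has_edge(u, v):
                g.remove_edge(u, v)

    return Network(g, seed, notes)
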