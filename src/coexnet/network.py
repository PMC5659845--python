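"""Hit-to-hit coexpression network: construction, connectivity, prediction, export.

For every hit gene found in the partner database, the (K+1) x (K+1) ordered
pairs over its neighborhood (the hit itself plus its K partners) are
enumerated as connection slots; 250 hits at K=40 therefore enumerate
250 x 41 x 41 = 420,250 slots.  A slot materializes an undirected edge only
when both members are hit genes; its weight accumulates the pair's
multiplicities over every neighborhood that contains it.  Non-hit genes that
are most connected to the hits can be integrated as "predicted" nodes, and
the whole network is exported in Cytoscape-ready SIF + attribute-table form.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .coexdb import CoexpressionDatabase
from .expression import HitList, color_bin

logger = logging.getLogger("coexnet")

ROLE_HIT = "hit"
ROLE_PREDICTED = "predicted"

#: Cluster label for nodes outside every marked cluster.
LABEL_OUTSIDE = "0"
#: Cluster label for hits absent from the coexpression database.
LABEL_ABSENT = "-"


@dataclass
class ConnectionNetwork:
    """Weighted undirected graph over hit (and optionally predicted) genes.

    ``considered_pairs`` counts every enumerated connection slot, materialized
    or not: ``|hits with a db entry| * (K+1)**2``.
    """

    graph: nx.Graph
    considered_pairs: int
    K: int

    def hit_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["role"] == ROLE_HIT]

    def predicted_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["role"] == ROLE_PREDICTED]

    def total_edge_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def _neighborhood_members(
    db: CoexpressionDatabase, hit: str
) -> dict[str, int] | None:
    """Hit's neighborhood as member -> multiplicity (the hit itself counts 1);
    None when the database does not know the gene."""
    nb = db.neighborhood(hit)
    if nb.absent:
        return None
    members: dict[str, int] = {hit: 1}
    for partner, mult in nb.partners:
        members[partner] = members.get(partner, 0) + mult
    return members


def build_network(hits: HitList | Sequence[str], db: CoexpressionDatabase) -> ConnectionNetwork:
    """Construct the hit-to-hit connection network.

    Every hit with a database entry contributes (K+1)**2 enumerated slots.
    An undirected edge (a, b) appears when a != b, both are hits, and both
    lie in some enumerated neighborhood; each such neighborhood adds the
    product of the two members' multiplicities to the edge weight (the
    neighborhood's own hit has multiplicity 1).  Hits missing from the
    database become isolated nodes flagged ``db_absent``.
    """
    hit_genes = tuple(hits.genes) if isinstance(hits, HitList) else tuple(hits)
    if not hit_genes:
        raise ValueError("hit list is empty")
    hit_set = set(hit_genes)

    g = nx.Graph()
    considered = 0
    for h in hit_genes:
        members = _neighborhood_members(db, h)
        g.add_node(h, role=ROLE_HIT, db_absent=members is None)
        if members is None:
            continue
        considered += (db.K + 1) ** 2
        hit_members = sorted(m for m in members if m in hit_set)
        for i, a in enumerate(hit_members):
            for b in hit_members[i + 1 :]:
                w = members[a] * members[b]
                if g.has_edge(a, b):
                    g[a][b]["weight"] += w
                else:
                    g.add_edge(a, b, weight=w)
    return ConnectionNetwork(graph=g, considered_pairs=considered, K=db.K)


def hit_inclusion_fraction(net: ConnectionNetwork) -> float:
    """Percentage of hit genes with at least one edge to another hit gene."""
    hits = net.hit_nodes()
    if not hits:
        raise ValueError("network has no hit nodes")
    hit_set = set(hits)
    included = sum(
        1 for h in hits if any(nb in hit_set for nb in net.graph.neighbors(h))
    )
    return 100.0 * included / len(hits)


def connections_per_hit(net: ConnectionNetwork) -> float:
    """Average summed incident edge weight per hit gene."""
    hits = net.hit_nodes()
    if not hits:
        raise ValueError("network has no hit nodes")
    total = sum(
        sum(d["weight"] for _, _, d in net.graph.edges(h, data=True)) for h in hits
    )
    return total / len(hits)


def predict_genes(
    hits: HitList | Sequence[str],
    db: CoexpressionDatabase,
    m: int = 50,
) -> tuple[list[str], bool]:
    """The m non-hit genes most connected to the hit neighborhoods.

    A non-hit gene's count sums its multiplicities over every hit
    neighborhood listing it.  Returned in descending count order with
    lexicographic tie-break; only genes with count >= 1 qualify.  The second
    element flags a shortfall (fewer than m connected non-hit genes exist).
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    hit_genes = tuple(hits.genes) if isinstance(hits, HitList) else tuple(hits)
    hit_set = set(hit_genes)
    counts: dict[str, int] = {}
    for h in hit_genes:
        members = _neighborhood_members(db, h)
        if members is None:
            continue
        for gene, mult in members.items():
            if gene not in hit_set:
                counts[gene] = counts.get(gene, 0) + mult
    ordered = sorted(counts, key=lambda gene: (-counts[gene], gene))
    shortfall = len(ordered) < m
    if shortfall:
        logger.warning("predict_genes: only %d connected non-hit genes (< m=%d)", len(ordered), m)
    return ordered[:m], shortfall


def integrate_predicted(
    net: ConnectionNetwork,
    predicted: Sequence[str],
    hits: HitList | Sequence[str],
    db: CoexpressionDatabase,
) -> ConnectionNetwork:
    """Add predicted genes as nodes with edges to the hits whose neighborhoods
    list them (weight = the listed multiplicity, summed across neighborhoods)."""
    hit_genes = tuple(hits.genes) if isinstance(hits, HitList) else tuple(hits)
    hit_set = set(hit_genes)
    pred_set = set(predicted)
    g = net.graph
    for p in predicted:
        g.add_node(p, role=ROLE_PREDICTED, db_absent=p not in db)
    for h in hit_genes:
        members = _neighborhood_members(db, h)
        if members is None:
            continue
        for gene, mult in members.items():
            if gene in pred_set:
                if g.has_edge(h, gene):
                    g[h][gene]["weight"] += mult
                else:
                    g.add_edge(h, gene, weight=mult)
    orphans = [p for p in predicted if g.degree(p) == 0]
    if orphans:
        # cannot happen for genes chosen by predict_genes; guard for manual lists
        logger.warning("removing %d predicted genes with no hit connection", len(orphans))
        g.remove_nodes_from(orphans)
    return net


@dataclass
class ClusterAssignment:
    """Node -> cluster label.

    Numbered labels ("1", "2", ...) mark clusters of at least ``min_size``
    genes; "0" marks nodes outside every marked cluster; "-" marks hits the
    database does not contain; "+"-joined labels (e.g. "1+2") mark nodes
    bridging two marked clusters.
    """

    labels: dict[str, str]
    min_size: int

    def members(self, label: str) -> set[str]:
        return {n for n, lab in self.labels.items() if lab == label}

    def numbered_labels(self) -> list[str]:
        nums = {lab for lab in self.labels.values() if lab.isdigit() and lab != LABEL_OUTSIDE}
        return sorted(nums, key=int)


def assign_clusters(
    net: ConnectionNetwork,
    min_size: int = 3,
    *,
    refine: bool = False,
    override: Mapping[str, str] | None = None,
) -> ClusterAssignment:
    """Deterministic cluster labels from network structure.

    Connected components of at least ``min_size`` nodes become numbered
    clusters, ordered by decreasing size (lexicographically smallest member
    breaks ties).  With ``refine=True`` each large component is further split
    by greedy modularity maximisation; nodes left outside every refined
    cluster but adjacent to two or more of them get a "+"-joined label.
    ``override`` forces labels for individual nodes (e.g. manually curated
    assignments).
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    g = net.graph
    labels: dict[str, str] = {}
    for node, data in g.nodes(data=True):
        labels[node] = LABEL_ABSENT if data.get("db_absent") else LABEL_OUTSIDE

    groups: list[set[str]] = []
    for comp in nx.connected_components(g):
        if len(comp) < min_size or len(comp) < 2:
            continue
        if refine:
            sub = g.subgraph(comp)
            communities = nx.algorithms.community.greedy_modularity_communities(
                sub, weight="weight"
            )
            groups.extend(set(c) for c in communities if len(c) >= min_size)
        else:
            groups.append(set(comp))
    groups.sort(key=lambda c: (-len(c), min(c)))
    for i, group in enumerate(groups, start=1):
        for node in group:
            labels[node] = str(i)

    if refine:
        numbered = {n: lab for n, lab in labels.items() if lab.isdigit() and lab != LABEL_OUTSIDE}
        for node, lab in list(labels.items()):
            if lab != LABEL_OUTSIDE:
                continue
            touching = sorted(
                {numbered[nb] for nb in g.neighbors(node) if nb in numbered}, key=int
            )
            if len(touching) >= 2:
                labels[node] = "+".join(touching)

    if override:
        labels.update({n: str(lab) for n, lab in override.items() if n in labels})
    return ClusterAssignment(labels=labels, min_size=min_size)


def export_network(
    net: ConnectionNetwork,
    clusters: ClusterAssignment,
    out_prefix: str | Path,
    *,
    node_means: Mapping[str, float] | None = None,
    manifest: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write Cytoscape-ready files: ``<prefix>.sif`` (edges), ``<prefix>.edges.tsv``
    (weights), ``<prefix>.nodes.tsv`` (attributes) and ``<prefix>.manifest.json``.

    Returns the written paths keyed by kind.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": Path(str(prefix) + ".sif"),
        "edges": Path(str(prefix) + ".edges.tsv"),
        "nodes": Path(str(prefix) + ".nodes.tsv"),
        "manifest": Path(str(prefix) + ".manifest.json"),
    }
    edges = sorted(
        (min(a, b), max(a, b), d["weight"]) for a, b, d in net.graph.edges(data=True)
    )
    with open(paths["sif"], "w") as fh:
        for a, b, _ in edges:
            fh.write(f"{a}\tcoex\t{b}\n")
    pd.DataFrame(edges, columns=["geneA", "geneB", "weight"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    rows = []
    for node in sorted(net.graph.nodes):
        data = net.graph.nodes[node]
        mean = node_means.get(node) if node_means else None
        rows.append(
            {
                "gene": node,
                "role": data["role"],
                "mean_log2_diff": mean,
                "color_bin": color_bin(mean) if mean is not None else "NA",
                "cluster": clusters.labels.get(node, LABEL_OUTSIDE),
                "db_absent": data.get("db_absent", False),
            }
        )
    pd.DataFrame(
        rows, columns=["gene", "role", "mean_log2_diff", "color_bin", "cluster", "db_absent"]
    ).to_csv(paths["nodes"], sep="\t", index=False, na_rep="NA")
    payload = {
        "considered_pairs": net.considered_pairs,
        "K": net.K,
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        **(dict(manifest) if manifest else {}),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_exported_edges(out_prefix: str | Path) -> dict[tuple[str, str], int]:
    """Re-import an exported edge table as {(geneA, geneB): weight} with
    lexicographically ordered pairs (round-trip check for exports)."""
    df = pd.read_csv(Path(str(out_prefix) + ".edges.tsv"), sep="\t", dtype={"weight": int})
    return {
        (min(a, b), max(a, b)): int(w)
        for a, b, w in zip(df["geneA"], df["geneB"], df["weight"])
    }
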