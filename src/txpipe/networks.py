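"""Interaction and co-expression networks.

Three constructions share one :class:`Network` wrapper around a networkx
graph: the pathway interaction network (significant pathways, typed edges),
the typed gene interaction network restricted to DEGs, and per-group
co-expression networks whose edges are Pearson correlations surviving a
Benjamini-Hochberg FDR cut.  k-core decomposition ranks hub nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RELATION_TYPES = (
    "activation",
    "binding/association",
    "compound",
    "expression",
    "indirect effect",
    "inhibition",
    "missing interaction",
    "phosphorylation",
    "dephosphorylation",
    "ubiquitination",
)

__all__ = [
    "RELATION_TYPES",
    "RelationTable",
    "Network",
    "pathway_act_network",
    "gene_act_network",
    "coexpression_network",
    "bh_fdr",
    "kcore_decompose",
]


@dataclass
class RelationTable:
    """Typed (src, dst, type, directed) relations from a curated source."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"src", "dst", "type"}
        if not required <= set(self.table.columns):
            raise ValueError(f"relation table needs columns {sorted(required)}")
        if "directed" not in self.table.columns:
            self.table = self.table.assign(directed=True)
        bad_types = set(self.table["type"]) - set(RELATION_TYPES)
        if bad_types:
            raise ValueError(f"unknown relation types: {sorted(bad_types)}")
        loops = self.table["src"] == self.table["dst"]
        if loops.any():
            raise ValueError("self-loop relations are not allowed")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RelationTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"src": str, "dst": str, "type": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class Network:
    """Graph plus per-node core numbers; thin wrapper over networkx."""

    graph: nx.Graph | nx.DiGraph
    kind: str  # pathway-act | gene-act | coexpression
    core_numbers: dict[str, int] | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        und = self.graph.to_undirected() if self.graph.is_directed() else self.graph
        return dict(und.degree())

    def central_nodes(self) -> list[str]:
        """Nodes attaining the maximum degree (all ties)."""
        deg = self.degrees()
        if not deg:
            return []
        top = max(deg.values())
        return sorted(n for n, d in deg.items() if d == top)

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v, data in self.graph.edges(data=True):
                rel = data.get("type", data.get("sign", "pp"))
                fh.write(f"{u}\t{rel}\t{v}\n")

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        if self.core_numbers:
            nx.set_node_attributes(g, self.core_numbers, "core")
        nx.write_graphml(g, path)


def pathway_act_network(significant_pathways: list[str] | set[str],
                        relations: RelationTable,
                        p_values: dict[str, float] | None = None) -> Network:
    """Induced subgraph of the pathway relation table on significant pathways.

    Node centrality is plain degree; :meth:`Network.central_nodes` gives the
    top-degree "central" pathways.
    """
    keep = set(significant_pathways)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(keep))
    for row in relations.table.itertuples(index=False):
        if row.src in keep and row.dst in keep:
            g.add_edge(row.src, row.dst, type=row.type)
    if p_values:
        nx.set_node_attributes(g, {n: p_values.get(n) for n in g.nodes if n in p_values}, "p_value")
    return Network(graph=g, kind="pathway-act")


def gene_act_network(deg_calls: dict[str, str], relations: RelationTable) -> Network:
    """Typed interaction subgraph on DEGs; node attribute = up/down call.

    *deg_calls* maps DEG id -> "up"/"down".  Relations touching genes not in
    the DEG set are dropped (count logged).
    """
    degs = set(deg_calls)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(degs))
    nx.set_node_attributes(g, deg_calls, "direction")
    dropped = 0
    for row in relations.table.itertuples(index=False):
        if row.src in degs and row.dst in degs:
            g.add_edge(row.src, row.dst, type=row.type)
        else:
            dropped += 1
    if dropped:
        logger.info("gene_act_network: dropped %d relations with non-DEG endpoints", dropped)
    return Network(graph=g, kind="gene-act")


def correlation_table(values: np.ndarray, gene_ids: list[str]) -> pd.DataFrame:
    """All-pairs Pearson r with two-sided t-test p-values and BH q-values.

    p from t = r sqrt((n-2)/(1-r^2)) on n-2 df.  Zero-variance genes are
    excluded up front (logged).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.info("coexpression: excluded %d zero-variance genes", int((~keep).sum()))
    values = values[keep]
    ids = [g for g, k in zip(gene_ids, keep) if k]
    if len(ids) < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    r = np.corrcoef(values)
    iu, ju = np.triu_indices(len(ids), k=1)
    rv = np.clip(r[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = rv * np.sqrt((n - 2) / np.maximum(1.0 - rv**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.minimum(p, 1.0)
    q = bh_fdr(p)
    return pd.DataFrame({
        "gene_a": [ids[i] for i in iu],
        "gene_b": [ids[j] for j in ju],
        "r": rv,
        "p_value": p,
        "q_value": q,
    })


def coexpression_network(values: np.ndarray, gene_ids: list[str],
                         fdr_threshold: float = 0.05,
                         directions: dict[str, str] | None = None) -> Network:
    """Signed co-expression network for one sample group.

    Edges are gene pairs whose Pearson correlation survives BH FDR <
    *fdr_threshold*; the sign of r is stored as the edge sign ("positive"
    drawn solid, "negative" dotted in the published figures), |r| as weight.
    """
    tab = correlation_table(values, gene_ids)
    g = nx.Graph()
    g.add_nodes_from(tab["gene_a"].tolist() + tab["gene_b"].tolist())
    passing = tab[tab["q_value"] < fdr_threshold]
    for row in passing.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b,
                   sign="positive" if row.r >= 0 else "negative",
                   r=float(row.r), weight=abs(float(row.r)),
                   q_value=float(row.q_value))
    if g.number_of_edges() == 0:
        logger.warning(
            "coexpression_network: no edge passed FDR < %g with %d samples; "
            "consider pooled samples or a looser --edge-alpha",
            fdr_threshold, values.shape[1])
    if directions:
        nx.set_node_attributes(g, {n: directions[n] for n in g.nodes if n in directions},
                               "direction")
    net = Network(graph=g, kind="coexpression")
    net.core_numbers = kcore_decompose(net)[0]
    return net


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def kcore_decompose(net: Network) -> tuple[dict[str, int], set[str]]:
    """Core number per node plus the max-core hub set.

    Iterative minimum-degree peeling on the undirected simple view: a node's
    core number is the largest k such that it survives in the subgraph where
    every node keeps at least k neighbours.  Ties for the maximum core all
    count as hubs.
    """
    g = net.graph.to_undirected() if net.graph.is_directed() else net.graph
    degree = {n: d for n, d in g.degree()}
    core: dict[str, int] = {}
    remaining = set(g.nodes)
    k = 0
    while remaining:
        # peel everything at the current minimum degree level
        min_deg = min(degree[n] for n in remaining)
        k = max(k, min_deg)
        peel = [n for n in remaining if degree[n] <= k]
        while peel:
            node = peel.pop()
            if node not in remaining:
                continue
            core[node] = k
            remaining.discard(node)
            for nb in g.neighbors(node):
                if nb in remaining:
                    degree[nb] -= 1
                    if degree[nb] <= k:
                        peel.append(nb)
    hubs = {n for n, c in core.items() if core and c == max(core.values())} if core else set()
    return core, hubs
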