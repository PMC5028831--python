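"""Ancestor-closed term subgraphs ("GO-trees") from significant terms.

The hierarchy comes in as child->parent edges (OBO-lite TSV; multi-parent
DAGs allowed).  The tree for a namespace contains every significant term
plus all of its ancestors, with ancestors flagged non-significant unless
they are significant themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TermGraph", "build_go_tree", "select_focus_terms"]


@dataclass
class TermGraph:
    """Child->parent DAG over terms with a significance flag per node."""

    graph: nx.DiGraph  # edge child -> parent

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"term hierarchy contains a cycle: {cycle}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def significant_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("significant")}

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)

    def write_dot(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("digraph terms {\n")
            for n, d in self.graph.nodes(data=True):
                shape = "box" if d.get("significant") else "ellipse"
                fh.write(f'  "{n}" [shape={shape}];\n')
            for u, v in self.graph.edges:
                fh.write(f'  "{u}" -> "{v}";\n')
            fh.write("}\n")


def build_go_tree(significant: list[str] | set[str],
                  hierarchy: list[tuple[str, str]],
                  p_values: dict[str, float] | None = None,
                  namespaces: dict[str, str] | None = None) -> TermGraph:
    """Close the significant-term set under ancestry.

    Nodes are the significant terms plus every ancestor reachable through
    the child->parent *hierarchy*; edges are the hierarchy edges restricted
    to that node set.
    """
    parents: dict[str, list[str]] = {}
    for child, parent in hierarchy:
        parents.setdefault(child, []).append(parent)

    significant = set(significant)
    nodes = set(significant)
    stack = list(significant)
    while stack:
        term = stack.pop()
        for parent in parents.get(term, ()):
            if parent not in nodes:
                nodes.add(parent)
                stack.append(parent)

    g = nx.DiGraph()
    for n in sorted(nodes):
        attrs = {"significant": n in significant}
        if p_values and n in p_values:
            attrs["p_value"] = float(p_values[n])
        if namespaces and n in namespaces:
            attrs["namespace"] = namespaces[n]
        g.add_node(n, **attrs)
    for child, plist in parents.items():
        if child in nodes:
            for parent in plist:
                if parent in nodes:
                    g.add_edge(child, parent)
    return TermGraph(graph=g)


def select_focus_terms(tree: TermGraph, patterns: list[str],
                       term_names: dict[str, str],
                       term_genes: dict[str, frozenset[str]],
                       deg_set: set[str]) -> tuple[list[str], pd.DataFrame]:
    """Pick tree terms whose names match any substring pattern and collect
    their DEG memberships.

    Returns (matched term ids, table of gene -> 1-based indices of the
    matched terms that contain it).  Each gene appears once, with all of its
    term indices.
    """
    if not patterns:
        raise ValueError("at least one name pattern required")
    lowered = [p.lower() for p in patterns]
    matched = [t for t in sorted(tree.nodes)
               if t in term_names and any(p in term_names[t].lower() for p in lowered)]
    if not matched:
        logger.warning("select_focus_terms: no term name matched %s", patterns)
        return [], pd.DataFrame(columns=["gene", "term_indices"])
    gene_terms: dict[str, list[int]] = {}
    for idx, term in enumerate(matched, start=1):
        for gene in term_genes.get(term, frozenset()) & deg_set:
            gene_terms.setdefault(gene, []).append(idx)
    table = pd.DataFrame(
        {"gene": sorted(gene_terms),
         "term_indices": [",".join(map(str, sorted(gene_terms[g]))) for g in sorted(gene_terms)]}
    )
    return matched, table
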