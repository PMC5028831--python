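"""Hypergeometric over-representation testing of gene sets against term
annotations (GO-style namespaces and pathways), with raw-P filtering and
top-k reporting.  A chi-square cross-check is available but the one-sided
Fisher/hypergeometric tail is authoritative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GO_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
NAMESPACES = GO_NAMESPACES + ("pathway",)

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "fisher_enrich",
    "chi2_enrich",
    "significant_terms",
    "top_k_report",
    "bh_adjust",
    "read_gmt",
    "GO_NAMESPACES",
    "NAMESPACES",
]


@dataclass
class AnnotationSet:
    """Named term -> gene-set collection with namespaces and hierarchy edges.

    ``terms`` maps term id to ``(name, namespace, gene set)``; ``hierarchy``
    is a list of (child, parent) edges restricted to same-namespace pairs;
    ``universe`` is the background gene set.
    """

    terms: dict[str, tuple[str, str, frozenset[str]]]
    universe: frozenset[str]
    hierarchy: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        for tid, (name, ns, genes) in list(self.terms.items()):
            genes = frozenset(genes)
            if not genes <= self.universe:
                raise ValueError(f"term {tid} has genes outside the universe")
            self.terms[tid] = (name, ns, genes)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents: dict[str, str] = {}
        for child, parent in self.hierarchy:
            parents.setdefault(child, parent)
        for start in parents:
            seen = {start}
            node = start
            while node in parents:
                node = parents[node]
                if node in seen:
                    raise ValueError(f"hierarchy cycle through term {node}")
                seen.add(node)

    def namespace_terms(self, namespace: str) -> list[str]:
        return [t for t, (_, ns, _) in self.terms.items() if ns == namespace]

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][2]

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid, (name, ns, genes) in self.terms.items():
                fields = [tid, f"{name}|{ns}"] + sorted(genes)
                fh.write("\t".join(fields) + "\n")

    def write_hierarchy_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("child\tparent\tnamespace\n")
            for child, parent in self.hierarchy:
                ns = self.terms[child][1]
                fh.write(f"{child}\t{parent}\t{ns}\n")


def read_gmt(path: str | Path, universe=None,
             hierarchy_path: str | Path | None = None) -> AnnotationSet:
    """Read a GMT file whose description field is ``name|namespace``.

    If *universe* is None it is taken as the union of all term gene sets.
    """
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            tid, desc = parts[0], parts[1]
            name, _, ns = desc.partition("|")
            genes = frozenset(g for g in parts[2:] if g)
            terms[tid] = (name, ns or "biological_process", genes)
    if universe is None:
        universe = frozenset().union(*(t[2] for t in terms.values())) if terms else frozenset()
    hierarchy: list[tuple[str, str]] = []
    if hierarchy_path is not None:
        hdf = pd.read_csv(hierarchy_path, sep="\t", dtype=str)
        hierarchy = list(zip(hdf["child"], hdf["parent"]))
    return AnnotationSet(terms=terms, universe=frozenset(universe), hierarchy=hierarchy)


@dataclass
class EnrichmentResult:
    """Per-term 2x2 enrichment table and one-sided p-value."""

    table: pd.DataFrame  # term, name, namespace, subset, k, K, n, N, p_value
    subset_label: str

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and not ((t["k"] <= t[["K", "n"]].min(axis=1)).all() and (t["k"] >= 0).all()):
            raise ValueError("invalid contingency counts: need 0 <= k <= min(K, n)")


def fisher_enrich(deg_set: set[str], annotation: AnnotationSet,
                  subset_label: str = "all") -> EnrichmentResult:
    """One-sided over-representation tail per term.

    P = sum_{i >= k} C(K,i) C(N-K, n-i) / C(N, n), the upper hypergeometric
    tail of observing *k* or more annotated genes among the *n* DEGs.
    Terms with no universe genes (K = 0) are skipped.
    """
    deg_set = set(deg_set)
    if not deg_set <= annotation.universe:
        raise ValueError("DEG set contains genes outside the annotation universe")
    N = len(annotation.universe)
    n = len(deg_set)
    rows = []
    skipped = 0
    for tid, (name, ns, genes) in annotation.terms.items():
        K = len(genes)
        if K == 0:
            skipped += 1
            continue
        k = len(genes & deg_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((tid, name, ns, subset_label, k, K, n, N, min(p, 1.0)))
    if skipped:
        logger.info("fisher_enrich: skipped %d empty terms", skipped)
    table = pd.DataFrame(
        rows,
        columns=["term", "name", "namespace", "subset", "k", "K", "n", "N", "p_value"],
    )
    return EnrichmentResult(table=table, subset_label=subset_label)


def chi2_enrich(k: int, K: int, n: int, N: int) -> float:
    """Yates-corrected chi-square p for one 2x2 table (cross-check only).

    Returns NaN when any expected cell is below 5, where the approximation
    is unreliable and the exact test should be used instead.
    """
    obs = np.array([[k, n - k], [K - k, N - K - (n - k)]], dtype=float)
    if np.any(obs < 0):
        raise ValueError("inconsistent contingency counts")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if np.any(expected < 5):
        return float("nan")
    _, p, _, _ = stats.chi2_contingency(obs, correction=True)
    return float(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (emitted for transparency; the
    enrichment filter itself uses raw P)."""
    from txpipe.networks import bh_fdr

    return bh_fdr(np.asarray(p, float))


def significant_terms(res: EnrichmentResult, p_threshold: float = 0.05) -> pd.DataFrame:
    """Terms with p strictly below threshold, sorted by p then term id."""
    t = res.table
    out = t[t["p_value"] < p_threshold].copy()
    out = out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    return out


def top_k_report(res: EnrichmentResult, k: int = 15,
                 p_threshold: float = 0.05) -> pd.DataFrame:
    """The k most significant terms per namespace (fewer if fewer pass)."""
    sig = significant_terms(res, p_threshold)
    return sig.groupby("namespace", group_keys=False, sort=True).head(k).reset_index(drop=True)


def enrichment_report(deg_sets: dict[str, set[str]],
                      annotation: AnnotationSet) -> pd.DataFrame:
    """Full enrichment table over subsets (e.g. all/up/down) with BH column."""
    frames = []
    for label, genes in deg_sets.items():
        res = fisher_enrich(genes, annotation, subset_label=label)
        tab = res.table.copy()
        if len(tab):
            tab["bh_q"] = bh_adjust(tab["p_value"].to_numpy())
        else:
            tab["bh_q"] = pd.Series(dtype=float)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
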