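"""End-to-end orchestration: quantify -> DE -> enrichment -> ontology tree ->
networks -> qPCR, from one config, with a checksum manifest of every
artifact written.  No stage mutates its inputs; identical config plus
inputs yields a byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from txpipe import diffexpr, enrichment, networks, ontology, qpcr, quantify
from txpipe.enrichment import GO_NAMESPACES

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and conventions for one pipeline run."""

    counts: str
    design: str
    outdir: str
    annotation: str | None = None
    hierarchy: str | None = None
    gene_relations: str | None = None
    pathway_relations: str | None = None
    qpcr_plate: str | None = None
    qpcr_reference_gene: str | None = None
    group1: str | None = None          # calibrator / denominator (QHMM-like)
    group2: str | None = None          # test / numerator (STH-like)
    lfc_threshold: float = 0.585
    de_fdr: float = 0.05
    enrich_p: float = 0.05
    coexpr_fdr: float = 0.05
    coexpr_samples: str = "per-group"  # or "pooled"
    top_k: int = 15
    focus_patterns: list[str] = field(default_factory=list)
    skip_qpcr: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v, lo, hi in [("lfc_threshold", self.lfc_threshold, 0, np.inf),
                                ("de_fdr", self.de_fdr, 0, 1),
                                ("enrich_p", self.enrich_p, 0, 1),
                                ("coexpr_fdr", self.coexpr_fdr, 0, 1)]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside valid range")
        if self.coexpr_samples not in ("per-group", "pooled"):
            raise ValueError("coexpr_samples must be 'per-group' or 'pooled'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", **kw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    thresholds_applied = {
        "lfc_threshold": cfg.lfc_threshold, "de_fdr": cfg.de_fdr,
        "enrich_p": cfg.enrich_p, "coexpr_fdr": cfg.coexpr_fdr,
        "top_k": cfg.top_k,
    }
    logger.info("thresholds: %s", thresholds_applied)

    # ---- quantify -------------------------------------------------------
    counts = quantify.read_counts_tsv(cfg.counts, cfg.design)
    labels = counts.group_labels
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    group1 = cfg.group1 or labels[0]
    group2 = cfg.group2 or next(g for g in labels if g != group1)

    factors = quantify.upper_quartile_factors(counts)
    norm = quantify.normalize_counts(counts, factors)
    expr_rpkm = quantify.rpkm(counts)
    expr_rpkm.write_tsv(outdir / "rpkm.tsv")
    norm.write_tsv(outdir / "normalized_counts.tsv")
    artifacts["rpkm"] = outdir / "rpkm.tsv"
    artifacts["normalized_counts"] = outdir / "normalized_counts.tsv"

    # ---- differential expression ---------------------------------------
    de = diffexpr.run_de(norm, group1, group2,
                         lfc_threshold=cfg.lfc_threshold, fdr_threshold=cfg.de_fdr)
    _write_tsv(de.table, outdir / "de_table.tsv")
    artifacts["de_table"] = outdir / "de_table.tsv"
    deg_calls = de.calls
    up = {g for g, c in deg_calls.items() if c == "up"}
    down = {g for g, c in deg_calls.items() if c == "down"}

    # ---- enrichment -----------------------------------------------------
    sig_terms = pd.DataFrame()
    annotation = None
    if cfg.annotation:
        detected = {g for g, tot in zip(counts.gene_ids, counts.counts.sum(axis=1)) if tot > 0}
        annotation = enrichment.read_gmt(cfg.annotation, universe=None,
                                         hierarchy_path=cfg.hierarchy)
        universe = frozenset(detected & set(annotation.universe)) or annotation.universe
        annotation = enrichment.AnnotationSet(
            terms={t: (n, ns, genes & universe)
                   for t, (n, ns, genes) in annotation.terms.items()},
            universe=universe, hierarchy=annotation.hierarchy)
        deg_sets = {"all": (up | down) & set(universe),
                    "up": up & set(universe), "down": down & set(universe)}
        table = enrichment.enrichment_report(deg_sets, annotation)
        _write_tsv(table, outdir / "enrichment.tsv")
        artifacts["enrichment"] = outdir / "enrichment.tsv"
        all_res = enrichment.EnrichmentResult(
            table=table[table["subset"] == "all"].reset_index(drop=True), subset_label="all")
        sig_terms = enrichment.significant_terms(all_res, cfg.enrich_p)
        _write_tsv(enrichment.top_k_report(all_res, cfg.top_k, cfg.enrich_p),
                   outdir / "top_terms.tsv")
        artifacts["top_terms"] = outdir / "top_terms.tsv"

    # ---- ontology tree --------------------------------------------------
    if cfg.annotation and cfg.hierarchy and len(sig_terms):
        go_sig = sig_terms[sig_terms["namespace"].isin(GO_NAMESPACES)]
        tree = ontology.build_go_tree(
            set(go_sig["term"]), annotation.hierarchy,
            p_values=dict(zip(go_sig["term"], go_sig["p_value"])),
            namespaces={t: ns for t, (_, ns, _) in annotation.terms.items()})
        tree.write_graphml(outdir / "go_tree.graphml")
        tree.write_dot(outdir / "go_tree.dot")
        artifacts["go_tree_graphml"] = outdir / "go_tree.graphml"
        artifacts["go_tree_dot"] = outdir / "go_tree.dot"
        if cfg.focus_patterns:
            matched, table = ontology.select_focus_terms(
                tree, cfg.focus_patterns,
                term_names={t: n for t, (n, _, _) in annotation.terms.items()},
                term_genes={t: genes for t, (_, _, genes) in annotation.terms.items()},
                deg_set=up | down)
            _write_tsv(table, outdir / "focus_genes.tsv")
            artifacts["focus_genes"] = outdir / "focus_genes.tsv"

    # ---- networks -------------------------------------------------------
    if cfg.pathway_relations and len(sig_terms):
        rel = networks.RelationTable.read_tsv(cfg.pathway_relations)
        sig_path = sig_terms[sig_terms["namespace"] == "pathway"]
        pnet = networks.pathway_act_network(
            set(sig_path["term"]), rel,
            p_values=dict(zip(sig_path["term"], sig_path["p_value"])))
        pnet.write_sif(outdir / "pathway_act.sif")
        pnet.write_graphml(outdir / "pathway_act.graphml")
        artifacts["pathway_act_sif"] = outdir / "pathway_act.sif"
        artifacts["pathway_act_graphml"] = outdir / "pathway_act.graphml"

    if cfg.gene_relations:
        rel = networks.RelationTable.read_tsv(cfg.gene_relations)
        gnet = networks.gene_act_network(deg_calls, rel)
        gnet.write_sif(outdir / "gene_act.sif")
        gnet.write_graphml(outdir / "gene_act.graphml")
        artifacts["gene_act_sif"] = outdir / "gene_act.sif"
        artifacts["gene_act_graphml"] = outdir / "gene_act.graphml"

    # co-expression on DEGs belonging to significant terms (union rule);
    # falls back to all DEGs when no annotation restricts the set
    coexpr_genes = sorted(up | down)
    if len(sig_terms) and annotation is not None:
        member = set().union(*(annotation.terms[t][2] for t in sig_terms["term"]))
        restricted = sorted((up | down) & member)
        if restricted:
            coexpr_genes = restricted
    if len(coexpr_genes) >= 2:
        gidx = {g: i for i, g in enumerate(norm.gene_ids)}
        rows = [gidx[g] for g in coexpr_genes]
        hub_rows = []
        span = [None] if cfg.coexpr_samples == "pooled" else [group1, group2]
        for grp in span:
            cols = (list(range(len(norm.sample_ids))) if grp is None
                    else norm.samples_of(grp))
            label = grp or "pooled"
            net = networks.coexpression_network(
                norm.values[np.ix_(rows, cols)], coexpr_genes,
                fdr_threshold=cfg.coexpr_fdr, directions=deg_calls)
            net.write_sif(outdir / f"coexpr_{label}.sif")
            net.write_graphml(outdir / f"coexpr_{label}.graphml")
            artifacts[f"coexpr_{label}_sif"] = outdir / f"coexpr_{label}.sif"
            artifacts[f"coexpr_{label}_graphml"] = outdir / f"coexpr_{label}.graphml"
            cores, hubs = networks.kcore_decompose(net)
            hub_rows += [(label, g, cores[g], g in hubs) for g in sorted(cores)]
        _write_tsv(pd.DataFrame(hub_rows, columns=["network", "gene", "core", "hub"]),
                   outdir / "coexpr_cores.tsv")
        artifacts["coexpr_cores"] = outdir / "coexpr_cores.tsv"

    # ---- qPCR -----------------------------------------------------------
    if cfg.qpcr_plate and not cfg.skip_qpcr:
        if not cfg.qpcr_reference_gene:
            raise ValueError("qpcr_reference_gene required when a plate is given")
        plate = qpcr.QpcrPlate.read_tsv(cfg.qpcr_plate,
                                        reference_gene=cfg.qpcr_reference_gene,
                                        calibrator_group=group1)
        rq_table = qpcr.ddct_all(plate, test_group=group2)
        _write_tsv(rq_table, outdir / "rq_table.tsv")
        artifacts["rq_table"] = outdir / "rq_table.tsv"
        lfc_map = dict(zip(de.table["gene"], de.table["log2fc"]))
        shared = [g for g in rq_table["gene"] if g in lfc_map and np.isfinite(lfc_map[g])]
        if shared:
            conc, frac = qpcr.concordance(rq_table[rq_table["gene"].isin(shared)], lfc_map)
            _write_tsv(conc, outdir / "qpcr_concordance.tsv")
            artifacts["qpcr_concordance"] = outdir / "qpcr_concordance.tsv"
            logger.info("qPCR/RNA-seq sign concordance: %.3f", frac)

    # ---- manifest -------------------------------------------------------
    manifest = {
        "config": asdict(cfg),
        "groups": {"group1": group1, "group2": group2},
        "artifacts": {name: {"path": str(p.relative_to(outdir)),
                             "sha256": _sha256(p), "bytes": p.stat().st_size}
                      for name, p in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
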