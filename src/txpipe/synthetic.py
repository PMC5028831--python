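"""Ground-truthed synthetic inputs for the whole pipeline.

Emulates a two-group, three-replicate bulk RNA-seq design: negative-binomial
counts with planted differential expression straddling the 1.5-fold
threshold, within-group co-expression modules driven by shared latent
factors, term annotations with planted enrichment among DE genes, typed
gene-gene relations, and Ct plates consistent with the planted expression.
Every generator draws from its own seeded stream, so stages are
independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from txpipe.enrichment import AnnotationSet, GO_NAMESPACES
from txpipe.networks import RELATION_TYPES, RelationTable
from txpipe.qpcr import QpcrPlate
from txpipe.quantify import CountMatrix

# stable per-stage stream offsets (mixed with the master seed)
_STAGE = {"counts": 1, "annotation": 2, "relations": 3, "qpcr": 4}

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "simulate_annotation",
           "simulate_relations", "simulate_qpcr", "write_fixture_dir"]


@dataclass
class SimConfig:
    """Knobs for all four generators.  Defaults mirror the two-breed,
    three-replicate study design with ~13-16M unique-mapped reads."""

    n_genes: int = 2000
    n_reps_per_group: int = 3
    groups: tuple[str, str] = ("QHMM", "STH")
    lib_size_range: tuple[float, float] = (12.8e6, 16.4e6)
    p_de: float = 0.1
    lfc_loc: float = 0.585          # planted |log2FC| = loc + Exponential(scale)
    lfc_scale: float = 0.8
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    dispersion_offset: float = 0.005
    dispersion_gamma_shape: float = 3.0
    dispersion_gamma_scale: float = 5.0
    gene_length_kb: float = 2.5
    n_modules: int = 2
    module_size: int = 20
    module_rho: float = 0.9
    n_terms: int = 50               # per namespace
    planted_terms: int = 5
    plant_odds: float = 10.0
    term_size_range: tuple[int, int] = (10, 100)
    edge_density: float = 0.002
    qpcr_noise_sd: float = 0.15
    qpcr_slope: float = 1.0
    qpcr_intercept: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_reps_per_group <= 0:
            raise ValueError("n_genes and n_reps_per_group must be positive")
        if not 0.0 <= self.p_de < 1.0:
            raise ValueError("p_de must lie in [0, 1)")
        if self.n_modules and not 0.0 < self.module_rho < 1.0:
            raise ValueError("module_rho must lie in (0, 1)")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ValueError("exactly two distinct group labels required")
        if self.planted_terms > self.n_terms:
            raise ValueError("planted_terms cannot exceed n_terms")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit into n_genes")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage]])

    @property
    def sample_ids(self) -> list[str]:
        prefix = {0: "A", 1: "B"}
        return [f"{prefix[g]}{i + 1}" for g in (0, 1) for i in range(self.n_reps_per_group)]

    @property
    def design(self) -> dict[str, str]:
        return {s: self.groups[0] if s.startswith("A") else self.groups[1]
                for s in self.sample_ids}


@dataclass
class SimTruth:
    """Everything that was planted, for downstream recovery checks."""

    de_flags: np.ndarray
    true_lfc: np.ndarray
    module_membership: np.ndarray   # 0 = background, 1..n_modules
    true_size_factors: np.ndarray
    gene_ids: list[str]
    enriched_terms: set[str] = field(default_factory=set)
    expected_means: np.ndarray | None = None   # genes x samples, pre-latent-factor
    dispersions: np.ndarray | None = None      # per-gene NB phi

    def __post_init__(self) -> None:
        if not np.array_equal(np.abs(self.true_lfc) > 0, self.de_flags.astype(bool)):
            raise ValueError("|true_lfc| > 0 must hold exactly for DE-flagged genes")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "de_flags": self.de_flags.astype(bool).tolist(),
            "true_lfc": self.true_lfc.tolist(),
            "module_membership": self.module_membership.astype(int).tolist(),
            "true_size_factors": self.true_size_factors.tolist(),
            "enriched_terms": sorted(self.enriched_terms),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """NB counts with planted fold changes and co-expression modules.

    Gene mean in sample j: baseline_g * size_factor_j * 2^(lfc_g * [group2])
    times, for module genes, a per-sample lognormal latent factor shared
    within the module so that within-group correlations approach
    ``module_rho``.
    """
    rng = cfg.rng("counts")
    G, n = cfg.n_genes, cfg.n_reps_per_group
    J = 2 * n
    gene_ids = [f"G{i:05d}" for i in range(G)]

    baseline = np.exp2(rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, G))
    lengths = np.round(np.exp(rng.normal(np.log(cfg.gene_length_kb * 1000), 0.5, G)))
    lengths = np.maximum(lengths, 200)

    de_flags = rng.random(G) < cfg.p_de
    magnitude = cfg.lfc_loc + rng.exponential(cfg.lfc_scale, G)
    sign = rng.choice([-1.0, 1.0], G)
    true_lfc = np.where(de_flags, sign * magnitude, 0.0)

    phi = cfg.dispersion_offset + 1.0 / rng.gamma(
        cfg.dispersion_gamma_shape, cfg.dispersion_gamma_scale, G)

    lib = rng.uniform(*cfg.lib_size_range, J)
    size_factors = lib / np.exp(np.mean(np.log(lib)))
    # scale baselines so library totals land near the requested depth
    baseline *= np.exp(np.mean(np.log(lib))) / baseline.sum()

    membership = np.zeros(G, dtype=int)
    order = rng.permutation(G)
    for m in range(cfg.n_modules):
        membership[order[m * cfg.module_size:(m + 1) * cfg.module_size]] = m + 1

    group2 = np.repeat([0.0, 1.0], n)
    mu = baseline[:, None] * size_factors[None, :] * np.exp2(true_lfc[:, None] * group2[None, :])

    if cfg.n_modules:
        # shared lognormal factor per (module, sample); per-gene strength
        # tau_g^2 = rho/(1-rho) * (phi_g + 1/mu_g) so each module pair's
        # log-scale correlation approaches module_rho regardless of its
        # dispersion or depth
        z = rng.normal(0.0, 1.0, (cfg.n_modules, J))
        # standardize across samples so the planted factor is guaranteed to
        # be present with unit spread in every realization
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        noise_var = phi + 1.0 / np.maximum(mu.mean(axis=1), 1e-9)
        tau = np.sqrt(cfg.module_rho / (1.0 - cfg.module_rho) * noise_var)
        for m in range(cfg.n_modules):
            sel = membership == m + 1
            mu[sel] *= np.exp(tau[sel, None] * z[m][None, :] - tau[sel, None]**2 / 2.0)

    if not np.all(np.isfinite(mu)):
        raise FloatingPointError("non-finite simulated means; check baseline/lfc settings")

    r = 1.0 / phi
    counts = rng.negative_binomial(r[:, None], (r / (r + mu.T)).T)

    cm = CountMatrix(gene_ids=gene_ids, lengths=lengths, counts=counts,
                     sample_ids=cfg.sample_ids, groups=cfg.design)
    truth = SimTruth(de_flags=de_flags, true_lfc=true_lfc,
                     module_membership=membership,
                     true_size_factors=size_factors, gene_ids=gene_ids,
                     expected_means=baseline[:, None] * size_factors[None, :]
                     * np.exp2(true_lfc[:, None] * group2[None, :]),
                     dispersions=phi)
    return cm, truth


def simulate_annotation(cfg: SimConfig, truth: SimTruth) -> AnnotationSet:
    """Random term memberships with planted enrichment among DE genes.

    Planted terms include DE genes with membership odds inflated by
    ``plant_odds``; the hierarchy is a random forest per namespace (each
    non-root term gets one earlier parent), so it is acyclic with at most
    T - 1 edges.
    """
    if cfg.planted_terms > cfg.n_terms:
        raise ValueError("planted_terms cannot exceed n_terms")
    rng = cfg.rng("annotation")
    genes = np.asarray(truth.gene_ids)
    de = truth.de_flags.astype(bool)
    namespaces = GO_NAMESPACES + ("pathway",)
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    hierarchy: list[tuple[str, str]] = []
    enriched: set[str] = set()

    for ns_i, ns in enumerate(namespaces):
        short = ns.split("_")[0][:4].upper() if ns != "pathway" else "PATH"
        ids = [f"{short}:{i:04d}" for i in range(cfg.n_terms)]
        planted_ids = set(ids[:cfg.planted_terms]) if ns_i == 0 and cfg.planted_terms else set()
        for tid in ids:
            size = int(rng.integers(*cfg.term_size_range))
            base_p = min(size / cfg.n_genes, 0.9)
            if tid in planted_ids:
                odds = base_p / (1.0 - base_p) * cfg.plant_odds
                p_de_member = odds / (1.0 + odds)
                pick = np.where(de, rng.random(cfg.n_genes) < p_de_member,
                                rng.random(cfg.n_genes) < base_p)
                enriched.add(tid)
            else:
                pick = rng.random(cfg.n_genes) < base_p
            terms[tid] = (f"{ns} term {tid}", ns, frozenset(genes[pick]))
        for i in range(1, len(ids)):  # random forest: parent among earlier terms
            if rng.random() < 0.9:
                parent = ids[int(rng.integers(0, i))]
                hierarchy.append((ids[i], parent))

    truth.enriched_terms = enriched
    return AnnotationSet(terms=terms, universe=frozenset(genes), hierarchy=hierarchy)


def simulate_relations(cfg: SimConfig, truth: SimTruth,
                       ids: list[str] | None = None) -> RelationTable:
    """Typed edges sampled uniformly over unordered pairs at ``edge_density``."""
    rng = cfg.rng("relations")
    ids = list(ids if ids is not None else truth.gene_ids)
    G = len(ids)
    n_pairs = G * (G - 1) // 2
    m = int(rng.binomial(n_pairs, cfg.edge_density)) if cfg.edge_density > 0 else 0
    rows = []
    seen: set[tuple[int, int]] = set()
    while len(rows) < m:
        i, j = rng.integers(0, G, 2)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        rtype = RELATION_TYPES[int(rng.integers(0, len(RELATION_TYPES)))]
        rows.append((ids[key[0]], ids[key[1]], rtype, True))
    return RelationTable(pd.DataFrame(rows, columns=["src", "dst", "type", "directed"]))


def simulate_qpcr(truth: SimTruth, genes: list[str], cfg: SimConfig,
                  reference_gene: str | None = None,
                  noise_sd: float | None = None) -> QpcrPlate:
    """Ct plates consistent with the planted expression.

    Ct = intercept - slope * log2(relative expression) + Normal noise, with
    the reference gene flat across groups; three animals x three technical
    replicates per group.  Refuses a DE-planted reference gene.
    """
    rng = cfg.rng("qpcr")
    noise_sd = cfg.qpcr_noise_sd if noise_sd is None else noise_sd
    index = {g: i for i, g in enumerate(truth.gene_ids)}
    unknown = [g for g in genes if g not in index]
    if unknown:
        raise ValueError(f"genes not in the simulation: {unknown}")
    if reference_gene is None:
        non_de = [g for g in truth.gene_ids if not truth.de_flags[index[g]]]
        if not non_de:
            raise ValueError("no non-DE gene available as reference")
        reference_gene = non_de[0]
    elif reference_gene in index and truth.de_flags[index[reference_gene]]:
        raise ValueError(
            f"reference gene {reference_gene} is DE-planted; "
            "house-keeping assumption violated")

    g1, g2 = cfg.groups
    rows = []
    offsets = {g: float(rng.uniform(-3, 3)) for g in [reference_gene, *genes]}
    for gene in [reference_gene, *genes]:
        lfc = 0.0 if gene == reference_gene else float(truth.true_lfc[index[gene]])
        for gi, group in enumerate((g1, g2)):
            rel = 2.0 ** (lfc * gi)  # expression relative to group1
            for animal in range(1, cfg.n_reps_per_group + 1):
                sample = f"{group}_{animal}"
                for rep in range(1, 4):
                    ct = (cfg.qpcr_intercept + offsets[gene]
                          - cfg.qpcr_slope * np.log2(rel)
                          + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
                    rows.append((gene, sample, group, rep, float(ct)))
    table = pd.DataFrame(rows, columns=["gene", "sample", "group", "replicate", "ct"])
    return QpcrPlate(table=table, reference_gene=reference_gene, calibrator_group=g1)


def write_fixture_dir(cfg: SimConfig, outdir: str | Path,
                      n_qpcr_genes: int = 9) -> dict[str, Path]:
    """Generate everything and write the on-disk input formats.

    Returns a name -> path map: counts/design/annotation/hierarchy/
    relations/qpcr/truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, truth = simulate_counts(cfg)
    annotation = simulate_annotation(cfg, truth)
    relations = simulate_relations(cfg, truth)
    de_idx = np.nonzero(truth.de_flags)[0]
    qpcr_genes = [truth.gene_ids[i] for i in de_idx[:n_qpcr_genes]]
    plate = simulate_qpcr(truth, qpcr_genes, cfg)

    paths = {name: outdir / fname for name, fname in [
        ("counts", "counts.tsv"), ("design", "design.tsv"),
        ("annotation", "annotation.gmt"), ("hierarchy", "hierarchy.tsv"),
        ("relations", "relations.tsv"), ("qpcr", "qpcr.tsv"),
        ("truth", "truth.json"),
    ]}
    counts.write_tsv(paths["counts"])
    pd.DataFrame({"sample": counts.sample_ids,
                  "group": [counts.groups[s] for s in counts.sample_ids]}
                 ).to_csv(paths["design"], sep="\t", index=False)
    annotation.write_gmt(paths["annotation"])
    annotation.write_hierarchy_tsv(paths["hierarchy"])
    relations.write_tsv(paths["relations"])
    plate.write_tsv(paths["qpcr"])
    truth.to_json(paths["truth"])
    meta = {"config": asdict(cfg), "reference_gene": plate.reference_gene,
            "calibrator_group": plate.calibrator_group, "qpcr_genes": qpcr_genes}
    (outdir / "sim_meta.json").write_text(json.dumps(meta, indent=1))
    paths["meta"] = outdir / "sim_meta.json"
    return paths
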