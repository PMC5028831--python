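# txpipe

A two-group bulk RNA-seq comparison pipeline, built around the classic
two-breed / three-replicate muscle transcriptome design:

- **quantify** — mapping-summary arithmetic, RPKM, and upper-quartile
  count normalization.
- **diffexpr** — empirical-Bayes negative-binomial differential expression:
  a two-pattern (equal vs differential) mixture with a shared Beta prior on
  the NB probability parameter, closed-form Beta-NB marginals, EM over the
  mixing proportion and prior shapes, and posterior-expectation FDR.  Calls
  use the |log2FC| > 0.585 (1.5-fold) and FDR < 0.05 rule.
- **enrichment** — one-sided hypergeometric over-representation of DEG sets
  (all/up/down) against GO-namespace and pathway annotations, raw P < 0.05
  filter, top-k reporting, BH q-values emitted for transparency.
- **ontology** — ancestor-closed "GO-tree" subgraphs of significant terms,
  with focus-term selection by name pattern.
- **networks** — pathway and gene interaction networks (typed edges, induced
  on significant pathways / DEGs), per-group co-expression networks with
  Pearson + BH-FDR edge selection, and k-core decomposition for hub genes.
- **qpcr** — 2^-ddCt relative quantification with Welch t-tests and sign
  concordance against the sequencing fold changes.
- **synthetic** — a fully ground-truthed generator (NB counts with planted
  fold changes, co-expression modules via shared latent factors, planted
  term enrichment, typed relations, consistent Ct plates) so the entire
  pipeline is testable offline.

## CLI

```sh
# generate a ground-truthed fixture directory
txpipe simulate --outdir fixture --n-genes 2000 --p-de 0.1 --seed 1

# full pipeline (quantify -> DE -> enrichment -> GO-tree -> networks -> qPCR)
txpipe run --counts fixture/counts.tsv --design fixture/design.tsv \
    --annotation fixture/annotation.gmt --hierarchy fixture/hierarchy.tsv \
    --gene-relations fixture/relations.tsv --qpcr-plate fixture/qpcr.tsv \
    --qpcr-reference-gene G00001 --outdir out

# single stages
txpipe de --counts ... --design ... --group1 QHMM --group2 STH --out de.tsv
txpipe enrich --de-table de.tsv --gmt fixture/annotation.gmt --out enr.tsv
txpipe network --norm-counts out/normalized_counts.tsv --design ... \
    --genes degs.txt --group STH --out-prefix coexpr_sth
txpipe qpcr --plate fixture/qpcr.tsv --reference-gene G00001 \
    --calibrator-group QHMM --out rq.tsv
```

`txpipe run` writes every artifact plus a `manifest.json` with sha256
checksums; identical inputs and config give byte-identical manifests.
Fold-change direction is always group2 vs group1 (default STH vs QHMM).
Per-group co-expression with 3 replicates cannot reach FDR < 0.05 (with
df = 1 a raw p < 0.05 already needs |r| > 0.997); the CLI warns loudly and
offers `--coexpr-samples pooled` and `--edge-alpha`.

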