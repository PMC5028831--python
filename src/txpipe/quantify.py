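"""Read-count containers, mapping-summary arithmetic, RPKM and upper-quartile
normalization.

The count matrix (genes x samples, with per-gene lengths and a sample->group
design) is the root input of the pipeline.  Expression is reported either as
RPKM (length- and depth-normalized) or as upper-quartile-scaled counts, the
latter feeding the differential-expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "MappingSummary",
    "ExpressionMatrix",
    "mapping_rates",
    "rpkm",
    "upper_quartile_factors",
    "normalize_counts",
    "read_counts_tsv",
    "read_design_tsv",
]


@dataclass
class CountMatrix:
    """Integer read counts per gene per sample plus design metadata.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers.
    lengths : ndarray
        Per-gene transcript length in bp, positive.
    counts : ndarray
        ``(n_genes, n_samples)`` non-negative integer counts.
    sample_ids : list of str
        Column identifiers.
    groups : dict
        Maps each sample id to its group label.
    """

    gene_ids: list[str]
    lengths: np.ndarray
    counts: np.ndarray
    sample_ids: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.lengths <= 0):
            raise ValueError("gene lengths must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts != np.floor(self.counts)):
            raise ValueError("counts must be integral")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order over samples."""
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> list[int]:
        """Column indices of the samples belonging to *group*."""
        return [j for j, s in enumerate(self.sample_ids) if self.groups[s] == group]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)
        df.insert(0, "length", self.lengths.astype(int))
        df.index.name = "gene_id"
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class MappingSummary:
    """Per-sample read-mapping bookkeeping with derived rates.

    ``mapped + unmapped`` must equal ``all_reads`` exactly;
    ``unique_mapped + repeat_mapped`` is allowed to deviate from ``mapped``
    by at most ``tolerance`` reads (published summaries show off-by-a-few
    inconsistencies, which we accept but do not repair).
    """

    sample_ids: list[str]
    all_reads: np.ndarray
    mapped: np.ndarray
    unmapped: np.ndarray
    unique_mapped: np.ndarray
    repeat_mapped: np.ndarray
    tolerance: int = 100

    def __post_init__(self) -> None:
        for name in ("all_reads", "mapped", "unmapped", "unique_mapped", "repeat_mapped"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        if not np.array_equal(self.mapped + self.unmapped, self.all_reads):
            raise ValueError("mapped + unmapped must equal all_reads exactly")
        gap = np.abs(self.unique_mapped + self.repeat_mapped - self.mapped)
        if np.any(gap > self.tolerance):
            bad = [self.sample_ids[i] for i in np.nonzero(gap > self.tolerance)[0]]
            raise ValueError(
                f"unique + repeat deviates from mapped by more than "
                f"{self.tolerance} reads in samples {bad}"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "MappingSummary":
        """Build from a frame with columns sample, all_reads, mapped, unmapped,
        unique_mapped, repeat_mapped."""
        return cls(
            sample_ids=list(df["sample"]),
            all_reads=df["all_reads"].to_numpy(),
            mapped=df["mapped"].to_numpy(),
            unmapped=df["unmapped"].to_numpy(),
            unique_mapped=df["unique_mapped"].to_numpy(),
            repeat_mapped=df["repeat_mapped"].to_numpy(),
            **kw,
        )


@dataclass
class ExpressionMatrix:
    """Non-negative real expression values (RPKM or normalized counts)."""

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    kind: str  # "RPKM" or "UQ-normalized-counts"
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    def samples_of(self, group: str) -> list[int]:
        return [j for j, s in enumerate(self.sample_ids) if self.groups.get(s) == group]

    def group_means(self) -> pd.DataFrame:
        """Per-gene mean expression within each group."""
        labels = []
        for s in self.sample_ids:
            g = self.groups.get(s)
            if g not in labels:
                labels.append(g)
        cols = {g: self.values[:, self.samples_of(g)].mean(axis=1) for g in labels}
        return pd.DataFrame(cols, index=self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def mapping_rates(summary: MappingSummary, decimals: int = 3) -> pd.DataFrame:
    """Per-sample mapped and unique-mapped rates, rounded for reporting.

    mapped_rate = mapped / all_reads, unique_rate = unique_mapped / all_reads.
    """
    if np.any(summary.all_reads <= 0):
        bad = [summary.sample_ids[i] for i in np.nonzero(summary.all_reads <= 0)[0]]
        raise ValueError(f"all_reads must be positive; offending samples: {bad}")
    mapped_rate = np.round(summary.mapped / summary.all_reads, decimals)
    unique_rate = np.round(summary.unique_mapped / summary.all_reads, decimals)
    return pd.DataFrame(
        {"mapped_rate": mapped_rate, "unique_rate": unique_rate},
        index=summary.sample_ids,
    )


def rpkm(counts: CountMatrix, mapped_totals: np.ndarray | None = None) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    value = 1e9 * C / (N * L) with N the per-sample total.  By default N is
    the within-matrix column sum so the computation is self-contained; pass
    aligner-reported totals via *mapped_totals* to override.
    """
    if np.any(counts.lengths <= 0):
        raise ValueError("zero-length gene encountered")
    totals = counts.counts.sum(axis=0) if mapped_totals is None else np.asarray(mapped_totals, float)
    if np.any(totals <= 0):
        bad = [counts.sample_ids[j] for j in np.nonzero(totals <= 0)[0]]
        raise ValueError(f"non-positive mapped-read total for samples: {bad}")
    values = 1e9 * counts.counts / (totals[None, :] * counts.lengths[:, None])
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        values=values,
        sample_ids=list(counts.sample_ids),
        kind="RPKM",
        groups=dict(counts.groups),
    )


def upper_quartile_factors(counts: CountMatrix) -> np.ndarray:
    """Per-sample size factors from the 75th percentile of nonzero counts.

    Factors are scaled to geometric mean 1 so neither group serves as the
    reference.  Raises if a sample has no nonzero gene.
    """
    q75 = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        col = counts.counts[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {counts.sample_ids[j]} has all-zero counts")
        q75[j] = np.percentile(nz, 75)  # linear interpolation
    log_gm = np.mean(np.log(q75))
    return q75 / np.exp(log_gm)


def normalize_counts(counts: CountMatrix, factors: np.ndarray) -> ExpressionMatrix:
    """Divide each sample's counts by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,):
        raise ValueError("one factor per sample required")
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        values=counts.counts / factors[None, :],
        sample_ids=list(counts.sample_ids),
        kind="UQ-normalized-counts",
        groups=dict(counts.groups),
    )


def read_design_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column sample/group design table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError("design table needs 'sample' and 'group' columns")
    return dict(zip(df["sample"], df["group"]))


def read_counts_tsv(path: str | Path, design: dict[str, str] | str | Path) -> CountMatrix:
    """Read a counts TSV (gene_id, length, one column per sample) plus design."""
    if not isinstance(design, dict):
        design = read_design_tsv(design)
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length" not in df.columns:
        raise ValueError("counts table needs a 'length' column")
    sample_cols = [c for c in df.columns if c != "length"]
    return CountMatrix(
        gene_ids=list(df.index.astype(str)),
        lengths=df["length"].to_numpy(float),
        counts=df[sample_cols].to_numpy(),
        sample_ids=sample_cols,
        groups={s: design[s] for s in sample_cols},
    )
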