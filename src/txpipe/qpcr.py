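"""Relative quantification of qPCR plates by the 2^-ddCt method.

Technical replicates are averaged per well group, dCt is taken against the
designated reference (house-keeping) gene within each sample, and ddCt
contrasts the test group against the calibrator group.  Per-gene
significance uses Welch's t-test on per-animal dCt values; sign concordance
against the sequencing-based fold changes summarizes validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QpcrPlate", "RelativeQuant", "ddct", "ddct_all", "concordance", "stars"]


@dataclass
class QpcrPlate:
    """Ct measurements: one row per (gene, sample, technical replicate).

    Columns of ``table``: gene, sample, group, replicate, ct.
    """

    table: pd.DataFrame
    reference_gene: str
    calibrator_group: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "group", "replicate", "ct"}
        if not required <= set(self.table.columns):
            raise ValueError(f"plate table needs columns {sorted(required)}")
        ct = self.table["ct"].to_numpy(float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0) or np.any(ct >= 45):
            raise ValueError("Ct values must be finite and within (0, 45)")
        samples = set(self.table["sample"])
        ref_samples = set(self.table.loc[self.table["gene"] == self.reference_gene, "sample"])
        missing = samples - ref_samples
        if missing:
            raise ValueError(
                f"reference gene {self.reference_gene} missing in samples: {sorted(missing)}")
        if self.calibrator_group not in set(self.table["group"]):
            raise ValueError(f"calibrator group {self.calibrator_group!r} absent from plate")

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.table["gene"]) - {self.reference_gene})

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.table["group"]))

    @classmethod
    def read_tsv(cls, path: str | Path, reference_gene: str,
                 calibrator_group: str) -> "QpcrPlate":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str, "group": str})
        return cls(df, reference_gene=reference_gene, calibrator_group=calibrator_group)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class RelativeQuant:
    """2^-ddCt result for one gene."""

    gene: str
    rq: float
    ddct: float
    dct_test: np.ndarray      # per-animal dCt, test group
    dct_calibrator: np.ndarray
    p_value: float
    stars: str

    def __post_init__(self) -> None:
        if not self.rq > 0:
            raise ValueError("relative quantity must be positive")


def stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _mean_ct(plate: QpcrPlate, gene: str) -> pd.Series:
    """Technical-replicate mean Ct per sample for one gene."""
    sub = plate.table[plate.table["gene"] == gene]
    return sub.groupby("sample")["ct"].mean()


def ddct(plate: QpcrPlate, gene: str, test_group: str | None = None) -> RelativeQuant:
    """Relative expression of *gene* in the test group vs the calibrator.

    dCt_s = Ct_gene,s - Ct_ref,s per sample (technical replicates averaged);
    ddCt = mean dCt over test samples - mean dCt over calibrator samples;
    rq = 2^-ddCt.  Welch's t-test on the per-animal dCt values gives p.
    """
    if gene == plate.reference_gene:
        raise ValueError("cannot quantify the reference gene against itself")
    groups = [g for g in plate.groups if g != plate.calibrator_group]
    if test_group is None:
        if len(groups) != 1:
            raise ValueError("ambiguous test group; pass test_group explicitly")
        test_group = groups[0]
    ct_gene = _mean_ct(plate, gene)
    ct_ref = _mean_ct(plate, plate.reference_gene)
    missing = set(ct_gene.index) - set(ct_ref.index)
    if missing:
        raise ValueError(f"missing reference wells for samples: {sorted(missing)}")
    dct = ct_gene - ct_ref.loc[ct_gene.index]
    sample_group = (plate.table.drop_duplicates("sample").set_index("sample")["group"])
    dct_test = dct[sample_group.loc[dct.index] == test_group].to_numpy(float)
    dct_cal = dct[sample_group.loc[dct.index] == plate.calibrator_group].to_numpy(float)
    if dct_test.size == 0 or dct_cal.size == 0:
        raise ValueError("both groups must be measured for the gene")
    dd = float(dct_test.mean() - dct_cal.mean())
    if dct_test.size > 1 and dct_cal.size > 1 and (dct_test.std() > 0 or dct_cal.std() > 0):
        p = float(stats.ttest_ind(dct_test, dct_cal, equal_var=False).pvalue)
    else:
        p = 1.0
    return RelativeQuant(gene=gene, rq=float(2.0 ** -dd), ddct=dd,
                         dct_test=dct_test, dct_calibrator=dct_cal,
                         p_value=p, stars=stars(p))


def ddct_all(plate: QpcrPlate, test_group: str | None = None) -> pd.DataFrame:
    """ddct for every non-reference gene on the plate, as a tidy table."""
    rows = []
    for gene in plate.genes:
        rq = ddct(plate, gene, test_group=test_group)
        rows.append((gene, rq.rq, rq.ddct, rq.p_value, rq.stars))
    return pd.DataFrame(rows, columns=["gene", "rq", "ddct", "p_value", "stars"])


def concordance(rq_table: pd.DataFrame, log2fc: dict[str, float]) -> tuple[pd.DataFrame, float]:
    """Sign agreement between qPCR fold changes and sequencing fold changes.

    A gene agrees iff sign(log2 rq) == sign(log2fc).  Returns the per-gene
    table and the overall agreement fraction over genes present in both.
    """
    shared = [g for g in rq_table["gene"] if g in log2fc]
    if not shared:
        raise ValueError("no genes shared between qPCR table and DE results")
    sub = rq_table.set_index("gene").loc[shared]
    qpcr_sign = np.sign(np.log2(sub["rq"].to_numpy(float)))
    seq_sign = np.sign(np.array([log2fc[g] for g in shared]))
    agree = qpcr_sign == seq_sign
    out = pd.DataFrame({
        "gene": shared,
        "rq": sub["rq"].to_numpy(float),
        "log2_rq": np.log2(sub["rq"].to_numpy(float)),
        "seq_log2fc": [log2fc[g] for g in shared],
        "agree": agree,
    })
    return out, float(agree.mean())
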