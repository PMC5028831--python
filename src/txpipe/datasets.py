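"""Bundled worked-example tables from the two-breed sheep longissimus muscle
study (GEO accession GSE84964): the published reads-mapping summary and the
curated table of 30 muscle-development DEGs with their normalized group
means, fold changes and FDR.  These small text tables drive the arithmetic
checks; the raw sequencing data are not required anywhere in the pipeline.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from txpipe.quantify import MappingSummary

# Published per-sample read-mapping counts (six samples, two breeds).
_MAPPING_TSV = """\
sample	group	all_reads	unmapped	mapped	unique_mapped	repeat_mapped
A1	QHMM	18752596	1415576	17337020	16437180	899853
A2	QHMM	17482106	1531813	15950293	14905935	1044371
A3	QHMM	16488130	1302393	15185737	14372858	812891
B1	STH	17458226	1334282	16123944	15292633	831323
B2	STH	14790361	1156221	13634140	12779250	854906
B3	STH	17408297	1371310	16036987	15237071	799930
"""

# Published rates as printed (3 decimals), for cross-checking arithmetic.
_PUBLISHED_RATES_TSV = """\
sample	mapped_rate	unique_rate
A1	0.925	0.877
A2	0.912	0.853
A3	0.921	0.872
B1	0.924	0.876
B2	0.922	0.864
B3	0.921	0.875
"""

# Curated 30-gene DEG table: normalized group means, published log2 fold
# change (STH vs QHMM), FDR, call, and 1-based indices of the ten selected
# muscle-development terms each gene is annotated to.
_DEG_TSV = """\
gene	qhmm_mean	sth_mean	log2fc	fdr	style	term_indices
BCL9L	364.4	156.2	-1.2	5.16e-03	down	7
BTG1	670.5	3228.5	2.3	9.08e-05	up	4,10
CASQ1	45168.0	17353.3	-1.4	5.41e-04	down	1,8
CASQ2	620.4	248.1	-1.3	1.90e-02	down	8
CDH15	122.5	263.7	1.1	1.66e-03	up	5
CITED2	155.9	289.7	0.9	2.54e-02	up	7
CSRP3	4896.3	18425.4	2.0	4.61e-02	up	1,9
FHOD3	502.7	172.0	-1.5	0	down	8,9
FOXP1	233.3	382.1	0.7	2.45e-02	up	1,8
GPX1	1529.1	761.9	-1.0	1.22e-06	down	3
HEYL	310.0	186.4	-0.7	7.27e-05	down	7
HLF	76.3	31.7	-1.3	1.02e-04	down	7
ITGA7	4307.8	1157.3	-1.9	0	down	1
KIAA1161	661.6	214.7	-1.6	1.19e-06	down	3
LMOD2	5623.4	12507.3	1.2	1.18e-08	up	9
MAFF	73.1	239.3	1.7	1.89e-03	up	7
MYF6	1688.6	4474.1	1.4	0	up	1,2,4,6,7,8,10
MYH6	12787.7	4502.7	-1.5	1.17e-10	down	8,9
MYL2	63933.5	23309.3	-1.5	7.13e-12	down	9
MYL6B	12018.3	1654.6	-2.9	3.77e-02	down	1
MYLK3	265.8	94.1	-1.5	6.03e-06	down	8,9
MYOD1	232.5	37.5	-2.6	3.46e-06	down	1,2,3,4,6,7,8,10
MYOG	501.8	148.6	-1.8	2.41e-04	down	1,2,3,4,6,7,8,10
NEO1	390.1	178.1	-1.1	2.90e-06	down	5
OMYHCS	225230.0	88659.7	-1.3	3.66e-14	down	8,9
PPP3CB	1978.0	1122.0	-0.8	3.85e-02	down	3
RXRG	1104.1	273.7	-2.0	2.89e-06	down	1
SETD3	1297.1	719.0	-0.9	1.02e-04	down	5
STAC3	5060.1	2569.4	-1.0	4.65e-03	down	3
XIRP1	7518.7	37631.7	2.3	1.11e-06	up	8
"""

# Headline DEG tally reported for the full dataset (not recomputable from
# the bundled tables; used only as an input to summary arithmetic).
REPORTED_DEG_COUNTS = {"up": 405, "down": 555}

# The ten selected muscle-development term names, 1-based index order.
FOCUS_TERMS = [
    "skeletal muscle tissue development",
    "positive regulation of skeletal muscle fiber development",
    "skeletal muscle fiber development",
    "positive regulation of myoblast differentiation",
    "positive regulation of muscle cell differentiation",
    "muscle cell fate commitment",
    "muscle cell differentiation",
    "sarcomere organization",
    "myofibril assembly",
    "myoblast differentiation",
]


def mapping_summary_frame() -> pd.DataFrame:
    return pd.read_csv(StringIO(_MAPPING_TSV), sep="\t")


def mapping_summary() -> MappingSummary:
    """The six-sample mapping summary as a validated object."""
    return MappingSummary.from_frame(mapping_summary_frame().drop(columns=["group"]))


def published_rates() -> pd.DataFrame:
    return pd.read_csv(StringIO(_PUBLISHED_RATES_TSV), sep="\t", index_col="sample")


def deg_table() -> pd.DataFrame:
    """The curated 30-row DEG table (group means, log2fc, fdr, style)."""
    return pd.read_csv(StringIO(_DEG_TSV), sep="\t")
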