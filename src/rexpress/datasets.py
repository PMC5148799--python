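"""Small bundled datasets.

``shared_gene_fpkm_panel`` carries the published mean pituitary FPKM values
of the 25 genes found enriched at all three sampled post-hatch ages (days
21, 22 and 42) in the broiler chicken pituitary study this package
re-implements. It is the canonical worked example for the fold-change
operation. Two rows (LOC101749894, SIX6) are digit-ambiguous in the
available source text; the readings used here are noted inline and neither
row serves as a numerical oracle.
"""

from __future__ import annotations

import pandas as pd

from .io import ExpressionMatrix, SampleMeta

QPCR_PANEL_GENES = ("CGA", "FSHB", "GH", "POMC", "PRL", "TSHB")

_SHARED_PANEL = [
    # gene, day 21, day 22, day 42 (mean pituitary FPKM)
    ("ADIRF", 2.16, 1.72, 21.8),
    ("CASR", 2.33, 2.57, 2.41),
    ("COL11A1", 17.17, 20.74, 24.49),
    ("DNAH5", 0.55, 0.4, 0.98),
    ("FAM135B", 1.82, 1.82, 2.08),
    ("FAM3B", 5.0, 3.98, 3.4),
    ("GPC3", 15.17, 15.82, 12.37),
    ("LOC101749214", 1.68, 1.45, 0.99),
    ("LOC101749680", 0.53, 0.76, 1.21),
    ("LOC101749716", 0.95, 0.67, 1.79),
    ("LOC101749894", 17.42, 20.41, 6.02),  # digit-ambiguous source row
    ("LOC101750727", 1777.2, 1074.1, 3958.83),
    ("LOC421690", 0.56, 0.82, 0.61),
    ("MATN4", 2.2, 2.1, 7.02),
    ("MDGA2", 14.16, 16.98, 14.25),
    ("MOV10L1", 4.53, 3.53, 6.09),
    ("MYT1", 8.5, 8.9, 7.35),
    ("NALCN", 14.0, 13.27, 10.73),
    ("NKX2-2", 20.34, 25.91, 8.47),
    ("RNF182", 1.43, 1.53, 3.14),
    ("SIX6", 53.92, 51.54, 4.8),  # digit-ambiguous source row
    ("SORCS1", 13.6, 14.65, 16.97),
    ("SOX3", 4.99, 5.04, 3.95),
    ("TRAPPC4", 36.72, 38.12, 34.17),
    ("UMODL1", 1.3, 1.52, 2.55),
]


def shared_gene_fpkm_panel() -> pd.DataFrame:
    """Mean pituitary FPKM of the 25 always-enriched genes, by post-hatch day.

    Returns a 25×3 DataFrame indexed by gene symbol with integer day columns
    21, 22, 42.
    """
    df = pd.DataFrame(_SHARED_PANEL, columns=["gene_id", 21, 22, 42])
    return df.set_index("gene_id")


def shared_panel_matrices() -> dict[int, ExpressionMatrix]:
    """The shared-gene panel as one single-sample pituitary matrix per day.

    Each day's matrix holds the published day-mean as one pituitary
    replicate, which is exactly what the mean-FPKM fold-change operation
    consumes.
    """
    panel = shared_gene_fpkm_panel()
    matrices = {}
    for day in (21, 22, 42):
        sid = f"pituitary_d{day}_r1"
        values = panel[[day]].rename(columns={day: sid})
        meta = [SampleMeta(sample_id=sid, tissue="pituitary", day=day, replicate=1)]
        matrices[day] = ExpressionMatrix(values, meta)
    return matrices
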