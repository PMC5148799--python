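"""Three-way set decomposition of per-day enriched gene lists, and
between-day fold changes for named genes.

The seven disjoint Venn regions of three gene sets A, B, C are keyed
``A_only``, ``B_only``, ``C_only``, ``AB_only``, ``AC_only``, ``BC_only``,
``ABC``. In study reports A is day 21, B day 22 and C day 42.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneList

REGION_ORDER = ("A_only", "B_only", "C_only", "AB_only", "AC_only", "BC_only", "ABC")


@dataclass(frozen=True)
class VennPartition:
    """The 7 disjoint regions of three gene sets, plus the set labels."""

    labels: Tuple[str, str, str]
    regions: Dict[str, frozenset]

    def sizes(self) -> Dict[str, int]:
        return {k: len(self.regions[k]) for k in REGION_ORDER}

    def union_size(self) -> int:
        return sum(len(self.regions[k]) for k in REGION_ORDER)

    def set_size(self, which: str) -> int:
        """Total size of input set A, B or C reconstructed from the regions."""
        parts = {
            "A": ("A_only", "AB_only", "AC_only", "ABC"),
            "B": ("B_only", "AB_only", "BC_only", "ABC"),
            "C": ("C_only", "AC_only", "BC_only", "ABC"),
        }[which]
        return sum(len(self.regions[k]) for k in parts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (k, len(self.regions[k]), ",".join(sorted(self.regions[k])))
            for k in REGION_ORDER
        ]
        return pd.DataFrame(rows, columns=["region", "size", "members"])


def venn_partition(set_a: GeneList, set_b: GeneList, set_c: GeneList) -> VennPartition:
    """Decompose three gene sets into their unique 7-region disjoint partition."""
    a, b, c = set_a.genes, set_b.genes, set_c.genes
    regions = {
        "ABC": a & b & c,
        "AB_only": (a & b) - c,
        "AC_only": (a & c) - b,
        "BC_only": (b & c) - a,
        "A_only": a - b - c,
        "B_only": b - a - c,
        "C_only": c - a - b,
    }
    return VennPartition(
        labels=(set_a.label, set_b.label, set_c.label),
        regions={k: frozenset(v) for k, v in regions.items()},
    )


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    day_from: int
    day_to: int
    mean_from: float
    mean_to: float
    fold_change: float


def fold_change(
    matrix_from: ExpressionMatrix,
    matrix_to: ExpressionMatrix,
    gene: str,
    focal_tissue: str,
    day_from: int,
    day_to: int,
    pseudocount: float = 0.0,
) -> FoldChangeResult:
    """Fold change of a gene's mean focal-tissue FPKM between two days.

    fold_change = (mean_to + eps) / (mean_from + eps). The default eps of 0
    gives the raw ratio of replicate means; pass the scoring pseudocount to
    stabilize genes silent on one day.
    """
    for m, d, which in ((matrix_from, day_from, "from"), (matrix_to, day_to, "to")):
        if gene not in m.gene_ids:
            raise KeyError(f"gene {gene!r} absent from the day-{d} ({which}) matrix")
    ids_from = matrix_from.select_samples(tissue=focal_tissue, day=day_from)
    ids_to = matrix_to.select_samples(tissue=focal_tissue, day=day_to)
    if not ids_from or not ids_to:
        raise ValueError(
            f"no {focal_tissue!r} samples on day {day_from} or {day_to}"
        )
    mean_from = float(matrix_from.values_for(ids_from).loc[gene].mean())
    mean_to = float(matrix_to.values_for(ids_to).loc[gene].mean())
    denominator = mean_from + pseudocount
    if denominator == 0:
        raise ZeroDivisionError(
            f"gene {gene!r} has zero mean FPKM on day {day_from} and pseudocount is 0"
        )
    return FoldChangeResult(
        gene_id=gene,
        day_from=day_from,
        day_to=day_to,
        mean_from=mean_from,
        mean_to=mean_to,
        fold_change=(mean_to + pseudocount) / denominator,
    )


def fold_change_table(
    matrix_from: ExpressionMatrix,
    matrix_to: ExpressionMatrix,
    genes,
    focal_tissue: str,
    day_from: int,
    day_to: int,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """``fold_change`` for several genes, as a DataFrame."""
    results = [
        fold_change(
            matrix_from, matrix_to, g, focal_tissue, day_from, day_to, pseudocount
        )
        for g in genes
    ]
    return pd.DataFrame(
        [
            (r.gene_id, r.day_from, r.day_to, r.mean_from, r.mean_to, r.fold_change)
            for r in results
        ],
        columns=["gene_id", "day_from", "day_to", "mean_from", "mean_to", "fold_change"],
    )
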