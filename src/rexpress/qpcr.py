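"""qPCR delta-Ct validation statistics.

Per gene and day, relative expression is summarized as the *inverse delta
Ct*: technical replicates are averaged within each biological replicate,
delta Ct = mean target Ct − mean reference Ct per biological replicate, and
the inverse (negated) deltas are averaged over biological replicates with
one standard error of the mean (sample SD / sqrt(n)). Higher inverse delta
Ct means higher expression relative to the reference gene. No calibrator-day
normalization (ddCt) or amplification-efficiency correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

CT_COLUMNS = (
    "gene_id",
    "day",
    "biological_replicate",
    "technical_replicate",
    "ct_target",
    "ct_reference",
)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: threshold cycles of the target and the reference gene."""

    gene_id: str
    day: int
    biological_replicate: int
    technical_replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            ct = getattr(self, name)
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(
                    f"{name} must be finite and > 0, got {ct!r} "
                    f"(gene {self.gene_id}, day {self.day})"
                )


@dataclass(frozen=True)
class DeltaCtResult:
    """Mean inverse delta Ct over biological replicates, with its SEM.

    ``sem`` is NaN and ``sem_defined`` False when only one biological
    replicate is available.
    """

    gene_id: str
    day: int
    n_biological: int
    mean_inverse_delta_ct: float
    sem: float
    sem_defined: bool


def delta_ct_summary(
    records: Sequence[CtRecord], gene: str, day: int
) -> DeltaCtResult:
    """Summarize inverse delta Ct for one (gene, day).

    Technical replicates are averaged first within each biological
    replicate; the mean and SEM are taken over biological replicates.
    """
    selected = [r for r in records if r.gene_id == gene and r.day == day]
    if not selected:
        raise ValueError(f"no Ct records for gene {gene!r}, day {day}")
    by_bio: dict[int, list[CtRecord]] = {}
    for r in selected:
        by_bio.setdefault(r.biological_replicate, []).append(r)
    inverse_deltas = []
    for bio in sorted(by_bio):
        wells = by_bio[bio]
        mean_target = float(np.mean([w.ct_target for w in wells]))
        mean_reference = float(np.mean([w.ct_reference for w in wells]))
        inverse_deltas.append(-(mean_target - mean_reference))
    n = len(inverse_deltas)
    mean = float(np.mean(inverse_deltas))
    if n > 1:
        sem = float(np.std(inverse_deltas, ddof=1) / math.sqrt(n))
        return DeltaCtResult(gene, day, n, mean, sem, True)
    return DeltaCtResult(gene, day, n, mean, float("nan"), False)


def delta_ct_table(records: Sequence[CtRecord]) -> pd.DataFrame:
    """``delta_ct_summary`` for every (gene, day) present, as a DataFrame."""
    pairs = sorted({(r.gene_id, r.day) for r in records})
    rows = []
    for gene, day in pairs:
        res = delta_ct_summary(records, gene, day)
        rows.append(
            (res.gene_id, res.day, res.n_biological,
             res.mean_inverse_delta_ct, res.sem)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "day", "n_biological", "mean_inverse_delta_ct", "sem"],
    )


def load_ct_table(path) -> List[CtRecord]:
    """Read a TSV Ct table with the :data:`CT_COLUMNS` header.

    Malformed rows (non-numeric or non-positive Ct, missing fields) raise a
    ValueError naming the line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                CtRecord(
                    gene_id=str(row.gene_id).strip(),
                    day=int(row.day),
                    biological_replicate=int(row.biological_replicate),
                    technical_replicate=int(row.technical_replicate),
                    ct_target=float(row.ct_target),
                    ct_reference=float(row.ct_reference),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def write_ct_table(records: Iterable[CtRecord], path) -> None:
    pd.DataFrame(
        [
            (r.gene_id, r.day, r.biological_replicate, r.technical_replicate,
             r.ct_target, r.ct_reference)
            for r in records
        ],
        columns=list(CT_COLUMNS),
    ).to_csv(path, sep="\t", index=False)
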