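"""Synthetic multi-tissue FPKM compendia with planted tissue-enriched genes.

The generator emulates the study design the pipeline targets: a focal tissue
(chicken pituitary, with 15/10/10 biological replicates at post-hatch days
21/22/42) plus 13 comparison tissues, profiled independently on each day.
Expression is log-normal: each gene draws a log2 baseline, each (gene,
tissue, day) a tissue offset, each sample a replicate noise term, and
FPKM = 2**(baseline + offset + noise). A configurable subset of genes is
"planted" as focal-enriched on chosen days (all focal-tissue values on that
day multiplied by ``planted_fold``), laid out in a three-way Venn pattern so
set-level recovery can be checked against ground truth. Per (gene, non-focal
tissue, day), expression is zeroed with probability ``dropout_fraction`` to
model tissue-absent genes — the degenerate case the scoring stage must
handle.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` stream; the same config yields bitwise-identical
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Tuple

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneList

DEFAULT_FOCAL_TISSUE = "pituitary"
DEFAULT_COMPARISON_TISSUES = (
    "abdominal_fat_pad",
    "heart_fat_pad",
    "breast_muscle",
    "cerebellum",
    "heart",
    "liver",
    "duodenum",
    "jejunum",
    "ileum",
    "spleen",
    "retina",
    "pineal",
    "hypothalamus",
)
DEFAULT_DAYS = (21, 22, 42)
DEFAULT_FOCAL_REPLICATES = {21: 15, 22: 10, 42: 10}
DEFAULT_OTHER_REPLICATES = 3

Region = FrozenSet[int]


def _region(*days: int) -> Region:
    return frozenset(days)


#: Planted-gene counts per Venn region of the three default days, matching
#: the enriched-gene structure reported for the chicken pituitary study:
#: 25 genes enriched on all three days, 295 shared by days 21 and 22 only,
#: 74 / 92 / 407 unique to days 21 / 22 / 42, and no 21∩42- or 22∩42-only
#: genes.
DEFAULT_VENN_COUNTS: Dict[Region, int] = {
    _region(21, 22, 42): 25,
    _region(21, 22): 295,
    _region(21, 42): 0,
    _region(22, 42): 0,
    _region(21): 74,
    _region(22): 92,
    _region(42): 407,
}


def region_name(region: Region) -> str:
    return "d" + "_d".join(str(d) for d in sorted(region))


def _default_replicates(
    tissues: Tuple[str, ...], days: Tuple[int, ...], focal: str
) -> Dict[str, Dict[int, int]]:
    out: Dict[str, Dict[int, int]] = {}
    for tissue in tissues:
        if tissue == focal:
            out[tissue] = {
                d: DEFAULT_FOCAL_REPLICATES.get(d, 10) for d in days
            }
        else:
            out[tissue] = {d: DEFAULT_OTHER_REPLICATES for d in days}
    return out


@dataclass
class SimulationConfig:
    """Parameters of the synthetic compendium.

    Defaults reproduce the study conditions: 5000 genes, pituitary plus 13
    comparison tissues, days 21/22/42 with 15/10/10 focal replicates (3 per
    comparison tissue), a 50-fold planted enrichment, and the published
    Venn layout of enriched genes.
    """

    n_genes: int = 5000
    tissues: Tuple[str, ...] = (DEFAULT_FOCAL_TISSUE,) + DEFAULT_COMPARISON_TISSUES
    focal_tissue: str = DEFAULT_FOCAL_TISSUE
    days: Tuple[int, ...] = DEFAULT_DAYS
    replicates_per_tissue_day: Dict[str, Dict[int, int]] | None = None
    baseline_log2_mean: float = 3.0
    baseline_log2_sd_between_genes: float = 2.0
    between_tissue_sd: float = 0.5
    replicate_sd: float = 0.25
    dropout_fraction: float = 0.05
    planted_fold: float = 50.0
    venn_counts: Dict[Region, int] = field(
        default_factory=lambda: dict(DEFAULT_VENN_COUNTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.tissues = tuple(self.tissues)
        self.days = tuple(self.days)
        if self.replicates_per_tissue_day is None:
            self.replicates_per_tissue_day = _default_replicates(
                self.tissues, self.days, self.focal_tissue
            )
        self.venn_counts = {frozenset(k): int(v) for k, v in self.venn_counts.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.focal_tissue not in self.tissues:
            raise ValueError(
                f"focal tissue {self.focal_tissue!r} not in tissue list"
            )
        if self.planted_fold <= 1:
            raise ValueError("planted_fold must exceed 1")
        for name in ("baseline_log2_sd_between_genes", "between_tissue_sd", "replicate_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.dropout_fraction <= 1:
            raise ValueError("dropout_fraction must lie in [0, 1]")
        total_planted = sum(self.venn_counts.values())
        if total_planted > self.n_genes:
            raise ValueError(
                f"venn_counts total {total_planted} exceeds n_genes {self.n_genes}"
            )
        day_set = set(self.days)
        for region in self.venn_counts:
            if not region or not region <= day_set:
                raise ValueError(
                    f"venn region {set(region)} not a non-empty subset of days {sorted(day_set)}"
                )
        for tissue in self.tissues:
            reps = self.replicates_per_tissue_day.get(tissue, {})
            for day in self.days:
                if reps.get(day, 0) < 1:
                    raise ValueError(
                        f"no replicate count for tissue {tissue!r}, day {day}"
                    )


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of the planted signal: gene → set of days on which it is
    focal-enriched."""

    planted: Mapping[str, Region]

    def genes_for_day(self, day: int, label: str | None = None) -> GeneList:
        return GeneList(
            label=label or f"day{day}",
            genes=frozenset(g for g, ds in self.planted.items() if day in ds),
        )

    def region_counts(self) -> Dict[Region, int]:
        counts: Dict[Region, int] = {}
        for region in self.planted.values():
            counts[region] = counts.get(region, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, ",".join(str(d) for d in sorted(ds)))
            for g, ds in sorted(self.planted.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "planted_days"])


def default_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-design defaults: pituitary + 13 tissues, days 21/22/42 with
    15/10/10 focal replicates, and the published enriched-gene Venn layout
    (25 shared by all days, 295 by days 21∩22 only, 74/92/407 unique)."""
    return SimulationConfig(seed=seed, **overrides)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_compendium(
    config: SimulationConfig,
) -> Tuple[Dict[int, ExpressionMatrix], TruthTable]:
    """Draw one FPKM matrix per day plus the planted-gene truth table.

    Gene baselines are shared across days; tissue offsets, replicate noise
    and dropout are redrawn per day, matching a design in which each day is
    analyzed independently. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)

    # assign planted genes to Venn regions from one shuffled pool
    pool = rng.permutation(config.n_genes)
    planted: Dict[str, Region] = {}
    cursor = 0
    for region in sorted(config.venn_counts, key=lambda r: tuple(sorted(r))):
        count = config.venn_counts[region]
        for idx in pool[cursor : cursor + count]:
            planted[genes[idx]] = region
        cursor += count
    truth = TruthTable(planted=planted)

    planted_mask_by_day: Dict[int, np.ndarray] = {}
    for day in config.days:
        mask = np.zeros(config.n_genes, dtype=bool)
        day_genes = {g for g, ds in planted.items() if day in ds}
        if day_genes:
            gene_pos = {g: i for i, g in enumerate(genes)}
            mask[[gene_pos[g] for g in day_genes]] = True
        planted_mask_by_day[day] = mask

    baselines = rng.normal(
        config.baseline_log2_mean,
        config.baseline_log2_sd_between_genes,
        config.n_genes,
    )
    log2_fold = np.log2(config.planted_fold)

    matrices: Dict[int, ExpressionMatrix] = {}
    for day in config.days:
        columns: dict[str, np.ndarray] = {}
        meta_rows = []
        for tissue in config.tissues:
            n_rep = config.replicates_per_tissue_day[tissue][day]
            offsets = rng.normal(0.0, config.between_tissue_sd, config.n_genes)
            noise = rng.normal(0.0, config.replicate_sd, (config.n_genes, n_rep))
            log2val = baselines[:, None] + offsets[:, None] + noise
            if tissue == config.focal_tissue:
                log2val[planted_mask_by_day[day], :] += log2_fold
            fpkm = np.exp2(log2val)
            if tissue != config.focal_tissue and config.dropout_fraction > 0:
                dropped = rng.random(config.n_genes) < config.dropout_fraction
                fpkm[dropped, :] = 0.0
            for rep in range(1, n_rep + 1):
                sid = f"{tissue}_d{day}_r{rep}"
                columns[sid] = fpkm[:, rep - 1]
                meta_rows.append((sid, tissue, day, rep))
        values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
        samples = pd.DataFrame(
            meta_rows, columns=["sample_id", "tissue", "day", "replicate"]
        )
        matrices[day] = ExpressionMatrix(values, samples)
    return matrices, truth


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-design config with no planted genes (all Venn counts zero)."""
    counts = {region: 0 for region in DEFAULT_VENN_COUNTS}
    overrides.setdefault("venn_counts", counts)
    return SimulationConfig(seed=seed, **overrides)
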