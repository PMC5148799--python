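"""Relative tissue expression (rEx) scoring.

For one post-hatch day, every gene is scored by comparing its *maximum* FPKM
across focal-tissue samples to its *median* FPKM across all other tissues'
samples:

    log2_ratio = log2((focal_max + eps) / (other_median + eps))

The log2 ratios are standardized against the all-gene ratio distribution
(z-score with the sample standard deviation), and a per-gene two-sided Welch
t-test compares log2(FPKM + eps) of focal vs. non-focal replicates. A gene
is called *enriched* in the focal tissue when its z-score exceeds the
threshold (default +2 standard deviations, upper tail only) and its t-test
p-value is below the threshold (default 0.05, uncorrected).

The pseudocount eps (default 0.1 FPKM) bounds the ratio when the non-focal
median is zero — the tissue-absent case — and keeps every gene scoreable.
Each day is scored independently; scores for a day depend only on that
day's samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneList

SCORE_COLUMNS = (
    "gene_id",
    "focal_max",
    "other_median",
    "log2_ratio",
    "z_score",
    "p_value",
    "enriched",
)


@dataclass(frozen=True)
class EnrichmentCriteria:
    """Thresholds and options of the enrichment call.

    z_threshold
        Minimum z-score of the log2 ratio, in standard deviations of the
        all-gene ratio distribution (upper tail only).
    p_threshold
        Maximum t-test p-value (applied to BH-adjusted values when
        ``multiple_testing="benjamini_hochberg"``).
    pseudocount
        FPKM added inside the log2 on both numerator and denominator.
    t_test
        ``"welch"``: per-gene two-sided Welch test of focal vs. non-focal
        log2(FPKM + eps) replicates (default). ``"ratio_normal"``: two-sided
        normal p-value of the gene's standardized log2 ratio — a one-sample
        test against the global ratio distribution.
    median_mode
        ``"pooled"``: median over all non-focal samples pooled (default);
        ``"per_tissue"``: median of per-tissue medians.
    min_focal_fpkm
        Optional expression floor: genes whose focal maximum falls below it
        are never called enriched (default off).
    """

    z_threshold: float = 2.0
    p_threshold: float = 0.05
    pseudocount: float = 0.1
    multiple_testing: Literal["none", "benjamini_hochberg"] = "none"
    t_test: Literal["welch", "ratio_normal"] = "welch"
    median_mode: Literal["pooled", "per_tissue"] = "pooled"
    min_focal_fpkm: float | None = None

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.multiple_testing not in ("none", "benjamini_hochberg"):
            raise ValueError(f"unknown multiple_testing {self.multiple_testing!r}")
        if self.t_test not in ("welch", "ratio_normal"):
            raise ValueError(f"unknown t_test mode {self.t_test!r}")
        if self.median_mode not in ("pooled", "per_tissue"):
            raise ValueError(f"unknown median_mode {self.median_mode!r}")


class DegenerateRatioError(ValueError):
    """All genes share one log2 ratio; the z-score is undefined."""


def compute_rex_scores(
    matrix: ExpressionMatrix,
    focal_tissue: str,
    day: int,
    criteria: EnrichmentCriteria = EnrichmentCriteria(),
) -> pd.DataFrame:
    """Score every gene of one day for focal-tissue enrichment.

    Returns a DataFrame with one row per gene and columns ``gene_id``,
    ``focal_max``, ``other_median``, ``log2_ratio``, ``z_score``,
    ``p_value`` (NaN when undefined, e.g. fewer than two replicates on a
    side of the Welch test or a zero-variance gene), ``p_adjusted`` (when
    BH correction is requested) and ``enriched``. Genes with an undefined
    p-value are never called enriched.
    """
    if focal_tissue not in set(matrix.samples["tissue"]):
        raise ValueError(f"focal tissue {focal_tissue!r} not present in matrix")
    if day not in set(matrix.samples["day"]):
        raise ValueError(f"day {day} absent from sample metadata")
    focal_ids = matrix.select_samples(tissue=focal_tissue, day=day)
    other_ids = matrix.select_samples(exclude_tissue=focal_tissue, day=day)
    if not focal_ids:
        raise ValueError(f"no {focal_tissue!r} samples on day {day}")
    if len(other_ids) < 2:
        raise ValueError(
            f"need at least 2 non-focal samples on day {day}, found {len(other_ids)}"
        )
    if matrix.n_genes == 0:
        raise ValueError("matrix has no genes")

    eps = criteria.pseudocount
    focal = matrix.values_for(focal_ids).to_numpy()
    other = matrix.values_for(other_ids).to_numpy()

    focal_max = focal.max(axis=1)
    if criteria.median_mode == "pooled":
        other_median = np.median(other, axis=1)
    else:
        other_meta = matrix.samples.set_index("sample_id").loc[other_ids]
        per_tissue = [
            np.median(
                matrix.values_for(
                    other_meta.index[other_meta["tissue"] == t]
                ).to_numpy(),
                axis=1,
            )
            for t in other_meta["tissue"].unique()
        ]
        other_median = np.median(np.column_stack(per_tissue), axis=1)

    log2_ratio = np.log2((focal_max + eps) / (other_median + eps))
    sd = log2_ratio.std(ddof=1) if len(log2_ratio) > 1 else 0.0
    if sd == 0:
        raise DegenerateRatioError("degenerate ratio distribution")
    z = (log2_ratio - log2_ratio.mean()) / sd

    if criteria.t_test == "welch":
        if focal.shape[1] >= 2:
            with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                # constant genes yield a 0/0 t statistic; they surface as
                # NaN p-values and are excluded from enrichment calls
                warnings.simplefilter("ignore", RuntimeWarning)
                _, p = stats.ttest_ind(
                    np.log2(focal + eps),
                    np.log2(other + eps),
                    axis=1,
                    equal_var=False,
                )
            p = np.asarray(p, dtype=float)
        else:
            # a single focal replicate leaves the Welch test undefined
            p = np.full(matrix.n_genes, np.nan)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))

    scores = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "focal_max": focal_max,
            "other_median": other_median,
            "log2_ratio": log2_ratio,
            "z_score": z,
            "p_value": p,
        }
    ).reset_index(drop=True)

    p_effective = scores["p_value"].to_numpy(copy=True)
    if criteria.multiple_testing == "benjamini_hochberg":
        defined = np.isfinite(p_effective)
        adjusted = np.full_like(p_effective, np.nan)
        if defined.any():
            adjusted[defined] = multipletests(
                p_effective[defined], method="fdr_bh"
            )[1]
        scores["p_adjusted"] = adjusted
        p_effective = adjusted

    with np.errstate(invalid="ignore"):
        enriched = (z > criteria.z_threshold) & (p_effective < criteria.p_threshold)
    enriched &= np.isfinite(scores["p_value"].to_numpy())
    if criteria.min_focal_fpkm is not None:
        enriched &= focal_max >= criteria.min_focal_fpkm
    scores["enriched"] = enriched
    return scores


def call_enriched(
    scores: pd.DataFrame,
    criteria: EnrichmentCriteria = EnrichmentCriteria(),
    label: str = "enriched",
) -> GeneList:
    """Apply the enrichment criteria to a score table and return the gene set.

    Re-derives the call from the ``z_score`` / ``p_value`` columns so it can
    be used on a stored score table with different thresholds; with
    ``multiple_testing="benjamini_hochberg"`` the p threshold is applied to
    BH-adjusted p-values.
    """
    if scores.empty:
        raise ValueError("score table is empty")
    z = scores["z_score"].to_numpy(dtype=float)
    p = scores["p_value"].to_numpy(dtype=float)
    defined = np.isfinite(p)
    p_effective = np.full_like(p, np.nan)
    if criteria.multiple_testing == "benjamini_hochberg":
        if defined.any():
            p_effective[defined] = multipletests(p[defined], method="fdr_bh")[1]
    else:
        p_effective[defined] = p[defined]
    with np.errstate(invalid="ignore"):
        mask = (z > criteria.z_threshold) & (p_effective < criteria.p_threshold)
    mask &= defined
    if criteria.min_focal_fpkm is not None and "focal_max" in scores:
        mask &= scores["focal_max"].to_numpy() >= criteria.min_focal_fpkm
    genes = frozenset(scores.loc[mask, "gene_id"])
    return GeneList(label=label, genes=genes)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)
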