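"""End-to-end orchestration: per-day rEx scoring → enriched lists → Venn
decomposition → optional term summaries, with a run manifest.

Each day is scored strictly independently; the three per-day enriched lists
are then decomposed into the 7-region Venn partition (A = earliest day,
B = middle, C = latest). When an annotation table is supplied, every day's
enriched list is additionally summarized against it with the Fisher
over-representation test, using that day's scored gene universe as
background.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd

from .annotation import filter_transcription_factors, summarize_terms
from .io import (
    AnnotationTable,
    ExpressionMatrix,
    GeneList,
    write_gene_list,
)
from .rex import EnrichmentCriteria, call_enriched, compute_rex_scores, write_scores
from .sets import VennPartition, venn_partition

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Record of one pipeline run: enough to re-execute it bit-identically."""

    config: dict
    seed: Optional[int]
    input_digests: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    scores: Dict[int, pd.DataFrame]
    enriched: Dict[int, GeneList]
    venn: VennPartition
    term_summaries: Dict[int, pd.DataFrame]
    tf_lists: Dict[int, GeneList]
    manifest: RunManifest


def run_full_analysis(
    matrices: Mapping[int, ExpressionMatrix],
    focal_tissue: str = "pituitary",
    criteria: EnrichmentCriteria = EnrichmentCriteria(),
    annotation: AnnotationTable | None = None,
    out_dir=None,
    seed: int | None = None,
    config_snapshot: dict | None = None,
) -> PipelineResult:
    """Run scoring, enrichment calls, the Venn decomposition and (optionally)
    term summaries for a three-day compendium.

    ``matrices`` maps post-hatch day → that day's expression matrix; exactly
    three days are required for the Venn decomposition. All outputs are
    plain TSV/text when ``out_dir`` is given, and a manifest recording
    output paths and stage counts is always produced.
    """
    days = sorted(matrices)
    if len(days) != 3:
        raise ValueError(f"need exactly 3 days for the Venn decomposition, got {days}")
    for day, m in matrices.items():
        if m.n_genes == 0:
            raise ValueError(f"day-{day} matrix has no genes")
    universes = [frozenset(matrices[d].gene_ids) for d in days]
    if not (universes[0] == universes[1] == universes[2]):
        raise ValueError("the per-day matrices must share one gene universe")

    manifest = RunManifest(
        config=config_snapshot
        or {"focal_tissue": focal_tissue, "criteria": dataclasses.asdict(criteria)},
        seed=seed,
    )
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    scores: Dict[int, pd.DataFrame] = {}
    enriched: Dict[int, GeneList] = {}
    term_summaries: Dict[int, pd.DataFrame] = {}
    tf_lists: Dict[int, GeneList] = {}

    for day in days:
        day_scores = compute_rex_scores(matrices[day], focal_tissue, day, criteria)
        day_list = call_enriched(day_scores, criteria, label=f"day{day}")
        scores[day] = day_scores
        enriched[day] = day_list
        manifest.counts[f"genes_scored_day{day}"] = len(day_scores)
        manifest.counts[f"genes_enriched_day{day}"] = len(day_list)
        logger.info(
            "day %d: scored %d genes, %d enriched", day, len(day_scores), len(day_list)
        )
        if out is not None:
            score_path = out / f"rex_scores_d{day}.tsv"
            list_path = out / f"enriched_d{day}.txt"
            write_scores(day_scores, score_path)
            write_gene_list(day_list, list_path)
            manifest.outputs[f"scores_day{day}"] = str(score_path)
            manifest.outputs[f"enriched_day{day}"] = str(list_path)
        if annotation is not None:
            universe = GeneList(
                label=f"universe_day{day}", genes=frozenset(matrices[day].gene_ids)
            )
            summary = summarize_terms(day_list, annotation, universe)
            term_summaries[day] = summary
            tf_lists[day] = filter_transcription_factors(day_list, annotation)
            manifest.counts[f"terms_hit_day{day}"] = len(summary)
            manifest.counts[f"tf_enriched_day{day}"] = len(tf_lists[day])
            if out is not None:
                term_path = out / f"terms_d{day}.tsv"
                summary.to_csv(term_path, sep="\t", index=False)
                manifest.outputs[f"terms_day{day}"] = str(term_path)

    venn = venn_partition(enriched[days[0]], enriched[days[1]], enriched[days[2]])
    for region, members in venn.sizes().items():
        manifest.counts[f"venn_{region}"] = members
    logger.info(
        "venn regions (A=day %d, B=day %d, C=day %d): %s",
        days[0], days[1], days[2], venn.sizes(),
    )
    if out is not None:
        venn_path = out / "venn.tsv"
        venn.to_frame().to_csv(venn_path, sep="\t", index=False)
        manifest.outputs["venn"] = str(venn_path)
        manifest_path = out / "manifest.json"
        manifest.write(manifest_path)
        manifest.outputs["manifest"] = str(manifest_path)

    return PipelineResult(
        scores=scores,
        enriched=enriched,
        venn=venn,
        term_summaries=term_summaries,
        tf_lists=tf_lists,
        manifest=manifest,
    )
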