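"""End-to-end orchestration: alignments in, expression tables out.

``run_pipeline`` wires the stages together: Stage-1 filtering of the
per-haplotype alignments, read-to-gene assignment with cross-haplotype
consistency, edit-distance weighting and candidate haplotype pairs per gene,
the switch-penalised shortest path over the gene order, and finally gene and
haplotype quantification. It accepts either in-memory alignment records (as
produced by the bundled simulator/aligner) or SAM/BAM paths from any mapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import alignio, assign, hapgraph, quantify, rates, refset
from .config import RunConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    calls: dict[str, hapgraph.HaplotypeCall]
    results: list[quantify.GeneExpression]
    expression: pd.DataFrame
    ratios: pd.DataFrame
    pair_scores: list[rates.PairScore]
    matrices: dict[str, rates.MappingRateMatrix]
    candidates: dict[str, list[rates.Pair]]
    assignments: list[assign.ReadGeneAssignment]
    discards: list[assign.DiscardRecord]
    filter_stats: dict[str, alignio.FilterStats]
    gene_order: list[str]


def load_alignments(
    sam_paths: Mapping[str, str],
    config: RunConfig,
) -> tuple[dict[str, list[alignio.ReadAlignment]], dict[str, alignio.FilterStats]]:
    """Read + Stage-1 filter one SAM/BAM per haplotype."""
    alignments: dict[str, list[alignio.ReadAlignment]] = {}
    stats: dict[str, alignio.FilterStats] = {}
    for hap, path in sam_paths.items():
        alignments[hap], stats[hap] = alignio.read_alignments(
            path, hap, min_mapq=config.min_mapq, md_fallback=config.md_fallback
        )
        log.info(
            "stage1 %s: %d records in, %d retained",
            hap, stats[hap].total, stats[hap].retained,
        )
    return alignments, stats


def filter_raw_alignments(
    raw: Mapping[str, Sequence[alignio.ReadAlignment]],
    config: RunConfig,
) -> tuple[dict[str, list[alignio.ReadAlignment]], dict[str, alignio.FilterStats]]:
    """Stage-1 filter already-parsed alignment records (in-memory path)."""
    out: dict[str, list[alignio.ReadAlignment]] = {}
    stats: dict[str, alignio.FilterStats] = {}
    for hap, records in raw.items():
        st = alignio.FilterStats(total=len(records))
        kept = []
        for a in records:
            if a.is_duplicate:
                st.duplicate += 1
            elif a.mapq < config.min_mapq:
                st.low_mapq += 1
            else:
                kept.append(a)
        kept, n_multi = alignio.drop_multi_locus(kept)
        st.multimapped = n_multi
        st.retained = len(kept)
        st.check()
        out[hap] = kept
        stats[hap] = st
    return out, stats


def run_pipeline(
    alignments: Mapping[str, Sequence[alignio.ReadAlignment]] | Mapping[str, str],
    panel: refset.HaplotypePanel,
    models: Sequence[refset.GeneModel],
    config: RunConfig | None = None,
    prefiltered: bool = False,
) -> PipelineResult:
    """Run assignment, weighting, graph solve and quantification.

    Parameters
    ----------
    alignments:
        Either haplotype -> SAM/BAM path, or haplotype -> in-memory
        :class:`~hapquant.alignio.ReadAlignment` records.
    panel, models:
        The haplotype panel and its (already filtered) gene models.
    prefiltered:
        Set when in-memory records have already passed Stage-1 filtering.
    """
    config = config or RunConfig()
    first = next(iter(alignments.values()), None)
    if first is None:
        raise refset.ValidationError("no alignments given")
    if isinstance(first, str):
        filtered, stats = load_alignments(alignments, config)  # type: ignore[arg-type]
    elif prefiltered:
        filtered = {h: list(v) for h, v in alignments.items()}  # type: ignore[union-attr]
        stats = {
            h: alignio.FilterStats(total=len(v), retained=len(v))
            for h, v in filtered.items()
        }
    else:
        filtered, stats = filter_raw_alignments(alignments, config)  # type: ignore[arg-type]

    assignments, discards = assign.assign_reads(
        filtered, models, stranded=config.stranded
    )
    log.info(
        "stage2: %d read pairs assigned, %d discarded",
        len(assignments), len(discards),
    )

    haps_by_gene: dict[str, list[str]] = {}
    for m in models:
        haps_by_gene.setdefault(m.gene_id, []).append(m.haplotype)

    by_gene: dict[str, list[assign.ReadGeneAssignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene_id, []).append(a)

    matrices: dict[str, rates.MappingRateMatrix] = {}
    scores_by_gene: dict[str, list[rates.PairScore]] = {}
    candidates: dict[str, list[rates.Pair]] = {}
    for gene_id, gene_assignments in by_gene.items():
        matrix = rates.mapping_rate_matrix(
            gene_assignments, score=config.score_function
        )
        scores = rates.pair_scores(
            matrix,
            gene_assignments,
            haplotypes=haps_by_gene[gene_id],
            pair_rate=config.pair_rate,
        )
        matrices[gene_id] = matrix
        scores_by_gene[gene_id] = scores
        candidates[gene_id] = rates.candidate_pairs(
            scores, top_percentile=config.top_percentile
        )

    _, order = refset.gene_order(models, panel)
    graph = hapgraph.build_gene_graph(
        order,
        candidates,
        scores_by_gene,
        penalty=config.penalty,
        epsilon=config.epsilon,
    )
    calls_list = hapgraph.best_haplotype_path(graph)
    calls = {c.gene_id: c for c in calls_list}
    log.info("stage3: %d genes called over %d-gene order", len(calls), len(order))

    results = quantify.quantify_genes(
        assignments, calls, unique_scope=config.unique_scope
    )
    expression = quantify.expression_frame(results)
    ratios = quantify.haplotype_ratio_table(results, min_depth=config.min_depth)
    all_scores = [s for gene in sorted(scores_by_gene) for s in scores_by_gene[gene]]
    return PipelineResult(
        calls=calls,
        results=results,
        expression=expression,
        ratios=ratios,
        pair_scores=all_scores,
        matrices=matrices,
        candidates=candidates,
        assignments=assignments,
        discards=discards,
        filter_stats=stats,
        gene_order=order,
    )
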