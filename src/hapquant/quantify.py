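"""Gene counts, haplotype counts, ratio tables and output files.

Gene counts are read-pair counts restricted to the called haplotype pair: a
pair counts once when it aligns to at least one member of the pair. Haplotype
counts split a gene's (normalised) count between the two called haplotypes by
the proportion of reads mapping uniquely to each member — a read is *unique*
when it aligns to exactly one haplotype of the called pair (a stricter
"global" scope, unique across the whole panel, is available). Homozygous
genes split evenly. Major/minor expression ratios are reported only for
heterozygous genes with at least ``min_depth`` (default 30) in both
haplotypes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assign import ReadGeneAssignment
from .hapgraph import HaplotypeCall
from .rates import MappingRateMatrix, PairScore


@dataclass
class GeneExpression:
    """Quantification result for one gene under its called pair."""

    gene_id: str
    pair: tuple[str, str] | None
    zygosity: str
    gene_count: int
    combined_rate: float | None
    hap_counts: dict[str, float]  # empty when undefined
    unique_counts: dict[str, int]
    mismatch_rates: dict[str, float]
    undefined_split: bool = False  # het gene with zero unique reads


def gene_counts(
    assignments: Sequence[ReadGeneAssignment],
    calls: Mapping[str, HaplotypeCall],
) -> dict[str, int]:
    """Read pairs per gene aligning to >= 1 member of the called pair."""
    counts: dict[str, int] = {g: 0 for g in calls}
    for a in assignments:
        call = calls.get(a.gene_id)
        if call is None or call.pair is None:
            continue
        if any(h in a.dist_by_haplotype for h in set(call.pair)):
            counts[a.gene_id] += 1
    return counts


def unique_read_counts(
    assignments: Sequence[ReadGeneAssignment],
    call: HaplotypeCall,
    scope: str = "pair",
) -> dict[str, int]:
    """Reads mapping uniquely to each member of the called pair.

    ``scope="pair"``: unique within the called pair (aligns to h1 xor h2).
    ``scope="global"``: additionally must align to no other haplotype at all.
    """
    assert call.pair is not None
    h1, h2 = call.pair
    uniq = {h1: 0, h2: 0}
    for a in assignments:
        if a.gene_id != call.gene_id:
            continue
        members = [h for h in {h1, h2} if h in a.dist_by_haplotype]
        if len(members) != 1:
            continue
        if scope == "global" and len(a.dist_by_haplotype) != 1:
            continue
        uniq[members[0]] += 1
    return uniq


def haplotype_counts(
    assignments: Sequence[ReadGeneAssignment],
    call: HaplotypeCall,
    normalized_gene_count: float,
    scope: str = "pair",
) -> tuple[dict[str, float], dict[str, int], bool]:
    """Split a gene count between the called haplotypes.

    Heterozygous: ``count_h = normalized_gene_count * unique_h / total_unique``
    (undefined, flagged, when no unique read exists). Homozygous: the count is
    halved between the two identical haplotype slots.

    Returns ``(hap_counts, unique_counts, undefined_flag)``.
    """
    assert call.pair is not None
    h1, h2 = call.pair
    uniq = unique_read_counts(assignments, call, scope=scope)
    if h1 == h2:
        return {h1: normalized_gene_count / 2.0}, uniq, False
    total = uniq[h1] + uniq[h2]
    if total == 0:
        return {}, uniq, True
    return (
        {
            h1: normalized_gene_count * uniq[h1] / total,
            h2: normalized_gene_count * uniq[h2] / total,
        },
        uniq,
        False,
    )


def mismatch_rate(
    assignments: Sequence[ReadGeneAssignment],
    call: HaplotypeCall,
) -> dict[str, float]:
    """Mean per-base edit distance of the gene's reads on each called
    haplotype (sum of distances / sum of aligned read bases)."""
    assert call.pair is not None
    rates: dict[str, float] = {}
    for h in sorted(set(call.pair)):
        dist = bases = 0
        for a in assignments:
            if a.gene_id == call.gene_id and h in a.dist_by_haplotype:
                dist += a.dist_by_haplotype[h]
                bases += a.bases
        rates[h] = dist / bases if bases else 0.0
    return rates


def quantify_genes(
    assignments: Sequence[ReadGeneAssignment],
    calls: Mapping[str, HaplotypeCall],
    unique_scope: str = "pair",
) -> list[GeneExpression]:
    """Full per-gene quantification under the called haplotype pairs.

    The normalised gene count equals the raw count at single-sample scope
    (cross-sample normalisation is outside the pipeline); the split formula
    applies to whatever count is provided downstream.
    """
    by_gene: dict[str, list[ReadGeneAssignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene_id, []).append(a)
    counts = gene_counts(assignments, calls)
    out: list[GeneExpression] = []
    for gene_id in calls:
        call = calls[gene_id]
        if call.pair is None:
            out.append(
                GeneExpression(
                    gene_id, None, "wildcard", 0, None, {}, {}, {}, False
                )
            )
            continue
        gene_assignments = by_gene.get(gene_id, [])
        count = counts[gene_id]
        hap, uniq, undefined = haplotype_counts(
            gene_assignments, call, float(count), scope=unique_scope
        )
        out.append(
            GeneExpression(
                gene_id=gene_id,
                pair=call.pair,
                zygosity=call.zygosity,
                gene_count=count,
                combined_rate=call.combined_rate,
                hap_counts=hap,
                unique_counts=uniq,
                mismatch_rates=mismatch_rate(gene_assignments, call),
                undefined_split=undefined,
            )
        )
    return out


def expression_frame(results: Sequence[GeneExpression]) -> pd.DataFrame:
    """Tidy one-row-per-gene table of the quantification results."""
    rows = []
    for r in results:
        h1, h2 = (r.pair if r.pair else (None, None))
        rows.append(
            {
                "gene_id": r.gene_id,
                "hap1": h1,
                "hap2": h2,
                "zygosity": r.zygosity,
                "gene_count": r.gene_count,
                "combined_rate": r.combined_rate,
                "count_hap1": r.hap_counts.get(h1) if h1 else None,
                "count_hap2": (
                    r.hap_counts.get(h2)
                    if h2 and h1 != h2
                    else (r.hap_counts.get(h1) if h1 else None)
                ),
                "unique_hap1": r.unique_counts.get(h1) if h1 else None,
                "unique_hap2": r.unique_counts.get(h2) if h2 else None,
                "mismatch_rate_hap1": r.mismatch_rates.get(h1) if h1 else None,
                "mismatch_rate_hap2": r.mismatch_rates.get(h2) if h2 else None,
                "undefined_split": r.undefined_split,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "hap1", "hap2", "zygosity", "gene_count",
            "combined_rate", "count_hap1", "count_hap2", "unique_hap1",
            "unique_hap2", "mismatch_rate_hap1", "mismatch_rate_hap2",
            "undefined_split",
        ],
    )


def haplotype_ratio_table(
    results: Sequence[GeneExpression],
    min_depth: float = 30.0,
) -> pd.DataFrame:
    """Major/minor expression ratios of well-covered heterozygous genes.

    Ratio >= 1 by convention; the orientation (which haplotype is major) is
    recorded so designed 1:2 and 2:1 mixtures stay distinguishable. Genes
    with an undefined split or with either haplotype below ``min_depth``
    are excluded.
    """
    rows = []
    for r in results:
        if r.zygosity != "het" or r.undefined_split or not r.pair:
            continue
        h1, h2 = r.pair
        c1, c2 = r.hap_counts[h1], r.hap_counts[h2]
        if min(c1, c2) < min_depth:
            continue
        if c1 >= c2:
            major, minor, cmaj, cmin = h1, h2, c1, c2
        else:
            major, minor, cmaj, cmin = h2, h1, c2, c1
        rows.append(
            {
                "gene_id": r.gene_id,
                "major_hap": major,
                "minor_hap": minor,
                "count_major": cmaj,
                "count_minor": cmin,
                "ratio": cmaj / cmin,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "major_hap", "minor_hap", "count_major",
            "count_minor", "ratio",
        ],
    )


def pair_score_frame(scores: Iterable[PairScore]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": s.gene_id,
            "hap1": s.pair[0],
            "hap2": s.pair[1],
            "combined_rate": s.combined_rate,
            "relative_edit_distance": s.relative_edit_distance,
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "hap1", "hap2", "combined_rate",
            "relative_edit_distance",
        ],
    )


def read_annotation_frame(
    assignments: Sequence[ReadGeneAssignment],
    calls: Mapping[str, HaplotypeCall],
) -> pd.DataFrame:
    """Optional per-read annotation: one row per surviving read pair."""
    rows = []
    for a in assignments:
        call = calls.get(a.gene_id)
        members = set(call.pair) if call and call.pair else set()
        rows.append(
            {
                "read_pair_id": a.read_pair_id,
                "gene_id": a.gene_id,
                "haplotypes": ",".join(sorted(a.dist_by_haplotype)),
                "edit_distances": ",".join(
                    str(a.dist_by_haplotype[h])
                    for h in sorted(a.dist_by_haplotype)
                ),
                "in_predicted_pair": bool(
                    members & set(a.dist_by_haplotype)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_pair_id", "gene_id", "haplotypes", "edit_distances",
            "in_predicted_pair",
        ],
    )


def report_data(
    matrices: Mapping[str, MappingRateMatrix],
    calls: Mapping[str, HaplotypeCall],
    haplotypes: Sequence[str],
) -> dict:
    """JSON-serialisable per gene x haplotype rate heatmap with calls."""
    genes = list(calls)
    return {
        "haplotypes": list(haplotypes),
        "genes": genes,
        "rates": {
            g: {
                h: (matrices[g].rate(h) if g in matrices else 0.0)
                for h in haplotypes
            }
            for g in genes
        },
        "predicted": {
            g: (list(calls[g].pair) if calls[g].pair else None) for g in genes
        },
    }


def write_outputs(
    out_dir: str,
    expression: pd.DataFrame,
    pair_scores_df: pd.DataFrame,
    ratios: pd.DataFrame | None = None,
    read_annotations: pd.DataFrame | None = None,
    report: dict | None = None,
) -> dict[str, str]:
    """Write all tables as TSV (plus the report as JSON); returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(out_dir, name)
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path

    _write(expression, "expression.tsv")
    _write(pair_scores_df, "pair_scores.tsv")
    if ratios is not None:
        _write(ratios, "haplotype_ratios.tsv")
    if read_annotations is not None:
        _write(read_annotations, "read_annotations.tsv")
    if report is not None:
        path = os.path.join(out_dir, "report.json")
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        paths["report.json"] = path
    return paths


def plot_report(report: dict, path: str) -> None:
    """Render the rate heatmap with predicted pairs outlined (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    genes = report["genes"]
    haps = report["haplotypes"]
    mat = np.array(
        [[report["rates"][g][h] for h in haps] for g in genes], dtype=float
    )
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.5 * len(haps), 1.0 + 0.3 * len(genes))
    )
    im = ax.imshow(mat, aspect="auto", cmap="YlOrRd", vmin=0, vmax=1)
    ax.set_xticks(range(len(haps)), haps, rotation=45, ha="right")
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    for i, g in enumerate(genes):
        pred = report["predicted"][g]
        if not pred:
            continue
        for h in set(pred):
            j = haps.index(h)
            ax.add_patch(
                plt.Rectangle(
                    (j - 0.5, i - 0.5), 1, 1, fill=False, edgecolor="red",
                    linewidth=1.5,
                )
            )
    fig.colorbar(im, ax=ax, label="mapping rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
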