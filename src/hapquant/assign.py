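"""Read-to-gene assignment across haplotypes.

A read pair is assigned to gene *g* on haplotype *h* when both mates' aligned
genomic intervals overlap *g*'s (filtered) span on *h*. Assignment is at gene
level, not exon level, so intron-spanning mates are not dropped, and by
default it is unstranded. The cross-haplotype consistency rules then apply:

* a pair touching two or more genes on any single haplotype is discarded
  ("multi-gene");
* a pair assigned to gene g1 on one haplotype and a different gene g2 on
  another is discarded ("cross-haplotype-conflict"), gene identity being the
  shared ``gene_id``.

Each surviving pair yields exactly one :class:`ReadGeneAssignment` holding its
combined edit distance on every haplotype where it aligned to the gene.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .alignio import ReadAlignment, pair_edit_distance
from .refset import GeneModel


@dataclass
class ReadGeneAssignment:
    """One surviving read pair attributed to one gene.

    ``dist_by_haplotype`` maps haplotype -> combined pair edit distance and
    only contains haplotypes where the pair aligned to the gene. ``bases`` is
    the total sequenced length of the pair (sum of mate lengths), the
    denominator unit for per-base relative edit distances.
    """

    read_pair_id: str
    gene_id: str
    dist_by_haplotype: dict[str, int]
    bases: int

    def __post_init__(self) -> None:
        if not self.dist_by_haplotype:
            raise ValueError("dist_by_haplotype must be non-empty")
        if any(d < 0 for d in self.dist_by_haplotype.values()):
            raise ValueError("edit distances must be >= 0")


@dataclass
class DiscardRecord:
    read_pair_id: str
    reason: str  # "multi-gene" | "cross-haplotype-conflict" | "unassigned"


class _GeneIndex:
    """Start-sorted interval index with prefix-max ends for overlap queries.

    Exact for arbitrarily overlapping gene spans; the backwards scan stops as
    soon as no earlier interval can still reach the query."""

    def __init__(self, intervals: list[tuple[int, int, str]]):
        intervals.sort()
        self.starts = [iv[0] for iv in intervals]
        self.ends = [iv[1] for iv in intervals]
        self.ids = [iv[2] for iv in intervals]
        self.max_end = []
        running = 0
        for e in self.ends:
            running = max(running, e)
            self.max_end.append(running)

    def overlap(self, start: int, end: int) -> set[str]:
        hits: set[str] = set()
        i = bisect_right(self.starts, end - 1) - 1
        while i >= 0 and self.max_end[i] > start:
            if self.ends[i] > start:
                hits.add(self.ids[i])
            i -= 1
        return hits


def _gene_trees(models: Iterable[GeneModel]) -> dict[str, _GeneIndex]:
    raw: dict[str, list[tuple[int, int, str]]] = {}
    for m in models:
        start, end = m.span
        raw.setdefault(m.haplotype, []).append((start, end, m.gene_id))
    return {hap: _GeneIndex(ivs) for hap, ivs in raw.items()}


def assign_reads(
    alignments_by_haplotype: Mapping[str, Sequence[ReadAlignment]],
    models: Iterable[GeneModel],
    stranded: bool = False,
) -> tuple[list[ReadGeneAssignment], list[DiscardRecord]]:
    """Assign Stage-1-filtered alignments to genes, enforcing consistency.

    Parameters
    ----------
    alignments_by_haplotype:
        Per-haplotype alignment lists of the *same* read set.
    models:
        Filtered gene models (all haplotypes together).
    stranded:
        When true, a mate only matches genes on its own strand (mate 1
        forward = gene ``+``; mate orientations follow FR layout).

    Returns the assignments plus a discard log. ``unassigned`` rows are pairs
    that aligned somewhere but never satisfied the both-mates-in-one-gene
    rule on any haplotype.
    """
    model_list = list(models)
    trees = _gene_trees(model_list)
    strand_by_gene = {(m.haplotype, m.gene_id): m.strand for m in model_list}

    # read_pair_id -> {haplotype: {gene_id: combined d}}
    per_pair: dict[str, dict[str, dict[str, int]]] = {}
    bases: dict[str, int] = {}
    seen_pairs: set[str] = set()
    multi_gene: set[str] = set()

    for hap, alns in alignments_by_haplotype.items():
        tree = trees.get(hap)
        by_read: dict[str, list[ReadAlignment]] = {}
        for a in alns:
            seen_pairs.add(a.read_id)
            by_read.setdefault(a.read_id, []).append(a)
        if tree is None:
            continue  # haplotype without annotation contributes nothing
        for read_id, mates in by_read.items():
            mates = sorted(mates, key=lambda a: a.mate)
            if len(mates) == 1 and mates[0].mate != 0:
                continue  # paired read with a single mate mapped here
            gene_sets = []
            for a in mates:
                hits = tree.overlap(a.pos, a.end)
                if stranded:
                    hits = {
                        g
                        for g in hits
                        if _mate_strand(a) == strand_by_gene[(hap, g)]
                    }
                gene_sets.append(hits)
            common = set.intersection(*gene_sets) if gene_sets else set()
            if not common:
                continue
            if len(common) > 1:
                multi_gene.add(read_id)
                continue
            gene_id = next(iter(common))
            if len(mates) == 2:
                d = pair_edit_distance(mates[0], mates[1])
            else:
                d = mates[0].edit_distance
            per_pair.setdefault(read_id, {})[hap] = {gene_id: d}
            bases[read_id] = max(
                bases.get(read_id, 0), sum(a.read_length for a in mates)
            )

    assignments: list[ReadGeneAssignment] = []
    discards: list[DiscardRecord] = [
        DiscardRecord(rid, "multi-gene") for rid in sorted(multi_gene)
    ]
    conflicted = set()
    for read_id, by_hap in per_pair.items():
        if read_id in multi_gene:
            continue
        genes = {g for gmap in by_hap.values() for g in gmap}
        if len(genes) > 1:
            conflicted.add(read_id)
            continue
        gene_id = next(iter(genes))
        assignments.append(
            ReadGeneAssignment(
                read_pair_id=read_id,
                gene_id=gene_id,
                dist_by_haplotype={
                    hap: gmap[gene_id] for hap, gmap in by_hap.items()
                },
                bases=bases[read_id],
            )
        )
    discards.extend(
        DiscardRecord(rid, "cross-haplotype-conflict") for rid in sorted(conflicted)
    )
    assigned_or_discarded = (
        {a.read_pair_id for a in assignments} | multi_gene | conflicted
    )
    discards.extend(
        DiscardRecord(rid, "unassigned")
        for rid in sorted(seen_pairs - assigned_or_discarded)
    )
    assignments.sort(key=lambda a: (a.gene_id, a.read_pair_id))
    return assignments, discards


def _mate_strand(a: ReadAlignment) -> str:
    # FR layout: mate 1 on the forward strand of a + transcript, mate 2 reverse.
    forward = (a.mate != 2) != a.reverse
    return "+" if forward else "-"


def write_discard_log(discards: Iterable[DiscardRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_pair_id\treason\n")
        for d in discards:
            fh.write(f"{d.read_pair_id}\t{d.reason}\n")
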