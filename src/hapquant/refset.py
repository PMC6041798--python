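"""Haplotype reference panels, gene annotation, and gene-level filters.

A *haplotype panel* is the multi-reference universe the whole pipeline works
against: a set of named, fully assembled alternate haplotype sequences for one
polymorphic region (the motivating case is the eight MHC Haplotype Project
assemblies, PGF, COX, QBL, ...), one of which is flagged as the primary
reference. Each haplotype carries its own gene annotation; a gene present on
several haplotypes keeps the same ``gene_id`` on all of them, while a gene may
simply be absent from a haplotype (absent means absent, not zero-length).

All coordinates are 0-based half-open internally; GTF is read as 1-based
closed per the format standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Named haplotype sequences for one genomic region.

    Parameters
    ----------
    haplotypes:
        Haplotype names in a stable order; must be unique.
    sequences:
        Mapping haplotype name -> nucleotide sequence (uppercase string).
    primary:
        Name of the haplotype that represents the primary reference
        (the one reads were originally mapped against).
    region:
        Optional ``(chrom, start, end)`` interval of the region on the primary
        reference, 0-based half-open.
    """

    haplotypes: list[str]
    sequences: dict[str, str]
    primary: str
    region: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValidationError("haplotype names must be unique")
        if self.primary not in self.haplotypes:
            raise ValidationError(f"primary {self.primary!r} not in panel")
        for name in self.haplotypes:
            if not self.sequences.get(name):
                raise ValidationError(f"haplotype {name!r} has empty sequence")

    def length(self, haplotype: str) -> int:
        return len(self.sequences[haplotype])

    def __contains__(self, name: str) -> bool:
        return name in self.sequences


def load_panel(
    fasta_paths: Sequence[str],
    names: Sequence[str] | None = None,
    primary: str | None = None,
) -> HaplotypePanel:
    """Load haplotype sequences from one or more FASTA files.

    Each file may hold one or more records; record ids are used as haplotype
    names unless ``names`` overrides them (then the total record count must
    match). The first haplotype is the primary unless ``primary`` is given.
    """
    records: list[tuple[str, str]] = []
    for path in fasta_paths:
        try:
            with open(path) as handle:
                for rec in SeqIO.parse(handle, "fasta"):
                    records.append((rec.id, str(rec.seq).upper()))
        except FileNotFoundError as exc:
            raise IOError(f"FASTA file not found: {path}") from exc
    if names is not None:
        if len(names) != len(records):
            raise ValidationError(
                f"{len(names)} names given for {len(records)} FASTA records"
            )
        records = [(n, seq) for n, (_, seq) in zip(names, records)]
    ordered = [n for n, _ in records]
    if len(set(ordered)) != len(ordered):
        raise ValidationError(f"duplicate haplotype names in {ordered}")
    if primary is None:
        primary = ordered[0]
    return HaplotypePanel(
        haplotypes=ordered,
        sequences=dict(records),
        primary=primary,
    )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    transcript_type: str = "protein_coding"
    level: int = 2

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"empty exon [{start},{end}) in {self.transcript_id}"
                )
            if start < prev_end:
                raise ValidationError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced (exonic) length."""
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    """One gene on one haplotype (the same gene_id may recur on others)."""

    gene_id: str
    gene_name: str
    haplotype: str
    strand: str
    transcripts: list[TranscriptModel]
    gene_type: str = "protein_coding"
    annotation_level: int = 2

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        """Union span of the (already filtered) transcripts."""
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def start(self) -> int:
        return self.span[0]


@dataclass
class AnnotationFilter:
    """Transcript inclusion rules: type whitelist and annotation-level cut."""

    gene_types: tuple[str, ...] = ("protein_coding",)
    max_level: int = 2


def parse_annotation(
    gtf_path: str,
    panel: HaplotypePanel | None = None,
    filter_config: AnnotationFilter | None = None,
) -> list[GeneModel]:
    """Parse a GENCODE-dialect GTF into filtered per-haplotype gene models.

    Only transcripts whose type is in ``filter_config.gene_types`` and whose
    ``level`` attribute is <= ``filter_config.max_level`` are kept; genes with
    no surviving transcript are dropped, and each gene's span is the union of
    the spans of its retained transcripts only.

    The GTF seqname column names the haplotype; when a ``panel`` is given all
    seqnames must be panel members and intervals must fit the sequences.
    """
    cfg = filter_config or AnnotationFilter()
    # (haplotype, gene_id) -> metadata + {transcript_id -> exon list}
    genes: dict[tuple[str, str], dict] = {}
    with open(gtf_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ValidationError(
                    f"{gtf_path}:{lineno}: unparseable GTF line ({exc})"
                ) from exc
            if feat.featuretype != "exon":
                continue
            seqname = feat.seqid
            strand = feat.strand
            start = feat.start - 1  # gffutils keeps GTF 1-based closed
            end = feat.end
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ValidationError(
                    f"{gtf_path}:{lineno}: missing gene_id/transcript_id"
                )
            if panel is not None:
                if seqname not in panel:
                    raise ValidationError(
                        f"{gtf_path}:{lineno}: seqname {seqname!r} not in panel"
                    )
                if end > panel.length(seqname):
                    raise ValidationError(
                        f"{gtf_path}:{lineno}: exon end {end} beyond "
                        f"{seqname} length {panel.length(seqname)}"
                    )
            key = (seqname, attrs["gene_id"])
            entry = genes.setdefault(
                key,
                {
                    "gene_name": attrs.get("gene_name", attrs["gene_id"]),
                    "gene_type": attrs.get("gene_type", "protein_coding"),
                    "strand": strand,
                    "transcripts": {},
                    "seqnames": set(),
                },
            )
            entry["seqnames"].add(seqname)
            tid = attrs["transcript_id"]
            ttype = attrs.get("transcript_type", entry["gene_type"])
            level = int(attrs.get("level", 1))
            tx = entry["transcripts"].setdefault(
                tid, {"exons": [], "type": ttype, "level": level}
            )
            tx["exons"].append((start, end))

    models: list[GeneModel] = []
    for (haplotype, gene_id), entry in genes.items():
        if len(entry["seqnames"]) != 1:
            raise ValidationError(
                f"gene {gene_id} spans multiple haplotype records"
            )
        kept: list[TranscriptModel] = []
        for tid, tx in entry["transcripts"].items():
            if tx["type"] not in cfg.gene_types or tx["level"] > cfg.max_level:
                continue
            kept.append(
                TranscriptModel(
                    transcript_id=tid,
                    exons=sorted(tx["exons"]),
                    transcript_type=tx["type"],
                    level=tx["level"],
                )
            )
        if not kept:
            continue
        kept.sort(key=lambda t: t.transcript_id)
        models.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=entry["gene_name"],
                haplotype=haplotype,
                strand=entry["strand"],
                transcripts=kept,
                gene_type=entry["gene_type"],
                annotation_level=min(t.level for t in kept),
            )
        )
    models.sort(key=lambda g: (g.haplotype, g.start, g.gene_id))
    return models


# ---------------------------------------------------------------------------
# Gene ordering
# ---------------------------------------------------------------------------

def gene_order(
    models: Iterable[GeneModel],
    panel: HaplotypePanel,
) -> tuple[dict[str, list[str]], list[str]]:
    """Order genes along each haplotype and derive a single global order.

    Per haplotype, genes sort by start coordinate (ties broken by gene_id).
    The global order is the primary haplotype's order; a gene absent from the
    primary is inserted after the nearest preceding already-placed gene on any
    haplotype that carries both, so that restricting the global order to one
    haplotype's genes preserves that haplotype's coordinate order.
    """
    per_hap: dict[str, list[str]] = {}
    by_hap: dict[str, list[GeneModel]] = {}
    for m in models:
        by_hap.setdefault(m.haplotype, []).append(m)
    for hap, ms in by_hap.items():
        per_hap[hap] = [
            m.gene_id for m in sorted(ms, key=lambda g: (g.start, g.gene_id))
        ]

    global_order = list(per_hap.get(panel.primary, []))
    placed = set(global_order)
    all_genes = sorted({m.gene_id for hap in by_hap for m in by_hap[hap]})
    pending = [g for g in all_genes if g not in placed]
    # Insert by neighbour rank, iterating until a pass places nothing new.
    progress = True
    while pending and progress:
        progress = False
        still = []
        for gid in pending:
            pos = _interpolate_position(gid, per_hap, global_order)
            if pos is None:
                still.append(gid)
                continue
            global_order.insert(pos, gid)
            placed.add(gid)
            progress = True
        pending = still
    # Anything unanchorable goes at the end, deterministically.
    global_order.extend(sorted(pending))
    return per_hap, global_order


def _interpolate_position(
    gid: str, per_hap: Mapping[str, list[str]], global_order: list[str]
) -> int | None:
    """Index at which to insert ``gid`` into ``global_order``, or None."""
    for order in per_hap.values():
        if gid not in order:
            continue
        i = order.index(gid)
        left = next(
            (g for g in reversed(order[:i]) if g in global_order), None
        )
        right = next((g for g in order[i + 1:] if g in global_order), None)
        if left is not None:
            return global_order.index(left) + 1
        if right is not None:
            return global_order.index(right)
    return None


# ---------------------------------------------------------------------------
# Gene reliability (simulation-calibrated inclusion filter)
# ---------------------------------------------------------------------------

@dataclass
class GeneReliability:
    """Simulation-derived trustworthiness of a gene's read attribution.

    ``unique_fraction`` is the share of the gene's simulated reads that end up
    uniquely attributed (a single gene locus; multimappers and multi-gene
    discards count against it). ``mismap_fraction`` is the share of reads
    assigned to the gene whose true source is a different gene. Genes with a
    low unique share or that attract foreign reads (homologous pairs such as
    HSPA1A/HSPA1B or C4A/C4B) are excluded from quantification.
    """

    gene_id: str
    unique_fraction: float
    mismap_fraction: float
    retained: bool
    no_data: bool = False

    MIN_UNIQUE = 0.8
    MAX_MISMAP = 0.2


def compute_gene_reliability(
    sim_truth,
    assignments,
    min_unique_fraction: float = GeneReliability.MIN_UNIQUE,
    max_mismap_fraction: float = GeneReliability.MAX_MISMAP,
) -> list[GeneReliability]:
    """Score each simulated gene's reliability from pipeline assignments.

    Parameters
    ----------
    sim_truth:
        A :class:`~hapquant.simulate.SimTruth` (anything exposing
        ``true_gene_by_pair``: read_pair_id -> gene_id).
    assignments:
        Iterable of :class:`~hapquant.assign.ReadGeneAssignment` produced by
        running the pipeline on the simulated reads.
    """
    truth = sim_truth.true_gene_by_pair
    totals: dict[str, int] = {}
    for gid in truth.values():
        totals[gid] = totals.get(gid, 0) + 1

    unique_counts: dict[str, int] = {g: 0 for g in totals}
    assigned_counts: dict[str, int] = {}
    foreign_counts: dict[str, int] = {}
    for a in assignments:
        true_gene = truth.get(a.read_pair_id)
        assigned_counts[a.gene_id] = assigned_counts.get(a.gene_id, 0) + 1
        if true_gene == a.gene_id:
            unique_counts[a.gene_id] = unique_counts.get(a.gene_id, 0) + 1
        else:
            foreign_counts[a.gene_id] = foreign_counts.get(a.gene_id, 0) + 1

    out: list[GeneReliability] = []
    genes = sorted(set(totals) | set(assigned_counts))
    for gid in genes:
        total = totals.get(gid, 0)
        assigned = assigned_counts.get(gid, 0)
        if total == 0 and assigned == 0:
            out.append(GeneReliability(gid, 0.0, 0.0, retained=False, no_data=True))
            continue
        uniq = unique_counts.get(gid, 0) / total if total else 0.0
        mismap = foreign_counts.get(gid, 0) / assigned if assigned else 0.0
        retained = uniq >= min_unique_fraction and mismap <= max_mismap_fraction
        if total == 0:
            retained = False
        out.append(
            GeneReliability(
                gid, uniq, mismap, retained=retained, no_data=(total == 0)
            )
        )
    return out
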