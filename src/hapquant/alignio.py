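"""Alignment ingestion and first-stage read filtering.

The pipeline consumes one alignment file per alternate haplotype: the same
read set mapped independently against each haplotype sequence by any mapper
that fills the standard SAM tags. Before any scoring, reads are filtered the
way the method prescribes: records with mapping quality below 20, duplicate-
flagged records, and reads hitting multiple loci on a haplotype are removed,
and for the original single-reference pass, reads overlapping the target
region plus all unmapped reads are the ones carried forward.

Edit distances come from the NM tag (substitutions + insertions + deletions);
an optional fallback recomputes them from the MD tag.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

import pysam

from .refset import ValidationError

log = logging.getLogger(__name__)

_CIGAR_REF_OPS = set("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_reference_span(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string (M/D/N/=/X ops)."""
    return sum(
        int(n) for n, op in _CIGAR_RE.findall(cigar) if op in _CIGAR_REF_OPS
    )


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """One mate's alignment to one haplotype, after Stage-1 filtering."""

    read_id: str
    mate: int  # 1 or 2; 0 for unpaired reads
    haplotype: str
    pos: int  # 0-based leftmost reference position
    cigar: str
    edit_distance: int
    mapq: int
    read_length: int
    reverse: bool = False
    is_duplicate: bool = False
    is_proper_pair: bool = True

    def __post_init__(self) -> None:
        if self.edit_distance < 0:
            raise ValidationError("edit distance must be >= 0")
        if not 0 <= self.mapq <= 255:
            raise ValidationError("MAPQ out of [0, 255]")

    @property
    def end(self) -> int:
        """0-based exclusive reference end (includes intron N gaps)."""
        return self.pos + cigar_reference_span(self.cigar)


@dataclass
class FilterStats:
    """Bookkeeping for Stage-1 filtering; removed + retained == input."""

    total: int = 0
    retained: int = 0
    low_mapq: int = 0
    multimapped: int = 0
    duplicate: int = 0
    secondary: int = 0
    unmapped: int = 0
    missing_nm: int = 0

    @property
    def removed(self) -> int:
        return (
            self.low_mapq
            + self.multimapped
            + self.duplicate
            + self.secondary
            + self.unmapped
            + self.missing_nm
        )

    def check(self) -> None:
        if self.removed + self.retained != self.total:
            raise AssertionError("FilterStats conservation violated")


def edit_distance_from_md(md: str, cigar: str) -> int:
    """Reconstruct NM from the MD tag plus CIGAR insertions.

    MD encodes matches (numbers), substitutions (letters) and deletions
    (``^`` + letters); read insertions only appear in the CIGAR.
    """
    subs = dels = 0
    for token in re.findall(r"\d+|\^[A-Z]+|[A-Z]", md):
        if token.startswith("^"):
            dels += len(token) - 1
        elif token.isalpha():
            subs += 1
    ins = sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op == "I")
    return subs + dels + ins


def _record_edit_distance(rec: pysam.AlignedSegment, md_fallback: bool) -> int | None:
    if rec.has_tag("NM"):
        return int(rec.get_tag("NM"))
    if md_fallback and rec.has_tag("MD"):
        return edit_distance_from_md(str(rec.get_tag("MD")), rec.cigarstring or "")
    return None


def read_alignments(
    sam_path: str,
    haplotype_name: str,
    min_mapq: int = 20,
    md_fallback: bool = False,
) -> tuple[list[ReadAlignment], FilterStats]:
    """Read and Stage-1-filter one haplotype's alignment file.

    Drops secondary/supplementary records, unmapped records, duplicates,
    records below ``min_mapq``, records without a usable edit distance, and
    all records of any (read, mate) that aligns to more than one locus on
    this haplotype. Filtering is order-independent by construction: the
    multi-locus rule is applied on the full record set.
    """
    stats = FilterStats()
    kept: list[ReadAlignment] = []
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for rec in fh:
            stats.total += 1
            if rec.is_secondary or rec.is_supplementary:
                stats.secondary += 1
                continue
            if rec.is_unmapped:
                stats.unmapped += 1
                continue
            if rec.is_duplicate:
                stats.duplicate += 1
                continue
            if rec.mapping_quality < min_mapq:
                stats.low_mapq += 1
                continue
            d = _record_edit_distance(rec, md_fallback)
            if d is None:
                stats.missing_nm += 1
                log.warning(
                    "dropping %s/%s on %s: no NM tag and no fallback",
                    rec.query_name,
                    2 if rec.is_read2 else 1,
                    haplotype_name,
                )
                continue
            mate = 0 if not rec.is_paired else (2 if rec.is_read2 else 1)
            kept.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    mate=mate,
                    haplotype=haplotype_name,
                    pos=rec.reference_start,
                    cigar=rec.cigarstring or "",
                    edit_distance=d,
                    mapq=rec.mapping_quality,
                    read_length=rec.query_length or len(rec.query_sequence or ""),
                    reverse=rec.is_reverse,
                    is_proper_pair=rec.is_proper_pair,
                )
            )
    kept, n_multi = drop_multi_locus(kept)
    stats.multimapped += n_multi
    stats.retained = len(kept)
    stats.check()
    return kept, stats


def drop_multi_locus(
    records: Iterable[ReadAlignment],
) -> tuple[list[ReadAlignment], int]:
    """Remove every record of a (read, mate) seen at more than one locus."""
    counts: dict[tuple[str, int], int] = {}
    records = list(records)
    for r in records:
        counts[(r.read_id, r.mate)] = counts.get((r.read_id, r.mate), 0) + 1
    kept = [r for r in records if counts[(r.read_id, r.mate)] == 1]
    return kept, len(records) - len(kept)


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) to 0-based half-open."""
    m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", region.replace(" ", ""))
    if not m:
        raise ValidationError(f"bad region syntax: {region!r}")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", "")) - 1
    end = int(m.group(3).replace(",", ""))
    if start >= end:
        raise ValidationError(f"empty region: {region!r}")
    return chrom, start, end


def extract_target_reads(sam_path: str, region: str) -> set[str]:
    """Read ids overlapping ``region`` on the primary reference + unmapped.

    Both mates of a pair are included as soon as either mate qualifies (the
    returned set holds read ids, not (read, mate) keys). Works on unsorted,
    unindexed SAM by streaming every record.
    """
    chrom, start, end = parse_region(region)
    ids: set[str] = set()
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        names = set(fh.references or [])
        if chrom not in names:
            raise ValidationError(
                f"region chromosome {chrom!r} absent from {sam_path} header"
            )
        for rec in fh:
            if rec.is_unmapped:
                ids.add(rec.query_name)
                continue
            if rec.reference_name != chrom:
                continue
            rec_end = rec.reference_end or (rec.reference_start + 1)
            if rec.reference_start < end and rec_end > start:
                ids.add(rec.query_name)
    return ids


def pair_edit_distance(mate1: ReadAlignment, mate2: ReadAlignment) -> int:
    """Combined edit distance of a read pair (sum of the mates')."""
    if mate1.haplotype != mate2.haplotype:
        raise ValidationError("mates aligned to different haplotypes")
    return mate1.edit_distance + mate2.edit_distance
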