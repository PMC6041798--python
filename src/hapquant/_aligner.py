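"""Desk-scale spliced read aligner over a haplotype panel's transcript sets.

Aligns every read against every haplotype independently, reporting the best
transcript-space hit per haplotype projected to genomic coordinates with
spliced (N-op) CIGARs and exact NM tags — the role a third-party RNA-seq
mapper plays for real data. Candidate loci come from exact k-mer seeds and
are verified by banded edit distance (edlib); when seeding yields nothing the
whole transcript set is scanned. The band is the maximum edit distance per
mate and doubles as the mapper's mismatch tolerance: a haplotype more distant
than the band reports the read unmapped, exactly like a real mapper losing a
read on a diverged reference. Within-haplotype ties across distinct loci get
MAPQ below 20 (the multimapper signal the first pipeline stage removes);
unique hits get MAPQ 60.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from .alignio import ReadAlignment
from .refset import GeneModel, HaplotypePanel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CIGAR_TOKEN = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Transcript references and genomic projection
# ---------------------------------------------------------------------------

@dataclass
class TranscriptRef:
    """One transcript on one haplotype, with mRNA sequence and exon map."""

    gene_id: str
    transcript_id: str
    haplotype: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, sorted
    seq: str  # mRNA, 5'->3'

    def __post_init__(self) -> None:
        self._cum = [0]
        for s, e in self.exons:
            self._cum.append(self._cum[-1] + (e - s))

    @property
    def length(self) -> int:
        return self._cum[-1]

    def plus_interval(self, a: int, b: int) -> tuple[int, int]:
        """mRNA interval -> interval on the plus-sense exon concatenation."""
        if self.strand == "+":
            return a, b
        return self.length - b, self.length - a

    def concat_to_genomic(self, c: int) -> int:
        """Plus-sense concatenation offset -> genomic coordinate."""
        for i, (s, e) in enumerate(self.exons):
            if c < self._cum[i + 1] or (i == len(self.exons) - 1):
                return s + (c - self._cum[i])
        raise AssertionError("unreachable")

    def genomic_span(self, a: int, b: int) -> tuple[int, int]:
        """Genomic (start, end) covered by mRNA interval [a, b)."""
        ca, cb = self.plus_interval(a, b)
        start = self.concat_to_genomic(ca)
        end = self.concat_to_genomic(cb - 1) + 1
        return start, end


def parse_extended_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_TOKEN.findall(cigar)]


def lift_cigar(
    tr: TranscriptRef, t_start: int, t_end: int, cigar: str
) -> tuple[int, str]:
    """Project a transcript-space alignment to a genomic spliced CIGAR.

    ``cigar`` is in mRNA orientation over mRNA interval [t_start, t_end);
    returns (genomic_start, genomic_cigar) in genomic plus-strand order, with
    N operations bridging introns. Match/mismatch distinctions are collapsed
    to M for SAM friendliness; NM carries the edit count.
    """
    ops = parse_extended_cigar(cigar)
    ca, _cb = tr.plus_interval(t_start, t_end)
    if tr.strand == "-":
        ops = ops[::-1]
    out: list[tuple[int, str]] = []
    c = ca  # cursor on the plus-sense exon concatenation
    exon_idx = 0
    while exon_idx + 1 < len(tr._cum) and tr._cum[exon_idx + 1] <= c:
        exon_idx += 1
    genomic_start = tr.concat_to_genomic(ca)

    def emit(length: int, op: str) -> None:
        if length <= 0:
            return
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + length, op)
        else:
            out.append((length, op))

    for length, op in ops:
        op_m = "M" if op in "=XM" else op
        if op_m == "I":
            emit(length, "I")
            continue
        # M and D consume the target: split across exon boundaries, and
        # bridge an intron with N only when more target follows.
        remaining = length
        while remaining:
            while (
                exon_idx + 1 < len(tr.exons) and c == tr._cum[exon_idx + 1]
            ):
                intron = tr.exons[exon_idx + 1][0] - tr.exons[exon_idx][1]
                emit(intron, "N")
                exon_idx += 1
            take = min(remaining, tr._cum[exon_idx + 1] - c)
            emit(take, op_m)
            c += take
            remaining -= take
    return genomic_start, "".join(f"{n}{o}" for n, o in out)


def build_transcript_refs(
    panel: HaplotypePanel, models: Iterable[GeneModel]
) -> dict[str, list[TranscriptRef]]:
    """Per-haplotype transcript references with mRNA sequences."""
    refs: dict[str, list[TranscriptRef]] = {h: [] for h in panel.haplotypes}
    for m in models:
        genome = panel.sequences[m.haplotype]
        for t in m.transcripts:
            concat = "".join(genome[s:e] for s, e in t.exons)
            seq = concat if m.strand == "+" else revcomp(concat)
            refs[m.haplotype].append(
                TranscriptRef(
                    gene_id=m.gene_id,
                    transcript_id=t.transcript_id,
                    haplotype=m.haplotype,
                    strand=m.strand,
                    exons=list(t.exons),
                    seq=seq,
                )
            )
    return refs


# ---------------------------------------------------------------------------
# Seeded banded alignment
# ---------------------------------------------------------------------------

@dataclass
class MateHit:
    """Best alignment of one mate on one haplotype."""

    transcript: TranscriptRef
    t_start: int
    t_end: int  # exclusive, mRNA coords
    edit_distance: int
    orientation_rev: bool  # read was reverse-complemented to match the mRNA
    tied: bool  # equally good hit at a distinct genomic locus exists
    cigar_t: str  # transcript-space extended CIGAR (mRNA orientation)

    @property
    def genome_reverse(self) -> bool:
        return self.orientation_rev != (self.transcript.strand == "-")


class HaplotypeAligner:
    """k-mer seeded, banded aligner against one haplotype's transcripts."""

    def __init__(
        self,
        transcripts: Sequence[TranscriptRef],
        band: int = 2,
        k: int = 17,
        cigars: bool = True,
    ):
        self.transcripts = list(transcripts)
        self.band = band
        self.k = k
        self.cigars = cigars
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ti, tr in enumerate(self.transcripts):
            seq = tr.seq
            for pos in range(0, len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((ti, pos))

    def _seed_candidates(self, read: str) -> set[tuple[int, int]]:
        k = self.k
        cands: set[tuple[int, int]] = set()
        n = len(read)
        index = self.index
        for off in (0, max(0, (n - k) // 2), max(0, n - k)):
            for ti, pos in index.get(read[off : off + k], ()):
                cands.add((ti, pos - off))
        return cands

    def align_mate(self, read: str, rev_first: bool = False) -> MateHit | None:
        """Best banded hit of one mate, either orientation.

        ``rev_first`` is a performance hint (e.g. FR mate 2): the reverse
        complement is tried first, and a perfect (0-edit) hit short-circuits
        the other orientation, which could not beat it.
        """
        # hits are (d, gene_id, transcript_id, t_start, t_end, ti, rev)
        hits: list[tuple] = []
        reads = ((read, False), (revcomp(read), True))
        if rev_first:
            reads = reads[::-1]
        for oriented, rev in reads:
            seen: set[tuple[int, int]] = set()
            for ti, approx in self._seed_candidates(oriented):
                bucket = (ti, approx // 8)
                if bucket in seen:
                    continue
                seen.add(bucket)
                self._verify_one(oriented, rev, ti, approx, hits)
            if any(h[0] == 0 for h in hits):
                break
        if not hits:
            # seeding found nothing: exhaustive scan (rare, diverged reads)
            for oriented, rev in reads:
                for ti in range(len(self.transcripts)):
                    self._verify_one(oriented, rev, ti, None, hits)
        if not hits:
            return None
        best = min(hits)
        best_d = best[0]
        # A tie across distinct gene loci is a multimapper; equally good
        # placements under different isoforms of one gene are not.
        loci = {h[1] for h in hits if h[0] == best_d}
        d, _gid, _tid, t_start, t_end, ti, rev = best
        tr = self.transcripts[ti]
        cigar_t = ""
        if self.cigars:
            oriented = revcomp(read) if rev else read
            pad = self.band + 2
            window_start = max(0, t_start - pad)
            window = tr.seq[window_start : t_end + pad]
            res = edlib.align(
                oriented, window, mode="HW", task="path", k=self.band
            )
            cigar_t = res["cigar"]
            t_start = window_start + res["locations"][0][0]
            t_end = window_start + res["locations"][0][1] + 1
        return MateHit(
            transcript=tr,
            t_start=t_start,
            t_end=t_end,
            edit_distance=d,
            orientation_rev=rev,
            tied=len(loci) > 1,
            cigar_t=cigar_t,
        )

    def _verify_one(
        self,
        oriented: str,
        rev: bool,
        ti: int,
        approx: int | None,
        hits: list[tuple],
    ) -> None:
        tr = self.transcripts[ti]
        if approx is None:
            window_start, window = 0, tr.seq
        else:
            pad = self.band + 2
            window_start = max(0, approx - pad)
            window = tr.seq[window_start : approx + len(oriented) + pad]
        if len(window) < len(oriented) - self.band:
            return
        res = edlib.align(
            oriented, window, mode="HW", task="locations", k=self.band
        )
        if res["editDistance"] < 0:
            return
        loc = res["locations"][0]
        hits.append(
            (
                res["editDistance"],
                tr.gene_id,
                tr.transcript_id,
                window_start + loc[0],
                window_start + loc[1] + 1,
                ti,
                rev,
            )
        )


def hit_to_alignment(
    read_id: str, mate: int, read_len: int, hit: MateHit
) -> ReadAlignment:
    """Project a mate hit to a genomic :class:`ReadAlignment`.

    Without a transcript-space CIGAR (span-only alignment mode) the record
    carries a placeholder CIGAR covering the full genomic span, which is all
    downstream gene assignment needs.
    """
    if hit.cigar_t:
        start, cigar = lift_cigar(
            hit.transcript, hit.t_start, hit.t_end, hit.cigar_t
        )
    else:
        start, end = hit.transcript.genomic_span(hit.t_start, hit.t_end)
        cigar = f"{end - start}M"
    return ReadAlignment(
        read_id=read_id,
        mate=mate,
        haplotype=hit.transcript.haplotype,
        pos=start,
        cigar=cigar,
        edit_distance=hit.edit_distance,
        mapq=3 if hit.tied else 60,
        read_length=read_len,
        reverse=hit.genome_reverse,
        is_proper_pair=True,
    )


def align_reads_to_panel(
    reads: Sequence,
    panel: HaplotypePanel,
    models: Iterable[GeneModel],
    band: int = 2,
    k: int = 17,
    cigars: bool = True,
) -> dict[str, list[ReadAlignment]]:
    """Align every read pair to every haplotype; returns raw alignments.

    ``reads`` is a sequence of ``(read_id, seq1, seq2)`` (``seq2`` may be
    None for single-end). The output is unfiltered: MAPQ encodes ties, so
    Stage-1 filtering applies downstream exactly as for a real mapper.
    ``cigars=False`` skips the alignment traceback and emits span
    placeholder CIGARs — faster, sufficient for in-memory quantification,
    but not for SAM output.
    """
    refs = build_transcript_refs(panel, models)
    out: dict[str, list[ReadAlignment]] = {}
    for hap in panel.haplotypes:
        aligner = HaplotypeAligner(refs[hap], band=band, k=k, cigars=cigars)
        alns: list[ReadAlignment] = []
        for read_id, seq1, seq2 in reads:
            mates = [(1, seq1)] if seq2 is None else [(1, seq1), (2, seq2)]
            for mate_no, seq in mates:
                hit = aligner.align_mate(seq, rev_first=(mate_no == 2))
                if hit is None:
                    continue
                mate_id = 0 if seq2 is None else mate_no
                alns.append(hit_to_alignment(read_id, mate_id, len(seq), hit))
        out[hap] = alns
    return out


def write_sam(
    alignments: Mapping[str, Sequence[ReadAlignment]],
    reads: Sequence,
    panel: HaplotypePanel,
    paths: Mapping[str, str],
) -> None:
    """Write one SAM file per haplotype (text, with @SQ headers and NM)."""
    seqs = {rid: (s1, s2) for rid, s1, s2 in reads}
    for hap, hap_alns in alignments.items():
        path = paths[hap]
        mapped: dict[tuple[str, int], ReadAlignment] = {
            (a.read_id, a.mate): a for a in hap_alns
        }
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(
                f"@SQ\tSN:{hap}\tLN:{panel.length(hap)}\n"
            )
            for rid, s1, s2 in reads:
                pair = [(1, s1)] if s2 is None else [(1, s1), (2, s2)]
                for mate_no, seq in pair:
                    key = (rid, 0 if s2 is None else mate_no)
                    a = mapped.get(key)
                    other = mapped.get((rid, 3 - mate_no)) if s2 else None
                    fh.write(
                        _sam_line(rid, mate_no, seq, a, other, hap, s2 is None)
                    )


def _sam_line(
    rid: str,
    mate_no: int,
    seq: str,
    a: ReadAlignment | None,
    other: ReadAlignment | None,
    hap: str,
    single: bool,
) -> str:
    flag = 0
    if not single:
        flag |= 0x1 | (0x40 if mate_no == 1 else 0x80)
        if other is None:
            flag |= 0x8
        elif other.reverse:
            flag |= 0x20
        if a is not None and other is not None:
            flag |= 0x2
    if a is None:
        flag |= 0x4
        return f"{rid}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n"
    if a.reverse:
        flag |= 0x10
        out_seq = revcomp(seq)
    else:
        out_seq = seq
    pnext = other.pos + 1 if other is not None else 0
    rnext = "=" if other is not None else "*"
    return (
        f"{rid}\t{flag}\t{hap}\t{a.pos + 1}\t{a.mapq}\t{a.cigar}\t{rnext}\t"
        f"{pnext}\t0\t{out_seq}\t*\tNM:i:{a.edit_distance}\n"
    )
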