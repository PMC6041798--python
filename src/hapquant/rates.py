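"""Edit-distance read weighting, mapping-rate matrices and candidate pairs.

For a gene, every assigned read pair gets a weight on each haplotype it
aligned to, derived from its combined edit distance *d* through a monotone
score function (default ``s(d) = 2**-d``: one extra edit halves the odds).
Weights are normalised to 1 across haplotypes per read, and the per-gene
mapping rate ``R(g, h)`` is the mean weight over the gene's reads, so
``sum_h R(g, h) == 1`` whenever the gene has reads.

Diploid hypotheses are unordered haplotype pairs {h1, h2} (h1 == h2 encodes a
homozygote). Each pair is scored by

* its combined mapping rate ``M_pair`` — the share of the gene's read pairs
  that align to at least one member of the pair (the "read counts of gene in
  the predicted haplotype(s) / total read count" statistic); an additive
  variant ``R(g,h1) + R(g,h2)`` is available via ``pair_rate="weight-sum"``;
* its relative edit distance ``D_pair`` — the per-base rate
  ``sum_r min(d_h1, d_h2) / (aligned pairs x pair length)`` over the pairs
  aligning to at least one member, taking each read's best member distance.

Candidate pairs for a gene are those attaining the minimum ``D_pair`` among
the pairs in the top 5% of ``M_pair`` values, ties kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .assign import ReadGeneAssignment

Pair = tuple[str, str]  # sorted, h1 <= h2

SCORE_FUNCTIONS: dict[str, Callable[[int], float]] = {
    "exp2": lambda d: 2.0 ** (-d),
    "inverse": lambda d: 1.0 / (1.0 + d),
}


def make_pair(h1: str, h2: str) -> Pair:
    return (h1, h2) if h1 <= h2 else (h2, h1)


def read_weights(
    dist_by_haplotype: Mapping[str, int],
    score: str | Callable[[int], float] = "exp2",
) -> dict[str, float]:
    """Normalised per-haplotype weights for one read pair.

    ``weight_h = s(d_h) / sum_h' s(d_h')`` over the haplotypes the pair
    aligned to; absent haplotypes implicitly weigh 0.
    """
    if not dist_by_haplotype:
        raise ValueError("dist_by_haplotype must be non-empty")
    s = SCORE_FUNCTIONS[score] if isinstance(score, str) else score
    raw = {h: s(d) for h, d in dist_by_haplotype.items()}
    total = sum(raw.values())
    return {h: v / total for h, v in raw.items()}


@dataclass
class MappingRateMatrix:
    """Per-gene normalised mapping rates R(g, h)."""

    gene_id: str
    n_reads: int
    rate_by_haplotype: dict[str, float]

    def rate(self, haplotype: str) -> float:
        return self.rate_by_haplotype.get(haplotype, 0.0)


@dataclass
class PairScore:
    """Diploid hypothesis score for one gene."""

    gene_id: str
    pair: Pair
    combined_rate: float  # M_pair in [0, 1]
    relative_edit_distance: float  # D_pair >= 0

    @property
    def homozygous(self) -> bool:
        return self.pair[0] == self.pair[1]


def mapping_rate_matrix(
    assignments: Sequence[ReadGeneAssignment],
    score: str | Callable[[int], float] = "exp2",
) -> MappingRateMatrix:
    """R(g, h) = sum of per-read weights on h / number of reads of the gene."""
    if not assignments:
        raise ValueError("mapping_rate_matrix needs at least one assignment")
    gene_id = assignments[0].gene_id
    sums: dict[str, float] = {}
    for a in assignments:
        if a.gene_id != gene_id:
            raise ValueError("assignments must all belong to one gene")
        for h, w in read_weights(a.dist_by_haplotype, score).items():
            sums[h] = sums.get(h, 0.0) + w
    n = len(assignments)
    return MappingRateMatrix(
        gene_id=gene_id,
        n_reads=n,
        rate_by_haplotype={h: v / n for h, v in sums.items()},
    )


def pair_scores(
    matrix: MappingRateMatrix,
    assignments: Sequence[ReadGeneAssignment],
    haplotypes: Sequence[str] | None = None,
    pair_rate: str = "count",
) -> list[PairScore]:
    """Score every unordered haplotype pair (including homozygous pairs).

    ``haplotypes`` restricts the pair universe (normally the haplotypes that
    annotate the gene); by default the haplotypes observed in the rate matrix
    are used. With K haplotypes there are K(K+1)/2 pairs.
    """
    if not assignments:
        return []
    if haplotypes is None:
        haplotypes = sorted(matrix.rate_by_haplotype)
    haplotypes = sorted(set(haplotypes))
    n = len(assignments)
    # reads x haplotypes edit-distance matrix, inf where the pair is absent
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    dmat = np.full((n, len(haplotypes)), np.inf)
    bases = np.empty(n)
    for ri, a in enumerate(assignments):
        bases[ri] = a.bases
        for h, d in a.dist_by_haplotype.items():
            if h in hap_index:
                dmat[ri, hap_index[h]] = d
    out: list[PairScore] = []
    for h1, h2 in itertools.combinations_with_replacement(haplotypes, 2):
        pair = make_pair(h1, h2)
        dmin = np.minimum(dmat[:, hap_index[h1]], dmat[:, hap_index[h2]])
        present = np.isfinite(dmin)
        covered = int(present.sum())
        if pair_rate == "count":
            m = covered / n
        elif pair_rate == "weight-sum":
            m = (
                matrix.rate(h1)
                if h1 == h2
                else matrix.rate(h1) + matrix.rate(h2)
            )
        else:
            raise ValueError(f"unknown pair_rate {pair_rate!r}")
        base_sum = float(bases[present].sum())
        d_rel = float(dmin[present].sum()) / base_sum if base_sum else 0.0
        out.append(
            PairScore(
                gene_id=matrix.gene_id,
                pair=pair,
                combined_rate=m,
                relative_edit_distance=d_rel,
            )
        )
    return out


def candidate_pairs(
    scores: Sequence[PairScore],
    top_percentile: float = 95.0,
    atol: float = 1e-12,
) -> list[Pair]:
    """Shortlist by combined rate, then pick the lowest relative distance.

    Shortlist = pairs whose ``M_pair`` reaches the ``top_percentile``-th
    percentile (linear interpolation) of all pair values for the gene, ties
    included; the result keeps every shortlisted pair attaining the minimum
    ``D_pair`` (within ``atol``), sorted for determinism.
    """
    if not scores:
        raise ValueError("candidate_pairs needs a non-empty score list")
    values = np.array([s.combined_rate for s in scores], dtype=float)
    threshold = float(np.percentile(values, top_percentile))
    shortlist = [s for s in scores if s.combined_rate >= threshold - atol]
    dmin = min(s.relative_edit_distance for s in shortlist)
    winners = sorted(
        s.pair for s in shortlist if s.relative_edit_distance <= dmin + atol
    )
    return winners
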