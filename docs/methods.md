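# Methods

## Model and procedure

`hapquant` estimates gene- and haplotype-level expression in a polymorphic
region for which several fully assembled alternate haplotype sequences
exist. The observation model is deliberately non-probabilistic: the same
read set is aligned independently against every haplotype, and each read
pair's vector of edit distances across haplotypes is the evidence unit.
The pipeline stages and their contracts:

1. **Stage-1 filtering** (`alignio`). Per haplotype: drop secondary/
   supplementary records, duplicate-flagged records, records with
   MAPQ < `min_mapq` (default 20), records without a usable edit distance,
   and every record of a (read, mate) that appears at more than one locus
   in one file. Filtering is order-independent because the multi-locus rule
   is evaluated on the complete record set. `extract_target_reads`
   implements the region + unmapped extraction used when the input comes
   from a whole-genome single-reference pass.
2. **Assignment** (`assign`). A pair is assigned to gene g on haplotype h
   iff both mates' aligned genomic intervals overlap g's span on h (gene
   level, not exon level, so intron-spanning mates survive; unstranded by
   default with a `stranded` switch). Pairs assigned to ≥ 2 genes on one
   haplotype, or to different gene_ids on different haplotypes, are
   discarded and logged. Survivors carry one combined (mate1 + mate2) edit
   distance per haplotype where they aligned.
3. **Weighting and candidate pairs** (`rates`). Read weights use
   s(d) = 2^(−d) normalised across haplotypes; the per-gene rate matrix is
   R(g,h) = mean weight. Diploid hypotheses are unordered pairs {h1,h2}.
   The combined pair rate M_pair is *count-based*: the fraction of the
   gene's pairs aligning to at least one member. The relative edit
   distance D_pair averages each covered pair's best member distance per
   sequenced base. Candidates = argmin D_pair within the top-5% M_pair
   shortlist (95th value-percentile, linear interpolation, ties kept).
4. **Path solving** (`hapgraph`). One state per (gene, candidate pair) in
   genomic gene order; genes without reads get a wildcard state compatible
   with anything at zero switches. Edge weight
   w = 1/(−log(1 − M̄)) + penalty × switches, with M̄ the arithmetic mean
   of the incident states' M_pair (clamped to [ε, 1−ε], ε = 1e-9) and
   switches the multiset difference of the two pairs (0, 1, 2). Terminal
   edges from the pseudo source/sink carry the adjacent state's weight and
   no penalty. All weights are non-negative, so any shortest-path
   algorithm applies; the solver is an exact dynamic program over the
   layered DAG — the same optimum Dijkstra finds — chosen so the tie-break
   is fully deterministic. `brute_force_path` (exhaustive enumeration) is
   retained as an oracle and refuses instances over 10^6 paths.
5. **Quantification** (`quantify`). Gene count = pairs touching ≥ 1 member
   of the called pair, counted once. Heterozygous splits multiply the
   (single-sample, hence raw) gene count by each member's share of
   *unique* reads — reads aligning to exactly one member of the called
   pair; `unique_scope="global"` additionally requires no alignment to any
   other haplotype. Homozygous counts are halved. Ratio tables keep het
   genes with ≥ `min_depth` (default 30) on both haplotypes, reporting
   major/minor ≥ 1 with the orientation recorded. The per-haplotype
   mismatch mapping rate is Σd / Σ sequenced bases over the reads aligned
   to that haplotype.

## Why the pair rate is count-based

With the additive definition M = R(g,h1) + R(g,h2), any haplotype X that
attracts even a trace of weight makes the heterozygous pair {A,X} strictly
outrank the homozygous {A,A}, so a true homozygote could never be called
whenever any read cross-maps — which at realistic divergence is always.
The count-based definition ties {A,A} with every {A,X} exactly when all
reads align to A, and the relative-distance stage plus the path tie-break
(homozygous preferred at exact ties, then lexicographic label order)
resolves the tie parsimoniously. The additive variant remains available as
`pair_rate="weight-sum"`. For the same reason the path tie-break prefers
homozygous states *before* label order: a pure label order would pick
{A,B} over a true {B,B} for every haplotype except the alphabetically
first.

Note an intended consequence of switch penalisation: an isolated
homozygous gene flanked by heterozygous neighbours can be pulled to a
heterozygous call sharing the neighbours' haplotypes when the evidence
ties. Gene counts are unaffected (the true haplotype is in the called
pair); only the allelic split for that gene is then filtered out by its
lack of unique reads.

## Simulator

`simulate` builds an ancestral sequence with a configurable architecture —
defaults: 30 genes of 2–4 exons (exons 260–600 bp, introns 80–250 bp,
intergenic gaps 300–600 bp), two isoforms for about half the genes (one
internal exon skipped), both strands — and mutates it independently per
haplotype (default 8) at `snp_rate` 0.005 substitutions/base and
`indel_rate` 2e-4 (1–3 bp), lifting all annotation through the indels so
every haplotype carries consistent gene models. ~0.5% per-haplotype
divergence yields ~1% between any two haplotypes, a deliberately *hard*
setting: classical HLA genes differ far more, making haplotypes easier to
separate than here.

Reads are drawn from transcript sequences: per (gene, haplotype) design
unit exactly `n_pairs` (default 2000) pairs, insert uniform in
[150, 350] bp, mates 100 bp (50 bp supported) in FR orientation, i.i.d.
base errors at `error_rate` (default 0). Heterozygous genes mix two
haplotypes at a designed ratio from {1, 1.125, 1.25, 1.5, 2}: the minor
haplotype receives the unit and the major unit × ratio, as exact integer
counts so the truth is noiseless. All randomness flows from one seed;
outputs are byte-reproducible.

The bundled aligner scores each mate against every haplotype's transcript
set by banded edit distance (edlib), seeded by exact k-mers (k = 17, three
probe offsets, full-scan fallback), and projects the best transcript-space
hit to genomic coordinates with spliced (N-op) CIGARs and exact NM. The
band (default 2 edits per mate) emulates a spliced mapper's mismatch
tolerance: a haplotype farther than the band reports the read unmapped,
which is precisely the mechanism that creates haplotype-unique reads.
Within-haplotype ties across *distinct genes* get MAPQ 3 (removed by
Stage 1, like real multimappers); equally good placements under two
isoforms of the same gene are one locus, not a multimapper. A consequence
of band-limited uniqueness worth knowing: a read is unique to its source
haplotype only if some mate accumulates ≥ band+1 edits on the sister
haplotype, so at 1% pairwise divergence genes whose variants never
cluster ≥ 3 in one mate produce *no* unique reads; their allelic split is
flagged undefined and excluded by the depth filter, exactly as such genes
are excluded on real data.

What the simulator does *not* emulate: position- or quality-dependent
error profiles, fragment GC/length bias, expression variation beyond the
designed counts, intronic/unspliced reads, and annotation errors. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under its own assumptions, not robustness to every artefact of
real libraries.

## Gene reliability filter

Genes are excluded when < 80% of their simulated reads end up uniquely
attributed or when > 20% of reads assigned to them originate elsewhere
(homologous gene pairs attract each other's reads). "Unique" is
interpreted as within-haplotype locus uniqueness — a read surviving to a
single-gene assignment — not cross-haplotype uniqueness, which would be
identically zero for any gene present on several haplotypes under an
exhaustive aligner. Both thresholds are boundary-inclusive (retain at
exactly 0.80 / 0.20) and configurable.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| `min_mapq` | 20 | Stage-1 mapping-quality cut |
| score function s(d) | 2^(−d) | one extra edit halves the odds; 1/(1+d) available |
| `pair_rate` | count | combined pair rate definition (see above) |
| `top_percentile` | 95 | M_pair shortlist percentile |
| `penalty` | 0.0028 | cost per switched haplotype between adjacent genes (standard error of the mean combined mapping rate, simulation-calibrated) |
| ε | 1e-9 | clamp keeping 1/(−log(1−M)) finite at M ∈ {0,1} |
| `min_depth` | 30 | per-haplotype depth floor for ratio reporting |
| `unique_scope` | pair | uniqueness within the called pair vs globally |
| `max_level` | 2 | annotation confidence cut (1 validated, 2 manual) |
| band | 2 | simulator-aligner edits tolerated per mate |

## Numerical and tie-break choices

Percentile thresholds use linear interpolation with an absolute tolerance
of 1e-12 when testing membership; D_pair minima likewise. Path costs
compare with relative tolerance 1e-9 before the tie key (homozygous-first,
then sorted labels, per gene along the path) applies, so exact ties are
resolved identically on every platform. Genes, states, haplotypes and
output rows are sorted wherever an order is observable; reruns are
byte-identical. Degenerate inputs: genes with zero reads become wildcard
calls with count 0; het genes with zero unique reads keep their gene count
but are flagged and excluded from ratio tables; empty pair-score lists and
empty gene graphs raise validation errors rather than guessing.

## Experiment sizes

The bundled benchmark (`hapquant.experiments.run_recovery_experiment`,
driven by `scripts/acceptance.py` and the acceptance tests) uses an
8-haplotype, 30-gene panel at the default rates with 2000 pairs per design
unit and all five ratios cycled across genes (~1 gene in 6 homozygous),
about 140k read pairs aligned against 8 haplotypes; plus a 12-gene
all-heterozygous 1:2 panel for the ratio end-point. These sizes keep a
full run in the minutes range on one CPU while leaving ~5–6 heterozygous
genes per ratio level for the medians.

## Known limitations

* Uniqueness — hence allelic splits — depends on the mapper's mismatch
  tolerance relative to local divergence; genes nearly identical between
  the carried haplotypes are reported but not split.
* The method selects among *known* haplotypes; it does not reconstruct
  novel ones, and an individual carrying an unrepresented haplotype will
  be forced onto the nearest panel members.
* Single-sample scope: "normalized gene count" equals the raw count;
  cross-sample normalisation and differential testing are downstream
  concerns.
* The gene-order interpolation for genes absent from the primary haplotype
  is rank-based; it does not attempt coordinate liftover between
  haplotypes.
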