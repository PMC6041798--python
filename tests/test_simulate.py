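"""Panel generation, read simulation, the bundled aligner, recovery metrics."""

import numpy as np
import pytest

import hapquant as hq
from hapquant import quantify, simulate
from hapquant._aligner import (
    HaplotypeAligner,
    TranscriptRef,
    build_transcript_refs,
    lift_cigar,
    revcomp,
)
from hapquant.refset import ValidationError


class TestSimulatePanel:
    def test_zero_rates_identical_haplotypes(self):
        spec = hq.PanelSpec(
            n_haplotypes=3, n_genes=2, snp_rate=0.0, indel_rate=0.0, seed=1
        )
        panel, models, variants = hq.simulate_panel(spec)
        seqs = set(panel.sequences.values())
        assert len(seqs) == 1
        assert variants.empty

    def test_deterministic_under_seed(self, tmp_path):
        spec = hq.PanelSpec(n_haplotypes=3, n_genes=2, seed=5, indel_rate=1e-3)
        out = []
        for name in ("a", "b"):
            panel, models, _ = hq.simulate_panel(spec)
            fa = tmp_path / f"{name}.fa"
            gtf = tmp_path / f"{name}.gtf"
            simulate.write_fasta(panel, str(fa))
            simulate.write_gtf(models, str(gtf))
            out.append((fa.read_bytes(), gtf.read_bytes()))
        assert out[0] == out[1]

    def test_substitution_count_near_binomial_expectation(self):
        spec = hq.PanelSpec(n_haplotypes=4, n_genes=8, snp_rate=0.01,
                            indel_rate=0.0, seed=8)
        panel, _, variants = hq.simulate_panel(spec)
        n = panel.length(panel.primary)
        expected = n * 0.01
        sd = np.sqrt(n * 0.01 * 0.99)
        for hap in panel.haplotypes:
            count = (variants.haplotype == hap).sum()
            assert abs(count - expected) < 3 * sd

    def test_annotation_consistent_across_haplotypes(self):
        spec = hq.PanelSpec(n_haplotypes=3, n_genes=4, seed=2, indel_rate=1e-3)
        panel, models, _ = hq.simulate_panel(spec)
        by_gene = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id, ms in by_gene.items():
            assert len(ms) == 3
            # same transcript ids and exon counts, coordinates may shift
            sigs = {
                tuple((t.transcript_id, len(t.exons)) for t in m.transcripts)
                for m in ms
            }
            assert len(sigs) == 1

    def test_missing_rate_drops_annotation_not_primary(self):
        spec = hq.PanelSpec(n_haplotypes=4, n_genes=10, seed=3,
                            missing_rate=0.4)
        panel, models, _ = hq.simulate_panel(spec)
        primary_genes = {
            m.gene_id for m in models if m.haplotype == panel.primary
        }
        assert len(primary_genes) == 10
        assert len(models) < 40


@pytest.fixture(scope="module")
def bundle():
    spec = hq.PanelSpec(n_haplotypes=3, n_genes=3, seed=4)
    panel, models, _ = hq.simulate_panel(spec)
    designs = hq.design_truth(
        models, seed=5, ratios=(2.0,), het_fraction=1.0, n_pairs=120
    )
    reads, truth = hq.simulate_reads(panel, models, designs, seed=6)
    return panel, models, designs, reads, truth


class TestSimulateReads:
    def test_counts_exactly_match_design(self, bundle):
        _, _, designs, _, truth = bundle
        observed = truth.reads.groupby(["gene_id", "haplotype"]).size()
        for d in designs:
            for hap, n in d.counts.items():
                assert observed[(d.gene_id, hap)] == n

    def test_one_to_two_ratio_is_exact(self, bundle):
        _, _, designs, _, _ = bundle
        for d in designs:
            minor, major = d.haplotypes
            assert d.counts[major] == 2 * d.counts[minor]

    def test_inserts_within_range(self, bundle):
        _, _, _, _, truth = bundle
        assert truth.reads["insert"].between(150, 350).all()

    def test_error_free_reads_are_exact_transcript_substrings(self, bundle):
        panel, models, _, reads, truth = bundle
        refs = build_transcript_refs(panel, models)
        tx = {
            (t.haplotype, t.transcript_id): t.seq
            for hap_refs in refs.values()
            for t in hap_refs
        }
        rows = truth.reads.set_index("read_id")
        for rid, s1, s2 in reads[:100]:
            row = rows.loc[rid]
            t = tx[(row.haplotype, row.transcript_id)]
            assert t[row.t_start : row.t_start + 100] == s1
            frag_end = row.t_start + row["insert"]
            assert t[frag_end - 100 : frag_end] == revcomp(s2)

    def test_fastq_deterministic_under_seed(self, bundle, tmp_path):
        panel, models, designs, _, _ = bundle
        blobs = []
        for name in ("x", "y"):
            reads, _ = hq.simulate_reads(panel, models, designs, seed=77)
            p1, p2 = tmp_path / f"{name}1.fq", tmp_path / f"{name}2.fq"
            simulate.write_fastq(reads, str(p1), str(p2))
            blobs.append(p1.read_bytes() + p2.read_bytes())
        assert blobs[0] == blobs[1]

    def test_insert_upper_bound_must_fit_two_mates(self, bundle):
        panel, models, designs, _, _ = bundle
        with pytest.raises(ValidationError):
            hq.simulate_reads(
                panel, models, designs, insert_range=(150, 180), read_len=100
            )


class TestLiftCigar:
    def test_plus_strand_spliced(self):
        tr = TranscriptRef(
            "g", "t", "h", "+", exons=[(100, 150), (200, 260)], seq="A" * 110
        )
        start, cigar = lift_cigar(tr, 40, 70, "30=")
        assert start == 140
        assert cigar == "10M50N20M"

    def test_minus_strand_reverses_operations(self):
        tr = TranscriptRef(
            "g", "t", "h", "-", exons=[(100, 150), (200, 260)],
            seq="A" * 110,
        )
        # mRNA interval [0, 30) sits at the genomic 3' end: exon2 tail
        start, cigar = lift_cigar(tr, 0, 30, "30=")
        assert start == 230
        assert cigar == "30M"

    def test_insertion_and_deletion_ops_preserved(self):
        tr = TranscriptRef("g", "t", "h", "+", exons=[(0, 100)], seq="A" * 100)
        start, cigar = lift_cigar(tr, 10, 40, "10=2I8=1D10=")
        assert start == 10
        assert cigar == "10M2I8M1D10M"


class TestAligner:
    def test_error_free_read_nm_zero_at_true_locus(self):
        spec = hq.PanelSpec(n_haplotypes=2, n_genes=2, seed=9)
        panel, models, _ = hq.simulate_panel(spec)
        designs = hq.design_truth(models, seed=10, het_fraction=0.0,
                                  hom_haplotype="hap01", n_pairs=30)
        reads, truth = hq.simulate_reads(panel, models, designs, seed=11)
        aln = hq.align_exhaustive(reads, panel, models)
        rows = truth.reads.set_index("read_id")
        for a in aln["hap01"]:
            if a.mate == 1:
                assert a.edit_distance == 0

    def test_single_substitution_scores_nm_one(self):
        seq = "ACGTTGCAACGGTTAACCGGTTAACGTACGTTGCAACGGTTAACCGGTA" * 2
        tr = TranscriptRef("g", "t", "h", "+", exons=[(0, len(seq))], seq=seq)
        aligner = HaplotypeAligner([tr], band=2, k=17)
        read = seq[10:60]
        mutated = read[:25] + ("A" if read[25] != "A" else "C") + read[26:]
        hit = aligner.align_mate(mutated)
        assert hit.edit_distance == 1
        assert hit.t_start == 10

    def test_reads_beyond_band_are_unmapped(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 400))
        tr = TranscriptRef("g", "t", "h", "+", exons=[(0, 400)], seq=seq)
        aligner = HaplotypeAligner([tr], band=1, k=17)
        read = list(seq[50:150])
        for i in (10, 40, 70):  # three substitutions > band 1
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        assert aligner.align_mate("".join(read)) is None

    def test_duplicated_locus_flags_multimapper_mapq(self):
        rng = np.random.default_rng(1)
        core = "".join(rng.choice(list("ACGT"), 300))
        t1 = TranscriptRef("gA", "tA", "h", "+", exons=[(0, 300)], seq=core)
        t2 = TranscriptRef("gB", "tB", "h", "+", exons=[(1000, 1300)], seq=core)
        aligner = HaplotypeAligner([t1, t2], band=2, k=17)
        hit = aligner.align_mate(core[100:200])
        assert hit.tied

    def test_nm_matches_unbanded_dp_oracle(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))

        def infix_distance(read, target):
            # unbanded semi-global DP: free target prefix and suffix
            prev = [0] * (len(target) + 1)
            for i, ca in enumerate(read, 1):
                cur = [i] + [0] * len(target)
                for j, cb in enumerate(target, 1):
                    cur[j] = min(
                        prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)
                    )
                prev = cur
            return min(prev)

        checked = 0
        for _ in range(25):
            target = "".join(rng.choice(bases, 300))
            tr = TranscriptRef("g", "t", "h", "+", exons=[(0, 300)], seq=target)
            aligner = HaplotypeAligner([tr], band=3, k=13)
            pos = int(rng.integers(0, 240))
            read = list(target[pos : pos + 60])
            for _k in range(int(rng.integers(0, 3))):
                i = int(rng.integers(0, len(read)))
                read[i] = str(rng.choice(bases))
            read = "".join(read)
            hit = aligner.align_mate(read)
            if hit is None:
                continue
            assert hit.edit_distance == infix_distance(read, target)
            checked += 1
        assert checked >= 15


@pytest.fixture(scope="module")
def truth():
    spec = hq.PanelSpec(n_haplotypes=4, n_genes=6, seed=12)
    _, models, _ = hq.simulate_panel(spec)
    designs = hq.design_truth(models, seed=13, n_pairs=100)
    import pandas as pd

    return hq.SimTruth(
        designs=designs, reads=pd.DataFrame(columns=["read_id", "gene_id"])
    )


class TestEvaluateRecovery:
    def _results(self, truth, factor=1.0):
        out = []
        for d in truth.designs:
            pair = (
                tuple(sorted(d.haplotypes))
                if d.zygosity == "het"
                else (d.haplotypes[0], d.haplotypes[0])
            )
            counts = {
                h: d.counts[h] * factor
                for h in d.haplotypes
            }
            out.append(
                quantify.GeneExpression(
                    gene_id=d.gene_id, pair=pair, zygosity=d.zygosity,
                    gene_count=int(d.total_pairs * factor),
                    combined_rate=1.0, hap_counts=counts,
                    unique_counts={}, mismatch_rates={},
                )
            )
        return out

    def test_perfect_estimates(self, truth):
        m = hq.evaluate_recovery(truth, self._results(truth), min_depth=0)
        assert m["r2_gene_counts"] == pytest.approx(1.0)
        assert m["fraction_underestimated_10pct"] == 0.0
        assert m["call_accuracy"] == 1.0

    def test_uniform_scaling_keeps_correlation(self, truth):
        # correlation is scale-free up to integer rounding of the counts
        m = hq.evaluate_recovery(truth, self._results(truth, 0.5), min_depth=0)
        assert m["r2_gene_counts"] == pytest.approx(1.0, abs=1e-3)
        assert m["fraction_underestimated_10pct"] == 1.0

    def test_too_few_genes_rejected(self, truth):
        with pytest.raises(ValidationError):
            hq.evaluate_recovery(truth, self._results(truth)[:2])
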