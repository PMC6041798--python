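"""Panel loading, annotation filtering, gene ordering, reliability filters."""

import pytest

import hapquant as hq
from hapquant import refset, simulate
from hapquant.refset import AnnotationFilter, ValidationError


GTF_LINE = (
    "{hap}\tsrc\texon\t{start}\t{end}\t.\t{strand}\t.\t"
    'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{gid}"; '
    'gene_type "{gtype}"; transcript_type "{ttype}"; level {level};\n'
)


def _write_gtf(path, rows):
    with open(path, "w") as fh:
        for r in rows:
            fh.write(GTF_LINE.format(**r))
    return str(path)


class TestLoadPanel:
    def test_two_files(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        p1.write_text(">A\nACGTACGT\n")
        p2.write_text(">B\nTTTTACGT\n")
        panel = hq.load_panel([str(p1), str(p2)])
        assert panel.haplotypes == ["A", "B"]
        assert panel.primary == "A"
        assert panel.sequences["B"] == "TTTTACGT"

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">A\nACGT\n>A\nACGG\n")
        with pytest.raises(ValidationError, match="duplicate"):
            hq.load_panel([str(p)])

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError, match="nowhere.fa"):
            hq.load_panel([str(tmp_path / "nowhere.fa")])

    def test_simulated_panel_roundtrip(self, tmp_path):
        spec = hq.PanelSpec(n_haplotypes=8, n_genes=2, seed=3)
        panel, _models, _ = hq.simulate_panel(spec)
        path = tmp_path / "panel.fa"
        simulate.write_fasta(panel, str(path))
        loaded = hq.load_panel([str(path)], primary=panel.primary)
        assert loaded.haplotypes == panel.haplotypes
        assert loaded.sequences == panel.sequences


class TestParseAnnotation:
    def test_type_filter_keeps_protein_coding_only(self, tmp_path):
        rows = [
            dict(hap="A", start=101, end=200, strand="+", gid="g1",
                 tid="t1", gtype="protein_coding", ttype="protein_coding",
                 level=1),
            dict(hap="A", start=101, end=500, strand="+", gid="g1",
                 tid="t2", gtype="protein_coding", ttype="lincRNA", level=1),
        ]
        models = hq.parse_annotation(_write_gtf(tmp_path / "a.gtf", rows))
        assert len(models) == 1
        assert [t.transcript_id for t in models[0].transcripts] == ["t1"]

    def test_empty_gtf(self, tmp_path):
        path = tmp_path / "e.gtf"
        path.write_text("# nothing here\n")
        assert hq.parse_annotation(str(path)) == []

    def test_level_filter_restricts_gene_span(self, tmp_path):
        # three-exon level-1 transcript spanning [100, 400); a second
        # level-3 transcript pushes the raw span to 900 but must be dropped
        rows = [
            dict(hap="A", start=101, end=150, strand="+", gid="g1",
                 tid="t1", gtype="protein_coding", ttype="protein_coding",
                 level=1),
            dict(hap="A", start=201, end=260, strand="+", gid="g1",
                 tid="t1", gtype="protein_coding", ttype="protein_coding",
                 level=1),
            dict(hap="A", start=351, end=400, strand="+", gid="g1",
                 tid="t1", gtype="protein_coding", ttype="protein_coding",
                 level=1),
            dict(hap="A", start=101, end=900, strand="+", gid="g1",
                 tid="t3", gtype="protein_coding", ttype="protein_coding",
                 level=3),
        ]
        models = hq.parse_annotation(
            _write_gtf(tmp_path / "a.gtf", rows),
            filter_config=AnnotationFilter(max_level=2),
        )
        assert len(models) == 1
        assert models[0].span == (100, 400)
        assert models[0].transcripts[0].exons == [
            (100, 150), (200, 260), (350, 400)
        ]

    def test_unparseable_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("A\tsrc\texon\tnot_a_number\n")
        with pytest.raises(ValidationError, match=":1"):
            hq.parse_annotation(str(path))

    def test_seqname_must_be_in_panel(self, tmp_path, toy_panel):
        rows = [
            dict(hap="Z", start=1, end=50, strand="+", gid="g1", tid="t1",
                 gtype="protein_coding", ttype="protein_coding", level=1),
        ]
        with pytest.raises(ValidationError, match="'Z'"):
            hq.parse_annotation(
                _write_gtf(tmp_path / "z.gtf", rows), panel=toy_panel
            )

    def test_simulator_gtf_roundtrip(self, tmp_path):
        spec = hq.PanelSpec(n_haplotypes=3, n_genes=4, seed=9, indel_rate=5e-4)
        panel, models, _ = hq.simulate_panel(spec)
        path = tmp_path / "sim.gtf"
        simulate.write_gtf(models, str(path))
        parsed = hq.parse_annotation(str(path), panel=panel)
        orig = {
            (m.haplotype, m.gene_id): m.span for m in models
        }
        back = {(m.haplotype, m.gene_id): m.span for m in parsed}
        assert orig == back


class TestGeneOrder:
    def _model(self, gid, hap, start, end, strand="+"):
        return hq.GeneModel(
            gene_id=gid, gene_name=gid, haplotype=hap, strand=strand,
            transcripts=[
                hq.TranscriptModel(transcript_id=f"{gid}.t", exons=[(start, end)])
            ],
        )

    def test_sorted_by_start(self, toy_panel):
        models = [
            self._model("g1", "A", 100, 200),
            self._model("g2", "A", 500, 600),
            self._model("g3", "A", 900, 1000),
        ]
        per_hap, global_order = hq.gene_order(models, toy_panel)
        assert per_hap["A"] == ["g1", "g2", "g3"]
        assert global_order == ["g1", "g2", "g3"]

    def test_equal_start_breaks_tie_by_gene_id(self, toy_panel):
        models = [
            self._model("gb", "A", 100, 300),
            self._model("ga", "A", 100, 200),
        ]
        _, order = hq.gene_order(models, toy_panel)
        assert order == ["ga", "gb"]

    def test_gene_absent_from_primary_interpolated(self, toy_panel):
        # gx exists only on B, between g1 and g2 there
        models = [
            self._model("g1", "A", 100, 200),
            self._model("g2", "A", 500, 600),
            self._model("g1", "B", 100, 200),
            self._model("gx", "B", 300, 400),
            self._model("g2", "B", 500, 600),
        ]
        _, order = hq.gene_order(models, toy_panel)
        assert order == ["g1", "gx", "g2"]

    def test_restriction_preserves_per_haplotype_order(self):
        spec = hq.PanelSpec(
            n_haplotypes=4, n_genes=8, seed=21, missing_rate=0.3
        )
        panel, models, _ = hq.simulate_panel(spec)
        per_hap, global_order = hq.gene_order(models, panel)
        rank = {g: i for i, g in enumerate(global_order)}
        for hap, order in per_hap.items():
            assert order == sorted(order, key=lambda g: rank[g])


class _Truth:
    def __init__(self, mapping):
        self.true_gene_by_pair = mapping


def _assignment(rid, gid, d=0):
    return hq.ReadGeneAssignment(
        read_pair_id=rid, gene_id=gid, dist_by_haplotype={"A": d}, bases=200
    )


class TestGeneReliability:
    def test_all_unique_and_correct(self):
        truth = _Truth({f"r{i}": "g1" for i in range(100)})
        assignments = [_assignment(f"r{i}", "g1") for i in range(100)]
        (rel,) = hq.compute_gene_reliability(truth, assignments)
        assert rel.unique_fraction == 1.0
        assert rel.mismap_fraction == 0.0
        assert rel.retained

    @pytest.mark.parametrize(
        "n_unique,retained", [(80, True), (79, False), (70, False)]
    )
    def test_unique_fraction_boundary(self, n_unique, retained):
        truth = _Truth({f"r{i}": "g1" for i in range(100)})
        assignments = [_assignment(f"r{i}", "g1") for i in range(n_unique)]
        (rel,) = hq.compute_gene_reliability(truth, assignments)
        assert rel.unique_fraction == n_unique / 100
        assert rel.retained is retained

    @pytest.mark.parametrize(
        "n_foreign,retained", [(20, True), (21, False), (25, False)]
    )
    def test_mismap_fraction_boundary(self, n_foreign, retained):
        mapping = {f"r{i}": "g1" for i in range(80)}
        mapping.update({f"f{i}": "g2" for i in range(n_foreign)})
        truth = _Truth(mapping)
        assignments = [_assignment(f"r{i}", "g1") for i in range(80)]
        assignments += [_assignment(f"f{i}", "g1") for i in range(n_foreign)]
        rel = {
            r.gene_id: r for r in hq.compute_gene_reliability(truth, assignments)
        }
        assert rel["g1"].mismap_fraction == pytest.approx(
            n_foreign / (80 + n_foreign)
        )
        assert rel["g1"].retained is retained

    def test_gene_with_zero_reads_flagged_not_raised(self):
        truth = _Truth({})
        rel = hq.compute_gene_reliability(truth, [_assignment("r0", "gX")])
        (gx,) = [r for r in rel if r.gene_id == "gX"]
        assert not gx.retained
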