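"""Shared fixtures: a small simulated panel run once per session."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import hapquant as hq


@dataclass
class SimBundle:
    spec: hq.PanelSpec
    panel: hq.HaplotypePanel
    models: list
    designs: list
    reads: list
    truth: hq.SimTruth
    alignments: dict
    result: hq.PipelineResult


@pytest.fixture(scope="session")
def sim_bundle() -> SimBundle:
    """Four haplotypes, six multi-exon genes, ~4k read pairs, full CIGARs.

    Zero sequencing error and the truth panel as the reference, so exact
    recovery properties hold; includes indels between haplotypes and both
    strands.
    """
    spec = hq.PanelSpec(n_haplotypes=4, n_genes=6, seed=13, indel_rate=3e-4)
    panel, models, _variants = hq.simulate_panel(spec)
    designs = hq.design_truth(models, seed=14, het_fraction=5 / 6, n_pairs=400)
    reads, truth = hq.simulate_reads(panel, models, designs, seed=15)
    alignments = hq.align_exhaustive(reads, panel, models, band=2, cigars=True)
    result = hq.run_pipeline(alignments, panel, models)
    return SimBundle(
        spec=spec,
        panel=panel,
        models=models,
        designs=designs,
        reads=reads,
        truth=truth,
        alignments=alignments,
        result=result,
    )


@pytest.fixture()
def toy_panel() -> hq.HaplotypePanel:
    return hq.HaplotypePanel(
        haplotypes=["A", "B"],
        sequences={"A": "ACGT" * 300, "B": "ACGT" * 300},
        primary="A",
    )
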