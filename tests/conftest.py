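"""Shared fixtures: tiny deterministic panels and cohorts."""

import numpy as np
import pytest

import pileuplr as pl


@pytest.fixture
def rng():
    return np.random.default_rng(20221024)


@pytest.fixture
def toy_panel():
    """Two-locus hand-built panel with explicit counts."""
    loci = [
        pl.VariantLocus(locus_id="1:100A>G", pathogenic_allele="G",
                        chrom="1", pos=100, ref="A", alt="G", condition="c1"),
        pl.VariantLocus(locus_id="2:200C>T", pathogenic_allele="T",
                        chrom="2", pos=200, ref="C", alt="T", condition="c2"),
    ]
    panel = pl.VariantPanel(loci)
    ids = panel.locus_ids
    # pathogenic allele 10x more frequent in A than B
    counts_a = pl.PopulationAlleleCounts(
        "A", ids, np.array([[900, 0, 100, 0], [0, 950, 0, 50]]))
    counts_b = pl.PopulationAlleleCounts(
        "B", ids, np.array([[990, 0, 10, 0], [0, 995, 0, 5]]))
    return panel, counts_a, counts_b


@pytest.fixture(scope="session")
def bundled():
    """The shipped 159-locus synthetic stand-in panel and counts."""
    return pl.load_bundled_panel()


@pytest.fixture(scope="session")
def bundled_cohort(bundled):
    panel, counts_a, _ = bundled
    cohort, truth = pl.generate_cohort(panel, counts_a, 6, None, 0.009, rng=7)
    return cohort, truth
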