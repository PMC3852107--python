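import numpy as np
import pytest

from lncarch.expression import DEFAULT_TIMEPOINTS, ExpressionTimecourse
from lncarch.genome_model import GeneAnnotation
from lncarch.synthetic_data import SimulationSpec, simulate_dataset


def make_tc(r1, r2, gene_id="g", timepoints=DEFAULT_TIMEPOINTS):
    """Two-replicate timecourse from plain value lists."""
    return ExpressionTimecourse(
        gene_id=gene_id, timepoints=timepoints, values=np.array([r1, r2], dtype=float)
    )


def make_gene(gene_id, start, end, strand, biotype, exons=None, chrom="chr1"):
    return GeneAnnotation(
        gene_id=gene_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exons=tuple(exons) if exons else ((start, end),),
        biotype=biotype,
    )


@pytest.fixture(scope="session")
def exemplar_dataset():
    """One planted pair per architecture class, default study conditions."""
    return simulate_dataset(SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def exemplar_sets(exemplar_dataset):
    a = exemplar_dataset.annotations
    return a.subset_biotype("lncRNA"), a.subset_biotype("protein_coding")
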