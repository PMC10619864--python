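import pytest

from thermoss.annotation import GeneModel, GenomeAnnotation
from thermoss.simulate import SimConfig, simulate
from thermoss import evaluate as ev


def make_annotation(spec):
    """Build a GenomeAnnotation from (gene_id, chrom, start, end) tuples."""
    genes = [GeneModel(g, c, s, e, "+") for g, c, s, e in spec]
    lengths = {}
    for _, c, _, e in spec:
        lengths[c] = max(lengths.get(c, 0), e + 10_000)
    return GenomeAnnotation(genes=genes, chrom_lengths=lengths)


@pytest.fixture(scope="session")
def bundle():
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return ev.run_pipeline(bundle)
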