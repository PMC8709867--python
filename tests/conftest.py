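import pytest

from genedecay.gene_models import GeneModel, MutationRecord, resolve_record, left_normalize
from genedecay.synthetic_data import make_fixture


@pytest.fixture(scope="session")
def galliform():
    return make_fixture("galliform")


@pytest.fixture(scope="session")
def rodent():
    return make_fixture("rodent")


@pytest.fixture(scope="session")
def cheetah():
    return make_fixture("cheetah")


@pytest.fixture(scope="session")
def sciuridae():
    return make_fixture("sciuridae")


@pytest.fixture
def tiny_reference():
    # ATG GCA CAG GGA CCA TAA split over two exons (phase 0 / 0)
    return GeneModel.from_sequences(
        "reference", "toy", ["ATGGCACAG", "GGACCATAA"]
    )


def canonical_records(records, reference):
    """Resolve + left-normalize records for identity comparison."""
    out = []
    for m in records:
        r = resolve_record(m, reference)
        exon_seq = reference.exons[r.exon - 1].sequence
        n = left_normalize(r, exon_seq)
        out.append((r.exon, r.kind, n.position, r.length, n.alt))
    return sorted(out)
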