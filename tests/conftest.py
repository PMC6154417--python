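import pytest

from sdpnet import AlignedSequence, AlignmentMatrix, default_spec, generate


def make_msa(rows: dict[str, str]) -> AlignmentMatrix:
    """Build a small alignment from {id: residue string}."""
    return AlignmentMatrix(
        [AlignedSequence(id=k, description="", residues=v) for k, v in rows.items()]
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic alignment + truth, shared across tests."""
    return generate(default_spec())


@pytest.fixture
def tiny_msa():
    return make_msa({"a": "AQ-E", "b": "AQGE"})
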