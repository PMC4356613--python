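import pytest

from motifarch import CoreMotif, MotifOccurrence, compile_motif


@pytest.fixture
def hox() -> CoreMotif:
    return compile_motif("Hox", "Acj6", "AATTA")


@pytest.fixture
def pou() -> CoreMotif:
    return compile_motif("Pou", "Acj6", "TGCAA/T")


def occ(name, start, end, strand="+", seq_id="s1", matched=None):
    """Shorthand occurrence builder for composite-element tests."""
    return MotifOccurrence(
        motif_name=name, seq_id=seq_id, start=start, end=end, strand=strand,
        matched=matched,
    )
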