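import numpy as np
import pytest

from sorfmine.orfdb import Transcript


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_transcript(rng, length=300, tid="TX1", biotype="noncoding"):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Transcript(transcript_id=tid, biotype=biotype, sequence=seq)


@pytest.fixture
def coding_transcript():
    # CDS [30, 90): ATG + 18 sense codons + TGA
    utr5 = "C" * 30
    cds = "ATG" + "GCT" * 18 + "TGA"
    utr3 = "C" * 40
    return Transcript(
        transcript_id="TXC",
        biotype="coding",
        sequence=utr5 + cds + utr3,
        cds=(30, 90),
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One generated synthetic dataset shared across read-only tests."""
    from sorfmine import synthetic

    out = tmp_path_factory.mktemp("ds")
    truth = synthetic.generate_dataset(out, seed=42)
    return out, truth
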