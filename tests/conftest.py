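import numpy as np
import pytest

from wophage.io import EvidenceTable, PeptideEvidence, ProteinRecord

ALPHA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng, length, locus="P1", **kw):
    seq = "".join(rng.choice(ALPHA, size=length))
    return ProteinRecord(locus_tag=locus, sequence=seq, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_db():
    """Three proteins with known shared/unique tryptic peptides."""
    return [
        ProteinRecord("WD0001", "MKTAYIAKQRQISFVK"),
        ProteinRecord("WD0002", "MKTAYIAKWWWNDEEK"),  # shares MKTAYIAK prefix
        ProteinRecord("WD0003", "GGGGHHHHPPPPLLLL"),
    ]


@pytest.fixture
def tiny_evidence():
    rows = [
        PeptideEvidence("MKTAYIAK", "D", confidence=0.99),   # shared by WD0001/2
        PeptideEvidence("QRQISFVK", "D", confidence=0.99),   # unique to WD0001
        PeptideEvidence("QRQISFVK", "E", confidence=0.99),
        PeptideEvidence("WWWNDEEK", "E", confidence=0.99),   # unique to WD0002
        PeptideEvidence("HHHHPPPP", "F", confidence=0.50),   # below threshold
        PeptideEvidence("NOTINDBPEPTIDE", "G", confidence=0.99),  # unmatched
    ]
    return EvidenceTable(rows=rows, dataset_ids=["D", "E", "F", "G"])


from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
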