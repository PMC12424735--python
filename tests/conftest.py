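import numpy as np
import pytest

from methylsite.records import ProteinRecord, WindowRecord


@pytest.fixture
def toy_protein():
    # lysines at 2, 5, 9, 12, 20
    return ProteinRecord("P001", "AKGTKAFCKLVKAGGTWEDKAVPSY")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_window(rng, label=0, task="methylation", acc="P", pos=16):
    aas = np.array(list("ACDEFGHILMNPQRSTVWY"))
    seq = "".join(rng.choice(aas, 31))
    seq = seq[:15] + "K" + seq[16:]
    return WindowRecord(accession=acc, position=pos, window=seq,
                        label=label, task=task)
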