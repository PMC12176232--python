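import numpy as np
import pytest

from protclass import (
    LabeledDataset,
    ProteinRecord,
    PropertyTable,
    SyntheticSpec,
    featurize_dataset,
    generate_dataset,
    pseaac_scheme,
)
from protclass.sequence_io import ALPHABET


@pytest.fixture(scope="session")
def props():
    return PropertyTable.default()


@pytest.fixture
def write_text(tmp_path):
    def _write(name, content):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def random_records(rng, n, min_len=20, max_len=120, prefix="R"):
    alphabet = np.array(list(ALPHABET))
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        out.append(ProteinRecord(f"{prefix}{i:03d}", "", seq))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_dataset():
    """Six short records, three per class."""
    pos = [
        ProteinRecord("P1", "", "AAKLLAKLAKLA"),
        ProteinRecord("P2", "", "LKALKAAKLLKA"),
        ProteinRecord("P3", "", "KKLALAKALLAA"),
    ]
    neg = [
        ProteinRecord("N1", "", "MSTCDEFGHIVW"),
        ProteinRecord("N2", "", "DECFGHMSTIWV"),
        ProteinRecord("N3", "", "GHCDEFMSTVWI"),
    ]
    labels = np.array([1, 1, 1, 0, 0, 0])
    return LabeledDataset(pos + neg, labels)


@pytest.fixture(scope="session")
def shifted_matrix():
    """PseAAC features of a seeded composition-shifted dataset (60 + 60)."""
    ds = generate_dataset(SyntheticSpec(60, 60, (60, 100), 2.0, seed=7))
    return featurize_dataset(ds, pseaac_scheme())
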