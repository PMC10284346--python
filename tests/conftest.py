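import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pseomp.indices import default_index_table
from pseomp.pseaac import PseAACConfig
from pseomp.seq_io import AMINO_ACIDS

from oracles import standardize_oracle


@pytest.fixture(scope="session")
def index_table():
    return default_index_table()


@pytest.fixture(scope="session")
def standardized_oracle_table(index_table):
    """Oracle-side standardized indices, built from the raw table values."""
    return standardize_oracle([list(row) for row in index_table.values])


@pytest.fixture()
def random_sequences():
    """Deterministic random amino-acid sequences of varied length."""

    def make(n, min_len=10, max_len=200, seed=42):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            length = int(rng.integers(min_len, max_len + 1))
            out.append("".join(AMINO_ACIDS[i]
                               for i in rng.integers(0, 20, size=length)))
        return out

    return make


@pytest.fixture()
def write_fasta_file(tmp_path):
    def make(entries, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in entries:
                fh.write(f">{rec_id}\n{seq}\n")
        return path

    return make


@pytest.fixture()
def small_config(index_table):
    return PseAACConfig(lam=3, weight=0.5, index_table=index_table)
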