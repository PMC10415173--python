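import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fasta_file(tmp_path):
    """Small FASTA with mixed case and a multi-line entry."""
    p = tmp_path / "toy.fasta"
    p.write_text(">s1\nacgtACGT\n>s2\nTTTT\nGGGG\n>s3\nacgu\n")
    return p


@pytest.fixture
def labels_file(tmp_path):
    p = tmp_path / "labels.tsv"
    p.write_text("id\tlabel\ns1\tBacteria\ns2\tArchaea\ns3\tBacteria\n")
    return p


@pytest.fixture
def separated_clouds(rng):
    """Two well-separated point clouds on the 4-simplex, 30 samples each."""
    a = rng.dirichlet([50, 2, 2, 2], size=30)  # A-heavy corner
    b = rng.dirichlet([2, 2, 2, 50], size=30)  # T-heavy corner
    X = np.vstack([a, b])
    y = ["alpha"] * 30 + ["beta"] * 30
    return X, y
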