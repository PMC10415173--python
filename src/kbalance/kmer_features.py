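"""Relative k-mer frequency profiles.

Each DNA fragment is featurized as the vector of relative frequencies of
all 4^k words of length k: a window of width k slides over the sequence
with step 1, windows containing any non-ACGT character are skipped, and
each count is divided by the number of valid windows. Profiles therefore
live on the probability simplex of dimension D = 4^k regardless of
ambiguity content.

Feature order is lexicographic with A < C < G < T, i.e. ``kmer_index``
is the base-4 value of the word with A=0, C=1, G=2, T=3. No
reverse-complement canonicalization is applied: both strands' words are
separate features.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_io import SeqRecord

__all__ = [
    "FeatureConfig",
    "KmerProfile",
    "kmer_index",
    "kmer_word",
    "feature_names",
    "extract_profile",
    "profile_matrix",
    "write_profiles",
    "read_profiles",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
# byte -> base code; -1 marks anything that is not A/C/G/T
_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i

FEATURE_ORDERING = "lex:ACGT"


@dataclass(frozen=True)
class FeatureConfig:
    """Word length k and the derived feature dimensionality D = 4^k.

    ``max_k`` guards against accidentally materializing huge profile
    matrices (4^9 > 260k columns); raise it explicitly if you mean it.
    """

    k: int = 3
    max_k: int = 8

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.max_k):
            raise ValueError(f"k must be in [1, {self.max_k}], got {self.k}")

    @property
    def D(self) -> int:
        return 4**self.k

    def fingerprint(self) -> dict:
        """Identity of the feature space, stored with trained models."""
        return {"k": self.k, "D": self.D, "ordering": FEATURE_ORDERING}


@dataclass
class KmerProfile:
    """Relative k-mer frequencies of one sequence.

    ``values`` is None when the sequence had no valid window (too short,
    or every window hit an ambiguous base); such profiles are dropped by
    :func:`profile_matrix`.
    """

    values: np.ndarray | None
    valid_windows: int

    @property
    def is_valid(self) -> bool:
        return self.valid_windows > 0


def kmer_index(word: str) -> int:
    """Lexicographic rank of ``word`` among all words of its length."""
    idx = 0
    for ch in word:
        code = _BASES.find(ch)
        if code < 0:
            raise ValueError(f"ambiguous or invalid base {ch!r} in k-mer {word!r}")
        idx = idx * 4 + code
    return idx


def kmer_word(index: int, k: int) -> str:
    if not (0 <= index < 4**k):
        raise ValueError(f"index {index} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


def feature_names(k: int) -> list[str]:
    """All 4^k words in feature (lexicographic) order."""
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def _window_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 code of every window plus its validity mask."""
    codes = _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        idx = idx * 4 + c  # garbage where c == -1; masked out below
        valid &= c >= 0
    return idx, valid


def extract_profile(record: SeqRecord, config: FeatureConfig) -> KmerProfile:
    """Featurize one record; returns an invalid profile if no window counts."""
    idx, valid = _window_codes(record.sequence, config.k)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return KmerProfile(values=None, valid_windows=0)
    counts = np.bincount(idx[valid], minlength=config.D)
    return KmerProfile(values=counts / n_valid, valid_windows=n_valid)


def profile_matrix(
    records: Sequence[SeqRecord], config: FeatureConfig
) -> tuple[np.ndarray, list[int]]:
    """Stack profiles of ``records`` row-wise, in input order.

    Returns the matrix and the indices of the records actually kept;
    records with no valid window are dropped (and logged). Raises if the
    input is empty or every record is invalid.
    """
    if len(records) == 0:
        raise ValueError("profile_matrix: empty input")
    rows, kept = [], []
    for i, rec in enumerate(records):
        prof = extract_profile(rec, config)
        if prof.is_valid:
            rows.append(prof.values)
            kept.append(i)
    if not rows:
        raise ValueError("profile_matrix: all records invalid (no countable k-mer windows)")
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.warning("profile_matrix: dropped %d of %d records with no valid window",
                       n_dropped, len(records))
    return np.vstack(rows), kept


def write_profiles(path, ids: Iterable[str], matrix: np.ndarray, config: FeatureConfig) -> None:
    """Write a profile matrix as TSV: id column + one column per k-mer word."""
    df = pd.DataFrame(matrix, columns=feature_names(config.k))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_profiles(path) -> tuple[list[str], np.ndarray, FeatureConfig]:
    """Read a profile TSV back; infers k from the column count."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2 or df.columns[0] != "id":
        raise ValueError(f"{path}: not a profile matrix (expected leading 'id' column)")
    d = df.shape[1] - 1
    k = round(np.log(d) / np.log(4))
    if 4**k != d:
        raise ValueError(f"{path}: column count {d} is not a power of 4")
    config = FeatureConfig(k=k)
    if list(df.columns[1:]) != feature_names(k):
        raise ValueError(f"{path}: k-mer columns are not in lexicographic order")
    return df["id"].astype(str).tolist(), df.iloc[:, 1:].to_numpy(dtype=float), config
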