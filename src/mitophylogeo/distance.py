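"""Pairwise sequence distances.

The study's genetic distance is the absolute number of nucleotide
differences between two mitogenomes, with pairwise deletion of columns
containing a gap or ambiguity in either member of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import SequenceAlignment


@dataclass
class DistanceMatrix:
    """A symmetric matrix over named items with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        idx = [index[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy())


def _encode(aln: SequenceAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes plus a validity mask (True for plain A/C/G/T)."""
    arr = aln.to_array()
    codes = np.full(arr.shape, 5, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == bytes([b])] = i
    codes[arr == b"-"] = 4
    valid = codes < 4
    kept = aln.kept_columns()
    codes = codes[:, kept]
    valid = valid[:, kept]
    return codes, valid


def difference_matrix(
    aln: SequenceAlignment, per_site: bool = False, block: int = 32
) -> DistanceMatrix:
    """Pairwise Hamming counts with pairwise deletion of gaps/ambiguities.

    With ``per_site=True``, each count is divided by the number of columns
    valid in both members of the pair.
    """
    if aln.n < 2:
        raise ValueError("need at least two sequences")
    codes, valid = _encode(aln)
    n = aln.n
    out = np.zeros((n, n), dtype=float)
    denom = np.zeros((n, n), dtype=float)
    for start in range(0, n, block):
        stop = min(start + block, n)
        a = codes[start:stop, None, :]
        b = codes[None, :, :]
        both = valid[start:stop, None, :] & valid[None, :, :]
        out[start:stop] = np.sum((a != b) & both, axis=2)
        denom[start:stop] = both.sum(axis=2)
    np.fill_diagonal(out, 0)
    if per_site:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, out / denom, 0.0)
        np.fill_diagonal(out, 0)
    return DistanceMatrix(list(aln.sample_ids), out)
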