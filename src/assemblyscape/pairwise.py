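"""Symmetric sample-by-sample matrices (dissimilarity, βNTI, Δlatitude, ...).

A thin labelled wrapper around a square numpy array.  Every pairwise quantity
in the package (Bray–Curtis, βNTI, RCbray, latitudinal difference, great-circle
distance, environmental deltas) travels through this container so that sample
alignment between matrices is checked once, in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognised values for :attr:`PairwiseMatrix.kind`
KINDS = frozenset(
    {
        "dissimilarity",
        "similarity",
        "bnti",
        "rcbray",
        "delta_latitude",
        "geographic_km",
        "delta_env",
    }
)

_SYMMETRY_TOL = 1e-12


@dataclass
class PairwiseMatrix:
    """A symmetric matrix of per-sample-pair values.

    Parameters
    ----------
    sample_ids
        Row/column labels, in order.
    values
        Square symmetric float array.  ``NaN`` marks undefined pairs
        (e.g. a degenerate βNTI null distribution).
    kind
        Semantic tag, one of :data:`KINDS`.
    """

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "dissimilarity"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} sample ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in PairwiseMatrix")
        if self.kind not in KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        finite = np.isfinite(self.values)
        both = finite & finite.T
        if not np.allclose(
            self.values[both], self.values.T[both], atol=_SYMMETRY_TOL, rtol=0.0
        ):
            raise ValueError("matrix is not symmetric within 1e-12")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    # -- basic protocol ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values[self._index[i], self._index[j]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values in row-major pair order."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]

    def pair_ids(self) -> list[tuple[str, str]]:
        """Sample-id pairs in the same order as :meth:`condensed`."""
        iu, ju = np.triu_indices(self.n_samples, k=1)
        return [(self.sample_ids[i], self.sample_ids[j]) for i, j in zip(iu, ju)]

    def reorder(self, sample_ids: list[str]) -> "PairwiseMatrix":
        """Return a copy with rows/columns in the given sample order."""
        missing = [s for s in sample_ids if s not in self._index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = np.array([self._index[s] for s in sample_ids])
        return PairwiseMatrix(list(sample_ids), self.values[np.ix_(idx, idx)], self.kind)

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path, kind: str = "dissimilarity") -> "PairwiseMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column sample ids differ")
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


def align(*matrices: PairwiseMatrix) -> tuple[PairwiseMatrix, ...]:
    """Restrict matrices to their common samples, in the first matrix's order."""
    common = [s for s in matrices[0].sample_ids if all(s in m._index for m in matrices)]
    if len(common) < 2:
        raise ValueError("fewer than 2 samples shared across matrices")
    return tuple(m.reorder(common) for m in matrices)
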