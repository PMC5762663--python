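"""Labeled symmetric pairwise matrices (similarity or distance).

The whole pipeline trades in station-by-station matrices: Jaccard
similarities, z-scored environmental distances, and symmetrized surface-ocean
transit times. Missing entries (unreachable station pairs, undefined
similarities) are carried as NaN and dropped by downstream consumers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["PairwiseMatrix"]


@dataclass
class PairwiseMatrix:
    """A labeled symmetric matrix over stations.

    Parameters
    ----------
    values : (n, n) ndarray
        Symmetric matrix; NaN marks undefined/unreachable pairs.
    labels : sequence of str
        Station identifiers, one per row/column.
    kind : str
        ``"similarity"`` (diagonal 1, entries in [0, 1]) or ``"distance"``
        (diagonal 0, non-negative entries).
    units : str, optional
        Physical units of the entries (e.g. ``"days"``).
    """

    values: np.ndarray
    labels: list[str]
    kind: str = "distance"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if self.kind not in ("similarity", "distance"):
            raise ValueError(f"kind must be similarity or distance, got {self.kind!r}")
        finite = np.isfinite(self.values)
        sym = self.values.copy()
        sym[~finite] = -1.0  # compare NaN placement symmetrically
        if not np.allclose(sym, sym.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) vectorization, scipy ``pdist`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pair_labels(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(self.n, k=1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(iu, ju)]

    def reorder(self, labels: Sequence[str]) -> "PairwiseMatrix":
        """Return a copy with rows/columns permuted to ``labels`` order."""
        idx = [self.labels.index(str(l)) for l in labels]
        return PairwiseMatrix(
            self.values[np.ix_(idx, idx)], list(labels), self.kind, self.units
        )

    def align_with(self, other: "PairwiseMatrix") -> None:
        if self.labels != other.labels:
            raise ValueError("matrices are defined on different station sets/orders")

    # ---------------------------------------------------------------- IO ---
    def to_csv(self, path) -> None:
        """Write as a labeled square CSV; NaN entries become empty cells."""
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "distance", units: str = "") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("row and column labels differ; not a square labeled matrix")
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), kind, units)

    @classmethod
    def from_condensed(
        cls,
        condensed: np.ndarray,
        labels: Sequence[str],
        kind: str = "distance",
        units: str = "",
    ) -> "PairwiseMatrix":
        from scipy.spatial.distance import squareform

        values = squareform(np.asarray(condensed, dtype=float), checks=False)
        if kind == "similarity":
            np.fill_diagonal(values, 1.0)
        return cls(values, list(labels), kind, units)
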