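"""1-D K-nearest-neighbor classifier over evolved-formula scalars.

The feature space is one-dimensional (the scalar output of the evolved
formula), so the distance is the absolute difference.  Reference sets are
small, so classification is exact brute force with fully specified tie
rules: distance ties are broken by reference insertion order (stable
sort), and an even-k vote tie is broken by the label of the single nearest
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SPIKE, NONSPIKE = 1, 0


@dataclass
class KNNModel:
    """Reference scalars with labels and the neighbor count k.

    k defaults to 100 and is clamped (with a warning) to the reference-set
    size so small fixtures run unchanged.
    """

    reference_values: np.ndarray
    reference_labels: np.ndarray
    k: int = 100

    def __post_init__(self) -> None:
        self.reference_values = np.asarray(self.reference_values, dtype=float)
        self.reference_labels = np.asarray(self.reference_labels, dtype=int)
        if self.reference_values.size == 0:
            raise ValueError("empty reference set")
        if self.reference_values.shape != self.reference_labels.shape:
            raise ValueError("values/labels length mismatch")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > self.reference_values.size:
            warnings.warn(
                f"k={self.k} exceeds reference size "
                f"{self.reference_values.size}; clamping",
                stacklevel=2,
            )
            self.k = self.reference_values.size

    def classify(self, query: float) -> int:
        """Majority label among the k nearest references to `query`."""
        return int(self.classify_many(np.array([query]))[0])

    def classify_many(self, queries: np.ndarray,
                      chunk: int = 4096) -> np.ndarray:
        """Vectorized classification of many query scalars."""
        queries = np.asarray(queries, dtype=float)
        if not np.all(np.isfinite(queries)):
            raise ValueError("queries must be finite")
        out = np.empty(queries.shape, dtype=int)
        flat = queries.ravel()
        for lo in range(0, flat.size, chunk):
            out.ravel()[lo:lo + chunk] = self._classify_block(
                flat[lo:lo + chunk])
        return out

    def _classify_block(self, queries: np.ndarray) -> np.ndarray:
        dist = np.abs(queries[:, None] - self.reference_values[None, :])
        # stable argsort: equal distances keep reference insertion order
        order = np.argsort(dist, axis=1, kind="stable")[:, : self.k]
        neigh_labels = self.reference_labels[order]
        votes = neigh_labels.sum(axis=1)
        decision = np.where(2 * votes > self.k, SPIKE, NONSPIKE)
        tie = 2 * votes == self.k
        if np.any(tie):
            decision[tie] = neigh_labels[tie, 0]  # 1-NN label breaks the tie
        return decision

    # -- persistence ------------------------------------------------------

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "value": self.reference_values,
            "label": self.reference_labels,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, k: int = 100) -> "KNNModel":
        df = pd.read_csv(path, sep="\t")
        return cls(df["value"].to_numpy(), df["label"].to_numpy(), k=k)
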