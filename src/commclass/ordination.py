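"""Principal coordinate analysis (classical metric scaling).

PCoA embeds a dissimilarity matrix into coordinates whose Euclidean
distances approximate the input dissimilarities: the squared
dissimilarities are double-centered (Gower transform) and
eigendecomposed; coordinates are eigenvectors scaled by the square roots
of their (positive) eigenvalues.  Negative eigenvalues — which arise for
non-Euclidean dissimilarities such as Bray-Curtis — are reported but
contribute no axis; no correction (Cailliez/Lingoes) is applied.  Each
axis's sign is fixed by making its largest-magnitude coordinate
positive, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .distances import DistanceMatrix
from .tables import ValidationError

__all__ = ["Ordination", "pcoa"]


@dataclass
class Ordination:
    """Sample coordinates on descending-eigenvalue axes."""

    sample_ids: list[str]
    coordinates: np.ndarray  # (n, m), column-centered
    eigenvalues: np.ndarray  # all n eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]

    def to_dataframe(self, labels=None) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)
        if labels is not None:
            df["class"] = list(labels)
        return df

    def write(self, path, labels=None) -> None:
        df = self.to_dataframe(labels)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", lineterminator="\n")


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical scaling of a dissimilarity matrix to ``n_axes`` coordinates.

    Returns at most ``n_axes`` axes; fewer when the matrix has fewer
    positive eigenvalues.  Eigenvalues (including negative ones) are
    reported in descending order.
    """
    n = d.n_samples
    if not 1 <= n_axes <= n - 1:
        raise ValidationError(f"n_axes must be in [1, {n - 1}], got {n_axes}")
    dd = d.data
    # Gower double-centering of -0.5 * D^2
    sq = dd**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    b = (b + b.T) / 2
    eigvals, eigvecs = eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    positive = eigvals > tol
    m = min(n_axes, int(positive.sum()))
    coords = eigvecs[:, :m] * np.sqrt(eigvals[:m])
    # deterministic sign: largest-magnitude loading per axis is positive
    for ax in range(m):
        col = coords[:, ax]
        if col[int(np.argmax(np.abs(col)))] < 0:
            coords[:, ax] = -col
    pos_sum = eigvals[positive].sum()
    prop = np.where(positive, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    return Ordination(list(d.sample_ids), coords, eigvals, prop)
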