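"""Pairwise dissimilarity matrices between samples.

Bray-Curtis on relative abundances is the main pipeline's metric:
d(i,j) = sum_k |y_ik - y_jk| / sum_k (y_ik + y_jk), 0 for identical
composition and 1 for disjoint taxon support.  The root Jensen-Shannon
divergence (base-2 logarithm, so bounded by 1) supports the k-medoids
replication path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import ProportionTable, ValidationError

__all__ = ["DistanceMatrix", "bray_curtis", "jensen_shannon"]

_SYM_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray
    metric_name: str = "unknown"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        d = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=_SYM_TOL):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=_SYM_TOL):
            raise ValidationError("distance matrix diagonal is not zero")
        if (d < -_SYM_TOL).any():
            raise ValidationError("distances must be non-negative")
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        np.fill_diagonal(d, 0.0)
        self.data = d

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, sample_ids: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return DistanceMatrix(
            list(sample_ids), self.data[np.ix_(idx, idx)], self.metric_name
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def read(cls, path, metric_name: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValidationError("row and column ids of a distance matrix must match")
        return cls(list(df.index.astype(str)), df.to_numpy(float), metric_name)


def bray_curtis(p: ProportionTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between every pair of samples."""
    if p.n_samples < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    d = squareform(pdist(p.proportions, metric="braycurtis"))
    return DistanceMatrix(list(p.sample_ids), d, "bray-curtis")


def jensen_shannon(p: ProportionTable, pseudocount: float = 1e-6) -> DistanceMatrix:
    """Root Jensen-Shannon divergence (base-2 log) between samples.

    Each row is smoothed by adding ``pseudocount`` to every taxon and
    renormalised, so zero abundances do not produce infinite divergence
    terms.  With the base-2 logarithm the square-root divergence is a
    metric bounded by 1.
    """
    if not pseudocount > 0:
        raise ValidationError(f"pseudocount must be positive, got {pseudocount}")
    if p.n_samples < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    x = p.proportions + pseudocount
    x = x / x.sum(axis=1, keepdims=True)
    # scipy's jensenshannon distance is sqrt(JSD) with natural log;
    # dividing by sqrt(ln 2) converts to the base-2 form bounded by 1.
    d = squareform(pdist(x, metric="jensenshannon")) / math.sqrt(math.log(2.0))
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(list(p.sample_ids), d, "root-jsd-base2")
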