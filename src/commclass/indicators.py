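"""Dufrene-Legendre indicator genera for community classes.

For genus i and cluster c, f_{i,c} is the fraction of cluster-c samples
in which the genus is present (abundance > 0) and a_{i,c} is the
cluster's mean abundance of the genus divided by the sum of the
per-cluster mean abundances across all K clusters.  The indicator value
d_{i,c} = f_{i,c} * a_{i,c} equals 1 for a perfect indicator: a genus
present in every sample of one cluster and absent everywhere else.

Significance is assessed by permuting sample-to-cluster labels and
comparing each genus's maximum-over-clusters indicator value with its
permutation distribution (add-one corrected, so p > 0 always).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Partition
from .tables import ProportionTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["IndicatorScore", "indval", "select_indicators", "write_indicator_table"]


@dataclass
class IndicatorScore:
    """Indicator statistics of one genus in one cluster."""

    genus: str
    cluster: object
    f: float  # sample frequency within the cluster
    a: float  # share of cross-cluster mean abundance
    d: float  # indicator value f * a
    p: float  # permutation p of the genus's max-over-clusters d
    is_max_cluster: bool  # True on the cluster attaining the genus's max d


def _cluster_stats(x: np.ndarray, onehot: np.ndarray, sizes: np.ndarray):
    """Return (f, a, d) matrices of shape (K, n_taxa)."""
    presence = (x > 0).astype(float)
    f = (onehot.T @ presence) / sizes[:, np.newaxis]
    cluster_mean = (onehot.T @ x) / sizes[:, np.newaxis]
    denom = cluster_mean.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, cluster_mean / denom, 0.0)
    return f, a, f * a


def indval(
    abund: ProportionTable,
    part: Partition,
    n_perm: int = 999,
    seed: int = 0,
) -> list[IndicatorScore]:
    """Indicator values for every (genus, cluster) pair with permutation p.

    The permutation statistic is each genus's maximum indicator value
    over clusters; labels are randomly reassigned across samples.  The
    genus-level p-value (1 + #exceedances) / (1 + n_perm) is attached to
    all of that genus's scores.  Genera absent from every sample are
    excluded and logged.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if set(part.sample_ids) - set(abund.sample_ids):
        raise ValidationError("partition contains samples missing from abundances")
    sub = abund.subset(list(part.sample_ids))
    x = sub.proportions
    labels = part.relabel_consecutive().labels
    k = labels.max() + 1
    n = len(labels)
    present_anywhere = (x > 0).any(axis=0)
    dropped = [t for t, keep in zip(sub.taxon_ids, present_anywhere) if not keep]
    if dropped:
        logger.info("excluding %d genera absent from all samples", len(dropped))
    taxa = [t for t, keep in zip(sub.taxon_ids, present_anywhere) if keep]
    x = x[:, present_anywhere]

    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    sizes = onehot.sum(axis=0)
    f, a, d = _cluster_stats(x, onehot, sizes)
    observed = d.max(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(taxa))
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        oh = np.zeros((n, k))
        oh[np.arange(n), perm_labels] = 1.0
        _, _, dp = _cluster_stats(x, oh, oh.sum(axis=0))
        exceed += dp.max(axis=0) >= observed - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    cluster_names = list(np.unique(part.labels))
    argmax_cluster = d.argmax(axis=0)
    scores = []
    for ti, genus in enumerate(taxa):
        for c in range(k):
            scores.append(
                IndicatorScore(
                    genus=genus,
                    cluster=cluster_names[c],
                    f=float(f[c, ti]),
                    a=float(a[c, ti]),
                    d=float(d[c, ti]),
                    p=float(pvals[ti]),
                    is_max_cluster=bool(c == argmax_cluster[ti]),
                )
            )
    return scores


def select_indicators(
    scores: list[IndicatorScore],
    p_max: float = 0.01,
    min_presence: float = 0.5,
) -> list[IndicatorScore]:
    """Apply the indicator-selection thresholds.

    Keeps, per genus, the score at its best cluster when the permutation
    p-value is below ``p_max`` and the genus is present in at least
    ``min_presence`` of the samples of at least one cluster.
    """
    if not 0 < p_max <= 1:
        raise ValidationError("p_max must be in (0, 1]")
    if not 0 <= min_presence <= 1:
        raise ValidationError("min_presence must be in [0, 1]")
    by_genus: dict[str, list[IndicatorScore]] = {}
    for s in scores:
        by_genus.setdefault(s.genus, []).append(s)
    kept = []
    for genus, rows in by_genus.items():
        if rows[0].p >= p_max:
            continue
        if max(r.f for r in rows) < min_presence:
            continue
        best = max(rows, key=lambda r: r.d)
        kept.append(best)
    kept.sort(key=lambda r: -r.d)
    return kept


def write_indicator_table(path, scores: list[IndicatorScore], selected=None) -> None:
    """Tab-delimited dump: genus, cluster, f, a, d, p, selected."""
    selected_keys = (
        {(s.genus, s.cluster) for s in selected} if selected is not None else set()
    )
    df = pd.DataFrame(
        {
            "genus": [s.genus for s in scores],
            "cluster": [s.cluster for s in scores],
            "f": [s.f for s in scores],
            "a": [s.a for s in scores],
            "d": [s.d for s in scores],
            "p": [s.p for s in scores],
            "selected": [(s.genus, s.cluster) in selected_keys for s in scores],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
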