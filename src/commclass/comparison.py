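"""Agreement of community-class partitions across habitats and visits.

The Adjusted Rand Index (ARI) is the chance-corrected pair-counting
agreement between two partitions of the same subjects: 1 for identical
partitions, expectation 0 for independent ones.  For longitudinal
stability the two visits are pooled and clustered jointly, so class
labels are directly comparable between visits and switching can be
tabulated as a class-by-class transition matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .clustering import Partition, cluster_counts
from .tables import CountTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedPartition",
    "TransitionSummary",
    "adjusted_rand_index",
    "cross_habitat_ari",
    "stability",
]


@dataclass
class PairedPartition:
    """Labels of the same subjects in two contexts (habitats or visits)."""

    subject_ids: list[str]
    labels_a: np.ndarray
    labels_b: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        la = np.asarray(self.labels_a)
        lb = np.asarray(self.labels_b)
        if la.shape != (len(self.subject_ids),) or lb.shape != la.shape:
            raise ValidationError("label vectors must match the subject list")
        self.labels_a, self.labels_b = la, lb

    @classmethod
    def from_partitions(cls, a: Partition, b: Partition) -> "PairedPartition":
        """Pair on the subjects present in both partitions (order of a)."""
        in_b = {s: l for s, l in zip(b.sample_ids, b.labels)}
        shared = [s for s in a.sample_ids if s in in_b]
        la = [l for s, l in zip(a.sample_ids, a.labels) if s in in_b]
        return cls(shared, np.asarray(la), np.asarray([in_b[s] for s in shared]))


@dataclass
class TransitionSummary:
    """Class switching between two visits of the same subjects."""

    classes: list
    matrix: np.ndarray  # rows: visit-1 class, columns: visit-2 class
    maintained_fraction: float
    ari: float
    paired: PairedPartition

    @property
    def n_subjects(self) -> int:
        return int(self.matrix.sum())

    def per_class_maintained(self) -> dict:
        return {
            c: int(self.matrix[i, i]) for i, c in enumerate(self.classes)
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": [str(c) for c in self.classes],
                "matrix": self.matrix.tolist(),
                "maintained_fraction": self.maintained_fraction,
                "ari": self.ari,
                "n_subjects": self.n_subjects,
            },
            indent=2,
        )


def adjusted_rand_index(pp: PairedPartition) -> float:
    """ARI of the two label vectors of a paired partition."""
    if len(pp.subject_ids) < 2:
        raise ValidationError("ARI needs at least 2 shared subjects")
    return float(adjusted_rand_score(pp.labels_a, pp.labels_b))


def cross_habitat_ari(
    data: Mapping[str, Partition] | Mapping[str, CountTable],
    k_range: Iterable[int] = range(2, 10),
    clusterer: str = "hclust",
    seed: int = 0,
    reselect_k: bool = True,
    fixed_k: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Pairwise ARI between habitats, restricted to shared subjects.

    When count tables are supplied, each habitat is re-clustered on the
    shared-subject subset with the standard pipeline before the ARI is
    computed (k re-selected by the silhouette scan unless ``reselect_k``
    is False and ``fixed_k`` gives a per-habitat k).  When partitions are
    supplied they are compared directly on the shared subjects.  Pairs
    with fewer than two shared subjects are left NaN and logged.
    """
    habitats = list(data)
    if len(habitats) < 2:
        raise ValidationError("need at least 2 habitats")
    table = pd.DataFrame(np.eye(len(habitats)), index=habitats, columns=habitats)
    first = data[habitats[0]]
    tables_mode = isinstance(first, CountTable)
    for i, ha in enumerate(habitats):
        for hb in habitats[i + 1 :]:
            a, b = data[ha], data[hb]
            shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
            if len(shared) < 2:
                logger.warning(
                    "habitat pair (%s, %s): fewer than 2 shared subjects", ha, hb
                )
                table.loc[ha, hb] = table.loc[hb, ha] = np.nan
                continue
            if tables_mode:
                parts = []
                for habitat, tab in ((ha, a), (hb, b)):
                    sub = tab.subset(shared)
                    if reselect_k or fixed_k is None or habitat not in fixed_k:
                        _, part, _, _ = cluster_counts(
                            sub, k_range=k_range, clusterer=clusterer, seed=seed
                        )
                    else:
                        from .clustering import _run_clusterer
                        from .distances import bray_curtis
                        from .tables import to_proportions

                        d = bray_curtis(to_proportions(sub))
                        part = _run_clusterer(clusterer, d, fixed_k[habitat], seed)
                    parts.append(part)
                pp = PairedPartition.from_partitions(*parts)
            else:
                pp = PairedPartition.from_partitions(a, b)
            table.loc[ha, hb] = table.loc[hb, ha] = adjusted_rand_index(pp)
    return table


def stability(
    visit1: CountTable,
    visit2: CountTable,
    k_range: Iterable[int] = range(2, 10),
    clusterer: str = "hclust",
    seed: int = 0,
) -> TransitionSummary:
    """Community-class stability between two visits of the same subjects.

    Samples from both visits are pooled and clustered jointly, subjects
    present at both visits are paired, and switching is summarised as a
    transition matrix, the maintained fraction (its trace over its
    total) and the ARI of the paired labels.  Subjects are matched by
    sample id across the two tables.
    """
    if visit1.taxon_ids != visit2.taxon_ids:
        raise ValidationError("the two visits must share one taxon axis")
    shared = [s for s in visit1.sample_ids if s in set(visit2.sample_ids)]
    if len(shared) < 2:
        raise ValidationError("need at least 2 subjects sampled at both visits")
    pooled = CountTable(
        [f"{s}__v1" for s in visit1.sample_ids]
        + [f"{s}__v2" for s in visit2.sample_ids],
        list(visit1.taxon_ids),
        np.vstack([visit1.counts, visit2.counts]),
    )
    _, part, _, _ = cluster_counts(
        pooled, k_range=k_range, clusterer=clusterer, seed=seed
    )
    label_of = dict(zip(part.sample_ids, part.labels))
    la = np.array([label_of[f"{s}__v1"] for s in shared])
    lb = np.array([label_of[f"{s}__v2"] for s in shared])
    pp = PairedPartition(shared, la, lb)
    classes = sorted(set(la) | set(lb))
    idx = {c: i for i, c in enumerate(classes)}
    matrix = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for x, y in zip(la, lb):
        matrix[idx[x], idx[y]] += 1
    maintained = float(np.trace(matrix)) / matrix.sum()
    return TransitionSummary(classes, matrix, maintained, adjusted_rand_index(pp), pp)
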