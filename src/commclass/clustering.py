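"""Community-class discovery: clustering, silhouette scoring, k selection.

The main recipe: complete-linkage agglomerative clustering of the
Bray-Curtis matrix, scored by the mean silhouette width over a scan of
candidate cluster numbers; the k with the highest mean silhouette wins,
and near-ties (difference below 0.02) are flagged for inspection.  A
refinement pass encodes the published manual-inspection rules: split
internally heterogeneous clusters when the split raises their silhouette,
drop clusters with fewer than two samples and re-cluster, and flag
negative-silhouette samples as outliers.

k-medoids (PAM) and a fuzzy medoid variant are provided as alternative
clusterers that operate directly on the dissimilarity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix, bray_curtis
from .tables import CountTable, ProportionTable, ValidationError, to_proportions

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "SilhouetteProfile",
    "ClusterSelection",
    "CommunityClassSolution",
    "SubsamplingResult",
    "RefinementError",
    "hierarchical_complete",
    "kmedoids",
    "fuzzy_medoids",
    "silhouette",
    "select_k",
    "refine_classes",
    "subsample_stability",
    "cluster_counts",
    "write_solution",
    "read_partition",
]

#: mean-silhouette difference below which two cluster numbers are
#: considered tied and flagged for manual inspection
AMBIGUITY_THRESHOLD = 0.02


@dataclass
class Partition:
    """A hard assignment of every sample to one of k clusters."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        labels = np.asarray(self.labels)
        if labels.shape != (len(self.sample_ids),):
            raise ValidationError("one label per sample required")
        self.labels = labels

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))

    def members(self, label) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    def relabel_consecutive(self) -> "Partition":
        """Map labels to 0..k-1 in order of first appearance."""
        mapping: dict = {}
        new = np.empty(len(self.labels), dtype=np.int64)
        for i, l in enumerate(self.labels):
            if l not in mapping:
                mapping[l] = len(mapping)
            new[i] = mapping[l]
        return Partition(list(self.sample_ids), new)


@dataclass
class SilhouetteProfile:
    """Per-sample silhouette widths s(i) = (b - a) / max(a, b)."""

    sample_ids: list[str]
    s: np.ndarray
    a: np.ndarray
    b: np.ndarray
    cluster_means: dict
    overall: float


@dataclass
class ClusterSelection:
    """Result of scanning k over a range and scoring by mean silhouette."""

    k_range: list[int]
    mean_silhouette: dict[int, float]
    chosen_k: int
    ambiguous: bool
    ambiguous_ks: list[int]
    clusterer: str = "hclust"


@dataclass
class CommunityClassSolution:
    """A refined partition with silhouettes, outliers and dominant taxa."""

    partition: Partition
    profile: SilhouetteProfile
    dominant_taxon: dict
    outliers: list[str]
    refinement_log: list[str] = field(default_factory=list)


@dataclass
class SubsamplingResult:
    """Optimal-k frequencies across random subsamples of increasing size."""

    sizes: list[int]
    replicates: int
    seed: int
    frequencies: pd.DataFrame  # index: size, columns: candidate k, rows sum to 1


class RefinementError(RuntimeError):
    def __init__(self, message: str, log: list[str]):
        super().__init__(message + "\n" + "\n".join(log))
        self.log = log


# ---------------------------------------------------------------------------
# clusterers


def hierarchical_complete(d: DistanceMatrix, k: int) -> Partition:
    """Complete-linkage agglomerative clustering cut to exactly k clusters.

    Complete linkage merges the pair of clusters whose most dissimilar
    members are closest, producing compact clusters.  Ties follow the
    linkage routine's deterministic ordering, so dendrograms reproduce.
    """
    n = d.n_samples
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return Partition(list(d.sample_ids), np.arange(n))
    z = linkage(squareform(d.data, checks=False), method="complete")
    labels = cut_tree(z, n_clusters=k).ravel()
    return Partition(list(d.sample_ids), labels)


def _pam_build(dmat: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD initialisation for PAM: best single medoid, then the
    point whose addition most reduces total dissimilarity."""
    n = dmat.shape[0]
    medoids = [int(np.argmin(dmat.sum(axis=1)))]
    nearest = dmat[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[np.newaxis, :] - dmat.T, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, dmat[:, best])
    return np.array(sorted(medoids))


def _pam_swap(dmat: np.ndarray, medoids: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """PAM swap phase: best-improvement swaps until a local optimum."""
    medoids = np.array(sorted(medoids))
    n = dmat.shape[0]
    for _ in range(max_iter):
        dm = dmat[:, medoids]  # (n, k)
        order = np.argsort(dm, axis=1, kind="stable")
        d1 = dm[np.arange(n), order[:, 0]]
        d2 = dm[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        nearest = order[:, 0]
        best_delta = -1e-12
        best_swap = None
        for j in range(len(medoids)):
            affected = nearest == j
            # cost with medoid j replaced by candidate h, for all h at once
            base = np.where(affected[:, None], np.minimum(d2[:, None], dmat),
                            np.minimum(d1[:, None], dmat))
            costs = base.sum(axis=0)
            costs[medoids] = np.inf
            h = int(np.argmin(costs))
            delta = costs[h] - d1.sum()
            if delta < best_delta:
                best_delta = delta
                best_swap = (j, h)
        if best_swap is None:
            break
        j, h = best_swap
        medoids = medoids.copy()
        medoids[j] = h
        medoids = np.array(sorted(medoids))
    return medoids


def kmedoids(d: DistanceMatrix, k: int, restarts: int = 10, seed: int = 0) -> Partition:
    """Partitioning-around-medoids minimising total dissimilarity to medoids.

    The first restart uses the greedy BUILD initialisation; further
    restarts start from random medoid sets.  The best local optimum over
    all restarts is returned; deterministic given the seed.
    """
    n = d.n_samples
    if not 2 <= k < n:
        raise ValidationError(f"k must be in [2, {n - 1}], got {k}")
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    dmat = d.data
    best_cost = np.inf
    best_medoids = None
    for r in range(restarts):
        init = _pam_build(dmat, k) if r == 0 else np.sort(
            rng.choice(n, size=k, replace=False)
        )
        medoids = _pam_swap(dmat, init)
        cost = dmat[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_medoids = medoids
    labels = np.argmin(dmat[:, best_medoids], axis=1)
    return Partition(list(d.sample_ids), labels)


def _fuzzy_memberships(
    dm: np.ndarray, membership_exponent: float
) -> np.ndarray:
    """Memberships u_ij proportional to d(i, m_j)^(-1/(m-1)); rows sum to 1."""
    n, k = dm.shape
    zero = dm <= 1e-15
    u = np.zeros((n, k))
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = np.where(dm > 0, dm, np.inf) ** (-1.0 / (membership_exponent - 1.0))
    u[~any_zero] = w[~any_zero] / w[~any_zero].sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return u


def fuzzy_medoids(
    d: DistanceMatrix,
    k: int,
    membership_exponent: float = 2.0,
    seed: int = 0,
    restarts: int = 5,
    max_iter: int = 200,
) -> tuple[Partition, np.ndarray]:
    """Fuzzy clustering on the dissimilarity matrix with medoid prototypes.

    Memberships follow the usual fuzzy rule u_ij proportional to
    d(i, m_j)^(-1/(m-1)); each medoid is then moved to the point
    minimising the membership-weighted dissimilarity to its cluster.
    The first restart starts from the greedy medoid build, further ones
    from random medoid sets; the restart with the lowest fuzzy objective
    wins.  Hard labels are the argmax memberships.  Returns (partition,
    memberships) where membership rows sum to 1.
    """
    n = d.n_samples
    if not 2 <= k < n:
        raise ValidationError(f"k must be in [2, {n - 1}], got {k}")
    if not membership_exponent > 1:
        raise ValidationError("membership exponent must be > 1")
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    dmat = d.data
    if np.allclose(dmat, 0):
        raise ValidationError("degenerate distance matrix: all dissimilarities zero")
    rng = np.random.default_rng(seed)
    best_obj = np.inf
    best_u = None
    for r in range(restarts):
        medoids = (
            _pam_build(dmat, k)
            if r == 0
            else np.sort(rng.choice(n, size=k, replace=False))
        )
        u = _fuzzy_memberships(dmat[:, medoids], membership_exponent)
        for _ in range(max_iter):
            u = _fuzzy_memberships(dmat[:, medoids], membership_exponent)
            weights = u**membership_exponent
            new_medoids = np.sort(
                np.array([int(np.argmin(dmat @ weights[:, j])) for j in range(k)])
            )
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        obj = float((u**membership_exponent * dmat[:, medoids]).sum())
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_u = u
    labels = np.argmax(best_u, axis=1)
    return Partition(list(d.sample_ids), labels), best_u


_CLUSTERERS = {"hclust", "kmedoids", "fuzzy"}


def _run_clusterer(name: str, d: DistanceMatrix, k: int, seed: int = 0) -> Partition:
    if name == "hclust":
        return hierarchical_complete(d, k)
    if name == "kmedoids":
        return kmedoids(d, k, seed=seed)
    if name == "fuzzy":
        return fuzzy_medoids(d, k, seed=seed)[0]
    raise ValidationError(f"unknown clusterer {name!r}; choose from {_CLUSTERERS}")


# ---------------------------------------------------------------------------
# silhouette and k selection


def silhouette(d: DistanceMatrix, p: Partition) -> SilhouetteProfile:
    """Silhouette widths of a partition against its dissimilarity matrix.

    a(i) is the mean dissimilarity of i to the other members of its
    cluster; b(i) the mean dissimilarity to the nearest other cluster;
    s(i) = (b - a)/max(a, b).  Members of singleton clusters get s = 0.
    """
    if p.k < 2:
        raise ValidationError("silhouette is undefined for fewer than 2 clusters")
    if list(p.sample_ids) != list(d.sample_ids):
        raise ValidationError("partition and distance matrix sample ids differ")
    labels = p.relabel_consecutive().labels
    k = labels.max() + 1
    n = d.n_samples
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    sizes = onehot.sum(axis=0)
    sums = d.data @ onehot  # (n, k): total distance from i to each cluster
    own = labels
    a = np.zeros(n)
    nonsingleton = sizes[own] > 1
    a[nonsingleton] = sums[np.arange(n), own][nonsingleton] / (
        sizes[own][nonsingleton] - 1
    )
    mean_to = sums / sizes[np.newaxis, :]
    mean_to[np.arange(n), own] = np.inf
    b = mean_to.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    s[~nonsingleton] = 0.0
    cluster_means = {}
    for orig in np.unique(p.labels):
        mask = p.labels == orig
        cluster_means[orig] = float(s[mask].mean())
    return SilhouetteProfile(
        list(p.sample_ids), s, a, b, cluster_means, float(s.mean())
    )


def select_k(
    d: DistanceMatrix,
    k_range: Iterable[int] = range(2, 10),
    clusterer: str = "hclust",
    seed: int = 0,
) -> ClusterSelection:
    """Scan candidate cluster numbers and pick the silhouette maximiser.

    The chosen k maximises the overall mean silhouette width (smallest k
    wins ties).  If any competitor lies within 0.02 of the best value the
    selection is flagged ambiguous, mirroring the manual-inspection rule.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = d.n_samples
    ks = [k for k in ks if 2 <= k <= n - 1]
    if not ks:
        raise ValidationError("k_range contains no feasible candidate in [2, n-1]")
    means: dict[int, float] = {}
    for k in ks:
        part = _run_clusterer(clusterer, d, k, seed=seed)
        if part.k < 2:
            means[k] = -1.0
            continue
        means[k] = silhouette(d, part).overall
    chosen = max(ks, key=lambda k: (means[k], -k))
    best = means[chosen]
    ambiguous_ks = [k for k in ks if best - means[k] < AMBIGUITY_THRESHOLD]
    ambiguous = len(ambiguous_ks) > 1
    return ClusterSelection(ks, means, chosen, ambiguous, ambiguous_ks, clusterer)


# ---------------------------------------------------------------------------
# refinement (the manual-inspection rules, made explicit)


def _dominant_taxa(part: Partition, abundance: ProportionTable) -> dict:
    sub = abundance.subset(list(part.sample_ids))
    out = {}
    for label in np.unique(part.labels):
        mask = part.labels == label
        medians = np.median(sub.proportions[mask], axis=0)
        out[label] = sub.taxon_ids[int(np.argmax(medians))]
    return out


def refine_classes(
    d: DistanceMatrix,
    sel: ClusterSelection,
    abundance: ProportionTable,
    high_threshold: float = 0.4,
    split_threshold: float = 0.2,
    max_iterations: int = 10,
    seed: int = 0,
) -> CommunityClassSolution:
    """Refine a selected clustering by the two inspection rules.

    (a) a cluster whose mean silhouette falls below ``split_threshold``
    while some other cluster is high (>= ``high_threshold``) is
    re-clustered at k=2; the split is kept when the better of the two
    sub-clusters improves on the original cluster mean.  (b) clusters
    with fewer than two samples are removed and the remainder is
    re-clustered with the same k-selection procedure.  Samples with
    negative silhouette in the final solution are flagged as outliers.
    Every action is appended to the refinement log.
    """
    log: list[str] = []
    clusterer = sel.clusterer
    current_d = d
    part = _run_clusterer(clusterer, current_d, sel.chosen_k, seed=seed)
    no_split: set = set()
    next_label = int(np.max(part.relabel_consecutive().labels)) + 1
    part = part.relabel_consecutive()
    for iteration in range(max_iterations):
        prof = silhouette(current_d, part)
        sizes = {l: int((part.labels == l).sum()) for l in np.unique(part.labels)}
        # rule (b): drop clusters with fewer than two samples, redo clustering
        small = [l for l, sz in sizes.items() if sz < 2]
        if small and part.k - len(small) >= 2:
            removed = [s for s, l in zip(part.sample_ids, part.labels) if l in small]
            keep = [s for s in part.sample_ids if s not in set(removed)]
            log.append(
                f"iteration {iteration}: removed {len(small)} cluster(s) with <2 "
                f"samples ({', '.join(removed)}); re-clustering {len(keep)} samples"
            )
            current_d = current_d.submatrix(keep)
            resel = select_k(current_d, sel.k_range, clusterer=clusterer, seed=seed)
            part = _run_clusterer(
                clusterer, current_d, resel.chosen_k, seed=seed
            ).relabel_consecutive()
            no_split.clear()
            next_label = part.k
            continue
        # rule (a): split a heterogeneous cluster when another is tight
        means = prof.cluster_means
        high = max(means.values())
        candidates = [
            l
            for l, m in sorted(means.items(), key=lambda kv: kv[1])
            if m < split_threshold
            and high >= high_threshold
            and sizes[l] >= 4
            and l not in no_split
        ]
        if candidates:
            target = candidates[0]
            members = part.members(target)
            sub_d = current_d.submatrix(members)
            sub_part = _run_clusterer(clusterer, sub_d, 2, seed=seed)
            trial = np.array(part.labels, dtype=np.int64)
            member_pos = {s: i for i, s in enumerate(part.sample_ids)}
            for s, sl in zip(sub_part.sample_ids, sub_part.labels):
                if sl == 1:
                    trial[member_pos[s]] = next_label
            trial_part = Partition(list(part.sample_ids), trial)
            if trial_part.k > part.k:
                trial_prof = silhouette(current_d, trial_part)
                new_means = [
                    trial_prof.cluster_means[target],
                    trial_prof.cluster_means[next_label],
                ]
                if max(new_means) > means[target] + 1e-12:
                    log.append(
                        f"iteration {iteration}: split cluster {target} "
                        f"(mean s = {means[target]:.3f}, n = {sizes[target]}) into "
                        f"two (mean s = {new_means[0]:.3f}, {new_means[1]:.3f})"
                    )
                    part = trial_part
                    next_label += 1
                    continue
            no_split.add(target)
            log.append(
                f"iteration {iteration}: rejected split of cluster {target} "
                f"(no silhouette improvement)"
            )
            continue
        break
    else:
        raise RefinementError(
            f"refinement did not converge in {max_iterations} iterations", log
        )
    prof = silhouette(current_d, part)
    outliers = [s for s, si in zip(part.sample_ids, prof.s) if si < 0]
    if outliers:
        log.append(f"flagged {len(outliers)} outlier(s) with negative silhouette")
    dominant = _dominant_taxa(part, abundance)
    return CommunityClassSolution(part, prof, dominant, outliers, log)


# ---------------------------------------------------------------------------
# pipeline helpers


def cluster_counts(
    table: CountTable,
    k_range: Iterable[int] = range(2, 10),
    clusterer: str = "hclust",
    seed: int = 0,
    copy_numbers=None,
    metric: str = "bray-curtis",
) -> tuple[ClusterSelection, Partition, SilhouetteProfile, DistanceMatrix]:
    """Counts -> (scaled) proportions -> distances -> silhouette k scan.

    The standard end-to-end clustering path used by the subsampling,
    cross-habitat and longitudinal analyses.
    """
    from .tables import scale_by_copy_number

    if copy_numbers is not None:
        props = to_proportions(scale_by_copy_number(table, copy_numbers))
    else:
        props = to_proportions(table)
    if metric == "bray-curtis":
        d = bray_curtis(props)
    elif metric in {"jsd", "root-jsd", "jensen-shannon"}:
        from .distances import jensen_shannon

        d = jensen_shannon(props)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    sel = select_k(d, k_range, clusterer=clusterer, seed=seed)
    part = _run_clusterer(clusterer, d, sel.chosen_k, seed=seed)
    prof = silhouette(d, part)
    return sel, part, prof, d


def subsample_stability(
    source: CountTable,
    sizes: Sequence[int],
    replicates: int,
    k_candidates: Iterable[int] = range(2, 6),
    seed: int = 0,
    clusterer: str = "hclust",
) -> SubsamplingResult:
    """How often each candidate k wins as samples are subsampled.

    Per replicate, draws the requested number of samples without
    replacement, runs the standard pipeline (proportions, Bray-Curtis,
    silhouette k scan) and records the winning k.  Frequencies per size
    sum to 1.
    """
    n = source.n_samples
    for size in sizes:
        if size > n:
            raise ValidationError(f"subsample size {size} exceeds {n} samples")
        if size < 3:
            raise ValidationError("subsample size must allow k >= 2 (size >= 3)")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ks = sorted(set(int(k) for k in k_candidates))
    counts = pd.DataFrame(0, index=list(sizes), columns=ks, dtype=float)
    for size in sizes:
        for _ in range(replicates):
            idx = rng.choice(n, size=size, replace=False)
            sub = source.subset([source.sample_ids[i] for i in sorted(idx)])
            sel, _, _, _ = cluster_counts(
                sub, k_range=ks, clusterer=clusterer, seed=seed
            )
            counts.loc[size, sel.chosen_k] += 1
    freqs = counts.div(counts.sum(axis=1), axis=0)
    return SubsamplingResult(list(sizes), replicates, seed, freqs)


# ---------------------------------------------------------------------------
# result IO


def write_solution(
    path, part: Partition, prof: SilhouetteProfile | None = None
) -> None:
    """Write (sample_id, label[, silhouette]) as tab-delimited text."""
    df = pd.DataFrame({"sample_id": part.sample_ids, "label": part.labels})
    if prof is not None:
        df["silhouette"] = prof.s
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_partition(path) -> Partition:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df or "label" not in df:
        raise ValidationError(f"{path}: expected columns sample_id and label")
    return Partition(list(df["sample_id"].astype(str)), df["label"].to_numpy())
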