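import numpy as np
import pytest

from commclass import (
    CountTable,
    DistanceMatrix,
    Partition,
    ValidationError,
    bray_curtis,
    fuzzy_medoids,
    hierarchical_complete,
    kmedoids,
    refine_classes,
    select_k,
    silhouette,
    subsample_stability,
    to_proportions,
)
from commclass.clustering import RefinementError
from commclass import synthetic

from conftest import random_distance


def brute_force_silhouette(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Double-loop silhouette oracle; singleton clusters get 0."""
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s


def naive_complete_linkage(d: np.ndarray, k: int) -> list[frozenset]:
    """O(n^3) merge replay: always merge the pair of clusters whose most
    dissimilar members are closest."""
    clusters = [frozenset([i]) for i in range(len(d))]
    while len(clusters) > k:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if dist < best[0] - 1e-15:
                    best = (dist, (i, j))
        i, j = best[1]
        merged = clusters[i] | clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return clusters


def as_sets(p: Partition) -> set[frozenset]:
    return {
        frozenset(i for i, l in enumerate(p.labels) if l == lab)
        for lab in set(p.labels)
    }


class TestHierarchicalComplete:
    def test_k_equals_n_gives_singletons(self, two_block_distance):
        p = hierarchical_complete(two_block_distance, 10)
        assert p.k == 10

    def test_k_one_gives_single_cluster(self, two_block_distance):
        p = hierarchical_complete(two_block_distance, 1)
        assert p.k == 1

    def test_recovers_two_blocks(self, two_block_distance):
        p = hierarchical_complete(two_block_distance, 2)
        assert as_sets(p) == {frozenset(range(5)), frozenset(range(5, 10))}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_merge_replay(self, seed):
        d = random_distance(np.random.default_rng(seed), 15)
        for k in (2, 3, 5, 8):
            ours = as_sets(hierarchical_complete(d, k))
            oracle = {frozenset(c) for c in naive_complete_linkage(d.data, k)}
            assert ours == oracle

    def test_merge_heights_non_decreasing(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        d = random_distance(np.random.default_rng(8), 20)
        z = linkage(squareform(d.data, checks=False), method="complete")
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_k_out_of_range(self, two_block_distance):
        with pytest.raises(ValidationError):
            hierarchical_complete(two_block_distance, 11)


class TestSilhouette:
    def test_hand_computed_two_pairs(self):
        d = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.1],
                [1.0, 1.0, 0.1, 0.0],
            ]
        )
        dm = DistanceMatrix(list("ABCD"), d)
        prof = silhouette(dm, Partition(list("ABCD"), np.array([0, 0, 1, 1])))
        assert np.allclose(prof.s, 0.9)
        assert prof.overall == pytest.approx(0.9)

    def test_equidistant_point_scores_zero(self):
        # E is at distance 0.5 from both tight pairs: a(E) == b(E)
        ids = list("ABCDE")
        d = np.zeros((5, 5))
        d[:2, :2] = 0.1; d[2:4, 2:4] = 0.1
        d[:2, 2:4] = d[2:4, :2] = 1.0
        d[4, :2] = d[:2, 4] = 0.5
        d[4, 2:4] = d[2:4, 4] = 0.5
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(ids, d)
        prof = silhouette(dm, Partition(ids, np.array([0, 0, 1, 1, 0])))
        assert prof.s[4] == pytest.approx(0.0, abs=1e-12)

    def test_misplaced_point_scores_negative(self, two_block_distance):
        labels = np.array([0] * 5 + [1] * 5)
        labels[0] = 1  # first sample placed in the wrong block
        prof = silhouette(two_block_distance, Partition(two_block_distance.sample_ids, labels))
        assert prof.s[0] < 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        d = random_distance(rng, n)
        labels = rng.integers(0, 4, size=n)
        while len(set(labels)) < 2:
            labels = rng.integers(0, 4, size=n)
        prof = silhouette(d, Partition(d.sample_ids, labels))
        assert np.allclose(prof.s, brute_force_silhouette(d.data, labels), atol=1e-12)
        assert prof.overall == pytest.approx(prof.s.mean())
        assert (prof.s >= -1).all() and (prof.s <= 1).all()

    def test_single_cluster_rejected(self, two_block_distance):
        with pytest.raises(ValidationError):
            silhouette(
                two_block_distance,
                Partition(two_block_distance.sample_ids, np.zeros(10, dtype=int)),
            )


class TestKMedoids:
    def test_recovers_blocks(self, two_block_distance):
        p = kmedoids(two_block_distance, 2, seed=0)
        assert as_sets(p) == {frozenset(range(5)), frozenset(range(5, 10))}

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_matches_brute_force_medoid_enumeration(self, seed):
        from itertools import combinations

        d = random_distance(np.random.default_rng(seed + 40), 12)
        p = kmedoids(d, 2, restarts=10, seed=seed)
        # our cost: sum over samples of distance to its cluster's best medoid
        best = min(
            d.data[:, list(pair)].min(axis=1).sum()
            for pair in combinations(range(12), 2)
        )
        labels = p.labels
        cost = 0.0
        for lab in set(labels):
            idx = np.where(labels == lab)[0]
            cost += min(d.data[np.ix_(idx, [m])].sum() for m in idx)
        assert cost == pytest.approx(best, abs=1e-9)

    def test_deterministic(self, two_block_distance):
        a = kmedoids(two_block_distance, 2, restarts=5, seed=3)
        b = kmedoids(two_block_distance, 2, restarts=5, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_k_out_of_range(self, two_block_distance):
        with pytest.raises(ValidationError):
            kmedoids(two_block_distance, 10)


class TestFuzzyMedoids:
    def test_recovers_blocks_and_memberships_normalised(self, two_block_distance):
        p, u = fuzzy_medoids(two_block_distance, 2, seed=0)
        assert as_sets(p) == {frozenset(range(5)), frozenset(range(5, 10))}
        assert np.allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic(self, two_block_distance):
        a, ua = fuzzy_medoids(two_block_distance, 2, seed=5)
        b, ub = fuzzy_medoids(two_block_distance, 2, seed=5)
        assert np.array_equal(a.labels, b.labels) and np.allclose(ua, ub)

    def test_degenerate_distances_rejected(self):
        d = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.raises(ValidationError, match="degenerate"):
            fuzzy_medoids(d, 2)

    def test_agrees_with_hierarchical_on_separated_classes(self):
        from sklearn.metrics import adjusted_rand_score

        spec = synthetic.well_separated(seed=2, n_subjects=60)
        t, _ = synthetic.simulate_habitat(spec)
        d = bray_curtis(to_proportions(t))
        ph = hierarchical_complete(d, 3)
        pf, _ = fuzzy_medoids(d, 3, seed=2)
        assert adjusted_rand_score(ph.labels, pf.labels) == pytest.approx(1.0)


class TestSelectK:
    def test_single_candidate(self, two_block_distance):
        sel = select_k(two_block_distance, [2])
        assert sel.chosen_k == 2 and not sel.ambiguous

    def test_equidistant_configuration_flags_ambiguity(self):
        n = 9
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        sel = select_k(DistanceMatrix([f"s{i}" for i in range(n)], d), range(2, 6))
        assert sel.ambiguous
        assert set(sel.ambiguous_ks) == {2, 3, 4, 5}

    def test_chosen_k_is_argmax_of_reported_scan(self, two_block_distance):
        sel = select_k(two_block_distance, range(2, 6))
        assert sel.chosen_k == max(sel.mean_silhouette, key=sel.mean_silhouette.get)
        assert sel.chosen_k == 2

    def test_recovers_planted_k_on_separated_classes(self):
        hits = 0
        for seed in range(10):
            spec = synthetic.well_separated(seed=seed, n_subjects=60)
            t, _ = synthetic.simulate_habitat(spec)
            sel = select_k(bray_curtis(to_proportions(t)), range(2, 8))
            hits += sel.chosen_k == 3 and not sel.ambiguous
        assert hits >= 9

    def test_empty_range_rejected(self, two_block_distance):
        with pytest.raises(ValidationError):
            select_k(two_block_distance, [])


class TestRefineClasses:
    def test_good_solution_is_fixed_point(self, two_block_distance):
        sel = select_k(two_block_distance, range(2, 5))
        props = to_proportions(
            CountTable(
                two_block_distance.sample_ids,
                ["gA", "gB"],
                np.array([[9, 1]] * 5 + [[1, 9]] * 5),
            )
        )
        sol = refine_classes(two_block_distance, sel, props)
        assert sol.partition.k == 2
        assert sol.refinement_log == [] or all(
            "outlier" in line for line in sol.refinement_log
        )
        assert sol.dominant_taxon in (
            {0: "gA", 1: "gB"},
            {0: "gB", 1: "gA"},
        )

    def test_singleton_cluster_removed_and_logged(self):
        # two blocks of 5 plus one far-away singleton
        n = 11
        d = np.full((n, n), 0.9)
        d[:5, :5] = 0.1
        d[5:10, 5:10] = 0.1
        d[10, :] = d[:, 10] = 2.0
        np.fill_diagonal(d, 0.0)
        d = d / d.max()
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
        sel = select_k(dm, range(2, 5))
        counts = np.array([[9, 1]] * 5 + [[1, 9]] * 5 + [[5, 5]])
        props = to_proportions(
            CountTable(dm.sample_ids, ["gA", "gB"], counts)
        )
        sol = refine_classes(dm, sel, props)
        assert "s10" not in sol.partition.sample_ids
        assert any("<2" in line for line in sol.refinement_log)
        assert sol.partition.k == 2

    def test_splits_heterogeneous_cluster_with_planted_small_classes(self):
        # one big tight class plus two small tight classes that hierarchical
        # clustering at the selected k may leave merged
        from sklearn.metrics import adjusted_rand_score

        ok = 0
        for seed in range(10):
            spec = synthetic.SyntheticSpec(
                n_subjects=80,
                classes=[("Propionibacterium", 0.7), ("Staphylococcus", 0.15),
                         ("Corynebacterium", 0.15)],
                dominance=400.0,
                base_concentration=0.08,
                seed=seed,
            )
            t, truth = synthetic.simulate_habitat(spec)
            props = to_proportions(t)
            d = bray_curtis(props)
            sel = select_k(d, range(2, 8))
            sol = refine_classes(d, sel, props)
            keep = [t.sample_ids.index(s) for s in sol.partition.sample_ids]
            ari = adjusted_rand_score(truth[keep], sol.partition.labels)
            ok += ari >= 0.9
        assert ok >= 8

    def test_nonconvergence_raises_with_log(self, two_block_distance):
        sel = select_k(two_block_distance, range(2, 5))
        props = to_proportions(
            CountTable(
                two_block_distance.sample_ids,
                ["gA", "gB"],
                np.array([[9, 1]] * 5 + [[1, 9]] * 5),
            )
        )
        with pytest.raises(RefinementError):
            refine_classes(
                two_block_distance, sel, props, max_iterations=0
            )


class TestSubsampleStability:
    def test_frequencies_sum_to_one_and_one_hot_for_single_replicate(self):
        spec = synthetic.well_separated(seed=0, n_subjects=50)
        t, _ = synthetic.simulate_habitat(spec)
        res = subsample_stability(t, sizes=[20, 30], replicates=1, k_candidates=range(2, 5), seed=0)
        assert np.allclose(res.frequencies.sum(axis=1), 1.0)
        assert ((res.frequencies == 0) | (res.frequencies == 1)).all().all()

    def test_oversized_subsample_rejected(self, small_counts):
        with pytest.raises(ValidationError):
            subsample_stability(small_counts, sizes=[10], replicates=1)
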