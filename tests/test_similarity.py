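"""Performance profiles, classical MDS, complete linkage, k-selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from microcyte.metrics import ConfusionMatrix, metric_set
from microcyte.similarity import (
    PROFILE_MEASURES,
    classical_mds,
    complete_linkage,
    profile_matrix,
    select_k_majority,
)


def brute_force_complete_linkage(d: np.ndarray):
    """Independent oracle: naive agglomeration recomputing max distances."""
    clusters = [[i] for i in range(len(d))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        merges.append((sorted(map(tuple, (clusters[i], clusters[j]))), dist))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def random_profiles(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, len(PROFILE_MEASURES))),
        index=[f"m{i}" for i in range(n)],
        columns=list(PROFILE_MEASURES),
    )


class TestProfileMatrix:
    def _metric_sets(self):
        cms = {
            "a": ConfusionMatrix(668, 60, 40, 410),
            "a2": ConfusionMatrix(668, 60, 40, 410),
            "b": ConfusionMatrix(300, 200, 408, 270),
        }
        return {k: metric_set(cm) for k, cm in cms.items()}

    def test_identical_methods_distance_zero(self):
        _, dist = profile_matrix(self._metric_sets())
        assert dist.loc["a", "a2"] == pytest.approx(0.0)

    def test_symmetric_zero_diagonal(self):
        _, dist = profile_matrix(self._metric_sets())
        d = dist.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_hand_computed_distances(self):
        raw = random_profiles(3, seed=5)
        profile, dist = profile_matrix(raw)
        z = (raw - raw.mean()) / raw.std(ddof=0)
        expected = squareform(pdist(z.to_numpy()))
        assert np.allclose(dist.to_numpy(), expected)

    def test_infinite_entry_errors_without_cap(self):
        raw = random_profiles(4)
        raw.iloc[0, raw.columns.get_loc("plr")] = np.inf
        with pytest.raises(ValueError, match="plr"):
            profile_matrix(raw)
        profile, _ = profile_matrix(raw, cap_percentile=95)
        assert np.isfinite(profile.to_numpy()).all()

    def test_too_few_methods(self):
        with pytest.raises(ValueError):
            profile_matrix(random_profiles(2))


class TestClassicalMds:
    def test_right_triangle_exact(self):
        d = np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], dtype=float)
        mm = classical_mds(d, k=2)
        embedded = sorted(pdist(mm.coords.to_numpy()))
        assert embedded == pytest.approx([3.0, 4.0, 5.0], abs=1e-9)
        assert np.allclose(mm.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(2)
        config = rng.normal(size=(15, 2))
        d = squareform(pdist(config))
        mm = classical_mds(d, k=2)
        assert np.allclose(
            squareform(pdist(mm.coords.to_numpy())), d, atol=1e-8
        )
        assert mm.strain == pytest.approx(0.0, abs=1e-12)

    def test_equilateral_symmetry(self):
        d = np.ones((3, 3)) - np.eye(3)
        mm = classical_mds(d, k=2)
        assert mm.eigenvalues[0] == pytest.approx(mm.eigenvalues[1])
        assert pdist(mm.coords.to_numpy()) == pytest.approx([1.0, 1.0, 1.0])

    def test_rank_deficit_warns(self):
        d = squareform(pdist(np.arange(4, dtype=float)[:, None]))  # 1-D input
        with pytest.warns(UserWarning, match="dimension"):
            mm = classical_mds(d, k=2)
        assert mm.coords.shape[1] == 1

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(9)
        config = rng.normal(size=(10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = config @ rot + np.array([5.0, -3.0])
        d1 = squareform(pdist(config))
        d2 = squareform(pdist(moved))
        e1 = pdist(classical_mds(d1).coords.to_numpy())
        e2 = pdist(classical_mds(d2).coords.to_numpy())
        assert np.allclose(e1, e2, atol=1e-8)

    def test_invalid_matrix_errors(self):
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestCompleteLinkage:
    def test_well_separated_pairs(self):
        points = np.array([[0.0], [0.1], [10.0], [10.1]])
        d = squareform(pdist(points))
        dendro = complete_linkage(d)
        assert len(dendro.heights) == 3
        assert dendro.heights[0] == pytest.approx(0.1)
        assert dendro.heights[-1] == pytest.approx(10.1)
        assert set(dendro.cut_k(2).values()) == {1, 2}

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        d = squareform(pdist(rng.normal(size=(n, 3))))
        dendro = complete_linkage(d)
        oracle = brute_force_complete_linkage(d)
        assert np.allclose(dendro.heights, [h for _, h in oracle])

    def test_heights_monotone(self):
        rng = np.random.default_rng(12)
        d = squareform(pdist(rng.normal(size=(20, 4))))
        heights = complete_linkage(d).heights
        assert np.all(np.diff(heights) >= -1e-12)

    def test_cut_extremes(self):
        rng = np.random.default_rng(4)
        d = squareform(pdist(rng.normal(size=(7, 3))))
        dendro = complete_linkage(d)
        assert len(set(dendro.cut_height(np.inf).values())) == 1
        assert len(set(dendro.cut_height(0.0).values())) == 7

    def test_newick_round_trip(self):
        import skbio

        rng = np.random.default_rng(5)
        labels = [f"m{i}" for i in range(6)]
        d = pd.DataFrame(
            squareform(pdist(rng.normal(size=(6, 2)))), index=labels, columns=labels
        )
        tree = skbio.TreeNode.read([complete_linkage(d).to_newick()])
        assert sorted(tip.name for tip in tree.tips()) == labels

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        profiles = random_profiles(12, seed=8)
        _, dist = profile_matrix(profiles)
        perm = rng.permutation(12)
        shuffled = profiles.iloc[perm]
        _, dist_perm = profile_matrix(shuffled)
        sel = select_k_majority(profiles, dist)
        sel_perm = select_k_majority(shuffled, dist_perm)
        assert sel.k == sel_perm.k
        clusters = complete_linkage(dist).cut_k(sel.k)
        clusters_perm = complete_linkage(dist_perm).cut_k(sel.k)
        # same partition (cluster ids may be renumbered)
        def canon(assign):
            groups = {}
            for name, cid in assign.items():
                groups.setdefault(cid, set()).add(name)
            return {frozenset(v) for v in groups.values()}
        assert canon(clusters) == canon(clusters_perm)


class TestSelectK:
    def test_three_separated_clusters_recovered(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(0, 1, (3, 10)) * 3
        rows = np.vstack([c + rng.normal(0, 0.15, (12, 10)) for c in centers])
        profiles = pd.DataFrame(
            rows, index=[f"m{i}" for i in range(36)],
            columns=list(PROFILE_MEASURES),
        )
        sel = select_k_majority(profiles)
        assert sel.k == 3
        assert not sel.weak_evidence

    def test_single_blob_returns_minimum_k(self):
        rng = np.random.default_rng(1)
        profiles = pd.DataFrame(
            rng.normal(0, 0.1, (20, 10)),
            index=[f"b{i}" for i in range(20)],
            columns=list(PROFILE_MEASURES),
        )
        sel = select_k_majority(profiles)
        # hierarchical cutting cannot return k=1; for a homogeneous cloud any
        # partition is arbitrary, so the vote lands somewhere in the candidate
        # range and the tally/scores expose how arbitrary it is
        assert 2 <= sel.k <= 8
        assert sel.scores.shape == (5, 7)

    def test_candidate_range_truncated_for_few_methods(self):
        sel = select_k_majority(random_profiles(5, seed=3))
        assert sel.k <= 4

    def test_too_few_indices_rejected(self):
        with pytest.raises(ValueError):
            select_k_majority(
                random_profiles(10), validity_indices=("silhouette", "dunn")
            )


class TestMajorityVote:
    def test_tie_goes_to_smallest_k(self):
        from microcyte.similarity import majority_vote
        winner, tally, weak = majority_vote({"a": 3, "b": 2, "c": 2, "d": 3})
        assert winner == 2
        assert tally == {2: 2, 3: 2}
        assert weak

    def test_clear_majority_not_weak(self):
        from microcyte.similarity import majority_vote
        winner, _, weak = majority_vote({"a": 3, "b": 3, "c": 3, "d": 2, "e": 3})
        assert winner == 3
        assert not weak
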