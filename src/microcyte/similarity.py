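"""Method-similarity meta-analysis: which discrimination methods behave alike?

Every method (index, rule set, tree) is summarised by a ten-measure
performance profile — sensitivity, specificity, PPV, NPV, Youden, accuracy,
PLR, NLR, F-measure, AUC — the profiles are z-standardized column-wise so
the unbounded likelihood ratios cannot dominate, and pairwise Euclidean
distances feed two complementary views:

* classical (Torgerson) multidimensional scaling — double-centred squared
  distances, eigendecomposition, top-2 coordinates — giving a planar map in
  which nearby methods perform alike;
* complete-linkage agglomerative clustering, whose monotone dendrogram is
  cut at the number of groups chosen by a majority vote of internal validity
  indices (Calinski-Harabasz, silhouette, Dunn, Davies-Bouldin, C-index).

The DOR is deliberately absent from the profile: it is the one measure that
reaches +inf for ordinary classifiers, and it is fully determined by PLR and
NLR anyway.  A percentile capping rule is available for user-supplied
profiles that still contain infinities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .metrics import MetricSet

__all__ = [
    "PROFILE_MEASURES",
    "profile_matrix",
    "classical_mds",
    "MethodMap",
    "complete_linkage",
    "Dendrogram",
    "select_k_majority",
    "KSelection",
]

PROFILE_MEASURES = (
    "sensitivity", "specificity", "ppv", "npv", "youden",
    "accuracy", "plr", "nlr", "f_measure", "auc",
)


def profile_matrix(
    metric_sets: Mapping[str, MetricSet] | pd.DataFrame,
    standardize: bool = True,
    cap_percentile: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the (methods x 10 measures) profile matrix and its Euclidean
    distance matrix.

    ``cap_percentile`` (e.g. 99) replaces infinite entries by that percentile
    of the finite values in the same column; without it, infinities are an
    error.  Columns with zero variance standardize to zeros.
    """
    if isinstance(metric_sets, pd.DataFrame):
        raw = metric_sets.loc[:, list(PROFILE_MEASURES)].astype(float).copy()
    else:
        raw = pd.DataFrame(
            {name: [getattr(ms, m) for m in PROFILE_MEASURES]
             for name, ms in metric_sets.items()},
            index=list(PROFILE_MEASURES),
        ).T
    if len(raw) < 3:
        raise ValueError("need at least 3 methods")
    values = raw.to_numpy()
    if not np.isfinite(values).all():
        if cap_percentile is None:
            bad = raw.columns[~np.isfinite(values).all(axis=0)].tolist()
            raise ValueError(
                f"non-finite profile entries in {bad}; enable cap_percentile "
                "or exclude the offending measure"
            )
        for j in range(values.shape[1]):
            col = values[:, j]
            finite = col[np.isfinite(col)]
            if len(finite) == 0:
                raise ValueError(f"column {raw.columns[j]} has no finite values")
            cap = np.percentile(finite, cap_percentile)
            col[np.isposinf(col)] = cap
            col[np.isneginf(col)] = finite.min()
            col[np.isnan(col)] = np.median(finite)
        raw = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    if standardize:
        mean = raw.mean(axis=0)
        std = raw.std(axis=0, ddof=0)
        std = std.where(std > 0, 1.0)
        profile = (raw - mean) / std
    else:
        profile = raw
    dist = pd.DataFrame(
        squareform(pdist(profile.to_numpy())),
        index=profile.index,
        columns=profile.index,
    )
    return profile, dist


@dataclass
class MethodMap:
    """Classical-MDS embedding: coordinates (centered), eigenvalues, strain."""

    coords: pd.DataFrame
    eigenvalues: np.ndarray
    strain: float


def classical_mds(distances: pd.DataFrame | np.ndarray, k: int = 2) -> MethodMap:
    """Torgerson scaling: B = -1/2 J D^2 J, eigendecomposition, top-k axes.

    When the input is an exact Euclidean distance matrix of configuration
    rank <= k, the embedded pairwise distances reproduce the input to
    machine precision (up to rotation/reflection).  Axis signs are fixed
    deterministically (largest-magnitude loading positive).
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = list(range(len(d)))
    n = len(d)
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distances must be a symmetric matrix with zero diagonal")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int((eigval > max(1e-10 * abs(eigval[0]), 1e-12)).sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); returning {n_pos} dimension(s)"
        )
    k_eff = min(k, max(n_pos, 1))
    coords = eigvec[:, :k_eff] * np.sqrt(np.maximum(eigval[:k_eff], 0.0))
    for jcol in range(coords.shape[1]):  # deterministic sign convention
        i_max = int(np.argmax(np.abs(coords[:, jcol])))
        if coords[i_max, jcol] < 0:
            coords[:, jcol] = -coords[:, jcol]
    strain_den = float((eigval ** 2).sum())
    strain = 0.0 if strain_den == 0 else float(
        1.0 - (eigval[:k_eff] ** 2).sum() / strain_den
    )
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"dim{i+1}" for i in range(k_eff)]
    )
    return MethodMap(frame, eigval, strain)


@dataclass
class Dendrogram:
    """Complete-linkage merge history (scipy linkage matrix) with labels."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut_k(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def cut_height(self, h: float) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=h, criterion="distance")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                name = str(self.labels[node.id]).replace(" ", "_").replace(",", "")
                return f"{name}:{parent_height - 0.0:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        body = walk(tree, tree.dist)
        return body.rsplit(":", 1)[0] + ";"


def complete_linkage(distances: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Agglomerative clustering merging on the maximum inter-cluster distance.

    Complete linkage is monotone, so the merge heights are non-decreasing and
    cutting at height h yields clusters with internal diameter <= h.
    """
    if isinstance(distances, pd.DataFrame):
        labels = tuple(str(i) for i in distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = tuple(str(i) for i in range(len(d)))
    if len(d) < 2:
        raise ValueError("need at least 2 methods")
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(z, labels)


# ---------------------------------------------------------------------------
# Cluster-count selection by majority vote of validity indices

def _dunn(d: np.ndarray, labels: np.ndarray) -> float:
    clusters = np.unique(labels)
    min_between = np.inf
    max_within = 0.0
    for i, a in enumerate(clusters):
        mask_a = labels == a
        if mask_a.sum() > 1:
            max_within = max(max_within, d[np.ix_(mask_a, mask_a)].max())
        for b in clusters[i + 1:]:
            mask_b = labels == b
            min_between = min(min_between, d[np.ix_(mask_a, mask_b)].min())
    if max_within == 0:
        return np.inf
    return float(min_between / max_within)


def _c_index(d: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    pair_d = d[iu]
    within = labels[iu[0]] == labels[iu[1]]
    n_w = int(within.sum())
    if n_w == 0 or n_w == len(pair_d):
        return np.nan
    s = pair_d[within].sum()
    pair_sorted = np.sort(pair_d)
    s_min = pair_sorted[:n_w].sum()
    s_max = pair_sorted[-n_w:].sum()
    if s_max == s_min:
        return 0.0
    return float((s - s_min) / (s_max - s_min))


#: index name -> (needs_features, maximize)
VALIDITY_INDICES = {
    "calinski_harabasz": (True, True),
    "silhouette": (False, True),
    "dunn": (False, True),
    "davies_bouldin": (True, False),
    "c_index": (False, False),
}


@dataclass
class KSelection:
    k: int
    votes: dict[str, int]          # index -> its preferred k
    tally: dict[int, int]          # k -> number of votes
    scores: pd.DataFrame           # index x k score table
    weak_evidence: bool = False


def select_k_majority(
    profiles: pd.DataFrame,
    distances: pd.DataFrame | None = None,
    k_candidates: Sequence[int] = range(2, 9),
    validity_indices: Sequence[str] = tuple(VALIDITY_INDICES),
) -> KSelection:
    """Choose the number of method groups by majority vote.

    Candidate partitions come from cutting the complete-linkage dendrogram at
    each k; every enabled validity index votes for its best k; the k with
    most votes wins, ties going to the smallest k.  The ``weak_evidence``
    flag marks near-ties (winning margin of at most one vote).
    """
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )

    unknown = set(validity_indices) - set(VALIDITY_INDICES)
    if unknown:
        raise ValueError(f"unknown validity indices: {sorted(unknown)}")
    if len(validity_indices) < 5:
        raise ValueError("at least 5 validity indices are required")
    if distances is None:
        d = squareform(pdist(profiles.to_numpy()))
    else:
        d = distances.to_numpy(dtype=float)
    n = len(profiles)
    ks = [k for k in k_candidates if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("no feasible cluster counts for this many methods")
    dendro = complete_linkage(
        pd.DataFrame(d, index=profiles.index, columns=profiles.index)
    )
    x = profiles.to_numpy()
    score_rows = {name: [] for name in validity_indices}
    for k in ks:
        labels = np.array(
            [dendro.cut_k(k)[str(i)] for i in profiles.index]
        )
        effective = len(np.unique(labels))
        for name in validity_indices:
            if effective < 2:
                score_rows[name].append(np.nan)
                continue
            if name == "calinski_harabasz":
                score = calinski_harabasz_score(x, labels)
            elif name == "silhouette":
                score = silhouette_score(d, labels, metric="precomputed")
            elif name == "davies_bouldin":
                score = davies_bouldin_score(x, labels)
            elif name == "dunn":
                score = _dunn(d, labels)
            else:
                score = _c_index(d, labels)
            score_rows[name].append(score)
    scores = pd.DataFrame(score_rows, index=ks).T
    votes: dict[str, int] = {}
    for name in validity_indices:
        row = scores.loc[name].to_numpy(dtype=float)
        maximize = VALIDITY_INDICES[name][1]
        row = row if maximize else -row
        if np.all(np.isnan(row)):
            continue
        votes[name] = int(ks[int(np.nanargmax(row))])
    winner, tally, weak = majority_vote(votes)
    return KSelection(
        k=winner, votes=votes, tally=tally, scores=scores, weak_evidence=weak
    )


def majority_vote(votes: Mapping[str, int]) -> tuple[int, dict[int, int], bool]:
    """Majority rule over per-index k votes; ties resolved to the smallest k.

    Returns (winner, tally, weak_evidence) where weak_evidence flags a
    winning margin of at most one vote.
    """
    if not votes:
        raise ValueError("no validity index produced a vote")
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    top = max(tally.values())
    winner = min(k for k, c in tally.items() if c == top)
    runner_up = max([c for k, c in tally.items() if k != winner], default=0)
    return winner, tally, (top - runner_up) <= 1
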