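"""Cluster sweep over buzz features with Fowlkes-Mallows validation.

Runs the full grid of 16 k-medoids (PAM) and 48 agglomerative hierarchical
models over the five acoustic variables, scores each configuration's k = 2
partition against the presumed behavior labels with the Fowlkes-Mallows
index, and extracts single-threshold rules from cluster assignments with an
exhaustive decision stump.

All algorithms are deterministic: PAM uses BUILD + steepest-descent SWAP
with lowest-index tie-breaking, and hierarchical merging uses
Lance-Williams updates with smallest-pair tie-breaking, so the sweep is
reproducible without seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import fowlkes_mallows_score

from .buzzfeatures import FEATURE_COLUMNS
from .errors import ConfigError, DegenerateScalingError, NoSplitError

FEATURES_5 = FEATURE_COLUMNS
FEATURES_2 = ("minICI", "ICIir")

DISTANCES = ("euclidean", "squared_euclidean", "manhattan")
LINKAGES = (
    "complete",
    "single",
    "average",
    "weighted_average",
    "centroid",
    "median",
    "ward",
)

# which distances each linkage accepts
_LINKAGE_DISTANCES = {
    "complete": ("euclidean", "manhattan"),
    "single": ("euclidean", "manhattan"),
    "average": ("euclidean", "manhattan"),
    "weighted_average": ("euclidean", "manhattan"),
    "centroid": ("squared_euclidean",),
    "median": ("euclidean",),
    "ward": ("euclidean", "squared_euclidean"),
}

_PDIST_METRIC = {
    "euclidean": "euclidean",
    "squared_euclidean": "sqeuclidean",
    "manhattan": "cityblock",
}


@dataclass(frozen=True)
class ClusterConfig:
    """One sweep configuration (family, distance, linkage, variables, scaling)."""

    family: str  # "pam" | "hierarchical"
    distance: str
    linkage: Optional[str]  # None for pam
    variables: tuple
    scaled: bool
    k: int = 2

    def __post_init__(self) -> None:
        if self.family not in ("pam", "hierarchical"):
            raise ConfigError(f"unknown family {self.family!r}")
        if self.distance not in DISTANCES:
            raise ConfigError(f"unknown distance {self.distance!r}")
        if self.k != 2:
            raise ConfigError("the sweep is defined for k = 2 only")
        if self.family == "pam":
            if self.linkage is not None:
                raise ConfigError("pam configurations take no linkage")
        else:
            if self.linkage not in LINKAGES:
                raise ConfigError(f"unknown linkage {self.linkage!r}")
            if self.distance not in _LINKAGE_DISTANCES[self.linkage]:
                raise ConfigError(
                    f"linkage {self.linkage!r} does not admit distance "
                    f"{self.distance!r}"
                )

    def label(self) -> str:
        link = self.linkage or "-"
        scale = "scaled" if self.scaled else "unscaled"
        return (
            f"{self.family}/{link}/{self.distance}/"
            f"{len(self.variables)}var/{scale}"
        )


@dataclass
class ClusterModelResult:
    """Assignments and Fowlkes-Mallows score of one configuration."""

    config: ClusterConfig
    assignments: np.ndarray
    fm_index: float


@dataclass(frozen=True)
class StumpRule:
    """A single-split threshold rule extracted from cluster assignments."""

    variable: str
    threshold: float
    below_class: object  # majority class where variable < threshold
    above_class: object
    impurity: float  # weighted Gini impurity of the two children


def scale_features(X, columns: Optional[Sequence[str]] = None):
    """Center each column and divide by its sample (n-1) standard deviation.

    Accepts a DataFrame or 2-D array and returns the same type.  A
    zero-variance column cannot be standardized and raises
    :class:`DegenerateScalingError` naming the column.
    """
    is_frame = isinstance(X, pd.DataFrame)
    arr = np.asarray(X, dtype=float) if not is_frame else X.to_numpy(float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("scaling requires a 2-D matrix with >= 2 rows")
    if np.isnan(arr).any():
        raise ValueError("scaling requires complete data (no missing values)")
    names = list(X.columns) if is_frame else (
        list(columns) if columns is not None else
        [f"column {i}" for i in range(arr.shape[1])]
    )
    sd = arr.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if len(zero):
        raise DegenerateScalingError(
            f"zero-variance column(s): {', '.join(str(names[i]) for i in zero)}"
        )
    out = (arr - arr.mean(axis=0)) / sd
    if is_frame:
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


def _distance_matrix(points: np.ndarray, distance: str) -> np.ndarray:
    if distance not in _PDIST_METRIC:
        raise ConfigError(f"unknown distance {distance!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        pts = pts.T if pts.shape[1] > 1 else pts
    return squareform(pdist(pts, metric=_PDIST_METRIC[distance]))


def _pam_cost(D: np.ndarray, medoids: Sequence[int]) -> float:
    return float(D[:, list(medoids)].min(axis=1).sum())


def pam_cluster(
    points: np.ndarray, distance: str = "euclidean", k: int = 2
) -> np.ndarray:
    """Partitioning around medoids: BUILD initialization + SWAP refinement.

    BUILD greedily picks medoids minimizing total dissimilarity; SWAP
    repeatedly applies the medoid/non-medoid exchange with the largest cost
    decrease until no exchange improves.  Ties are broken toward lowest row
    indices throughout: equal-gain BUILD candidates take the lowest index,
    and an equal-cost exchange is accepted when it moves the medoid set to
    a lexicographically smaller one (each step strictly decreases
    ``(cost, medoid set)``, so the walk terminates and is deterministic).

    Like any BUILD+SWAP search this is a local heuristic: the returned
    medoids admit no improving single exchange, but need not be the global
    cost minimizer.

    Returns integer labels ``0..k-1``; points are assigned to the nearest
    medoid (lowest-index medoid on ties).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    D = _distance_matrix(pts, distance)

    # BUILD: first medoid minimizes total dissimilarity; each later medoid
    # maximizes the reduction in cost (argmin/argmax take the first = lowest
    # index on ties).
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dnear = D[:, medoids].min(axis=1)
        gains = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP: steepest descent over all (medoid, candidate) exchanges, with
    # equal-cost moves taken toward lexicographically smaller medoid sets.
    state = tuple(sorted(medoids))
    current = _pam_cost(D, state)
    while True:
        best_cost, best_state = current, state
        for mi in range(k):
            for h in range(n):
                if h in state:
                    continue
                trial = tuple(sorted(state[:mi] + state[mi + 1 :] + (h,)))
                c = _pam_cost(D, trial)
                if c < best_cost - 1e-12 or (
                    abs(c - best_cost) <= 1e-12 and trial < best_state
                ):
                    best_cost, best_state = c, trial
        if best_state == state:
            break
        current, state = best_cost, best_state

    return np.asarray(np.argmin(D[:, list(state)], axis=1), dtype=int)


def pam_brute_force(
    points: np.ndarray, distance: str = "euclidean", k: int = 2
) -> tuple:
    """Exhaustive search over all medoid subsets (oracle for small n).

    Returns ``(medoids, cost)`` of the global optimum, lexicographically
    smallest medoid set on ties.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    D = _distance_matrix(pts, distance)
    best = None
    for combo in itertools.combinations(range(len(pts)), k):
        c = _pam_cost(D, combo)
        if best is None or c < best[1] - 1e-12:
            best = (combo, c)
    return best


def _lance_williams(linkage: str, ni: int, nj: int, nk: int) -> tuple:
    """(alpha_i, alpha_j, beta, gamma) update coefficients."""
    if linkage == "single":
        return 0.5, 0.5, 0.0, -0.5
    if linkage == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if linkage == "average":
        s = ni + nj
        return ni / s, nj / s, 0.0, 0.0
    if linkage == "weighted_average":
        return 0.5, 0.5, 0.0, 0.0
    if linkage == "centroid":
        s = ni + nj
        return ni / s, nj / s, -(ni * nj) / (s * s), 0.0
    if linkage == "median":
        return 0.5, 0.5, -0.25, 0.0
    if linkage == "ward":
        t = ni + nj + nk
        return (ni + nk) / t, (nj + nk) / t, -nk / t, 0.0
    raise ConfigError(f"unknown linkage {linkage!r}")


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges[m] = (a, b, height)`` records that clusters ``a`` and ``b``
    (original points are ``0..n-1``; merge ``m`` creates cluster ``n+m``)
    were joined at the given cophenetic height.
    """

    n: int
    merges: list = field(default_factory=list)

    def cut(self, k: int = 2) -> np.ndarray:
        """Labels 0..k-1 after undoing the last k-1 merges.

        Clusters are numbered by their smallest member index.
        """
        if not 1 <= k <= self.n:
            raise ValueError(f"k must be in 1..{self.n}")
        parent = list(range(self.n + len(self.merges)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for m, (a, b, _h) in enumerate(self.merges[: self.n - k]):
            new = self.n + m
            parent[find(a)] = new
            parent[find(b)] = new
        roots = [find(i) for i in range(self.n)]
        first_member: dict = {}
        for i, r in enumerate(roots):
            first_member.setdefault(r, i)
        order = sorted(set(roots), key=lambda r: first_member[r])
        relabel = {r: j for j, r in enumerate(order)}
        return np.asarray([relabel[r] for r in roots], dtype=int)

    def to_newick(self, labels: Optional[Sequence[str]] = None) -> str:
        """Nested-parenthesis export with cophenetic heights as branch lengths."""
        if labels is None:
            labels = [str(i) for i in range(self.n)]
        node: dict = {i: (str(labels[i]), 0.0) for i in range(self.n)}
        for m, (a, b, h) in enumerate(self.merges):
            (sa, ha), (sb, hb) = node.pop(a), node.pop(b)
            la, lb = max(h - ha, 0.0) / 2, max(h - hb, 0.0) / 2
            node[self.n + m] = (f"({sa}:{la:.6g},{sb}:{lb:.6g})", h / 2)
        forest = ",".join(s for s, _ in node.values())
        return (forest if len(node) == 1 else f"({forest})") + ";"


def agglomerate(D: np.ndarray, linkage: str) -> Dendrogram:
    """Agglomerative clustering of a precomputed dissimilarity matrix.

    Inter-cluster dissimilarities are maintained with the Lance-Williams
    update for the requested linkage, applied to the matrix exactly as
    given (squared-Euclidean variants are produced by squaring the input
    beforehand).  The closest pair is merged at each step; ties go to the
    pair of oldest clusters (smallest indices).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    # working copy indexed by cluster id; inactive rows masked with inf
    size = n + (n - 1)
    W = np.full((size, size), np.inf)
    W[:n, :n] = D
    np.fill_diagonal(W, np.inf)
    active = list(range(n))
    counts = {i: 1 for i in range(n)}
    dendro = Dendrogram(n=n)
    for m in range(n - 1):
        # smallest pairwise dissimilarity among active clusters; row-major
        # argmin over the ordered active list breaks ties at oldest pair
        best = (np.inf, None)
        for ia, a in enumerate(active):
            row = W[a, active]
            j = int(np.argmin(row))
            if row[j] < best[0] and j != ia:
                best = (row[j], (min(a, active[j]), max(a, active[j])))
        h, (a, b) = best
        new = n + m
        ni, nj = counts[a], counts[b]
        for c in active:
            if c in (a, b):
                continue
            ai, aj, beta, gamma = _lance_williams(linkage, ni, nj, counts[c])
            W[new, c] = W[c, new] = (
                ai * W[a, c]
                + aj * W[b, c]
                + beta * h
                + gamma * abs(W[a, c] - W[b, c])
            )
        active = [c for c in active if c not in (a, b)] + [new]
        active.sort()
        counts[new] = ni + nj
        dendro.merges.append((a, b, float(h)))
    return dendro


def hierarchical_cluster(
    points: np.ndarray,
    distance: str,
    linkage: str,
    k: int = 2,
    return_tree: bool = False,
):
    """Agglomerative clustering of points, cut at ``k`` clusters.

    The admissible distance/linkage pairings mirror the sweep grid:
    complete/single/average/weighted_average with Euclidean or Manhattan,
    centroid with squared Euclidean only, median with Euclidean only, Ward
    with either Euclidean or squared Euclidean.
    """
    if linkage not in LINKAGES:
        raise ConfigError(f"unknown linkage {linkage!r}")
    if distance not in _LINKAGE_DISTANCES[linkage]:
        raise ConfigError(
            f"linkage {linkage!r} does not admit distance {distance!r}"
        )
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    D = _distance_matrix(pts, distance)
    dendro = agglomerate(D, linkage)
    labels = dendro.cut(k)
    return (labels, dendro) if return_tree else labels


def fowlkes_mallows(assignments, presumed_labels) -> float:
    """Pair-counting agreement between two partitions, in [0, 1].

    ``B = T / sqrt(P * Q)`` where, over all unordered pairs of
    observations, ``T`` counts pairs co-clustered in both partitions and
    ``P``/``Q`` pairs co-clustered in each one alone.  Returns 0 when
    either partition has no co-clustered pair.
    """
    a = np.asarray(assignments)
    b = np.asarray(presumed_labels)
    if a.shape != b.shape:
        raise ValueError(
            f"length mismatch: {a.shape} assignments vs {b.shape} labels"
        )
    return float(fowlkes_mallows_score(b, a))


def enumerate_configs() -> list:
    """The study grid: 16 PAM and 48 hierarchical configurations.

    PAM: the 5-variable and 2-variable sets crossed with the three
    distances and two scalings (12), plus the two single-variable sets
    crossed with the two scalings (4; distance is immaterial in one
    dimension and recorded as Euclidean).

    Hierarchical: complete/single/average/weighted_average crossed with
    Euclidean and Manhattan distance, both variable sets, both scalings
    (32); centroid with squared Euclidean (4); median with Euclidean (4);
    Ward with Euclidean and with squared Euclidean (8).
    """
    configs = []
    for variables in (FEATURES_5, FEATURES_2):
        for distance in DISTANCES:
            for scaled in (False, True):
                configs.append(
                    ClusterConfig("pam", distance, None, variables, scaled)
                )
    for variables in (("minICI",), ("ICIir",)):
        for scaled in (False, True):
            configs.append(
                ClusterConfig("pam", "euclidean", None, variables, scaled)
            )
    for linkage in ("complete", "single", "average", "weighted_average"):
        for distance in ("euclidean", "manhattan"):
            for variables in (FEATURES_5, FEATURES_2):
                for scaled in (False, True):
                    configs.append(
                        ClusterConfig(
                            "hierarchical", distance, linkage, variables, scaled
                        )
                    )
    for linkage, dists in (
        ("centroid", ("squared_euclidean",)),
        ("median", ("euclidean",)),
        ("ward", ("euclidean", "squared_euclidean")),
    ):
        for distance in dists:
            for variables in (FEATURES_5, FEATURES_2):
                for scaled in (False, True):
                    configs.append(
                        ClusterConfig(
                            "hierarchical", distance, linkage, variables, scaled
                        )
                    )
    return configs


def run_sweep(features: pd.DataFrame, presumed_labels) -> list:
    """Run every configuration and score it against the presumed behavior.

    ``features`` must contain the five acoustic variable columns.  Results
    are sorted by Fowlkes-Mallows index descending, ties broken by
    enumeration order.
    """
    missing = [c for c in FEATURES_5 if c not in features.columns]
    if missing:
        raise ValueError(f"missing variable column(s): {', '.join(missing)}")
    labels = np.asarray(presumed_labels)
    if len(labels) != len(features):
        raise ValueError("labels and features must have equal length")
    results = []
    for order, config in enumerate(enumerate_configs()):
        X = features[list(config.variables)].to_numpy(float)
        if config.scaled:
            X = scale_features(X, columns=config.variables)
        if config.family == "pam":
            assign = pam_cluster(X, config.distance, config.k)
        else:
            assign = hierarchical_cluster(
                X, config.distance, config.linkage, config.k
            )
        results.append(
            (order, ClusterModelResult(config, assign, fowlkes_mallows(assign, labels)))
        )
    results.sort(key=lambda item: (-item[1].fm_index, item[0]))
    return [r for _, r in results]


def sweep_report(results: Sequence[ClusterModelResult]) -> pd.DataFrame:
    """One row per configuration: family, distance, linkage, variables, score."""
    return pd.DataFrame(
        {
            "family": [r.config.family for r in results],
            "distance": [r.config.distance for r in results],
            "linkage": [r.config.linkage or "" for r in results],
            "variables": ["+".join(r.config.variables) for r in results],
            "scaled": [r.config.scaled for r in results],
            "fm_index": [r.fm_index for r in results],
        }
    )


def _gini(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    _, counts = np.unique(y, return_counts=True)
    p = counts / len(y)
    return float(1.0 - np.sum(p * p))


def fit_stump(
    features: pd.DataFrame,
    cluster_assignments,
    variable_order: Optional[Sequence[str]] = None,
) -> StumpRule:
    """Exhaustive single-split search minimizing child Gini impurity.

    Candidate cuts are the midpoints between consecutive sorted unique
    values of each variable.  Among equally pure splits, the variable
    listed earliest in ``variable_order`` (default: the frame's column
    order) wins, then the lowest cut value.
    """
    y = np.asarray(cluster_assignments)
    if len(np.unique(y)) < 2:
        raise NoSplitError("cannot split single-class data")
    if variable_order is None:
        variable_order = [c for c in features.columns if c in FEATURES_5] or list(
            features.columns
        )
    n = len(y)
    best: Optional[StumpRule] = None
    for var in variable_order:
        x = features[var].to_numpy(float)
        uniq = np.unique(x)
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            cut = (lo + hi) / 2.0
            left, right = y[x < cut], y[x >= cut]
            score = (len(left) * _gini(left) + len(right) * _gini(right)) / n
            if best is None or score < best.impurity - 1e-12:
                below = _majority(left)
                above = _majority(right)
                best = StumpRule(var, float(cut), below, above, float(score))
    assert best is not None
    return best


def _majority(y: np.ndarray):
    vals, counts = np.unique(y, return_counts=True)
    return vals[int(np.argmax(counts))]
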