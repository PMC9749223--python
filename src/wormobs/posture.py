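"""Posture syntax: eigenworms, posture libraries, mirror merging, abundance.

Posture vectors (24 intersegment angles) from moving, well-skeletonized
worms are summarized two ways:

* **Eigenworms** — eigenvectors of the 24x24 covariance matrix of posture
  vectors; worm postures are low-dimensional, so a handful of eigenworms
  captures most variance.
* **Posture library** — k-means (k=200) centroids over the angle vectors.
  Because dorsal and ventral cannot be distinguished at plate magnification,
  a posture and its left-right mirror (the negated angle vector) are the
  same behavior; mirrored centroid pairs are therefore merged into single
  posture classes, roughly halving the library.  A second k-means (k=3)
  over all posture classes pooled across conditions yields three coarse
  "meta-posture" groups (stiff/straight vs. increasingly bent).

Class occurrences per time bin, z-scored per class across bins, give the
time-resolved posture-syntax picture of an experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .geometry import N_ANGLES

#: track-eligibility thresholds for posture/eigenworm analysis
MIN_TRACK_DURATION_S = 5.0
MIN_SPEED_MM_S = 0.01
MAX_ANGULAR_VELOCITY_DEG_S = 50.0


def eligible_for_eigenworms(duration_s: float, speed: float,
                            angular_velocity: float) -> bool:
    """Moving-worm filter for posture analysis: track duration >= 5 s,
    speed > 0.01 mm/s, angular velocity < 50 deg/s."""
    return (
        duration_s >= MIN_TRACK_DURATION_S
        and speed > MIN_SPEED_MM_S
        and angular_velocity < MAX_ANGULAR_VELOCITY_DEG_S
    )


class Eigenworms(BaseEstimator):
    """Eigen-decomposition of the posture-angle covariance matrix.

    Fits the orthonormal basis of principal bend modes ("eigenworms") from a
    sample of posture vectors; ``transform`` projects postures onto the
    leading modes.

    Attributes (after ``fit``)
    --------------------------
    components_ : (n_modes, 24) eigenvectors, rows, by decreasing eigenvalue
    eigenvalues_ : corresponding variances
    explained_variance_ratio_ : eigenvalue fractions (sum to 1)
    mean_ : (24,) sample mean removed before decomposition
    """

    def __init__(self, n_modes: int | None = None):
        self.n_modes = n_modes

    def fit(self, X: np.ndarray, y=None) -> "Eigenworms":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_angles)")
        n, d = X.shape
        if n < d:
            warnings.warn(
                f"only {n} posture vectors for {d} dimensions; "
                "basis is rank-deficient and truncated", stacklevel=2)
        self.mean_ = X.mean(axis=0)
        cov = np.cov(X - self.mean_, rowvar=False)
        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        total = evals.sum()
        keep = self.n_modes or min(n, d)
        self.eigenvalues_ = evals[:keep]
        self.components_ = evecs[:, :keep].T
        self.explained_variance_ratio_ = (
            evals[:keep] / total if total > 0 else np.zeros(keep)
        )
        if total == 0:
            warnings.warn("zero posture variance; eigenworm basis is empty",
                          stacklevel=2)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, float) @ self.components_ + self.mean_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def compute_eigenworms(posture_vectors: np.ndarray,
                       n_modes: int | None = None) -> Eigenworms:
    """Functional wrapper over :class:`Eigenworms`."""
    return Eigenworms(n_modes=n_modes).fit(posture_vectors)


def sample_symmetric_postures(n_pairs: int, noise: float = 0.15,
                              seed: int = 0,
                              scales: tuple = (1.0, 0.6)) -> np.ndarray:
    """Negation-symmetric synthetic posture sample for mirror-merge checks.

    Draws ``n_pairs`` 24-angle vectors from a two-bend-mode mixture with
    additive Gaussian noise and appends the negation of every vector, so the
    returned ``(2 * n_pairs, 24)`` set is exactly closed under mirroring.
    """
    from .simulate import default_bend_modes

    rng = np.random.default_rng(seed)
    modes = default_bend_modes()
    coeff = rng.normal(size=(n_pairs, 2)) * np.asarray(scales)
    X = coeff @ modes + rng.normal(0.0, noise, size=(n_pairs, N_ANGLES))
    return np.vstack([X, -X])


def mirror_merge_reduction(n_pairs: int = 10_000, k: int = 200,
                           seeds: tuple = (0, 1, 2, 3, 4),
                           noise: float = 0.15) -> float:
    """Mean percent reduction of the posture-library size by mirror merging,
    measured on negation-symmetric samples over several seeds."""
    reductions = []
    for s in seeds:
        X = sample_symmetric_postures(n_pairs, noise=noise, seed=s)
        lib = PostureLibrary(k=k, random_state=int(s)).fit(X)
        reductions.append(lib.reduction_percent)
    return float(np.mean(reductions))


def find_mirror_pairs(centroids: np.ndarray,
                      match_quantile: float = 0.75) -> dict[int, int]:
    """Identify mirrored (negated) centroid pairs.

    Pairs are assigned greedily by increasing mirror distance
    ``d(-c_i, c_j)``, each centroid used at most once, and accepted only at
    or below a scale-adaptive gate: the ``match_quantile`` of
    nearest-neighbor distances among the centroids themselves.  (Greedy
    matching rather than strict mutual nearest neighbors: k-means tilings of
    a symmetric posture cloud are not exactly symmetric, and the mutual-NN
    relation systematically under-pairs them.)  A centroid whose own
    negation is nearby (a symmetric posture) may pair with itself; unpaired
    centroids map to themselves.
    """
    C = np.asarray(centroids, dtype=float)
    k = len(C)
    if k == 0:
        return {}
    if k == 1 or match_quantile <= 0:
        return {i: i for i in range(k)}
    d_cc = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=2)
    np.fill_diagonal(d_cc, np.inf)
    gate = float(np.quantile(d_cc.min(axis=1), match_quantile))

    d_neg = np.linalg.norm(-C[:, None, :] - C[None, :, :], axis=2)  # d(-c_i, c_j)
    cand = [
        (d_neg[i, j], i, j)
        for i in range(k) for j in range(i, k)
        if d_neg[i, j] <= gate
    ]
    cand.sort()
    pairs: dict[int, int] = {}
    used: set[int] = set()
    for _, i, j in cand:
        if i in used or j in used:
            continue
        pairs[i] = j
        pairs[j] = i
        used.update((i, j))
    for i in range(k):
        pairs.setdefault(i, i)
    return pairs


def merge_mirror_classes(mirror_map: dict[int, int]) -> np.ndarray:
    """Collapse mirror pairs into merged class ids (0..n_classes-1)."""
    k = len(mirror_map)
    class_of = np.full(k, -1, dtype=int)
    next_class = 0
    for i in range(k):
        if class_of[i] >= 0:
            continue
        class_of[i] = next_class
        j = mirror_map[i]
        if class_of[j] < 0:
            class_of[j] = next_class
        next_class += 1
    return class_of


class PostureLibrary(BaseEstimator):
    """k-means posture dictionary with mirror-pair merging.

    ``fit`` clusters posture vectors (k=200 by default, k-means++ with
    multiple restarts), identifies mirrored centroid pairs, and merges each
    pair into one posture class.  ``predict`` maps new posture vectors to
    merged class ids (a vector and its negation land in the same class
    whenever their centroids are a merged pair).

    Attributes (after ``fit``)
    --------------------------
    centroids_ : (k, 24) raw k-means centroids
    mirror_map_ : dict centroid -> mirror partner (or itself)
    class_of_centroid_ : (k,) merged class id per centroid
    n_classes_ : number of merged posture classes (<= k)
    class_representatives_ : (n_classes, 24) count-weighted mean centroid
        per merged class (mirror pairs averaged after sign alignment)
    class_counts_ : training occurrences per merged class
    """

    def __init__(self, k: int = 200, match_quantile: float = 0.75,
                 n_init: int = 10, random_state: int = 0):
        self.k = k
        self.match_quantile = match_quantile
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "PostureLibrary":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_ANGLES:
            raise ValueError(f"X must be (n_samples, {N_ANGLES})")
        if len(X) < self.k:
            raise ValueError(f"need at least k={self.k} posture vectors, got {len(X)}")
        km = KMeans(n_clusters=self.k, n_init=self.n_init,
                    random_state=self.random_state)
        labels = km.fit_predict(X)
        self.centroids_ = km.cluster_centers_
        self.mirror_map_ = find_mirror_pairs(self.centroids_, self.match_quantile)
        self.class_of_centroid_ = merge_mirror_classes(self.mirror_map_)
        self.n_classes_ = int(self.class_of_centroid_.max()) + 1

        counts = np.bincount(labels, minlength=self.k)
        reps = np.zeros((self.n_classes_, X.shape[1]))
        cls_counts = np.zeros(self.n_classes_, dtype=int)
        for c in range(self.n_classes_):
            members = np.nonzero(self.class_of_centroid_ == c)[0]
            anchor = members[0]
            # align mirror partner by negation before averaging
            acc = np.zeros(X.shape[1])
            for m in members:
                v = self.centroids_[m]
                if m != anchor and np.dot(v, self.centroids_[anchor]) < 0:
                    v = -v
                acc += counts[m] * v
            tot = counts[members].sum()
            reps[c] = acc / max(tot, 1)
            cls_counts[c] = tot
        self.class_representatives_ = reps
        self.class_counts_ = cls_counts
        self.labels_ = self.class_of_centroid_[labels]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Merged class id for each posture vector.

        Because a merged class stands for a posture *and* its mirror, the
        distance of a vector to a centroid is taken as the smaller of the
        distances of the vector and of its negation; prediction is therefore
        exactly invariant under left-right mirroring of the input.
        """
        X = np.asarray(X, dtype=float)
        d_pos = np.linalg.norm(X[:, None, :] - self.centroids_[None, :, :], axis=2)
        d_neg = np.linalg.norm(-X[:, None, :] - self.centroids_[None, :, :], axis=2)
        d = np.minimum(d_pos, d_neg)
        return self.class_of_centroid_[d.argmin(axis=1)]

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_

    @property
    def reduction_percent(self) -> float:
        """Percent reduction of the library size achieved by mirror merging."""
        return 100.0 * (self.k - self.n_classes_) / self.k


def build_posture_library(posture_vectors: np.ndarray, k: int = 200,
                          match_quantile: float = 0.75,
                          rng_seed: int = 0) -> PostureLibrary:
    """Functional wrapper over :class:`PostureLibrary`."""
    return PostureLibrary(k=k, match_quantile=match_quantile,
                          random_state=rng_seed).fit(posture_vectors)


@dataclass
class MetaPostureGroups:
    """3-group coarse partition of pooled posture classes."""

    group_of_class: np.ndarray       # (n_pooled_classes,) in {0, 1, 2}
    group_centroids: np.ndarray      # (3, 24)
    member_vectors: list             # per group, (m_i, 24) member representatives

    @property
    def n_groups(self) -> int:
        return len(self.group_centroids)


def assign_meta_postures(class_representatives: np.ndarray, k: int = 3,
                         rng_seed: int = 0, n_init: int = 10) -> MetaPostureGroups:
    """Second-round k-means (k=3) over pooled posture-class representatives.

    Pool the merged-class representative vectors of every condition's
    library, then cluster into the three most diverging posture groups
    (meta-postures p1, p2, p3).
    """
    X = np.asarray(class_representatives, dtype=float)
    if len(X) < k:
        raise ValueError(f"need at least {k} pooled postures")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_seed)
    labels = km.fit_predict(X)
    members = [X[labels == g] for g in range(k)]
    return MetaPostureGroups(group_of_class=labels,
                             group_centroids=km.cluster_centers_,
                             member_vectors=members)


@dataclass
class AbundanceMatrix:
    """Relative posture-class occurrence per time bin, plus z-scores."""

    raw: pd.DataFrame        # rows = time bins (h.a.t.), cols = class ids; rows sum to 1
    zscore: pd.DataFrame     # per-class z-score across time bins
    counts: pd.DataFrame


def abundance_over_time(class_ids: np.ndarray, hat: np.ndarray,
                        bin_hours: float = 1.0,
                        n_classes: int | None = None) -> AbundanceMatrix:
    """Time-resolved relative class abundance and per-class z-scores.

    Frames are binned on the h.a.t. axis (1-h bins by default); each row of
    the raw matrix is the within-bin relative frequency over classes (rows
    sum to 1); the z-score is taken per class (column) across time bins.
    Empty bins yield NaN rows.
    """
    class_ids = np.asarray(class_ids, dtype=int)
    hat = np.asarray(hat, dtype=float)
    if len(class_ids) != len(hat):
        raise ValueError("class_ids and hat must align")
    n_classes = n_classes if n_classes is not None else (class_ids.max() + 1 if len(class_ids) else 0)
    bin_idx = np.floor(hat / bin_hours).astype(int)
    lo, hi = (bin_idx.min(), bin_idx.max()) if len(bin_idx) else (0, -1)
    rows = []
    index = []
    for b in range(lo, hi + 1):
        sel = class_ids[bin_idx == b]
        counts = np.bincount(sel, minlength=n_classes).astype(float)
        rows.append(counts)
        index.append(b * bin_hours)
    counts_df = pd.DataFrame(rows, index=pd.Index(index, name="hat"),
                             columns=np.arange(n_classes))
    totals = counts_df.sum(axis=1)
    raw = counts_df.div(totals.where(totals > 0), axis=0)  # empty bins -> NaN
    sd = raw.std(axis=0, ddof=0)
    z = (raw - raw.mean(axis=0)) / sd.where(sd > 0)
    return AbundanceMatrix(raw=raw, zscore=z, counts=counts_df)


def group_abundance_over_time(class_ids: np.ndarray, hat: np.ndarray,
                              group_of_class: np.ndarray,
                              bin_hours: float = 1.0) -> pd.DataFrame:
    """Meta-posture relative occurrence per time bin, additionally
    normalized per group by its condition-wide mean occurrence (so 1 means
    'at its average level for this condition')."""
    groups = np.asarray(group_of_class)[np.asarray(class_ids, dtype=int)]
    ab = abundance_over_time(groups, hat, bin_hours=bin_hours,
                             n_classes=int(groups.max()) + 1 if len(groups) else 0)
    raw = ab.raw
    norm = raw / raw.mean(axis=0)
    norm.columns = [f"p{g + 1}" for g in norm.columns]
    out = raw.copy()
    out.columns = [f"p{g + 1}" for g in raw.columns]
    return out.join(norm, rsuffix="_norm")
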