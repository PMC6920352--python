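"""Step 1: key features from low-magnification patch codes.

Bottleneck codes of the 128-px patches are clustered with k-means into K
features (K = 100 by default).  Clusters dominated by white glass
background are flagged and excluded.  Each patch is assigned one-hot to its
nearest centroid,

    u_{i,j,k} = 1  if k = argmin_k d_{i,j,k},  else 0,

and per-feature positive/negative degrees are the group-normalised
assignment counts

    r_pos,k = sum_+ u_{i,j,k} / n_pos,      r_neg,k = sum_- u_{i,j,k} / n_neg,

where n_pos and n_neg count all patches of each outcome group.  The impact
score of feature k is

    I_k = r_pos,k / (r_pos,k + r_neg,k)   in [0, 1],

undefined (stored as NaN) when both degrees vanish, and the impact score of
a patch is that of its assigned feature, I_{i,j} = sum_k I_k u_{i,j,k}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

DEFAULT_K = 100


@dataclass
class ClusterModel:
    """K-means centroids in code space plus flagged background clusters."""

    centroids: np.ndarray                 # (K, code_dim)
    seed: int
    background: set[int] = field(default_factory=set)
    inertia: float = float("nan")

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def save(self, path) -> None:
        np.savez(path, centroids=self.centroids,
                 meta=np.frombuffer(json.dumps({
                     "seed": self.seed,
                     "background": sorted(self.background),
                     "inertia": self.inertia,
                 }).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            return cls(data["centroids"], meta["seed"],
                       set(meta["background"]), meta["inertia"])


@dataclass
class Assignment:
    """Nearest-feature index and centroid distance per patch (one-hot u)."""

    labels: np.ndarray     # (N,) int, assigned feature k*
    distances: np.ndarray  # (N,) float, Euclidean distance to that centroid
    n_clusters: int

    def __len__(self) -> int:
        return len(self.labels)

    def one_hot(self) -> np.ndarray:
        """The u_{i,j,k} indicator matrix, exactly one 1 per row."""
        u = np.zeros((len(self.labels), self.n_clusters), dtype=np.int8)
        u[np.arange(len(self.labels)), self.labels] = 1
        return u


@dataclass
class ImpactProfile:
    """Per-feature degrees and impact scores with group totals."""

    r_positive: np.ndarray   # (K,)
    r_negative: np.ndarray   # (K,)
    impact: np.ndarray       # (K,) I_k, NaN where undefined
    n_positive: int
    n_negative: int
    background: set[int] = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        return len(self.impact)

    def weights(self) -> np.ndarray:
        """Predictive feature weights w_k = 1 + |I_k - 0.5| (1 where undefined)."""
        w = 1.0 + np.abs(self.impact - 0.5)
        return np.where(np.isnan(self.impact), 1.0, w)

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(self.n_clusters)
        return pd.DataFrame({
            "k": k,
            "r_positive": self.r_positive,
            "r_negative": self.r_negative,
            "impact": self.impact,
            "background": np.isin(k, sorted(self.background)),
        })


def fit_clusters(codes: np.ndarray, k: int = DEFAULT_K, seed: int = 0,
                 n_init: int = 10) -> ClusterModel:
    """K-means over patch codes with fixed-seed multiple restarts."""
    codes = np.asarray(codes, dtype=np.float64)
    if len(codes) < k:
        raise ValueError(
            f"{len(codes)} code rows cannot support K={k} clusters; "
            "use a smaller K"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(codes)
    return ClusterModel(km.cluster_centers_.copy(), seed,
                        inertia=float(km.inertia_))


def assign(codes: np.ndarray, model: ClusterModel) -> Assignment:
    """One-hot nearest-centroid assignment; ties go to the smallest index."""
    codes = np.asarray(codes, dtype=np.float64)
    if codes.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"code width {codes.shape[1]} does not match centroid width "
            f"{model.centroids.shape[1]}"
        )
    # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2, computed blockwise for memory
    c2 = (model.centroids ** 2).sum(axis=1)
    labels = np.empty(len(codes), dtype=np.int64)
    dists = np.empty(len(codes))
    for s in range(0, len(codes), 4096):
        x = codes[s:s + 4096]
        d2 = (x ** 2).sum(axis=1)[:, None] - 2 * x @ model.centroids.T + c2
        np.maximum(d2, 0.0, out=d2)
        lab = np.argmin(d2, axis=1)  # argmin takes the smallest index on ties
        labels[s:s + 4096] = lab
        dists[s:s + 4096] = np.sqrt(d2[np.arange(len(x)), lab])
    return Assignment(labels, dists, model.n_clusters)


def flag_background_clusters(model: ClusterModel, patches: np.ndarray,
                             assignment: Assignment,
                             brightness_threshold: float = 240.0,
                             saturation_threshold: float = 0.05) -> set[int]:
    """Flag clusters whose member patches are white glass background.

    A cluster is flagged iff the mean pixel brightness of its members is at
    least ``brightness_threshold`` (on 0-255) and their mean saturation
    (1 - min/max over channels) is at most ``saturation_threshold``.  The
    flag set is stored on the model and the flagged features are excluded
    from feature counting and impact scoring downstream.
    """
    if len(patches) != len(assignment):
        raise ValueError("patches and assignment must align")
    x = np.asarray(patches, dtype=np.float64)
    if x.max() <= 1.0:
        x = x * 255.0
    flat = x.reshape(len(x), -1, 3)
    brightness = flat.mean(axis=(1, 2))
    mx = flat.max(axis=2)
    mn = flat.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, 1.0 - mn / mx, 0.0).mean(axis=1)
    flagged = set()
    for k in range(model.n_clusters):
        members = assignment.labels == k
        if not members.any():
            continue
        if (brightness[members].mean() >= brightness_threshold
                and sat[members].mean() <= saturation_threshold):
            flagged.add(k)
    model.background = flagged
    return flagged


def compute_impact_profile(assignment: Assignment, is_positive: np.ndarray,
                           background: Optional[set[int]] = None
                           ) -> ImpactProfile:
    """Positive/negative degrees and impact scores over the features.

    ``is_positive`` labels every patch by its slide's outcome group.  Group
    totals n_pos/n_neg count all patches of the group; background features
    keep undefined (NaN) impact and are never counted downstream.
    """
    is_positive = np.asarray(is_positive, dtype=bool)
    if len(is_positive) != len(assignment):
        raise ValueError("group labels and assignment must align")
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome groups need at least one patch")
    k = assignment.n_clusters
    pos_counts = np.bincount(assignment.labels[is_positive], minlength=k)
    neg_counts = np.bincount(assignment.labels[~is_positive], minlength=k)
    r_pos = pos_counts / n_pos
    r_neg = neg_counts / n_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        impact = np.where(r_pos + r_neg > 0, r_pos / (r_pos + r_neg), np.nan)
    background = set() if background is None else set(background)
    impact[sorted(background)] = np.nan
    return ImpactProfile(r_pos, r_neg, impact, n_pos, n_neg, background)


def patch_impact(assignment: Assignment, profile: ImpactProfile) -> np.ndarray:
    """Per-patch impact I_{i,j} = I_{k*}; NaN marks unscored patches."""
    if profile.n_clusters != assignment.n_clusters:
        raise ValueError("profile and assignment have different K")
    return profile.impact[assignment.labels]


def select_representatives(model: ClusterModel, assignment: Assignment,
                           top_n: int = 10) -> dict[int, np.ndarray]:
    """Per non-background feature, member patch indices by centroid distance.

    Mirrors the representative-image panels: the ``top_n`` member patches
    closest to each centroid, ascending in distance (fewer if the feature
    has fewer members).
    """
    out: dict[int, np.ndarray] = {}
    for k in range(model.n_clusters):
        if k in model.background:
            continue
        members = np.flatnonzero(assignment.labels == k)
        order = members[np.argsort(assignment.distances[members],
                                   kind="stable")]
        out[k] = order[:top_n]
    return out
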