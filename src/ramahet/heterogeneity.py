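"""Cluster discovery in the spectral-vital subset and control assignment.

After the classifier's threshold re-labels every tumor spectrum as
spectrally necrotic or vital, the vital subset is subsampled per patient,
embedded with UMAP for display, and decomposed by k-means in the
standardized spectral feature space (NOT the embedding space — the two
methods stay independent and cross-validate each other).  The number of
clusters K is chosen from the within-cluster-sum-of-squares (WSS) curve so
that a handful of major clusters hold the bulk of the spectra while rare
subgroups and outliers still get clusters of their own.  Healthy-control
spectra are then assigned to the fitted clusters by nearest centroid.

Cluster ids are 1-based and ordered by descending size (cluster 1 is the
largest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .classify import NecrosisRandomForest
from .dataset import CONTROL_CLASSES, SpectraSet

__all__ = [
    "RelabeledSet", "EmbeddingResult", "WSSCurve", "SpectralKMeans",
    "ClusterSummary", "AssignmentResult", "OverlapReport",
    "relabel", "subsample_per_patient", "embed", "wss_curve", "select_k",
    "fit_clusters", "summarize_clusters", "assign_external", "overlap_report",
    "necrosis_probability_overlay", "rounded_percentages",
]

SPECTRAL_NECROTIC = "spectral_necrotic"
SPECTRAL_VITAL = "spectral_vital"


def rounded_percentages(counts) -> np.ndarray:
    """Counts -> integer percentages (half-up), e.g. 47 of 55 -> 85."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts, dtype=int)
    return np.floor(100.0 * counts / total + 0.5).astype(int)


# ---------------------------------------------------------------------------
# Re-labeling by the classifier threshold
# ---------------------------------------------------------------------------

@dataclass
class RelabeledSet:
    """Tumor spectra with necrosis scores and binary spectral labels."""

    sset: SpectraSet
    scores: np.ndarray
    threshold: float

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.scores >= self.threshold,
                        SPECTRAL_NECROTIC, SPECTRAL_VITAL)

    @property
    def counts(self) -> dict[str, int]:
        lab = self.labels
        return {SPECTRAL_NECROTIC: int((lab == SPECTRAL_NECROTIC).sum()),
                SPECTRAL_VITAL: int((lab == SPECTRAL_VITAL).sum())}

    def vital_subset(self) -> SpectraSet:
        return self.sset.subset(self.labels == SPECTRAL_VITAL)

    def score_table(self) -> pd.DataFrame:
        return pd.DataFrame({"necrosis_score": self.scores,
                             "spectral_label": self.labels},
                            index=self.sset.meta.index)


def relabel(model: NecrosisRandomForest, sset: SpectraSet) -> RelabeledSet:
    """Score every tumor spectrum and split at the model threshold.

    Input must be standardized with the model's stored statistics; control
    spectra are not part of the tumor data set and are rejected.
    """
    if np.isin(sset.class_labels, CONTROL_CLASSES).any():
        raise ValueError("relabel applies to tumor spectra only; remove "
                         "control_gray/control_white records first")
    if model.grid_hash is not None and sset.grid.hash() != model.grid_hash:
        raise ValueError("grid mismatch with the classifier fingerprint")
    scores = model.score_samples(sset.intensities)
    return RelabeledSet(sset, scores, float(model.threshold_))


def subsample_per_patient(sset: SpectraSet, cap: int = 30,
                          rng: np.random.Generator | int | None = None
                          ) -> SpectraSet:
    """Keep at most *cap* spectra per patient (uniform, without replacement)."""
    rng = np.random.default_rng(rng)
    kept: list[str] = []
    for _, grp in sset.meta.groupby("patient_id", sort=True):
        ids = grp.index.to_numpy()
        if len(ids) > cap:
            ids = rng.choice(ids, size=cap, replace=False)
        kept.extend(sorted(ids))
    return sset.subset(kept)


# ---------------------------------------------------------------------------
# UMAP display embedding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    """2-D display coordinates per spectrum plus the parameters used."""

    coords: pd.DataFrame  # index spectrum_id, columns x, y
    n_neighbors: int
    min_dist: float
    metric: str
    seed: int


def embed(sset: SpectraSet, n_neighbors: int = 15, min_dist: float = 0.1,
          seed: int = 0, metric: str = "euclidean") -> EmbeddingResult:
    """UMAP embedding of standardized spectra (deterministic per seed)."""
    if sset.n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} "
                         f"spectra, got {sset.n}")
    import umap  # deferred: numba compilation is expensive at import time

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                            metric=metric, n_components=2, random_state=seed)
        xy = reducer.fit_transform(sset.intensities)
    if not np.all(np.isfinite(xy)):
        raise RuntimeError("embedding produced non-finite coordinates")
    coords = pd.DataFrame(xy, columns=["x", "y"], index=sset.meta.index)
    return EmbeddingResult(coords, n_neighbors, min_dist, metric, seed)


# ---------------------------------------------------------------------------
# WSS curve and K selection
# ---------------------------------------------------------------------------

@dataclass
class WSSCurve:
    """k-means inertia (within-cluster sum of squares) for K = 1..kmax."""

    ks: np.ndarray
    wss: np.ndarray
    sizes_by_k: dict[int, np.ndarray]  # cluster sizes (unsorted) per K
    n_init: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "wss": self.wss})


def wss_curve(sset_or_X, kmax: int = 50, n_init: int = 10,
              seed: int = 0) -> WSSCurve:
    """Best-of-``n_init`` k-means (k-means++, Euclidean) inertia for each K."""
    X = sset_or_X.intensities if isinstance(sset_or_X, SpectraSet) else np.asarray(sset_or_X, dtype=float)
    n = X.shape[0]
    if n <= kmax:
        warnings.warn(f"n={n} <= kmax={kmax}; truncating kmax to {n}")
        kmax = n
    ks, wss, sizes = [], [], {}
    for k in range(1, kmax + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        ks.append(k)
        wss.append(float(km.inertia_))
        sizes[k] = np.bincount(labels, minlength=k)
    return WSSCurve(np.array(ks), np.array(wss), sizes, n_init, seed)


def _elbow(ks: np.ndarray, wss: np.ndarray) -> int:
    """K with maximum perpendicular distance to the chord from first to last."""
    p1 = np.array([ks[0], wss[0]], dtype=float)
    p2 = np.array([ks[-1], wss[-1]], dtype=float)
    chord = p2 - p1
    norm = np.linalg.norm(chord)
    pts = np.column_stack([ks, wss]).astype(float) - p1
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / max(norm, 1e-12)
    return int(ks[int(np.argmax(dist))])


def select_k(curve: WSSCurve, cluster_sizes_by_k: dict[int, np.ndarray] | None = None,
             majority_top_m: int = 7, majority_fraction: float = 0.9,
             min_minor_clusters: int = 3, minor_size: int = 10) -> int:
    """Choose K so few clusters hold the majority but rare groups get their own.

    A candidate K qualifies when (a) its ``majority_top_m`` largest clusters
    jointly hold at least ``majority_fraction`` of the spectra and (b) at
    least ``min_minor_clusters`` clusters have fewer than ``minor_size``
    spectra.  The selected K is the smallest qualifying K that is not below
    the WSS elbow (max-perpendicular-distance rule), so trivially-qualifying
    tiny K cannot short-circuit the curve; if no K qualifies the elbow is
    returned with a warning.
    """
    if len(curve.ks) == 0:
        raise ValueError("empty WSS curve")
    sizes_by_k = cluster_sizes_by_k if cluster_sizes_by_k is not None else curve.sizes_by_k
    elbow = _elbow(curve.ks, curve.wss)
    qualifying = []
    for k in curve.ks:
        sizes = np.sort(np.asarray(sizes_by_k[int(k)]))[::-1]
        n = sizes.sum()
        cov = sizes[:majority_top_m].sum() / n
        n_minor = int((sizes < minor_size).sum())
        if cov >= majority_fraction and n_minor >= min_minor_clusters:
            qualifying.append(int(k))
    for k in qualifying:
        if k >= elbow:
            return k
    if qualifying:  # all qualifying K sit below the elbow
        return qualifying[-1]
    warnings.warn("no K satisfies the majority/minor-cluster criterion; "
                  f"falling back to the WSS elbow K={elbow}")
    return elbow


# ---------------------------------------------------------------------------
# Final clustering
# ---------------------------------------------------------------------------

class SpectralKMeans(ClusterMixin, BaseEstimator):
    """k-means over standardized spectra with size-ordered 1-based cluster ids.

    After fitting, clusters are renumbered by descending size so that
    cluster 1 is the largest; ``predict`` assigns the nearest centroid
    (Euclidean), breaking exact ties toward the lower cluster id.

    Fitted attributes: ``centroids_`` (K x n_bins, row i is cluster i+1),
    ``labels_`` (1-based), ``inertia_``, ``sizes_``, ``spectrum_ids_``.
    """

    def __init__(self, n_clusters: int = 21, n_init: int = 10,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None, spectrum_ids=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.n_clusters:
            raise ValueError(f"n={X.shape[0]} < K={self.n_clusters}")
        km = KMeans(n_clusters=self.n_clusters, n_init=self.n_init,
                    random_state=self.random_state)
        km.fit(X)
        order = np.argsort(-np.bincount(km.labels_, minlength=self.n_clusters),
                           kind="stable")
        self.centroids_ = km.cluster_centers_[order]
        self.labels_ = self._assign(X)
        self.inertia_ = float(km.inertia_)
        self.sizes_ = np.bincount(self.labels_, minlength=self.n_clusters + 1)[1:]
        self.spectrum_ids_ = (np.asarray(spectrum_ids)
                              if spectrum_ids is not None else None)
        self.n_features_in_ = X.shape[1]
        return self

    def _assign(self, X) -> np.ndarray:
        d = cdist(X, self.centroids_)  # argmin returns the lowest id on ties
        return np.argmin(d, axis=1) + 1

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("grid mismatch with the fitted clustering")
        return self._assign(X)

    def transform(self, X) -> np.ndarray:
        """Euclidean distance of each spectrum to every centroid."""
        return cdist(np.asarray(X, dtype=float), self.centroids_)


#: the fitted estimator *is* the cluster model artifact
ClusterModel = SpectralKMeans


def fit_clusters(sset: SpectraSet, K: int, n_init: int = 10,
                 seed: int = 0) -> SpectralKMeans:
    model = SpectralKMeans(n_clusters=K, n_init=n_init, random_state=seed)
    return model.fit(sset.intensities, spectrum_ids=sset.spectrum_ids)


@dataclass
class ClusterSummary:
    """Size taxonomy: major (>=10), small (2-9) and singleton clusters."""

    sizes: pd.Series              # index cluster id, descending size
    major: list[int]
    small: list[int]
    singletons: list[int]
    major_coverage: float         # fraction of spectra in major clusters

    def to_dict(self) -> dict:
        return {"sizes": {int(k): int(v) for k, v in self.sizes.items()},
                "major": self.major, "small": self.small,
                "singletons": self.singletons,
                "major_coverage": self.major_coverage}


def summarize_clusters(model: SpectralKMeans,
                       major_min_size: int = 10) -> ClusterSummary:
    sizes = pd.Series(model.sizes_, index=np.arange(1, model.n_clusters + 1),
                      name="size").sort_values(ascending=False, kind="stable")
    major = [int(c) for c, s in sizes.items() if s >= major_min_size]
    small = [int(c) for c, s in sizes.items() if 2 <= s < major_min_size]
    singles = [int(c) for c, s in sizes.items() if s == 1]
    n = int(sizes.sum())
    cov = float(sizes.loc[major].sum() / n) if n and major else 0.0
    return ClusterSummary(sizes, major, small, singles, cov)


# ---------------------------------------------------------------------------
# External (healthy-control) assignment and tag overlap
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    """Nearest-centroid assignment of external spectra to fitted clusters."""

    table: pd.DataFrame  # index spectrum_id; columns class_label, cluster, distance

    def class_distribution(self, cls: str) -> pd.DataFrame:
        """Counts and integer-rounded percentages over clusters for one class."""
        sub = self.table[self.table["class_label"] == cls]
        counts = sub["cluster"].value_counts().sort_index()
        pct = rounded_percentages(counts.to_numpy())
        return pd.DataFrame({"count": counts, "percent": pct})

    def to_dict(self) -> dict:
        return {cls: {int(c): {"count": int(r["count"]), "percent": int(r["percent"])}
                      for c, r in self.class_distribution(cls).iterrows()}
                for cls in sorted(self.table["class_label"].unique())}


def assign_external(model: SpectralKMeans, external: SpectraSet,
                    standardizer=None) -> AssignmentResult:
    """Assign external spectra to the trained clusters (no refitting).

    If *standardizer* is given the external intensities are first projected
    with the TRAINING bin statistics; otherwise they must already be in the
    model's standardized feature space.
    """
    X = external.intensities
    if standardizer is not None:
        X = standardizer.transform(X)
    if X.shape[1] != model.n_features_in_:
        raise ValueError("grid mismatch with the fitted clustering")
    d = model.transform(X)
    cluster = np.argmin(d, axis=1) + 1
    dist = d[np.arange(len(cluster)), cluster - 1]
    table = pd.DataFrame({
        "class_label": external.class_labels,
        "cluster": cluster,
        "distance": dist,
    }, index=external.meta.index)
    return AssignmentResult(table)


@dataclass
class OverlapReport:
    """Cluster occupancy of tagged spectra and overlap with designated clusters."""

    per_tag: dict[str, pd.Series]        # tag -> counts per cluster
    designated_clusters: tuple[int, ...]
    overlap: dict[str, dict]             # tag -> {count, total, percent}

    def to_dict(self) -> dict:
        return {
            "designated_clusters": list(self.designated_clusters),
            "per_tag": {t: {int(c): int(v) for c, v in s.items()}
                        for t, s in self.per_tag.items()},
            "overlap": self.overlap,
        }


def overlap_report(cluster_labels, tags, designated_clusters) -> OverlapReport:
    """Count, per histology tag, spectra per cluster and in the designated set.

    *cluster_labels* is one cluster id per spectrum and *tags* one iterable
    of tag strings per spectrum (aligned).
    """
    cluster_labels = np.asarray(cluster_labels)
    designated = tuple(int(c) for c in designated_clusters)
    tag_sets = [frozenset(t) if not isinstance(t, str) else frozenset([t]) if t else frozenset()
                for t in tags]
    all_tags = sorted(set().union(*tag_sets)) if tag_sets else []
    per_tag, overlap = {}, {}
    for tag in all_tags:
        mask = np.array([tag in t for t in tag_sets])
        counts = pd.Series(cluster_labels[mask]).value_counts().sort_index()
        total = int(mask.sum())
        in_designated = int(counts.reindex(designated, fill_value=0).sum())
        per_tag[tag] = counts
        overlap[tag] = {
            "count": in_designated, "total": total,
            "percent": int(rounded_percentages(
                np.array([in_designated, total - in_designated]))[0]) if total else 0,
        }
    return OverlapReport(per_tag, designated, overlap)


def necrosis_probability_overlay(relabeled: RelabeledSet,
                                 embedding: EmbeddingResult) -> pd.DataFrame:
    """Join embedding coordinates with necrosis scores for display export."""
    scores = relabeled.score_table()
    missing = embedding.coords.index.difference(scores.index)
    if len(missing):
        raise ValueError(f"spectrum ids missing from the relabeled set: "
                         f"{list(missing[:5])}")
    out = embedding.coords.join(scores, how="inner")
    if len(out) != len(embedding.coords):
        raise ValueError("embedding and relabeled set ids do not match")
    return out
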