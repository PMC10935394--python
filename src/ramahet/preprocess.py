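"""Spectral cleanup, baseline removal, two-stage standardization and QC.

The three processing steps are scikit-learn transformers operating on plain
``(n_spectra, n_bins)`` arrays so they compose with sklearn pipelines; the
module-level functions wrap them for :class:`~ramahet.dataset.SpectraSet`
and maintain the provenance log.  Canonical order::

    remove_cosmic_rays -> baseline_correct -> standardize

Re-applying a step to an already-processed set emits a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectraSet

__all__ = [
    "CosmicRayCleaner", "IterativeBaselineCorrector", "TwoStageStandardizer",
    "QCReport", "remove_cosmic_rays", "baseline_correct", "standardize",
    "qc_dendrogram",
]


class CosmicRayCleaner(TransformerMixin, BaseEstimator):
    """Replace single-bin spikes by a running-median estimate.

    A bin is corrected when its residual against a running median (window
    ``window`` bins) exceeds ``z_threshold`` times the per-spectrum robust
    standard deviation (1.4826 x median absolute residual).  Stateless.
    """

    def __init__(self, z_threshold: float = 8.0, window: int = 5):
        self.z_threshold = z_threshold
        self.window = window

    def fit(self, X, y=None):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        X = np.asarray(X, dtype=float)
        if self.window > X.shape[-1]:
            raise ValueError("median window larger than the grid")
        return self

    def transform(self, X):
        X, mask = self._correct(np.asarray(X, dtype=float))
        return X

    def transform_with_counts(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Like transform, but also returns corrected-bin counts per spectrum."""
        X, mask = self._correct(np.asarray(X, dtype=float))
        return X, mask.sum(axis=1)

    def _correct(self, X):
        self.fit(X)
        med = median_filter(X, size=(1, self.window), mode="nearest")
        resid = X - med
        robust_sd = 1.4826 * np.median(np.abs(resid), axis=1, keepdims=True)
        robust_sd = np.maximum(robust_sd, 1e-12)
        mask = np.abs(resid) > self.z_threshold * robust_sd
        out = np.where(mask, med, X)
        return out, mask


class IterativeBaselineCorrector(TransformerMixin, BaseEstimator):
    """Iterative Savitzky-Golay baseline / fluorescence removal.

    Smooths the spectrum with an SG filter, clips the working curve to the
    running minimum of itself and the smooth (suppressing peaks), re-smooths,
    and after ``n_iter`` rounds subtracts the final smooth curve.  The broad
    fluorescence background survives the clipping while Raman bands do not.
    Output may contain small negatives; they are intentionally not clipped
    because standardization makes the sign irrelevant.
    """

    def __init__(self, window: int = 101, polyorder: int = 3, n_iter: int = 10):
        self.window = window
        self.polyorder = polyorder
        self.n_iter = n_iter

    def fit(self, X, y=None):
        if self.window % 2 == 0:
            raise ValueError("SG window must be odd")
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be < window")
        X = np.asarray(X, dtype=float)
        if self.window > X.shape[-1]:
            raise ValueError("SG window larger than the grid")
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) - self.baseline(X)

    def baseline(self, X) -> np.ndarray:
        self.fit(X)
        X = np.asarray(X, dtype=float)
        b = X.copy()
        smooth = b
        for _ in range(self.n_iter):
            smooth = savgol_filter(b, self.window, self.polyorder,
                                   axis=-1, mode="interp")
            b = np.minimum(b, smooth)
        return smooth


class TwoStageStandardizer(TransformerMixin, BaseEstimator):
    """Standardize per spectrum (SNV) then per frequency bin.

    Stage 1 centers and scales each spectrum to zero mean / unit sd across
    its bins (standard normal variate); stage 2 centers and scales each bin
    across spectra.  The fitted bin statistics (``bin_mean_``, ``bin_scale_``)
    are stored so external spectra (e.g. healthy controls) can later be
    standardized with the training statistics.
    """

    def fit(self, X, y=None):
        X = self._snv(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("need at least 2 spectra to fit bin statistics")
        self.n_features_in_ = X.shape[1]
        self.bin_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.bin_scale_ = np.where(scale > 0, scale, 1.0)
        return self

    def transform(self, X):
        X = self._snv(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("grid mismatch with fitted standardizer")
        return (X - self.bin_mean_) / self.bin_scale_

    @staticmethod
    def snv_flags(X) -> np.ndarray:
        """Boolean mask of constant (zero-variance) spectra that cannot be SNV'd."""
        X = np.asarray(X, dtype=float)
        return X.std(axis=1) == 0

    @staticmethod
    def _snv(X):
        sd = X.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant spectrum: SNV undefined (sd = 0)")
        return (X - X.mean(axis=1, keepdims=True)) / sd


@dataclass
class QCReport:
    """Summary of the top levels of a Ward dendrogram over the spectra.

    ``levels`` holds, for cuts into 2, 3 and 4 clusters, the merge height and
    the branch sizes; ``flagged`` lists spectra sitting in a branch smaller
    than ``max(2, 0.5% of n)`` at any inspected level.
    """

    n: int
    levels: list[dict] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> bool:
        """True iff strong outliers are present."""
        return len(self.flagged) > 0

    def to_dict(self) -> dict:
        return {"n": self.n, "levels": self.levels,
                "flagged": self.flagged, "strong_outliers_present": self.verdict}


# ---------------------------------------------------------------------------
# SpectraSet wrappers
# ---------------------------------------------------------------------------

def _warn_if_rerun(sset: SpectraSet, op: str) -> None:
    if any(entry.startswith(op) for entry in sset.log):
        warnings.warn(f"{op} already recorded in provenance log; re-running "
                      f"on processed data", stacklevel=3)


def remove_cosmic_rays(sset: SpectraSet, z_threshold: float = 8.0,
                       window: int = 5) -> SpectraSet:
    """Despike all spectra; logs the number of corrected bins."""
    _warn_if_rerun(sset, "remove_cosmic_rays")
    cleaner = CosmicRayCleaner(z_threshold=z_threshold, window=window)
    X, counts = cleaner.transform_with_counts(sset.intensities)
    return sset.with_intensities(
        X, op=f"remove_cosmic_rays(z={z_threshold:g}, corrected_bins={int(counts.sum())})")


def baseline_correct(sset: SpectraSet, window: int = 101,
                     polyorder: int = 3) -> SpectraSet:
    """Subtract the iterative-SG baseline from every spectrum."""
    _warn_if_rerun(sset, "baseline_correct")
    corrector = IterativeBaselineCorrector(window=window, polyorder=polyorder)
    X = corrector.transform(sset.intensities)
    return sset.with_intensities(
        X, op=f"baseline_correct(window={window}, polyorder={polyorder})")


def standardize(sset: SpectraSet,
                standardizer: TwoStageStandardizer | None = None,
                ) -> tuple[SpectraSet, TwoStageStandardizer]:
    """Two-stage standardization; returns the set and the fitted transformer.

    If *standardizer* is already fitted its stored bin statistics are applied
    (required when projecting external spectra into a trained model's space);
    otherwise a new one is fitted on *sset*.  Constant spectra cannot be
    standardized: they are excluded with a warning.
    """
    _warn_if_rerun(sset, "standardize")
    flags = TwoStageStandardizer.snv_flags(sset.intensities)
    if flags.any():
        bad = list(sset.spectrum_ids[flags])
        warnings.warn(f"excluding {len(bad)} constant spectra from "
                      f"standardization: {bad[:5]}")
        sset = sset.subset(~flags)
    if sset.n < 2:
        raise ValueError("standardization needs at least 2 spectra")
    if standardizer is None:
        standardizer = TwoStageStandardizer().fit(sset.intensities)
    X = standardizer.transform(sset.intensities)
    return sset.with_intensities(X, op="standardize(snv+bin)"), standardizer


def qc_dendrogram(sset: SpectraSet, branch_fraction: float = 0.005,
                  height_fraction: float = 0.5) -> QCReport:
    """Ward-linkage outlier scan over the top three dendrogram levels.

    A spectrum is flagged as a strong outlier when, at one of the cuts into
    2/3/4 clusters, it falls in a branch of size < ``max(2, branch_fraction
    * n)`` AND that cut's merge height is at least ``height_fraction`` of
    the top merge height — a strong outlier separates from the rest of the
    data early and high, whereas small branches that only appear at low
    merge heights are ordinary within-class structure.  Cuts at zero height
    (duplicate spectra) never flag anything.
    """
    if sset.n < 4:
        raise ValueError("dendrogram QC needs at least 4 spectra")
    Z = linkage(sset.intensities, method="ward")
    report = QCReport(n=sset.n)
    min_branch = max(2, int(np.ceil(branch_fraction * sset.n)))
    top_height = float(Z[-1, 2])
    flagged: set[str] = set()
    ids = sset.spectrum_ids
    for level, k in enumerate((2, 3, 4), start=1):
        height = float(Z[-(k - 1), 2])
        labels = fcluster(Z, t=k, criterion="maxclust")
        sizes = np.bincount(labels)[1:]
        report.levels.append({
            "level": level, "n_clusters": int(len(sizes)),
            "merge_height": height,
            "branch_sizes": sorted((int(s) for s in sizes), reverse=True),
        })
        if height > 0 and height >= height_fraction * top_height:
            for cl, size in enumerate(sizes, start=1):
                if size < min_branch:
                    flagged.update(ids[labels == cl])
    report.flagged = sorted(flagged)
    return report
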