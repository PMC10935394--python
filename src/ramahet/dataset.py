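"""Core containers for Raman spectra on a shared wavenumber grid.

A :class:`SpectraSet` is the unit the whole pipeline operates on: a metadata
table (one row per spectrum) plus a dense ``(n_spectra, n_bins)`` intensity
matrix, tied to one :class:`WavenumberGrid`.  A provenance log records the
processing steps that were applied, in order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLASS_LABELS = (
    "necrosis",
    "vital",
    "heterogeneous",
    "control_gray",
    "control_white",
    "unknown",
)
TUMOR_CLASSES = ("necrosis", "vital", "heterogeneous")
CONTROL_CLASSES = ("control_gray", "control_white")
TAGS = ("infiltration_zone", "hemorrhage")

#: column order of the metadata table / wide-CSV header
META_COLUMNS = (
    "patient_id",
    "specimen_id",
    "class_label",
    "tags",
    "acquisition_time_s",
    "n_acquisitions",
)


@dataclass(frozen=True)
class WavenumberGrid:
    """Evenly spaced Raman-shift axis in cm^-1 (bin centers inclusive)."""

    start: float
    end: float
    n_bins: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"grid start ({self.start}) must be < end ({self.end})")
        if self.n_bins < 16:
            raise ValueError(f"grid needs at least 16 bins, got {self.n_bins}")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_bins)

    @property
    def step(self) -> float:
        return (self.end - self.start) / (self.n_bins - 1)

    def index_of(self, wavenumber: float) -> int:
        """Index of the bin center nearest to *wavenumber*."""
        return int(np.argmin(np.abs(self.centers - wavenumber)))

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.end

    def hash(self) -> str:
        h = hashlib.sha256(f"{self.start!r}|{self.end!r}|{self.n_bins}".encode())
        return h.hexdigest()[:16]

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "n_bins": self.n_bins}

    @classmethod
    def from_dict(cls, d: dict) -> "WavenumberGrid":
        return cls(float(d["start"]), float(d["end"]), int(d["n_bins"]))


@dataclass
class SpectrumRecord:
    """One measured or simulated spectrum with its acquisition metadata."""

    spectrum_id: str
    patient_id: str
    specimen_id: str
    class_label: str
    tags: frozenset = frozenset()
    acquisition_time_s: float = 1.0
    n_acquisitions: int = 1
    intensities: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        unknown_tags = set(self.tags) - set(TAGS)
        if unknown_tags:
            raise ValueError(f"unknown tags {sorted(unknown_tags)}")
        if not self.acquisition_time_s > 0:
            raise ValueError("acquisition_time_s must be positive")
        if not 1 <= int(self.n_acquisitions) <= 30:
            raise ValueError("n_acquisitions must be in 1..30")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"non-finite intensities in {self.spectrum_id}")


def join_tags(tags) -> str:
    return "|".join(sorted(tags))


def split_tags(s) -> frozenset:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return frozenset()
    return frozenset(str(s).split("|"))


class SpectraSet:
    """Spectra sharing one wavenumber grid.

    Parameters
    ----------
    grid : WavenumberGrid
    meta : pandas.DataFrame
        Indexed by unique ``spectrum_id``, with columns ``META_COLUMNS``
        (``tags`` stored as a ``|``-joined string).
    intensities : ndarray of shape (n_spectra, n_bins)
    log : list of str, optional
        Provenance: names of operations applied so far, in order.
    """

    def __init__(self, grid: WavenumberGrid, meta: pd.DataFrame,
                 intensities: np.ndarray, log: list[str] | None = None):
        intensities = np.asarray(intensities, dtype=float)
        if intensities.ndim != 2 or intensities.shape != (len(meta), grid.n_bins):
            raise ValueError(
                f"intensities shape {intensities.shape} does not match "
                f"{len(meta)} spectra x {grid.n_bins} bins")
        if not np.all(np.isfinite(intensities)):
            raise ValueError("non-finite intensities")
        if meta.index.has_duplicates:
            dup = meta.index[meta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate spectrum ids: {dup}")
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        bad = set(meta["class_label"]) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}")
        self.grid = grid
        self.meta = meta.loc[:, list(META_COLUMNS)].copy()
        self.meta.index.name = "spectrum_id"
        self.intensities = intensities
        self.log: list[str] = list(log) if log else []

    # -- basic protocol -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def n(self) -> int:
        return len(self.meta)

    @property
    def spectrum_ids(self) -> np.ndarray:
        return self.meta.index.to_numpy()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.meta["patient_id"].to_numpy()

    @property
    def class_labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    def tags_of(self, spectrum_id: str) -> frozenset:
        return split_tags(self.meta.at[spectrum_id, "tags"])

    def has_tag(self, tag: str) -> np.ndarray:
        """Boolean mask of spectra carrying *tag*."""
        return self.meta["tags"].map(lambda s: tag in split_tags(s)).to_numpy()

    # -- derivation ---------------------------------------------------------

    def with_intensities(self, intensities: np.ndarray, op: str | None = None) -> "SpectraSet":
        out = SpectraSet(self.grid, self.meta, intensities, self.log)
        if op:
            out.log.append(op)
        return out

    def subset(self, mask_or_ids) -> "SpectraSet":
        """Row subset by boolean mask or list of spectrum ids (order kept)."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            meta = self.meta.loc[mask_or_ids]
            inten = self.intensities[mask_or_ids]
        else:
            ids = list(mask_or_ids)
            pos = self.meta.index.get_indexer(ids)
            if (pos < 0).any():
                missing = [i for i, p in zip(ids, pos) if p < 0]
                raise KeyError(f"unknown spectrum ids: {missing[:5]}")
            meta = self.meta.iloc[pos]
            inten = self.intensities[pos]
        return SpectraSet(self.grid, meta, inten, self.log)

    def select_classes(self, classes) -> "SpectraSet":
        mask = np.isin(self.class_labels, list(classes))
        return self.subset(mask)

    @classmethod
    def from_records(cls, grid: WavenumberGrid, records: list[SpectrumRecord],
                     log: list[str] | None = None) -> "SpectraSet":
        rows, inten = [], []
        for r in records:
            if r.intensities.shape != (grid.n_bins,):
                raise ValueError(f"record {r.spectrum_id} not on grid")
            rows.append({
                "spectrum_id": r.spectrum_id,
                "patient_id": r.patient_id,
                "specimen_id": r.specimen_id,
                "class_label": r.class_label,
                "tags": join_tags(r.tags),
                "acquisition_time_s": r.acquisition_time_s,
                "n_acquisitions": int(r.n_acquisitions),
            })
            inten.append(r.intensities)
        meta = pd.DataFrame(rows).set_index("spectrum_id")
        return cls(grid, meta, np.asarray(inten), log)

    def to_records(self) -> list[SpectrumRecord]:
        out = []
        for i, (sid, row) in enumerate(self.meta.iterrows()):
            out.append(SpectrumRecord(
                spectrum_id=sid, patient_id=row["patient_id"],
                specimen_id=row["specimen_id"], class_label=row["class_label"],
                tags=split_tags(row["tags"]),
                acquisition_time_s=float(row["acquisition_time_s"]),
                n_acquisitions=int(row["n_acquisitions"]),
                intensities=self.intensities[i]))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (f"SpectraSet(n={self.n}, bins={self.grid.n_bins}, "
                f"grid=[{self.grid.start:g}, {self.grid.end:g}] cm^-1, "
                f"log={self.log})")
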