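"""Reading and writing spectra tables.

Canonical on-disk format is a wide CSV (one row per spectrum: metadata
columns then one intensity column per wavenumber bin) with a JSON sidecar
carrying the grid definition and the provenance log.  A long format
(spectrum_id, wavenumber, intensity) is supported for interchange.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import META_COLUMNS, SpectraSet, WavenumberGrid


class SpectraParseError(ValueError):
    pass


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_spectra(sset: SpectraSet, path, float_format: str = "%.17g") -> None:
    """Write wide CSV + JSON sidecar (grid, provenance).  Round-trips exactly."""
    path = Path(path)
    cols = [f"{c:.6f}" for c in sset.grid.centers]
    wide = pd.concat(
        [sset.meta,
         pd.DataFrame(sset.intensities, index=sset.meta.index, columns=cols)],
        axis=1)
    wide.to_csv(path, float_format=float_format)
    sidecar = {"grid": sset.grid.to_dict(), "log": sset.log,
               "n_spectra": sset.n}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_spectra(path) -> SpectraSet:
    """Read the wide-CSV format; validates grid, ids and intensities."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SpectraParseError(f"missing grid sidecar {sidecar}")
    meta_json = json.loads(sidecar.read_text())
    grid = WavenumberGrid.from_dict(meta_json["grid"])
    df = pd.read_csv(path, index_col="spectrum_id",
                     dtype={"tags": str}, keep_default_na=False,
                     na_values=[""], float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise SpectraParseError(f"duplicate spectrum ids: {dup[:5]}")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraParseError(f"missing metadata columns {missing}")
    bin_cols = [c for c in df.columns if c not in META_COLUMNS]
    if len(bin_cols) != grid.n_bins:
        raise SpectraParseError(
            f"{len(bin_cols)} intensity columns but grid declares "
            f"{grid.n_bins} bins")
    centers = np.array([float(c) for c in bin_cols])
    if not np.allclose(centers, grid.centers, atol=1e-4):
        raise SpectraParseError("intensity column wavenumbers disagree with "
                                "the sidecar grid")
    inten = df[bin_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if np.isnan(inten).any():
        rows = df.index[np.isnan(inten).any(axis=1)].tolist()
        lines = [int(df.index.get_loc(r)) + 2 for r in rows[:5]]
        raise SpectraParseError(
            f"non-numeric intensities in rows {rows[:5]} (lines {lines})")
    meta = df[list(META_COLUMNS)].copy()
    meta["tags"] = meta["tags"].fillna("")
    meta["acquisition_time_s"] = meta["acquisition_time_s"].astype(float)
    meta["n_acquisitions"] = meta["n_acquisitions"].astype(int)
    try:
        return SpectraSet(grid, meta, inten, log=meta_json.get("log", []))
    except ValueError as exc:
        raise SpectraParseError(str(exc)) from exc


def to_long(sset: SpectraSet) -> pd.DataFrame:
    """Wide -> long (spectrum_id, wavenumber, intensity)."""
    n, b = sset.intensities.shape
    return pd.DataFrame({
        "spectrum_id": np.repeat(sset.spectrum_ids, b),
        "wavenumber": np.tile(sset.grid.centers, n),
        "intensity": sset.intensities.ravel(),
    })


def from_long(long_df: pd.DataFrame, grid: WavenumberGrid,
              meta: pd.DataFrame) -> SpectraSet:
    """Long -> SpectraSet; *meta* provides the per-spectrum metadata."""
    pivot = long_df.pivot(index="spectrum_id", columns="wavenumber",
                          values="intensity")
    pivot = pivot.reindex(columns=np.sort(pivot.columns))
    if pivot.shape[1] != grid.n_bins or \
            not np.allclose(pivot.columns.to_numpy(float), grid.centers, atol=1e-4):
        raise SpectraParseError("long-format wavenumbers do not match the grid")
    if pivot.isna().any().any():
        raise SpectraParseError("long format has missing (spectrum, bin) pairs")
    meta = meta.loc[pivot.index]
    return SpectraSet(grid, meta, pivot.to_numpy(float))
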