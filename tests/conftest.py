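import numpy as np
import pytest

from ramahet.dataset import SpectraSet, WavenumberGrid
from ramahet.synthdata import (CohortConfig, PeakSpec, TissueClassProfile,
                               generate_cohort)


@pytest.fixture(scope="session")
def grid_small():
    return WavenumberGrid(400.0, 1800.0, 256)


def make_profile(name, centers_amps, fluor=0.0, decay=0.002, width=12.0):
    """Build a simple test profile from (center, amplitude) pairs."""
    peaks = tuple(PeakSpec(c, width, a) for c, a in centers_amps)
    return TissueClassProfile(name, peaks, fluor, decay)


@pytest.fixture(scope="session")
def nv_profiles():
    """Well-separated necrosis / vital profiles (no background)."""
    return (
        make_profile("necrosis", [(700, 5.0), (1340, 6.0), (1660, 2.0)],
                     fluor=8.0, decay=0.0015),
        make_profile("vital", [(1004, 5.0), (1450, 6.0), (1660, 5.0)],
                     fluor=8.0, decay=0.0015),
    )


@pytest.fixture(scope="session")
def nv_cohort(grid_small, nv_profiles):
    """Separable two-class cohort: 6+6 patients, 12 spectra each."""
    cfg = CohortConfig(
        grid=grid_small, profiles=nv_profiles,
        n_patients_per_class={"necrosis": 6, "vital": 6},
        spectra_per_patient=12,
        noise_sd_base=0.3, patient_gain_sd=0.1, patient_shift_sd=1.0,
        cosmic_ray_rate=0.0, hot_pixel_rate=0.0, seed=7)
    sset, truth = generate_cohort(cfg)
    return sset, truth


@pytest.fixture(scope="session")
def nv_standardized(nv_cohort):
    from ramahet.preprocess import standardize
    sset, truth = nv_cohort
    std, standardizer = standardize(sset)
    return std, truth, standardizer


@pytest.fixture(scope="session")
def small_study(grid_small):
    """Scaled-down full-pipeline run with known ground truth.

    Same generative structure as the reference preset (necrosis + 7 abundant
    + 3 rare non-necrotic profiles, gray/white controls) at roughly a third
    of the cohort size so the whole suite stays fast.
    """
    from dataclasses import replace

    from ramahet.pipeline import ClassifyParams, ClusterParams, run_study
    from ramahet.synthdata import reference_cohort_config

    cfg = reference_cohort_config(3)
    cfg = replace(
        cfg,
        grid=grid_small,
        n_patients_per_class={"necrosis": 5, "vital": 14,
                              "heterogeneous": 3, "control_gray": 1,
                              "control_white": 1},
        n_spectra_per_class={"necrosis": 60, "vital": 450,
                             "heterogeneous": 30, "control_gray": 25,
                             "control_white": 15})
    return run_study(
        3, cohort_config=cfg,
        classify_params=ClassifyParams(
            param_grid={"n_estimators": [100], "max_features": ["sqrt"]}),
        cluster_params=ClusterParams(kmax=25))


def flat_set(grid, X, prefix="s"):
    """Wrap a plain intensity matrix into a SpectraSet with dummy metadata."""
    import pandas as pd

    from ramahet.dataset import META_COLUMNS
    n = X.shape[0]
    meta = pd.DataFrame({
        "patient_id": [f"p{i % 4}" for i in range(n)],
        "specimen_id": ["f1"] * n,
        "class_label": ["unknown"] * n,
        "tags": [""] * n,
        "acquisition_time_s": [1.0] * n,
        "n_acquisitions": [1] * n,
    }, index=pd.Index([f"{prefix}{i}" for i in range(n)], name="spectrum_id"))
    return SpectraSet(grid, meta[list(META_COLUMNS)], X)
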