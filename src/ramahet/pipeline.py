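"""End-to-end pipeline driver.

Two entry points:

* :func:`run_study` — run the whole analysis in memory on a (synthetic)
  cohort and return every intermediate artifact plus a dict of headline
  numbers; this is what the acceptance script and the end-to-end tests use.
* :func:`run_pipeline` — the disk-backed driver behind ``ramahet run``:
  stages write their artifacts under an output directory, a manifest records
  hashes and seeds, and completed stages are skipped on resume (refusing to
  resume under a changed configuration).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import classify, heterogeneity, preprocess
from .dataset import CONTROL_CLASSES, TUMOR_CLASSES, SpectraSet
from .io import read_spectra, write_spectra
from .synthdata import CohortConfig, generate_cohort, reference_cohort_config

__version__ = "0.1.0"


class PreprocessParams(BaseModel):
    cosmic_z: float = Field(8.0, gt=0)
    sg_window: int = 101
    sg_polyorder: int = 3

    def model_post_init(self, _ctx) -> None:
        if self.sg_window % 2 == 0 or self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_window must be odd and > sg_polyorder")


class ClassifyParams(BaseModel):
    validation_fraction: float = Field(0.25, gt=0, lt=1)
    per_patient_cap: int = Field(15, ge=1)
    n_splits: int = Field(5, ge=2)
    n_repeats: int = Field(3, ge=1)
    param_grid: dict | None = None


class ClusterParams(BaseModel):
    per_patient_cap: int = Field(30, ge=1)
    kmax: int = Field(50, ge=2)
    n_init: int = Field(10, ge=1)
    majority_top_m: int = Field(7, ge=1)
    majority_fraction: float = Field(0.9, gt=0, le=1)
    min_minor_clusters: int = Field(3, ge=0)
    umap_n_neighbors: int = Field(15, ge=2)
    umap_min_dist: float = Field(0.1, ge=0)


class PipelineConfig(BaseModel):
    """Self-validating configuration for the full run (embedded in reports)."""

    seed: int = 0
    cohort: dict | None = None   # CohortConfig as dict; None -> reference preset
    preprocess: PreprocessParams = Field(default_factory=PreprocessParams)
    classify: ClassifyParams = Field(default_factory=ClassifyParams)
    cluster: ClusterParams = Field(default_factory=ClusterParams)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, outputs: list[str], seed: int | None = None,
               skipped: bool = False) -> None:
        self.stages.append({
            "stage": name, "outputs": outputs, "seed": seed,
            "skipped": skipped, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "hashes": {o: _file_hash(o) for o in outputs if Path(o).exists()},
        })

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "version": self.version, "stages": self.stages}


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# In-memory study
# ---------------------------------------------------------------------------

def preprocess_cohort(cohort: SpectraSet, params: PreprocessParams | None = None):
    """Clean + baseline-correct the cohort, then standardize.

    The two-stage standardizer is fit on the tumor spectra (the analysis
    set) and its bin statistics are reused to project the healthy-control
    spectra into the same feature space.  Returns
    ``(tumor_std, controls_std, standardizer, qc_report)``.
    """
    params = params or PreprocessParams()
    clean = preprocess.remove_cosmic_rays(cohort, z_threshold=params.cosmic_z)
    clean = preprocess.baseline_correct(clean, window=params.sg_window,
                                        polyorder=params.sg_polyorder)
    tumor = clean.select_classes(TUMOR_CLASSES)
    controls = clean.select_classes(CONTROL_CLASSES)
    tumor_std, standardizer = preprocess.standardize(tumor)
    if controls.n:
        controls_std, _ = preprocess.standardize(controls, standardizer=standardizer)
    else:
        controls_std = controls
    qc = preprocess.qc_dendrogram(tumor_std)
    return tumor_std, controls_std, standardizer, qc


def run_study(seed: int = 0,
              cohort_config: CohortConfig | None = None,
              preprocess_params: PreprocessParams | None = None,
              classify_params: ClassifyParams | None = None,
              cluster_params: ClusterParams | None = None,
              compute_embedding: bool = True) -> dict:
    """Full in-memory analysis of a synthetic cohort with known ground truth.

    Returns a dict with every intermediate artifact and a ``headline``
    sub-dict of the scalar results (classifier metrics, selected K, major
    coverage, control concordance, ...).
    """
    cp = classify_params or ClassifyParams()
    kp = cluster_params or ClusterParams()
    cfg = cohort_config or reference_cohort_config(seed)
    rng = np.random.default_rng(seed)

    cohort, truth = generate_cohort(cfg)
    tumor_std, controls_std, standardizer, qc = preprocess_cohort(
        cohort, preprocess_params)

    # -- supervised stage: necrosis vs vital -------------------------------
    nv = tumor_std.select_classes(["necrosis", "vital"])
    split = classify.split_patientwise(
        nv, validation_fraction=cp.validation_fraction,
        per_patient_cap=cp.per_patient_cap, rng=rng)
    model = classify.tune_and_fit(
        nv, split, param_grid=cp.param_grid, n_splits=cp.n_splits,
        n_repeats=cp.n_repeats, rng=int(seed))
    metrics = classify.evaluate(model, nv.subset(split.validation_ids))
    importance = classify.feature_importance_report(model)

    # -- threshold transfer: re-label the whole tumor set ------------------
    relabeled = heterogeneity.relabel(model, tumor_std)
    vital = relabeled.vital_subset()
    vital_sub = heterogeneity.subsample_per_patient(
        vital, cap=kp.per_patient_cap, rng=rng)

    # -- unsupervised stage: cluster discovery -----------------------------
    curve = heterogeneity.wss_curve(vital_sub, kmax=kp.kmax,
                                    n_init=kp.n_init, seed=int(seed))
    K = heterogeneity.select_k(curve, majority_top_m=kp.majority_top_m,
                               majority_fraction=kp.majority_fraction,
                               min_minor_clusters=kp.min_minor_clusters)
    clusters = heterogeneity.fit_clusters(vital_sub, K, n_init=kp.n_init,
                                          seed=int(seed))
    summary = heterogeneity.summarize_clusters(clusters)
    embedding = (heterogeneity.embed(vital_sub,
                                     n_neighbors=kp.umap_n_neighbors,
                                     min_dist=kp.umap_min_dist, seed=int(seed))
                 if compute_embedding else None)

    # -- healthy-control integration ---------------------------------------
    assignment = heterogeneity.assign_external(clusters, controls_std)
    control_modal = {
        cls: int(assignment.class_distribution(cls)["count"].idxmax())
        for cls in sorted(set(controls_std.class_labels))
    } if controls_std.n else {}
    designated = tuple(sorted(set(control_modal.values())))
    tag_sets = [vital_sub.tags_of(sid) for sid in vital_sub.spectrum_ids]
    overlap = heterogeneity.overlap_report(clusters.labels_, tag_sets,
                                           designated or (1, 2))

    # -- ground-truth scoring ----------------------------------------------
    sub_truth = truth.loc[vital_sub.spectrum_ids]
    cluster_of_profile = (
        pd.Series(clusters.labels_, index=vital_sub.spectrum_ids)
        .groupby(sub_truth["latent_profile"]).agg(lambda s: s.value_counts().idxmax()))
    concordance = float("nan")
    if controls_std.n:
        gen_profile = truth.loc[controls_std.spectrum_ids, "latent_profile"]
        expected = gen_profile.map(cluster_of_profile).to_numpy()
        assigned = assignment.table["cluster"].to_numpy()
        concordance = float(np.mean(assigned == expected))

    necro_truth = truth.loc[tumor_std.spectrum_ids, "latent_profile"] == "necrosis"
    removed = float(np.mean(
        relabeled.labels[necro_truth.to_numpy()] == heterogeneity.SPECTRAL_NECROTIC)) \
        if necro_truth.any() else float("nan")
    planted_nonnecrotic = int(
        (truth.loc[vital_sub.spectrum_ids, "latent_profile"] != "necrosis")
        .groupby(truth.loc[vital_sub.spectrum_ids, "latent_profile"]).any().sum())

    headline = {
        "n_tumor_spectra": int(tumor_std.n),
        "n_control_spectra": int(controls_std.n),
        "qc_strong_outliers": bool(qc.verdict),
        "validation_accuracy": metrics.accuracy,
        "validation_auroc_necrosis": metrics.per_class["necrosis"]["auroc"],
        "validation_auroc_vital": metrics.per_class["vital"]["auroc"],
        "validation_aupr_necrosis": metrics.per_class["necrosis"]["aupr"],
        "validation_aupr_vital": metrics.per_class["vital"]["aupr"],
        "misclassification_ratio_necrosis":
            metrics.per_class["necrosis"]["misclassification_ratio"],
        "misclassification_ratio_vital":
            metrics.per_class["vital"]["misclassification_ratio"],
        "decision_threshold": float(model.threshold_),
        "top20_importance_share": importance.top_k_share,
        "max_importance_share": importance.max_share,
        "n_spectral_vital": int(relabeled.counts[heterogeneity.SPECTRAL_VITAL]),
        "necrosis_profile_removed_fraction": removed,
        "selected_k": int(K),
        "planted_nonnecrotic_profiles": planted_nonnecrotic,
        "n_major_clusters": len(summary.major),
        "major_coverage": summary.major_coverage,
        "control_assignment_concordance": concordance,
        "control_modal_clusters": control_modal,
    }
    return {
        "config": cfg, "cohort": cohort, "truth": truth,
        "tumor_std": tumor_std, "controls_std": controls_std,
        "standardizer": standardizer, "qc": qc, "split": split,
        "model": model, "metrics": metrics, "importance": importance,
        "relabeled": relabeled, "vital_sub": vital_sub, "curve": curve,
        "clusters": clusters, "summary": summary, "embedding": embedding,
        "assignment": assignment, "overlap": overlap, "headline": headline,
    }


# ---------------------------------------------------------------------------
# Disk-backed pipeline (CLI `ramahet run`)
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute all stages, persisting artifacts under *out_dir*.

    Re-running with the same config resumes: stages whose outputs already
    exist are skipped and their artifacts loaded.  A pre-existing manifest
    with a different config hash refuses to resume.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != chash:
            raise ValueError(
                "output directory holds artifacts from a different "
                "configuration (config hash mismatch); refusing to resume")
    manifest = RunManifest(config_hash=chash, seed=config.seed)

    def stage(name, outputs, compute, load):
        paths = [out / o for o in outputs]
        if all(p.exists() for p in paths):
            manifest.record(name, [str(p) for p in paths], config.seed,
                            skipped=True)
            return load(*paths)
        result = compute(*paths)
        manifest.record(name, [str(p) for p in paths], config.seed)
        manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2))
        return result

    # simulate ----------------------------------------------------------------
    def _simulate(spectra_path, truth_path):
        cfg = (CohortConfig.from_json(json.dumps(config.cohort))
               if config.cohort else reference_cohort_config(config.seed))
        cohort, truth = generate_cohort(cfg)
        write_spectra(cohort, spectra_path)
        truth.to_csv(truth_path)
        return cohort, truth

    cohort, truth = stage(
        "simulate", ["spectra_raw.csv", "ground_truth.csv"], _simulate,
        lambda p, t: (read_spectra(p), pd.read_csv(t, index_col="spectrum_id")))

    # preprocess ---------------------------------------------------------------
    def _preprocess(tumor_path, control_path, std_path, qc_path):
        tumor_std, controls_std, standardizer, qc = preprocess_cohort(
            cohort, config.preprocess)
        write_spectra(tumor_std, tumor_path)
        write_spectra(controls_std, control_path)
        joblib.dump(standardizer, std_path)
        qc_path.write_text(json.dumps(qc.to_dict(), indent=2))
        return tumor_std, controls_std, standardizer

    tumor_std, controls_std, standardizer = stage(
        "preprocess",
        ["tumor_clean.csv", "controls_clean.csv", "standardizer.bin", "qc.json"],
        _preprocess,
        lambda t, c, s, q: (read_spectra(t), read_spectra(c), joblib.load(s)))

    # classify -----------------------------------------------------------------
    def _classify(model_path, metrics_path):
        cp = config.classify
        nv = tumor_std.select_classes(["necrosis", "vital"])
        split = classify.split_patientwise(
            nv, validation_fraction=cp.validation_fraction,
            per_patient_cap=cp.per_patient_cap,
            rng=np.random.default_rng(config.seed))
        model = classify.tune_and_fit(nv, split, param_grid=cp.param_grid,
                                      n_splits=cp.n_splits,
                                      n_repeats=cp.n_repeats, rng=config.seed)
        metrics = classify.evaluate(model, nv.subset(split.validation_ids))
        classify.save_model(model, model_path)
        report = {"metrics": metrics.to_dict(),
                  "split": {"train_patients": sorted(split.train_patients),
                            "validation_patients": sorted(split.validation_patients)},
                  "feature_importance":
                      classify.feature_importance_report(model).to_dict()}
        metrics_path.write_text(json.dumps(report, indent=2))
        return model

    model = stage("classify", ["model.bin", "classifier_report.json"],
                  _classify, lambda m, r: classify.load_model(m))

    # heterogeneity ------------------------------------------------------------
    def _cluster(relabel_path, wss_path, labels_path, summary_path,
                 embed_path):
        kp = config.cluster
        relabeled = heterogeneity.relabel(model, tumor_std)
        relabeled.score_table().to_csv(relabel_path)
        vital_sub = heterogeneity.subsample_per_patient(
            relabeled.vital_subset(), cap=kp.per_patient_cap,
            rng=np.random.default_rng(config.seed))
        curve = heterogeneity.wss_curve(vital_sub, kmax=kp.kmax,
                                        n_init=kp.n_init, seed=config.seed)
        curve.to_frame().to_csv(wss_path, index=False)
        K = heterogeneity.select_k(curve, majority_top_m=kp.majority_top_m,
                                   majority_fraction=kp.majority_fraction,
                                   min_minor_clusters=kp.min_minor_clusters)
        clusters = heterogeneity.fit_clusters(vital_sub, K, n_init=kp.n_init,
                                              seed=config.seed)
        pd.Series(clusters.labels_, index=vital_sub.spectrum_ids,
                  name="cluster").to_csv(labels_path)
        summary = heterogeneity.summarize_clusters(clusters)
        summary_path.write_text(json.dumps(
            {"selected_k": int(K), **summary.to_dict()}, indent=2))
        emb = heterogeneity.embed(vital_sub, n_neighbors=kp.umap_n_neighbors,
                                  min_dist=kp.umap_min_dist, seed=config.seed)
        heterogeneity.necrosis_probability_overlay(
            relabeled, emb).to_csv(embed_path)
        return vital_sub, clusters

    vital_sub, clusters = stage(
        "cluster",
        ["relabeled.csv", "wss_curve.csv", "cluster_labels.csv",
         "cluster_summary.json", "embedding.csv"],
        _cluster,
        lambda r, w, l, s, e: _reload_cluster(tumor_std, r, l, s))

    # assign + overlap ----------------------------------------------------------
    def _assign(assign_path, overlap_path):
        assignment = heterogeneity.assign_external(clusters, controls_std)
        assign_path.write_text(json.dumps(assignment.to_dict(), indent=2))
        modal = {cls: int(assignment.class_distribution(cls)["count"].idxmax())
                 for cls in sorted(set(controls_std.class_labels))}
        tag_sets = [vital_sub.tags_of(sid) for sid in vital_sub.spectrum_ids]
        report = heterogeneity.overlap_report(
            clusters.labels_, tag_sets, tuple(sorted(set(modal.values()))))
        overlap_path.write_text(json.dumps(
            {"control_modal_clusters": modal, **report.to_dict()}, indent=2))
        return assignment

    stage("assign", ["assignment.json", "overlap.json"], _assign,
          lambda a, o: None)

    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest


def _reload_cluster(tumor_std, relabel_path, labels_path, summary_path):
    labels = pd.read_csv(labels_path, index_col=0)["cluster"]
    vital_sub = tumor_std.subset(list(labels.index))
    summary = json.loads(Path(summary_path).read_text())
    model = heterogeneity.SpectralKMeans(n_clusters=int(summary["selected_k"]))
    # recompute centroids from the persisted labels (cheap, deterministic)
    X = vital_sub.intensities
    cents = np.vstack([X[labels.to_numpy() == k].mean(axis=0)
                       for k in range(1, model.n_clusters + 1)])
    model.centroids_ = cents
    model.labels_ = labels.to_numpy()
    model.sizes_ = np.bincount(model.labels_, minlength=model.n_clusters + 1)[1:]
    model.inertia_ = float(((X - cents[model.labels_ - 1]) ** 2).sum())
    model.n_features_in_ = X.shape[1]
    model.spectrum_ids_ = vital_sub.spectrum_ids
    return vital_sub, model
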