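# Methods

`ramahet` implements a histology-independent procedure for decomposing the
spectral heterogeneity of fresh tumor-tissue Raman measurements, of the kind
acquired perioperatively on glioblastoma resections. The procedure has three
stages: (1) a supervised binary classifier separates spectrally necrotic
from vital tissue and its cross-validated optimal decision threshold
re-labels the entire data set; (2) the resulting "spectral vital" subset is
decomposed by unsupervised k-means clustering with a data-driven choice of
the cluster count, displayed on an independently computed UMAP embedding;
(3) healthy-control spectra (autoptic gray and white matter) are projected
into the fitted clustering by nearest-centroid similarity, identifying the
clusters that represent (infiltrated) normal brain tissue. Because cohorts
of this kind are rarely deposited, the package ships a synthetic-cohort
generator with full ground truth that reproduces the statistical structure
the pipeline assumes, so every stage can be validated end to end.

## Data model

Spectra live on a shared, evenly spaced wavenumber grid (`WavenumberGrid`,
cm⁻¹). Each `SpectrumRecord` carries patient/specimen ids, a histological
class label (necrosis / vital / heterogeneous / control gray / control
white), optional histology tags (infiltration zone, hemorrhage), acquisition
time (0.7–10 s) and number of co-added acquisitions (1–30). A `SpectraSet`
is the working container: a metadata table plus an `(n, bins)` intensity
matrix and a provenance log of the operations applied.

The grid itself is configurable; the default is 400–1800 cm⁻¹ with 1024
bins, covering the biological fingerprint region at roughly instrument
resolution. Nothing downstream depends on the specific range.

## Synthetic cohorts

Each tissue entity is a `TissueClassProfile`: a sum of Gaussian bands
(center, σ, amplitude — Gaussian rather than Voigt shapes, since no stage of
the pipeline exploits line shape) on a broad fluorescence background
`A·exp(−λ(ν−ν₀))`. A spectrum is

    gain · [Σ peaks(ν; center+shift) + fluorescence(ν)] + ε,
    ε ~ N(0, σ₀²/t),

where `gain` (lognormal, sd 0.15) and `shift` (normal, sd 1.5 cm⁻¹) are
drawn once per patient — a minimal batch-effect model with one
multiplicative and one spectral-axis component, exactly the confounders the
dendrogram QC and the patient-wise splitting are meant to guard against.
Noise scales as `1/√t` with acquisition time `t`, emulating co-added
acquisitions; `σ₀ = 0.4` intensity units at 1 s puts single-spectrum
band-SNR around 10–40, which is what a fresh-tissue spectrometer with
sub-10-second exposures delivers. Two detector artifacts are injected with
configurable per-spectrum rates: a single-bin cosmic-ray spike (amplitude
≥ 10× the tallest band; rate 0.05) and a fixed saturated hot-pixel bin
(rate 0.005). Intensities are clipped at zero, as on a real detector.

The reference preset (`reference_cohort_config`) mirrors the cohort shape of
the motivating study: 43 tumor cases yielding 1456 spectra with class counts
81 necrosis / 1304 vital / 71 heterogeneous, plus 87 autoptic control
spectra (55 gray, 32 white matter — the white count inferred from the
totals). Histologically "vital" spectra draw a latent profile from a
mixture of 10 non-necrotic entities: 5 vital-tumor subtypes plus
gray-matter-like and white-matter-like profiles (7 abundant entities,
weights 0.077–0.21) and 3 rare entities (joint weight 0.013) standing in
for rare spectral subgroups such as bone chips or burnt tissue.
"Heterogeneous" specimens mix 30% necrosis profile with the vital mixture.
Controls are generated from the same gray/white profiles, which is what
makes the control-assignment concordance checkable against ground truth.
Spectra generated from the gray/white profiles inside tumor specimens are
tagged `infiltration_zone` with probability 0.6.

What the generator deliberately does **not** emulate: instrument response
and wavenumber miscalibration, Voigt/asymmetric line shapes, water/substrate
bands, spatial correlation between neighboring measurement spots, and
label noise in the histological ground truth. Passing the end-to-end tests
therefore demonstrates that the pipeline recovers planted structure under
its own model assumptions, not that a real cohort of this size would yield
the same accuracy.

## Preprocessing

Canonical order (recorded in the provenance log; re-running a step warns):

1. **Cosmic-ray removal** — bins whose residual against a running median
   (window 5 bins) exceeds `z = 8` times the per-spectrum robust sd
   (1.4826 × median |residual|) are replaced by the median value. At `z = 8`
   the false-correction probability per Gaussian-noise bin is ~1e−15, so
   clean spectra pass untouched. The detector assumes bands are resolved
   (several bins wide); on grids so coarse that bands occupy ~2 bins the
   despiker cannot distinguish a band top from a spike.
2. **Baseline / fluorescence removal** — an iterative Savitzky–Golay
   scheme: smooth (window 101 bins, polynomial order 3), clip the working
   curve to the pointwise minimum of itself and the smooth, repeat 10
   times, subtract the final smooth curve. The broad fluorescence
   background survives the clipping; Raman bands do not. This is a
   functional re-implementation of on-instrument SG baseline removal, not a
   bit-exact one. Small negative residuals are kept — standardization makes
   the sign irrelevant.
3. **Two-stage standardization** — each spectrum is centered/scaled to unit
   sd across bins (standard normal variate, which removes per-spectrum
   gain and offset), then each frequency bin is centered/scaled across
   spectra. Spectrum-first order is fixed (configurable in principle
   but not exposed as a knob). The fitted bin statistics are stored so
   external spectra — the healthy controls — are later projected with the
   *training* statistics, never refit. Constant spectra (sd 0) are excluded
   with a warning. Stage-2 column statistics are exactly (0, 1) on the fit
   set, which the tests assert at 1e−9.

**Dendrogram QC.** Ward-linkage agglomerative clustering on the
standardized spectra; the top three split levels (cuts into 2/3/4 clusters)
are summarized. A spectrum is flagged as a strong outlier when it falls in
a branch smaller than `max(2, 0.5% n)` at a cut whose merge height is at
least half the top merge height. The height condition encodes "strong":
an outlier separates from everything else early and high in the tree,
whereas small branches that only appear at low merge heights are ordinary
within-class structure. Both constants are arguments. Zero-height cuts
(duplicate spectra) never flag.

## Necrosis/vital classification

Only histologically labeled necrosis and vital spectra enter training.

* **Patient-wise split** (`split_patientwise`): whole patients are assigned
  to train or validation (default validation fraction 0.25, stratified by
  each patient's majority class), and within each patient spectra are
  subsampled without replacement to at most 15 per split, limiting the
  leverage of heavily measured patients.
* **Model** (`NecrosisRandomForest`): a random forest scored as the
  probability of the necrosis class. Hyperparameters are tuned over a small
  grid (trees 100/500 × depth ∞/20 × features √p/0.1p) by 5-fold
  cross-validation repeated 3 times; folds are both stratified and
  patient-grouped (a patient never spans a fold's train/test halves —
  stricter than plain repeated CV, consistent with the patient-wise design).
  Folds whose test half lacks positive samples are excluded from the f1
  average, since f1 is undefined there. The winning grid point (mean
  out-of-fold necrosis f1 at cutoff 0.5) is refit on all training data.
* **Decision threshold** (`optimal_threshold`): computed on the pooled
  out-of-fold scores of the winning grid point — never on the external
  validation split. Candidates are 0, 1 and midpoints between consecutive
  distinct scores; the f1-maximizing candidate is returned, ties broken
  toward the lower threshold (the more necrosis-sensitive choice). A
  property test checks the search against an exhaustive brute-force sweep.
* **Evaluation** (`evaluate`): refuses any validation set sharing a patient
  with training (leakage guard). Reports per-class AUROC/AUPR (each class
  in turn as positive), precision/recall/f1, accuracy, macro and
  support-weighted averages, and the misclassification ratio, defined as
  the per-class error rate 1 − recall. With validation supports of
  40 necrosis / 45 vital, error rates 0.15 / 0.31 compose to an overall
  accuracy of ≈ 76% — the arithmetic the acceptance script reproduces.
* **Feature importances**: normalized impurity-based importances with the
  top-k cumulative share (default k = 20) and the maximum single-bin share.
  On heterogeneous tissue the discriminative signal is spread over many
  bins rather than a few marker bands; the report quantifies that spread.

## Heterogeneity decomposition

* **Re-labeling** (`relabel`): every tumor spectrum (including the
  heterogeneous class, which never entered training) is scored; spectra
  with score ≥ threshold are "spectral necrotic", the rest form the
  *spectral vital* set. The boundary convention (≥) is fixed and tested.
* **Per-patient subsampling**: the spectral-vital set is reduced to at most
  30 spectra per patient before clustering, again limiting patient-specific
  bias. (The classifier stage uses cap 15; the clustering stage cap 30 —
  both are exposed.)
* **WSS curve** (`wss_curve`): k-means (k-means++, Euclidean, best of
  `n_init = 10` restarts) for K = 1..50; inertia is non-increasing in K up
  to restart noise (asserted at 1e−6 relative), WSS(1) equals the total sum
  of squares and WSS(n) = 0. A brute-force best-2-partition oracle checks
  K = 2 on small data.
* **Choosing K** (`select_k`): the study goal is a decomposition where few
  clusters hold the majority of spectra while rare subgroups and outliers
  still get clusters of their own. Operationalized as: K qualifies when its
  7 largest clusters jointly hold ≥ 90% of spectra AND at least 3 clusters
  have fewer than 10 spectra; the selected K is the smallest qualifying K
  at or above the WSS elbow (maximum perpendicular distance to the chord of
  the curve). The elbow floor prevents trivially small K from qualifying
  when the minor-cluster requirement is relaxed (with
  `min_minor_clusters = 0`, any K would otherwise qualify); if no K
  qualifies the elbow itself is returned with a warning. All constants are
  arguments.
* **Clustering** (`fit_clusters` / `SpectralKMeans`): k-means in the
  standardized spectral feature space, **not** in UMAP coordinates — the
  embedding is display-only, and keeping the two methods independent lets
  them cross-validate each other (the tests assert that cluster labels form
  positive-silhouette groups in the embedding plane). Cluster ids are
  1-based and ordered by descending size, so cluster 1 is always the
  largest; exact centroid ties break toward the lower id.
* **Taxonomy** (`summarize_clusters`): major clusters have ≥ 10 spectra,
  small clusters 2–9, singletons 1; the coverage of the major set is
  reported.
* **Control assignment** (`assign_external`): external spectra, projected
  with the training standardization statistics, are assigned to the nearest
  centroid; per-class distributions are reported as counts and integer
  percentages (half-up rounding, matching how such tables are printed).
* **Tag overlap** (`overlap_report`): per histology tag, counts per cluster
  and the fraction falling into a designated cluster set (by default the
  control-dominated clusters), as count/total and integer percent.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeds; every
  stage is bit-reproducible given its seed, and the disk pipeline
  (`run_pipeline`) records seeds and content hashes in a manifest, resumes
  from completed stages, and refuses to resume under a changed
  configuration.
* UMAP runs with `n_neighbors = 15`, `min_dist = 0.1`, Euclidean metric and
  a fixed `random_state` (single-threaded, hence deterministic).
* Internal-CV model selection uses f1 at cutoff 0.5 *before* threshold
  tuning; the threshold is then derived from the selected model's pooled
  out-of-fold scores. Tuning the threshold per grid point would leak the
  selection criterion into the threshold; this ordering keeps the two
  decisions separate.
* The standardizer is fit on the full tumor set before the patient split
  (mirroring a workflow where standardization precedes splitting); the
  patient-grouped CV and the patient-disjoint validation split are the
  leakage safeguards that matter for the reported metrics.
* Percentages are rounded half-up (`floor(x + 0.5)`) so that printed
  count tables reproduce exactly.

## Problem sizes used in the shipped checks

The end-to-end acceptance run uses the full reference-shaped preset
(1456 + 87 spectra, 1024 bins, kmax = 50), which completes in a few minutes
on one CPU; the unit/property suites run on scaled-down cohorts (256-bin
grid, a few hundred spectra) chosen to exercise the same code paths at
interactive speed.

## Known limitations

* The synthetic generator's class separation is optimistic; real
  necrosis/vital AUROC (≈ 0.8 in fresh-tissue cohorts) will be lower than
  the near-perfect separation achieved on planted profiles.
* `select_k` formalizes a verbal criterion; other operationalizations
  (gap statistic, silhouette) are deliberately out of scope.
* The iterative-SG baseline assumes bands are narrow relative to the
  smoothing window; very broad real bands (amide envelopes on top of steep
  fluorescence) can be partially absorbed into the baseline.
* The misclassification ratio is defined as 1 − recall; other definitions
  (e.g. FDR-style) would not compose to the reported accuracy.
* `assign_external` always returns the nearest cluster, with no novelty
  detection: a spectrum unlike anything in the training set is still
  assigned somewhere (the distance column is reported so users can screen).
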