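"""Synthetic multi-patient Raman cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in fresh-tissue tumor cohorts: tissue classes with distinct spectral
profiles (sums of Gaussian bands on a decaying fluorescence background),
per-patient batch effects (one multiplicative gain and one global wavenumber
shift per patient), shot-noise that shrinks with acquisition time as
``1/sqrt(t)``, and the two common detector artifacts — single-bin cosmic-ray
spikes and a fixed saturated hot pixel.

Ground truth (latent profile per spectrum, patient gain/shift, artifact
positions) is returned alongside the cohort so downstream recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (CLASS_LABELS, SpectraSet, SpectrumRecord,
                      WavenumberGrid, join_tags)

__all__ = [
    "PeakSpec", "TissueClassProfile", "CohortConfig",
    "generate_spectrum", "generate_cohort",
    "default_profiles", "reference_cohort_config",
]


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian Raman band: center (cm^-1), sigma (cm^-1), amplitude."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("peak width must be > 0")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")


@dataclass(frozen=True)
class TissueClassProfile:
    """Noise-free spectral signature of one tissue entity.

    ``fluorescence_amplitude`` and ``fluorescence_decay`` parameterize a
    broad background ``A * exp(-decay * (nu - grid.start))`` that the
    baseline-correction step is expected to remove.
    """

    name: str
    peaks: tuple[PeakSpec, ...]
    fluorescence_amplitude: float = 0.0
    fluorescence_decay: float = 0.0

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"profile {self.name!r} needs at least one peak")
        if self.fluorescence_amplitude < 0:
            raise ValueError("fluorescence_amplitude must be >= 0")

    def template(self, grid: WavenumberGrid, shift: float = 0.0) -> np.ndarray:
        """Noiseless signal (peaks shifted by *shift*) + fluorescence."""
        nu = grid.centers
        y = self.fluorescence_amplitude * np.exp(
            -self.fluorescence_decay * (nu - grid.start))
        for p in self.peaks:
            c = p.center + shift
            if not grid.contains(c):
                raise ValueError(
                    f"peak at {p.center} cm^-1 (shift {shift:+g}) leaves the "
                    f"grid [{grid.start}, {grid.end}]")
            y = y + p.amplitude * np.exp(-0.5 * ((nu - c) / p.width) ** 2)
        return y

    def max_peak_amplitude(self) -> float:
        return max(p.amplitude for p in self.peaks)


@dataclass
class CohortConfig:
    """Full description of a simulated multi-patient cohort.

    ``n_spectra_per_class`` (exact totals, spread near-evenly over that
    class's patients) overrides the uniform ``spectra_per_patient``.
    ``profile_weights`` maps each class to a mixture over profile names; by
    default each class draws from the single profile with the same name.
    """

    grid: WavenumberGrid
    profiles: tuple[TissueClassProfile, ...]
    n_patients_per_class: dict[str, int] = field(default_factory=dict)
    spectra_per_patient: int = 5
    n_spectra_per_class: dict[str, int] | None = None
    profile_weights: dict[str, dict[str, float]] | None = None
    patient_gain_sd: float = 0.15          # sd of log-gain (lognormal)
    patient_shift_sd: float = 1.5          # cm^-1
    noise_sd_base: float = 0.4             # intensity sd at 1 s acquisition
    acquisition_time_range: tuple[float, float] = (0.7, 10.0)
    cosmic_ray_rate: float = 0.05          # probability per spectrum
    hot_pixel_rate: float = 0.005          # probability per spectrum
    hot_pixel_bin: int | None = None       # default: bin at 80% of the grid
    hot_pixel_value: float = 1000.0
    infiltration_tag_profiles: tuple[str, ...] = ()
    infiltration_tag_prob: float = 0.0
    hemorrhage_tag_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = {p.name for p in self.profiles}
        if len(names) != len(self.profiles):
            raise ValueError("duplicate profile names")
        for rate in (self.cosmic_ray_rate, self.hot_pixel_rate,
                     self.infiltration_tag_prob, self.hemorrhage_tag_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        lo, hi = self.acquisition_time_range
        if not (0.7 <= lo <= hi <= 10.0):
            raise ValueError("acquisition times must lie within [0.7, 10] s")
        for sd in (self.patient_gain_sd, self.patient_shift_sd, self.noise_sd_base):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for cls in self.n_patients_per_class:
            if cls not in CLASS_LABELS:
                raise ValueError(f"unknown class {cls!r}")
        if self.spectra_per_patient < 1:
            raise ValueError("spectra_per_patient must be positive")
        weights = self.profile_weights or {}
        for cls, w in weights.items():
            unknown = set(w) - names
            if unknown:
                raise ValueError(f"class {cls!r} references unknown profiles {unknown}")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"profile weights for {cls!r} must sum to 1")

    def profile_by_name(self, name: str) -> TissueClassProfile:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(name)

    def class_mixture(self, cls: str) -> dict[str, float]:
        if self.profile_weights and cls in self.profile_weights:
            return self.profile_weights[cls]
        names = {p.name for p in self.profiles}
        if cls not in names:
            raise ValueError(
                f"class {cls!r} has no profile of the same name and no "
                f"explicit profile_weights entry")
        return {cls: 1.0}

    # JSON (de)serialization for the CLI -----------------------------------

    def to_json(self) -> str:
        d = {
            "grid": self.grid.to_dict(),
            "profiles": [
                {"name": p.name,
                 "peaks": [[q.center, q.width, q.amplitude] for q in p.peaks],
                 "fluorescence_amplitude": p.fluorescence_amplitude,
                 "fluorescence_decay": p.fluorescence_decay}
                for p in self.profiles],
            "n_patients_per_class": self.n_patients_per_class,
            "spectra_per_patient": self.spectra_per_patient,
            "n_spectra_per_class": self.n_spectra_per_class,
            "profile_weights": self.profile_weights,
            "patient_gain_sd": self.patient_gain_sd,
            "patient_shift_sd": self.patient_shift_sd,
            "noise_sd_base": self.noise_sd_base,
            "acquisition_time_range": list(self.acquisition_time_range),
            "cosmic_ray_rate": self.cosmic_ray_rate,
            "hot_pixel_rate": self.hot_pixel_rate,
            "hot_pixel_bin": self.hot_pixel_bin,
            "hot_pixel_value": self.hot_pixel_value,
            "infiltration_tag_profiles": list(self.infiltration_tag_profiles),
            "infiltration_tag_prob": self.infiltration_tag_prob,
            "hemorrhage_tag_prob": self.hemorrhage_tag_prob,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        profiles = tuple(
            TissueClassProfile(
                name=p["name"],
                peaks=tuple(PeakSpec(*q) for q in p["peaks"]),
                fluorescence_amplitude=p.get("fluorescence_amplitude", 0.0),
                fluorescence_decay=p.get("fluorescence_decay", 0.0))
            for p in d["profiles"])
        return cls(
            grid=WavenumberGrid.from_dict(d["grid"]),
            profiles=profiles,
            n_patients_per_class=d.get("n_patients_per_class", {}),
            spectra_per_patient=d.get("spectra_per_patient", 5),
            n_spectra_per_class=d.get("n_spectra_per_class"),
            profile_weights=d.get("profile_weights"),
            patient_gain_sd=d.get("patient_gain_sd", 0.15),
            patient_shift_sd=d.get("patient_shift_sd", 1.5),
            noise_sd_base=d.get("noise_sd_base", 0.4),
            acquisition_time_range=tuple(d.get("acquisition_time_range", (0.7, 10.0))),
            cosmic_ray_rate=d.get("cosmic_ray_rate", 0.05),
            hot_pixel_rate=d.get("hot_pixel_rate", 0.005),
            hot_pixel_bin=d.get("hot_pixel_bin"),
            hot_pixel_value=d.get("hot_pixel_value", 1000.0),
            infiltration_tag_profiles=tuple(d.get("infiltration_tag_profiles", ())),
            infiltration_tag_prob=d.get("infiltration_tag_prob", 0.0),
            hemorrhage_tag_prob=d.get("hemorrhage_tag_prob", 0.0),
            seed=d.get("seed", 0),
        )


def generate_spectrum(profile: TissueClassProfile, grid: WavenumberGrid,
                      patient_gain: float = 1.0, patient_shift: float = 0.0,
                      acquisition_time: float = 1.0,
                      rng: np.random.Generator | None = None,
                      *,
                      noise_sd_base: float = 0.0,
                      cosmic_ray_rate: float = 0.0,
                      hot_pixel_rate: float = 0.0,
                      hot_pixel_bin: int | None = None,
                      hot_pixel_value: float = 1000.0,
                      spectrum_id: str = "s0", patient_id: str = "p0",
                      specimen_id: str = "sp0", class_label: str = "unknown",
                      tags: frozenset = frozenset(),
                      n_acquisitions: int = 1,
                      ) -> tuple[SpectrumRecord, dict]:
    """Simulate one spectrum; returns the record and an artifact log.

    Intensity model per bin::

        gain * [sum of Gaussian peaks(center + shift) + fluorescence] + eps,
        eps ~ N(0, noise_sd_base^2 / acquisition_time)

    then optional single-bin cosmic-ray spike (>= 10x the tallest peak) and a
    fixed saturated hot pixel, each with the configured per-spectrum
    probability; negative intensities are clipped to zero.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if acquisition_time <= 0:
        raise ValueError("acquisition_time must be positive")
    clean = patient_gain * profile.template(grid, shift=patient_shift)
    noise_sd = noise_sd_base / np.sqrt(acquisition_time)
    y = clean + rng.normal(0.0, noise_sd, size=grid.n_bins) if noise_sd > 0 else clean.copy()

    artifacts = {"cosmic_ray_bin": -1, "hot_pixel": False}
    if cosmic_ray_rate > 0 and rng.random() < cosmic_ray_rate:
        b = int(rng.integers(0, grid.n_bins))
        amp = 10.0 * profile.max_peak_amplitude() * (1.0 + rng.random())
        y[b] += amp
        artifacts["cosmic_ray_bin"] = b
    if hot_pixel_rate > 0 and rng.random() < hot_pixel_rate:
        b = hot_pixel_bin if hot_pixel_bin is not None else int(0.8 * grid.n_bins)
        y[b] = hot_pixel_value
        artifacts["hot_pixel"] = True

    np.clip(y, 0.0, None, out=y)
    rec = SpectrumRecord(
        spectrum_id=spectrum_id, patient_id=patient_id, specimen_id=specimen_id,
        class_label=class_label, tags=tags,
        acquisition_time_s=float(acquisition_time),
        n_acquisitions=int(n_acquisitions), intensities=y)
    return rec, artifacts


def _spread(total: int, parts: int) -> list[int]:
    """Split *total* into *parts* near-equal positive integers."""
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def generate_cohort(config: CohortConfig) -> tuple[SpectraSet, pd.DataFrame]:
    """Generate a full cohort; returns (spectra, ground-truth table).

    The ground-truth table has one row per spectrum: latent generating
    profile, patient gain/shift, and injected artifact positions.  Fully
    reproducible from ``config.seed``.
    """
    if not config.n_patients_per_class or \
            all(v == 0 for v in config.n_patients_per_class.values()):
        raise ValueError("cohort needs at least one patient")
    rng = np.random.default_rng(config.seed)
    records: list[SpectrumRecord] = []
    truth_rows: list[dict] = []

    for cls, n_pat in config.n_patients_per_class.items():
        if n_pat <= 0:
            raise ValueError(f"class {cls!r} needs >= 1 patient")
        mixture = config.class_mixture(cls)
        mix_names = list(mixture)
        mix_w = np.array([mixture[m] for m in mix_names])
        if config.n_spectra_per_class and cls in config.n_spectra_per_class:
            per_patient = _spread(config.n_spectra_per_class[cls], n_pat)
        else:
            per_patient = [config.spectra_per_patient] * n_pat
        for ip in range(n_pat):
            patient = f"{cls}-p{ip + 1:02d}"
            gain = float(rng.lognormal(0.0, config.patient_gain_sd)) \
                if config.patient_gain_sd > 0 else 1.0
            shift = float(rng.normal(0.0, config.patient_shift_sd)) \
                if config.patient_shift_sd > 0 else 0.0
            for isp in range(per_patient[ip]):
                sid = f"{patient}-s{isp + 1:04d}"
                prof_name = mix_names[int(rng.choice(len(mix_names), p=mix_w))] \
                    if len(mix_names) > 1 else mix_names[0]
                profile = config.profile_by_name(prof_name)
                t_lo, t_hi = config.acquisition_time_range
                t = float(rng.uniform(t_lo, t_hi))
                n_acq = int(rng.integers(1, 31))
                tags = set()
                if (config.infiltration_tag_prob > 0
                        and prof_name in config.infiltration_tag_profiles
                        and cls in ("vital", "heterogeneous")
                        and rng.random() < config.infiltration_tag_prob):
                    tags.add("infiltration_zone")
                if config.hemorrhage_tag_prob > 0 and \
                        cls in ("vital", "heterogeneous") and \
                        rng.random() < config.hemorrhage_tag_prob:
                    tags.add("hemorrhage")
                rec, artifacts = generate_spectrum(
                    profile, config.grid, patient_gain=gain, patient_shift=shift,
                    acquisition_time=t, rng=rng,
                    noise_sd_base=config.noise_sd_base,
                    cosmic_ray_rate=config.cosmic_ray_rate,
                    hot_pixel_rate=config.hot_pixel_rate,
                    hot_pixel_bin=config.hot_pixel_bin,
                    hot_pixel_value=config.hot_pixel_value,
                    spectrum_id=sid, patient_id=patient,
                    specimen_id=f"{patient}-f{isp // 25 + 1}",  # <=25 spots per fragment
                    class_label=cls, tags=frozenset(tags),
                    n_acquisitions=n_acq)
                records.append(rec)
                truth_rows.append({
                    "spectrum_id": sid, "patient_id": patient,
                    "class_label": cls, "latent_profile": prof_name,
                    "patient_gain": gain, "patient_shift": shift,
                    "acquisition_time_s": t,
                    "cosmic_ray_bin": artifacts["cosmic_ray_bin"],
                    "hot_pixel": artifacts["hot_pixel"],
                    "tags": join_tags(tags),
                })

    sset = SpectraSet.from_records(config.grid, records, log=["simulate"])
    truth = pd.DataFrame(truth_rows).set_index("spectrum_id")
    return sset, truth


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

DEFAULT_GRID = WavenumberGrid(400.0, 1800.0, 1024)

# Bands shared by all tissue profiles (phenylalanine ring breathing, CH2
# deformation, amide I) with profile-specific amplitude scaling, plus a few
# distinguishing bands per profile.  Amplitudes are arbitrary intensity units.
_COMMON = ((1004.0, 6.0), (1450.0, 14.0), (1660.0, 16.0))


def _profile(name, common_amps, extra, fluor=8.0, decay=0.002):
    peaks = [PeakSpec(c, w, a) for (c, w), a in zip(_COMMON, common_amps)]
    peaks += [PeakSpec(c, w, a) for (c, w, a) in extra]
    return TissueClassProfile(name, tuple(peaks), fluor, decay)


def default_profiles() -> tuple[TissueClassProfile, ...]:
    """Built-in tissue profiles: necrosis, 8 vital subtypes, gray, white.

    The necrosis profile is spectrally distinct (shifted amide-I weight,
    strong 1340 band); gray/white-matter-like profiles mimic infiltrated and
    peritumoral brain tissue and double as the healthy-control profiles.
    Subtypes 6-8 are deliberately rare entities (bone chips, burnt tissue,
    blood-dominated spots have this role in real cohorts).
    """
    return (
        _profile("necrosis", (2.0, 5.5, 2.5),
                 [(1340.0, 12.0, 5.0), (1745.0, 10.0, 3.5), (720.0, 8.0, 2.0)],
                 fluor=12.0),
        _profile("vital_subtype_1", (4.0, 3.0, 5.0),
                 [(785.0, 8.0, 4.0), (1095.0, 9.0, 3.0)]),
        _profile("vital_subtype_2", (3.0, 4.0, 4.5),
                 [(855.0, 8.0, 3.5), (938.0, 8.0, 2.5)]),
        _profile("vital_subtype_3", (2.5, 5.0, 4.0),
                 [(1265.0, 11.0, 3.5), (1305.0, 9.0, 2.5)]),
        _profile("vital_subtype_4", (3.5, 3.5, 5.5),
                 [(621.0, 7.0, 2.0), (1555.0, 9.0, 3.0)]),
        _profile("vital_subtype_5", (2.0, 4.5, 3.5),
                 [(960.0, 8.0, 4.0), (1130.0, 9.0, 2.0)]),
        _profile("vital_subtype_6", (1.5, 2.5, 2.0),
                 [(590.0, 7.0, 6.0), (1770.0, 8.0, 4.0)], fluor=4.0),
        _profile("vital_subtype_7", (1.0, 2.0, 1.5),
                 [(505.0, 7.0, 6.0), (1610.0, 8.0, 5.0)], fluor=15.0),
        _profile("vital_subtype_8", (2.5, 1.5, 1.0),
                 [(680.0, 7.0, 5.0), (1490.0, 8.0, 4.5)], fluor=6.0),
        _profile("gray", (3.0, 4.0, 6.0),
                 [(1060.0, 9.0, 2.0), (1230.0, 10.0, 3.0)], fluor=9.0),
        _profile("white", (2.5, 6.5, 4.5),
                 [(700.0, 8.0, 3.0), (1078.0, 9.0, 4.0), (1440.0, 8.0, 2.0)],
                 fluor=7.0),
    )


#: mixture of latent profiles within histologically "vital" specimens:
#: 7 abundant entities (5 tumor subtypes + infiltrated gray/white matter)
#: and 3 rare ones.
VITAL_MIXTURE = {
    "white": 0.21, "gray": 0.19,
    "vital_subtype_1": 0.15, "vital_subtype_2": 0.13,
    "vital_subtype_3": 0.12, "vital_subtype_4": 0.10,
    "vital_subtype_5": 0.087,
    "vital_subtype_6": 0.006, "vital_subtype_7": 0.004,
    "vital_subtype_8": 0.003,
}

#: heterogeneous specimens mix necrotic and vital tissue
HETEROGENEOUS_MIXTURE = {"necrosis": 0.30,
                         **{k: round(v * 0.70, 6) for k, v in VITAL_MIXTURE.items()}}
_het_sum = sum(HETEROGENEOUS_MIXTURE.values())
HETEROGENEOUS_MIXTURE["necrosis"] += 1.0 - _het_sum  # exact unit mass


def reference_cohort_config(seed: int = 0) -> CohortConfig:
    """Cohort preset matching the reference study shape.

    43 tumor cases yielding 1456 spectra with class counts 81 necrosis /
    1304 vital / 71 heterogeneous, plus 87 autoptic control spectra
    (55 gray, 32 white matter).
    """
    return CohortConfig(
        grid=DEFAULT_GRID,
        profiles=default_profiles(),
        n_patients_per_class={
            "necrosis": 6, "vital": 33, "heterogeneous": 4,
            "control_gray": 1, "control_white": 1,
        },
        n_spectra_per_class={
            "necrosis": 81, "vital": 1304, "heterogeneous": 71,
            "control_gray": 55, "control_white": 32,
        },
        profile_weights={
            "vital": VITAL_MIXTURE,
            "heterogeneous": HETEROGENEOUS_MIXTURE,
            "control_gray": {"gray": 1.0},
            "control_white": {"white": 1.0},
        },
        infiltration_tag_profiles=("gray", "white"),
        infiltration_tag_prob=0.6,
        hemorrhage_tag_prob=0.05,
        seed=seed,
    )
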