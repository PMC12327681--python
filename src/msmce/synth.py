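"""Synthetic labeled MS runs with the statistical structure the pipeline
assumes: class-specific peak templates, per-spectrum calibration jitter,
log-normal intensity variability, shared background peaks, uniform baseline
noise, retention-time structure and a controllable fraction of sub-threshold
(low-TIC) scans.

Peaks are rendered as point centroids; at 0.1 Da bin width the distinction
from profile-mode traces is immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .ms_io import Run, Spectrum
from .preprocess import (DEFAULT_TIC_THRESHOLD, BinGrid, FeatureMatrix,
                         build_feature_matrix, tic_normalize)
from .training import stratified_file_split

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "generate_dataset", "make_benchmark", "Benchmark",
           "PROFILES"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 2
    files_per_class: int = 3
    spectra_per_file: int = 20
    rt_spacing: float = 1.0
    mz_range: tuple[float, float] = (100.0, 300.0)
    peaks_per_class: int = 30
    shared_peaks: int = 40
    peak_sigma: float = 0.02
    jitter_sd: float = 0.0
    intensity_lognorm_sd: float = 0.3
    baseline_level: float = 0.0
    baseline_peaks: int = 50
    low_tic_fraction: float = 0.0
    template_overlap: float = 0.0  # fraction of class peaks shared across classes
    mean_tic: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "files_per_class", "spectra_per_file",
                     "peaks_per_class"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.low_tic_fraction < 1.0:
            raise ValueError("low_tic_fraction must be in [0, 1)")
        lo, hi = self.mz_range
        if not (0 < lo < hi):
            raise ValueError(f"implausible mz_range {self.mz_range}")


def _class_templates(spec: SyntheticSpec, rng: np.random.Generator):
    """Fixed per-class peak positions and relative intensities."""
    lo, hi = spec.mz_range
    span = hi - lo
    margin = 0.02 * span
    n_common = int(round(spec.template_overlap * spec.peaks_per_class))
    common_mz = rng.uniform(lo + margin, hi - margin, size=n_common)
    templates = []
    for _ in range(spec.n_classes):
        own = rng.uniform(lo + margin, hi - margin,
                          size=spec.peaks_per_class - n_common)
        mz = np.concatenate([common_mz, own])
        rel = rng.lognormal(0.0, 0.5, size=spec.peaks_per_class)
        templates.append((mz, rel))
    if spec.n_classes > 1:
        # crude separability check on 0.1-Da bins
        bins = [set(np.floor(t[0] / 0.1).astype(int)) for t in templates]
        worst = max(len(a & b) / max(len(a), 1)
                    for i, a in enumerate(bins) for b in bins[i + 1:])
        if worst > 0.8:
            logger.warning("class templates overlap heavily (%.0f%%); "
                           "classes may not be separable", 100 * worst)
    shared_mz = rng.uniform(lo + margin, hi - margin, size=spec.shared_peaks)
    shared_rel = rng.lognormal(0.0, 0.5, size=spec.shared_peaks)
    return templates, (shared_mz, shared_rel)


def _draw_spectrum(spec: SyntheticSpec, template, shared, rt: float,
                   rng: np.random.Generator) -> Spectrum:
    lo, hi = spec.mz_range
    tmpl_mz, tmpl_rel = template
    shared_mz, shared_rel = shared
    shift = rng.normal(0.0, spec.jitter_sd) if spec.jitter_sd > 0 else 0.0
    mz = np.concatenate([tmpl_mz, shared_mz]) + shift
    if spec.peak_sigma > 0:
        mz = mz + rng.normal(0.0, spec.peak_sigma, size=mz.size)
    rel = np.concatenate([tmpl_rel, shared_rel])
    inten = rel * rng.lognormal(0.0, spec.intensity_lognorm_sd, size=rel.size)
    if spec.baseline_level > 0 and spec.baseline_peaks > 0:
        # baseline_level is relative to the mean template peak intensity
        noise_mz = rng.uniform(lo, hi, size=spec.baseline_peaks)
        noise_int = rng.uniform(0.0, spec.baseline_level * rel.mean(),
                                size=spec.baseline_peaks)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    keep = (mz > lo) & (mz < hi)
    mz, inten = mz[keep], inten[keep]
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    # merge exact duplicates so m/z stays strictly increasing
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size < mz.size:
        inten = np.bincount(inverse, weights=inten)
        mz = uniq
    scale = spec.mean_tic * rng.lognormal(0.0, 0.2) / inten.sum()
    return Spectrum(mz, inten * scale, rt)


def generate_dataset(spec: SyntheticSpec) -> list[Run]:
    """Deterministic (given ``spec.seed``) list of labeled runs."""
    rng = np.random.default_rng(spec.seed)
    templates, shared = _class_templates(spec, rng)
    runs = []
    for c in range(spec.n_classes):
        label = f"class{c}"
        for f in range(spec.files_per_class):
            spectra = []
            for i in range(spec.spectra_per_file):
                s = _draw_spectrum(spec, templates[c], shared,
                                   rt=i * spec.rt_spacing, rng=rng)
                if spec.low_tic_fraction > 0 and rng.random() < spec.low_tic_fraction:
                    target = rng.uniform(0.05, 0.95) * DEFAULT_TIC_THRESHOLD
                    s = Spectrum(s.mz, s.intensity * (target / s.intensity.sum()), s.rt)
                spectra.append(s)
            runs.append(Run(spectra, label=label, file_id=f"{label}_file{f}"))
    return runs


# --------------------------------------------------------------------------
# Named benchmark profiles
# --------------------------------------------------------------------------

@dataclass
class Benchmark:
    train: FeatureMatrix
    test: FeatureMatrix
    classes: list[str]
    meta: dict

    @property
    def X_train(self) -> np.ndarray:
        return self.train.values

    @property
    def X_test(self) -> np.ndarray:
        return self.test.values

    @property
    def y_train(self) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.classes)}
        return np.array([idx[l] for l in self.train.labels], dtype=np.int64)

    @property
    def y_test(self) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.classes)}
        return np.array([idx[l] for l in self.test.labels], dtype=np.int64)


PROFILES: dict[str, dict] = {
    # 2 well-separated classes, ~200 instances, D ~ 2000 bins
    "easy": dict(
        spec=SyntheticSpec(n_classes=2, files_per_class=5, spectra_per_file=20,
                           mz_range=(100.0, 300.0), peaks_per_class=30,
                           shared_peaks=30, jitter_sd=0.02,
                           intensity_lognorm_sd=0.3, baseline_level=0.1,
                           low_tic_fraction=0.05),
        mode="spidermass",
    ),
    # 4 classes, few files each, half the template peaks shared across classes
    "hard": dict(
        spec=SyntheticSpec(n_classes=4, files_per_class=5, spectra_per_file=15,
                           mz_range=(100.0, 250.0), peaks_per_class=25,
                           shared_peaks=40, jitter_sd=0.04,
                           intensity_lognorm_sd=0.6, baseline_level=0.8,
                           baseline_peaks=80, template_overlap=0.5,
                           low_tic_fraction=0.05),
        mode="spidermass",
    ),
    # high-dimensional raw input sized to destabilise sequence baselines:
    # heavy calibration jitter misaligns raw bins across spectra and most of
    # the template mass is shared between classes
    "collapse-prone": dict(
        spec=SyntheticSpec(n_classes=2, files_per_class=6, spectra_per_file=18,
                           mz_range=(100.0, 509.6), peaks_per_class=25,
                           shared_peaks=60, jitter_sd=0.18, peak_sigma=0.05,
                           intensity_lognorm_sd=0.9, baseline_level=0.8,
                           baseline_peaks=150, template_overlap=0.6,
                           low_tic_fraction=0.05),
        mode="spidermass",
    ),
}


def make_benchmark(profile: str, seed: int = 0) -> Benchmark:
    """Generate a named profile through the real preprocessing pipeline and
    split it at file level into train and hold-out matrices."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; "
                         f"choose from {sorted(PROFILES)}")
    cfg = PROFILES[profile]
    spec: SyntheticSpec = replace(cfg["spec"], seed=seed)
    runs = generate_dataset(spec)
    grid = BinGrid(spec.mz_range[0], spec.mz_range[1], 0.1)
    files = [(r.file_id, r.label) for r in runs]
    train_ids, test_ids = stratified_file_split(files, test_frac=0.10, seed=seed)
    by_id = {r.file_id: r for r in runs}
    train_fm = build_feature_matrix([by_id[i] for i in train_ids], grid,
                                    mode=cfg["mode"])
    test_fm = build_feature_matrix([by_id[i] for i in test_ids], grid,
                                   mode=cfg["mode"])
    train_fm = tic_normalize(train_fm)
    test_fm = tic_normalize(test_fm)
    classes = sorted({r.label for r in runs})
    meta = {"profile": profile, "seed": seed, "mode": cfg["mode"],
            "n_bins": grid.n_bins, "n_train": train_fm.n_instances,
            "n_test": test_fm.n_instances, "classes": classes}
    return Benchmark(train_fm, test_fm, classes, meta)
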