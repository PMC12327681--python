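"""Raw-spectrum preprocessing: TIC filtering, m/z binning, retention-time
window aggregation, feature-matrix assembly and TIC normalization.

Two acquisition modes are supported.  LC-MS runs are binned along m/z and then
aggregated within fixed retention-time windows (elementwise mean over the
spectra falling in each window).  Ambient ("spidermass") runs have no
chromatographic dimension: low-TIC scans are discarded and every retained scan
becomes one instance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ms_io import Run, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "BinGrid", "FeatureMatrix", "tic", "filter_low_tic", "bin_spectrum",
    "aggregate_rt", "build_feature_matrix", "tic_normalize",
    "DEFAULT_BIN_WIDTH", "DEFAULT_RT_WINDOW", "DEFAULT_TIC_THRESHOLD",
]

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_RT_WINDOW = 10.0
DEFAULT_TIC_THRESHOLD = 1e4


@dataclass(frozen=True)
class BinGrid:
    """Half-open m/z bins [mz_min + b*width, mz_min + (b+1)*width)."""

    mz_min: float
    mz_max: float
    width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if self.mz_max <= self.mz_min:
            raise ValueError(f"mz_max ({self.mz_max}) must exceed mz_min ({self.mz_min})")
        if self.width <= 0:
            raise ValueError(f"bin width must be positive, got {self.width}")

    @property
    def n_bins(self) -> int:
        return math.ceil((self.mz_max - self.mz_min) / self.width)

    @property
    def edges(self) -> np.ndarray:
        """Left edges of all bins."""
        return self.mz_min + self.width * np.arange(self.n_bins)


@dataclass
class FeatureMatrix:
    """Instances x m/z-bins matrix with per-row provenance."""

    values: np.ndarray
    labels: list[str]
    file_ids: list[str]
    grid: BinGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n = self.values.shape[0]
        if len(self.labels) != n or len(self.file_ids) != n:
            raise ValueError("labels/file_ids length must match row count")
        if self.values.shape[1] != self.grid.n_bins:
            raise ValueError(
                f"column count {self.values.shape[1]} != grid n_bins {self.grid.n_bins}")
        if np.any(self.values < 0):
            raise ValueError("negative feature values")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        """Tabular export: label and file_id columns, then one column per bin
        named by its left edge.  ``.gz`` suffix triggers compression."""
        df = pd.DataFrame(self.values, columns=[f"{e:.6g}" for e in self.grid.edges])
        df.insert(0, "file_id", self.file_ids)
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: BinGrid | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").astype(str).tolist()
        file_ids = df.pop("file_id").astype(str).tolist()
        edges = np.array([float(c) for c in df.columns])
        if grid is None:
            width = float(edges[1] - edges[0]) if edges.size > 1 else DEFAULT_BIN_WIDTH
            grid = BinGrid(float(edges[0]), float(edges[-1]) + width, width)
        return cls(df.to_numpy(dtype=np.float64), labels, file_ids, grid)


def tic(spectrum: Spectrum) -> float:
    """Total ion count: sum of all intensities (0 for an empty scan)."""
    return float(spectrum.intensity.sum())


def filter_low_tic(run: Run, threshold: float = DEFAULT_TIC_THRESHOLD) -> Run:
    """Drop spectra whose TIC is strictly below ``threshold``."""
    kept = [s for s in run.spectra if tic(s) >= threshold]
    if not kept:
        raise ValueError(f"empty run after TIC filtering: {run.file_id!r}")
    return Run(kept, label=run.label, file_id=run.file_id)


def bin_spectrum(spectrum: Spectrum, grid: BinGrid) -> np.ndarray:
    """Sum peak intensities into the grid's half-open bins; out-of-range
    peaks are dropped."""
    idx = np.floor((spectrum.mz - grid.mz_min) / grid.width).astype(np.int64)
    in_range = (spectrum.mz >= grid.mz_min) & (spectrum.mz < grid.mz_max)
    # guard the rare float edge case where mz < mz_max but idx == n_bins
    in_range &= idx < grid.n_bins
    return np.bincount(idx[in_range], weights=spectrum.intensity[in_range],
                       minlength=grid.n_bins).astype(np.float64)


def aggregate_rt(binned: list[tuple[float, np.ndarray]],
                 window: float = DEFAULT_RT_WINDOW) -> list[np.ndarray]:
    """Average binned spectra within half-open RT windows anchored at the
    first spectrum's retention time; empty windows yield no row."""
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if not binned:
        return []
    t0 = binned[0][0]
    groups: dict[int, list[np.ndarray]] = {}
    for rt, vec in binned:
        groups.setdefault(int(math.floor((rt - t0) / window)), []).append(vec)
    return [np.mean(groups[k], axis=0) for k in sorted(groups)]


def build_feature_matrix(runs: list[Run], grid: BinGrid, mode: str = "lcms",
                         window: float = DEFAULT_RT_WINDOW,
                         tic_threshold: float = DEFAULT_TIC_THRESHOLD) -> FeatureMatrix:
    """Assemble one matrix row per processed instance across all runs.

    ``mode="lcms"``: bin every scan, then aggregate within RT windows.
    ``mode="spidermass"``: TIC-filter, then one row per retained scan.
    """
    if mode not in ("lcms", "spidermass"):
        raise ValueError(f"unknown mode {mode!r}")
    rows, labels, file_ids = [], [], []
    for run in runs:
        if mode == "lcms":
            binned = [(s.rt, bin_spectrum(s, grid)) for s in run.spectra]
            vecs = aggregate_rt(binned, window=window)
        else:
            filtered = filter_low_tic(run, threshold=tic_threshold)
            vecs = [bin_spectrum(s, grid) for s in filtered.spectra]
        if not vecs:
            raise ValueError(f"run {run.file_id!r} produced no instances")
        rows.extend(vecs)
        labels.extend([run.label] * len(vecs))
        file_ids.extend([run.file_id] * len(vecs))
    return FeatureMatrix(np.vstack(rows), labels, file_ids, grid)


def tic_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each row by its sum (relative abundance).  All-zero rows are
    left untouched with a warning."""
    sums = matrix.values.sum(axis=1)
    zero = sums == 0
    if np.any(zero):
        logger.warning("tic_normalize: %d all-zero rows left unnormalized",
                       int(zero.sum()))
    safe = np.where(zero, 1.0, sums)
    return FeatureMatrix(matrix.values / safe[:, None], list(matrix.labels),
                         list(matrix.file_ids), matrix.grid)
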