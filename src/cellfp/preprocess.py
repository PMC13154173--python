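"""Raw spectra -> normalized, scaled feature matrix.

The chain is fixed: clip/mask -> 0.04-ppm bucketing -> probabilistic
quotient normalization (PQN) -> per-feature standard scaling, with the
scaler fitted on training rows only.  With the default clip limits
(-0.1 to 8.6 ppm) and the water region retained as zeroed buckets, the grid
has exactly floor(8.7 / 0.04) = 217 features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .io import FeatureMatrix, SpectraSet, Spectrum

logger = logging.getLogger(__name__)


@dataclass
class PreprocessSpec:
    keep_low_ppm: float = -0.1
    keep_high_ppm: float = 8.6
    mask_ranges: list[tuple[float, float]] = field(default_factory=lambda: [(4.6, 5.1)])
    bucket_width_ppm: float = 0.04
    bucket_stat: str = "area"        # {"area", "mean"}
    water_buckets: str = "retain_zeroed"  # {"retain_zeroed", "drop"}

    def __post_init__(self) -> None:
        if self.keep_low_ppm >= self.keep_high_ppm:
            raise ValueError("keep_low_ppm must be below keep_high_ppm")
        if self.bucket_width_ppm <= 0:
            raise ValueError("bucket_width_ppm must be positive")
        if self.bucket_stat not in ("area", "mean"):
            raise ValueError(f"unknown bucket_stat {self.bucket_stat!r}")
        if self.water_buckets not in ("retain_zeroed", "drop"):
            raise ValueError(f"unknown water_buckets {self.water_buckets!r}")
        self.mask_ranges = [tuple(sorted(r)) for r in self.mask_ranges]


def n_buckets(spec: PreprocessSpec) -> int:
    """Bucket count is a pure function of the kept range and the width."""
    span = spec.keep_high_ppm - spec.keep_low_ppm
    full = int(math.floor(span / spec.bucket_width_ppm + 1e-9))
    if spec.water_buckets == "drop":
        uppers = spec.keep_high_ppm - spec.bucket_width_ppm * np.arange(full)
        keep = ~_fully_masked(uppers, uppers - spec.bucket_width_ppm, spec.mask_ranges)
        return int(keep.sum())
    return full


def _fully_masked(uppers: np.ndarray, lowers: np.ndarray,
                  mask_ranges: Sequence[tuple[float, float]]) -> np.ndarray:
    out = np.zeros(uppers.shape, dtype=bool)
    tol = 1e-9
    for lo, hi in mask_ranges:
        out |= (lowers >= lo - tol) & (uppers <= hi + tol)
    return out


def clip_and_mask(spectrum: Spectrum, spec: PreprocessSpec) -> Spectrum:
    """Remove points outside the kept range and blank the masked regions.

    With ``water_buckets='retain_zeroed'`` masked points are set to zero so
    the bucket grid stays contiguous; with ``'drop'`` they are removed.
    """
    ppm, y = spectrum.ppm, spectrum.intensities.copy()
    if ppm.min() > spec.keep_low_ppm or ppm.max() < spec.keep_high_ppm:
        raise ValueError(
            f"grid [{ppm.min():.3f}, {ppm.max():.3f}] does not cover the kept "
            f"range [{spec.keep_low_ppm}, {spec.keep_high_ppm}]")
    keep = (ppm >= spec.keep_low_ppm) & (ppm <= spec.keep_high_ppm)
    masked = np.zeros_like(keep)
    for lo, hi in spec.mask_ranges:
        masked |= (ppm > lo) & (ppm < hi)
    if spec.water_buckets == "retain_zeroed":
        y = np.where(masked, 0.0, y)
    else:
        keep &= ~masked
    return Spectrum(ppm[keep], y[keep], spectrum.sample_id)


def bucket(spectrum: Spectrum, spec: PreprocessSpec) -> FeatureMatrix:
    """Integrate a clipped spectrum over uniform half-open ppm buckets.

    The grid starts at ``keep_high_ppm`` and steps down by the bucket width;
    a trailing partial bucket is dropped.  ``bucket_stat='area'`` integrates
    the linear interpolant exactly (trapezoid rule); ``'mean'`` averages the
    grid points falling in the half-open interval [upper, lower).
    """
    span = spec.keep_high_ppm - spec.keep_low_ppm
    full = int(math.floor(span / spec.bucket_width_ppm + 1e-9))
    if full < 1:
        raise ValueError("bucket width larger than the kept range")
    uppers = spec.keep_high_ppm - spec.bucket_width_ppm * np.arange(full)
    lowers = uppers - spec.bucket_width_ppm

    ppm_desc, y_desc = spectrum.ppm, spectrum.intensities
    x = ppm_desc[::-1]          # ascending for integration
    y = y_desc[::-1]

    if spec.bucket_stat == "area":
        # cumulative integral once, bucket area by interpolation at the edges
        cum = np.concatenate([[0.0], cumulative_trapezoid(y, x)])
        edges_lo = np.interp(lowers, x, cum)
        edges_hi = np.interp(uppers, x, cum)
        values = edges_hi - edges_lo
    else:
        values = np.empty(full)
        for i in range(full):
            inside = (ppm_desc <= uppers[i] + 1e-12) & (ppm_desc > lowers[i] + 1e-12)
            values[i] = y_desc[inside].mean() if inside.any() else 0.0

    if spec.water_buckets == "drop":
        keep = ~_fully_masked(uppers, lowers, spec.mask_ranges)
        uppers, lowers, values = uppers[keep], lowers[keep], values[keep]

    centers = (uppers + lowers) / 2.0
    edges = np.column_stack([uppers, lowers])
    return FeatureMatrix(values[None, :], centers, edges, [spectrum.sample_id], "raw")


def bucket_spectra(spectra_set: SpectraSet, spec: PreprocessSpec) -> FeatureMatrix:
    """Clip, mask and bucket every spectrum of a set into one matrix."""
    rows, ids = [], []
    centers = edges = None
    for s in spectra_set:
        fm = bucket(clip_and_mask(s, spec), spec)
        rows.append(fm.values[0])
        ids.append(s.sample_id)
        centers, edges = fm.bucket_centers, fm.bucket_edges
    if centers is None:
        raise ValueError("empty spectra set")
    return FeatureMatrix(np.vstack(rows), centers, edges, ids, "raw")


@dataclass
class PQNResult:
    normalized: FeatureMatrix
    reference_spectrum: np.ndarray
    quotient_medians: np.ndarray


def pqn(matrix: FeatureMatrix) -> PQNResult:
    """Probabilistic quotient normalization against the median spectrum.

    The per-bucket median over samples, rescaled to unit mean, is the
    reference; each sample is divided by the median of its bucket-wise
    quotients against that reference (buckets with reference at machine
    scale or negative sample values are excluded).  The unit-mean reference
    makes the result invariant to any global positive rescaling of the
    input; the quotient medians are the per-sample dilution estimates.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("PQN needs at least two samples")
    ref = np.median(X, axis=0)
    scale = ref.mean()
    if not np.any(np.abs(ref) > 0) or scale <= 0:
        raise ValueError("reference (median) spectrum is all-zero or non-positive")
    ref = ref / scale
    eps = np.finfo(float).eps * float(np.max(np.abs(ref))) * X.shape[1]
    usable_ref = ref > eps
    medians = np.empty(X.shape[0])
    for i, row in enumerate(X):
        use = usable_ref & (row > 0)
        if not use.any():
            raise ValueError(f"sample {matrix.sample_ids[i]!r} has no usable buckets for PQN")
        medians[i] = np.median(row[use] / ref[use])
    normalized = matrix.with_values(X / medians[:, None], state="pqn")
    return PQNResult(normalized, ref, medians)


@dataclass
class ScalerState:
    means: np.ndarray
    sds: np.ndarray
    zero_variance: np.ndarray


def fit_scaler(train: FeatureMatrix) -> ScalerState:
    """Learn per-bucket means/sds on training rows only."""
    X = train.values
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    floor = max(1e-12, 1e-12 * float(np.max(np.abs(X), initial=1.0)))
    zero_var = sds <= floor
    if zero_var.any():
        logger.warning("%d zero-variance bucket(s) pass through as 0 after scaling",
                       int(zero_var.sum()))
    sds = np.where(zero_var, 1.0, sds)
    return ScalerState(means, sds, zero_var)


def apply_scaler(state: ScalerState, matrix: FeatureMatrix) -> FeatureMatrix:
    Z = (matrix.values - state.means) / state.sds
    Z[:, state.zero_variance] = 0.0  # carries no training information
    return matrix.with_values(Z, state="scaled")


def preprocess(spectra_set: SpectraSet, spec: PreprocessSpec | None = None) -> PQNResult:
    """clip/mask -> bucket -> PQN; scaling is applied separately on splits."""
    if spec is None:
        spec = PreprocessSpec()
    return pqn(bucket_spectra(spectra_set, spec))
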