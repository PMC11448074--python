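"""Spectral preprocessing chain for linear-mode MALDI-TOF profiles.

The chain is fixed in this order, with each spectrum carrying its processing
state so out-of-order application raises:

1. square-root transform (variance stabilization),
2. SNIP baseline estimation and subtraction,
3. total-ion-current (TIC) normalization,
4. SNR-based peak detection,
5. cross-spectrum peak binning,
6. feature-matrix construction (spectra x binned peak intensities).

SNIP (statistics-sensitive nonlinear iterative peak clipping) estimates the
baseline by iteratively replacing each point with the minimum of itself and
the mean of its two neighbours at distance *i*; the decreasing-window variant
(window from ``iterations`` down to 1) is the default because it distorts
peak flanks less than the increasing schedule.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.stats import median_abs_deviation

from .spectrum import PeakList, Spectrum

logger = logging.getLogger(__name__)

def _snip_passes_numpy(
    y: np.ndarray, windows: np.ndarray, max_passes: int, tol: float
) -> np.ndarray:
    for _ in range(max_passes):
        previous = y.copy()
        for i in windows:
            mid = 0.5 * (y[..., : -2 * i] + y[..., 2 * i :])
            np.minimum(y[..., i:-i], mid, out=y[..., i:-i])
        if np.max(np.abs(y - previous)) <= tol:
            break
    return y


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable knobs of the preprocessing chain, with conventional defaults."""

    snip_iterations: int = 100
    snip_decreasing: bool = True
    snr_threshold: float = 3.0
    half_window: int = 20
    bin_tolerance: float = 0.002
    fill: str = "interpolate"  # or "zero"
    smooth_half_window: int = 0  # moving-average smoother, off by default


def sqrt_transform(s: Spectrum) -> Spectrum:
    """Elementwise square root; the first step of the chain."""
    s.require_state("raw", "sqrt_transform")
    if np.any(s.intensity < 0):
        raise ValueError("raw intensities must be non-negative")
    return s.advanced("sqrt", np.sqrt(s.intensity))


def smooth(s: Spectrum, half_window: int) -> Spectrum:
    """Optional centred moving-average smoother (state-preserving)."""
    if half_window < 1:
        return s
    kernel = np.ones(2 * half_window + 1) / (2 * half_window + 1)
    pad = np.pad(s.intensity, half_window, mode="edge")
    y = np.convolve(pad, kernel, mode="valid")
    return s.advanced(s.current_state, y)


def snip_baseline(
    s: Spectrum | np.ndarray,
    iterations: int = 100,
    decreasing: bool = True,
    max_passes: int = 50,
    tol: float = 1e-12,
) -> np.ndarray:
    """SNIP baseline estimate of a spectrum (or a stack of spectra, last axis).

    For window ``i`` the clipping step is
    ``y_k <- min(y_k, (y_{k-i} + y_{k+i}) / 2)`` over interior points, with
    boundary points held fixed.  The window schedule (decreasing from
    ``iterations`` to 1 by default) is repeated until the estimate stops
    changing (a fixed point, typically reached within ~20 passes), so the
    returned baseline never exceeds the input and a further application
    leaves it unchanged.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y = np.array(s.intensity if isinstance(s, Spectrum) else s, dtype=float)
    n = y.shape[-1]
    max_window = (n - 1) // 2
    if iterations > max_window:
        logger.warning(
            "SNIP iterations %d exceed half the spectrum length; clamped to %d",
            iterations,
            max_window,
        )
        iterations = max_window
    windows = (
        np.arange(iterations, 0, -1) if decreasing else np.arange(1, iterations + 1)
    )
    return _snip_passes_numpy(y, windows, max_passes, tol)


def subtract_baseline(s: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Subtract a baseline estimate, flooring at zero."""
    s.require_state("sqrt", "subtract_baseline")
    baseline = np.asarray(baseline, float)
    if baseline.shape != s.intensity.shape:
        raise ValueError(
            f"baseline length {baseline.size} does not match spectrum length {s.intensity.size}"
        )
    return s.advanced("baseline_subtracted", np.clip(s.intensity - baseline, 0.0, None))


def tic_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities so the total ion current (sum over points) equals 1."""
    s.require_state("baseline_subtracted", "tic_normalize")
    total = float(s.intensity.sum())
    if total <= 0:
        raise ValueError("cannot TIC-normalize a spectrum with zero total intensity")
    return s.advanced("tic_normalized", s.intensity / total)


def estimate_noise(s: Spectrum | np.ndarray) -> float:
    """Robust noise level: median absolute deviation scaled by 1.4826."""
    y = s.intensity if isinstance(s, Spectrum) else np.asarray(s, float)
    return float(median_abs_deviation(y, scale="normal"))


def detect_peaks(
    s: Spectrum,
    snr_threshold: float = 3.0,
    half_window: int = 20,
) -> PeakList:
    """Detect local maxima over +-half_window whose SNR meets the threshold.

    SNR is apex intensity over the spectrum's MAD noise level.  With a zero
    noise estimate (noise-free synthetic input) any non-flat local maximum
    qualifies and its SNR is reported as infinity.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    s.require_state("tic_normalized", "detect_peaks")
    y = s.intensity
    size = 2 * half_window + 1
    noise = estimate_noise(s)
    is_max = y == maximum_filter1d(y, size=size, mode="nearest")
    not_flat = y > minimum_filter1d(y, size=size, mode="nearest")
    threshold = snr_threshold * noise
    candidates = np.flatnonzero(is_max & not_flat & (y >= threshold) & (y > 0))

    # collapse plateau runs (consecutive indices of equal height) to their centre
    kept: list[int] = []
    run_start = None
    prev = None
    for idx in candidates:
        if run_start is None:
            run_start = prev = idx
        elif idx == prev + 1 and y[idx] == y[run_start]:
            prev = idx
        else:
            kept.append((run_start + prev) // 2)
            run_start = prev = idx
    if run_start is not None:
        kept.append((run_start + prev) // 2)

    idx = np.asarray(kept, dtype=int)
    snr = y[idx] / noise if noise > 0 else np.full(idx.size, np.inf)
    return PeakList(
        mz=s.mz[idx],
        intensity=y[idx],
        snr=snr,
        source_spectrum_id=s.spectrum_id,
    )


def _split_bins(mz_sorted: np.ndarray, lo: int, hi: int, tol: float, edges: list[int]) -> None:
    """Recursive divisive binning: split at the largest gap until within tolerance."""
    seg = mz_sorted[lo:hi]
    ref = seg.mean()
    if np.max(np.abs(seg - ref)) <= tol * ref or hi - lo == 1:
        edges.append(hi)
        return
    gaps = np.diff(seg)
    cut = lo + int(np.argmax(gaps)) + 1
    _split_bins(mz_sorted, lo, cut, tol, edges)
    _split_bins(mz_sorted, cut, hi, tol, edges)


def bin_peaks(
    peaklists: Sequence[PeakList],
    tolerance: float = 0.002,
) -> tuple[list[PeakList], np.ndarray]:
    """Group peaks across spectra into shared m/z bins (divisive strict binning).

    All peak m/z values are pooled and sorted, then recursively split at the
    largest gap until every member of a bin deviates from the bin reference
    (the mean member m/z) by at most ``tolerance`` (relative).  Member m/z
    values are reassigned the bin reference; the procedure is deterministic
    and independent of spectrum order.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    sizes = [len(pl) for pl in peaklists]
    all_mz = np.concatenate([pl.mz for pl in peaklists]) if peaklists else np.array([])
    if all_mz.size == 0:
        return [
            PeakList(np.array([]), np.array([]), np.array([]), pl.source_spectrum_id)
            for pl in peaklists
        ], np.array([])

    order = np.argsort(all_mz, kind="stable")
    mz_sorted = all_mz[order]
    edges: list[int] = []
    _split_bins(mz_sorted, 0, mz_sorted.size, tolerance, edges)

    refs = []
    bin_of_sorted = np.empty(mz_sorted.size, dtype=int)
    lo = 0
    for b, hi in enumerate(edges):
        refs.append(mz_sorted[lo:hi].mean())
        bin_of_sorted[lo:hi] = b
        lo = hi
    refs_arr = np.asarray(refs)

    bin_of_peak = np.empty(all_mz.size, dtype=int)
    bin_of_peak[order] = bin_of_sorted

    binned: list[PeakList] = []
    start = 0
    for pl, size in zip(peaklists, sizes):
        bins = bin_of_peak[start : start + size]
        start += size
        # a spectrum contributing two peaks to one bin keeps the stronger one
        uniq, inverse = np.unique(bins, return_inverse=True)
        intensity = np.zeros(uniq.size)
        snr = np.zeros(uniq.size)
        np.maximum.at(intensity, inverse, pl.intensity)
        np.maximum.at(snr, inverse, pl.snr)
        binned.append(
            PeakList(
                mz=refs_arr[uniq],
                intensity=intensity,
                snr=snr,
                source_spectrum_id=pl.source_spectrum_id,
            )
        )
    return binned, refs_arr


@dataclass
class FeatureMatrix:
    """Spectra x binned-peak intensity table, the classifier input.

    ``intensities`` holds one row per spectrum and one column per bin
    reference m/z; ``detected`` flags which cells come from an actually
    detected peak (pre-fill); ``labels`` carries the class per row when known.
    """

    intensities: pd.DataFrame
    detected: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.intensities.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")
        cols = np.asarray(self.intensities.columns, dtype=float)
        if cols.size > 1 and np.any(np.diff(cols) <= 0):
            raise ValueError("bin m/z columns must be strictly increasing")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.intensities.index)

    @property
    def spectrum_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def bin_mz(self) -> np.ndarray:
        return np.asarray(self.intensities.columns, dtype=float)

    def subset(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            intensities=self.intensities.loc[list(ids)],
            detected=self.detected.loc[list(ids)],
            labels=None if self.labels is None else self.labels.loc[list(ids)],
        )

    def with_labels(self, labels: pd.Series) -> "FeatureMatrix":
        return FeatureMatrix(self.intensities, self.detected, labels)

    def to_tsv(self, path: str | Path, config_hash: str | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if config_hash:
                fh.write(f"# config_hash={config_hash}\n")
            out = self.intensities.copy()
            out.columns = [f"{c:.1f}" for c in self.bin_mz]
            out.index.name = "spectrum_id"
            out.to_csv(fh, sep="\t", float_format="%.6g")


def read_feature_matrix(
    path: str | Path, labels: pd.Series | None = None
) -> FeatureMatrix:
    """Read a feature matrix written by :meth:`FeatureMatrix.to_tsv`.

    The TSV does not carry the pre-fill detection mask; cells with non-zero
    intensity are treated as detected, which is exact under zero-fill and an
    approximation under interpolation fill.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col="spectrum_id")
    df.columns = [float(c) for c in df.columns]
    return FeatureMatrix(intensities=df, detected=df > 0, labels=labels)


def build_feature_matrix(
    binned: Sequence[PeakList],
    spectra: Sequence[Spectrum],
    bin_refs: np.ndarray,
    fill: str = "interpolate",
    labels: pd.Series | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix from binned peak lists.

    Cells without a detected peak are filled either by linear interpolation of
    the spectrum's preprocessed intensity at the bin m/z (default) or with
    zero.  Bin references outside a spectrum's mass range are zero-filled
    with a warning.
    """
    if fill not in ("interpolate", "zero"):
        raise ValueError(f"unknown fill policy {fill!r}")
    if len(binned) != len(spectra):
        raise ValueError("need one peak list per spectrum")
    bin_refs = np.asarray(bin_refs, dtype=float)
    ids = []
    rows = np.zeros((len(spectra), bin_refs.size))
    det = np.zeros((len(spectra), bin_refs.size), dtype=bool)
    for r, (pl, s) in enumerate(zip(binned, spectra)):
        if pl.source_spectrum_id and s.spectrum_id and pl.source_spectrum_id != s.spectrum_id:
            raise ValueError(
                f"peak list {pl.source_spectrum_id!r} does not match spectrum {s.spectrum_id!r}"
            )
        ids.append(s.spectrum_id or f"spectrum_{r}")
        if fill == "interpolate":
            rows[r] = np.interp(bin_refs, s.mz, s.intensity)
        out_of_range = (bin_refs < s.mz[0]) | (bin_refs > s.mz[-1])
        if np.any(out_of_range):
            warnings.warn(
                f"{int(out_of_range.sum())} bin(s) outside the mass range of "
                f"spectrum {s.spectrum_id!r}; zero-filled",
                stacklevel=2,
            )
            rows[r, out_of_range] = 0.0
        if len(pl):
            cols = np.searchsorted(bin_refs, pl.mz)
            if np.any(cols >= bin_refs.size) or np.any(bin_refs[cols] != pl.mz):
                raise ValueError("binned peak m/z not found among bin references")
            rows[r, cols] = pl.intensity
            det[r, cols] = True
    intensities = pd.DataFrame(rows, index=ids, columns=bin_refs)
    detected = pd.DataFrame(det, index=ids, columns=bin_refs)
    return FeatureMatrix(intensities=intensities, detected=detected, labels=labels)


def preprocess_spectrum(s: Spectrum, params: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Run sqrt -> SNIP -> subtract -> TIC on one raw spectrum."""
    s = sqrt_transform(s)
    if params.smooth_half_window > 0:
        s = smooth(s, params.smooth_half_window)
    baseline = snip_baseline(s, params.snip_iterations, params.snip_decreasing)
    s = subtract_baseline(s, baseline)
    return tic_normalize(s)


def preprocess_cohort(
    spectra: Sequence[Spectrum],
    params: PreprocessParams = PreprocessParams(),
    labels: pd.Series | None = None,
) -> tuple[FeatureMatrix, list[Spectrum], list[PeakList]]:
    """Full chain over a cohort: per-spectrum preprocessing, detection, binning, matrix."""
    processed = [preprocess_spectrum(s, params) for s in spectra]
    peaklists = [
        detect_peaks(s, params.snr_threshold, params.half_window) for s in processed
    ]
    binned, refs = bin_peaks(peaklists, params.bin_tolerance)
    features = build_feature_matrix(binned, processed, refs, fill=params.fill, labels=labels)
    logger.info(
        "preprocessed %d spectra -> %d peak bins (%.1f mean peaks/spectrum)",
        len(spectra),
        refs.size,
        float(np.mean([len(p) for p in peaklists])) if peaklists else math.nan,
    )
    return features, processed, peaklists
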