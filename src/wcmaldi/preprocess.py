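"""Raw spectra → binned feature matrix.

The chain mirrors standard whole-cell MALDI biotyping practice:

1. TIC normalization (every spectrum sums to a common target),
2. Top-Hat baseline subtraction (morphological opening with a flat
   structuring element),
3. peak picking as strict local maxima with a signal-to-noise cutoff
   (default SNR > 5, half window 20 points),
4. binning of the pooled peak lists at a relative m/z tolerance
   (default 0.002) into a single samples × features matrix.

Absent peaks are stored as 0, which the downstream variance filter and
concentration-response fits require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DataError
from .spectra_io import SampleSheet, Spectrum

logger = logging.getLogger(__name__)


@dataclass
class PeakList:
    """Picked peaks of one spectrum: centroid m/z, height, and SNR."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (len(self.mz) == len(self.intensity) == len(self.snr)):
            raise DataError("PeakList arrays differ in length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise DataError("PeakList m/z must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class FeatureMatrix:
    """Samples × binned-m/z intensity table plus the sample sheet.

    ``features`` holds bin-center m/z values (strictly increasing);
    ``intensities`` is non-negative with 0 marking an absent peak; row order
    matches ``sample_ids`` and, when present, the sheet's row order.
    """

    features: np.ndarray
    intensities: np.ndarray
    sample_ids: list
    sheet: SampleSheet | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.sample_ids), len(self.features)):
            raise DataError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.features)} features"
            )
        if len(self.features) > 1 and not np.all(np.diff(self.features) > 0):
            raise DataError("feature m/z must be strictly increasing")
        if np.any(self.intensities < 0):
            raise DataError("feature intensities must be non-negative")
        if self.sheet is not None and self.sheet.sample_ids != list(self.sample_ids):
            self.sheet = self.sheet.reindex(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.intensities,
            index=list(self.sample_ids),
            columns=[f"{m:.4f}" for m in self.features],
        ).rename_axis("sample_id")

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def tic_normalize(s: Spectrum, target: float = 1.0) -> Spectrum:
    """Scale intensities so the total ion current equals ``target``."""
    if target <= 0:
        raise DataError("TIC target must be positive")
    tic = s.tic
    if tic <= 0:
        raise DataError(f"spectrum {s.sample_id!r} has non-positive TIC")
    return Spectrum(s.mz, s.intensity * (target / tic), s.sample_id, dict(s.metadata))


def tophat_baseline(s: Spectrum, half_window: int = 75):
    """Top-Hat baseline: morphological opening with a flat structuring element.

    Returns ``(baseline, corrected)`` where the baseline is grey-scale
    erosion followed by dilation over ``2*half_window + 1`` points, which
    never exceeds the signal, and ``corrected`` clips the difference at 0.
    """
    if half_window < 1:
        raise DataError("half_window must be >= 1")
    if len(s) <= 2 * half_window:
        raise DataError(
            f"spectrum length {len(s)} too short for half_window {half_window}"
        )
    size = 2 * half_window + 1
    baseline = ndimage.grey_opening(s.intensity, size=size, mode="reflect")
    corrected = np.maximum(s.intensity - baseline, 0.0)
    return baseline, Spectrum(s.mz, corrected, s.sample_id, dict(s.metadata))


def estimate_noise(s: Spectrum, half_window: int = 20, floor: float | None = None) -> np.ndarray:
    """Local noise curve for SNR computation.

    Running median of the absolute (baseline-corrected) intensity over
    ``2*half_window + 1`` points, scaled by 1.4826 for consistency with a
    Gaussian standard deviation. A positive floor (default
    ``1e-12 × max intensity``) keeps the curve strictly positive; SNR at
    index ``i`` is ``intensity[i] / noise[i]``.
    """
    size = 2 * half_window + 1
    med = ndimage.median_filter(np.abs(s.intensity), size=size, mode="reflect")
    noise = 1.4826 * med
    if floor is None:
        peak = float(np.max(s.intensity, initial=0.0))
        floor = 1e-12 * peak if peak > 0 else np.finfo(float).tiny
    return np.maximum(noise, floor)


def pick_peaks(
    s: Spectrum,
    snr_min: float = 5.0,
    half_window: int = 20,
    noise: np.ndarray | None = None,
) -> PeakList:
    """Pick strict local maxima with SNR above ``snr_min``.

    A point is a peak when it is the unique maximum within ±``half_window``
    points and its intensity divided by the local noise exceeds ``snr_min``.
    Centroid m/z and height are taken at the maximum point. When two maxima
    fall inside one window, only the larger survives.
    """
    y = s.intensity
    if noise is None:
        noise = estimate_noise(s, half_window=half_window)
    size = 2 * half_window + 1
    local_max = ndimage.maximum_filter1d(y, size=size, mode="reflect")
    candidates = np.flatnonzero((y == local_max) & (y > 0))
    keep = []
    n = len(y)
    for i in candidates:
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        window = y[lo:hi]
        # strictness: the maximum must be attained once only in its window
        if np.count_nonzero(window == y[i]) == 1 and y[i] / noise[i] > snr_min:
            keep.append(i)
    idx = np.asarray(keep, dtype=int)
    return PeakList(s.mz[idx], y[idx], y[idx] / noise[idx], sample_id=s.sample_id)


def bin_peaks(lists, tolerance: float = 0.002) -> FeatureMatrix:
    """Greedy hierarchical binning of pooled peak lists.

    The pooled, m/z-sorted peak set is recursively split at its largest
    internal gap until every bin satisfies
    ``(max - min) / mean <= tolerance`` and contains at most one peak per
    sample. Bin center = mean member m/z; matrix cell = member peak height
    (0 when the sample is absent from the bin).
    """
    lists = [pl for pl in lists]
    if not lists or all(len(pl) == 0 for pl in lists):
        raise DataError("bin_peaks requires at least one non-empty peak list")
    sample_ids = [pl.sample_id for pl in lists]
    mz_all, int_all, who = [], [], []
    for si, pl in enumerate(lists):
        mz_all.append(pl.mz)
        int_all.append(pl.intensity)
        who.append(np.full(len(pl), si))
    mz_all = np.concatenate(mz_all)
    int_all = np.concatenate(int_all)
    who = np.concatenate(who)
    order = np.argsort(mz_all, kind="stable")
    mz_all, int_all, who = mz_all[order], int_all[order], who[order]

    bins: list[tuple[int, int]] = []

    def split(lo: int, hi: int) -> None:  # [lo, hi)
        if hi - lo <= 1:
            bins.append((lo, hi))
            return
        seg = mz_all[lo:hi]
        width_ok = (seg[-1] - seg[0]) / np.mean(seg) <= tolerance
        unique_ok = len(np.unique(who[lo:hi])) == hi - lo
        if width_ok and unique_ok:
            bins.append((lo, hi))
            return
        gaps = np.diff(seg)
        cut = int(np.argmax(gaps)) + 1
        if gaps[cut - 1] <= 0:  # all-identical m/z: split in the middle
            cut = (hi - lo) // 2
        split(lo, lo + cut)
        split(lo + cut, hi)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(mz_all) + 100))
    try:
        split(0, len(mz_all))
    finally:
        sys.setrecursionlimit(old_limit)

    bins.sort()
    centers = np.array([np.mean(mz_all[lo:hi]) for lo, hi in bins])
    matrix = np.zeros((len(lists), len(bins)))
    for b, (lo, hi) in enumerate(bins):
        matrix[who[lo:hi], b] = int_all[lo:hi]
    return FeatureMatrix(centers, matrix, sample_ids)


@dataclass
class PreprocessConfig:
    """Stage parameters for the preprocessing chain."""

    tic_target: float = 1.0
    baseline_half_window: int = 75
    peak_half_window: int = 20
    snr_min: float = 5.0
    bin_tolerance: float = 0.002

    def validate(self) -> None:
        from .errors import ConfigError

        if self.tic_target <= 0:
            raise ConfigError("tic_target must be positive")
        if self.baseline_half_window < 1 or self.peak_half_window < 1:
            raise ConfigError("half windows must be >= 1")
        if self.snr_min < 0:
            raise ConfigError("snr_min must be non-negative")
        if self.bin_tolerance <= 0:
            raise ConfigError("bin_tolerance must be positive")


def preprocess_spectrum(s: Spectrum, config: PreprocessConfig | None = None) -> PeakList:
    """TIC-normalize, baseline-subtract and peak-pick a single spectrum."""
    config = config or PreprocessConfig()
    s = tic_normalize(s, target=config.tic_target)
    _baseline, corrected = tophat_baseline(s, half_window=config.baseline_half_window)
    return pick_peaks(
        corrected, snr_min=config.snr_min, half_window=config.peak_half_window
    )


def preprocess_pipeline(spectra, sheet: SampleSheet, config: PreprocessConfig | None = None) -> FeatureMatrix:
    """Full chain over an iterable of spectra, returning a FeatureMatrix.

    Spectra are consumed one at a time (iterables are not materialized), so
    large simulated datasets can stream through. Rows of the result follow
    the sample-sheet order regardless of input order.
    """
    config = config or PreprocessConfig()
    config.validate()
    peak_lists = []
    for s in spectra:
        sheet.row(s.sample_id)  # raises if uncovered
        pl = preprocess_spectrum(s, config)
        logger.debug("sample %s: %d peaks", s.sample_id, len(pl))
        peak_lists.append(pl)
    if not peak_lists:
        raise DataError("no spectra supplied")
    fm = bin_peaks(peak_lists, tolerance=config.bin_tolerance)
    order = [fm.sample_ids.index(sid) for sid in sheet.sample_ids if sid in fm.sample_ids]
    if len(order) != fm.n_samples:
        raise DataError("sample sheet does not cover all spectra")
    fm = FeatureMatrix(
        fm.features,
        fm.intensities[order],
        [fm.sample_ids[i] for i in order],
        sheet=sheet,
    )
    logger.info(
        "feature matrix: %d samples × %d features", fm.n_samples, fm.n_features
    )
    return fm
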