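"""Multivariate fingerprint evaluation.

Square-root variance stabilization, PCA by singular value decomposition
(centering only, no unit-variance scaling), a cluster-separation score
``j_overlap``, a matrix-suppression score ``mse_mod``, and spot-to-spot
repeatability R².

``j_overlap`` and ``mse_mod`` are this package's own operational
definitions, chosen for monotone agreement with their intended use
(ranking preparation protocols); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .preprocess import FeatureMatrix
from .spectra_io import Spectrum

#: Common positive-mode ions of the DHB (2,5-dihydroxybenzoic acid) matrix:
#: [DHB+H-H2O]+, [DHB]+., [DHB+H]+, [DHB+Na]+, [DHB+K]+, [2DHB+H-2H2O]+,
#: [2DHB+H-H2O]+. User-overridable via MatrixIonSet.
DEFAULT_DHB_IONS = (
    137.0233,
    154.0261,
    155.0339,
    177.0158,
    192.9898,
    273.0394,
    291.0499,
)


@dataclass
class MatrixIonSet:
    """m/z values attributed to the MALDI matrix, with a relative tolerance."""

    mz_list: tuple = DEFAULT_DHB_IONS
    tolerance: float = 0.002

    def __post_init__(self) -> None:
        self.mz_list = tuple(float(m) for m in self.mz_list)
        if not self.mz_list:
            raise DataError("matrix ion set must not be empty")
        if self.tolerance <= 0:
            raise DataError("matrix ion tolerance must be positive")


@dataclass
class PcaResult:
    """PCA scores, loadings and per-component explained-variance fractions."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray


def sqrt_transform(fm: FeatureMatrix) -> FeatureMatrix:
    """Element-wise square root of the intensity matrix; metadata untouched."""
    if np.any(fm.intensities < 0):
        raise DataError("negative intensity cell; sqrt transform undefined")
    return FeatureMatrix(fm.features, np.sqrt(fm.intensities), list(fm.sample_ids), fm.sheet)


def pca(fm: FeatureMatrix, n_components: int) -> PcaResult:
    """PCA via SVD of the column-centered intensity matrix (no scaling).

    ``scores = U·S`` and ``loadings = V`` truncated to ``n_components``;
    explained-variance fractions are squared singular values over the total
    centered sum of squares.
    """
    X = fm.intensities
    n, p = X.shape
    if n < 2:
        raise DataError("PCA requires at least 2 samples")
    if n_components > min(n - 1, p) or n_components < 1:
        raise DataError(
            f"n_components={n_components} exceeds min(samples-1, features)="
            f"{min(n - 1, p)}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    k = n_components
    return PcaResult(U[:, :k] * s[:k], Vt[:k].T, frac[:k])


def j_overlap(scores: np.ndarray, labels) -> float:
    """Between/within scatter ratio of labeled groups in score space.

    ``J = trace(S_between) / trace(S_within)`` where ``S_within`` sums
    squared deviations from each group mean and ``S_between`` sums
    group-size-weighted squared deviations of group means from the grand
    mean. Higher = better separated; invariant to rigid rotation.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(labels):
        raise DataError("scores rows and labels differ in length")
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise DataError("j_overlap requires at least 2 groups")
    grand = scores.mean(axis=0)
    s_within = 0.0
    s_between = 0.0
    for g in groups:
        block = scores[labels == g]
        if len(block) < 2:
            raise DataError(f"group {g!r} has fewer than 2 members")
        mu = block.mean(axis=0)
        s_within += float(np.sum((block - mu) ** 2))
        s_between += len(block) * float(np.sum((mu - grand) ** 2))
    if s_within == 0.0:
        return float("inf") if s_between > 0 else 0.0
    return s_between / s_within


def mse_mod(s: Spectrum, matrix_ions: MatrixIonSet) -> float:
    """Matrix-suppression score: TIC fraction *not* within matrix-ion windows.

    ``1 - (Σ intensity within ± relative tolerance of any matrix ion) / TIC``
    clipped to [0, 1]; 1 means complete matrix suppression. Invariant to
    global intensity scaling.
    """
    tic = s.tic
    if tic <= 0:
        raise DataError("mse_mod undefined for non-positive TIC")
    mask = np.zeros(len(s), dtype=bool)
    for ion in matrix_ions.mz_list:
        mask |= np.abs(s.mz - ion) <= matrix_ions.tolerance * ion
    share = float(np.sum(s.intensity[mask])) / tic
    return float(np.clip(1.0 - share, 0.0, 1.0))


def repeatability_r2(fm: FeatureMatrix, sample_a: str, sample_b: str) -> float:
    """R² of the least-squares line through paired per-feature intensities."""
    ids = list(fm.sample_ids)
    for sid in (sample_a, sample_b):
        if sid not in ids:
            raise DataError(f"sample {sid!r} not in feature matrix")
    x = fm.intensities[ids.index(sample_a)]
    y = fm.intensities[ids.index(sample_b)]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero-variance intensity vector; R² undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot
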