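"""Two-step drug-sensitive feature filtration and marker calling.

Step 1 removes inert features by their intensity variance across all spectra
(threshold = mean of all feature variances, keep strictly above). Step 2
averages technical replicates and fits each surviving feature, per
biological replicate, to a four-parameter logistic concentration-response

    descending:  f(x) = top + (bottom - top) / (1 + 10^((LogIC50 - x)·HillSlope))
    ascending:   f(x) = bottom + (top - bottom) / (1 + 10^((LogIC50 - x)·HillSlope))

where x is the decadal logarithm of the molar drug concentration. Ascending
(and biphasic) series are truncated after their maximal point before
fitting, and a curve must keep at least five points. Features are ranked by
R² and called markers when every required biological replicate fits with
R² ≥ 0.9 in the same direction; pIC50 = −LogIC50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError
from .preprocess import FeatureMatrix
from .spectra_io import SampleSheet

logger = logging.getLogger(__name__)

MIN_POINTS = 5  # a curve has to be defined by at least five data points


@dataclass
class ConcentrationSeries:
    """Mean intensities of one feature across doses for one biological replicate."""

    feature_mz: float
    x: np.ndarray  # log10 molar concentration, strictly increasing
    y: np.ndarray  # mean intensity over technical replicates, >= 0
    bio_rep: int = 0
    truncated: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise DataError("x and y differ in length")
        if len(self.x) > 1 and not np.all(np.diff(self.x) > 0):
            raise DataError("concentration axis must be strictly increasing")
        if np.any(self.y < 0):
            raise DataError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class DoseResponseFit:
    """Fitted four-parameter logistic with fit-quality metadata."""

    top: float
    bottom: float
    log_ic50: float
    hill_slope: float
    direction: str  # "descending" | "ascending"
    r2: float
    n_points: int
    truncated: bool = False
    ok: bool = True
    reason: str | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        frac = 1.0 / (1.0 + 10.0 ** ((self.log_ic50 - x) * self.hill_slope))
        return self.top + (self.bottom - self.top) * frac


@dataclass
class MarkerCall:
    """Per-feature verdict: per-replicate fits, pIC50 values, reproducibility."""

    feature_mz: float
    fits: dict  # bio_rep -> DoseResponseFit
    pic50_per_rep: dict  # bio_rep -> float (nan for failed fits)
    pic50_mean: float
    direction: str
    mean_r2: float
    reproducible: bool


def _failed_fit(direction: str, n_points: int, reason: str, truncated: bool = False) -> DoseResponseFit:
    return DoseResponseFit(
        top=np.nan, bottom=np.nan, log_ic50=np.nan, hill_slope=np.nan,
        direction=direction, r2=-np.inf, n_points=n_points,
        truncated=truncated, ok=False, reason=reason,
    )


def logistic_descending(x, top, bottom, log_ic50, hill_slope):
    """f(x) decreasing from ``top`` to ``bottom`` for positive HillSlope."""
    return top + (bottom - top) / (1.0 + 10.0 ** ((log_ic50 - x) * hill_slope))


def logistic_ascending(x, top, bottom, log_ic50, hill_slope):
    """f(x) increasing from ``bottom`` to ``top`` for positive HillSlope."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x) * hill_slope))


def _fit_logistic(series: ConcentrationSeries, direction: str) -> DoseResponseFit:
    """Multi-start bounded nonlinear least squares for either direction.

    Starts: HillSlope ∈ {0.5, 1, 2} × LogIC50 ∈ {min(x), median(x), max(x)};
    top/bottom initialized from max/min of y. Bounds keep plateaus ≥ 0,
    |HillSlope| ≤ 10 and LogIC50 within [min(x)−2, max(x)+2]. Best
    sum-of-squares wins; ties go to the smaller |HillSlope|. The result is
    canonicalized so that top ≥ bottom.
    """
    x, y = series.x, series.y
    n = len(x)
    if n < MIN_POINTS:
        return _failed_fit(direction, n, "insufficient points", series.truncated)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return _failed_fit(direction, n, "constant intensities", series.truncated)

    model = logistic_descending if direction == "descending" else logistic_ascending
    lo = [0.0, 0.0, float(x.min()) - 2.0, -10.0]
    hi = [np.inf, np.inf, float(x.max()) + 2.0, 10.0]
    top0, bottom0 = float(y.max()), float(y.min())
    best = None  # (ss_res, |hill|, params)
    for hill0 in (0.5, 1.0, 2.0):
        for lic0 in (float(x.min()), float(np.median(x)), float(x.max())):
            p0 = [top0, max(bottom0, 1e-12), lic0, hill0]
            try:
                popt, _ = curve_fit(
                    model, x, y, p0=p0, bounds=(lo, hi), maxfev=300, method="trf"
                )
            except (RuntimeError, ValueError):
                continue
            ss = float(np.sum((y - model(x, *popt)) ** 2))
            tol = 1e-12 * ss_tot
            if (
                best is None
                or ss < best[0] - tol
                or (abs(ss - best[0]) <= tol and abs(popt[3]) < best[1])
            ):
                best = (ss, abs(popt[3]), popt)
        if best is not None and best[0] <= 1e-14 * ss_tot:
            break  # numerically exact already; later starts cannot improve
    if best is None:
        return _failed_fit(direction, n, "no start converged", series.truncated)
    ss_res, _, (top, bottom, log_ic50, hill) = best
    if top < bottom:  # identical curve under (top,bottom,H) -> (bottom,top,-H)
        top, bottom, hill = bottom, top, -hill
    return DoseResponseFit(
        top=float(top), bottom=float(bottom), log_ic50=float(log_ic50),
        hill_slope=float(hill), direction=direction,
        r2=1.0 - ss_res / ss_tot, n_points=n, truncated=series.truncated,
    )


def fit_descending(series: ConcentrationSeries) -> DoseResponseFit:
    """Fit the descending four-parameter logistic to the full series."""
    return _fit_logistic(series, "descending")


def fit_ascending(series: ConcentrationSeries) -> DoseResponseFit:
    """Fit the ascending logistic; expects a max-truncated series.

    Series with fewer than five remaining points are skipped with a recorded
    reason rather than fitted.
    """
    return _fit_logistic(series, "ascending")


def truncate_after_max(series: ConcentrationSeries) -> ConcentrationSeries:
    """Drop concentrations after the (last) maximal intensity.

    Biphasic responses — intensity rising then collapsing at toxic doses —
    keep only their rising flank this way. Ties keep everything through the
    last maximal point; idempotent.
    """
    if len(series) == 0:
        return series
    last_max = len(series.y) - 1 - int(np.argmax(series.y[::-1]))
    if last_max == len(series.y) - 1:
        return series
    return ConcentrationSeries(
        series.feature_mz,
        series.x[: last_max + 1],
        series.y[: last_max + 1],
        bio_rep=series.bio_rep,
        truncated=True,
    )


def fit_best_direction(series: ConcentrationSeries) -> DoseResponseFit:
    """Classify direction by fitting both parameterizations.

    The descending model is fitted to the full series, the ascending model
    to the max-truncated series (when ≥ 5 points remain); the higher-R² fit
    wins, ties going to the descending fit.
    """
    desc = fit_descending(series)
    asc = fit_ascending(truncate_after_max(series))
    return asc if asc.r2 > desc.r2 else desc


def pic50(fit: DoseResponseFit) -> float:
    """pIC50 = −LogIC50 (concentrations are molar). NaN for failed fits."""
    if not fit.ok or not np.isfinite(fit.log_ic50):
        return float("nan")
    return -fit.log_ic50


def variance_filter(fm: FeatureMatrix):
    """Keep features whose intensity variance is strictly above the mean variance.

    Returns ``(kept_indices, variances, threshold)``. The bulk of inert
    features produces a right-skewed variance histogram whose mean falls to
    the right of the histogram peak; anything strictly above it is
    considered drug-modulated.
    """
    if fm.n_samples < 2:
        raise DataError("variance filter requires at least 2 samples")
    variances = np.var(fm.intensities, axis=0, ddof=1)
    threshold = float(np.mean(variances))
    kept = np.flatnonzero(variances > threshold)
    logger.info(
        "variance filter: %d/%d features above threshold %.3g",
        len(kept), fm.n_features, threshold,
    )
    return kept, variances, threshold


def average_technical_replicates(fm: FeatureMatrix) -> FeatureMatrix:
    """Arithmetic mean over technical replicates.

    One output row per (compound, concentration, bio_rep), in order of first
    appearance; synthesized sample ids encode the group key.
    """
    if fm.sheet is None:
        raise DataError("averaging requires a sample sheet")
    import pandas as pd

    table = fm.sheet.table
    keys = ["compound", "concentration_molar", "bio_rep"]
    rows, ids, meta = [], [], []
    for key, group in table.groupby(keys, sort=False):
        idx = group.index.to_numpy()
        if len(idx) == 0:
            raise DataError(f"empty replicate group {key}")
        rows.append(fm.intensities[idx].mean(axis=0))
        compound, conc, bio = key
        sid = f"{compound}|c{conc:g}|b{bio}"
        ids.append(sid)
        meta.append(
            {"sample_id": sid, "compound": compound, "concentration_molar": conc,
             "tech_rep": 0, "bio_rep": bio}
        )
    sheet = SampleSheet(pd.DataFrame(meta))
    return FeatureMatrix(fm.features, np.vstack(rows), ids, sheet=sheet)


def rank_and_call_markers(
    fits_by_feature: dict,
    r2_min: float = 0.9,
    n_reps_required: int = 3,
) -> list:
    """Rank features by mean R² and call reproducible markers.

    ``fits_by_feature`` maps feature m/z to ``{bio_rep: DoseResponseFit}``.
    A feature is a marker iff at least ``n_reps_required`` replicates were
    fitted and every replicate's fit reaches ``r2_min`` with one common
    direction.
    """
    calls = []
    for mz, per_rep in fits_by_feature.items():
        fits = dict(sorted(per_rep.items()))
        finite = [f.r2 for f in fits.values() if np.isfinite(f.r2)]
        mean_r2 = float(np.mean(finite)) if finite else -np.inf
        directions = {f.direction for f in fits.values() if f.ok}
        reproducible = (
            len(fits) >= n_reps_required
            and all(f.ok and f.r2 >= r2_min for f in fits.values())
            and len(directions) == 1
        )
        p_per_rep = {rep: pic50(f) for rep, f in fits.items()}
        p_vals = [p for p in p_per_rep.values() if np.isfinite(p)]
        calls.append(
            MarkerCall(
                feature_mz=float(mz),
                fits=fits,
                pic50_per_rep=p_per_rep,
                pic50_mean=float(np.mean(p_vals)) if p_vals else float("nan"),
                direction=directions.pop() if len(directions) == 1 else "mixed",
                mean_r2=mean_r2,
                reproducible=reproducible,
            )
        )
    calls.sort(key=lambda c: -c.mean_r2)
    return calls


@dataclass
class ResponseConfig:
    """Parameters of the filtration + marker-calling stage."""

    r2_min: float = 0.9
    n_reps_required: int = 3
    min_points: int = MIN_POINTS
    vehicle: str = "anchor"  # "anchor" | "exclude"
    vehicle_offset_decades: float = 2.0
    exclude_mz: tuple = ()
    exclude_tolerance: float = 0.002

    def validate(self) -> None:
        from .errors import ConfigError

        if not 0 < self.r2_min <= 1:
            raise ConfigError("r2_min must be in (0, 1]")
        if self.n_reps_required < 1:
            raise ConfigError("n_reps_required must be >= 1")
        if self.vehicle not in ("anchor", "exclude"):
            raise ConfigError(f"unknown vehicle mode {self.vehicle!r}")


@dataclass
class AnalysisResult:
    """Marker calls plus the variance-filter bookkeeping for reporting."""

    calls: list
    variances: np.ndarray
    threshold: float
    kept_features: np.ndarray
    compound: str

    @property
    def markers(self) -> list:
        return [c for c in self.calls if c.reproducible]


def _series_for_feature(avg: FeatureMatrix, fi: int, compound: str, bio: int,
                        config: ResponseConfig) -> ConcentrationSeries | None:
    table = avg.sheet.table
    own = (table["compound"] == compound) & (table["bio_rep"] == bio) & (
        table["concentration_molar"] > 0
    )
    veh = (table["concentration_molar"] == 0) & (table["bio_rep"] == bio)
    rows = table[own]
    if rows.empty:
        return None
    x = np.log10(rows["concentration_molar"].to_numpy())
    y = avg.intensities[rows.index.to_numpy(), fi]
    if config.vehicle == "anchor" and veh.any():
        # vehicle rows anchor the drug-free plateau two decades below the
        # lowest nonzero dose (a log axis cannot host concentration 0)
        x0 = float(x.min()) - config.vehicle_offset_decades
        x = np.concatenate([[x0], x])
        y = np.concatenate([[avg.intensities[table[veh].index.to_numpy(), fi].mean()], y])
    order = np.argsort(x)
    return ConcentrationSeries(float(avg.features[fi]), x[order], y[order], bio_rep=bio)


def find_markers(fm: FeatureMatrix, config: ResponseConfig | None = None,
                 compound: str | None = None) -> AnalysisResult:
    """Run the two-step filtration on a feature matrix for one compound.

    The variance filter operates on the supplied (TIC-normalized, non-sqrt)
    matrix; technical replicates are then averaged and each kept feature is
    fitted per biological replicate in both directions.
    """
    config = config or ResponseConfig()
    config.validate()
    if fm.sheet is None:
        raise DataError("find_markers requires a sample sheet")
    table = fm.sheet.table
    compounds = sorted(table.loc[table["concentration_molar"] > 0, "compound"].unique())
    if compound is None:
        if len(compounds) != 1:
            raise DataError(
                f"matrix holds {len(compounds)} compounds {compounds}; pass compound="
            )
        compound = compounds[0]

    kept, variances, threshold = variance_filter(fm)
    excl = np.asarray(config.exclude_mz, dtype=float)
    if len(excl):
        mzs = fm.features[kept]
        mask = ~np.any(
            np.abs(mzs[:, None] - excl[None, :]) <= config.exclude_tolerance * excl[None, :],
            axis=1,
        )
        kept = kept[mask]

    avg = average_technical_replicates(fm)
    bio_reps = sorted(
        avg.sheet.table.loc[
            avg.sheet.table["compound"] == compound, "bio_rep"
        ].unique()
    )
    fits_by_feature = {}
    for fi in kept:
        per_rep = {}
        for bio in bio_reps:
            series = _series_for_feature(avg, fi, compound, bio, config)
            if series is None:
                continue
            per_rep[bio] = fit_best_direction(series)
        if per_rep:
            fits_by_feature[float(fm.features[fi])] = per_rep
    calls = rank_and_call_markers(
        fits_by_feature, r2_min=config.r2_min, n_reps_required=config.n_reps_required
    )
    logger.info(
        "%s: %d features, %d past variance filter, %d markers",
        compound, fm.n_features, len(kept), sum(c.reproducible for c in calls),
    )
    return AnalysisResult(calls, variances, threshold, kept, compound)
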