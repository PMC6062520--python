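"""Synthetic whole-cell MALDI-TOF-like spectra with planted dose responses.

The generator emulates reflector-positive profile spectra over m/z
200–2,000: Gaussian analyte peaks on a uniform m/z grid, matrix-ion
clusters whose intensity is suppressed as analyte load rises, an
exponentially decaying chemical baseline, multiplicative lognormal
biological and technical replicate variability, and additive detector
noise. Each analyte may carry a descending, ascending or biphasic
four-parameter-logistic concentration response, so every pipeline stage can
be validated against known ground truth without instrument data.

All randomness flows from the single config seed; identical configs yield
byte-identical spectra.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import FeatureMatrix
from .response import logistic_ascending, logistic_descending
from .spectra_io import SampleSheet, Spectrum

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class AnalytePeak:
    """One simulated analyte: location, abundance and concentration response.

    ``base_intensity`` is the drug-free peak height; the response curve (a
    multiplier between ``bottom`` and ``top``) rescales it per dose.
    Biphasic analytes rise with the ascending logistic at ``log_ic50`` and
    collapse again around ``tox_log_ic50`` (toxicity at high dose).
    """

    mz: float
    base_intensity: float
    response: str = "none"  # none | descending | ascending | biphasic
    log_ic50: float | None = None
    hill_slope: float = 1.0
    top: float = 1.0
    bottom: float = 0.25
    tox_log_ic50: float | None = None
    name: str = ""

    def response_multiplier(self, x: float) -> float:
        """Curve value at log10 molar concentration ``x``."""
        if self.response == "none":
            return 1.0
        if self.log_ic50 is None:
            raise ConfigError(f"analyte {self.name or self.mz}: log_ic50 required")
        if self.response == "descending":
            return float(
                logistic_descending(x, self.top, self.bottom, self.log_ic50, self.hill_slope)
            )
        if self.response == "ascending":
            return float(
                logistic_ascending(x, self.top, self.bottom, self.log_ic50, self.hill_slope)
            )
        if self.response == "biphasic":
            tox = self.tox_log_ic50 if self.tox_log_ic50 is not None else self.log_ic50 + 1.2
            rise = logistic_ascending(x, self.top, self.bottom, self.log_ic50, self.hill_slope)
            fall = logistic_descending(x, 1.0, 0.0, tox, 1.5)
            return float(rise * fall)
        raise ConfigError(f"unknown response shape {self.response!r}")


def default_analyte_panel() -> list:
    """The stock panel: one descending marker, one biphasic marker, inert lipids.

    The descending marker at m/z 826.6 (LogIC50 −6.3, ~3.6-fold dynamic
    range) and the biphasic one at m/z 616.2 mimic the lipid/porphyrin
    markers a kinase-inhibitor response produces in leukemia cells; the
    remaining peaks are inert fingerprint background.
    """
    panel = [
        AnalytePeak(826.6, 60.0, "descending", log_ic50=-6.3, hill_slope=1.0,
                    top=1.0, bottom=0.28, name="PC-like marker"),
        AnalytePeak(616.2, 40.0, "biphasic", log_ic50=-6.8, hill_slope=1.0,
                    top=1.0, bottom=0.15, tox_log_ic50=-5.1, name="heme-like marker"),
    ]
    inert = [
        (203.1, 35.0), (239.1, 18.0), (258.1, 22.0), (369.35, 55.0),
        (496.34, 30.0), (520.34, 48.0), (544.5, 26.0), (577.52, 14.0),
        (603.58, 33.0), (633.5, 20.0), (703.57, 75.0), (734.57, 42.0),
        (760.59, 66.0), (782.57, 38.0), (798.54, 52.0), (810.6, 28.0),
        (848.56, 24.0), (872.57, 17.0), (904.62, 12.0), (1466.05, 9.0),
    ]
    panel += [
        AnalytePeak(mz, h, "none", name=f"inert_{mz:.1f}") for mz, h in inert
    ]
    return panel


def default_matrix_ions() -> list:
    """DHB cluster ions with plausible relative heights."""
    return [
        (137.0233, 180.0), (154.0261, 60.0), (155.0339, 140.0),
        (177.0158, 90.0), (192.9898, 45.0), (273.0394, 70.0), (291.0499, 35.0),
    ]


def default_doses() -> tuple:
    """Eight log-spaced molar doses from 1 nM to ~32 µM."""
    return tuple(np.logspace(-9.0, -4.5, 8))


@dataclass
class SimConfig:
    """Full description of a synthetic concentration-response experiment."""

    seed: int
    compound: str = "drugX"
    mz_range: tuple = (200.0, 2000.0)
    grid_step: float = 0.02
    resolving_power: float = 10000.0
    analytes: list = field(default_factory=default_analyte_panel)
    matrix_ions: list = field(default_factory=default_matrix_ions)
    suppression_k: float = 1.0
    baseline_amplitude: float = 2.0
    baseline_scale: float = 300.0
    noise_cv: float = 0.15
    bio_cv: float = 0.10
    additive_noise: float = 0.05
    doses: tuple = field(default_factory=default_doses)
    n_tech: int = 8
    n_bio: int = 3

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ConfigError("mz_range must be (low, high) with low < high")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be positive")
        doses = np.asarray(self.doses, dtype=float)
        if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
            raise ConfigError("doses must be non-negative and strictly ascending")
        if self.noise_cv < 0 or self.bio_cv < 0 or self.additive_noise < 0:
            raise ConfigError("noise levels must be non-negative")
        if self.n_tech < 1 or self.n_bio < 1:
            raise ConfigError("replicate counts must be >= 1")
        for a in self.analytes:
            if not lo <= a.mz <= hi:
                raise ConfigError(f"analyte m/z {a.mz} outside mz_range {self.mz_range}")

    def grid(self) -> np.ndarray:
        lo, hi = self.mz_range
        return np.arange(lo, hi + self.grid_step / 2, self.grid_step)

    def sigma_at(self, mz: float) -> float:
        return (mz / self.resolving_power) / _FWHM_TO_SIGMA


@dataclass
class GroundTruth:
    """Planted parameters plus per-sample pre-noise peak heights."""

    analytes: list  # dicts: name, mz, response, log_ic50, true pIC50, ...
    per_sample: dict  # sample_id -> {analyte name: height before additive noise}
    doses: tuple
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "doses": list(self.doses),
                    "analytes": self.analytes,
                    "per_sample": self.per_sample,
                },
                fh, indent=1,
            )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative factor with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _render(grid: np.ndarray, peaks, baseline: np.ndarray, noise: np.ndarray | None) -> np.ndarray:
    """Sum Gaussian peaks + baseline (+ additive noise), clipped at zero."""
    y = baseline.copy()
    step = grid[1] - grid[0]
    for mz, height, sigma in peaks:
        half = 5.0 * sigma
        lo = max(0, int((mz - half - grid[0]) / step))
        hi = min(len(grid), int((mz + half - grid[0]) / step) + 2)
        seg = grid[lo:hi]
        y[lo:hi] += height * np.exp(-0.5 * ((seg - mz) / sigma) ** 2)
    if noise is not None:
        y += noise
    return np.clip(y, 0.0, None)


def simulate_experiment(cfg: SimConfig):
    """Generate (spectra, sample sheet, ground truth) for a dose-response run.

    Per sample, analyte heights are ``response(x) × base × bio factor ×
    tech factor`` with unit-mean lognormal factors; matrix-ion heights are
    divided by ``1 + k × relative analyte load``; additive Gaussian noise
    is drawn last. Deterministic given the config seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    baseline = cfg.baseline_amplitude * np.exp(-(grid - grid[0]) / cfg.baseline_scale)
    base_load = sum(a.base_intensity for a in cfg.analytes) or 1.0

    names = [a.name or f"analyte_{a.mz:.4f}" for a in cfg.analytes]
    bio_factors = {
        (b, i): float(_lognormal_factor(rng, cfg.bio_cv))
        for b in range(1, cfg.n_bio + 1)
        for i in range(len(cfg.analytes))
    }

    spectra, rows, per_sample = [], [], {}
    for di, dose in enumerate(cfg.doses):
        x = math.log10(dose) if dose > 0 else -np.inf
        for b in range(1, cfg.n_bio + 1):
            for t in range(1, cfg.n_tech + 1):
                sid = f"s_d{di}_b{b}_t{t}"
                heights = []
                for i, a in enumerate(cfg.analytes):
                    mult = 1.0 if dose == 0 else a.response_multiplier(x)
                    tech = float(_lognormal_factor(rng, cfg.noise_cv))
                    heights.append(a.base_intensity * mult * bio_factors[(b, i)] * tech)
                load = sum(heights) / base_load
                peaks = [
                    (a.mz, h, cfg.sigma_at(a.mz))
                    for a, h in zip(cfg.analytes, heights)
                ]
                peaks += [
                    (mz, h / (1.0 + cfg.suppression_k * load), cfg.sigma_at(mz))
                    for mz, h in cfg.matrix_ions
                ]
                # detector noise is a non-negative ripple riding on the
                # profile (half-normal), keeping intensities >= 0 without a
                # clipping artifact in baseline-free regions
                noise = (
                    np.abs(rng.normal(0.0, cfg.additive_noise, size=len(grid)))
                    if cfg.additive_noise > 0
                    else None
                )
                spectra.append(Spectrum(grid, _render(grid, peaks, baseline, noise), sid))
                rows.append(
                    {"sample_id": sid, "compound": cfg.compound,
                     "concentration_molar": dose, "tech_rep": t, "bio_rep": b}
                )
                per_sample[sid] = dict(zip(names, map(float, heights)))

    sheet = SampleSheet(pd.DataFrame(rows))
    truth = GroundTruth(
        analytes=[
            {
                "name": n, "mz": a.mz, "response": a.response,
                "base_intensity": a.base_intensity,
                "log_ic50": a.log_ic50,
                "pic50": (-a.log_ic50 if a.log_ic50 is not None else None),
                "hill_slope": a.hill_slope, "top": a.top, "bottom": a.bottom,
            }
            for n, a in zip(names, cfg.analytes)
        ],
        per_sample=per_sample,
        doses=tuple(float(d) for d in cfg.doses),
        seed=cfg.seed,
    )
    return spectra, sheet, truth


def simulate_cell_dilution(cfg: SimConfig, cell_counts, ref_cells: float = 1000.0):
    """Noise-free matrix-vs-analyte competition across cell loadings.

    Analyte heights scale linearly with cell count; matrix ions are divided
    by ``1 + k × (count / ref_cells)``, the simplest monotone saturating
    suppression law. Returns ``[(count, Spectrum), …]`` for feeding the
    matrix-suppression score; baseline and noise are omitted so the score
    isolates the matrix/analyte intensity ratio.
    """
    cfg.validate()
    if any(c < 0 for c in cell_counts):
        raise ConfigError("cell counts must be non-negative")
    grid = cfg.grid()
    zero_baseline = np.zeros_like(grid)
    out = []
    for count in cell_counts:
        scale = count / ref_cells
        peaks = [
            (a.mz, a.base_intensity * scale, cfg.sigma_at(a.mz)) for a in cfg.analytes
        ]
        peaks += [
            (mz, h / (1.0 + cfg.suppression_k * scale), cfg.sigma_at(mz))
            for mz, h in cfg.matrix_ions
        ]
        spectrum = Spectrum(
            grid, _render(grid, peaks, zero_baseline, None), f"cells_{count:g}"
        )
        out.append((count, spectrum))
    return out


def simulate_feature_matrix(
    seed: int,
    n_features: int = 50,
    responsive_index: int = 17,
    doses=None,
    n_tech: int = 8,
    n_bio: int = 3,
    cv: float = 0.15,
    bio_cv: float = 0.10,
    log_ic50: float = -6.3,
    hill_slope: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.28,
    responsive_base: float = 100.0,
    compound: str = "drugX",
) -> FeatureMatrix:
    """Feature-matrix-level simulation: one descending feature among inert ones.

    Bypasses spectrum rendering for fast Monte-Carlo studies of the
    filtration and fitting stages: every feature gets lognormal technical
    and biological multiplicative noise; only ``responsive_index`` follows
    the descending logistic. The responsive feature is planted as an
    abundant one (``responsive_base``): variance filtration targets markers
    whose drug-driven swing dominates replicate noise, so the toy plants a
    marker in exactly that regime.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(default_doses() if doses is None else doses, dtype=float)
    features = np.sort(200.0 + 1700.0 * rng.random(n_features))
    base = 20.0 + 80.0 * rng.random(n_features)
    base[responsive_index] = responsive_base
    bio_factors = _lognormal_factor(rng, bio_cv, size=(n_bio, n_features))
    rows, meta = [], []
    for di, dose in enumerate(doses):
        x = np.log10(dose)
        mult = np.ones(n_features)
        mult[responsive_index] = logistic_descending(x, top, bottom, log_ic50, hill_slope)
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                tech = _lognormal_factor(rng, cv, size=n_features)
                rows.append(base * mult * bio_factors[b - 1] * tech)
                meta.append(
                    {"sample_id": f"m_d{di}_b{b}_t{t}", "compound": compound,
                     "concentration_molar": float(dose), "tech_rep": t, "bio_rep": b}
                )
    sheet = SampleSheet(pd.DataFrame(meta))
    return FeatureMatrix(features, np.vstack(rows), [m["sample_id"] for m in meta], sheet)
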