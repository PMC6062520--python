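# Methods

## Scope and model

`wcmaldi` implements an automated workflow for discovering and quantifying
lipid/metabolite drug-response markers in whole-cell MALDI-TOF mass
fingerprints. Cultured cells are treated across a concentration series of a
drug, spotted with matrix, and measured in reflector positive mode over
m/z 200–2,000; the package takes over from the exported profile spectra.

The analysis chain is:

1. **Preprocessing** — TIC normalization, Top-Hat (morphological opening)
   baseline subtraction, peak picking at SNR > 5 with a 20-point half
   window, and binning of pooled peak lists at a relative m/z tolerance of
   0.002 into a single samples × features intensity matrix (absent peaks
   stored as 0).
2. **Two-step feature filtration** — (i) per-feature intensity variance
   across all spectra, thresholded at the mean of all feature variances
   (the variance histogram is right-skewed, so the mean falls right of the
   bulk and passes only drug-modulated features); (ii) four-parameter
   logistic concentration-response fits on technical-replicate-averaged
   intensities, keeping features with R² ≥ 0.9 reproduced across the
   biological replicates.
3. **Concentration-response model** — with x = log10 molar concentration,

       descending:  f(x) = top + (bottom − top) / (1 + 10^((LogIC50 − x)·HillSlope))
       ascending:   f(x) = bottom + (top − bottom) / (1 + 10^((LogIC50 − x)·HillSlope))

   Biphasic responses (rise, then collapse at toxic doses) are handled by
   truncating the series after its (last) maximal point before the
   ascending fit; a fit requires at least five remaining points. pIC50 =
   −LogIC50.
4. **Accurate-mass identification support** — monoisotopic masses from
   elemental formulas, adduct m/z with explicit electron-mass bookkeeping
   (proton +1.007276 Da; K⁺ +38.963707 − mₑ; radical cation −mₑ), ppm
   matching against an offline compound table at ≤ 3 ppm with the
   odd-acyl-carbon exclusion for lipids, exact multinomial isotope-pattern
   prediction, and CID neutral-loss fragment assignment at ~1 mDa.

## Parameters that matter

| Parameter | Default | Units | Notes |
|---|---|---|---|
| `snr_min` | 5 | – | peak acceptance threshold |
| `peak_half_window` | 20 | points | local-maximum and noise window |
| `baseline_half_window` | 75 | points | Top-Hat structuring element half width |
| `bin_tolerance` | 0.002 | relative Δm/z | interpreted as relative (≈1.6 Da at m/z 800), matching low-resolution TOF bins such as "m/z 826.6" |
| `r2_min` | 0.9 | – | per-replicate fit-quality cutoff |
| `n_reps_required` | 3 | – | biological replicates that must agree |
| `max_ppm` | 3 | ppm | accurate-mass search cutoff |
| `tol_mda` | 1.5 | mDa | fragment-assignment tolerance |
| vehicle anchor | 2 | decades | see below |

## Numerical and design choices

* **Noise estimate / SNR.** SNR uses a running median of the absolute
  baseline-corrected intensity over `2·half_window + 1` points, scaled by
  1.4826 (MAD-consistent for Gaussian noise), floored at `1e-12 × max
  intensity` so the curve stays strictly positive. This is a robust,
  reproducible stand-in for smoother-based noise models whose bandwidth
  conventions vary between implementations.
* **Binning.** Greedy hierarchical splitting of the pooled sorted peak set
  at the largest internal gap until each bin satisfies the relative width
  tolerance and holds at most one peak per sample; deterministic, with bin
  center = mean member m/z.
* **Fit initialization.** Multi-start nonlinear least squares
  (`scipy.optimize.curve_fit`, trust-region reflective, ≤300 function
  evaluations per start) over HillSlope ∈ {0.5, 1, 2} × LogIC50 ∈ {min(x),
  median(x), max(x)}, top/bottom initialized from max/min of y. Bounds:
  plateaus ≥ 0, |HillSlope| ≤ 10, LogIC50 ∈ [min(x)−2, max(x)+2] (stops
  plateau-only degeneracies). Best sum of squares wins; ties break to the
  smaller |HillSlope|; parameters are canonicalized so top ≥ bottom. A fit
  in which no start converges is flagged (R² = −∞), never raised.
* **Direction classification.** Each feature is fitted both ways — the
  descending model on the full series and the ascending model on the
  max-truncated series — and the higher-R² fit wins (ties to descending).
  On noise-free descending data the descending fit always wins.
* **Vehicle controls.** Concentration 0 cannot enter a log axis; vehicle
  rows anchor the drug-free plateau at x = log10(lowest nonzero dose) − 2
  (configurable, or excluded entirely).
* **Variance filtering input.** Operates on the TIC-normalized,
  *non*-sqrt matrix; the square-root transform is applied only for
  multivariate analysis (PCA).
* **PCA.** SVD of the column-centered matrix, no unit-variance scaling.
  Explained-variance fractions are squared singular values over the total
  centered sum of squares.
* **`j_overlap` and `mse_mod`.** Defined operationally in this package:
  `j_overlap` = trace(between-group scatter)/trace(within-group scatter)
  over PCA scores (higher = better separated; rotation invariant);
  `mse_mod` = 1 − (TIC share within ± relative tolerance of any matrix
  ion), clipped to [0, 1] (1 = complete matrix suppression; scale
  invariant). Both are used only for ranking, where monotone agreement
  with the intended notion is what matters. The default matrix-ion list
  holds common positive-mode DHB cluster ions and is user-overridable.
* **ppm convention.** Denominator = theoretical mass. The proton mass is
  used directly for [M+H]⁺; the H-atom-minus-electron route is numerically
  identical (asserted in tests to 2×10⁻⁸ Da).
* **Isotope patterns.** Exact multinomial expansion aggregated by nucleon
  number, reporting offsets 0 … n−1 relative to the monoisotopic
  composition, renormalized. Satellites *below* the monoisotopic peak
  (e.g. ⁵⁴Fe at M−2 for heme B) are outside the reported M, M+1, …
  ladder. Peak m/z = abundance-weighted mean mass per nucleon offset; for
  iron-containing species this centroid can deviate from the lightest
  composition by a few 10⁻⁵ Da, below the 4-decimal reporting precision.
* **mzML.** A minimal self-contained reader/writer (profile spectra,
  base64 little-endian 32/64-bit floats, uncompressed or zlib) backs
  `read_spectrum_mzml`/`write_mzml`; two-column text profiles are the
  primary exchange format.

## The synthetic-data generator

`simulate.simulate_experiment` emulates the study conditions: profile
spectra on a uniform 0.02-Th grid over m/z 200–2,000, Gaussian peaks with
FWHM = m/z / 10,000 (reflector-TOF-like), an exponentially decaying
chemical baseline, DHB matrix-ion clusters suppressed by
1/(1 + k·analyte load) as cellular material increases, eight technical and
three biological replicates per dose, eight log-spaced doses from 1 nM to
~32 µM, multiplicative lognormal technical (CV 15%) and biological
(CV 10%) variability, and non-negative half-normal detector noise drawn
last. The stock analyte panel plants one descending marker at m/z 826.6
(LogIC50 −6.3, ~3.6-fold dynamic range, mimicking a potassiated
phosphatidylcholine) and one biphasic marker at m/z 616.2 (>6-fold,
mimicking a heme-like differentiation marker with toxicity above ~8 µM),
among twenty inert fingerprint peaks. All randomness flows from the single
config seed; identical configs give byte-identical spectra.

`simulate_cell_dilution` isolates the matrix-vs-analyte competition:
analyte load scales linearly with cell count, matrix ions divide by
(1 + k·count/ref); baseline and noise are omitted so the suppression score
reflects the intensity ratio alone. The 1/(1+k·load) law is the simplest
monotone saturating form and reproduces a plateau at high cell numbers.

`simulate_feature_matrix` skips spectrum rendering for fast Monte-Carlo
studies of the filtration/fitting stages; it plants the responsive feature
as an abundant one, since variance filtration by construction targets
markers whose drug-driven swing dominates replicate noise.

What the generator does **not** emulate: TOF flight-time physics and
sqrt-time m/z spacing, isotope envelopes in profile spectra, m/z
calibration drift between spectra, chemical interference/overlapping
peaks, and detector saturation. Passing tests therefore demonstrate
correctness of the computational chain under a realistic noise model, not
robustness to instrument-specific artifacts.

## Validation problem sizes

The bundled recovery study (`wcmaldi.validation`) runs 20 independently
seeded full-scale experiments (8 doses × 8 technical × 3 biological
replicates = 192 spectra of 90,001 points each) and scores how often the
planted descending marker is called reproducibly and how far its estimated
pIC50 lies from the generating value. The filtration toy uses a 50-feature
matrix with one responsive feature. These sizes keep a complete run of the
study in the minutes range on a single core.

## Known limitations

* The odd-carbon exclusion applies only to records carrying
  `acyl_carbons` metadata; formulas alone cannot distinguish acyl-chain
  from head-group carbons.
* Only singly charged species are handled; fine isotope structure is
  aggregated by nucleon number.
* No confidence intervals on pIC50, no mixed-effects dose-response
  models, no outlier rejection.
* m/z axes are assumed recalibrated upstream; no cross-spectrum alignment
  is performed.
* Printed calibrant [M+H]⁺ values in some vendor tables sit ~2.016 Da
  below proton-adduct masses computed from published formulas (consistent
  with [M−H]⁺ species); the bundled compound table carries formulas only
  and computes adducts explicitly.
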