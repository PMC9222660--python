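# Methods

## Scope and data model

The package analyses isothermal accelerated-storage trials of a packaged
fermented-vegetable product. The canonical in-memory objects are:

* `QualityIndexSeries` — one quality index at one storage temperature:
  strictly increasing storage days, per-day replicate means and standard
  deviations (replicate-level values optionally attached), a replicate count,
  and a declared direction of change. Direction is metadata, not inferred:
  hardness, lightness and sensory score decrease during storage while total
  acid increases, and noisy endpoints must not flip that.
* `ETongueProfile` — a named vector of taste-sensor responses for one sample.
* `NIRSpectrum` — an absorbance spectrum on a strictly increasing 900–1600 nm
  grid, optionally annotated with total acid and storage day.

Temperatures are kelvin internally (conversion constant 273.15); files use °C
by default. Input tables are long-format delimited text (comma default, tab
accepted); the wide per-temperature layouts used in print are re-encoded, not
parsed. The printed study tables ship as packaged fixtures exactly as printed
(2-decimal means, no back-computed replicates).

## Kinetics

Zero-order (A = A₀ − k·t) and first-order (A = A₀·e^(−k·t)) fits are ordinary
least squares — the first order on ln A, with diagnostics (R², RMSE) mapped
back to the original scale. Closed-form fitting was chosen over iterative
nonlinear least squares for determinism; a nonlinear refinement exists for the
Arrhenius stage but is off by default.

Conventions, chosen once and used consistently:

* k is stored signed as −slope, so decaying indices carry k > 0 and
  accumulating ones (total acid) k < 0. Temperature-model fits always use |k|
  and the direction is reattached downstream.
* RMSE = √(SSE/n), not n−p.
* Fits default to the per-time means (the only data available in print); a
  flag switches to replicate-level rows. With equal replicate counts per time
  point both give identical k and A₀ (the tests assert this), though R²/RMSE
  differ.
* Order selection keeps the larger R²; exact ties go to zero order.
* A series with fewer than 3 distinct time points, or zero variance in A, is
  an error, as is any non-positive value under first-order kinetics.

## Temperature models

The Arrhenius model is carried in two linked parameterizations: the
reference-centered one (k_ref at T_ref, with T_ref the arithmetic mean of the
study temperatures) and the classic pre-exponential one
(A = k_ref·exp(Eₐ/(R·T_ref))). Both are fitted in one pass by OLS of ln k on
(1/T − 1/T_ref), and the identity between them holds to 1e-12 relative by
construction. Published "k_ref" values are ambiguous between the two readings;
per-temperature activation-parameter tables are read as the centered form and
the shelf-life prediction constants as classic pre-exponential factors — the
conversion identity reconciles the two (0.0453 d⁻¹ at 308.15 K with
Eₐ = 70.07 kJ/mol ↔ 3.41×10¹⁰ d⁻¹ classic).

The Eyring model regresses ln(k/T) on 1/T: slope −ΔH*/R, intercept
ln(k_B/h) + ΔS*/R. Two unit conventions are supported:

* `day` (default): k stays in d⁻¹ against k_B/h in SI. Dimensionally
  inconsistent, but it is the convention under which the tabulated ΔS* values
  (e.g. −60.98 J/(mol·K) for radish lightness) are reproducible, so it is the
  default for comparability.
* `si`: k converted to s⁻¹ first; ΔS* shifts by exactly R·ln 86400
  (≈ 94.5 J/(mol·K)).

Physical constants are fixed at the precision used throughout the analysis:
R = 8.3144 J/(mol·K), k_B = 1.381×10⁻²³ J/K, h = 6.626×10⁻³⁴ J·s.

On a 25–45 °C span, ΔH* ≈ Eₐ − R·T̄ (difference ≈ 2.6 kJ/mol); the tests
assert this within 2%.

## Shelf-life prediction and inversion

Each index's prediction model is the tuple (A₀, k_ref classic, Eₐ,
direction); quality evolves as A(T, t) = A₀ ∓ k(T)·t with
k(T) = k_ref·e^(−Eₐ/(R·T)), the minus for decaying indices and the plus for
total acid (the absolute-value form |A₀ − A| of the printed models). The
printed prediction-model table writes its exponent in the centered form while
its k_ref magnitudes (10⁶–10¹¹ d⁻¹) are only numerically consistent with the
classic form; the classic reading is adopted because it reproduces all the
published shelf-lives and critical values within ~1%. Shelf-life is the
closed-form inversion t = |A₀ − A_c|/k(T); inversion then prediction is an
identity to 1e-12 relative.

End-of-shelf-life critical values are computed at 45 °C, day 56 — the
e-tongue-defined shelf-life at 45 °C — which is the endpoint choice that
reproduces the published quintuple. The consensus check reports the relative
spread (max−min)/max of shelf-lives implied by different indices and passes
within a 15% tolerance by default.

Percent-change summaries are 100·(A_first − A_ref)/A_first with A_ref either
the last mean or the mean furthest from the initial one (texture indices
rebound near the end of storage, so the extreme need not be the endpoint).

## Taste classification

Attributes are z-scored before PCA and FDA: e-tongue channels live on
heterogeneous scales (sourness ~15–18 vs umami ~1.3–2) and would otherwise
dominate both decompositions. PCA is the standard maximum-variance
decomposition (eigendecomposition of the correlation matrix when
standardized); no varimax rotation by default.

The Fisher discriminant uses the pooled within-class covariance with
proportional priors; a singular pooled covariance gets a 1e-6 ridge on its
diagonal with a logged warning, and discriminant-score ties resolve to the
lowest class index. The ⅔–⅓ calibration/prediction split is stratified by
class and seeded; one uniform draw per sample orders samples within each
class, so the partition is invariant under relabelling the classes. Published
per-class accuracies and the printed variance shares depend on unpublished
raw sensor data and are reference values, not fitting targets; the tests
instead assert exact agreement with an independent pooled-covariance
discriminant (scikit-learn's LDA) and perfect classification of separable
clusters across 100 split seeds.

Acceptability periods are configuration: at 45 °C the defaults are
0–28 / 28–56 / 56–84 days and at 35 °C 0–42 / 42–126 / 126–154 days; other
temperatures require user-supplied boundaries. `label_periods` partitions
[0, b₃] exactly (closed on the left edge, right-closed intervals).

## NIR → chemistry network

A single hidden layer of 20 logistic units with a linear 2-output head maps
the absorbance grid to (total acid, storage day) jointly. Inputs are min-max
scaled per wavelength (z-score optional), targets are z-scored internally,
and samples are split 70/15/15 (floor rule on the first two fractions,
remainder to the test set) by a seeded permutation. Training is full-batch
adam (learning rate 0.02) with early stopping on validation loss (patience
100 epochs, cap 2000) and restoration of the best weights; the epoch loop
wraps scikit-learn's `MLPRegressor.partial_fit`, so a fixed seed and data
give a bit-identical report. "20 hidden layers" in the source description is
read as 20 hidden units in one layer, the standard fitting-tool default.
The published split R² values were obtained on unavailable real spectra and
serve as documentation; the tests pin seeded results on synthetic spectra
instead (test R² ≥ 0.95 with zero spectral noise across 10 seeds, ≥ 0.8 at
the default 2% noise).

Peak finding reports local absorbance maxima whose prominence exceeds a
fraction (default 5%) of the spectrum's absorbance range.

## Synthetic study generator

The generator's defaults are the study conditions: storage at
298.15/308.15/318.15 K for 336/154/84 days sampled every 56/14/7 days with 10
replicates per point; per-index true parameters equal to the packaged
prediction-model constants; Gaussian replicate noise with per-index standard
deviations at the scale of the printed dispersions (hardness ≈ 70/40 gf,
L* ≈ 2.8, total acid ≈ 0.2 g/kg, sensory ≈ 0.3 points), or optionally a
relative noise level (the recovery tests use 2%). Sensory scores live on the
1–9 scale; a series is truncated after the last time point whose true mean is
above the index's floor (a panel stops scoring a spoiled product), and
replicate draws are clipped to the scale. At the defaults this only shortens
the 45 °C sensory series (score crosses 1 near day 66).

E-tongue profiles are drawn per acceptability period from a multivariate
normal whose sourness means rise (14.79 → 17.5) and umami means fall
(2.03 → 1.31) across periods while the other four channels stay flat, with an
equicorrelation of 0.6 across channels (a common sensor factor — e-tongue
channels drift together), three profiles per sampling day at 45 and 35 °C
(75 total). NIR spectra are a sloped baseline plus Gaussians at
960/1150/1450 nm whose amplitudes grow affinely with storage day and total
acid, with 2% multiplicative noise by default; 90 samples with days drawn
uniformly over the 45 °C storage window.

What passing on synthetic data does and does not show: the generator matches
the study's sampling design, noise scale and cluster geometry, but its noise
is Gaussian and homoscedastic (real texture dispersions are strongly
heteroscedastic), its taste clusters are exactly normal with a single shared
correlation, and its spectra contain no instrument baseline drift or
scattering effects. Recovery and separability results therefore validate the
estimators' correctness and stability, not their robustness to real
instrument artefacts.

## Problem sizes and numerical choices

The test suite and acceptance checks run at the study's own scale (at most 13
time points per series, 75 taste profiles, 90 spectra of 141 grid points);
the stochastic guarantees use 200 seeded study replicates for parameter
recovery, 100 split seeds for discriminant separability and 10 seeds for
network generalization. Degenerate inputs fail loudly rather than silently:
zero-variance responses, constant targets, constant attributes under
standardization, single-temperature thermal fits and out-of-range period days
all raise typed errors. CSV round-trips use `repr` on write and round-trip
float parsing on read, so written studies reload bit-exactly.

## Known limitations

* Only zero- and first-order kinetics are provided; no Weibull, Gompertz or
  Q10-style models, and no non-isothermal storage profiles.
* Published fitted parameters (per-temperature rate tables, activation
  energies) are not exactly reproducible from the printed means — refits land
  within ~2–9% — because the original fitting data and solver settings are
  unavailable; the packaged copies of those tables are treated as reference
  constants, and all pipeline guarantees are established on synthetic data.
* The e-tongue sensor-to-attribute mapping and replicate pooling of the
  original instrument are unknown; the generator's cluster geometry is a
  plausible stand-in, not a calibrated emulation.
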