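# Methods

This note documents the models, numerical choices and known limitations of
kiwispec, in the spirit of a package vignette. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Reflectance calibration and spectral windows

Raw counts are converted to relative reflectance per pixel and band:

    I = (I_raw − I_dark) / (I_white − I_dark)

Dark frames capture sensor thermal signal; white frames a ~99 % diffuse
reflector. The equation defines no clipping, and none is applied: noisy
pixels with `raw < dark` legitimately produce negative reflectance, which
matters downstream (distribution maps report, rather than hide, out-of-range
predictions). A non-positive `white − dark` at any band aborts with the
offending band named, since it indicates a saturated or defective reference.

Both camera ranges have noisy ends; the working windows are 450–1000 nm
(Vis/NIR, 512 bands over 380–1023 nm) and 951–1670 nm (NIR, 256 bands over
874–1734 nm). Trimming keeps bands with `lo ≤ λ ≤ hi` inclusive.

Wavelength→band lookup is nearest-neighbor with a tolerance of half the
local band spacing: named wavelengths (700 nm mask band, the published
effective wavelengths) need not coincide with band centers. Pixel-wise
mapping relaxes the tolerance to one full spacing, because a named EW can
sit marginally past a trim boundary (e.g. 1000 nm against a 450–1000 nm
window whose last band center is 999.1 nm).

ENVI I/O is implemented in the package (text header + flat binary; BIL, BIP
and BSQ interleaves; little/big endian) with a bit-exact round-trip
guarantee, tested on hand-laid byte fixtures.

## Synthetic scenes

The generator exists so that every pipeline stage can be exercised against
ground truth; it emulates the statistical structure the pipeline assumes,
not kiwifruit radiative transfer.

* **Attributes.** Per fruit, firmness/SSC/pH are drawn independently and
  uniformly over the reference dataset's ranges (firmness 44.086–642.213
  N cm⁻², SSC 13.56–18.69 °Brix, pH 3.64–4.04); only range, mean and SD of
  the real distributions are known, so uniform is the least-committal
  choice, with a range-truncated Gaussian (published mean/SD) available for
  realism.
* **Spectra.** Reflectance is a smooth continuum (low in the blue, broad
  peak near 820 nm) minus Gaussian dips at 673, 835, 970, 1200, 1460 nm —
  the chlorophyll, carbohydrate O–H and water features of kiwifruit flesh.
  Dip depth is *linear* in the attributes through a link matrix (defaults:
  firmness→673 nm; SSC→835+970 nm; pH→1200+1460 nm). The links are free
  modelling parameters, not estimates of fruit biology; their defaults put
  each attribute's signature at distinct centers so that recovery of the
  attribute by a calibration model is an identifiability statement. Because
  pH links only to NIR features, it is (realistically) not predictable from
  the Vis/NIR window.
* **Scenes.** Four fruits per scan, rendered as non-overlapping disks
  (radius 15 px in a 100×100 frame) on a flat 0.05-reflectance background;
  shape realism is explicitly not a goal. An optional left-to-right linear
  ramp of one attribute within each fruit (`gradient`, as a fraction of the
  fruit's value at the rim) gives pixel maps a ground-truth spatial pattern.
  Raw counts are synthesized by inverting the calibration equation against
  a constant dark frame (96 counts) and a smooth white frame (~3000 counts),
  so calibration is exercised nontrivially and round-trips to machine
  precision at zero noise. Sensor noise is i.i.d. Gaussian in reflectance
  units added to the raw frame only (default 0.002; 0 for exactness tests).
  All randomness flows through `numpy` Generators seeded from the scene
  seed; identical configuration + seed reproduces bit-identical cubes.

What passing tests on these scenes shows: the pipeline's algebra, selection
logic and bookkeeping are correct, and the models recover a known linear
spectrum–attribute link at realistic sample sizes (88 calibration / 45
prediction) and noise. What it does not show: performance on real fruit,
where scattering, fruit-to-fruit continuum variation, curvature-induced
illumination gradients and correlated attributes make the problem harder.

## Segmentation

The fruit mask thresholds a single band (default 700 nm, where flesh
reflects strongly and the dark belt does not); the default threshold is
Otsu's method on that band, with a numeric override. Labeling uses
4-connectivity (conservative against diagonal bridges between adjacent
fruits); components under `min_area = 50` px are discarded as speckle;
regions are ordered by centroid, top-to-bottom then left-to-right. The ROI
is the whole fruit region and its per-band arithmetic mean spectrum
represents the sample. Whether to threshold reflectance or raw counts is a
genuinely open choice; reflectance is used, being illumination-corrected.

## Effective-wavelength selection

* **BW.** The reduced-form regression coefficients of the full-spectrum
  PLSR model at its LOO-optimal LV count; the k largest |BW| win. With
  `peak_picking=True` candidates are first restricted to local maxima of
  the |BW| curve, so selections spread across distinct spectral features
  instead of crowding the flanks of one peak.
* **SPA.** For every start band and chain length m ≤ `max_vars`, the chain
  appends the band with the largest norm after projection onto the
  orthogonal complement of the chain span. Projections run on centered,
  unit-norm columns of the internal calibration part (standard SPA
  formulation; prevents magnitude bias); the winner is the chain with
  minimum MLR RMSE on a held-out validation part (an internal seeded 1/3 of
  the calibration set, consistent with the pipeline's global 2:1
  convention). Exactly collinear columns have zero residual norm and are
  never co-selected. Correctness is tested against exhaustive enumeration
  of all start×length chains on 8-band problems.
* **GAPLS.** Many short runs (default 100) of a small binary GA:
  population 30, 100 fitness evaluations per run, one-point crossover at
  probability 0.5, 1 % bit mutation, at most 30 active bands per
  chromosome (repaired by random deactivation), tournament selection with
  worst-replacement. Fitness is 5-fold CV PLS RMSE minimized over the LV
  count. Each run's best chromosome votes for its bands with weight equal
  to the run's best CV explained variance (1 − RMSECV²/var(y)), so
  uninformative runs count less — the aggregation weighting is a documented
  design choice, as is the default cutoff (bands reaching ≥ half the
  maximum weighted frequency; `top_k` and `freq_cutoff` override it).

All tie-breaks resolve to the lowest band index; every selector is
deterministic given its seed. A note on symmetry: the GA's random draws are
positional, so stream-level equivariance under band permutation cannot hold
with a fixed seed; equivariance is instead verified on data whose active
bands are identifiable, where the outcome is fitness-determined.

## Calibration models

Preprocessing is mean-centering only — no SNV/MSC/derivative pretreatment
is applied by default (none is assumed by the reference workflow); opt-in
hooks are deliberately out of scope of the default path.

* **MLR** solves least squares with intercept via `lstsq`. It requires
  `n_samples > n_bands + 1` and refuses genuinely collinear varying bands
  with a hint to run selection first; constant bands degrade gracefully to
  the intercept. LOO-CV residuals come from the hat-matrix identity
  `e_loo = e/(1 − h_ii)` at no refit cost.
* **PLSR** is single-response NIPALS on mean-centered X and y, with
  reduced-form coefficients accumulated per component (`B_a = Σ q_j r_j`,
  `r_j` the orthogonalized weights). The LV count is the argmin of LOO
  RMSECV over 1..`max_lvs` (default 20; ties to the smaller count).
  Extraction stops early when the deflated covariance collapses. The
  implementation is cross-checked against scikit-learn's NIPALS in a test,
  which is never the implementation path.
* **LS-SVM** solves `[[0, 1ᵀ],[1, K + I/γ]] [b; α] = [0; y]` with RBF
  kernel `exp(−‖u−v‖²/σ²)` on mean-centered spectra. LOO residuals use the
  closed form `e_i = α_i/(A⁻¹)_ii` (verified against explicit refits), so
  the grid search is cheap. Tuning is a two-step search: a 10×10
  log-uniform grid over [1e−2, 1e8]² for (γ, σ²), then a 10×10 grid
  spanning one coarse cell around the optimum, clamped to the bounds, with
  the coarse optimum retained so refinement never worsens the LOO RMSE.
  The default upper bound 1e8 (rather than 1e5) reflects that optimal γ on
  near-noiseless data is routinely ≥ 1e6. An ill-conditioned system gets
  one 1e−8 ridge-jitter retry.

## Evaluation

`split_dataset` floors the calibration share (`floor(2n/3)`: 133 → 88/45),
optionally within variety strata. `evaluate` reports R/RMSE for
calibration, LOO cross-validation (from the model's stored fold
predictions) and prediction, plus SEP, Bias, the prediction-set SD of the
*measured* values (divisor M−1) and RPD = STD/SEP. That STD convention is
verified: it reproduces the reference dataset's printed RPDs to 2 d.p.
(e.g. 189.78/40.3191 = 4.71). A perfect fit (SEP = 0) is flagged as
infinite RPD rather than an error. Full precision is kept internally;
rounding to reporting precision happens only at presentation.

## Distribution maps

A reduced image is formed at the model's EWs, the model predicts each
masked pixel, and the map stores raw values: pixels outside the display
range (default: the calibration-set y range) are counted in
`out_of_range_fraction` and saturated only at render time. Per-pixel pH is
not physically meaningful (pH characterizes the juiced whole fruit), so pH
maps require an explicit flag. The published SPA-MLR mapping equations are
shipped as version-1 coefficient fixtures exactly as printed (7 significant
figures) and are usable as `RegressionModel`s anywhere a fitted model is.

For linear models, pixel-wise prediction commutes with spatial averaging
exactly (to float tolerance), which ties map means to whole-fruit
predictions and is covered by a test.

## Problem sizes

The test suite and acceptance script run the full pipeline at the reference
scale — 133 fruits (34 scenes of four 15-px-radius fruits, 512 bands
trimmed to 437) with noise SD 0.002 — chosen as the realistic working point
for this workflow; unit tests use smaller cubes and band counts where the
property under test does not depend on scale.

## Known limitations

* The generator's linear attribute–dip link makes linear models exactly
  well-specified; LS-SVM's nonlinear headroom is therefore exercised on
  constructed nonlinear targets, not on scenes.
* Disk-shaped fruits and a flat background make segmentation easy by
  construction; Otsu robustness is tested only down to ~10× class
  separation over noise.
* Touching fruits (watershed), stem/calyx exclusion, BRDF/curvature
  correction and spectral pretreatments are out of scope.
* GAPLS at its 100-run default is the slowest stage (tens of seconds on a
  single core at reference scale); tests use fewer runs where aggregation
  behavior itself is not under test.
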