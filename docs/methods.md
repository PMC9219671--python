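# Methods

This note documents the models, conventions and design choices behind
`serslda`: what the synthetic generator emulates, how each preprocessing
step is defined, how the discriminant model is solved, how feature
importance is computed, and what the tests do and do not establish.

## Synthetic data model

Real acquisitions of this kind — SERS spectra of one glycoprotein (ACE)
purified from three tissues — are not publicly available, so the package
generates analogs with the statistical structure the analysis relies on.
One spectrum is

    y(ν) = b(u) + Σ_j L_j(ν) + ε(ν),   u = (ν − ν_min)/(ν_max − ν_min)

* **Grid**: 1024 equally spaced points over 250–1900 cm⁻¹ (the instrument
  resolution of the emulated spectrometer), so that the 300–1800 cm⁻¹
  analysis window is a proper subset. On this grid the window retains 931
  points; a 941-point grid over the same span retains exactly 855, which
  is used when the analysis should run at that dimensionality.
* **Bands** `L_j`: Lorentzian by default (the usual Raman line shape;
  Gaussian selectable), parameterized by centre, half-width at half
  maximum, and amplitude. The three default class profiles share the 31
  bands of the packaged assignment table that are observed in all three
  classes, with identical centres across profiles; the five most intense
  bands (766, 1011, 1348, 1459, 1663 cm⁻¹) have amplitude 1.0 and the
  rest 0.35, with HWHM 6 cm⁻¹. Each class adds its exclusive minor bands
  (seminal: 453, 492, 572, 591, 683, 1069, 1095; lung: 1623; heart: 502,
  1279, 1600 cm⁻¹) at amplitude 0.15 — 15% of the strongest band,
  matching the "minor vibration band" character of the real differences —
  with HWHM 5 cm⁻¹. Per-spectrum jitter: centre N(0, 0.5 cm⁻¹),
  amplitude ×(1 + N(0, 0.05)).
* **Baseline** `b`: cubic polynomial in u with mean coefficients
  (0.6, 0.4, −0.3, 0.15) and per-spectrum coefficient jitter N(0, 0.05),
  emulating the smooth fluorescence background that rubber-band
  correction must remove.
* **Noise** `ε`: i.i.d. Gaussian, SD 0.03 (3% of the strongest band) —
  consistent with the high signal-to-noise of long-accumulation SERS
  acquisitions.
* **Dataset**: 197 spectra split 66/66/65 across the classes (the
  per-class counts are not documented for the original experiment; an
  even split is the neutral choice). Cosmic-ray spikes are planted on
  request: by default 6 spectra receive 1–3 single-channel positive
  spikes of 20× that spectrum's SD, at grid points inside the analysis
  window, with the spiked indices returned as exact ground truth.

Determinism: every function takes a seed; a dataset seed spawns one child
seed per spectrum, and the draw order inside a spectrum (baseline
coefficients, per-band centre and amplitude, noise vector) is part of the
contract, so seeded draws can be replayed independently.

**What the generator does not emulate**: plasmonic enhancement physics,
substrate heterogeneity, detector response, wavelength-dependent noise,
band asymmetry, or correlated (non-diagonal) noise. Consequently, perfect
classification on the synthetic data shows the chain is correct and
sensitive at the planted effect size; it does not by itself establish
performance on real instrument data.

## Preprocessing

Fixed stage order: range selection → rubber-band baseline → outlier
elimination → standardization → smoothing. The order is recorded in the
run metadata and asserted by a test.

* **Range selection**: keep grid points with 300 ≤ ν ≤ 1800 cm⁻¹
  (inclusive on both ends).
* **Rubber-band baseline**: the lower convex hull of the (ν, y) points,
  computed by Andrew's monotone chain and linearly interpolated between
  hull vertices; the corrected spectrum y − baseline is ≥ 0 with equality
  at the vertices, and both endpoints are always vertices. Verified
  against an exhaustive pairwise-chord convex-envelope oracle.
* **Outlier elimination**: per wavenumber, the median and MAD across
  spectra define a robust scale 1.4826·MAD; a spectrum is dropped
  entirely if any of its points exceeds median + 8 × scale at that
  wavenumber (cosmic-ray hits are positive and single-channel, so the
  rule is one-sided and removal is whole-spectrum). The original
  experiment's exact algorithm is not documented; this rule is a stand-in
  with one stabilization: each column's scale is floored at the global
  robust SD of all deviations. Without the floor, the columns adjacent to
  the range edges — which baseline correction pins to single noisy hull
  vertices — have near-degenerate MADs and heavy tails, and ordinary
  spectra get flagged there in a substantial fraction of runs. Planted
  20-SD spikes sit roughly two orders of magnitude above either scale, so
  the floor leaves their detection untouched (verified exactly over 40
  seeds at full scale).
* **Standardization**: each spectrum to its own mean and SD. The
  population SD (divide by n) is used here and for archetype SDs; the
  choice is a convention and tests pin it.
* **Smoothing**: Savitzky–Golay, window 11, order 2, mirror-padded edges
  so length is preserved. Rows are standardized *before* smoothing and
  not re-standardized after; smoothing perturbs row means by ≲3×10⁻⁴ and
  shrinks row SDs by a few percent.
* **Archetypes**: per-class mean spectrum with per-wavenumber population
  SD, as a reproducibility summary; requires ≥ 2 members.

## Discriminant model

With class sets D_i, class means x̄_i and grand mean X̄:

    S_W = Σ_i Σ_{x∈D_i} (x − x̄_i)(x − x̄_i)ᵀ
    S_B = Σ_i (x̄_i − X̄)(x̄_i − X̄)ᵀ

The between-class sum is **unweighted** over classes (no N_i factor), and
is paired with the unweighted mean of class means as X̄, so that
Σ_i (x̄_i − X̄) = 0 exactly and rank(S_B) ≤ c − 1 holds exactly regardless
of class sizes; a three-class problem therefore has exactly two
discriminant directions with nonzero eigenvalue. The textbook N_i-weighted
form (with the pooled sample mean) is available via `weighted=True`; with
near-equal class sizes the two subspaces are essentially identical.

The projection matrix V solves S_B v = λ (S_W + γ·tr(S_W)/p·I) v as a
symmetric generalized eigenproblem, eigenvalues descending. The ridge
term is required whenever features outnumber training samples (p ≈ 931
vs n ≈ 96 here, so S_W is always singular at full resolution); the
default γ = 10⁻³ adds a sliver of the average within-class variance to
every direction. With γ = 0 and singular S_W the fit refuses and points
at the parameter. Columns of V are unit-normalized with the sign fixed so
the largest-magnitude entry is positive (reproducibility only). On small
nonsingular instances the subspace agrees with a dense eigendecomposition
of S_W⁻¹S_B to < 10⁻⁶ rad principal angles, and in the two-class case
with Fisher's closed form S_W⁻¹(x̄₁ − x̄₂).

Scores are Z = (X − X̄)V. The centering is a deliberate addition: it
anchors the LD-plane origin at the overall mean and has no effect on
nearest-centroid classification. Classification assigns the nearest
centroid (projected class mean) in Euclidean LD distance, ties toward the
lexicographically smallest class name. Metrics are per-class precision,
sensitivity and F (harmonic mean) plus overall accuracy; metrics that are
undefined (class absent from truth or predictions) are reported as NaN
and flagged, never silently zeroed.

Train/test handling: stratified 50:50 random split (every class must
populate both halves), then the training half is augmented with 2
Gaussian-noise copies at 5% of each feature's training SD — a standard
cheap regularizer for small spectral datasets.

## Feature importance

The linear score of class i at input x is z·z̄_i − ‖z̄_i‖²/2 with
z = (x − X̄)V, so its gradient in feature space is w_i = V z̄_i. The c×p
weight matrix is normalized by its global maximum absolute entry.
Whether the original analysis derived its per-class importances this way
or from one-vs-rest coefficients is not documented; this definition is
declared, not inferred.

* **Filter**: per class, keep features with |w| strictly above that
  class's 95% linear-interpolation quantile of |w| (≈ 42–43 of 855
  features per class), and drop 10 features at each range edge (edge
  contributions are artifacts of baseline pinning and windowing; the
  margin width is a choice). With three classes at 855 features, at least
  855 − 3×43 = 726 features are eliminated for all classes.
* **Ranking**: by max-over-classes |normalized weight|, descending, ties
  toward the lower wavenumber; quantile-retained features first, the
  filtered remainder after, so the ranking covers all p features.
* **Incremental experiment**: for k = 1, 2, …, refit the full
  split → augment → LDA → nearest-centroid chain on the top-k feature
  columns over 20 random splits and record mean ± SD accuracy. The same
  per-repeat split seeds are reused across k (common random numbers), and
  the sweep stops once the mean stays ≥ 0.999 for 5 consecutive k — a
  concrete stand-in for an unquantified "until convergence".
* **Intervals**: the top-k features (k = 25 by default) are attributed to
  the class with the largest |weight| and merged into maximal runs with
  gaps ≤ 2 grid steps; each interval reports its cm⁻¹ bounds and peak
  normalized importance, and is matched against the band table.

A note on band-shape: per-spectrum standardization and centre jitter can
make the importance profile of a band peak on its flanks and dip at the
apex, so an interval can straddle a planted centre with a small gap at
coarse grid resolution. The planted-recovery tests therefore run on the
full 1024-point grid, where every band spans several features.

## Band table

The packaged CSV carries the full 50-row assignment table: per-class band
positions (absences preserved), vibrational-mode assignment, amino acid or
dipeptide attribution, literature band position and reference tag. Two
internal inconsistencies of the source data are preserved rather than
resolved: (1) the narrative seminal-only list has seven bands while the
table has nine seminal-only rows (extra rows at 435 and 1441 cm⁻¹); (2)
in the lung/heart pairwise comparison the narrative places 1623 cm⁻¹ on
the lung side and 502/1279/1600 cm⁻¹ on the heart side, while the table's
columns have them swapped. `exclusive_bands` follows the table (the
structured source); the synthetic generator's default profiles follow the
narrative split so that each class owns a distinct, physically plausible
set of minor bands. Both choices are annotated in the API docs.

Peak assignment matches each picked peak to the nearest position in the
class's column within 5 cm⁻¹ (typical SERS position variability), ties to
the smaller row index; rows without assignment text (e.g. 502 cm⁻¹) match
but report as unassigned.

## Problem sizes, tolerances, degeneracies

* Default end-to-end run: 197 spectra × 1024 points → 191 × 931 matrix;
  one run takes ~1 s on a single core, the incremental curve a few
  seconds more (it converges and stops after single-digit k).
* Property tests run at reduced sizes chosen for coverage per unit time:
  oracle comparisons at p ≤ 10, planted-spike trials on 24-spectrum sets
  (plus full-scale checks), the amplitude–accuracy monotonicity sweep on
  512-point grids with 60 spectra per level.
* Numerical tolerances: scatter symmetry is enforced by averaging with
  the transpose; eigenvalues are clipped at 0; subspace comparisons use
  principal angles (sine-based for near-zero angles); standardization is
  exact to 10⁻⁹.
* Degenerate inputs raise typed errors: constant spectra (SD 0), single
  member groups, single-class matrices, empty range selections,
  all-removed outlier passes, γ = 0 with singular S_W, even SG windows.

## Known limitations

* The outlier rule and the importance definition are documented stand-ins
  for procedures the original analysis does not fully specify.
* The reported 100% separation is a property of the synthetic conditions
  (planted effect size vs noise); the package makes the effect size a
  parameter and verifies chance-level behaviour when it is zero, but no
  claim is made about real instrument data.
* Baselines other than rubber-band (polynomial, asymmetric least squares)
  and classifiers beyond nearest centroid in LD space are out of scope.
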