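# serslda

Classification of surface-enhanced Raman scattering (SERS) spectra of a
glycoprotein with linear discriminant analysis built directly from scatter
matrices, plus the wavenumber feature-importance procedure that identifies
which spectral intervals drive the separation.

## The problem

Angiotensin I-converting enzyme (ACE) is the same protein whether it is
purified from seminal fluid, lung or heart tissue, but it is N-glycosylated
differently in each cell type. Those glycan differences leave only subtle
traces in SERS spectra: the major vibrational bands coincide, and the
classes differ in a handful of minor bands and small shifts. This package
implements the chemometric chain that separates such spectra anyway:

1. **Preprocessing** — select 300–1800 cm⁻¹, rubber-band baseline
   correction (lower convex hull), median/MAD cosmic-ray outlier removal,
   per-spectrum standardization, Savitzky–Golay smoothing (window 11,
   order 2). The result is a samples × features matrix **X**.
2. **Discriminant analysis** — within-class scatter
   S_W = Σᵢ Σ_{x∈Dᵢ} (x − x̄ᵢ)(x − x̄ᵢ)ᵀ and between-class scatter
   S_B = Σᵢ (x̄ᵢ − X̄)(x̄ᵢ − X̄)ᵀ; the projection **V** holds the leading
   eigenvectors of S_W⁻¹S_B (solved as a symmetric generalized
   eigenproblem with ridge shrinkage, since p ≫ n for full-resolution
   spectra); scores Z = (X − X̄)V with two components LD1, LD2; nearest
   centroid classification with per-class precision / sensitivity / F.
3. **Feature importance** — per-class weight vectors wᵢ = V z̄ᵢ,
   normalized, filtered at the per-class 95% absolute-weight quantile with
   a boundary margin, ranked, refit incrementally on the top-k features
   over repeated random splits, and grouped into contiguous cm⁻¹ intervals
   that are matched against a packaged 50-row vibrational band-assignment
   table.

The original instrument spectra are not publicly deposited, so the package
ships a first-class synthetic generator (`serslda.synth`) that emulates
their statistical structure — shared major bands from the assignment
table, class-exclusive minor bands, baseline drift, noise, and cosmic-ray
spikes with exact ground truth — and every claim is tested against it.

## Worked example

```python
from serslda import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=42))
print(f"n={report.stages['n']} p={report.stages['p']} "
      f"test accuracy {report.metrics['accuracy']:.2f} "
      f"k@1.0 {report.k_at_full_accuracy}")
```

prints

```
n=191 p=931 test accuracy 1.00 k@1.0 2
```

i.e. the 197 generated spectra lose exactly the 6 spike-contaminated ones
(191 × 931 matrix), the held-out half is classified perfectly, and the
incremental-feature experiment already reaches mean accuracy 1.0 with the
top 2 ranked features. The `examples/` directory has one short script per
capability (generation, preprocessing, discriminant fit, importance and
intervals, band assignment, full run); each prints the numbers it computes
and a line on what they mean. For instance `examples/03_train_lda.py`:

```
train 96 (augmented to 288), test 95
leading eigenvalues: [1453.3  452.7]
test accuracy: 1.00
  heart    precision 1.00  sensitivity 1.00  F 1.00  n=31
  lung     precision 1.00  sensitivity 1.00  F 1.00  n=32
  seminal  precision 1.00  sensitivity 1.00  F 1.00  n=32
```

## Layout

```
src/serslda/       synth, io, preprocess, lda, importance, bands, pipeline
src/serslda/data/  packaged ACE band-assignment table (CSV)
examples/          one narrative script per capability
tests/             unit, property and end-to-end suites
docs/methods.md    models, conventions, parameter choices, limitations
```
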