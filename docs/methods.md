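# Methods

This note records the model assumptions, numerical conventions and design
choices behind `fluorotax`, and what the synthetic-data tests do and do not
demonstrate about field data.

## Pigment chemotaxonomy

Group compositions are point estimates from non-negative least squares on
the eleven marker pigments: minimize ‖b − (R/100)ᵀx‖₂ with x ≥ 0, where b
is the sample's pigment concentration vector (µg/L) and R the fixed
nine-group ratio matrix. Fractions are x/Σx; the per-group chlorophyll x
is kept alongside. Choices:

- The misfit is computed on raw concentrations, unweighted. Weighting by
  pigment (or fitting chlorophyll-normalized ratios) would change the
  relative influence of abundant pigments; the unweighted-concentration
  convention is this package's documented choice, not a claim about any
  particular laboratory's practice.
- The ratio matrix is held fixed. CHEMTAX-style iterative re-optimization
  of ratios is deliberately out of scope; ratios are a versioned data file
  (`data/ratio_matrix.csv`).
- Neoxanthin and lutein are carried in `PigmentSample` but excluded from
  the fit (they carry no weight in the ratio matrix).
- An all-zero pigment vector raises an explicit "undefined composition"
  error rather than returning NaN fractions.

Uncertainty sampling (e.g. MCMC over the non-negative orthant) is not
implemented: everything downstream consumes point compositions only.

## TChla calibration

`fit_robust_zero_intercept` estimates TChla = slope·F by iteratively
reweighted M-estimation (statsmodels RLM): Tukey bisquare ψ with tuning
constant 4.685, scale from the MAD of residuals, at most 50 iterations,
1e-8 slope tolerance. The zero intercept guarantees non-negative predicted
chlorophyll. Bisquare weights reach exactly zero, so the outlier rule
(weight < 10⁻³) is a genuine rejection rule rather than a soft threshold.
Conventions and edge cases:

- Standard error is the asymptotic M-estimator value reported by the
  fitter on the final weights.
- r² is computed through the origin on non-outlier points,
  1 − SSres/Σy² (the uncentered convention appropriate for zero-intercept
  fits; a centered convention can go negative).
- Exactly proportional data collapse the MAD scale to zero, where IRLS is
  undefined; the fit then falls back to the OLS slope with unit weights
  (OLS is the M-estimate in that degenerate case).
- Channel selection fits every channel independently and takes the
  highest r²; ties break toward the shorter wavelength; channels that
  cannot be fitted (all-zero fluorescence) are recorded as failed.
- The published model (slope 0.54095, se 0.02205, r² 0.8844 at 435 nm,
  n = 271) is available as `published_calibration()` and is applied to
  raw — never standardized — 435 nm fluorescence.

When matching discrete bottle depths to sensor readings, nearest-1-m-bin
matching with a ±1 m tolerance is the intended convention.

## Spectral decomposition and reconstruction

Unknown spectra are standardized (divided by their nine-channel sum), then
decomposed over the active reference spectra by box-constrained least
squares (scipy `lsq_linear`, BVLS, bounds [0, 1], tol 1e-12). There is
deliberately **no** Σα = 1 constraint: only the bounds and minimal
residual are imposed. The assemblage is p = Σαᵢ·Pᵢ, renormalized to sum
to 1; the raw Σα is kept as a diagnostic.

**Non-uniqueness.** With more references than channels the minimizer is an
affine family intersected with the box; BVLS returns one deterministic
member of it. Two consequences are documented and tested:

- converting a reference record's own spectrum against the full database
  reproduces its spectrum essentially exactly (residual < 1e-8) but its
  composition only approximately (mean absolute error < 0.05 per group on
  the synthetic database) — exact self-reproduction holds only when the
  active references are linearly independent (n ≤ 9);
- reconstructed p is stable under exchanging collinear references only
  when their compositions agree; the maximum pairwise correlation among
  active references is surfaced in the conversion diagnostics.

Near-duplicate reference spectra are not deduplicated. TChla_MEX comes
from the raw 435 nm channel, so composition is intensity-invariant while
biomass scales with intensity.

## Cross-validation, bootstrap, PERMANOVA

- Leave-one-out excludes every record sharing the target's (cruise,
  station, depth) key, so replicate bottles never vouch for each other;
  leave-area-out excludes the target's whole area.
- Per-group comparison: ordinary regression of estimated on true
  proportion (slope, t, p, r²), mean absolute difference in percentage
  points, and a 95% difference interval. The interval half-width is
  computed both as empirical 2.5/97.5 percentiles (primary; robust to
  skew) and as 1.96·sd (for comparability with symmetric ± reporting).
  Zero-variance truth skips the regression with a flag.
- Bootstrap sensitivity resamples the same-key-excluded reference set with
  replacement (same size), R = 1000 by default, fully seeded; CV is
  100·sd/mean of the converted proportion per group, undefined (excluded,
  counted) where the mean proportion is zero.
- PERMANOVA partitions Gower-centered squared Bray–Curtis distances
  against the nine standardized channel values as continuous predictors,
  added sequentially in wavelength order (Type-I SS, the
  McArdle–Anderson distance-based RDA construction; verified to match R
  `vegan::adonis2(..., by="terms")` to printed precision). Pseudo-F uses
  the full-model residual; p-values permute the distance matrix rows.
  Because standardized channels sum to 1, one channel is always aliased
  and reported as skipped. Constant predictors are likewise skipped.

## Field pipeline

- Observations are maximal runs at ≥ 2 m depth lasting ≥ 300 s; any
  shallower sample breaks the run (no gap tolerance — a configurable
  option left at 0 s).
- Despiking: per whole-second median (midpoint-average for even counts),
  timestamped at the window start.
- Binning: half-open [k, k+1) m bins from 2 m; the per-bin mean spectrum
  is converted, so each bin yields one composition and TChla_MEX. Empty
  bins are absent and linearly interpolated only at integration time.
- QCoD = (Q3 − Q1)/(Q3 + Q1) with quartiles by linear interpolation
  between order statistics (numpy default). QCoD is sensitive to the
  quartile convention; this one is pinned. Q1 + Q3 = 0 is undefined (NaN,
  excluded from summaries, never flagged). The heterogeneity threshold is
  mean + 2·sd over all defined QCoD values.
- Integration is trapezoidal over depth of fraction × TChla_MEX per group
  (1 µg/L over 1 m ≡ 1 mg/m²); because linear interpolation commutes with
  the per-bin sum, group integrals add up to the TChla integral exactly.
- NMDS: two dimensions, Kruskal stress-1, 20 seeded random restarts
  (scikit-learn SMACOF with non-metric scaling); all-identical rows short-
  circuit to coincident points with stress 0.
- Depth is taken as already expressed in meters by the instrument export;
  no pressure-to-depth conversion is re-derived. Down- and up-cast samples
  within an observation are binned together.

## Synthetic data: what it emulates, what it does not

`make_endmember_spectra` builds nine standardized Gaussian-mixture shapes
over the nine channels, with a small seeded multiplicative jitter. They
respect the qualitative photophysics that motivates the instrument — broad
blue (≈ 420–470 nm) main peaks; dinoflagellates elevated at 505 nm
relative to diatoms (peridinin–chlorophyll protein); cyanophytes and
prochlorophytes carrying 570/590 nm phycobilin shoulders — and they are
constructed to be mutually identifiable (condition number ≈ 37, max
pairwise correlation ≈ 0.89, checked at generation time). They are
**synthetic**: not measured excitation spectra, and more separable than
real taxa, whose excitation spectra overlap strongly. Consequently the
synthetic recovery results bound what the pipeline's numerics can do, not
what any instrument achieves at sea.

`simulate_reference_db` draws, per sample: an area (cycling through up to
four area labels), a composition from an area-specific Dirichlet
(dominance-structured means — diatom-heavy subarctic areas, a
picocyanobacteria-heavy warm-current area, a small-eukaryote-heavy
marginal sea; concentration parameter 2.0, i.e. most samples have one or
two leading groups, the regime these contrasting regions represent),
TChla log-uniform in 0.05–5 µg/L, pigments from the ratio-matrix forward
model with 5% lognormal noise, and a spectrum from the
chlorophyll-weighted endmember mixture with 5% multiplicative channel
noise. The calibration is fitted on the simulated 435 nm channel and its
outliers excluded, exactly as with field data. Everything is deterministic
under the seed.

Known behaviour worth understanding: even at zero noise, leave-one-out
slopes settle slightly below 1 (≈ 0.92 at n = 200) because bounded
coefficients cannot extrapolate outside the convex hull of the remaining
references — targets near the compositional simplex boundary are pulled
inward. This is a property of the bounded decomposition itself, shared by
any reference-based implementation of it, and it grows as the reference
set thins or compositions become more extreme. Recovery error increases
monotonically with spectral/pigment noise (tested at 0%, 5%, 15%).

`simulate_cast` descends at 0.2 m/s sampling at 10 Hz through
user-specified layers, with an optional Gaussian subsurface chlorophyll
maximum and optional spike contamination (for exercising the median
despiking). Instrument gain is an arbitrary constant (2.0 raw units per
µg/L per unit mixture); only ratios of channels and the fitted calibration
matter downstream.

## Problem sizes used in the test suite

The default suite simulates campaigns of 40–200 samples, casts of ≤ 80 m,
bootstrap with small R, and 200 PERMANOVA simulations at n = 50 with 199
permutations — sizes chosen so the full suite completes in well under a
minute while still exercising every code path at campaign-like scale.

## Known limitations

- The conversion transfers whatever biases the reference chemotaxonomy
  has; groups lacking distinctive optical signatures (the small eukaryote
  lineages) are the first to degrade under leave-area-out validation, and
  merging them (`aggregate_groups`) is the recommended reporting level in
  that regime.
- No photochemical quenching correction: daytime near-surface fluorescence
  underestimates chlorophyll, and the calibration absorbs this only on
  average.
- No up/down-cast separation and no gap tolerance in segmentation.
- The Bayesian uncertainty layer of the compositional inversion is not
  implemented (point estimates only).
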