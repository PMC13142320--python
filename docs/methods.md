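# Methods

This note documents the statistical procedures implemented in `fcenrich`,
the conventions chosen where several were defensible, and what the synthetic
validation does and does not establish.

## The enrichment curve and its aggregates

The core quantity relates one reference atlas (a per-region molecular or
network annotation) to one functional connectome (a symmetric region x
region matrix, conventionally Fisher-z Pearson correlations with the
diagonal stored as 0 and excluded from every mean).

1. Atlas values are converted to percentiles of their own distribution:
   percentile_i = 100 · (average ascending rank of value_i) / N. Tied values
   share the average-rank percentile, so tied regions always enter and leave
   threshold masks together; a tie-free maximum sits at exactly 100 and the
   minimum at 100/N > 0.
2. For each threshold t on the grid {0, 5, ..., 95}, the connectome is
   masked to edges between regions with percentile strictly greater than t,
   and the surviving edges are averaged. Strict inclusion makes threshold 0
   include every region (the mean over all edges = the global connectivity)
   and threshold 95 retain exactly the top 5% of a tie-free map.
3. The global connectivity is subtracted from every point, anchoring the
   curve at 0 and removing between-subject and acquisition differences in
   overall connectivity level. Negative edges participate in all means; the
   subtraction, not edge censoring, handles the baseline.
4. The curve is aggregated as a trapezoidal AUC over the grid (x in raw
   percentile units; no normalization — scores are only ever compared with
   null scores computed identically, so the scale merely has to be fixed),
   or alternatively as the leading coefficient of a least-squares
   second-degree polynomial, which captures curve shape rather than area.
   The polynomial is fitted to the global-subtracted curve; on a fixed grid
   the subtraction only shifts the intercept, which is free in the fit
   anyway, so the leading coefficient is unaffected by that choice.

The "minus" direction inverts the atlas around its mean (v -> 2·mean(v) − v)
before step 1 and repeats everything, testing enrichment among low-density
regions. AUC−(atlas) = AUC+(inverted atlas) holds bit-exactly because the
minus path literally calls the inversion.

Because only ranks enter the masks, any strictly increasing transform of the
atlas leaves all scores bit-identical, and adding a constant to every edge
leaves the curve unchanged up to floating-point rounding. Single-map means
are accumulated with correctly-rounded summation (`math.fsum`), so a
consistent permutation of regions across atlas, connectome and geometry
reproduces every score bit-exactly.

Covariate control: `residualize_atlas` replaces atlas values by OLS
residuals on an intercept plus one or more covariate maps (rank-deficient
designs and numerically constant residuals are errors), after which the
pipeline runs unchanged on the residual map.

A guard requires N ≥ ceil(200 / (100 − t_max)) regions for a grid with top
threshold t_max (N ≥ 40 for the default grid), so the top mask always keeps
at least two regions for tie-free maps; smaller systems must pass a custom
grid explicitly.

## Null models

Spatial smoothness shared between brain maps inflates naive association
tests, so inference compares the observed score with scores of surrogate
atlases that preserve spatial autocorrelation. The connectomes are never
perturbed; any subject-specific artifact in the connectome affects observed
and null scores identically.

**Cortex — mirrored spin test.** Cortical parcels carry unit-norm spherical
centroids. For each surrogate, a rotation R is drawn uniformly from SO(3)
(QR orthogonalization of a standard-normal 3x3 matrix with the sign/
determinant fix). The left hemisphere is rotated by R and the right by
M·R·M with M = diag(−1, 1, 1), the reflection of the left-right axis, so the
hemispheres rotate as mirror images and interhemispheric symmetry is
preserved. Each original parcel then takes the value of the nearest rotated
parcel within its own hemisphere (largest dot product on the sphere). The
reassignment is many-to-one: some source values are duplicated and others
dropped, which is the standard behaviour of parcel-level spin tests.

**Subcortex — Moran spectral randomization (singleton).** Subcortical
parcels are not on a sphere, so surrogates come from the Moran eigenvector
basis of the doubly-centered inverse-Euclidean-distance weight matrix (zero
diagonal; coincident centroids are an error). The observed map's expansion
coefficients in that basis are re-signed at random, which preserves the
mean, the variance and Moran's I of the map exactly while scrambling its
orientation. The basis is explicitly re-orthonormalized against the
constant vector so the mean is preserved to machine precision.

Cortical and subcortical surrogates are generated independently and
concatenated into complete maps; percentile conversion always happens on the
complete map, never per structure.

**Exact p and robust z.** With n null scores, the upper-tail p is
(1 + #{null ≥ observed}) / (1 + n) (add-one estimator: p is never 0, the
smallest attainable value is 1/(n+1), and ties count toward the tail —
conservative). Lower tail symmetric, two-sided = min(1, 2·min(upper,
lower)). Default tails: upper for AUC+ and AUC− (each is a directional
hypothesis about its own map), two-sided for the AUC+−AUC− delta. The
robust z is (observed − null median) / (1.4826 · MAD), the MAD scaled to be
consistent with the standard deviation under normality
(1/Φ⁻¹(0.75) ≈ 1.4826). Group-level inference compares the across-subject
mean of observed scores with the across-subject mean per null map, which
requires every subject to be scored against the same null ensemble; group
means use correctly-rounded summation so subject order is irrelevant.

**Degenerate surrogates at coarse parcellations.** Nearest-neighbour
reassignment can duplicate so many values on a small parcellation that a
surrogate map has no region above the top grid thresholds (with average
ranks, a top tie group of g of N regions falls to percentile
100·(2N−g+1)/(2N)). When that happens, the test truncates the grid to the
longest prefix on which *every* map in the ensemble — observed and all
surrogates — keeps at least two regions, so all maps are scored with the
identical statistic and no surrogate is discarded. The truncation depends
only on the maps, never on the connectomes, and is shared across subjects.
Measured on the desk-scale fixture (68 regions), this scheme is well
calibrated (empirical size 0.046–0.050 at nominal 0.05 over 500 simulated
subjects), whereas discarding degenerate surrogates was measurably
conservative (~0.040) because the discarded maps are precisely the
tie-compressed ones. At realistic parcellation sizes (e.g. 200 regions) the
required tie multiplicity never occurs and no truncation takes place.

## Multiple testing, meta-analysis, reliability

- **M_eff / Šidák.** Reference atlases are correlated, so the effective
  number of tests is estimated from the eigenvalues λ of the Pearson
  correlation matrix of the score columns: M_eff = 1 + (M−1)(1 − Var(λ)/M)
  with the sample variance of the eigenvalues (Nyholt's estimator; clamped
  to [1, M]; orthogonal columns give M, identical columns give 1). A
  Li–Ji-style estimator is available behind `method="li-ji"`. Corrected
  p = 1 − (1 − p)^M_eff; the m_eff = 1 case returns p unchanged exactly.
- **Stouffer.** One-sided p-values are mapped to normal quantiles
  z_i = Φ⁻¹(1 − p_i), combined as Z = Σ w_i z_i / sqrt(Σ w_i²) with dataset
  sample sizes as weights, and mapped back to an upper-tail p. Inputs are
  clipped to [1e-15, 1 − 1e-15]; with 1000-null exact p-values (bounded
  below by ~1e-3) the clip only guards pathological inputs.
- **Profiles.** Atlas profiles (vectors of robust z per atlas) are compared
  across cohorts/modalities with Spearman's rho; multi-dataset
  reproducibility is ICC(3,1) (two-way mixed, single measure, consistency)
  with atlases as targets and datasets as raters.
- **Test-retest.** ICC(2,k) (two-way random, average measures, absolute
  agreement) from ANOVA mean squares: (MS_R − MS_E) / (MS_R + (MS_C −
  MS_E)/n). WCV is the root mean square of per-subject coefficients of
  variation (sample SD over |mean|; near-zero means are an error since the
  CV is then undefined). Its permutation null shuffles scores across
  subjects independently within each run column (1000 permutations,
  add-one p for small WCV). The literal alternative — swapping session
  labels within subjects — leaves the CV of two runs unchanged and is a
  no-op, so the across-subject scheme is implemented instead.
  All mean squares use n−1 denominators, and tables must be complete
  (subjects with missing runs are dropped upstream; the statistics have no
  missing-data semantics here).

## Influence and dynamics

- **Leave-one-region-out / leave-one-connection-out.** The AUC is
  recomputed with all edges of one region (or one single edge of a focal
  region) removed; importance = full AUC − reduced AUC, averaged across
  subjects. Percentile ranks are frozen from the full atlas — only
  connections are removed — so the perturbation is purely connectomic; the
  global mean and all masked means are recomputed on the reduced edge set.
  Note the sign this produces: removing a region whose edges are strong
  everywhere lowers the global baseline more than the top-percentile means,
  so the enrichment *rises* and strongly coupled regions receive negative
  importance (in the 4-region worked example the top region scores
  −0.20833). Strict mode raises if a threshold loses all edges after
  removal; tolerant mode drops such thresholds from both the full and
  reduced AUC so the difference is taken on a matched grid.
- **Bounded-AUC emergence.** The AUC's maximum percentile bound is varied
  over {5, ..., 90} and the group-level exact p computed per bound (curves
  are computed once; truncated AUCs are trapezoid prefixes). Reported is
  the lowest bound above which p < alpha holds at every bound up to the
  maximum — "continuously" read literally. If even the top bound is not
  significant the result is none.
- **Sliding windows.** Rectangular windows (default 60 s length, 10 s
  step; lengths converted to samples by rounding against the sampling
  interval) each get their own Pearson + Fisher-z connectome and their own
  global subtraction, exactly as in the static analysis; no taper and no
  detrending beyond Pearson's implicit mean removal. Window count =
  floor((T − L)/S) + 1 in samples. Per-window (rather than session-level)
  global subtraction is used because the static definition is applied to
  each window's connectome verbatim.

Correlations are clipped to ±(1 − 1e-7) before the Fisher z-transform so
duplicated signals give large finite edges instead of infinities;
zero-variance regions are an error naming the region (and the window, in
sliding-window mode). Matrices read from disk may be asymmetric by up to
1e-8 (averaged away, tolerating I/O rounding only); larger asymmetry is an
error, as are missing values inside matrices — subjects are dropped whole
upstream rather than edges imputed.

## Synthetic validation

The fixture generators emulate exactly the structure the statistic assumes:

- **Geometry.** A Fibonacci lattice on the unit sphere restricted to x < 0
  forms the left hemisphere; the right hemisphere is its exact mirror, which
  is what the mirrored spin test expects. Subcortical centroids are drawn in
  a ball of radius 0.2 at the origin (mirrored in pairs when the count is
  even). Default: 30 parcels per hemisphere + 8 subcortical.
- **Atlases.** Zero-mean Gaussian fields with exponential covariance
  exp(−d/ρ) over 3-D chord distances (chord rather than geodesic: monotone
  in geodesic distance on the sphere and cheaper), sampled through a
  symmetric eigenvalue square root with 1e-10 jitter, standardized to unit
  variance. ρ = 0.5 (chord units, sphere radius 1) is the default —
  smooth enough that spin nulls matter, rough enough that maps decorrelate
  across the sphere. ρ → 0 gives Moran's I ≈ 0; ρ = 10 gives median
  I ≈ 0.6 under local (5-nearest-neighbour) weights.
- **Coupled time series.** Region i follows w_i·s(t) + σ·ε_i(t) with a
  shared standard-normal signal s and loading w_i = β·logistic(z_i) of the
  standardized atlas value z_i, so pairwise correlation increases with the
  joint atlas density w_i·w_j — the synchronization structure the statistic
  is designed to detect. The logistic link keeps loadings positive and
  bounded, so inverse-direction fixtures follow from negating z. β = 0
  yields independent noise (the calibration condition). Default T = 200
  samples at 1 s, noise σ = 1.
- **Score tables.** score(s, r) = μ + b_s + e_{s,r} with Gaussian
  between/within components — the classical two-way model whose ICC has a
  closed form (e.g. 2/3 for σ_b = σ_e, k = 2 average measures).

What passing these tests shows: the implementation computes the declared
statistics exactly (oracle agreement to 1e-12), the exact p is calibrated
under the null at desk scale, and planted couplings are detected with the
expected monotone dose-response. What it does not show: behaviour under
hemodynamic confounds, head motion, physiological noise, non-Gaussian edge
distributions or realistic parcellation geometry — none of which the
generators emulate.

Validation study sizes (one CPU, minutes): calibration uses 500 i.i.d.
subjects x 199 nulls at 68 regions; power uses 100 cohorts of 20 subjects;
effect-size monotonicity uses 50 replicates per β in {0, 0.5, 1, 2}.
Per-subject null ensembles in the calibration study are generated
independently so the rejection count is exactly binomial.

## Known limitations

- The spin test is parcel-level; vertex-level spins and variogram-matching
  surrogates are out of scope, as are null models of the connectome itself.
- Nearest-neighbour reassignment is many-to-one by design; a
  uniqueness-enforcing variant is not provided.
- The MSR implementation is the singleton procedure with inverse-distance
  weights; pair-rotation variants and other kernels are not implemented.
- Aggregates are means over edges; median or trimmed variants and weighted
  AUCs are not provided.
- The WCV permutation scheme is the across-subject substitute described
  above; with only two runs no within-subject scheme is informative.
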