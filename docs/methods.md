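# Methods

This note documents the statistical model behind `wingmorph`, the
numerical choices that affect results, what the synthetic-data generator
does and does not emulate, and the known limitations.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Shape model

A wing is 19 ordered 2D landmarks.  Shape is the equivalence class of a
configuration under translation, uniform scaling and rotation —
reflections are *not* quotiented out; left wings are made comparable by an
explicit mirror (x → −x) before alignment, keeping raw digitizations
faithful to the image.

**Generalized Procrustes analysis.**  All configurations are centred and
scaled to unit centroid size; starting from the first wing as provisional
consensus, each iteration rotates every configuration to the consensus
(closed-form optimal rotation for 2D, computed in complex arithmetic) and
re-estimates the consensus as the normalized mean.  Iteration stops when
the consensus moves by less than 1e-10 (max 100 iterations; on generic
data 3–6 suffice).  Determinism: initialization from the first wing, no
randomness.

Two choices deserve emphasis:

* **Orientation gauge.**  The Procrustes consensus is defined only up to a
  joint rotation, inherited from whichever wing initializes it.  To make
  the output a function of the *set* of shapes (and hence invariant to
  per-wing similarity transforms of the input, which the suite asserts at
  1e-8), the consensus is rotated into its principal-axis frame, with the
  sign fixed by the x-skewness of its landmarks.  For generic wing shapes
  this gauge is stable; exactly isotropic or symmetric configurations
  would leave it to floating-point luck.
* **Tangent projection.**  Aligned unit-size configurations are projected
  orthogonally onto the affine tangent plane {t : t·c = 1} at the
  consensus c.  With 2 translation, 1 scale and 1 rotation dimension
  removed, tangent coordinates of generic data span exactly 34 of the 38
  coordinates — the dimension retained everywhere downstream.
  A consequence: rerunning GPA on its own output is idempotent only to
  second order in the shape dispersion (the projection moves points
  slightly off unit centroid size).  The suite asserts < 1e-8 agreement at
  small dispersion and a dispersion-scaled bound at realistic dispersion.

**Full vs partial Procrustes.**  Scaling is full (unit centroid size
throughout), matching the common desktop-morphometrics workflow this
pipeline mirrors.

## Traits

Wing size is ln CS; at the conventional 2400 dpi image resolution the
fixture's intra-Carpathian colonies average 6.48–6.49.  The cubital index
is the length ratio of two cubital-cell vein segments.  Which landmark
pairs bound those segments is a *convention* of the landmarking scheme,
not recoverable from coordinates, so it ships as a named, editable
`CubitalIndexConvention` ("identifly-19": vein a = landmarks 15→16,
vein b = 16→17, 0-based).  The index is computed on raw landmarks — it is
similarity-invariant, and alignment would only add projection distortion.

## Group statistics

Colony-level analysis: wings are aligned jointly, tangent coordinates are
averaged within colonies, and PCA / CVA / classification run on colony
means.  PCA retains k = 34 components by default (truncated with a warning
if the data cannot support them).

* **Pooled covariance.**  S = Σ_g Σ_{i∈g} (xᵢ−μ_g)(xᵢ−μ_g)ᵀ / (N − g).
  When S is numerically singular (reference groups can have as few as 2
  colonies) an eigenvalue-thresholded pseudo-inverse is used (relative
  tolerance 1e-8) and the model is flagged, never silently densified.
* **CVA.**  Between-group scatter is whitened by S (via the same
  thresholded inverse square root) and eigendecomposed; at most
  min(g−1, rank) canonical axes, normalized so aᵀSa = 1.  With two groups
  the single axis coincides with Fisher's discriminant direction (asserted
  up to sign).
* **Mahalanobis distances.**  D² = (μ₁−μ₂)ᵀ S⁻¹ (μ₁−μ₂), the plain
  estimator, which is what desktop packages report.  It is positively
  biased in small samples — expectation (ν/(ν−p−1))·(D² + p(1/n₁+1/n₂))
  for ν = N−g pooled df and p dimensions, i.e. ≈ +78% at 50 colonies per
  group with p = 34 and ≈ +5% at 500 — so `mahalanobis_sq(...,
  unbiased=True)` also exposes the classical correction
  ((ν−p−1)/ν)·D̂² − p(1/n₁+1/n₂).  The suite asserts both the recovery of
  truth by the corrected estimator and the shrink-with-N bias of the
  plain one.  Pairwise significance uses Hotelling's T² mapped to an exact
  F (the table-rendering significance codes: *** < 1e-4, ** < 1e-3,
  * < 0.05).
* **Classification.**  Smallest squared Mahalanobis distance with equal
  priors (group sizes are sampling artifacts, not prevalences); exact ties
  warn and take the first group in model order.  Leave-one-out
  cross-validation refits the group model (means + pooled covariance)
  without each colony; GPA and PCA are *not* refit per fold by default —
  the basis change is rank-preserving and Mahalanobis classification is
  affine-invariant up to truncation, so refitting mostly costs time — but
  `loo_cross_validation_refit_pca` exposes the stricter protocol because
  published workflows differ on it.

## Hypothesis tests

The study design is an unbalanced 2×2 (area × collection period) over
colonies.  MANOVA and the trait ANOVAs use effect coding (+1/−1) with
Type III sums of (cross-)products, so each factor is adjusted for the
other and the interaction — the behaviour of the commercial packages this
workflow replaces; which SS type such packages used originally is not
documentable, so Type III is a design choice, recorded here.  All tested
effects have one hypothesis df, for which the F transform of Wilks' Λ is
exact: F = ((1−Λ)/Λ)·(ν−p+1)/p on (p, ν−p+1) df.  Responses whose
dimension reaches the residual df raise an explicit "reduce k" error
rather than truncating silently.  Multivariate regression on a single
covariate uses the same machinery with ν = n−2.  Under a simulated null
both p-values are uniform (asserted by Kolmogorov–Smirnov over 500
replicates).  The tests are cross-checked against
`statsmodels.multivariate.manova.MANOVA` and `anova_lm(typ=3)` with Sum
contrasts on small unbalanced instances.

No multiple-testing adjustment is applied across the report's many tests;
p-values are reported raw.

## Identification data

`ClassifierSpec` stores everything needed to classify a new sample:
consensus shape (alignment target), PCA mean and basis, group means,
pooled covariance, counts, and a chaining map from a stage-1 label to a
stage-2 classifier (subspecies → subpopulation).  New wings are aligned
one at a time to the stored consensus, projected, and the sample is
represented by the *mean* of per-wing scores (mirroring colony-level
averaging; a per-wing majority vote is available via `aggregate="vote"`).
The XML dialect (`wingmorph-classifier` version 1) serializes numbers at
full `repr` precision, so write→read round trips are lossless;
compatibility with any external tool's identification-file format is not
claimed, since no such schema is published.

## Synthetic data: the stated world

The generator emulates the sampling structure the analysis assumes:

| parameter | default | units | rationale |
|---|---|---|---|
| colony effect sd | 0.004 | tangent coordinate | between-colony shape variation of the magnitude seen in bee wing studies |
| wing noise sd | 0.006 | tangent coordinate | within-colony variation exceeding the colony effect |
| wings per colony | Poisson, means 34.2 / 28.1 / 39.1 (min 5) | wings | the three documented collection modes (historical mounts, 2016 colonies, 2019 flower catches) |
| group sizes (fixture) | 52 / 50 / 36 / 59 (+15, +2 reference) | colonies | the documented 197-sample two-area × two-period design |
| ln CS mean | 6.48 intra, 6.44 extra | ln pixels at 2400 dpi | documented wing-size scale; intra-Carpathian wings larger |
| latitude slope of ln CS | 0.008 | per degree | size increases to the northwest |
| size sds (colony, wing) | 0.02, 0.015 | ln CS | modest size repeatability within colonies |
| cubital index targets | 2.75 intra, 2.67 extra, 2.46 / 2.40 reference | ratio | documented race-character values |
| temperature model | 11.3 − 0.0065·altitude + N(0, 0.45) | °C, m | environmental lapse rate; noise set so r(temp, alt) ≈ −0.93 |
| geography | per-area lat/lon boxes, altitude N(550,150) intra vs N(250,130) extra | deg, m | higher intra-Carpathian plateau |
| nuisance transforms | rotation U(−π, π), translation U(0, 3000) px, 50% left wings | — | force superimposition to do real work |

**Exact separations.**  Group mean shapes are tangent-space offsets built
by classical MDS of the target D² matrix, scaled by the colony-mean sd
σ_eff = √(colony_sd² + wing_sd²·E[1/n]); the construction is verified to
1e-8 at build time, and infeasible targets (non-Euclidean distance
matrices) raise.  The six-group fixture matrix is exactly embeddable, so
the packaged truths are exact, not approximate.  With Poisson wing counts
σ_eff uses the exact truncated-Poisson E[1/n]; with fixed counts (the
recovery experiments) it is exact outright.

**Cubital index overlay.**  Index targets are realized as offset
components inside the span of the two vein-length gradients (leaving
vein a unchanged), with the D² embedding confined to the orthogonal
complement so it cannot disturb either vein length to first order.
Because the index is a ratio with a short denominator vein, per-wing
landmark noise inflates its expectation (Jensen); the generator
pre-compensates with a delta-method factor, landing realized Romanian
group means within ~0.01 of target.  The reference taxa carry much larger
offsets whose second-order geometry leaves their realized indices
~0.05–0.2 off target; only the group ordering is asserted for them.

**What the generator does not emulate** — and what a green test therefore
does not establish: directional left–right asymmetry (left wings are exact
mirrors); landmark-level digitization error structure (noise is isotropic
in tangent space, not concentrated on hard-to-place junctions);
non-Gaussian or allometric shape variation (size and shape are generated
independently, so tests cannot detect allometry-induced bias); spatial
autocorrelation beyond the area factor (colonies are exchangeable within
areas, so geographic regressions detect confounded area structure rather
than smooth clines); admixture gradients (groups are homogeneous, with no
hybrid colonies near the ridge).

## Degenerate inputs and tie-breaks

All-coincident landmark configurations raise on centroid size; rank-0
cross-covariances raise in rotation fitting; a singleton group is skipped
by LOO with a warning rather than poisoning the fold; classification ties
(below 1e-12) warn and resolve to the first group; empty samples are
excluded from trait tables with a log entry; samples lacking temperature
metadata are dropped from the 9 °C partition (a `StudyConfig` threshold,
default 9.0) with a report note.

## Limitations

* The 19-landmark scheme is treated as an ordered abstract convention; no
  anatomical identity is asserted for any landmark, and the cubital-vein
  convention is configurable rather than anatomically guaranteed.
* Estimated D² tables at study scale (≈50 colonies/group, 34 dimensions)
  are inflated by the documented small-sample bias; compare like with
  like, or use the corrected estimator.
* The MANOVA's Type III + exact-F choices are a documented convention, not
  a claim about how any historical software computed its numbers.
* The identification XML is this package's own schema; it cannot read or
  write other tools' classifier files.
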