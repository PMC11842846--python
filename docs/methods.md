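# Methods

This note documents the models, estimators, numerical choices and known
limitations of `epimorph`, in the order data flows through the pipeline.

## Synthetic lineage model

Cells divide in synchronous rounds. A division splits the mother area `A`
into `f·A` and `(1 − f)·A` with `f ~ Normal(0.5, division_asymmetry_sd)`
truncated to (0.05, 0.95) by rejection; the two daughter fractions sum to 1,
so area is conserved exactly at every division. Between divisions the cell
grows with a size-proportional law, `dA/dt = growth_rate · A`, evaluated at
hourly samples over `growth_hours` (a linear-growth option exists for
sensitivity analyses). The nucleus is a fixed multiplicative companion:
at birth each cell draws `ε ~ Normal(0, nc_noise_sd)` and keeps
`A_nuc = ρ · A_cell · e^ε` throughout growth, so nucleus–cell coordination
is established at division and maintained during growth.

Because growth is deterministic and multiplicative, all area variability
comes from the division fractions: `Var(ln A)` grows by `Var(ln f)` per
round, and after many rounds `ln A` is a sum of i.i.d. terms — terminal
areas are asymptotically log-normal. The defaults
(`generations = 8`, `division_asymmetry_sd = 0.055`) were set by quadrature
on the truncated normal so that `8 · Var(ln f) ≈ 0.097`, i.e. the terminal
mean-normalised areas carry `2σ² ≈ 0.19`, the steady-state log-normal width
this analysis family reports for crowded monolayers. `nc_noise_sd = 0.2`
puts the nucleus–cell area Pearson r near 0.83 at the terminal generation,
in the range observed for confluent epithelia. With 16 independent founder
cells the pooled terminal population's sample variance is stable despite
shared ancestry within each tree (cousins share path segments; across
trees there is none).

Default units: initial area 250 μm² (a typical confluent epithelial cell),
growth rate 0.05 h⁻¹ (~35% over a 6-h tracking window), NC area ratio
ρ = 0.3.

## Synthetic monolayer renderer

A field of `n_cells` seeds on a jittered square lattice (jitter ±0.28 of
the lattice spacing) is tessellated by anisotropically weighted
nearest-seed assignment: each seed carries an independent target relative
area `s ~ LogNormal(μ = −0.05, σ² = 0.19/2)` and an independent
elongation drawn from the aspect-ratio model
`AR = 1 + (⟨AR⟩ − 1)·x`, `x ~ Gamma(k = 2.43, mean 1)`, with uniform
orientation. A pixel joins the seed minimising
`(u/a)² + (v/b)²` with `a·b ∝ s` and `a/b = AR` in the seed's frame
(candidates restricted to the 8 Euclidean-nearest seeds). Because size and
shape are drawn independently per seed, measured cell area and cell AR are
uncorrelated by construction — mean |Pearson r| ≈ 0.03 across default
fields — mirroring the near-zero area–AR correlation seen in real
monolayers. Packing compresses realised areas relative to their targets
(measured `2σ̂² ≈ 0.14` versus the sampling model's 0.19); the parametric
area/AR models themselves (exposed as `sample_areas` /
`sample_aspect_ratios`) carry the exact stated parameters.

Nuclei are ellipses at the cell centroid, oriented along the cell's
second-moment long axis, with `A_nuc = ρ · A_cell · e^ε` and their own
gamma-model AR (mean 1.3), clipped to the parent cell; a counter records
nuclei whose ellipse had to be clipped below 90% of target. Channels:

* DAPI — constant per-nucleus level `exp(Normal(0, 0.1))`;
* each mark — per-nucleus DAPI-normalised level
  `1 + slope · (A_nuc − ⟨A⟩)/⟨A⟩ + Normal(0, noise)`, clipped at 0.05,
  times the DAPI level, times a radial weight
  `1 + g · (d̄ − d̃)/0.5` where `d̃` is the boundary distance normalised to
  the nucleus' maximum and `d̄` its per-nucleus mean (so the weight has unit
  mean) and `g = radial_coupling · (A_nuc − ⟨A⟩)/⟨A⟩`. Positive coupling
  makes the periphery relatively brighter in larger nuclei, giving a
  positive size–(periphery/center ratio) correlation; negative coupling the
  opposite.

Default marks: an H3K27me3-like channel (slope −0.3, coupling −0.4;
repressive marks are depleted in larger nuclei) and an H3K9ac-like channel
(+0.3, +0.4). Additive Gaussian pixel noise at 2% of the mean channel
intensity, clipped at zero. Everything is drawn from one seeded generator,
so fields are bit-reproducible.

What the generator does **not** emulate: segmentation errors, z-projection
artefacts, uneven illumination, mitotic figures, multinucleation, spatial
neighbourhood correlations of size or marks, and vertex-model mechanics.
Passing tests therefore certify the statistical pipeline, not robustness to
real-world imaging pathology.

## Morphometry

Features are computed per matched cell/nucleus pair from the label masks
via region properties; intensity statistics are taken over the nucleus mask
(DAPI and histone marks are nuclear stains). Definitions follow the
ImageJ-style conventions of this analysis family literally: shape index
`P/√A`, solidity `A/A_convex`, circularity `A/P²`, roundness `A/L_major²`,
aspect ratio `L_major/L_minor` from the second-moment ellipse.
`conventional_shape=True` restores the 4π-/4-π-scaled textbook variants.
The normalised mark level is the ratio of means (mark mean / DAPI mean),
which is robust to pixel noise, rather than the mean of per-pixel ratios.

Perimeter: no discrete estimator is simultaneously exact for axis-aligned
polygons and accurate for smooth shapes. The default is the 4-direction
Crofton estimator (disk circularity within ~1% of `1/4π`; squares
underestimated by a known ≈6% factor). `perimeter_method="crack"` switches
to the exact crack length (unit object/background edges): exact `4s` for an
`s×s` square, ~27% high on disks. Analyses comparing compactness across
roughly isotropic cells should use the default; the crack option exists for
rectilinear geometry and closed-form checks.

Exclusions: objects touching any image border are removed (their
morphology is truncated), as are mitotic cells — by a user-supplied label
list, or optionally a DAPI-outlier rule (mean > median + 3·MAD). When the
two masks share no label ids, nuclei are re-matched to cells by
centroid-in-mask; cells claimed by two nuclei are excluded and reported.

## Distribution fits

Areas are normalised to their mean; aspect ratios rescaled as
`x = (AR − 1)/(⟨AR⟩ − 1)` (undefined when all objects are circles — an
explicit error). Log-normal fitting is exact MLE: `μ̂ = ⟨ln x⟩`,
`σ̂² = population (1/n) variance of ln x` — the 1/n form is the MLE and is
what the reported `2σ̂² ≈ 0.19` refers to. The unit-mean gamma shape solves
`ln k − ψ(k) = ln⟨x⟩ − ⟨ln x⟩` by Newton iteration from Minka's starting
value with a bracketing bisection safeguard on [1e−3, 1e3]; a
histogram-least-squares mode exists for comparison. Goodness of fit is a KS
test against the fitted CDF; two-sample collapse tests use the exact KS
p-value below n = 30 and the asymptotic form above. Degenerate samples
(zero variance) are rejected rather than fitted.

## Correlation statistics

Pearson r is computed as covariance over the product of standard
deviations by direct summation; Spearman ρ is Pearson on average ranks.
Confidence intervals use the Fisher z-transform with
`z_crit = 1.959964` and SE `1/√(n − 3)` — validated against the printed
24-h interval for r = 0.637, N = 124 ([0.519, 0.731] at 3 d.p.). The
permutation p-value re-pairs y against x `n_permutations` times (default
10 000) and applies an add-one correction,
`p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + n_perm)`, so p is never zero; the
permuted array is chosen by a canonical byte-order rule so the result is
invariant to swapping x and y. The family FDR pools all tests' permutation
nulls: for each observed |r|, FDR = (expected null exceedances per
permutation replicate)/(observed exceedances), clipped to the resolution
floor and monotonised so a stronger correlation never has a larger FDR.

The spatial autocorrelation curve bins unordered pairs by centroid
distance; bin 0 holds self-pairs (value 1 by construction); each bin
reports `⟨(v_i − v̄)(v_j − v̄)⟩/Var(v)`; bins with fewer than 10 pairs are
flagged, fewer than 2 are NaN.

## Radial chromatin statistics

The nucleus mask is hole-filled (nucleolus-like voids), padded by one
background pixel (mask pixels on the crop edge are boundary pixels), and
the Euclidean distance transform computed. Pixels are ranked by distance
(stable ties in scan order) and the bottom `round(f·A)` pixels form the
periphery — this quantile rule reaches the closest achievable fraction on
any mask, unlike whole-shell erosion, which is retained as
`method="erosion"`. Intensity statistics use only original mask pixels.
The periphery/center statistic is the ratio of mean intensities
(total/area per region), invariant to rescaling the channel; the CV is
sd/mean over the whole mask on raw intensities. Nuclei under 50 px or with
zero center intensity are excluded and counted. `split_robustness` repeats
the size correlation across fractions 0.10–0.30 to show the conclusion does
not hinge on the 80/20 convention.

## Multivariable models

Predictions are 5-fold cross-validated (seeded KFold with shuffling); the
reported accuracy is the Pearson r between out-of-fold predictions and
measured values. Linear models are OLS on z-scored predictors
(rank-deficiency falls back to the pseudoinverse). The nonparametric model
is kernel ridge with a squared-exponential kernel; the length-scale grid is
the median pairwise-distance heuristic × {0.25, 1, 4} and the ridge/noise
level {1e−3, 1e−2, 1e−1}, selected by inner 3-fold CV — a GP posterior
mean under a fixed noise level, exposed as a scikit-learn estimator. For
DAPI-normalised histone targets the DAPI mean/sd/CV predictors are dropped
automatically: their arithmetic relationship to a mark/DAPI target is not
biology. Dropout importance removes one predictor at a time on the same
folds; Δr = full − reduced, ranks by descending Δr with name-order
tie-breaks. CCA is the classical SVD of the whitened cross-covariance of
z-scored blocks, with an automatic logged ridge term on singular
within-block covariance; PCA operates on z-scored features, dropping
constant columns with a warning, with explained-variance fractions summing
to 1 over all retained components.

## Pipeline

`run_pipeline` executes generate → extract/filter → distribution fits →
correlations (with family FDR) → radial statistics → multivariable stages
in dependency order, each stage reading only upstream artifacts, and writes
a manifest listing every artifact with its SHA-256. Identical config + seed
reproduces every artifact bit-for-bit; stages without their inputs (e.g.
radial statistics in feature-table mode) are skipped with an explicit
reason. Monolayers are stored as 16-bit TIFFs (labels directly; intensities
at 1e−4 resolution with scale factors in the JSON sidecar).

## Problem sizes and tolerances

Parameter-recovery checks use 20 000 samples (k̂ within ±0.05 of 2.43,
2σ̂² within ±0.01 of 0.19); field-level checks use 20 default ~1000-cell
monolayers; permutation calibration uses 500 repeats at n = 100 with 1000
permutations. Oracle-equivalence checks run on masks ≤ 64×64 where
O(n²) brute force is cheap: area/solidity exact, moment axes to 1e−9,
perimeters within 1% of their per-pixel reimplementations, radial
partitions pixel-identical.

## Known limitations

* Rendered cell-area distributions are narrower than the sampling model
  (packing); quantitative area-width recovery is therefore anchored on the
  parametric model, and field-level checks are sign/independence checks.
* The lineage model has no cell-cycle length variability, no growth-rate
  noise, and divisions are synchronous; it reproduces the variance
  mechanism, not population kinetics. The reported ~1.12 (cell) / ~0.88
  (nucleus) post-division amplification slopes are not parameterised.
* The permutation FDR's family is whatever set of reports is passed in one
  call; family scope is an analysis decision.
* GP predictive uncertainty is not aggregated across folds; only posterior
  means are cross-validated.
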