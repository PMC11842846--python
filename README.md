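# epimorph

Quantitative analysis of cell and nucleus morphological heterogeneity in
epithelial monolayers, for researchers studying crowding/jamming in
epithelia and its chromatin-level consequences.

In crowded epithelia (MDCK-like monolayers, developing epithelium), cell
and nucleus sizes vary far more than their means shift, yet the two are
tightly coordinated. `epimorph` implements the statistical machinery for
this analysis family:

* **Distribution collapse and fits.** Mean-normalised areas
  `x = A/⟨A⟩` follow a log-normal, `ln x ~ N(μ, σ²)` with
  μ ≈ −0.05 and σ² ≈ 0.19/2; rescaled aspect ratios
  `x = (AR − 1)/(⟨AR⟩ − 1)` follow the one-parameter unit-mean gamma
  `PDF(x; k) = k^k x^{k−1} e^{−kx}/Γ(k)` with k ≈ 2.43. Maximum-likelihood
  fits (the gamma shape solved from `ln k − ψ(k) = ln⟨x⟩ − ⟨ln x⟩` by
  safeguarded Newton), KS goodness of fit and cross-condition collapse
  tests.
* **Nucleus–cell coordination.** Pearson/Spearman correlations with
  Fisher-z confidence intervals (`z = atanh r`, SE `1/√(n−3)`),
  Monte-Carlo permutation p-values and pooled-permutation-null FDR, plus a
  spatial area–area autocorrelation curve.
* **Morphometrics.** Per-object features from paired cell/nucleus label
  masks (area, perimeter, second-moment axes, aspect ratio, shape index
  `P/√A`, solidity, circularity `A/P²`, roundness `A/L_major²`, NC ratios,
  per-channel intensity statistics and DAPI-normalised mark levels), with
  the standard exclusion rules (edge-touching and mitotic objects).
* **Radial chromatin statistics.** Each nucleus is split by the interior
  distance transform into an outer periphery (20% of the area by default)
  and an inner center; the periphery/center mean-intensity ratio and the
  intensity CV are correlated against nucleus size.
* **Multivariable prediction.** Cross-validated linear and
  squared-exponential-kernel regression of histone-mark levels
  (H3K27me3-like, H3K9ac-like) from morphology, single-feature dropout
  importance, CCA between cellular and nuclear feature blocks, and PCA
  biplot data. DAPI intensity predictors are excluded for DAPI-normalised
  targets.
* **Synthetic data.** Because the underlying microscopy data are not
  publicly deposited, the package ships first-class generators that
  reproduce this statistical structure: an asymmetric-division lineage
  simulator (multiplicative splits `f·A`/`(1−f)·A`, size-proportional
  growth) and a rendered monolayer generator (weighted Voronoi-style
  tessellation, elliptical nuclei, DAPI + mark channels with size-coupled
  levels and radial gradients). Every downstream stage is tested against
  these generators and against brute-force per-pixel oracles.

## Worked example

```python
import numpy as np
from epimorph import (MonolayerParams, generate_monolayer, extract_features,
                      match_and_filter, normalize_areas, rescale_ar,
                      fit_lognormal, fit_unit_mean_gamma, correlate)

mono = generate_monolayer(MonolayerParams(seed=1))        # ~1000 cells
feats, report = match_and_filter(extract_features(mono))
print(report)
area_fit = fit_lognormal(normalize_areas(feats.cell_area))
ar_fit = fit_unit_mean_gamma(rescale_ar(feats.cell_aspect_ratio))
nc = correlate(feats.cell_area, feats.nucleus_area, seed=1)
print(f"2*sigma2 = {2 * area_fit.params['sigma2']:.3f}")
print(f"k_hat    = {ar_fit.params['k']:.2f}")
print(f"NC r     = {nc.pearson_r:.3f}  CI [{nc.ci95_low:.3f}, {nc.ci95_high:.3f}]"
      f"  p = {nc.permutation_p:.2e}")
```

Output (seed 1):

```
{'n_in': 992, 'n_out': 873, 'n_edge_excluded': 119, 'n_mitotic_excluded': 0}
2*sigma2 = 0.141
k_hat    = 2.49
NC r     = 0.789  CI [0.763, 0.813]  p = 1.00e-04
```

119 of 992 rendered cells touch the field border and are excluded. The
measured area spread (0.141) sits below the sampling model's 0.19 because
neighbour packing compresses the realised Voronoi areas relative to their
targets; the aspect-ratio shape k̂ ≈ 2.49 and the strong nucleus–cell area
correlation with its Fisher-z interval are the two headline coordination
statistics. The permutation p sits at its resolution floor,
1/(n_permutations + 1) = 1e−4 at the default 10 000 permutations: no random
re-pairing reaches the observed correlation.

The same stages run from the shell:

```bash
epimorph generate --seed 1 --out run/mono
epimorph extract run/mono --out run/features.csv
epimorph fit-dist run/features.csv --column cell_aspect_ratio --family gamma
epimorph run-all --seed 1 --out run/full     # full pipeline + manifest
```

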