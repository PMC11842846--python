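"""Pairwise association statistics with permutation inference.

Pearson r is the covariance divided by the product of standard deviations;
Spearman rho is the Pearson r of the (average-tie) ranks. Confidence
intervals use the Fisher z-transform (atanh r, SE 1/sqrt(n-3)); p-values
come from a Monte-Carlo permutation null with an add-one correction, and
the family-wise false-discovery rate from the pooled permutation null.
A spatial area-area autocorrelation curve is included for lineage /
neighbourhood analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationReport",
    "AutocorrelationCurve",
    "correlate",
    "fisher_ci",
    "fdr_monte_carlo",
    "spatial_autocorrelation",
]


@dataclass
class CorrelationReport:
    name_x: str
    name_y: str
    n: int
    pearson_r: float
    spearman_rho: float
    ci95_low: float
    ci95_high: float
    slope: float
    intercept: float
    permutation_p: float
    fdr: float | None = None
    # raw data retained so the FDR machinery can re-permute
    x: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    return float((xc * yc).sum() / denom)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z confidence interval for a Pearson correlation.

    z = atanh(r), half-width z_crit/sqrt(n-3), bounds tanh(z -/+ half-width).
    """
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for a Fisher z interval")
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = np.arctanh(r)
    z_crit = stats.norm.ppf(0.5 * (1.0 + level))
    hw = z_crit / np.sqrt(n - 3)
    return float(np.tanh(z - hw)), float(np.tanh(z + hw))


def _null_abs_r(x: np.ndarray, y: np.ndarray, n_permutations: int,
                rng: np.random.Generator) -> np.ndarray:
    """|r| under random re-pairings of y against x, vectorised.

    The array that gets permuted is chosen by a canonical byte-order
    comparison so the result is invariant to swapping x and y.
    """
    if y.tobytes() < x.tobytes():
        x, y = y, x
    xc = x - x.mean()
    sx = np.sqrt((xc * xc).sum())
    perms = rng.permuted(np.broadcast_to(y, (n_permutations, y.size)).copy(),
                         axis=1)
    pc = perms - perms.mean(axis=1, keepdims=True)
    sy = np.sqrt((pc * pc).sum(axis=1))
    return np.abs(pc @ xc) / (sx * sy)


def correlate(x, y, n_permutations: int = 10_000, seed: int = 0,
              name_x: str = "x", name_y: str = "y") -> CorrelationReport:
    """Full association report for one variable pair.

    The permutation p-value is (1 + #{|r_perm| >= |r_obs|}) /
    (1 + n_permutations); the least-squares line of y on x is reported
    alongside. Zero variance in either variable is an error (the
    correlation is undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")

    r = _pearson(x, y)
    rho = _pearson(stats.rankdata(x), stats.rankdata(y))
    slope, intercept = np.polyfit(x, y, 1)
    try:
        lo, hi = fisher_ci(r, x.size)
    except ValueError:  # |r| = 1: CI degenerates
        lo = hi = r
    rng = np.random.default_rng(seed)
    null = _null_abs_r(x, y, n_permutations, rng)
    p = (1.0 + np.count_nonzero(null >= abs(r) - 1e-15)) / (1.0 + n_permutations)
    return CorrelationReport(name_x, name_y, int(x.size), r, float(rho),
                             lo, hi, float(slope), float(intercept),
                             float(p), x=x, y=y)


def fdr_monte_carlo(reports: list[CorrelationReport],
                    n_permutations: int = 1000, seed: int = 0) -> np.ndarray:
    """Empirical FDR for a family of correlations from a pooled permutation null.

    For each test i with observed |r_i|, the FDR estimate is the expected
    number of null tests in the family exceeding |r_i| per permutation
    replicate, divided by the observed number of tests exceeding |r_i|,
    clipped to [resolution floor, 1] and monotonised in |r|. Each report's
    ``fdr`` field is filled in; the values are also returned.
    """
    if not reports:
        raise ValueError("empty report family")
    for rep in reports:
        if rep.x is None or rep.y is None:
            raise ValueError("reports must carry raw data for permutation FDR")
    rng = np.random.default_rng(seed)
    obs = np.array([abs(rep.pearson_r) for rep in reports])
    pooled = np.concatenate([
        _null_abs_r(rep.x, rep.y, n_permutations, rng) for rep in reports])
    order = np.argsort(-obs)  # strongest first
    fdr = np.empty_like(obs)
    for i, j in enumerate(order):
        expected_fp = np.count_nonzero(pooled >= obs[j]) / n_permutations
        observed_pos = i + 1
        fdr[j] = expected_fp / observed_pos
    floor = 1.0 / (n_permutations * len(reports))
    fdr = np.clip(fdr, floor, 1.0)
    # monotone in |r|: each test's fdr is the minimum over itself and all
    # weaker tests (so a stronger |r| never has a larger fdr)
    s = fdr[order]
    fdr[order] = np.minimum.accumulate(s[::-1])[::-1]
    for rep, v in zip(reports, fdr):
        rep.fdr = float(v)
    return fdr


@dataclass
class AutocorrelationCurve:
    bin_centers: np.ndarray  # um
    values: np.ndarray
    pair_counts: np.ndarray
    low_count_flags: np.ndarray  # bins with < 10 pairs


def spatial_autocorrelation(values, centroids, bin_width: float
                            ) -> AutocorrelationCurve:
    """Distance-binned autocorrelation of a per-cell scalar.

    Bin 0 holds the self-pairs (value 1 by construction); bin k >= 1 covers
    distances ((k-1)*w, k*w] with centre (k-0.5)*w and carries
    C(d) = <(v_i - vbar)(v_j - vbar)> / Var(v) over the unordered pairs in
    the bin. Bins with fewer than 2 pairs are NaN; bins with fewer than 10
    pairs are flagged.
    """
    v = np.asarray(values, dtype=float).ravel()
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] != v.size:
        raise ValueError("centroids must be (n, 2) matching values")
    if v.size < 2:
        raise ValueError("need at least 2 points")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    var = v.var()
    if var == 0:
        raise ValueError("zero variance: autocorrelation undefined")
    vc = v - v.mean()
    iu, ju = np.triu_indices(v.size, k=1)
    d = np.sqrt(((pts[iu] - pts[ju]) ** 2).sum(axis=1))
    prod = vc[iu] * vc[ju] / var
    k = np.ceil(d / bin_width).astype(int)
    k[d == 0] = 0  # coincident points count as self-distance
    n_bins = int(k.max()) + 1 if k.size else 1
    counts = np.bincount(k, minlength=n_bins)
    sums = np.bincount(k, weights=prod, minlength=n_bins)
    values_out = np.full(n_bins, np.nan)
    nz = counts > 0
    values_out[nz] = sums[nz] / counts[nz]
    # bin 0: self-pairs
    counts[0] += v.size
    values_out[0] = 1.0
    centers = np.concatenate([[0.0],
                              (np.arange(1, n_bins) - 0.5) * bin_width])
    flags = counts < 10
    flags[0] = False
    return AutocorrelationCurve(centers, values_out, counts, flags)
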