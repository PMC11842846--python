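"""Distribution collapse and fitting for morphological heterogeneity.

Cell and nucleus areas, once normalised to their means, collapse onto a
common log-normal master curve; aspect ratios, once rescaled as
``x = (AR - 1)/(<AR> - 1)``, collapse onto a one-parameter unit-mean gamma

    PDF(x; k) = k**k * x**(k-1) * exp(-k*x) / Gamma(k)

whose maximum-likelihood shape solves ln k - psi(k) = ln(mean x) - mean(ln x)
(psi = digamma). Both fits are exposed as small estimator classes with
``fit`` and trailing-underscore attributes, plus thin functional wrappers
returning a :class:`DistributionFit`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "DistributionFit",
    "LogNormalFit",
    "UnitMeanGammaFit",
    "normalize_areas",
    "rescale_ar",
    "fit_lognormal",
    "fit_unit_mean_gamma",
    "collapse_test",
]


@dataclass(frozen=True)
class DistributionFit:
    """Fitted parameters and goodness of fit for one family."""

    family: str  # "lognormal" | "unit_mean_gamma"
    params: dict[str, float]
    n: int
    log_likelihood: float
    ks_statistic: float
    ks_p: float


def _as_positive(x, name: str = "x", min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    bad = np.flatnonzero(x <= 0)
    if bad.size:
        raise ValueError(f"{name} must be strictly positive; "
                         f"first offender at index {bad[0]}")
    return x


def normalize_areas(areas) -> np.ndarray:
    """Normalise areas to their mean, so the output has mean exactly 1."""
    x = _as_positive(areas, "areas", min_n=2)
    return x / x.mean()


def rescale_ar(ar_values) -> np.ndarray:
    """Rescale aspect ratios as x = (AR - 1)/(<AR> - 1); output mean is 1."""
    ar = np.asarray(ar_values, dtype=float).ravel()
    if ar.size < 2:
        raise ValueError("need at least 2 aspect ratios")
    if not np.all(np.isfinite(ar)):
        raise ValueError("aspect ratios contain non-finite values")
    if np.any(ar < 1.0):
        raise ValueError("aspect ratios must be >= 1")
    mean_ar = ar.mean()
    if mean_ar <= 1.0:
        raise ValueError("mean aspect ratio is 1 (all circles); "
                         "rescaling is undefined")
    return (ar - 1.0) / (mean_ar - 1.0)


class LogNormalFit:
    """Maximum-likelihood log-normal fit of positive samples.

    Fitted attributes: ``mu_`` (mean of ln x), ``sigma2_`` (population, i.e.
    1/n, variance of ln x — the MLE), ``ks_statistic_``, ``ks_p_``,
    ``log_likelihood_``, ``n_``.
    """

    def __init__(self, min_n: int = 10):
        self.min_n = min_n

    def fit(self, x) -> "LogNormalFit":
        x = _as_positive(x, "x", min_n=self.min_n)
        logx = np.log(x)
        mu = float(logx.mean())
        sigma2 = float(logx.var())  # population (1/n) estimator = MLE
        if sigma2 <= 0:
            raise ValueError("degenerate sample: all values equal, "
                             "log-normal fit undefined")
        sigma = np.sqrt(sigma2)
        ks = stats.kstest(x, stats.lognorm(s=sigma, scale=np.exp(mu)).cdf)
        self.mu_ = mu
        self.sigma2_ = sigma2
        self.n_ = int(x.size)
        self.log_likelihood_ = float(
            np.sum(stats.lognorm.logpdf(x, s=sigma, scale=np.exp(mu))))
        self.ks_statistic_ = float(ks.statistic)
        self.ks_p_ = float(ks.pvalue)
        return self

    def result(self) -> DistributionFit:
        return DistributionFit("lognormal",
                               {"mu": self.mu_, "sigma2": self.sigma2_},
                               self.n_, self.log_likelihood_,
                               self.ks_statistic_, self.ks_p_)


def _gamma_shape_mle(s: float, lo: float = 1e-3, hi: float = 1e3) -> float:
    """Solve ln k - psi(k) = s for k by safeguarded Newton iteration.

    ln k - psi(k) is strictly decreasing from +inf to 0 on (0, inf), so a
    root exists for any s > 0; the bracket [lo, hi] is maintained and a
    bisection step replaces any Newton step that leaves it.
    """
    if not np.isfinite(s) or s <= 0:
        raise ValueError("ln(mean x) - mean(ln x) must be positive; "
                         "sample too degenerate for a gamma fit")

    def g(k):
        return np.log(k) - special.digamma(k) - s

    if g(lo) < 0 or g(hi) > 0:
        raise ValueError(f"no gamma shape root in [{lo}, {hi}] for s={s!r}")
    # classical starting value (Minka's approximation)
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    k = min(max(k, lo), hi)
    a, b = lo, hi
    for _ in range(100):
        gk = g(k)
        if abs(gk) < 1e-12:
            break
        if gk > 0:
            a = k
        else:
            b = k
        dg = 1.0 / k - special.polygamma(1, k)
        step = gk / dg if dg != 0 else np.inf
        k_new = k - step
        if not (a < k_new < b):
            k_new = 0.5 * (a + b)  # bisection safeguard
        if abs(k_new - k) < 1e-14 * max(1.0, k):
            k = k_new
            break
        k = k_new
    return float(k)


class UnitMeanGammaFit:
    """MLE of the shape k for the unit-mean gamma PDF(x;k) = k^k x^{k-1} e^{-kx}/Gamma(k).

    Fitted attributes: ``k_``, ``ks_statistic_``, ``ks_p_``,
    ``log_likelihood_``, ``n_``. ``method="histogram"`` performs a
    least-squares fit of the density to a histogram instead (comparison
    mode).
    """

    def __init__(self, min_n: int = 10, method: str = "mle", bins: int = 50):
        self.min_n = min_n
        self.method = method
        self.bins = bins

    def fit(self, x) -> "UnitMeanGammaFit":
        x = _as_positive(x, "x", min_n=self.min_n)
        if self.method == "mle":
            s = float(np.log(x.mean()) - np.mean(np.log(x)))
            k = _gamma_shape_mle(s)
        elif self.method == "histogram":
            dens, edges = np.histogram(x, bins=self.bins, density=True)
            centers = 0.5 * (edges[:-1] + edges[1:])

            def sse(logk):
                kk = np.exp(logk)
                pdf = stats.gamma.pdf(centers, a=kk, scale=1.0 / kk)
                return np.sum((pdf - dens) ** 2)

            res = optimize.minimize_scalar(sse, bounds=(np.log(1e-3),
                                                        np.log(1e3)),
                                           method="bounded")
            k = float(np.exp(res.x))
        else:
            raise ValueError("method must be 'mle' or 'histogram'")
        dist = stats.gamma(a=k, scale=1.0 / k)
        ks = stats.kstest(x, dist.cdf)
        self.k_ = k
        self.n_ = int(x.size)
        self.log_likelihood_ = float(np.sum(dist.logpdf(x)))
        self.ks_statistic_ = float(ks.statistic)
        self.ks_p_ = float(ks.pvalue)
        return self

    def result(self) -> DistributionFit:
        return DistributionFit("unit_mean_gamma", {"k": self.k_}, self.n_,
                               self.log_likelihood_, self.ks_statistic_,
                               self.ks_p_)


def fit_lognormal(x, **kwargs) -> DistributionFit:
    """Functional wrapper over :class:`LogNormalFit`."""
    return LogNormalFit(**kwargs).fit(x).result()


def fit_unit_mean_gamma(x, **kwargs) -> DistributionFit:
    """Functional wrapper over :class:`UnitMeanGammaFit`."""
    return UnitMeanGammaFit(**kwargs).fit(x).result()


def collapse_test(groups: dict[str, np.ndarray]):
    """Pairwise two-sample KS tests between named groups of normalised values.

    Returns ``(table, max_ks)`` where ``table`` has one row per unordered
    pair with the KS statistic and p-value (exact p at n < 30, asymptotic
    otherwise), and ``max_ks`` summarises how far the groups are from a
    common master curve.
    """
    import pandas as pd

    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for name in names:
        a = np.asarray(groups[name], dtype=float).ravel()
        if a.size < 10:
            raise ValueError(f"group {name!r} needs n >= 10")
        arrays[name] = a
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            a, b = arrays[na], arrays[nb]
            method = "exact" if min(a.size, b.size) < 30 else "asymp"
            res = stats.ks_2samp(a, b, method=method)
            rows.append({"group_a": na, "group_b": nb,
                         "ks": float(res.statistic), "p": float(res.pvalue)})
    table = pd.DataFrame(rows)
    return table, float(table["ks"].max())
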