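"""Synthetic epithelial monolayers and division lineages.

Two generators provide test beds with the statistical structure observed in
crowded epithelial monolayers:

* :func:`simulate_lineage` — an asymmetric-division lineage. Each division
  splits the mother area ``A`` into ``f*A`` and ``(1-f)*A`` with
  ``f ~ Normal(0.5, sd)`` truncated to (0.05, 0.95); between divisions cells
  grow with a size-proportional (exponential) law. Repeated multiplicative
  splits drive the terminal area distribution towards a log-normal, with
  ``Var(ln A)`` growing linearly in the number of division rounds.
* :func:`generate_monolayer` — a rendered field of view: an anisotropically
  weighted nearest-seed tessellation of a perturbed lattice gives cell
  regions whose target areas follow a log-normal (in units of the mean) and
  whose elongations follow the unit-mean gamma law for rescaled aspect
  ratios x = (AR - 1)/(<AR> - 1). Nuclei are oriented ellipses with
  area = rho * cell_area * exp(eps), a DAPI channel, and histone-mark
  channels whose per-nucleus DAPI-normalised levels couple linearly to
  nucleus area (negative slope: H3K27me3-like; positive: H3K9ac-like) and
  carry a radial intensity gradient whose periphery/centre contrast couples
  to nucleus area.

Areas and aspect ratios are drawn independently of each other, matching the
observed near-zero correlation between cell area and cell AR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .containers import LabeledMonolayer

__all__ = [
    "LineageParams",
    "MonolayerParams",
    "MarkParams",
    "simulate_lineage",
    "lineage_to_population",
    "generate_monolayer",
    "dilution_osmolarity",
    "sample_areas",
    "sample_aspect_ratios",
    "EmptyTimepointError",
]


class EmptyTimepointError(ValueError):
    """Raised when a lineage query selects no live cells."""


def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class LineageParams:
    """Parameters of the asymmetric-division lineage simulation.

    ``division_asymmetry_sd`` is the standard deviation of the daughter
    fraction ``f`` around 0.5; ``growth_rate`` is the per-hour relative
    growth rate (exponential law by default); ``nc_ratio`` is the mean
    nucleus/cell area ratio rho; ``nc_noise_sd`` the standard deviation of
    the multiplicative log-noise on nucleus area, redrawn at each birth and
    held fixed during growth.

    The defaults are calibrated so that eight division rounds give
    ``2 * Var(ln area) ~ 0.19`` on mean-normalised terminal areas, the
    steady-state log-normal width observed in crowded monolayers (see
    docs/methods.md for the quadrature calibration).
    """

    initial_area: float = 250.0  # um^2
    division_asymmetry_sd: float = 0.055
    growth_rate: float = 0.05  # 1/h
    growth_hours: int = 6
    nc_ratio: float = 0.3
    nc_noise_sd: float = 0.2
    generations: int = 8
    n_initial: int = 16
    growth_law: str = "exponential"  # or "linear"
    seed: int = 0

    def validate(self) -> None:
        for name in ("initial_area", "division_asymmetry_sd", "growth_rate",
                     "nc_ratio", "nc_noise_sd"):
            _check_finite(name, getattr(self, name))
        if self.initial_area <= 0:
            raise ValueError("initial_area must be > 0")
        if not 0 <= self.division_asymmetry_sd <= 0.25:
            raise ValueError("division_asymmetry_sd must lie in [0, 0.25]")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.growth_hours < 0 or int(self.growth_hours) != self.growth_hours:
            raise ValueError("growth_hours must be a non-negative integer")
        if not 0 < self.nc_ratio < 1:
            raise ValueError("nc_ratio must lie in (0, 1)")
        if self.nc_noise_sd < 0:
            raise ValueError("nc_noise_sd must be >= 0")
        if self.generations < 1 or int(self.generations) != self.generations:
            raise ValueError("generations must be an integer >= 1")
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")
        if self.growth_law not in ("exponential", "linear"):
            raise ValueError("growth_law must be 'exponential' or 'linear'")


_F_LO, _F_HI = 0.05, 0.95  # truncation of the daughter fraction


def _draw_fractions(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Daughter fractions f ~ Normal(0.5, sd) truncated to (0.05, 0.95)."""
    if sd == 0:
        return np.full(n, 0.5)
    f = rng.normal(0.5, sd, size=n)
    bad = (f <= _F_LO) | (f >= _F_HI)
    while bad.any():
        f[bad] = rng.normal(0.5, sd, size=int(bad.sum()))
        bad = (f <= _F_LO) | (f >= _F_HI)
    return f


def simulate_lineage(params: LineageParams) -> pd.DataFrame:
    """Simulate an asymmetric-division lineage.

    Returns a table with one row per cell per tracked hour, columns
    ``cell_id, parent_id, generation, time_h, cell_area, nucleus_area``.
    Generation g cells are born at ``g * growth_hours`` hours; roots have
    ``parent_id = -1``. Daughter areas sum exactly to the mother's area at
    division. Deterministic given the seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    gh = int(params.growth_hours)
    hours = np.arange(gh + 1)
    if params.growth_law == "exponential":
        growth = np.exp(params.growth_rate * hours)
    else:
        growth = 1.0 + params.growth_rate * hours

    ids = np.arange(params.n_initial, dtype=np.int64)
    parents = np.full(params.n_initial, -1, dtype=np.int64)
    areas = np.full(params.n_initial, float(params.initial_area))
    next_id = params.n_initial

    chunks: list[pd.DataFrame] = []
    for gen in range(params.generations + 1):
        n = ids.size
        nuc_factor = params.nc_ratio * np.exp(
            rng.normal(0.0, params.nc_noise_sd, size=n)) if params.nc_noise_sd > 0 \
            else np.full(n, params.nc_ratio)
        birth_t = gen * gh
        # hourly growth track for this cohort
        track = areas[:, None] * growth[None, :]
        chunks.append(pd.DataFrame({
            "cell_id": np.repeat(ids, gh + 1),
            "parent_id": np.repeat(parents, gh + 1),
            "generation": gen,
            "time_h": np.tile(birth_t + hours, n),
            "cell_area": track.ravel(),
            "nucleus_area": (track * nuc_factor[:, None]).ravel(),
        }))
        if gen == params.generations:
            break
        # divide: conserve area exactly
        end_areas = track[:, -1]
        f = _draw_fractions(rng, n, params.division_asymmetry_sd)
        areas = np.concatenate([f * end_areas, (1.0 - f) * end_areas])
        parents = np.concatenate([ids, ids])
        ids = np.arange(next_id, next_id + 2 * n, dtype=np.int64)
        next_id += 2 * n

    table = pd.concat(chunks, ignore_index=True)
    return table


def lineage_to_population(table: pd.DataFrame, time_h: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    """All live (cell_area, nucleus_area) pairs at an absolute time.

    Pairing is preserved so nucleus-cell coordination can be analysed
    downstream. At a division time the dividing mothers' final sample
    coincides with the daughters' birth; the daughters (latest generation)
    are the live population and are the ones returned. Raises
    :class:`EmptyTimepointError` when no cell is tracked at the requested
    time.
    """
    sel = table[np.isclose(table["time_h"].to_numpy(dtype=float), time_h)]
    if sel.empty:
        raise EmptyTimepointError(f"no cells tracked at t = {time_h} h")
    sel = sel[sel["generation"] == sel["generation"].max()]
    return (sel["cell_area"].to_numpy(dtype=float),
            sel["nucleus_area"].to_numpy(dtype=float))


def dilution_osmolarity(medium_osmolarity: float, medium_fraction: float) -> float:
    """Osmolarity after diluting culture medium with pure water.

    Water contributes no solute, so a mixture that is ``medium_fraction``
    medium has osmolarity ``medium_osmolarity * medium_fraction``
    (290 mOsm medium at 5% -> 14.5 mOsm).
    """
    _check_finite("medium_osmolarity", medium_osmolarity)
    _check_finite("medium_fraction", medium_fraction)
    if not 0.0 <= medium_fraction <= 1.0:
        raise ValueError("medium_fraction must lie in [0, 1]")
    return medium_osmolarity * medium_fraction


# ---------------------------------------------------------------------------
# monolayer rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkParams:
    """One histone-mark channel of the synthetic monolayer.

    ``slope`` couples the per-nucleus DAPI-normalised level to nucleus area
    (level = 1 + slope * (A - <A>)/<A> + noise); ``radial_coupling`` couples
    the periphery/centre intensity contrast to nucleus area the same way.
    Negative slopes emulate repressive marks (H3K27me3), positive slopes
    active marks (H3K9ac).
    """

    slope: float = -0.3
    noise_sd: float = 0.05
    radial_coupling: float = 0.0


def _default_marks() -> dict[str, MarkParams]:
    return {
        "H3K27me3": MarkParams(slope=-0.3, noise_sd=0.05, radial_coupling=-0.4),
        "H3K9ac": MarkParams(slope=0.3, noise_sd=0.05, radial_coupling=0.4),
    }


@dataclass(frozen=True)
class MonolayerParams:
    """Parameters of the rendered synthetic monolayer.

    The area model is ``area/<area> ~ LogNormal(mu, sigma2)`` with the
    observed defaults mu = -0.05, sigma2 = 0.19/2; the aspect-ratio model is
    ``(AR-1)/(<AR>-1) ~ Gamma(k, mean 1)`` with k = 2.43.
    """

    n_cells: int = 1000
    field_size: int = 1024
    area_lognormal_mu: float = -0.05
    area_lognormal_sigma2: float = 0.19 / 2
    ar_gamma_k: float = 2.43
    mean_ar: float = 1.4
    nucleus_mean_ar: float = 1.3
    nc_ratio: float = 0.3
    nc_noise_sd: float = 0.2
    marks: dict[str, MarkParams] = field(default_factory=_default_marks)
    dapi_level_sd: float = 0.1
    pixel_noise_frac: float = 0.02
    pixel_size: float = 0.5  # um / px
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 4:
            raise ValueError("n_cells must be >= 4")
        if self.field_size < 16:
            raise ValueError("field_size must be >= 16 px")
        for name in ("area_lognormal_mu", "area_lognormal_sigma2",
                     "ar_gamma_k", "mean_ar", "nucleus_mean_ar",
                     "nc_ratio", "nc_noise_sd", "dapi_level_sd",
                     "pixel_noise_frac", "pixel_size"):
            _check_finite(name, getattr(self, name))
        if self.area_lognormal_sigma2 <= 0:
            raise ValueError("area_lognormal_sigma2 must be > 0")
        if self.ar_gamma_k <= 0:
            raise ValueError("ar_gamma_k must be > 0")
        if self.mean_ar < 1 or self.nucleus_mean_ar < 1:
            raise ValueError("mean aspect ratios must be >= 1")
        if not 0 < self.nc_ratio < 1:
            raise ValueError("nc_ratio must lie in (0, 1)")
        if self.nc_noise_sd < 0 or self.dapi_level_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.pixel_noise_frac < 0:
            raise ValueError("pixel_noise_frac must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


def sample_areas(n: int, params: MonolayerParams | None = None,
                 rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw areas (in units of the mean) from the default log-normal model."""
    params = params or MonolayerParams()
    rng = np.random.default_rng(rng)
    return np.exp(rng.normal(params.area_lognormal_mu,
                             math.sqrt(params.area_lognormal_sigma2), size=n))


def sample_aspect_ratios(n: int, params: MonolayerParams | None = None,
                         rng: np.random.Generator | int | None = None,
                         mean_ar: float | None = None) -> np.ndarray:
    """Draw aspect ratios AR = 1 + (<AR>-1) * x, x ~ unit-mean Gamma(k)."""
    params = params or MonolayerParams()
    rng = np.random.default_rng(rng)
    mean_ar = params.mean_ar if mean_ar is None else mean_ar
    x = rng.gamma(shape=params.ar_gamma_k, scale=1.0 / params.ar_gamma_k, size=n)
    return 1.0 + (mean_ar - 1.0) * x


def _label_moments(labels: np.ndarray, n_labels: int):
    """Areas, centroids and orientation angles of all labels via bincount."""
    rows, cols = np.indices(labels.shape)
    flat = labels.ravel()
    r = rows.ravel().astype(float)
    c = cols.ravel().astype(float)
    counts = np.bincount(flat, minlength=n_labels + 1).astype(float)
    counts[counts == 0] = np.nan
    r0 = np.bincount(flat, weights=r, minlength=n_labels + 1) / counts
    c0 = np.bincount(flat, weights=c, minlength=n_labels + 1) / counts
    dr = r - r0[flat]
    dc = c - c0[flat]
    mu20 = np.bincount(flat, weights=dr * dr, minlength=n_labels + 1) / counts
    mu02 = np.bincount(flat, weights=dc * dc, minlength=n_labels + 1) / counts
    mu11 = np.bincount(flat, weights=dr * dc, minlength=n_labels + 1) / counts
    angle = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)  # major-axis angle, (row, col)
    return counts, r0, c0, angle


def _render_ellipse(shape, r0, c0, a, b, angle, clip_mask=None):
    """Boolean mask of an ellipse with semi-axes (a, b), major axis at
    ``angle`` in the (row, col) plane, optionally intersected with a mask."""
    h, w = shape
    rmin = max(int(np.floor(r0 - a)), 0)
    rmax = min(int(np.ceil(r0 + a)) + 1, h)
    cmin = max(int(np.floor(c0 - a)), 0)
    cmax = min(int(np.ceil(c0 + a)) + 1, w)
    if rmin >= rmax or cmin >= cmax:
        return None, (0, 0, 0, 0)
    rr, cc = np.meshgrid(np.arange(rmin, rmax), np.arange(cmin, cmax),
                         indexing="ij")
    dr = rr - r0
    dc = cc - c0
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if clip_mask is not None:
        inside &= clip_mask[rmin:rmax, cmin:cmax]
    return inside, (rmin, rmax, cmin, cmax)


def generate_monolayer(params: MonolayerParams | None = None) -> LabeledMonolayer:
    """Render a synthetic segmented monolayer field.

    Cell regions come from an anisotropically weighted nearest-seed
    tessellation of a jittered lattice: each seed carries an independent
    target area (log-normal model) and an independent elongation/orientation
    (gamma AR model), so measured cell area and cell AR are uncorrelated by
    construction. Nuclei are oriented ellipses clipped to their cell, with
    DAPI and histone-mark channels rendered as described in the module
    docstring. Deterministic given the seed.
    """
    params = params or MonolayerParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = int(params.field_size)

    # --- seed lattice -----------------------------------------------------
    gx = max(2, int(round(math.sqrt(params.n_cells))))
    gy = max(2, int(round(params.n_cells / gx)))
    n = gx * gy
    sx = fs / gx
    sy = fs / gy
    jitter = 0.28
    seed_r = ((np.arange(gx) + 0.5)[:, None] * sx
              + rng.uniform(-jitter, jitter, size=(gx, gy)) * sx).ravel()
    seed_c = ((np.arange(gy) + 0.5)[None, :] * sy
              + rng.uniform(-jitter, jitter, size=(gx, gy)) * sy).ravel()
    seeds = np.column_stack([seed_r, seed_c])

    # per-seed independent size and shape draws
    rel_area = sample_areas(n, params, rng)
    cell_ar = sample_aspect_ratios(n, params, rng)
    theta = rng.uniform(0.0, np.pi, size=n)
    scale = np.sqrt(rel_area)  # linear size weight
    ax_a = scale * np.sqrt(cell_ar)   # along major axis
    ax_b = scale / np.sqrt(cell_ar)

    # fused per-seed coefficients of the anisotropic norm, float32 for speed
    cos_t = np.cos(theta)
    sin_t = np.sin(theta)
    coef = np.stack([cos_t / ax_a, sin_t / ax_a,
                     -sin_t / ax_b, cos_t / ax_b,
                     seed_r, seed_c]).astype(np.float32)

    tree = cKDTree(seeds)
    k = min(8, n)
    labels = np.empty((fs, fs), dtype=np.int32)
    chunk = max(1, (1 << 21) // fs)  # ~2M pixels per block
    cols_idx = np.arange(fs, dtype=np.float32)
    for start in range(0, fs, chunk):
        stop = min(start + chunk, fs)
        rr, cc = np.meshgrid(np.arange(start, stop, dtype=np.float32),
                             cols_idx, indexing="ij")
        pts = np.column_stack([rr.ravel(), cc.ravel()])
        _, cand = tree.query(pts, k=k)
        if k == 1:
            cand = cand[:, None]
        ca, sa, sb, cb, sr, sc = coef[:, cand]
        dr = pts[:, 0:1] - sr
        dc = pts[:, 1:2] - sc
        u = dr * ca
        u += dc * sa
        v = dr * sb
        v += dc * cb
        u *= u
        v *= v
        u += v  # u now holds the squared anisotropic distance
        best = cand[np.arange(cand.shape[0]), np.argmin(u, axis=1)]
        labels[start:stop, :] = (best + 1).reshape(stop - start, fs)

    # --- nuclei -----------------------------------------------------------
    counts, r0, c0, angle = _label_moments(labels, n)
    present = np.flatnonzero(~np.isnan(counts[1:])) + 1
    cell_area_px = counts  # indexed by label id

    nuc_eps = rng.normal(0.0, params.nc_noise_sd, size=n + 1)
    nuc_ar = sample_aspect_ratios(n + 1, params, rng,
                                  mean_ar=params.nucleus_mean_ar)
    nucleus_labels = np.zeros_like(labels)
    n_clipped = 0
    nuc_area_px = np.zeros(n + 1)
    for lab in present:
        target = params.nc_ratio * cell_area_px[lab] * math.exp(nuc_eps[lab])
        ar = nuc_ar[lab]
        a = math.sqrt(target * ar / math.pi)
        b = a / ar
        inside, (rmin, rmax, cmin, cmax) = _render_ellipse(
            labels.shape, r0[lab], c0[lab], a, b, angle[lab],
            clip_mask=(labels == lab))
        if inside is None or not inside.any():
            # degenerate: claim the pixel nearest the centroid inside the cell
            rs, cs = np.nonzero(labels == lab)
            j = np.argmin((rs - r0[lab]) ** 2 + (cs - c0[lab]) ** 2)
            nucleus_labels[rs[j], cs[j]] = lab
            nuc_area_px[lab] = 1
            n_clipped += 1
            continue
        achieved = int(inside.sum())
        if achieved < 0.9 * target:
            n_clipped += 1
        block = nucleus_labels[rmin:rmax, cmin:cmax]
        block[inside] = lab
        nuc_area_px[lab] = achieved

    # --- channels ---------------------------------------------------------
    mean_nuc = np.nanmean(np.where(nuc_area_px > 0, nuc_area_px, np.nan))
    rel_nuc = (nuc_area_px - mean_nuc) / mean_nuc

    dapi_level = np.exp(rng.normal(0.0, params.dapi_level_sd, size=n + 1))
    channels: dict[str, np.ndarray] = {}
    dapi = np.zeros(labels.shape)
    nuc_mask = nucleus_labels > 0
    dapi[nuc_mask] = dapi_level[nucleus_labels[nuc_mask]]

    # per-nucleus normalised boundary distance for the radial gradient
    dist = ndimage.distance_transform_edt(nuc_mask)
    dmax = ndimage.maximum(dist, labels=nucleus_labels,
                           index=np.arange(n + 1))
    dmax = np.where(dmax > 0, dmax, 1.0)
    dnorm = np.zeros_like(dist)
    dnorm[nuc_mask] = dist[nuc_mask] / dmax[nucleus_labels[nuc_mask]]
    dmean = ndimage.mean(dnorm, labels=nucleus_labels,
                         index=np.arange(n + 1))
    dmean = np.nan_to_num(dmean)

    truth = {"label_id": present,
             "cell_area_px": cell_area_px[present],
             "nucleus_area_px": nuc_area_px[present],
             "dapi_level": dapi_level[present]}

    mark_images: dict[str, np.ndarray] = {}
    for name, mp in params.marks.items():
        level = 1.0 + mp.slope * rel_nuc
        if mp.noise_sd > 0:
            level = level + rng.normal(0.0, mp.noise_sd, size=n + 1)
        level = np.clip(level, 0.05, None)
        # periphery-brightness factor: positive g -> periphery brighter
        g = np.clip(mp.radial_coupling * rel_nuc, -0.9, 0.9)
        img = np.zeros(labels.shape)
        lab_img = nucleus_labels[nuc_mask]
        w = 1.0 + g[lab_img] * (dmean[lab_img] - dnorm[nuc_mask]) / 0.5
        w = np.clip(w, 0.05, None)
        img[nuc_mask] = level[lab_img] * dapi_level[lab_img] * w
        mark_images[name] = img
        truth[f"{name}_level"] = level[present]
    channels["DAPI"] = dapi
    channels.update(mark_images)

    if params.pixel_noise_frac > 0:
        for name, img in channels.items():
            pos = img[img > 0]
            sd = params.pixel_noise_frac * (pos.mean() if pos.size else 1.0)
            img = img + rng.normal(0.0, sd, size=img.shape)
            channels[name] = np.clip(img, 0.0, None)

    return LabeledMonolayer(
        cell_labels=labels,
        nucleus_labels=nucleus_labels,
        channels=channels,
        pixel_size=params.pixel_size,
        truth=pd.DataFrame(truth),
        n_clipped_nuclei=n_clipped,
    )
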