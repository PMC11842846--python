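"""End-to-end orchestration: generate -> extract -> fit -> correlate ->
radial -> multivariable, with a hashed artifact manifest.

A :class:`RunConfig` selects exactly one input mode — ``synthetic``
(generate a monolayer), ``masks`` (read a monolayer directory) or
``features`` (start from a feature CSV) — and toggles the analysis stages.
Stages whose upstream inputs are unavailable are skipped with an explicit
reason recorded in the manifest. Identical config + seed reproduces every
artifact bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import correlations, distributions, morphometry, multivar, radial
from .io import read_monolayer, write_monolayer
from .synthetic import MarkParams, MonolayerParams, generate_monolayer

log = logging.getLogger("epimorph")

__all__ = ["RunConfig", "run_pipeline"]

MORPHOLOGY_PREDICTORS = [
    "cell_area", "cell_perimeter", "cell_aspect_ratio", "cell_shape_index",
    "cell_solidity", "cell_circularity", "cell_roundness",
    "nucleus_area", "nucleus_perimeter", "nucleus_aspect_ratio",
    "nucleus_shape_index", "nucleus_solidity", "nucleus_circularity",
    "nucleus_roundness",
]
NC_RATIO_PREDICTORS = ["nc_area_ratio", "nc_ar_ratio"]


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "masks" | "features"
    input_path: str | None = None  # monolayer dir or features CSV
    out_dir: str = "epimorph_run"
    seed: int = 0
    generator: MonolayerParams | None = None
    run_distributions: bool = True
    run_correlations: bool = True
    run_radial: bool = True
    run_multivar: bool = True
    split_fraction: float = 0.20
    n_permutations: int = 2000
    multivar_models: tuple[str, ...] = ("linear", "se_kernel")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            marks = {k: MarkParams(**v) for k, v in gen.pop("marks", {}).items()}
            cfg.generator = MonolayerParams(**gen, marks=marks) if marks \
                else MonolayerParams(**gen)
        return cfg

    def validate(self) -> None:
        if self.mode not in ("synthetic", "masks", "features"):
            raise ValueError("mode must be synthetic, masks or features")
        if self.mode in ("masks", "features") and not self.input_path:
            raise ValueError(f"mode {self.mode!r} requires input_path")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: dict, stage: str, artifacts: list[Path]) -> None:
    manifest["stages"][stage] = {
        "status": "ok",
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }


def _skip(manifest: dict, stage: str, reason: str) -> None:
    log.info("stage %s skipped: %s", stage, reason)
    manifest["stages"][stage] = {"status": "skipped", "reason": reason}


def _report_row(rep: correlations.CorrelationReport) -> dict:
    return {"x": rep.name_x, "y": rep.name_y, "n": rep.n,
            "r_pearson": rep.pearson_r, "r_spearman": rep.spearman_rho,
            "ci95_low": rep.ci95_low, "ci95_high": rep.ci95_high,
            "slope": rep.slope, "intercept": rep.intercept,
            "p_permutation": rep.permutation_p, "fdr": rep.fdr}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "mode": config.mode, "stages": {}}

    monolayer = None
    features = None

    # --- generate / load --------------------------------------------------
    if config.mode == "synthetic":
        params = config.generator or MonolayerParams(seed=config.seed)
        if config.generator is None:
            params = MonolayerParams(seed=config.seed)
        monolayer = generate_monolayer(params)
        mdir = write_monolayer(monolayer, out / "monolayer", params=params)
        _record(manifest, "generate", list(mdir.glob("*")))
    elif config.mode == "masks":
        monolayer = read_monolayer(config.input_path)
        _skip(manifest, "generate", "mask input mode")
    else:
        features = pd.read_csv(config.input_path)
        _skip(manifest, "generate", "feature-table input mode")

    # --- extract + filter -------------------------------------------------
    if monolayer is not None:
        features = morphometry.extract_features(monolayer)
        features, filt = morphometry.match_and_filter(features)
        fpath = out / "features.csv"
        features.to_csv(fpath, index=False)
        rpath = out / "reconciliation.json"
        rpath.write_text(json.dumps(
            {"reconciliation": features.attrs.get("reconciliation", {}),
             "filter": filt}, indent=2, sort_keys=True))
        _record(manifest, "extract", [fpath, rpath])
    else:
        _skip(manifest, "extract", "features supplied directly")

    # --- distribution fits ------------------------------------------------
    if config.run_distributions:
        fits = {}
        for col in ("cell_area", "nucleus_area"):
            if col in features:
                x = distributions.normalize_areas(features[col])
                fits[col] = dataclasses.asdict(distributions.fit_lognormal(x))
        for col in ("cell_aspect_ratio", "nucleus_aspect_ratio"):
            if col in features:
                x = distributions.rescale_ar(features[col])
                fits[col] = dataclasses.asdict(
                    distributions.fit_unit_mean_gamma(x))
        fits_path = out / "fits.json"
        fits_path.write_text(json.dumps(fits, indent=2, sort_keys=True))
        _record(manifest, "fit-dist", [fits_path])
    else:
        _skip(manifest, "fit-dist", "disabled")

    # --- correlations -----------------------------------------------------
    if config.run_correlations:
        pairs = [("cell_area", "nucleus_area"),
                 ("cell_aspect_ratio", "nucleus_aspect_ratio"),
                 ("cell_area", "cell_aspect_ratio")]
        mark_cols = [c for c in features.columns if c.endswith("_norm")]
        pairs += [("nucleus_area", m) for m in mark_cols]
        reports = []
        for cx, cy in pairs:
            if cx in features and cy in features:
                sub = features[[cx, cy]].dropna()
                reports.append(correlations.correlate(
                    sub[cx], sub[cy], n_permutations=config.n_permutations,
                    seed=config.seed, name_x=cx, name_y=cy))
        if reports:
            correlations.fdr_monte_carlo(
                reports, n_permutations=min(config.n_permutations, 1000),
                seed=config.seed)
            cpath = out / "correlations.csv"
            pd.DataFrame([_report_row(r) for r in reports]).to_csv(
                cpath, index=False)
            _record(manifest, "correlate", [cpath])
        else:
            _skip(manifest, "correlate", "no analysable variable pairs")
    else:
        _skip(manifest, "correlate", "disabled")

    # --- radial -----------------------------------------------------------
    if config.run_radial:
        if monolayer is None:
            _skip(manifest, "radial", "no masks")
        else:
            paths = []
            for name in monolayer.channels:
                if name == "DAPI":
                    continue
                tab = radial.radial_stat(monolayer, name,
                                         split_fraction=config.split_fraction)
                p = out / f"radial_{name}.csv"
                tab.to_csv(p, index=False)
                paths.append(p)
            if paths:
                _record(manifest, "radial", paths)
            else:
                _skip(manifest, "radial", "no mark channels")
    else:
        _skip(manifest, "radial", "disabled")

    # --- multivariable ----------------------------------------------------
    if config.run_multivar:
        mark_cols = [c for c in features.columns if c.endswith("_norm")]
        preds = [p for p in MORPHOLOGY_PREDICTORS if p in features.columns]
        if not mark_cols or len(preds) < 2 or len(features) < 30:
            _skip(manifest, "multivar",
                  "needs mark levels, >=2 morphology predictors and >=30 rows")
        else:
            paths = []
            pred_rows, imp_frames = [], []
            for target in mark_cols:
                for kind in config.multivar_models:
                    res = multivar.predict(features, target, preds,
                                           model_kind=kind, seed=config.seed)
                    pred_rows.append({"target": target, "model": kind,
                                      "prediction_r": res.prediction_r,
                                      "n": res.y_true.size})
                imp = multivar.dropout_importance(features, target, preds,
                                                  seed=config.seed)
                t = imp.table.copy()
                t.insert(0, "target", target)
                imp_frames.append(t)
            ppath = out / "predictions.csv"
            pd.DataFrame(pred_rows).to_csv(ppath, index=False)
            ipath = out / "importance.csv"
            pd.concat(imp_frames, ignore_index=True).to_csv(ipath, index=False)
            paths += [ppath, ipath]

            cell_block = [c for c in preds if c.startswith("cell_")]
            nuc_block = [c for c in preds if c.startswith("nucleus_")]
            extras = {}
            if len(cell_block) >= 2 and len(nuc_block) >= 2:
                sub = features[cell_block + nuc_block].dropna()
                cca = multivar.cca_predict(sub[cell_block], sub[nuc_block])
                extras["cca"] = {
                    "correlations": cca.correlations.tolist(),
                    "prediction_r": cca.prediction_r, "ridge": cca.ridge}
            pca_cols = preds + mark_cols
            pca = multivar.pca_biplot_data(features, include=pca_cols)
            extras["pca"] = {
                "variance_fractions": pca.variance_fractions.tolist(),
                "loadings": pca.loadings.round(6).to_dict(),
                "dropped": pca.dropped}
            xpath = out / "multivar.json"
            xpath.write_text(json.dumps(extras, indent=2, sort_keys=True))
            paths.append(xpath)
            _record(manifest, "multivar", paths)
    else:
        _skip(manifest, "multivar", "disabled")

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
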