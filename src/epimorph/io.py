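"""Reading and writing monolayer fields and lineage tables.

A :class:`~epimorph.containers.LabeledMonolayer` is stored as a directory of
16-bit TIFFs (``cell_labels.tif``, ``nucleus_labels.tif``, one
``<channel>.tif`` per intensity channel) plus a JSON sidecar
(``monolayer.json``) holding the pixel size, per-channel intensity scale
factors and, for synthetic fields, the generator parameters and seed.
Lineage tables are plain CSV with the canonical column order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import LabeledMonolayer

__all__ = ["write_monolayer", "read_monolayer",
           "write_lineage", "read_lineage"]

LINEAGE_COLUMNS = ["cell_id", "parent_id", "generation", "time_h",
                   "cell_area", "nucleus_area"]
_CHANNEL_SCALE = 10_000.0  # intensity units per 16-bit count


def _params_to_jsonable(params) -> dict:
    if params is None:
        return {}
    d = dataclasses.asdict(params)
    for key, val in d.items():
        if isinstance(val, dict):
            d[key] = {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                          else v) for k, v in val.items()}
    return d


def write_monolayer(monolayer: LabeledMonolayer, out_dir, params=None) -> Path:
    """Write a monolayer as 16-bit TIFFs with a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if monolayer.cell_labels.max() >= 2 ** 16:
        raise ValueError("more than 65535 labels; 16-bit TIFF cannot hold them")
    tifffile.imwrite(out / "cell_labels.tif",
                     monolayer.cell_labels.astype(np.uint16))
    tifffile.imwrite(out / "nucleus_labels.tif",
                     monolayer.nucleus_labels.astype(np.uint16))
    scales = {}
    for name, img in monolayer.channels.items():
        counts = np.clip(np.round(img * _CHANNEL_SCALE), 0, 2 ** 16 - 1)
        tifffile.imwrite(out / f"{name}.tif", counts.astype(np.uint16))
        scales[name] = 1.0 / _CHANNEL_SCALE
    sidecar = {
        "pixel_size": monolayer.pixel_size,
        "channels": list(monolayer.channels),
        "channel_scales": scales,
        "n_clipped_nuclei": monolayer.n_clipped_nuclei,
        "params": _params_to_jsonable(params),
    }
    (out / "monolayer.json").write_text(json.dumps(sidecar, indent=2,
                                                   sort_keys=True))
    return out


def read_monolayer(in_dir) -> LabeledMonolayer:
    """Read a monolayer directory written by :func:`write_monolayer`."""
    src = Path(in_dir)
    sidecar = json.loads((src / "monolayer.json").read_text())
    cell = tifffile.imread(src / "cell_labels.tif").astype(np.int32)
    nuc = tifffile.imread(src / "nucleus_labels.tif").astype(np.int32)
    channels = {}
    for name in sidecar["channels"]:
        scale = sidecar["channel_scales"].get(name, 1.0)
        channels[name] = tifffile.imread(src / f"{name}.tif").astype(float) * scale
    return LabeledMonolayer(cell, nuc, channels,
                            pixel_size=sidecar["pixel_size"],
                            n_clipped_nuclei=sidecar.get("n_clipped_nuclei", 0))


def write_lineage(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[LINEAGE_COLUMNS].to_csv(path, index=False)
    return path


def read_lineage(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in LINEAGE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"lineage CSV missing columns: {missing}")
    return table
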