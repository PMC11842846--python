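"""Per-object morphometrics from paired cell/nucleus label masks.

One record is produced per matched cell/nucleus pair, carrying the standard
2-D shape descriptors used in epithelial morphometrics plus per-channel
intensity statistics measured over the nucleus mask (DAPI and histone marks
are nuclear stains).

Shape definitions follow the literal ImageJ-style conventions used in this
analysis family:

* aspect ratio   = major axis / minor axis (second-moment ellipse fit)
* shape index    = perimeter / sqrt(area)
* solidity       = area / convex area
* circularity    = area / perimeter**2
* roundness      = area / major_axis**2

``circularity`` and ``roundness`` are therefore *not* the 4*pi- and
4/pi-scaled textbook variants; pass ``conventional_shape=True`` to restore
those (circularity = 4*pi*area/perimeter**2, roundness =
4*area/(pi*major**2)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops_table

from .containers import LabeledMonolayer

__all__ = ["extract_features", "match_and_filter", "match_nuclei_to_cells"]

_PROPS = ("label", "area", "perimeter_crofton", "axis_major_length",
          "axis_minor_length", "solidity", "centroid")


def _border_labels(labels: np.ndarray) -> set[int]:
    edge = np.concatenate([labels[0, :], labels[-1, :],
                           labels[:, 0], labels[:, -1]])
    return set(np.unique(edge[edge > 0]).tolist())


def crack_perimeter(mask: np.ndarray) -> float:
    """Total boundary crack length: the number of unit edges between object
    and non-object pixels (image borders included). Exact for axis-aligned
    polygons (4s for an s-by-s square) but overestimates oblique or curved
    boundaries, where the isotropy-corrected Crofton estimator is better."""
    m = np.asarray(mask, dtype=bool)
    return float(np.count_nonzero(m[:, 1:] != m[:, :-1])
                 + np.count_nonzero(m[1:, :] != m[:-1, :])
                 + m[0, :].sum() + m[-1, :].sum()
                 + m[:, 0].sum() + m[:, -1].sum())


def _crack_perimeters(labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    objs = ndimage.find_objects(labels)
    out = np.zeros(ids.size)
    for i, lab in enumerate(ids.tolist()):
        sl = objs[lab - 1]
        out[i] = crack_perimeter(labels[sl] == lab)
    return out


def _object_table(labels: np.ndarray, prefix: str, pixel_size: float,
                  perimeter_method: str = "crofton") -> pd.DataFrame:
    tab = pd.DataFrame(regionprops_table(labels, properties=_PROPS))
    ps = pixel_size
    if perimeter_method == "crofton":
        perim_px = tab["perimeter_crofton"].to_numpy()
    elif perimeter_method == "crack":
        perim_px = _crack_perimeters(labels, tab["label"].to_numpy())
    else:
        raise ValueError("perimeter_method must be 'crofton' or 'crack'")
    minor = np.maximum(tab["axis_minor_length"].to_numpy(), 1e-9)
    out = pd.DataFrame({
        "label_id": tab["label"].astype(int),
        f"{prefix}_area": tab["area"] * ps ** 2,
        f"{prefix}_perimeter": perim_px * ps,
        f"{prefix}_major_axis": tab["axis_major_length"] * ps,
        f"{prefix}_minor_axis": tab["axis_minor_length"] * ps,
        f"{prefix}_aspect_ratio": tab["axis_major_length"] / minor,
        f"{prefix}_solidity": tab["solidity"],
    })
    area = out[f"{prefix}_area"].to_numpy()
    perim = np.maximum(out[f"{prefix}_perimeter"].to_numpy(), 1e-9)
    major = np.maximum(out[f"{prefix}_major_axis"].to_numpy(), 1e-9)
    out[f"{prefix}_shape_index"] = perim / np.sqrt(area)
    out[f"{prefix}_circularity"] = area / perim ** 2
    out[f"{prefix}_roundness"] = area / major ** 2
    if prefix == "cell":
        out["centroid_row"] = tab["centroid-0"] * ps
        out["centroid_col"] = tab["centroid-1"] * ps
    return out


def match_nuclei_to_cells(cell_labels: np.ndarray, nucleus_labels: np.ndarray
                          ) -> tuple[dict[int, int], list[int]]:
    """Map nucleus label -> cell label by nucleus-centroid-in-cell-mask.

    Returns the mapping and the list of nucleus labels involved in
    ambiguous matches (two nuclei whose centroids fall in the same cell);
    ambiguous nuclei are excluded from the mapping.
    """
    nuc_ids = np.unique(nucleus_labels)
    nuc_ids = nuc_ids[nuc_ids > 0]
    if nuc_ids.size == 0:
        return {}, []
    centroids = ndimage.center_of_mass(nucleus_labels > 0, nucleus_labels,
                                       nuc_ids)
    mapping: dict[int, int] = {}
    by_cell: dict[int, list[int]] = {}
    for nid, (r, c) in zip(nuc_ids.tolist(), centroids):
        cell = int(cell_labels[int(round(r)), int(round(c))])
        if cell > 0:
            by_cell.setdefault(cell, []).append(nid)
    ambiguous: list[int] = []
    for cell, nids in by_cell.items():
        if len(nids) == 1:
            mapping[nids[0]] = cell
        else:
            ambiguous.extend(nids)
    return mapping, sorted(ambiguous)


def extract_features(monolayer: LabeledMonolayer,
                     conventional_shape: bool = False,
                     perimeter_method: str = "crofton") -> pd.DataFrame:
    """Extract one :class:`CellRecord`-style row per matched cell/nucleus pair.

    Axes come from the second-moment ellipse fit; the perimeter uses the
    isotropy-corrected 4-direction Crofton estimator by default
    (``perimeter_method="crack"`` switches to the exact crack length, which
    is preferable for axis-aligned geometry); lengths/areas are in
    micrometres via ``pixel_size``. Objects without a partner are dropped
    and counted in ``df.attrs["reconciliation"]``. When the cell and nucleus
    masks share no label ids, nuclei are re-matched to cells by
    centroid-in-mask and relabelled.
    """
    cell_labels = monolayer.cell_labels
    nucleus_labels = monolayer.nucleus_labels
    cell_ids = set(np.unique(cell_labels[cell_labels > 0]).tolist())
    nuc_ids = set(np.unique(nucleus_labels[nucleus_labels > 0]).tolist())
    recon = {"n_cells": len(cell_ids), "n_nuclei": len(nuc_ids),
             "relabelled": False, "ambiguous_nuclei": []}
    if cell_ids and nuc_ids and not (cell_ids & nuc_ids):
        mapping, ambiguous = match_nuclei_to_cells(cell_labels, nucleus_labels)
        relabel = np.zeros(int(nucleus_labels.max()) + 1,
                           dtype=nucleus_labels.dtype)
        for nid, cid in mapping.items():
            relabel[nid] = cid
        nucleus_labels = relabel[nucleus_labels]
        recon["relabelled"] = True
        recon["ambiguous_nuclei"] = ambiguous
        nuc_ids = set(mapping.values())

    cells = _object_table(cell_labels, "cell", monolayer.pixel_size,
                          perimeter_method)
    nucs = _object_table(nucleus_labels, "nucleus", monolayer.pixel_size,
                         perimeter_method)
    df = cells.merge(nucs, on="label_id", how="inner")
    recon["n_unmatched_cells"] = len(cells) - len(df)
    recon["n_unmatched_nuclei"] = len(nucs) - len(df)

    if conventional_shape:
        for p in ("cell", "nucleus"):
            df[f"{p}_circularity"] *= 4.0 * np.pi
            df[f"{p}_roundness"] *= 4.0 / np.pi

    df["nc_area_ratio"] = df["nucleus_area"] / df["cell_area"]
    df["nc_ar_ratio"] = df["nucleus_aspect_ratio"] / df["cell_aspect_ratio"]

    # intensity statistics over the nucleus mask
    ids = df["label_id"].to_numpy()
    for name, img in monolayer.channels.items():
        mean = ndimage.mean(img, labels=nucleus_labels, index=ids)
        sd = ndimage.standard_deviation(img, labels=nucleus_labels, index=ids)
        df[f"{name}_mean"] = mean
        df[f"{name}_sd"] = sd
        df[f"{name}_cv"] = np.divide(sd, mean, out=np.zeros_like(sd),
                                     where=mean > 0)
    if "DAPI" in monolayer.channels:
        dapi = df["DAPI_mean"].to_numpy()
        for name in monolayer.channels:
            if name == "DAPI":
                continue
            df[f"{name}_norm"] = np.divide(
                df[f"{name}_mean"].to_numpy(), dapi,
                out=np.full(len(df), np.nan), where=dapi > 0)

    border = (_border_labels(cell_labels)
              | _border_labels(nucleus_labels))
    df["edge_flag"] = df["label_id"].isin(border)
    df["mitotic_flag"] = False
    df.attrs["reconciliation"] = recon
    return df


def match_and_filter(records: pd.DataFrame,
                     mitotic_labels: list[int] | None = None,
                     dapi_outlier_rule: bool = False
                     ) -> tuple[pd.DataFrame, dict]:
    """Apply the analysis exclusion rules.

    Removes records touching any image border (their morphology cannot be
    measured accurately) and records flagged as actively dividing — either
    from a supplied ``mitotic_labels`` list or, when ``dapi_outlier_rule``
    is on, nuclei whose DAPI mean exceeds median + 3*MAD.

    Returns the surviving records and a report of exclusion counts.
    """
    df = records.copy()
    if mitotic_labels:
        df.loc[df["label_id"].isin(set(mitotic_labels)), "mitotic_flag"] = True
    if dapi_outlier_rule and "DAPI_mean" in df.columns:
        dapi = df["DAPI_mean"].to_numpy()
        med = np.median(dapi)
        mad = np.median(np.abs(dapi - med))
        df.loc[dapi > med + 3.0 * mad, "mitotic_flag"] = True
    n_edge = int(df["edge_flag"].sum())
    n_mitotic = int((df["mitotic_flag"] & ~df["edge_flag"]).sum())
    keep = ~(df["edge_flag"] | df["mitotic_flag"])
    out = df[keep].reset_index(drop=True)
    report = {"n_in": len(df), "n_out": len(out),
              "n_edge_excluded": n_edge, "n_mitotic_excluded": n_mitotic}
    out.attrs["filter_report"] = report
    return out, report
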