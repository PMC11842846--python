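"""Shared in-memory containers for monolayer fields of view.

A :class:`LabeledMonolayer` bundles the co-registered images for one field:
an integer cell label mask, an integer nucleus label mask sharing label ids
with the cells, and any number of named intensity channels (DAPI plus one or
more histone-mark channels). All images share one shape; areas are converted
to physical units through ``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabeledMonolayer:
    """One segmented field of view.

    Parameters
    ----------
    cell_labels, nucleus_labels
        2-D integer images; 0 is background, positive ids label objects.
        Nucleus ids correspond to cell ids where the segmentation pipeline
        provides matched labels.
    channels
        Mapping of channel name (e.g. ``"DAPI"``, ``"H3K27me3"``) to a
        non-negative 2-D intensity image of the same shape as the masks.
    pixel_size
        Physical pixel edge length in micrometres per pixel.
    truth
        Optional per-object ground-truth table attached by the synthetic
        generator (sampled areas and mark levels before rendering). ``None``
        for real data.
    n_clipped_nuclei
        Count of nuclei whose target ellipse did not fit inside the parent
        cell and were clipped during synthesis.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size: float = 1.0
    truth: pd.DataFrame | None = None
    n_clipped_nuclei: int = 0

    def __post_init__(self) -> None:
        self.cell_labels = np.asarray(self.cell_labels)
        self.nucleus_labels = np.asarray(self.nucleus_labels)
        if self.cell_labels.ndim != 2:
            raise ValueError("cell_labels must be a 2-D image")
        if self.cell_labels.shape != self.nucleus_labels.shape:
            raise ValueError("cell and nucleus label images must share a shape")
        if not np.issubdtype(self.cell_labels.dtype, np.integer):
            raise ValueError("cell_labels must be an integer image")
        if not np.issubdtype(self.nucleus_labels.dtype, np.integer):
            raise ValueError("nucleus_labels must be an integer image")
        for name, img in self.channels.items():
            img = np.asarray(img, dtype=float)
            if img.shape != self.cell_labels.shape:
                raise ValueError(f"channel {name!r} shape differs from masks")
            self.channels[name] = img
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError("pixel_size must be positive and finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_labels.shape

    def label_ids(self) -> np.ndarray:
        """Ids present in both the cell and the nucleus mask, sorted."""
        cells = np.unique(self.cell_labels)
        nucs = np.unique(self.nucleus_labels)
        shared = np.intersect1d(cells, nucs)
        return shared[shared > 0]
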