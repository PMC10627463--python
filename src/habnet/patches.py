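"""Habitat-patch delineation from a continuous suitability surface.

A continuous suitability raster (values in [0, 1]) is binarized at a
threshold — by default the ROC point balancing sensitivity and specificity —
then intersected with an environmental mask (water bodies, spawning sites).
Connected components of the masked suitable cells become habitat patches,
each carrying its area (cell count x cell_size^2) and its habitat
suitability index (HSI), the mean continuous suitability over member cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping
from shapely.ops import unary_union
from skimage import measure

from .rasters import Raster

__all__ = [
    "Patch",
    "PatchSet",
    "roc_balance_threshold",
    "binarize",
    "delineate_patches",
    "patchset_from_labels",
]


@dataclass
class Patch:
    """One habitat patch: a connected set of suitable, masked cells."""

    patch_id: int
    rows: np.ndarray  # member-cell row indices
    cols: np.ndarray  # member-cell col indices
    area: float  # m^2
    hsi: float  # mean suitability over member cells, in [0, 1]

    @property
    def n_cells(self) -> int:
        return len(self.rows)


@dataclass
class PatchSet:
    """Ordered collection of patches sharing one raster grid.

    ``labels`` maps each grid cell to its patch_id (0 = no patch), which
    makes point-in-patch lookups O(1).
    """

    patches: list[Patch]
    labels: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self) -> Iterator[Patch]:
        return iter(self.patches)

    def __getitem__(self, i: int) -> Patch:
        return self.patches[i]

    @property
    def patch_ids(self) -> list[int]:
        return [p.patch_id for p in self.patches]

    def by_id(self, patch_id: int) -> Patch:
        for p in self.patches:
            if p.patch_id == patch_id:
                return p
        raise KeyError(patch_id)

    def geometry(self, patch: Patch):
        """Shapely polygon of the patch: union of its cell squares."""
        x0, y0 = self.origin
        cs = self.cell_size
        cells = [
            box(x0 + c * cs, y0 - (r + 1) * cs, x0 + (c + 1) * cs, y0 - r * cs)
            for r, c in zip(patch.rows, patch.cols)
        ]
        return unary_union(cells)

    def boundary_cells(self, patch: Patch) -> tuple[np.ndarray, np.ndarray]:
        """Member cells with at least one non-member 4-neighbour."""
        member = self.labels == patch.patch_id
        interior = np.zeros_like(member)
        interior[1:-1, 1:-1] = (
            member[1:-1, 1:-1]
            & member[:-2, 1:-1]
            & member[2:, 1:-1]
            & member[1:-1, :-2]
            & member[1:-1, 2:]
        )
        edge = member & ~interior
        rr, cc = np.nonzero(edge)
        return rr, cc

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patch_id": [p.patch_id for p in self.patches],
                "area_m2": [p.area for p in self.patches],
                "hsi": [p.hsi for p in self.patches],
                "n_cells": [p.n_cells for p in self.patches],
            }
        )

    def to_geojson(self, path) -> None:
        features = []
        for p in self.patches:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(self.geometry(p)),
                    "properties": {
                        "patch_id": p.patch_id,
                        "area_m2": p.area,
                        "hsi": p.hsi,
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def roc_balance_threshold(
    scores_presence: Sequence[float], scores_background: Sequence[float]
) -> float:
    """Threshold balancing sensitivity and specificity.

    Scans every observed score value as a candidate threshold t and returns
    the one minimizing |sensitivity(t) - specificity(t)|, where sensitivity
    is the fraction of presence scores >= t and specificity the fraction of
    background scores < t. Ties break toward the smaller t.
    """
    pres = np.asarray(scores_presence, dtype=float)
    back = np.asarray(scores_background, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    candidates = np.unique(np.concatenate([pres, back]))
    best_t, best_gap = None, np.inf
    for t in candidates:  # ascending, so first minimum wins ties toward small t
        sens = float(np.mean(pres >= t))
        spec = float(np.mean(back < t))
        gap = abs(sens - spec)
        if gap < best_gap - 1e-12:
            best_t, best_gap = float(t), gap
    return best_t


def binarize(raster: Raster, threshold: float) -> np.ndarray:
    """Suitable = suitability >= threshold; nodata cells are never suitable."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return (raster.data >= threshold) & raster.valid_mask()


def delineate_patches(
    binary: np.ndarray,
    mask: Raster | np.ndarray,
    suitability: Raster,
    connectivity: int = 8,
) -> PatchSet:
    """Label connected components of (suitable AND masked) cells as patches.

    Parameters
    ----------
    binary:
        Boolean suitable/unsuitable grid from :func:`binarize`.
    mask:
        Environmental mask (water bodies etc.) aligned to the suitability
        raster; only masked cells can belong to a patch.
    suitability:
        The continuous raster, used for per-patch HSI.
    connectivity:
        8 (default; diagonal neighbours merge) or 4.
    """
    mask_data = mask.data if isinstance(mask, Raster) else np.asarray(mask)
    if isinstance(mask, Raster) and not mask.aligned_with(suitability):
        raise ValueError("mask and suitability rasters are not aligned")
    if mask_data.shape != binary.shape:
        raise ValueError("mask and binary grids have different shapes")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")

    habitat = binary & mask_data.astype(bool)
    labels = measure.label(habitat, connectivity=2 if connectivity == 8 else 1)
    cell_area = suitability.cell_size**2
    patches = []
    for pid in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == pid)
        patches.append(
            Patch(
                patch_id=pid,
                rows=rr,
                cols=cc,
                area=float(len(rr) * cell_area),
                hsi=float(np.mean(suitability.data[rr, cc])),
            )
        )
    return PatchSet(
        patches=patches,
        labels=labels,
        cell_size=suitability.cell_size,
        origin=suitability.origin,
        provenance={"connectivity": connectivity},
    )


def patchset_from_labels(labels: Raster, suitability: Raster) -> PatchSet:
    """Rebuild a PatchSet from a stored label grid and its suitability raster."""
    if not labels.aligned_with(suitability):
        raise ValueError("label and suitability rasters are not aligned")
    lab = labels.data.astype(int)
    cell_area = suitability.cell_size**2
    patches = []
    for pid in np.unique(lab):
        if pid == 0:
            continue
        rr, cc = np.nonzero(lab == pid)
        patches.append(
            Patch(
                patch_id=int(pid),
                rows=rr,
                cols=cc,
                area=float(len(rr) * cell_area),
                hsi=float(np.mean(suitability.data[rr, cc])),
            )
        )
    return PatchSet(
        patches=patches,
        labels=lab,
        cell_size=suitability.cell_size,
        origin=suitability.origin,
        provenance={"source": "labels"},
    )
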