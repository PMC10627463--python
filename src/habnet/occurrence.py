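"""Occurrence-state assignment from opportunistic multi-species records.

Non-systematically collected observation records cannot support formal
site-occupancy models, so each patch is labelled by sampling intensity: a
"visit" is a distinct (patch, date) pair with at least one record of any
target-group species. A patch with a focal-species record is a presence (1).
A patch never yielding the focal species despite at least ``threshold``
visits is a likely absence (0, a target-group absence); less-visited focal-
free patches stay unlabeled and are excluded from model fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .patches import PatchSet

__all__ = [
    "sampling_intensity",
    "detection_curve",
    "select_intensity_threshold",
    "assign_occurrence_state",
]

REQUIRED_COLUMNS = ("x", "y", "date", "species")


def sampling_intensity(
    records: pd.DataFrame,
    patches: PatchSet,
    focal_species: str,
    snap_distance: float = 0.0,
) -> pd.DataFrame:
    """Per-patch visit and focal-detection counts.

    Each record is assigned to the patch containing its coordinates, or to
    the nearest patch within ``snap_distance`` metres (records farther from
    any patch are dropped). Visits count distinct (patch, date) pairs over
    all species; focal detections count them for ``focal_species`` only.
    Returns a DataFrame indexed by patch_id with columns ``visits`` and
    ``focal_detections``, covering every patch (zeros where unvisited).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table lacks columns: {missing}")

    out = pd.DataFrame(
        0, index=pd.Index(patches.patch_ids, name="patch_id"),
        columns=["visits", "focal_detections"],
    )
    if len(records) and len(patches):
        x0, y0 = patches.origin
        cs = patches.cell_size
        cols = np.floor((records["x"].to_numpy() - x0) / cs).astype(int)
        rows = np.floor((y0 - records["y"].to_numpy()) / cs).astype(int)
        nrow, ncol = patches.labels.shape
        inside = (rows >= 0) & (rows < nrow) & (cols >= 0) & (cols < ncol)
        pid = np.zeros(len(records), dtype=int)
        pid[inside] = patches.labels[rows[inside], cols[inside]]

        if snap_distance > 0 and np.any(pid == 0):
            rr, cc = np.nonzero(patches.labels > 0)
            if len(rr):
                cx = x0 + (cc + 0.5) * cs
                cy = y0 - (rr + 0.5) * cs
                tree = cKDTree(np.column_stack([cx, cy]))
                unassigned = np.nonzero(pid == 0)[0]
                pts = records.iloc[unassigned][["x", "y"]].to_numpy()
                dist, idx = tree.query(pts)
                # nearest-cell-centre distance stands in for polygon distance
                ok = dist <= snap_distance
                pid[unassigned[ok]] = patches.labels[rr[idx[ok]], cc[idx[ok]]]

        assigned = records.assign(patch_id=pid).loc[pid > 0]
        visits = assigned.groupby("patch_id")["date"].nunique()
        focal = (
            assigned.loc[assigned["species"] == focal_species]
            .groupby("patch_id")["date"]
            .nunique()
        )
        out.loc[visits.index, "visits"] = visits
        out.loc[focal.index, "focal_detections"] = focal
    return out


def detection_curve(table: pd.DataFrame) -> pd.Series:
    """Mean focal detections per visit-count stratum.

    For every observed visit count v, the mean of ``focal_detections``
    among patches visited exactly v times — the plot from which the
    sampling-intensity threshold is read.
    """
    if table.empty:
        raise ValueError("empty occurrence table")
    return table.groupby("visits")["focal_detections"].mean().sort_index()


def select_intensity_threshold(
    curve: pd.Series,
    saturation_fraction: float = 0.9,
    manual_override: int | None = None,
) -> int:
    """Visit count where the detection curve saturates.

    Returns the smallest visit count at which the cumulative maximum of the
    curve reaches ``saturation_fraction`` of its overall maximum; beyond it,
    extra visits add little chance of a first detection, so a focal-free
    patch is plausibly unoccupied. A ``manual_override`` bypasses the
    heuristic (the recommended path when reproducing a specific study).
    """
    if manual_override is not None:
        return int(manual_override)
    if not 0 < saturation_fraction <= 1:
        raise ValueError("saturation_fraction must be in (0, 1]")
    curve = curve[curve.index > 0].sort_index()
    peak = curve.max() if len(curve) else 0.0
    if peak is None or not np.isfinite(peak) or peak <= 0:
        raise ValueError(
            "detection curve is flat at zero; choose a threshold manually"
        )
    cummax = curve.cummax()
    ok = cummax >= saturation_fraction * peak
    return int(curve.index[ok.to_numpy()][0])


def assign_occurrence_state(table: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Label patches 1 / 0 / unlabeled from visit and detection counts.

    state 1: at least one focal detection (regardless of visits);
    state 0: no focal detection and visits >= threshold;
    unlabeled (NaN): no focal detection, visits below threshold.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out = table.copy()
    state = np.where(
        out["focal_detections"] >= 1,
        1.0,
        np.where(out["visits"] >= threshold, 0.0, np.nan),
    )
    out["state"] = state
    return out
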