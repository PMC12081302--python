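"""3D immunofluorescence quantification of nuclei.

Implements the quantification chain for confocal stacks: Otsu-threshold 3D
nucleus segmentation, DNA-damage focus counting (dataset-level top-percentile
intensity threshold on median-filtered stacks, foci larger than three voxels,
assigned to the nucleus containing their centroid), the nuclear flatness
index (bounding-box height over the shorter horizontal extent, with >3
treated as a segmentation outlier), marker positivity (mean nuclear YAP
intensity above a cutoff) and cohort percentage summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import GeometryError, ParameterError

__all__ = [
    "segment_nuclei_3d",
    "dataset_focus_threshold",
    "detect_foci",
    "flatness_index",
    "measure_nuclei",
    "classify_and_summarize",
    "FOCI_CUTOFF",
    "YAP_CUTOFF",
    "FLATNESS_CUTOFF",
    "FLATNESS_OUTLIER",
]

FOCI_CUTOFF = 5          # nuclei with >= 5 foci count as damage-high
YAP_CUTOFF = 3000.0      # mean nuclear intensity strictly above -> positive
FLATNESS_CUTOFF = 0.8    # flatness strictly below -> flat nucleus
FLATNESS_OUTLIER = 3.0   # flatness strictly above -> discarded as outlier
MIN_FOCUS_VOXELS = 4     # foci larger than three voxels are counted


def segment_nuclei_3d(dna_stack: np.ndarray, min_volume_voxels: int = 200,
                      threshold: float | None = None) -> np.ndarray:
    """Segment nuclei in a single-channel 3D stack.

    Global Otsu threshold (unless given), 26-connected components, then a
    minimum-volume filter.  Returns a label volume (0 = background) with
    consecutive labels; an empty result is a valid outcome.
    """
    stack = np.asarray(dna_stack)
    if stack.ndim != 3:
        raise ParameterError("dna_stack must be 3D (z, y, x)")
    thr = float(threshold_otsu(stack)) if threshold is None else float(threshold)
    labels = cc_label(stack > thr, connectivity=3)
    out = np.zeros_like(labels)
    next_id = 1
    for prop in regionprops(labels):
        if prop.area >= min_volume_voxels:
            out[labels == prop.label] = next_id
            next_id += 1
    return out


def _top_percentile_threshold(values: np.ndarray, top_percentile: float) -> float:
    n = values.size
    k = int(round(n * top_percentile / 100.0))
    k = max(k, 1)
    # value of the k-th brightest voxel
    return float(np.partition(values, n - k)[n - k])


def dataset_focus_threshold(stacks: Iterable[np.ndarray], top_percentile: float = 0.02,
                            median_radius: int = 1) -> float:
    """Dataset-level focus intensity threshold.

    Pools the (median-filtered) voxel intensities of every stack in the
    dataset and returns the value of the brightest ``top_percentile`` percent
    rank — e.g. at 0.02 on 10^6 voxels, the 200th-brightest voxel.  A single
    threshold per dataset keeps counts comparable across conditions.
    """
    if not 0.0 < top_percentile < 100.0:
        raise ParameterError("top_percentile must lie in (0, 100)")
    pools = []
    for s in stacks:
        s = np.asarray(s)
        if median_radius > 0:
            s = median_filter(s, size=2 * median_radius + 1)
        pools.append(s.ravel())
    if not pools:
        raise ParameterError("no stacks supplied")
    return _top_percentile_threshold(np.concatenate(pools), top_percentile)


def detect_foci(channel_stack: np.ndarray, labels: np.ndarray,
                threshold: float | None = None, top_percentile: float = 0.02,
                min_size_voxels: int = MIN_FOCUS_VOXELS,
                median_radius: int = 1) -> pd.Series:
    """Count DNA-damage foci per nucleus.

    3D median filter, intensity threshold (dataset-level value preferred;
    computed from this stack when absent), 26-connected components, keep
    components of at least ``min_size_voxels`` voxels (default 4, i.e.
    larger than three), and assign each focus to the nucleus containing its
    centroid.  Returns counts indexed by nucleus label (all labels present,
    zeros included).
    """
    stack = np.asarray(channel_stack)
    if stack.shape != labels.shape:
        raise ParameterError("channel stack and label volume must share a shape")
    if median_radius > 0:
        stack = median_filter(stack, size=2 * median_radius + 1)
    if threshold is None:
        threshold = _top_percentile_threshold(stack.ravel(), top_percentile)
    comps = cc_label(stack >= threshold, connectivity=3)
    nucleus_ids = [int(v) for v in np.unique(labels) if v != 0]
    counts = {nid: 0 for nid in nucleus_ids}
    for prop in regionprops(comps):
        if prop.area < min_size_voxels:
            continue
        cz, cy, cx = (int(round(c)) for c in prop.centroid)
        nid = int(labels[cz, cy, cx])
        if nid != 0:
            counts[nid] = counts.get(nid, 0) + 1
    return pd.Series(counts, name="foci").sort_index()


def flatness_index(bbox_extents_xyz: Sequence[float]) -> tuple[float, bool]:
    """Flatness = bounding-box height / shorter horizontal extent.

    Returns (flatness, is_outlier); values above 3 flag a segmentation
    outlier that cohort summaries must exclude.
    """
    ex, ey, ez = (float(v) for v in bbox_extents_xyz)
    if min(ex, ey, ez) <= 0:
        raise GeometryError("bounding-box extents must be positive")
    f = ez / min(ex, ey)
    return f, f > FLATNESS_OUTLIER


def measure_nuclei(labels: np.ndarray, channels: Mapping[str, np.ndarray],
                   foci_counts: Mapping[str, pd.Series] | None = None,
                   replicate: str | int | None = None) -> pd.DataFrame:
    """Per-nucleus records: bbox extents, flatness, per-channel mean
    intensity and (optional) per-channel focus counts."""
    rows = []
    foci_counts = foci_counts or {}
    for prop in regionprops(labels):
        zmin, ymin, xmin, zmax, ymax, xmax = prop.bbox
        extents = (xmax - xmin, ymax - ymin, zmax - zmin)
        flat, outlier = flatness_index(extents)
        row = {"label": prop.label,
               "extent_x": extents[0], "extent_y": extents[1], "extent_z": extents[2],
               "flatness": flat, "outlier": outlier}
        if replicate is not None:
            row["replicate"] = replicate
        mask = labels == prop.label
        for ch, stack in channels.items():
            row[f"mean_{ch}"] = float(np.asarray(stack)[mask].mean())
        for ch, series in foci_counts.items():
            row[f"foci_{ch}"] = int(series.get(prop.label, 0))
        rows.append(row)
    return pd.DataFrame(rows)


def classify_and_summarize(records: pd.DataFrame, foci_cutoff: int = FOCI_CUTOFF,
                           yap_cutoff: float = YAP_CUTOFF,
                           flat_cutoff: float = FLATNESS_CUTOFF,
                           foci_column: str = "foci_damage",
                           yap_column: str = "mean_yap") -> dict:
    """Cohort summary percentages.

    Outlier nuclei (flatness > 3) are excluded.  ``foci_high`` is inclusive
    (count >= cutoff); YAP positivity and flatness use strict comparisons
    (mean > 3,000; flatness < 0.8).  Per-replicate means are reported when a
    ``replicate`` column is present.
    """
    if records.empty:
        return {"n_nuclei": 0}
    rec = records.loc[~records.get("outlier", False).astype(bool)].copy()
    n = len(rec)
    out: dict = {"n_nuclei": int(n), "n_outliers": int(len(records) - n)}
    if n == 0:
        return out
    if foci_column in rec:
        rec["foci_high"] = rec[foci_column] >= foci_cutoff
        out["pct_foci_high"] = 100.0 * rec["foci_high"].mean()
    if yap_column in rec:
        rec["yap_positive"] = rec[yap_column] > yap_cutoff
        out["pct_yap_positive"] = 100.0 * rec["yap_positive"].mean()
    rec["flat"] = rec["flatness"] < flat_cutoff
    out["pct_flat"] = 100.0 * rec["flat"].mean()
    if "replicate" in rec:
        per = {}
        for metric in ("foci_high", "yap_positive", "flat"):
            if metric in rec:
                per[f"pct_{metric}"] = (100.0 * rec.groupby("replicate")[metric].mean()).to_dict()
        out["per_replicate"] = per
    return out
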