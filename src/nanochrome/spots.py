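"""Spot detection and per-particle photometry on two-channel frames.

Mirrors the image-analysis stage of the assay: find each local brightest
light spot (one per nanoparticle) on the R+G sum image, integrate its
background-subtracted intensity separately in the R and G channels, compute
the chromatic contrast gamma, and exclude oversized spots (aggregates) by a
pixel-area threshold.

Background under each spot is estimated robustly from an annulus (median,
with spread = 1.4826 x MAD).  The spot area is the count of pixels inside
the measurement disk exceeding max(background + 3 x spread, 5% of the
background-subtracted peak); the relative term makes the footprint measure
insensitive to the d^6 brightness spread of single particles, so the area
threshold separates doublets from bright singles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Spot",
    "DetectionParams",
    "detect_spots",
    "measure_spot",
    "filter_spots",
    "analyze_frame",
    "analyze_dataset",
    "calibrate_max_area",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the detection/measurement stage.

    min_peak_prominence: counts above local background for a peak (ADU);
    local_max_window: odd side of the local-maximum neighbourhood (px);
    measure_radius: photometry disk radius (px); background_annulus:
    (inner, outer) radii of the background ring (px); max_area: pixel-area
    threshold above which a spot is excluded as an aggregate (None = keep
    all); peak_area_fraction: relative component of the area threshold.
    """

    min_peak_prominence: float = 100.0
    local_max_window: int = 7
    measure_radius: float = 7.0
    background_annulus: tuple[float, float] = (9.0, 13.0)
    max_area: float | None = None
    peak_area_fraction: float = 0.05

    def __post_init__(self):
        if self.local_max_window < 3 or self.local_max_window % 2 == 0:
            raise ValueError("local_max_window must be odd and >= 3")
        inner, outer = self.background_annulus
        if not self.measure_radius < inner < outer:
            raise ValueError("radii must satisfy measure_radius < inner < outer")


@dataclass
class Spot:
    """One measured light spot."""

    frame: int
    row: float
    col: float
    peak: float
    area: int
    r_scat: float
    g_scat: float
    gamma: float
    excluded: bool = False
    reason: str = ""


def _coarse_background(frame: np.ndarray, block: int = 64) -> np.ndarray:
    """Smooth background map from block-wise medians (bilinear upsampled)."""
    h, w = frame.shape
    nb_r = max(h // block, 1)
    nb_c = max(w // block, 1)
    trimmed = frame[: nb_r * block, : nb_c * block].reshape(nb_r, block, nb_c, block)
    med = np.median(trimmed, axis=(1, 3))
    zoom = (h / med.shape[0], w / med.shape[1])
    return ndimage.zoom(med, zoom, order=1, mode="nearest", grid_mode=True)


def detect_spots(sum_frame: np.ndarray, params: DetectionParams) -> list[tuple[float, float, float]]:
    """Local maxima of the sum frame with prominence over the local
    background >= min_peak_prominence.

    Returns (row, col, peak_height) sorted by peak height descending.
    Plateaus (connected pixels of equal maximal value) are collapsed to
    their centroid.
    """
    frame = np.asarray(sum_frame, dtype=float)
    if frame.ndim != 2 or not np.all(np.isfinite(frame)):
        raise ValueError("sum_frame must be a finite 2-D array")
    bg = _coarse_background(frame)
    prominence = frame - bg
    is_max = frame == ndimage.maximum_filter(frame, size=params.local_max_window)
    cand = is_max & (prominence >= params.min_peak_prominence)
    if not cand.any():
        return []
    labels, n = ndimage.label(cand)
    centroids = ndimage.center_of_mass(cand, labels, range(1, n + 1))
    peaks = []
    for r, c in centroids:
        ri, ci = int(round(r)), int(round(c))
        peaks.append((float(r), float(c), float(frame[ri, ci])))
    peaks.sort(key=lambda t: -t[2])
    return peaks


def _disk_mask(shape, row, col, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def measure_spot(
    r_frame: np.ndarray,
    g_frame: np.ndarray,
    peak: tuple[float, float, float],
    params: DetectionParams,
    frame_index: int = 0,
) -> Spot:
    """Photometry of one detected peak.

    r_scat/g_scat are background-subtracted sums over the measurement disk;
    the background per channel is the annulus median; gamma = (R-G)/(R+G).
    Peaks whose annulus extends outside the frame are flagged excluded with
    reason "edge".
    """
    row, col, _ = peak
    h, w = r_frame.shape
    outer = params.background_annulus[1]
    if (
        row - outer < -0.5
        or col - outer < -0.5
        or row + outer > h - 0.5
        or col + outer > w - 0.5
    ):
        return Spot(frame_index, row, col, 0.0, 0, 0.0, 0.0, np.nan, True, "edge")

    ri, ci = int(round(row)), int(round(col))
    size = int(np.ceil(outer)) + 1
    r0, r1 = ri - size, ri + size + 1
    c0, c1 = ci - size, ci + size + 1
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    rw = np.asarray(r_frame[r0c:r1c, c0c:c1c], dtype=float)
    gw = np.asarray(g_frame[r0c:r1c, c0c:c1c], dtype=float)
    lr, lc = row - r0c, col - c0c
    rr, cc = np.ogrid[: rw.shape[0], : rw.shape[1]]
    dist2 = (rr - lr) ** 2 + (cc - lc) ** 2
    disk = dist2 <= params.measure_radius**2
    inner = params.background_annulus[0]
    annulus = (dist2 >= inner**2) & (dist2 <= outer**2)
    if annulus.sum() < 8:
        return Spot(frame_index, row, col, 0.0, 0, 0.0, 0.0, np.nan, True, "edge")

    sum_w = rw + gw
    bg_r = float(np.median(rw[annulus]))
    bg_g = float(np.median(gw[annulus]))
    bg_s = bg_r + bg_g
    spread = 1.4826 * float(np.median(np.abs(sum_w[annulus] - bg_s)))
    r_scat = float(rw[disk].sum() - disk.sum() * bg_r)
    g_scat = float(gw[disk].sum() - disk.sum() * bg_g)
    peak_sub = float(sum_w[disk].max() - bg_s)
    thresh = max(bg_s + 3.0 * spread, bg_s + params.peak_area_fraction * peak_sub)
    area = int((sum_w[disk] > thresh).sum())

    # intensity-weighted centroid within the disk (sub-pixel refinement)
    weights = np.clip(sum_w - bg_s, 0, None) * disk
    tot = weights.sum()
    if tot > 0:
        row = float((weights * (rr + r0c)).sum() / tot)
        col = float((weights * (cc + c0c)).sum() / tot)

    total = r_scat + g_scat
    gamma = (r_scat - g_scat) / total if total > 0 else np.nan
    return Spot(frame_index, row, col, peak_sub, area, r_scat, g_scat, gamma)


def filter_spots(spots: list[Spot], params: DetectionParams) -> list[Spot]:
    """Flag oversized spots (area > max_area) as excluded aggregates.

    Returns the kept spots; the input objects are mutated in place so the
    caller can still account for every detection."""
    kept = []
    for s in spots:
        if s.excluded:
            continue
        if params.max_area is not None and s.area > params.max_area:
            s.excluded = True
            s.reason = "oversize"
        else:
            kept.append(s)
    return kept


def analyze_frame(
    r_frame: np.ndarray, g_frame: np.ndarray, params: DetectionParams, frame_index: int = 0
) -> list[Spot]:
    sum_frame = np.asarray(r_frame, dtype=float) + np.asarray(g_frame, dtype=float)
    peaks = detect_spots(sum_frame, params)
    return [measure_spot(r_frame, g_frame, p, params, frame_index) for p in peaks]


def _spots_to_frame(spots: list[Spot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": s.frame,
                "row": s.row,
                "col": s.col,
                "peak": s.peak,
                "area_px": s.area,
                "r_scat": s.r_scat,
                "g_scat": s.g_scat,
                "gamma": s.gamma,
                "excluded": s.excluded,
                "reason": s.reason,
            }
            for s in spots
        ],
        columns=[
            "frame",
            "row",
            "col",
            "peak",
            "area_px",
            "r_scat",
            "g_scat",
            "gamma",
            "excluded",
            "reason",
        ],
    )


def analyze_dataset(
    r_stack: np.ndarray, g_stack: np.ndarray, params: DetectionParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Detect, measure and filter spots over a full two-channel stack.

    Returns (table, summary): the table holds one row per detection in
    stable order (frame index, then peak rank) with exclusion flags; the
    summary counts detections, kept spots and exclusions by reason.
    """
    params = params or DetectionParams()
    r_stack = np.asarray(r_stack)
    g_stack = np.asarray(g_stack)
    if r_stack.shape != g_stack.shape:
        raise ValueError("R and G stacks must have identical shapes")
    if r_stack.ndim == 2:
        r_stack = r_stack[None]
        g_stack = g_stack[None]
    all_spots: list[Spot] = []
    for f in range(r_stack.shape[0]):
        spots = analyze_frame(r_stack[f], g_stack[f], params, f)
        filter_spots(spots, params)
        all_spots.extend(spots)
    table = _spots_to_frame(all_spots)
    reasons = table.loc[table["excluded"], "reason"].value_counts().to_dict()
    summary = {
        "n_frames": int(r_stack.shape[0]),
        "detected": int(len(table)),
        "kept": int((~table["excluded"]).sum()),
        "excluded": {k: int(v) for k, v in reasons.items()},
    }
    return table, summary


def match_spots(
    table: pd.DataFrame, ground_truth: pd.DataFrame, radius: float = 2.0
) -> pd.Series:
    """Match detections to ground-truth spots frame by frame.

    Returns, for each row of ``table``, the ground-truth index of the
    nearest true spot within ``radius`` px (or -1 if none).
    """
    from scipy.spatial import cKDTree

    match = np.full(len(table), -1, dtype=int)
    for f, gt in ground_truth.groupby("frame"):
        sel = np.flatnonzero(table["frame"].to_numpy() == f)
        if sel.size == 0:
            continue
        tree = cKDTree(gt[["row", "col"]].to_numpy())
        dist, idx = tree.query(table.iloc[sel][["row", "col"]].to_numpy())
        ok = dist <= radius
        match[sel[ok]] = gt.index.to_numpy()[idx[ok]]
    return pd.Series(match, index=table.index, name="gt_index")


def max_area_from_table(
    table: pd.DataFrame,
    ground_truth: pd.DataFrame,
    percentile: float = 99.5,
    match_radius: float = 2.0,
) -> float:
    """Oversize threshold = percentile of single-particle spot areas, using
    ground-truth identity to select non-aggregate detections."""
    match = match_spots(table, ground_truth, match_radius)
    is_single = ~ground_truth["is_aggregate"]
    ok = (match >= 0) & (~table["excluded"]) & match.map(
        lambda i: bool(is_single.get(i, False))
    )
    areas = table.loc[ok, "area_px"].to_numpy()
    if areas.size == 0:
        raise ValueError("no matched single-particle spots; cannot calibrate")
    return float(np.percentile(areas, percentile))


def calibrate_max_area(
    r_stack: np.ndarray,
    g_stack: np.ndarray,
    ground_truth: pd.DataFrame,
    params: DetectionParams | None = None,
    percentile: float = 99.5,
    match_radius: float = 2.0,
) -> float:
    """Set the oversize threshold from a ground-truthed reference run.

    Measures all spots (no area filter) and returns the requested
    percentile of the areas of detections that match non-aggregate
    ground-truth positions.  Run once on a negative control to calibrate
    DetectionParams.max_area.
    """
    from dataclasses import replace

    params = replace(params or DetectionParams(), max_area=None)
    table, _ = analyze_dataset(r_stack, g_stack, params)
    return max_area_from_table(table, ground_truth, percentile, match_radius)
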