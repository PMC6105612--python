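"""Circular-ROI statistics and tumor-to-background ratios.

ROIs are circles (default radius 51 pixels) placed over the standards, the
tumor, adjacent normal brain, and the dark floor.  The red channel of each
frame is summarised as mean +/- sample SD over the ROI pixels; pixels are
included when their centre lies within the circle (0-based (row, col)
coordinates, origin top-left).  No autofluorescence subtraction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ROI:
    id: str
    center: tuple[int, int]  # (row, col), 0-based
    radius: int = 51
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


def load_rois(path: str | Path) -> list[ROI]:
    """Read an ROI config: JSON with a ``rois`` list of
    ``{id, row, col, radius, label}``."""
    data = json.loads(Path(path).read_text())
    entries = data["rois"] if isinstance(data, dict) else data
    return [ROI(id=str(e["id"]), center=(int(e["row"]), int(e["col"])),
                radius=int(e.get("radius", 51)), label=str(e.get("label", e["id"])))
            for e in entries]


def circular_roi_mask(center: tuple[int, int], radius: float,
                      image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centre is within ``radius`` of ``center``.

    The circle must lie fully inside the image.
    """
    r0, c0 = center
    if (r0 - radius < 0 or c0 - radius < 0
            or r0 + radius > image_shape[0] - 1 or c0 + radius > image_shape[1] - 1):
        raise ValueError(
            f"ROI circle (centre {center}, radius {radius}) exceeds image bounds "
            f"{image_shape}")
    rr, cc = np.ogrid[: image_shape[0], : image_shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def roi_stats(image: np.ndarray, roi: ROI) -> tuple[float, float]:
    """Mean and sample SD of ``image`` over the ROI pixels."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("roi_stats expects a single 2D channel")
    mask = circular_roi_mask(roi.center, roi.radius, image.shape)
    vals = image[mask].astype(float)
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd


@dataclass
class ROITimeSeries:
    """Per-(ROI, time) red-channel statistics for one image stack."""

    table: pd.DataFrame  # columns: roi, label, time_min, mean, sd
    times_min: tuple[float, ...]

    def mean_series(self, roi_id: str) -> pd.Series:
        sub = self.table[self.table["roi"] == roi_id].sort_values("time_min")
        if sub.empty:
            raise KeyError(f"no ROI with id {roi_id!r}")
        return pd.Series(sub["mean"].to_numpy(), index=sub["time_min"].to_numpy())

    def roi_by_label(self, label: str) -> str:
        ids = self.table.loc[self.table["label"] == label, "roi"].unique()
        if len(ids) != 1:
            raise KeyError(f"expected exactly one ROI labelled {label!r}, found {len(ids)}")
        return str(ids[0])


def extract_timeseries(stack: np.ndarray, rois: list[ROI],
                       times_min: list[float] | tuple[float, ...],
                       channel: int = 0) -> ROITimeSeries:
    """Extract red-channel ROI statistics from a (T, H, W, 3) RGB stack.

    ``channel=0`` selects red (RGB order).  2D (T, H, W) stacks are treated
    as already being the channel of interest.
    """
    stack = np.asarray(stack)
    if stack.ndim == 4:
        chan = stack[..., channel]
    elif stack.ndim == 3:
        chan = stack
    else:
        raise ValueError("stack must be (T, H, W[, 3])")
    if chan.shape[0] != len(times_min):
        raise ValueError(f"{chan.shape[0]} frames but {len(times_min)} time points")

    masks = {roi.id: circular_roi_mask(roi.center, roi.radius, chan.shape[1:])
             for roi in rois}
    rows = []
    for ti, t in enumerate(times_min):
        frame = chan[ti].astype(float)
        for roi in rois:
            vals = frame[masks[roi.id]]
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            rows.append({"roi": roi.id, "label": roi.label or roi.id,
                         "time_min": float(t), "mean": float(np.mean(vals)), "sd": sd})
    return ROITimeSeries(table=pd.DataFrame(rows), times_min=tuple(float(t) for t in times_min))


def tumor_background_ratio(ts: ROITimeSeries, tumor_label: str = "tumor",
                           background_label: str = "brain") -> pd.Series:
    """Per-time tumor-to-background ratio of ROI mean intensities.

    Background defaults to the adjacent normal-brain ROI.  The ratio is
    invariant to any per-frame multiplicative gain.  Time points with a
    zero background mean yield NaN (flagged undefined, not an exception).
    """
    tum = ts.mean_series(ts.roi_by_label(tumor_label))
    bkg = ts.mean_series(ts.roi_by_label(background_label))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tum / bkg
    return ratio.where(bkg != 0, np.nan)


def write_timeseries_csv(ts: ROITimeSeries, path: str | Path,
                         specimen: int | str = 0) -> None:
    df = ts.table.copy()
    df.insert(0, "specimen", specimen)
    df.to_csv(path, index=False)


def read_timeseries_csv(path: str | Path) -> ROITimeSeries:
    df = pd.read_csv(path)
    times = tuple(sorted(df["time_min"].unique()))
    cols = [c for c in ("roi", "label", "time_min", "mean", "sd") if c in df.columns]
    return ROITimeSeries(table=df[cols], times_min=times)
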