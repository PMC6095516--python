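"""Background-subtraction detection of the moving animal in each view.

Per frame and per camera the chain is:

    absolute difference against a static background model
    -> masked to the tracking area
    -> locally adaptive threshold, optionally gated by a colour range
    -> erosion then dilation (disc structuring elements)
    -> connected components, area filter, largest blob centroid.

All parameters are explicit in :class:`SegmentationParams` because the
right values depend on sunlight, wind ripple and water clarity at the
site; they are tuned manually per recording setup and then held fixed.
The chain is deterministic: identical frame and parameters always give
the identical centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from skimage.filters import threshold_local
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, erosion

__all__ = [
    "SegmentationParams",
    "Blob",
    "SegmentationError",
    "subtract_background",
    "binarize",
    "morphological_cleanup",
    "extract_centroid",
    "segment_frame",
    "track_frames",
    "build_background",
    "write_centroids_csv",
    "read_centroids_csv",
]

CENTROID_COLUMNS = ["camera_id", "frame", "u", "v", "area", "valid"]


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentationParams:
    """Manually tuned detection parameters for one camera.

    ``adaptive_threshold_offset`` follows the "local mean minus offset"
    convention, so a *negative* offset raises the threshold above the
    local mean; the default of -10 grey levels suppresses sensor noise.
    A pixel with zero difference is never foreground regardless of the
    offset.  ``colour_range`` is an optional per-channel (min, max) gate
    applied to the *original* frame, for when the animal's colour
    separates it from glare or ripple that also moves.
    """

    background: np.ndarray | None = None
    adaptive_threshold_block: int = 101
    adaptive_threshold_offset: float = -10.0
    colour_range: tuple[tuple[float, float], ...] | None = None
    erosion_radius: int = 1
    dilation_radius: int = 2
    min_blob_area: int = 200
    max_blob_area: int = 50000
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.adaptive_threshold_block % 2 == 0:
            raise SegmentationError("adaptive_threshold_block must be odd")
        if self.erosion_radius < 0 or self.dilation_radius < 0:
            raise SegmentationError("morphology radii must be >= 0")
        if self.min_blob_area >= self.max_blob_area:
            raise SegmentationError("min_blob_area must be < max_blob_area")


@dataclass(frozen=True)
class Blob:
    """A detected foreground component."""

    centroid: tuple[float, float]          # (u, v) pixels
    area: int
    bounding_box: tuple[int, int, int, int]  # (u_min, v_min, u_max, v_max)


def _grey(frame: np.ndarray) -> np.ndarray:
    """Collapse a colour frame to a single channel for differencing."""
    arr = np.asarray(frame, dtype=float)
    return arr.mean(axis=2) if arr.ndim == 3 else arr


def build_background(frames: Iterable[np.ndarray]) -> np.ndarray:
    """Static background model: per-pixel median over the given frames."""
    stack = np.stack([np.asarray(f, dtype=float) for f in frames])
    if stack.shape[0] == 0:
        raise SegmentationError("no frames for background model")
    return np.median(stack, axis=0)


def subtract_background(frame: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Absolute grey-level difference to the background, zero outside the mask."""
    if params.background is None:
        raise SegmentationError("background model not initialized")
    g = _grey(frame)
    bg = _grey(params.background)
    if g.shape != bg.shape:
        raise SegmentationError(
            f"frame shape {g.shape} does not match background {bg.shape}"
        )
    diff = np.abs(g - bg)
    if params.mask is not None:
        if params.mask.shape != g.shape:
            raise SegmentationError("mask shape does not match frame")
        diff = np.where(params.mask.astype(bool), diff, 0.0)
    return diff


def binarize(difference: np.ndarray, params: SegmentationParams,
             frame: np.ndarray | None = None) -> np.ndarray:
    """Foreground where the difference exceeds the local adaptive threshold.

    The threshold at each pixel is the mean difference over the
    ``adaptive_threshold_block`` window minus ``adaptive_threshold_offset``.
    If a ``colour_range`` is configured and the original ``frame`` is
    supplied, pixels must additionally fall inside the per-channel range.
    """
    diff = np.asarray(difference, dtype=float)
    thresh = threshold_local(
        diff, block_size=params.adaptive_threshold_block,
        method="mean", offset=params.adaptive_threshold_offset,
    )
    fg = (diff > thresh) & (diff > 0)
    if params.colour_range is not None and frame is not None:
        arr = np.asarray(frame, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if len(params.colour_range) != arr.shape[2]:
            raise SegmentationError("colour_range channel count mismatch")
        gate = np.ones(arr.shape[:2], dtype=bool)
        for ch, (lo, hi) in enumerate(params.colour_range):
            gate &= (arr[:, :, ch] >= lo) & (arr[:, :, ch] <= hi)
        fg &= gate
    if params.mask is not None:
        fg &= params.mask.astype(bool)
    return fg


def morphological_cleanup(binary: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Erosion then dilation with disc structuring elements (radius 0 = no-op)."""
    out = np.asarray(binary, dtype=bool)
    if params.erosion_radius > 0:
        out = erosion(out, disk(params.erosion_radius))
    if params.dilation_radius > 0:
        out = dilation(out, disk(params.dilation_radius))
    return np.asarray(out, dtype=bool)


def extract_centroid(binary: np.ndarray, params: SegmentationParams) -> Blob | None:
    """Area-weighted centroid of the largest admissible component, or None.

    Components are 8-connected; those with area outside
    ``[min_blob_area, max_blob_area]`` are discarded.  Ties on area break
    to the component with the lowest (v, u) centroid.  Absence of a
    detection is a value, not an error.
    """
    labelled = label(np.asarray(binary, dtype=bool), connectivity=2)
    best: Blob | None = None
    best_key = None
    for region in regionprops(labelled):
        if not (params.min_blob_area <= region.area <= params.max_blob_area):
            continue
        v, u = region.centroid
        rmin, cmin, rmax, cmax = region.bbox
        blob = Blob(centroid=(float(u), float(v)), area=int(region.area),
                    bounding_box=(cmin, rmin, cmax - 1, rmax - 1))
        key = (-region.area, v, u)
        if best_key is None or key < best_key:
            best, best_key = blob, key
    return best


def segment_frame(frame: np.ndarray, params: SegmentationParams) -> Blob | None:
    """Run the whole per-frame chain and return the animal blob (or None)."""
    diff = subtract_background(frame, params)
    fg = binarize(diff, params, frame=frame)
    fg = morphological_cleanup(fg, params)
    return extract_centroid(fg, params)


def track_frames(frames: Iterable[np.ndarray], params: SegmentationParams,
                 camera_id: str = "cam") -> pd.DataFrame:
    """Segment a frame sequence into a per-frame centroid table.

    Returns a DataFrame with columns ``camera_id, frame, u, v, area,
    valid``; frames without an admissible blob get ``valid = False`` and
    NaN coordinates.
    """
    rows = []
    for i, frame in enumerate(frames):
        blob = segment_frame(frame, params)
        if blob is None:
            rows.append((camera_id, i, np.nan, np.nan, 0, False))
        else:
            rows.append((camera_id, i, blob.centroid[0], blob.centroid[1],
                         blob.area, True))
    return pd.DataFrame(rows, columns=CENTROID_COLUMNS)


def write_centroids_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_centroids_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
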