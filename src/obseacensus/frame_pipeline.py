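"""Automated still-image fish counting for a fixed underwater camera.

The chain mirrors the classical fixed-camera protocol: subtract a fish-free
reference frame, stretch the absolute difference to the full 8-bit range,
run Sobel edge detection independently on the R, G and B channels, merge the
three binary edge maps with a logical OR, fill the closed contours, and keep
connected components whose pixel area lies in a plausible fish-size window
(default 10–5000 px at the nominal 480 x 360 geometry). The per-frame output
is the object count and the cumulative object area.

All raster operations accept plain ``uint8`` numpy arrays (H x W x 3 for
colour frames, H x W for masks); masks are boolean in memory and serialised
as {0, 255}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

#: Nominal frame geometry of the deployed camera (width, height).
NOMINAL_FRAME_SIZE = (480, 360)

#: Fish-size window in pixels, inclusive on both ends.
DEFAULT_MIN_AREA = 10
DEFAULT_MAX_AREA = 5000


class GeometryError(ValueError):
    """Raised when a frame and its reference disagree in shape."""


class PipelineConfigError(ValueError):
    """Raised for inconsistent pipeline parameters."""


@dataclass(frozen=True)
class PipelineParams:
    """Tunable parameters of the counting chain.

    Parameters
    ----------
    min_area, max_area:
        Inclusive pixel-area bounds for a connected component to count as a
        fish-sized object.
    sobel_threshold_mode:
        ``"auto"`` applies Otsu's threshold to each channel's Sobel gradient
        magnitude; ``"fixed"`` uses ``sobel_threshold`` on every channel.
    sobel_threshold:
        Gradient-magnitude threshold used in ``"fixed"`` mode.
    connectivity:
        Pixel adjacency (4 or 8) used for labelling and hole filling.
    expand_per_channel:
        If true, the 0-255 expansion uses a separate min/max per channel
        instead of one joint pair for the whole image.
    """

    min_area: int = DEFAULT_MIN_AREA
    max_area: int = DEFAULT_MAX_AREA
    sobel_threshold_mode: str = "auto"
    sobel_threshold: Optional[float] = None
    connectivity: int = 8
    expand_per_channel: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_area <= self.max_area:
            raise PipelineConfigError(
                f"need 0 < min_area <= max_area, got ({self.min_area}, {self.max_area})"
            )
        if self.sobel_threshold_mode not in ("auto", "fixed"):
            raise PipelineConfigError(
                f"sobel_threshold_mode must be 'auto' or 'fixed', got {self.sobel_threshold_mode!r}"
            )
        if self.sobel_threshold_mode == "fixed" and self.sobel_threshold is None:
            raise PipelineConfigError("fixed threshold mode requires sobel_threshold")
        if self.connectivity not in (4, 8):
            raise PipelineConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass(frozen=True)
class DetectedObject:
    """One connected component that passed the size filter."""

    label: int
    area: int
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open
    centroid: tuple[float, float]


@dataclass(frozen=True)
class FrameCensus:
    """Automated census of a single frame: object count and cumulative area."""

    timestamp: Optional[object] = None
    count: int = 0
    cumulative_area: int = 0
    objects: tuple[DetectedObject, ...] = ()
    error: Optional[str] = None

    def __post_init__(self) -> None:
        if self.error is None:
            assert self.count == len(self.objects)
            assert self.cumulative_area == sum(o.area for o in self.objects)


def _as_rgb(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise GeometryError(f"expected an H x W x 3 frame, got shape {arr.shape}")
    return arr


def subtract_reference(frame: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Absolute per-pixel difference between a frame and the fish-free reference.

    Both inputs must share geometry; the subtraction is done in signed
    arithmetic so the absolute value is exact, and the result is ``uint8``.
    """
    frame = _as_rgb(frame)
    reference = _as_rgb(reference)
    if frame.shape != reference.shape:
        raise GeometryError(
            f"frame geometry {frame.shape} does not match reference geometry {reference.shape}"
        )
    diff = np.abs(frame.astype(np.int16) - reference.astype(np.int16))
    return diff.astype(np.uint8)


def expand_to_byte(image: np.ndarray, per_channel: bool = False) -> np.ndarray:
    """Linearly stretch an image to the full [0, 255] range.

    A constant image maps to all zeros (a featureless difference image must
    yield zero detections).  By default a single min/max pair is used for the
    whole image; ``per_channel=True`` stretches each channel independently.
    """
    arr = np.asarray(image).astype(np.float64)
    out = np.zeros_like(arr)
    if per_channel and arr.ndim == 3:
        for c in range(arr.shape[2]):
            out[..., c] = _expand_plane(arr[..., c])
    else:
        out = _expand_plane(arr)
    return np.rint(out).astype(np.uint8)


def _expand_plane(arr: np.ndarray) -> np.ndarray:
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) * (255.0 / (hi - lo))


def sobel_gradient_magnitude(channel: np.ndarray) -> np.ndarray:
    """3x3 Sobel gradient magnitude sqrt(gx^2 + gy^2), borders edge-replicated."""
    chan = np.asarray(channel, dtype=np.float64)
    gx = ndi.sobel(chan, axis=1, mode="nearest")
    gy = ndi.sobel(chan, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def sobel_channel_edges(
    image: np.ndarray, params: PipelineParams = PipelineParams()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel Sobel edge masks for an RGB image.

    Each channel's gradient magnitude is thresholded to a boolean mask:
    Otsu's method per channel in ``auto`` mode, a user value in ``fixed``
    mode.  A gradient-free (constant) channel yields an all-false mask.
    """
    image = _as_rgb(image)
    masks = []
    for c in range(3):
        mag = sobel_gradient_magnitude(image[..., c])
        if params.sobel_threshold_mode == "fixed":
            thr = float(params.sobel_threshold)  # type: ignore[arg-type]
        else:
            if mag.max() == mag.min():
                masks.append(np.zeros(mag.shape, dtype=bool))
                continue
            thr = threshold_otsu(mag)
        masks.append(mag > thr)
    return masks[0], masks[1], masks[2]


def combine_masks(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Merge the three channel edge masks: a pixel is set iff any channel set it."""
    r, g, b = (np.asarray(m, dtype=bool) for m in (r, g, b))
    if not (r.shape == g.shape == b.shape):
        raise GeometryError(f"mask geometries differ: {r.shape}, {g.shape}, {b.shape}")
    return r | g | b


def fill_objects(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Fill holes: background regions not connected to the raster border.

    With 8-connected foreground the enclosed background is flooded with the
    complementary 4-connectivity, and vice versa.
    """
    mask = np.asarray(mask, dtype=bool)
    # duality: foreground connectivity 8 <=> background connectivity 4
    structure = ndi.generate_binary_structure(2, 1 if connectivity == 8 else 2)
    return ndi.binary_fill_holes(mask, structure=structure)


def filter_by_size(
    mask: np.ndarray, params: PipelineParams = PipelineParams()
) -> list[DetectedObject]:
    """Label connected components and keep those with min_area <= area <= max_area.

    Returned objects are sorted by bounding-box (row_min, col_min).
    """
    mask = np.asarray(mask, dtype=bool)
    labelled = cc_label(mask, connectivity=2 if params.connectivity == 8 else 1)
    kept = []
    for region in regionprops(labelled):
        if params.min_area <= region.area <= params.max_area:
            kept.append(
                DetectedObject(
                    label=int(region.label),
                    area=int(region.area),
                    bbox=tuple(int(v) for v in region.bbox),
                    centroid=tuple(float(v) for v in region.centroid),
                )
            )
    kept.sort(key=lambda o: (o.bbox[0], o.bbox[1]))
    return kept


def census_frame(
    frame: np.ndarray,
    reference: np.ndarray,
    params: PipelineParams = PipelineParams(),
    timestamp: Optional[object] = None,
) -> FrameCensus:
    """Run the full counting chain on one frame and return its census."""
    diff = subtract_reference(frame, reference)
    expanded = expand_to_byte(diff, per_channel=params.expand_per_channel)
    r, g, b = sobel_channel_edges(expanded, params)
    combined = combine_masks(r, g, b)
    filled = fill_objects(combined, connectivity=params.connectivity)
    objects = filter_by_size(filled, params)
    return FrameCensus(
        timestamp=timestamp,
        count=len(objects),
        cumulative_area=sum(o.area for o in objects),
        objects=tuple(objects),
    )


def census_sequence(
    frames: Sequence[tuple[Optional[object], np.ndarray]],
    reference: np.ndarray,
    params: PipelineParams = PipelineParams(),
) -> list[FrameCensus]:
    """Census an ordered sequence of (timestamp, frame) pairs.

    A frame that fails (bad geometry, undecodable content) yields a flagged
    entry with ``error`` set rather than aborting the run; order and
    timestamps are preserved.  An empty input yields an empty output.
    """
    out: list[FrameCensus] = []
    for ts, frame in frames:
        try:
            out.append(census_frame(frame, reference, params, timestamp=ts))
        except Exception as exc:  # noqa: BLE001 - per-frame isolation is the contract
            logger.warning("frame at %s failed: %s", ts, exc)
            out.append(FrameCensus(timestamp=ts, error=str(exc)))
    return out


def mask_to_byte(mask: np.ndarray) -> np.ndarray:
    """Serialise a boolean mask as a {0, 255} uint8 raster."""
    return np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
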