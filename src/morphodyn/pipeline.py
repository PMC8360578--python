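"""Mask normalization pipeline: orientation-aligned, area-normalized frames.

Raw binary cell masks (from microscopy or from thresholding simulated phase
fields) are converted into the canonical representation the shape classifier
consumes: (i) the migration direction is measured from the centroid
displacement over a configurable frame interval, (ii) the mask is rotated so
that direction points down the image (increasing row), and (iii) it is
rescaled so the foreground area equals that of a circle of 25 px diameter,
then embedded at the centre of a blank 64 x 64 frame.

Image convention: row-major arrays, "down" = increasing row index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform as sktransform

logger = logging.getLogger(__name__)

__all__ = [
    "FRAME_SIZE",
    "TARGET_DIAMETER_PX",
    "TARGET_AREA_PX",
    "MaskFrame",
    "MaskTimeSeries",
    "NormalizedMask",
    "EmptyMaskError",
    "UndefinedDirectionError",
    "ClippingError",
    "binarize_phase",
    "centroid",
    "migration_direction",
    "normalize_mask",
    "normalize_series",
    "read_mask_stack",
    "write_mask_stack",
]

FRAME_SIZE = 64
TARGET_DIAMETER_PX = 25.0
TARGET_AREA_PX = np.pi * (TARGET_DIAMETER_PX / 2.0) ** 2  # ~490.87 px^2
# displacement below this is treated as an undefined migration direction
MIN_DISPLACEMENT_PX = 0.25


class EmptyMaskError(ValueError):
    """A mask with no foreground cannot be processed."""


class UndefinedDirectionError(ValueError):
    """Centroid displacement too small to define a migration direction."""


class ClippingError(ValueError):
    """The rescaled mask does not fit in the 64 x 64 frame."""


@dataclass
class MaskFrame:
    """A single binary mask with optional physical pixel size and timestamp."""

    mask: np.ndarray
    pixel_size: float | None = None  # um / px
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class MaskTimeSeries:
    """Ordered mask frames at a uniform frame interval (seconds)."""

    frames: list[MaskFrame]
    frame_interval: float
    source: str = ""

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, idx: int) -> MaskFrame:
        return self.frames[idx]


@dataclass
class NormalizedMask:
    """64 x 64 canonical mask plus the transform that produced it."""

    mask: np.ndarray
    rotation_deg: float
    scale: float
    source_index: int | None = None

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def equivalent_diameter_px(self) -> float:
        return 2.0 * np.sqrt(self.mask.sum() / np.pi)


def binarize_phase(phi: np.ndarray, threshold: float = 0.5) -> MaskFrame:
    """Threshold a phase field at the 0.5 level set and keep the largest
    connected component; discarded fragment areas are logged."""
    phi = np.asarray(phi, dtype=float)
    if not np.isfinite(phi).all():
        raise ValueError("phase field contains non-finite values")
    mask = phi >= threshold
    if not mask.any():
        raise EmptyMaskError("thresholded phase field is empty")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        dropped = [int(s) for i, s in enumerate(sizes, start=1) if i != keep]
        logger.info("binarize_phase: kept %d px, dropped fragments %s px", int(sizes[keep - 1]), dropped)
        mask = labels == keep
    return MaskFrame(mask)


def centroid(frame: MaskFrame | np.ndarray) -> np.ndarray:
    """Arithmetic mean (row, col) of the foreground pixel coordinates."""
    mask = frame.mask if isinstance(frame, MaskFrame) else np.asarray(frame).astype(bool)
    if not mask.any():
        raise EmptyMaskError("cannot compute the centroid of an empty mask")
    coords = np.argwhere(mask)
    return coords.mean(axis=0)


def migration_direction(
    series: MaskTimeSeries, index: int, interval_frames: int = 5
) -> np.ndarray:
    """Unit vector (row, col) of centroid displacement over ``interval_frames``.

    Raises :class:`UndefinedDirectionError` when the displacement is below
    0.25 px; such frames are skipped by downstream feature statistics.
    """
    if index - interval_frames < 0:
        raise IndexError("not enough preceding frames for the direction interval")
    disp = centroid(series[index]) - centroid(series[index - interval_frames])
    norm = float(np.linalg.norm(disp))
    if norm < MIN_DISPLACEMENT_PX:
        raise UndefinedDirectionError(
            f"centroid displacement {norm:.3f} px is below {MIN_DISPLACEMENT_PX} px"
        )
    return disp / norm


def _recenter(float_mask: np.ndarray, size: int) -> np.ndarray:
    """Shift (sub-pixel) so the mass centroid sits at the frame centre."""
    total = float_mask.sum()
    if total <= 0:
        raise EmptyMaskError("mask vanished during normalization")
    idx = np.indices(float_mask.shape)
    c = np.array([(idx[0] * float_mask).sum(), (idx[1] * float_mask).sum()]) / total
    target = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    return ndimage.shift(float_mask, target - c, order=1, mode="constant", cval=0.0)


def _binarize_to_area(float_mask: np.ndarray, target_area: float) -> np.ndarray:
    """Binarize at the threshold (within [0.25, 0.75]) whose foreground area
    is closest to ``target_area``; interpolated edge values make the area
    response quasi-continuous, absorbing resampling bias."""
    vals = float_mask[(float_mask > 0.25) & (float_mask < 0.75)]
    candidates = [0.5] if len(vals) == 0 else np.unique(vals)
    base = (float_mask >= 0.75).sum()
    counts = base + np.arange(len(candidates), 0, -1) if len(vals) else None
    if counts is None:
        return float_mask >= 0.5
    # area when thresholding at candidate t = #(values >= t) among edge vals + base
    order = np.sort(vals)
    areas = base + len(order) - np.searchsorted(order, candidates, side="left")
    best = int(np.argmin(np.abs(areas - target_area)))
    return float_mask >= candidates[best]


def normalize_mask(frame: MaskFrame | np.ndarray, direction: np.ndarray) -> NormalizedMask:
    """Rotate, rescale and embed a mask into the canonical 64 x 64 frame.

    ``direction`` is a (row, col) unit vector; after normalization it maps to
    the downward image axis (+row).  Scaling (to foreground area
    pi * 12.5^2 px^2) is applied before rotation to minimize aliasing; all
    resampling is bilinear on the 0/1 mask followed by re-thresholding at 0.5.
    """
    mask = frame.mask if isinstance(frame, MaskFrame) else np.asarray(frame).astype(bool)
    if not mask.any():
        raise EmptyMaskError("cannot normalize an empty mask")
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0 or not np.isfinite(norm):
        raise UndefinedDirectionError("invalid migration direction")
    direction = direction / norm

    # angle (CCW, image convention) that brings `direction` onto (+row, 0);
    # skimage rotates CCW with the y axis pointing down for arrays.
    angle_deg = float(np.degrees(np.arctan2(direction[1], direction[0])))

    # tight crop with margin, then area rescale (iterate once or twice: the
    # bilinear resample + re-threshold shifts the area slightly)
    coords = np.argwhere(mask)
    lo, hi = coords.min(axis=0), coords.max(axis=0) + 1
    cropped = mask[lo[0] : hi[0], lo[1] : hi[1]].astype(float)
    pad = max(cropped.shape) // 2 + 2
    work = np.pad(cropped, pad)

    # the mask stays float through rescale -> rotate -> embed -> recenter and
    # is binarized once at the end, so resampling bias does not accumulate
    scale_total = float(np.sqrt(TARGET_AREA_PX / (work >= 0.5).sum()))
    work = sktransform.rescale(work, scale_total, order=1, anti_aliasing=scale_total < 1)

    rotated = sktransform.rotate(work, -angle_deg, resize=True, order=1)
    coords = np.argwhere(rotated >= 0.5)
    if len(coords) == 0:
        raise EmptyMaskError("mask vanished during normalization")
    extent = coords.max(axis=0) - coords.min(axis=0) + 1
    if extent.max() > FRAME_SIZE:
        raise ClippingError(
            f"rescaled mask extent {tuple(extent)} exceeds the {FRAME_SIZE} px frame"
        )

    # embed the region around the mass centroid in the 64 x 64 frame
    c = coords.mean(axis=0)
    r0 = int(round(c[0])) - FRAME_SIZE // 2
    c0 = int(round(c[1])) - FRAME_SIZE // 2
    src = np.zeros((FRAME_SIZE, FRAME_SIZE))
    rr_lo, rr_hi = max(0, r0), min(rotated.shape[0], r0 + FRAME_SIZE)
    cc_lo, cc_hi = max(0, c0), min(rotated.shape[1], c0 + FRAME_SIZE)
    src[rr_lo - r0 : rr_hi - r0, cc_lo - c0 : cc_hi - c0] = rotated[rr_lo:rr_hi, cc_lo:cc_hi]
    out = _recenter(src, FRAME_SIZE)
    final = _binarize_to_area(out, TARGET_AREA_PX)
    return NormalizedMask(final, rotation_deg=-angle_deg, scale=scale_total)


@dataclass
class NormalizationResult:
    """Per-series output: normalized frames plus a motion table."""

    normalized: list[NormalizedMask]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    skipped: list[int] = field(default_factory=list)


def normalize_series(
    series: MaskTimeSeries, interval_frames: int = 5
) -> NormalizationResult:
    """Normalize every frame of a series with a defined migration direction.

    Frames whose direction is undefined (sub-threshold displacement, or too
    early in the series) are skipped and recorded.
    """
    out: list[NormalizedMask] = []
    rows = []
    skipped: list[int] = []
    for idx in range(len(series)):
        if idx < interval_frames:
            skipped.append(idx)
            continue
        try:
            direction = migration_direction(series, idx, interval_frames)
            nm = normalize_mask(series[idx], direction)
        except (UndefinedDirectionError, EmptyMaskError, ClippingError) as err:
            logger.info("frame %d skipped: %s", idx, err)
            skipped.append(idx)
            continue
        nm.source_index = idx
        out.append(nm)
        cent = centroid(series[idx])
        rows.append(
            {
                "frame": idx,
                "centroid_row": cent[0],
                "centroid_col": cent[1],
                "dir_row": direction[0],
                "dir_col": direction[1],
                "rotation_deg": nm.rotation_deg,
                "scale": nm.scale,
                "area_px": nm.area_px,
            }
        )
    return NormalizationResult(out, pd.DataFrame(rows), skipped)


# -- I/O ----------------------------------------------------------------------


def read_mask_stack(path: str | Path, frame_interval: float = 1.0) -> MaskTimeSeries:
    """Read a PNG/TIFF mask stack (nonzero = foreground)."""
    import imageio.v3 as iio

    data = np.asarray(iio.imread(path))
    if data.ndim == 2:
        data = data[None]
    frames = [MaskFrame(frame != 0, timestamp=i * frame_interval) for i, frame in enumerate(data)]
    return MaskTimeSeries(frames, frame_interval, source=str(path))


def write_mask_stack(masks: list[np.ndarray] | list[NormalizedMask], path: str | Path) -> None:
    """Write masks as an 8-bit TIFF/PNG stack (255 = foreground)."""
    import imageio.v3 as iio

    arrays = [m.mask if isinstance(m, NormalizedMask) else np.asarray(m) for m in masks]
    stack = (np.stack(arrays).astype(np.uint8)) * 255
    iio.imwrite(path, stack)
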