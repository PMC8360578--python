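"""Boundary kymographs: curvature and protrusion speed along the cell edge.

Each frame's contour is resampled to a fixed number of boundary points and
registered to the previous frame by the cyclic offset that minimizes the
summed squared point displacement, so a boundary coordinate tracks the same
piece of membrane over time.  Protrusion speed is the outward normal
component of the registered point displacement divided by the frame
interval (positive = outward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contour import BoundaryContour, ContourError, contour_curvature, extract_contour

__all__ = ["Kymograph", "curvature_kymograph", "protrusion_speed_kymograph", "registered_contours"]


@dataclass
class Kymograph:
    """values[boundary coordinate, frame]; ``offsets`` records the cyclic
    registration shift applied to each frame, ``times`` the frame stamps."""

    values: np.ndarray
    times: np.ndarray
    offsets: np.ndarray
    kind: str = ""
    dropped_frames: list[int] = field(default_factory=list)

    @property
    def n_boundary(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _best_cyclic_offset(prev: np.ndarray, curr: np.ndarray) -> int:
    """Cyclic shift of ``curr`` minimizing sum |curr(i+s) - prev(i)|^2.

    Expanding the square, only the cross term depends on s; both dot-product
    sums over the cyclic shift are correlations computed via FFT.
    """
    n = len(prev)
    fa = np.fft.rfft(prev, axis=0, n=n)
    fb = np.fft.rfft(curr, axis=0, n=n)
    cross = np.fft.irfft((fa.conj() * fb).sum(axis=1), n=n)
    return int(np.argmax(cross.real))


def _extract_series(series, n_points: int, spacing: float, times) -> tuple[list[BoundaryContour], list[int], np.ndarray]:
    contours, kept, dropped = [], [], []
    for i, frame in enumerate(series):
        arr = frame.mask if hasattr(frame, "mask") else np.asarray(frame)
        t = float(times[i]) if times is not None else float(i)
        try:
            contours.append(extract_contour(arr.astype(float), n_points, spacing=spacing, frame_time=t))
            kept.append(i)
        except ContourError:
            dropped.append(i)
    if len(contours) < 2:
        raise ContourError("fewer than 2 frames yielded a valid contour")
    return contours, dropped, np.array([c.frame_time for c in contours])


def registered_contours(series, n_points: int = 128, spacing: float = 1.0, times=None):
    """Contours for every frame, cyclically aligned to the first frame."""
    contours, dropped, tt = _extract_series(series, n_points, spacing, times)
    offsets = [0]
    for k in range(1, len(contours)):
        shift = _best_cyclic_offset(contours[k - 1].points, contours[k].points)
        contours[k].points = np.roll(contours[k].points, -shift, axis=0)
        offsets.append(shift)
    return contours, np.asarray(offsets), dropped, tt


def curvature_kymograph(series, n_points: int = 128, spacing: float = 1.0, times=None) -> Kymograph:
    """Signed boundary curvature (1/length-unit) over boundary coordinate and time."""
    contours, offsets, dropped, tt = registered_contours(series, n_points, spacing, times)
    values = np.column_stack([contour_curvature(c) for c in contours])
    return Kymograph(values, tt, offsets, kind="curvature", dropped_frames=dropped)


def protrusion_speed_kymograph(series, n_points: int = 128, spacing: float = 1.0,
                               times=None, frame_interval: float | None = None) -> Kymograph:
    """Outward normal boundary velocity (length-unit/s), positive = protrusion.

    The displacement between consecutive registered contours is projected on
    the outward normal of the earlier contour; the first column repeats the
    first computable value so the kymograph has one column per frame.
    """
    contours, offsets, dropped, tt = registered_contours(series, n_points, spacing, times)
    if frame_interval is None:
        dt_frames = np.diff(tt)
        if (dt_frames <= 0).any():
            raise ValueError("frame times must be strictly increasing")
    cols = []
    for k in range(1, len(contours)):
        prev, curr = contours[k - 1], contours[k]
        pts = prev.points * spacing
        tangent = (np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0))
        tangent /= np.maximum(np.linalg.norm(tangent, axis=1, keepdims=True), 1e-12)
        # for a CCW contour in (x, y) = (c, -r), outward normal = tangent
        # rotated by -90 deg: n = (t_y, -t_x) in (x,y) -> (row, col) form below
        normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
        # orient outward: normal should point away from the centroid
        rel = pts - pts.mean(axis=0)
        sign = np.sign((normal * rel).sum(axis=1).mean())
        normal *= sign if sign != 0 else 1.0
        disp = (curr.points - prev.points) * spacing
        dt = frame_interval if frame_interval is not None else (tt[k] - tt[k - 1])
        cols.append((disp * normal).sum(axis=1) / dt)
    values = np.column_stack([cols[0]] + cols)
    return Kymograph(values, tt, offsets, kind="protrusion_speed", dropped_frames=dropped)
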