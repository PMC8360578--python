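"""Automated pseudopod event detection on protrusion-speed kymographs.

Protrusive events are connected regions of the (cyclic) boundary-coordinate
x time kymograph where the outward speed exceeds a threshold for a minimum
duration and boundary width.  Each event is classified by its relation to
pre-existing protrusive activity at onset:

    de novo       : the onset interval does not overlap any region active in
                    the preceding window;
    Y-split       : it overlaps an active parent region that remains active
                    after the onset (two coexisting fronts);
    one-way-split : it overlaps a parent that stops being active (the front
                    steers into the new direction).

The extension angle is the unsigned angle between the boundary-point
displacement over the 10 s following onset and the concurrent centroid
velocity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kymograph import Kymograph

logger = logging.getLogger(__name__)

__all__ = ["PseudopodEvent", "DetectionThresholds", "detect_pseudopod_events", "pseudopod_statistics"]

EXTENSION_DELAY_S = 10.0


@dataclass
class DetectionThresholds:
    """speed_percentile sets the activity threshold on the kymograph values;
    min_duration_frames and min_width_fraction (of the perimeter) filter
    small blobs; parent_window_frames is the look-back used to classify."""

    speed_percentile: float = 80.0
    min_duration_frames: int = 3
    min_width_fraction: float = 0.05
    parent_window_frames: int = 3
    parent_proximity_rows: int = 3


@dataclass
class PseudopodEvent:
    onset_time: float
    onset_frame: int
    boundary_location: float     # fractional boundary coordinate in [0, 1)
    boundary_index: int
    event_type: str              # "de_novo" | "y_split" | "one_way_split"
    extension_angle_deg: float | None = None
    region_id: int | None = None


def _cyclic_label(active: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components of a boundary (axis 0, cyclic) x time mask."""
    labels, n = ndimage.label(active)
    if n == 0:
        return labels, 0
    # merge components touching across the cyclic boundary coordinate
    top, bottom = labels[0, :], labels[-1, :]
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(top, bottom):
        if a > 0 and b > 0:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    remap = np.zeros(n + 1, dtype=labels.dtype)
    roots = sorted({find(i) for i in range(1, n + 1)})
    for new, root in enumerate(roots, 1):
        for i in range(1, n + 1):
            if find(i) == root:
                remap[i] = new
    return remap[labels], len(roots)


def detect_pseudopod_events(
    kymo: Kymograph, thresholds: DetectionThresholds | None = None
) -> list[PseudopodEvent]:
    """Detect and classify protrusive events on a speed kymograph."""
    th = thresholds or DetectionThresholds()
    if kymo.n_frames < 2:
        raise ValueError("kymograph needs at least 2 frames")
    values = kymo.values
    nb = kymo.n_boundary
    positive = values[values > 0]
    if positive.size == 0:
        return []
    cut = np.percentile(positive, th.speed_percentile)
    active = values >= cut
    labels, n = _cyclic_label(active)
    min_width = max(1, int(np.ceil(th.min_width_fraction * nb)))

    events: list[PseudopodEvent] = []
    for rid in range(1, n + 1):
        region = labels == rid
        frames = np.nonzero(region.any(axis=0))[0]
        duration = frames[-1] - frames[0] + 1
        width = int(region.any(axis=1).sum())
        if duration < th.min_duration_frames or width < min_width:
            continue
        onset_frame = int(frames[0])
        rows = np.nonzero(region[:, onset_frame])[0]
        # circular mean of the onset interval
        ang = 2 * np.pi * rows / nb
        loc = (np.arctan2(np.sin(ang).sum(), np.cos(ang).sum()) % (2 * np.pi)) / (2 * np.pi)
        onset_rows = set(rows.tolist())

        # classification against activity in the preceding window
        lo = max(0, onset_frame - th.parent_window_frames)
        event_type = "de_novo"
        if onset_frame > 0:
            prior = labels[:, lo:onset_frame]
            parent_ids = {int(p) for r in onset_rows for p in prior[r] if p > 0 and p != rid}
            # also treat activity adjacent to (within 2 rows of) the onset
            # interval as a potential parent
            if not parent_ids:
                grown = ndimage.binary_dilation(
                    region[:, onset_frame], iterations=th.parent_proximity_rows
                )
                parent_ids = {
                    int(p)
                    for r in np.nonzero(grown)[0]
                    for p in prior[r]
                    if p > 0 and p != rid
                }
            if parent_ids:
                after = labels[:, onset_frame + 1 : onset_frame + 1 + th.parent_window_frames]
                survives = any((after == p).any() for p in parent_ids)
                event_type = "y_split" if survives else "one_way_split"
        events.append(
            PseudopodEvent(
                onset_time=float(kymo.times[onset_frame]),
                onset_frame=onset_frame,
                boundary_location=float(loc),
                boundary_index=int(round(loc * nb)) % nb,
                event_type=event_type,
                region_id=rid,
            )
        )
    events.sort(key=lambda e: (e.onset_time, e.boundary_location))
    return events


def pseudopod_statistics(
    events: list[PseudopodEvent],
    contours: list[np.ndarray] | None,
    centroids: np.ndarray,
    times: np.ndarray,
    n_bins: int = 9,
) -> dict:
    """De novo fraction and extension-angle histogram.

    contours : registered contour point arrays per frame (or None to skip
        angles); centroids (n, 2) and times (n,) must align with the frames.
    The extension vector is the displacement of the event's boundary point
    over the 10 s after onset; the angle is measured against the centroid
    displacement over the same window.  Events too close to the series end
    are dropped from the histogram (logged).
    """
    if not events:
        return {"n_events": 0, "de_novo_fraction": np.nan, "fractions": {},
                "angles_deg": [], "histogram": None}
    types = [e.event_type for e in events]
    fractions = {t: types.count(t) / len(types) for t in ("de_novo", "y_split", "one_way_split")}
    angles: list[float] = []
    if contours is not None:
        times = np.asarray(times, dtype=float)
        for ev in events:
            target = ev.onset_time + EXTENSION_DELAY_S
            j = int(np.searchsorted(times, target))
            if j >= len(times):
                logger.info("event at t=%.1f too close to series end; angle dropped", ev.onset_time)
                continue
            p0 = contours[ev.onset_frame][ev.boundary_index]
            p1 = contours[j][ev.boundary_index]
            ext = np.asarray(p1) - np.asarray(p0)
            cen = centroids[j] - centroids[ev.onset_frame]
            if np.linalg.norm(ext) < 1e-9 or np.linalg.norm(cen) < 1e-9:
                continue
            cosang = np.clip(
                np.dot(ext, cen) / (np.linalg.norm(ext) * np.linalg.norm(cen)), -1.0, 1.0
            )
            angles.append(float(np.degrees(np.arccos(cosang))))
    hist, edges = np.histogram(angles, bins=n_bins, range=(0.0, 180.0))
    ev_angles = dict(zip([f"{edges[i]:.0f}-{edges[i+1]:.0f}" for i in range(n_bins)], hist.tolist()))
    return {
        "n_events": len(events),
        "de_novo_fraction": fractions["de_novo"],
        "fractions": fractions,
        "angles_deg": angles,
        "histogram": ev_angles,
    }
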