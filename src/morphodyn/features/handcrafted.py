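"""Hand-crafted morphology features on aligned (normalized) masks.

h1: elongation parallel to the front-tail axis (vertical extent over the
    equivalent-circle diameter),
h2: elongation orthogonal to it (horizontal extent over the same diameter),
h3: circularity 4 pi A / P^2 with P the perimeter of the traced contour
    (1 for a circle, decreasing with boundary complexity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from ..pipeline import EmptyMaskError, NormalizedMask

__all__ = ["HandcraftedFeatures", "handcrafted_features"]


@dataclass
class HandcraftedFeatures:
    h1: float  # parallel (vertical) elongation
    h2: float  # orthogonal (horizontal) elongation
    h3: float  # circularity

    def as_array(self) -> np.ndarray:
        return np.array([self.h1, self.h2, self.h3])


def handcrafted_features(mask: NormalizedMask | np.ndarray) -> HandcraftedFeatures:
    m = mask.mask if isinstance(mask, NormalizedMask) else np.asarray(mask).astype(bool)
    if not m.any():
        raise EmptyMaskError("cannot featurize an empty mask")
    area = float(m.sum())
    eq_diam = 2.0 * np.sqrt(area / np.pi)
    rows = np.nonzero(m.any(axis=1))[0]
    cols = np.nonzero(m.any(axis=0))[0]
    h1 = (rows[-1] - rows[0] + 1) / eq_diam
    h2 = (cols[-1] - cols[0] + 1) / eq_diam
    # perimeter from the smoothed traced contour: the raw marching-squares
    # polyline overestimates the length of pixelated boundaries by ~5-8%
    try:
        from ..analysis.contour import extract_contour

        c = extract_contour(m.astype(float), n_points=256, smooth_px=1.0)
        perimeter = c.perimeter
    except Exception:
        contours = measure.find_contours(m.astype(float), 0.5)
        perimeter = max(
            float(np.sqrt((np.diff(cc, axis=0) ** 2).sum(axis=1)).sum()) for cc in contours
        )
    h3 = min(1.0, 4.0 * np.pi * area / perimeter**2)
    return HandcraftedFeatures(h1=float(h1), h2=float(h2), h3=float(h3))
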