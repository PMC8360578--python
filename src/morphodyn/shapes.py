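"""Synthetic probe-shape library.

Well-defined geometric objects used to chart the feature space and as a
synthetic training fixture: 7 base objects (circle, isosceles triangle,
right triangle, rectangle, rhombus, pentagon, five-point star), vertical
flips of the four asymmetric ones (11 basic shapes), aspect-ratio variants
1:1 / 1:2 / 2:1 of each (33 shapes), ellipse aspect/rotation series, and
seeded multi-edge asymmetric forms.

Canonical vertex proportions are frozen here; only relative placement in the
feature space matters, so the exact proportions are a documented convention
(e.g. the star uses an inner/outer radius ratio of 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw as skdraw

from .pipeline import MaskFrame

__all__ = [
    "GeometryShape",
    "basic_shapes",
    "expanded_library",
    "ellipse_mask",
    "multi_edge_mask",
    "synthetic_classes",
    "ELLIPSE_ASPECTS",
]

# canvas on which shapes are rasterized before normalization
_CANVAS = 200
_RADIUS = 70.0

# x:y aspect ratios probed for ellipses and polygons
ELLIPSE_ASPECTS = [(1, 3), (2, 5), (1, 2), (2, 3), (1, 1), (3, 2), (2, 1), (5, 2), (3, 1)]


@dataclass
class GeometryShape:
    name: str
    category: str
    flipped: bool
    aspect: str  # "1:1", "1:2" (laterally elongated) or "2:1" (vertically)
    rotation_deg: float
    frame: MaskFrame


def _rasterize_polygon(vertices: np.ndarray) -> np.ndarray:
    """Vertices in (x, y) centred coordinates -> boolean canvas mask."""
    rows = _CANVAS / 2.0 - vertices[:, 1]  # y up -> row down
    cols = _CANVAS / 2.0 + vertices[:, 0]
    rr, cc = skdraw.polygon(rows, cols, shape=(_CANVAS, _CANVAS))
    mask = np.zeros((_CANVAS, _CANVAS), dtype=bool)
    mask[rr, cc] = True
    return mask


def _regular_polygon(n: int, phase_deg: float = 90.0) -> np.ndarray:
    ang = np.deg2rad(phase_deg) + 2.0 * np.pi * np.arange(n) / n
    return _RADIUS * np.column_stack([np.cos(ang), np.sin(ang)])


def _star(n_points: int = 5, inner_ratio: float = 0.5, phase_deg: float = 90.0) -> np.ndarray:
    ang = np.deg2rad(phase_deg) + np.pi * np.arange(2 * n_points) / n_points
    radii = np.where(np.arange(2 * n_points) % 2 == 0, _RADIUS, inner_ratio * _RADIUS)
    return np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])


def _base_vertices() -> dict[str, np.ndarray]:
    r = _RADIUS
    return {
        "isosceles_triangle": np.array([[0, r], [-0.6 * r, -r * 0.6], [0.6 * r, -r * 0.6]]),
        "right_triangle": np.array([[-0.6 * r, -0.6 * r], [0.9 * r, -0.6 * r], [-0.6 * r, r]]),
        "rectangle": np.array([[-0.5 * r, -0.8 * r], [0.5 * r, -0.8 * r], [0.5 * r, 0.8 * r], [-0.5 * r, 0.8 * r]]),
        "rhombus": np.array([[0, r], [0.55 * r, 0], [0, -r], [-0.55 * r, 0]]),
        "pentagon": _regular_polygon(5),
        "star": _star(),
    }


def _circle_mask() -> np.ndarray:
    rr, cc = skdraw.disk((_CANVAS / 2.0, _CANVAS / 2.0), _RADIUS, shape=(_CANVAS, _CANVAS))
    mask = np.zeros((_CANVAS, _CANVAS), dtype=bool)
    mask[rr, cc] = True
    return mask


# shapes whose vertical flip is a genuinely new object
_FLIPPABLE = ("isosceles_triangle", "right_triangle", "pentagon", "star")


def _apply_aspect(mask: np.ndarray, aspect: str) -> np.ndarray:
    """Stretch a canvas mask: '1:2' doubles x (lateral), '2:1' doubles y."""
    from skimage import transform as sktransform

    if aspect == "1:1":
        return mask
    sy, sx = (1.0, 2.0) if aspect == "1:2" else (2.0, 1.0)
    out = sktransform.rescale(mask.astype(float), (sy, sx), order=1)
    # crop/pad back around the centre to a square canvas
    side = max(out.shape)
    padded = np.zeros((side, side))
    r0 = (side - out.shape[0]) // 2
    c0 = (side - out.shape[1]) // 2
    padded[r0 : r0 + out.shape[0], c0 : c0 + out.shape[1]] = out
    return padded >= 0.5


def basic_shapes() -> list[GeometryShape]:
    """The 11 basic objects: 7 base shapes + 4 vertical flips, fixed order."""
    out: list[GeometryShape] = []
    out.append(GeometryShape("circle", "circle", False, "1:1", 0.0, MaskFrame(_circle_mask())))
    for name, verts in _base_vertices().items():
        out.append(GeometryShape(name, name, False, "1:1", 0.0, MaskFrame(_rasterize_polygon(verts))))
    for name in _FLIPPABLE:
        verts = _base_vertices()[name] * np.array([1.0, -1.0])
        out.append(
            GeometryShape(f"{name}_flipped", name, True, "1:1", 0.0, MaskFrame(_rasterize_polygon(verts)))
        )
    return out


def expanded_library() -> list[GeometryShape]:
    """33 shapes: each basic object at aspect 1:1, 1:2 and 2:1."""
    out: list[GeometryShape] = []
    for shape in basic_shapes():
        for aspect in ("1:1", "1:2", "2:1"):
            mask = _apply_aspect(shape.frame.mask, aspect)
            suffix = "" if aspect == "1:1" else f"_{aspect.replace(':', 'x')}"
            out.append(
                GeometryShape(shape.name + suffix, shape.category, shape.flipped, aspect, 0.0, MaskFrame(mask))
            )
    return out


def ellipse_mask(aspect: float | tuple[float, float], rotation_deg: float = 0.0) -> MaskFrame:
    """Filled ellipse with x:y aspect ratio, optionally rotated (CCW)."""
    if isinstance(aspect, tuple):
        ax, ay = aspect
    else:
        ax, ay = float(aspect), 1.0
    if ax <= 0 or ay <= 0:
        raise ValueError("aspect components must be positive")
    # equal-area semi-axes
    scale = _RADIUS / np.sqrt(ax * ay)
    a, b = ax * scale, ay * scale
    canvas = int(2.5 * max(a, b)) | 1
    rr, cc = skdraw.ellipse(
        canvas / 2.0, canvas / 2.0, b, a, shape=(canvas, canvas),
        rotation=np.deg2rad(rotation_deg),
    )
    mask = np.zeros((canvas, canvas), dtype=bool)
    mask[rr, cc] = True
    return MaskFrame(mask)


def multi_edge_mask(n_edges: int, asymmetry: float = 0.5, seed: int = 0) -> MaskFrame:
    """Star-like polygon with ``n_edges`` protrusions of seeded jitter.

    ``asymmetry`` in [0, 1] scales the random perturbation of protrusion
    lengths and angles; 0 reproduces the regular star.  Deterministic per
    seed.
    """
    if n_edges < 3:
        raise ValueError("n_edges must be >= 3")
    if not 0.0 <= asymmetry <= 1.0:
        raise ValueError("asymmetry must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ang = np.deg2rad(90.0) + np.pi * np.arange(2 * n_edges) / n_edges
    radii = np.where(np.arange(2 * n_edges) % 2 == 0, _RADIUS, 0.5 * _RADIUS)
    jitter_r = 1.0 + asymmetry * rng.uniform(-0.45, 0.45, size=2 * n_edges)
    jitter_a = asymmetry * rng.uniform(-0.35, 0.35, size=2 * n_edges) * np.pi / n_edges
    radii = radii * jitter_r
    ang = ang + jitter_a
    verts = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
    return MaskFrame(_rasterize_polygon(verts))


def synthetic_classes(
    n_per_class: int = 200, seed: int = 0, normalize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Three separable synthetic shape classes for classifier validation.

    'disk' (compact), 'vbar' (vertically elongated ~2:1 ellipse) and 'hbar'
    (laterally elongated ~1:2 ellipse), with seeded jitter in aspect and
    rotation; returns normalized 64x64 masks and their labels.
    """
    from .pipeline import normalize_mask

    rng = np.random.default_rng(seed)
    masks, labels = [], []
    specs = {
        "disk": (1.0, 0.08),
        "hbar": (2.2, 0.25),
        "vbar": (1 / 2.2, 0.05),
    }
    for label, (aspect, jitter) in specs.items():
        for _ in range(n_per_class):
            a = aspect * np.exp(rng.normal(0.0, jitter))
            rot = rng.normal(0.0, 4.0)
            frame = ellipse_mask((a, 1.0), rotation_deg=rot)
            if normalize:
                masks.append(normalize_mask(frame, np.array([1.0, 0.0])).mask)
            else:
                masks.append(frame.mask)
            labels.append(label)
    return np.stack(masks), np.asarray(labels)
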