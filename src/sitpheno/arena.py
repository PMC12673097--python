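"""Arena calibration and social-interaction-zone geometry.

The social interaction test runs in a square arena (42 x 42 cm by study
convention) imaged from above; all tracking is in image pixels (origin
top-left, y increasing downward).  Calibration maps pixels to physical
units via the mean arena edge length.  The point of interest (POI) is the
midpoint of the two cage corners that face the open arena, and the social
interaction zone (SIZ) is a convex region around the cage face — by
default the cage footprint expanded by an 8 cm corridor into the arena,
always overridable with an explicit pixel polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaSpec",
    "DegenerateGeometryError",
    "make_arena",
    "px_to_m",
    "in_zone",
    "DEFAULT_SIDE_CM",
    "DEFAULT_SIZ_CORRIDOR_CM",
]

#: Physical side length of the square arena (cm).
DEFAULT_SIDE_CM = 42.0

#: Default depth of the interaction corridor in front of the cage face (cm).
DEFAULT_SIZ_CORRIDOR_CM = 8.0


class DegenerateGeometryError(ValueError):
    """Arena corners are collinear or otherwise do not bound an area."""


@dataclass(frozen=True)
class ArenaSpec:
    """Calibration plus zone/POI geometry for one recording setup.

    Attributes
    ----------
    arena_corners_px : (4, 2) array
        Arena corner pixel coordinates, any cyclic order.
    side_cm : float
        Physical side length of the (square) arena.
    scale : float
        Pixels per centimetre, mean arena edge length / ``side_cm``.
    cage_corners_px : (2, 2) array
        The two cage corners adjacent to the open arena.
    siz_polygon_px : (k, 2) array
        Convex polygon bounding the social interaction zone, in pixels.
    poi_px : (2,) array
        Point of interest — the exact midpoint of ``cage_corners_px``.
    """

    arena_corners_px: np.ndarray
    side_cm: float
    scale: float
    cage_corners_px: np.ndarray
    siz_polygon_px: np.ndarray
    poi_px: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "arena_corners": self.arena_corners_px.tolist(),
            "side_cm": self.side_cm,
            "cage_corners": self.cage_corners_px.tolist(),
            "siz_polygon": self.siz_polygon_px.tolist(),
        }


def _order_convex(corners: np.ndarray) -> np.ndarray:
    """Order 4 points counter-clockwise (in image coords) around their mean."""
    c = corners.mean(axis=0)
    ang = np.arctan2(corners[:, 1] - c[1], corners[:, 0] - c[0])
    return corners[np.argsort(ang)]


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def make_arena(
    arena_corners_px,
    side_cm: float = DEFAULT_SIDE_CM,
    cage_corners_px=None,
    siz_spec=None,
) -> ArenaSpec:
    """Build an :class:`ArenaSpec` from raw pixel geometry.

    Parameters
    ----------
    arena_corners_px : sequence of 4 (x, y) pairs
        The arena's corners in image pixels; order is normalised internally.
    side_cm
        Physical side length; the pixel scale is the mean of the four edge
        lengths divided by this.
    cage_corners_px : sequence of 2 (x, y) pairs
        The two cage corners facing the open arena.  The POI is their exact
        midpoint (invariant under swapping the two).
    siz_spec
        Either an explicit polygon — sequence of >= 3 (x, y) pixel pairs —
        or ``{"corridor_width_cm": w}`` to expand the cage face by a
        ``w``-cm-deep corridor into the arena (default 8 cm), spanning the
        full cage face.

    Raises
    ------
    DegenerateGeometryError
        If the arena corners are collinear (zero area).
    ValueError
        If ``side_cm`` is not positive or inputs have the wrong shape.
    """
    corners = np.asarray(arena_corners_px, dtype=float)
    if corners.shape != (4, 2):
        raise ValueError(f"need 4 arena corners, got shape {corners.shape}")
    if side_cm <= 0:
        raise ValueError(f"side_cm must be positive, got {side_cm}")
    corners = _order_convex(corners)
    if _polygon_area(corners) <= 1e-9:
        raise DegenerateGeometryError("arena corners are collinear")
    edges = np.linalg.norm(np.roll(corners, -1, axis=0) - corners, axis=1)
    scale = float(edges.mean() / side_cm)

    if cage_corners_px is None:
        raise ValueError("cage_corners_px (the 2 arena-facing cage corners) is required")
    cage = np.asarray(cage_corners_px, dtype=float)
    if cage.shape != (2, 2):
        raise ValueError(f"need 2 cage corners, got shape {cage.shape}")
    poi = cage.mean(axis=0)

    if siz_spec is None:
        siz_spec = {"corridor_width_cm": DEFAULT_SIZ_CORRIDOR_CM}
    if isinstance(siz_spec, dict):
        width_px = float(siz_spec["corridor_width_cm"]) * scale
        face = cage[1] - cage[0]
        face_len = np.linalg.norm(face)
        if face_len == 0:
            raise DegenerateGeometryError("cage corners coincide")
        # inward normal: pick the direction pointing toward the arena centre
        n = np.array([-face[1], face[0]]) / face_len
        centre = corners.mean(axis=0)
        if np.dot(centre - poi, n) < 0:
            n = -n
        siz = np.array([cage[0], cage[1], cage[1] + n * width_px, cage[0] + n * width_px])
    else:
        siz = np.asarray(siz_spec, dtype=float)
        if siz.ndim != 2 or siz.shape[0] < 3 or siz.shape[1] != 2:
            raise ValueError("explicit SIZ polygon needs >= 3 (x, y) points")
        siz = _order_convex(siz) if siz.shape[0] == 4 else siz
    if _polygon_area(siz) <= 0:
        raise DegenerateGeometryError("SIZ polygon has zero area")

    return ArenaSpec(
        arena_corners_px=corners,
        side_cm=float(side_cm),
        scale=scale,
        cage_corners_px=cage,
        siz_polygon_px=siz,
        poi_px=poi,
    )


def px_to_m(spec: ArenaSpec, d_px) -> np.ndarray | float:
    """Convert pixel distances to metres (``d_px / scale / 100``)."""
    return np.asarray(d_px, dtype=float) / spec.scale / 100.0


def in_zone(point_px, zone: np.ndarray) -> np.ndarray | bool:
    """Membership test against a convex polygon; the boundary counts as inside.

    Works on a single (x, y) point or an (n, 2) array of points, returning a
    scalar bool or boolean array respectively.  Points exactly on an edge or
    vertex are inside.
    """
    pts = np.atleast_2d(np.asarray(point_px, dtype=float))
    poly = np.asarray(zone, dtype=float)
    nxt = np.roll(poly, -1, axis=0)
    edge = nxt - poly  # (k, 2)
    # cross product sign of each point against each directed edge
    rel = pts[:, None, :] - poly[None, :, :]  # (n, k, 2)
    cross = edge[None, :, 0] * rel[:, :, 1] - edge[None, :, 1] * rel[:, :, 0]
    eps = 1e-9 * max(1.0, float(np.abs(poly).max()))
    inside = np.all(cross >= -eps, axis=1) | np.all(cross <= eps, axis=1)
    if np.asarray(point_px).ndim == 1:
        return bool(inside[0])
    return inside
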