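"""Lymph-node morphometry from serial-section contour stacks.

A node is represented as an ordered stack of simple closed planar polygons
(one per B-mode slice, vertices in mm, common in-plane frame) with a uniform
elevational spacing.  Volume is the Cavalieri estimate (sum of slice areas
times spacing); length is the longest in-plane chord over all slices
(convex-hull diameter); width is the longest chord in that same slice whose
direction is perpendicular, within a small angular tolerance, to the length
chord.  A node is "round" when length/width < 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LinearRing

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "ContourStack",
    "LNMorphometry",
    "polygon_area",
    "volume_from_stack",
    "length_width",
    "volume_ratio",
    "measure_stack",
    "ROUNDNESS_CUTOFF",
]

#: length/width ratio below which a node is classified round (suspicious).
ROUNDNESS_CUTOFF = 2.0

#: default tolerance (degrees) around perpendicularity for the width chord.
DEFAULT_ANGLE_TOL_DEG = 5.0

#: boundary densification used before chord searches.
DEFAULT_DENSIFY_POINTS = 256


@dataclass
class ContourStack:
    """Ordered planar contours of one node plus the slice spacing.

    Parameters
    ----------
    slices
        List of (n_i, 2) float arrays, each a simple closed polygon
        (vertices in mm; the closing edge is implicit).
    spacing_mm
        Uniform distance between consecutive slices along the probe
        translation axis, in mm.
    node_id
        Identifier of the node the stack belongs to.
    """

    slices: list[np.ndarray]
    spacing_mm: float
    node_id: str = ""

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise InvalidInputError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        if len(self.slices) < 1:
            raise DegenerateGeometryError("contour stack needs at least one slice")
        self.slices = [np.asarray(s, dtype=float) for s in self.slices]
        for i, s in enumerate(self.slices):
            if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 3:
                raise DegenerateGeometryError(
                    f"slice {i} of node {self.node_id!r}: need >= 3 (x, y) vertices"
                )

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def validate_simple(self) -> None:
        """Raise if any slice polygon self-intersects."""
        for i, s in enumerate(self.slices):
            if not LinearRing(s).is_simple:
                raise DegenerateGeometryError(
                    f"slice {i} of node {self.node_id!r} is self-intersecting"
                )


@dataclass
class LNMorphometry:
    """Size and shape descriptors of one node."""

    node_id: str
    volume_mm3: float
    length_mm: float
    width_mm: float
    lw_ratio: float = field(init=False)
    is_round: bool = field(init=False)
    length_slice_index: int = 0

    def __post_init__(self) -> None:
        self.lw_ratio = float(self.length_mm / self.width_mm)
        self.is_round = bool(self.lw_ratio < ROUNDNESS_CUTOFF)


def polygon_area(polygon: np.ndarray) -> float:
    """Absolute shoelace area of a simple closed polygon (mm^2).

    Orientation-independent; the closing edge is implicit.
    """
    p = np.asarray(polygon, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise DegenerateGeometryError("polygon needs at least 3 (x, y) vertices")
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def volume_from_stack(stack: ContourStack) -> float:
    """Cavalieri volume estimate: spacing times the sum of slice areas."""
    return stack.spacing_mm * sum(polygon_area(s) for s in stack.slices)


def _densify(polygon: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polygon boundary at equal arc-length intervals."""
    ring = LinearRing(polygon)
    d = np.linspace(0.0, ring.length, n_points, endpoint=False)
    pts = shapely.line_interpolate_point(ring, d)
    return shapely.get_coordinates(pts)


def _hull_diameter(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum vertex-pair chord (length, unit direction) of a point set."""
    try:
        hull = ConvexHull(points)
        hv = points[hull.vertices]
    except QhullError:  # collinear boundary: fall back to all points
        hv = points
    diff = hv[:, None, :] - hv[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    length = dist[i, j]
    if length == 0.0:
        raise DegenerateGeometryError("all boundary points coincide")
    return length, (hv[j] - hv[i]) / length


def _perpendicular_breadth(points: np.ndarray, direction: np.ndarray) -> float:
    """Extent of a point set perpendicular to `direction` (caliper width)."""
    normal = np.array([-direction[1], direction[0]])
    proj = points @ normal
    return float(proj.max() - proj.min())


def _max_perpendicular_chord(
    points: np.ndarray, direction: np.ndarray, angle_tol_deg: float
) -> float:
    """Longest chord within angle_tol_deg of perpendicular to `direction`."""
    diff = points[:, None, :] - points[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(diff[..., 0] * direction[0] + diff[..., 1] * direction[1]) / dist
    # perpendicular within tol  <=>  |cos(angle)| <= sin(tol)
    ok = (dist > 0) & (cosang <= np.sin(np.radians(angle_tol_deg)) + 1e-12)
    if not ok.any():
        return 0.0
    return float(dist[ok].max())


def length_width(
    stack: ContourStack,
    angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
    densify_points: int = DEFAULT_DENSIFY_POINTS,
    width_method: str = "breadth",
) -> tuple[float, float, int]:
    """Node length, width and the slice index both were measured on.

    Length is the maximum in-plane chord over all slices (the convex-hull
    diameter of the densified boundary).  Width, measured in the same
    slice, is by default the caliper breadth perpendicular to the length
    chord (the extent between the two supporting lines parallel to it —
    how a perpendicular-diameter caliper is placed on an image).  With
    ``width_method='chord'`` it is instead the longest chord whose
    direction lies within ``angle_tol_deg`` of perpendicular to the length
    chord; the boundary is densified first because discrete polygons
    rarely contain an exactly perpendicular vertex chord.
    """
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for idx, poly in enumerate(stack.slices):
        try:
            pts = _densify(poly, densify_points)
            length, direction = _hull_diameter(pts)
        except DegenerateGeometryError:
            continue
        if best is None or length > best[0]:
            best = (length, direction, pts, idx)
    if best is None:
        raise DegenerateGeometryError(
            f"all slices of node {stack.node_id!r} are degenerate"
        )
    length, direction, pts, idx = best
    if width_method == "breadth":
        width = _perpendicular_breadth(pts, direction)
    elif width_method == "chord":
        width = _max_perpendicular_chord(pts, direction, angle_tol_deg)
    else:
        raise InvalidInputError(f"unknown width_method {width_method!r}")
    if width == 0.0:
        raise DegenerateGeometryError(
            f"no chord perpendicular to the length axis in node {stack.node_id!r}"
        )
    return length, width, idx


def volume_ratio(left_volume_mm3: float, right_volume_mm3: float) -> float:
    """Left/right volume quotient (tumor-draining over internal control)."""
    if left_volume_mm3 <= 0 or right_volume_mm3 <= 0:
        raise InvalidInputError(
            f"volumes must be positive, got {left_volume_mm3}, {right_volume_mm3}"
        )
    return left_volume_mm3 / right_volume_mm3


def measure_stack(
    stack: ContourStack,
    angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
    densify_points: int = DEFAULT_DENSIFY_POINTS,
    check_simple: bool = True,
) -> LNMorphometry:
    """Full morphometry of one contour stack."""
    if check_simple:
        stack.validate_simple()
    vol = volume_from_stack(stack)
    length, width, idx = length_width(stack, angle_tol_deg, densify_points)
    return LNMorphometry(
        node_id=stack.node_id,
        volume_mm3=vol,
        length_mm=length,
        width_mm=width,
        length_slice_index=idx,
    )
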