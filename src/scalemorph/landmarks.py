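"""Landmark + semilandmark configurations along a scale outline.

The default configuration is 5 fixed landmarks on the scale margin plus 80
semilandmarks: 40 along the (highly variable) anterior margin between
landmarks 1 and 2, and 10 along each of the four other inter-landmark
margins, every semilandmark equidistant in arc length along its margin.

Landmark anatomy (carried as metadata only; landmarks are inputs, never
detected): 1 = dorsal anterior tip, 2 = ventral anterior tip, 3 = ventral
posterior tip, 4 = middle of posterior margin, 5 = dorsal posterior tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .outline import OutlinePolygon

__all__ = [
    "LandmarkedShape",
    "DEFAULT_SEGMENT_PLAN",
    "snap_landmarks",
    "build_configuration",
]

DEFAULT_SEGMENT_PLAN = (40, 10, 10, 10, 10)
"""Semilandmarks per margin 1->2 (anterior), 2->3, 3->4, 4->5, 5->1."""

N_LANDMARKS = 5

LANDMARK_ANATOMY = {
    1: "dorsal anterior tip",
    2: "ventral anterior tip",
    3: "ventral posterior tip",
    4: "middle of posterior margin",
    5: "dorsal posterior tip",
}


@dataclass(frozen=True)
class LandmarkedShape:
    """Ordered point configuration of fixed landmarks and semilandmarks.

    ``roles[i]`` is ``"fixed"`` or ``"semi"``; ``segment_of[i]`` gives the
    margin (1..5, margin m running landmark m -> m+1 cyclically) for
    semilandmarks and 0 for fixed landmarks. Point order follows the outline:
    landmark 1, its trailing semilandmarks, landmark 2, and so on.
    """

    points: np.ndarray = field(repr=False)
    roles: tuple = ()
    segment_of: tuple = ()
    landmark_index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (k, 2)")
        if len(self.roles) != len(pts) or len(self.segment_of) != len(pts):
            raise ValueError("roles/segment_of must parallel points")
        object.__setattr__(self, "points", pts)
        self.points.setflags(write=False)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_fixed(self) -> int:
        return sum(r == "fixed" for r in self.roles)

    @property
    def is_semi(self) -> np.ndarray:
        return np.array([r == "semi" for r in self.roles])

    def with_points(self, points: np.ndarray) -> "LandmarkedShape":
        """Same structure, new coordinates (alignment steps use this)."""
        return LandmarkedShape(points=points, roles=self.roles,
                               segment_of=self.segment_of,
                               landmark_index=dict(self.landmark_index))

    @classmethod
    def from_matrix(cls, points: np.ndarray) -> "LandmarkedShape":
        """Wrap a bare point matrix, treating every point as fixed."""
        k = len(points)
        return cls(points=points, roles=("fixed",) * k, segment_of=(0,) * k,
                   landmark_index={})


def _nearest_on_polygon(poly: OutlinePolygon, point: np.ndarray) -> tuple[float, float]:
    """Arc position and distance of the closest point of ``poly`` to ``point``."""
    a = poly.vertices
    b = np.roll(a, -1, axis=0)
    ab = b - a
    ap = point - a
    denom = (ab**2).sum(axis=1)
    t = np.clip((ap * ab).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = ((proj - point) ** 2).sum(axis=1)
    best = int(np.argmin(d2))
    s = poly.arc_positions[best] + t[best] * np.sqrt(denom[best])
    return float(s % poly.perimeter), float(np.sqrt(d2[best]))


def snap_landmarks(poly: OutlinePolygon, raw_landmarks,
                   min_separation: float = 0.01):
    """Snap 5 digitized landmarks to their nearest points on the outline.

    Returns ``(positions, poly_out, reversed_flag)``: arc-length positions of
    landmarks 1..5 on ``poly_out``. If the labels run clockwise around the
    counterclockwise outline (digitizer y-axis mismatch), the traversal is
    re-oriented: arc positions are re-expressed along the reversed direction
    and ``reversed_flag`` is True; the geometry itself is unchanged.

    Raises if two landmarks snap closer than ``min_separation`` of the
    perimeter (implausible digitization), or if the labels are in no cyclic
    order at all.
    """
    raw = np.asarray(raw_landmarks, dtype=float)
    if raw.shape != (N_LANDMARKS, 2):
        raise ValueError(f"expected {N_LANDMARKS} landmarks, got shape {raw.shape}")
    per = poly.perimeter
    snapped = [_nearest_on_polygon(poly, p) for p in raw]
    positions = np.array([s for s, _ in snapped])

    gaps = np.abs(positions[:, None] - positions[None, :])
    gaps = np.minimum(gaps, per - gaps)
    iu = np.triu_indices(N_LANDMARKS, k=1)
    if (gaps[iu] < min_separation * per).any():
        i, j = np.argwhere((gaps < min_separation * per) & np.triu(np.ones_like(gaps, bool), 1))[0]
        raise ValueError(
            f"landmarks {i + 1} and {j + 1} snap within {min_separation:.0%} of the "
            "perimeter of each other: implausible digitization"
        )

    if _is_cyclic_increasing(positions, per):
        return positions, poly, False
    rev_positions = (per - positions) % per
    if _is_cyclic_increasing(rev_positions, per):
        # labels run clockwise: re-orient traversal (mirror the arc coordinate)
        return rev_positions, _reversed_traversal(poly), True
    order = list(np.argsort(positions) + 1)
    raise ValueError(f"landmarks are not in cyclic order along the outline: {order}")


def _is_cyclic_increasing(positions: np.ndarray, perimeter: float) -> bool:
    diffs = np.diff(np.concatenate((positions, positions[:1]))) % perimeter
    return np.isclose(diffs.sum(), perimeter) and (diffs > 0).all()


def _reversed_traversal(poly: OutlinePolygon) -> OutlinePolygon:
    """Polygon with the opposite traversal direction, arc origin preserved.

    Arc position s on the original corresponds to (perimeter - s) here.
    Constructed by reversing the vertex chain while keeping vertex 0 first;
    the constructor restores counterclockwise storage, so only the arc
    parameterization used by callers changes.
    """
    v = poly.vertices
    return _RawTraversal(np.vstack((v[:1], v[1:][::-1])))


class _RawTraversal(OutlinePolygon):
    """Outline wrapper that preserves a clockwise vertex chain as given.

    Used only for re-oriented landmark traversal: downstream configuration
    building needs arc positions measured along the reversed direction, which
    the counterclockwise-normalizing constructor would undo.
    """

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        keep = np.linalg.norm(v - np.roll(v, 1, axis=0), axis=1) > 1e-12
        v = v[keep]
        if len(v) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        object.__setattr__(self, "vertices", v)
        self.vertices.setflags(write=False)


def build_configuration(poly: OutlinePolygon, lm_positions,
                        counts=DEFAULT_SEGMENT_PLAN) -> LandmarkedShape:
    """Place semilandmarks at equal arc spacing along each inter-landmark margin.

    ``counts[m]`` semilandmarks go strictly between landmark m+1 and the next
    landmark, at spacing (margin arc length)/(count+1). Output order is
    landmark 1, its margin's semilandmarks, landmark 2, ... around the
    outline; total points = 5 + sum(counts).
    """
    positions = np.asarray(lm_positions, dtype=float)
    if positions.shape != (N_LANDMARKS,):
        raise ValueError(f"expected {N_LANDMARKS} arc positions")
    counts = tuple(int(c) for c in counts)
    if len(counts) != N_LANDMARKS or any(c < 0 for c in counts):
        raise ValueError("counts must be 5 non-negative integers (margins 1-2,...,5-1)")
    per = poly.perimeter
    if not _is_cyclic_increasing(positions, per):
        raise ValueError("landmark positions must be in cyclic order; snap first")

    pts, roles, segs = [], [], []
    landmark_index = {}
    for m in range(N_LANDMARKS):
        s0 = positions[m]
        s1 = positions[(m + 1) % N_LANDMARKS]
        length = (s1 - s0) % per
        if length <= 0:
            raise ValueError(f"margin {m + 1} has zero arc length")
        landmark_index[m + 1] = len(pts)
        pts.append(poly.point_at(s0))
        roles.append("fixed")
        segs.append(0)
        step = length / (counts[m] + 1)
        for k in range(1, counts[m] + 1):
            pts.append(poly.point_at(s0 + k * step))
            roles.append("semi")
            segs.append(m + 1)
    return LandmarkedShape(points=np.asarray(pts), roles=tuple(roles),
                           segment_of=tuple(segs), landmark_index=landmark_index)
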