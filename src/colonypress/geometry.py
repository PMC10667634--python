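"""Capsule (spherocylinder) geometry for rod-shaped cells.

A cell body is a 2D capsule: a line segment of half-length ``half_length``
swept by a disc of ``radius``.  Total body length is
``2 * half_length + 2 * radius``.  All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi

_EPS = 1e-12


@dataclass
class CellBody:
    """Rigid capsule in a 2D plane.

    Parameters
    ----------
    centroid : (2,) array-like
        Position of the body centre (um).  In vertical-section mode the
        second coordinate is height above the substrate.
    angle : float
        Orientation of the long axis, radians, normalised to [0, 2*pi).
    half_length : float
        Half of the axis segment length (um), >= 0.  Zero gives a disc.
    radius : float
        Capsule radius (um), > 0.
    """

    centroid: np.ndarray
    angle: float
    half_length: float
    radius: float

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.shape != (2,):
            raise ValueError("centroid must be a 2-vector")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.half_length < 0:
            raise ValueError("half_length must be >= 0")
        self.angle = float(self.angle) % TWO_PI

    @property
    def length(self) -> float:
        """Total body length: axis plus both hemispherical caps."""
        return 2.0 * self.half_length + 2.0 * self.radius

    @property
    def direction(self) -> np.ndarray:
        return np.array([np.cos(self.angle), np.sin(self.angle)])

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis segment endpoints (not including the caps)."""
        d = self.direction * self.half_length
        return self.centroid - d, self.centroid + d

    def lowest_point(self) -> float:
        """Smallest second coordinate reached by the capsule outline."""
        drop = self.half_length * abs(np.sin(self.angle)) + self.radius
        return float(self.centroid[1]) - drop

    def copy(self) -> "CellBody":
        return CellBody(self.centroid.copy(), self.angle, self.half_length, self.radius)


def segment_closest_points(p1, q1, p2, q2):
    """Closest points between segments [p1,q1] and [p2,q2] (vectorised).

    Implements the standard clamped closest-point-between-segments
    algorithm.  Degenerate (point-like) segments are handled.  Inputs may
    be single points (shape ``(2,)``) or stacked arrays (``(n, 2)``).

    Returns ``(dist, c1, c2)``: the minimum distance and one achieving
    point on each segment.
    """
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    q1 = np.atleast_2d(np.asarray(q1, dtype=float))
    p2 = np.atleast_2d(np.asarray(p2, dtype=float))
    q2 = np.atleast_2d(np.asarray(q2, dtype=float))

    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)

    a_deg = a <= _EPS
    e_deg = e <= _EPS

    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > _EPS, (b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0.0)
        s = np.clip(s, 0.0, 1.0)
        t = np.where(e_deg, 0.0, (b * s + f) / np.where(e_deg, 1.0, e))

        # Re-clamp s when t left [0, 1].
        t_low = t < 0.0
        t_high = t > 1.0
        s = np.where(t_low, np.clip(-c / np.where(a_deg, 1.0, a), 0.0, 1.0), s)
        s = np.where(t_high, np.clip((b - c) / np.where(a_deg, 1.0, a), 0.0, 1.0), s)
        t = np.clip(t, 0.0, 1.0)

        # Degenerate second segment: t = 0, project p2 on segment 1.
        s = np.where(e_deg & ~a_deg,
                     np.clip(-c / np.where(a_deg, 1.0, a), 0.0, 1.0), s)
        # Degenerate first segment: s = 0, project p1 on segment 2.
        s = np.where(a_deg, 0.0, s)
        t = np.where(a_deg & ~e_deg, np.clip(f / np.where(e_deg, 1.0, e), 0.0, 1.0), t)
        t = np.where(a_deg & e_deg, 0.0, t)

    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2
    dist = np.linalg.norm(c1 - c2, axis=1)
    return dist, c1, c2


def segment_distance(p1, q1, p2, q2):
    """Minimum distance between two segments plus one achieving point pair.

    Scalar convenience wrapper around :func:`segment_closest_points`; the
    result is symmetric under exchanging the two segments.
    """
    dist, c1, c2 = segment_closest_points(p1, q1, p2, q2)
    return float(dist[0]), c1[0], c2[0]


def elongate_axis(centroid, angle, half_length, pole, amount):
    """Grow the axis by ``amount`` at one pole, keeping the far pole fixed.

    ``pole`` is +1 or -1 (the sign of the growing axis endpoint along the
    orientation vector).  The axis gains ``amount`` in total length, so the
    half-length grows by ``amount / 2`` and the centroid shifts by
    ``amount / 2`` toward the growing pole, leaving the opposite axis
    endpoint (and cap tip) exactly in place.
    """
    u = np.array([np.cos(angle), np.sin(angle)])
    new_half = half_length + amount / 2.0
    new_centroid = np.asarray(centroid, dtype=float) + pole * u * (amount / 2.0)
    return new_centroid, new_half


def split_axis(centroid, angle, half_length):
    """Split an axis at its midpoint into two half axes.

    Returns ``((centroid_a, half_a), (centroid_b, half_b))`` with daughter
    a on the -pole side.  The daughters' segment lengths sum exactly to the
    parent's segment length.
    """
    u = np.array([np.cos(angle), np.sin(angle)])
    c = np.asarray(centroid, dtype=float)
    h = half_length / 2.0
    return (c - u * h, h), (c + u * h, h)
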