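"""Discrete z-layer bookkeeping for top-down colonies.

Cells live on integer layers (1 = substrate).  Only same-layer cells
collide; a promoted cell passes freely over its former neighbours (cells
share the same xy-space at different z-levels).  A cell is promoted one
layer up when pressure on it stays above a threshold for a persistence
time while the solver fails to move it sideways — the cell has no
collision-free space left in its plane — and it has at least one
overlapping same-layer cell to climb onto.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .state import MODE_TOP_DOWN, MODE_VERTICAL, ColonyState, top_envelope, top_layer_at_points


@dataclass
class PromotionRule:
    """When does an over-pressured cell leave its plane?

    ``promote_threshold`` (um of mean residual penetration), persistence
    ``tau`` (consecutive steps the signal must stay above threshold) and
    ``displacement_epsilon`` (um; the net sideways displacement the solver
    achieved over those steps must stay below it).
    """

    promote_threshold: float = 0.06
    persistence: int = 25
    displacement_epsilon: float = 0.2

    def validate(self) -> None:
        problems = []
        if self.promote_threshold <= 0:
            problems.append("promote_threshold must be > 0")
        if self.persistence < 1:
            problems.append("persistence must be >= 1")
        if self.displacement_epsilon <= 0:
            problems.append("displacement_epsilon must be > 0")
        if problems:
            raise ValueError("; ".join(problems))


def pair_filter(cell_a, cell_b, mode: str = MODE_TOP_DOWN) -> bool:
    """Collision eligibility of a cell pair.

    Top-down: cells collide iff they occupy the same layer.  In
    vertical-section mode there is a single physical plane, so every pair
    is eligible.
    """
    if mode == MODE_VERTICAL:
        return True
    return cell_a.layer == cell_b.layer


def select_promotions(signals, over_count, net_displacement, contact_counts,
                      rule: PromotionRule):
    """Indices of cells to promote this step, in processing order.

    A cell qualifies when (a) its pressure signal exceeded the threshold
    for ``persistence`` consecutive steps, (b) the solver-achieved net
    lateral displacement over those steps is below ``displacement_epsilon``
    (nowhere left to slide), and (c) it currently overlaps at least one
    same-layer cell (support to climb onto).  Candidates are ordered by
    descending pressure, ties by index, and each cell is promoted at most
    one layer per step.
    """
    signals = np.asarray(signals, dtype=float)
    eligible = (
        (np.asarray(over_count) >= rule.persistence)
        & (np.asarray(net_displacement) < rule.displacement_epsilon)
        & (np.asarray(contact_counts) >= 1)
    )
    idx = np.nonzero(eligible)[0]
    if idx.size == 0:
        return idx
    order = np.lexsort((idx, -signals[idx]))
    return idx[order]


def height_map(state: ColonyState, grid_spacing: float = 0.5):
    """Gridded colony height field (um).

    Top-down mode: height at a grid point is (max layer among covering
    cells) x cell diameter.  Vertical-section mode: the top envelope of
    the capsule outlines along the substrate axis (a 1 x k grid).
    Returns ``(xs, ys, H)`` with ``H`` of shape ``(len(ys), len(xs))``;
    heights are 0 outside the colony footprint.
    """
    if state.n == 0:
        xs = np.array([0.0])
        ys = np.array([0.0])
        return xs, ys, np.zeros((1, 1))
    reach = state.half_length + state.radius
    lo = (state.pos - reach[:, None]).min(axis=0)
    hi = (state.pos + reach[:, None]).max(axis=0)
    xs = np.arange(lo[0], hi[0] + grid_spacing, grid_spacing)
    if state.mode == MODE_VERTICAL:
        ys = np.array([0.0])
        return xs, ys, top_envelope(state, xs)[None, :]
    ys = np.arange(lo[1], hi[1] + grid_spacing, grid_spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    layers = top_layer_at_points(state, pts).reshape(gy.shape)
    return xs, ys, layers * state.diameter


def outer_ring_layers(state: ColonyState, ring_fraction: float = 0.15) -> int:
    """Maximum layer index within the colony's outer annulus.

    The annulus holds every cell whose centroid lies farther than
    ``(1 - ring_fraction) * colony_radius`` from the colony centroid.  A
    value of 1 means the periphery is a monolayer.  Degenerate colonies
    (fewer than 10 cells) report 1 with a warning.
    """
    if state.n < 10:
        warnings.warn("outer_ring_layers on a degenerate colony (< 10 cells)")
        return 1
    dist = np.linalg.norm(state.pos - state.centroid, axis=1)
    cutoff = (1.0 - ring_fraction) * state.colony_radius
    ring = dist > cutoff
    if not ring.any():
        warnings.warn("outer annulus is empty; reporting 1")
        return 1
    return int(state.layer[ring].max())
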