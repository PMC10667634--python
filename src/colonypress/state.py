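"""Immutable colony snapshots shared by the engine, metrics and I/O.

A :class:`ColonyState` is a struct-of-arrays view of every cell at one
time point.  In top-down mode positions are substrate-plane (x, y)
coordinates and the integer ``layer`` carries the discrete z-level; in
vertical-section mode positions are (x, z) in a single vertical plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cells import Cell
from .geometry import CellBody

MODE_TOP_DOWN = "top_down"
MODE_VERTICAL = "vertical_section"


@dataclass
class ColonyState:
    step: int
    ids: np.ndarray
    pos: np.ndarray       # (n, 2)
    angle: np.ndarray
    half_length: np.ndarray
    radius: np.ndarray
    layer: np.ndarray
    generation: np.ndarray
    birth_step: np.ndarray
    pressure: np.ndarray  # current pressure signal per cell (um)
    mode: str = MODE_TOP_DOWN
    ancestry: np.ndarray | None = None  # founder index (two-colony runs)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def lengths(self) -> np.ndarray:
        return 2.0 * self.half_length + 2.0 * self.radius

    @property
    def diameter(self) -> float:
        """Cell diameter (um); the unit of discrete layer height."""
        return float(2.0 * self.radius.max()) if self.n else 1.0

    @property
    def ages(self) -> np.ndarray:
        """Current interdivision age of every cell, in steps."""
        return self.step - self.birth_step

    @property
    def centroid(self) -> np.ndarray:
        return self.pos.mean(axis=0)

    @property
    def colony_radius(self) -> float:
        """Largest centroid distance from the colony centroid."""
        if self.n == 0:
            return 0.0
        return float(np.linalg.norm(self.pos - self.centroid, axis=1).max())

    def bodies(self) -> list[CellBody]:
        return [
            CellBody(self.pos[i].copy(), float(self.angle[i]),
                     float(self.half_length[i]), float(self.radius[i]))
            for i in range(self.n)
        ]

    def to_cells(self) -> list[Cell]:
        cells = []
        for i in range(self.n):
            cells.append(Cell(
                id=int(self.ids[i]),
                body=CellBody(self.pos[i].copy(), float(self.angle[i]),
                              float(self.half_length[i]), float(self.radius[i])),
                layer=int(self.layer[i]),
                generation=int(self.generation[i]),
                birth_time=int(self.birth_step[i]),
                pressure_window=[float(self.pressure[i])],
            ))
        return cells

    @classmethod
    def from_cells(cls, cells, step=0, mode=MODE_TOP_DOWN, ancestry=None):
        n = len(cells)
        pos = np.zeros((n, 2))
        angle = np.zeros(n)
        hl = np.zeros(n)
        rad = np.full(n, 0.5)
        layer = np.ones(n, np.int64)
        gen = np.zeros(n, np.int64)
        birth = np.zeros(n, np.int64)
        pressure = np.zeros(n)
        ids = np.zeros(n, np.int64)
        for i, c in enumerate(cells):
            ids[i] = c.id
            pos[i] = c.body.centroid
            angle[i] = c.body.angle
            hl[i] = c.body.half_length
            rad[i] = c.body.radius
            layer[i] = c.layer
            gen[i] = c.generation
            birth[i] = c.birth_time
            pressure[i] = np.mean(c.pressure_window) if c.pressure_window else 0.0
        return cls(step=step, ids=ids, pos=pos, angle=angle, half_length=hl,
                   radius=rad, layer=layer, generation=gen, birth_step=birth,
                   pressure=pressure, mode=mode,
                   ancestry=None if ancestry is None else np.asarray(ancestry))


def top_layer_at_points(state: ColonyState, points: np.ndarray) -> np.ndarray:
    """Highest layer index of any cell footprint covering each point.

    A point is covered by a cell when its distance to the cell's axis
    segment is at most the capsule radius.  Returns 0 for uncovered
    points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    best = np.zeros(len(pts), dtype=np.int64)
    for i in range(state.n):
        u = np.array([np.cos(state.angle[i]), np.sin(state.angle[i])])
        e1 = state.pos[i] - u * state.half_length[i]
        d = 2.0 * u * state.half_length[i]
        dd = float(d @ d)
        w = pts - e1
        t = np.clip((w @ d) / dd, 0.0, 1.0) if dd > 0 else np.zeros(len(pts))
        dist = np.linalg.norm(w - t[:, None] * d, axis=1)
        covered = dist <= state.radius[i]
        if covered.any():
            best[covered] = np.maximum(best[covered], state.layer[i])
    return best


def top_envelope(state: ColonyState, xs: np.ndarray,
                 sample_ds: float = 0.1) -> np.ndarray:
    """Top envelope of the capsule outlines over horizontal positions.

    Vertical-section mode only: each capsule is the union of discs along
    its axis; the envelope at x is the highest outline point of any disc
    whose x-extent covers it.  Returns 0 where no cell is overhead.
    """
    xs = np.asarray(xs, dtype=float)
    heights = np.zeros_like(xs)
    if len(xs) < 2:
        dx = sample_ds
    else:
        dx = xs[1] - xs[0]
    for i in range(state.n):
        hl = state.half_length[i]
        r = state.radius[i]
        u = np.array([np.cos(state.angle[i]), np.sin(state.angle[i])])
        k = max(2, int(np.ceil(2.0 * hl / min(sample_ds, max(dx, 1e-6)))) + 1)
        s = np.linspace(-hl, hl, k)
        centres = state.pos[i] + s[:, None] * u
        lo = np.searchsorted(xs, centres[:, 0].min() - r)
        hi = np.searchsorted(xs, centres[:, 0].max() + r)
        if lo >= hi:
            continue
        dxs = xs[lo:hi][None, :] - centres[:, 0][:, None]
        inside = np.abs(dxs) <= r
        top = np.where(
            inside,
            centres[:, 1][:, None] + np.sqrt(np.maximum(r * r - dxs * dxs, 0.0)),
            -np.inf,
        ).max(axis=0)
        seg = heights[lo:hi]
        heights[lo:hi] = np.maximum(seg, np.where(np.isfinite(top), top, 0.0))
    return np.maximum(heights, 0.0)
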