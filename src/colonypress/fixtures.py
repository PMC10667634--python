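"""Deterministic synthetic states used by tests, examples and the CLI.

Each fixture is constructed from closed-form geometry — no simulation —
so metrics and solver behaviour can be checked against known answers.
"""

from __future__ import annotations

import numpy as np

from .cells import Cell, GrowthConfig
from .geometry import CellBody
from .metrics import SectionProfile
from .state import MODE_TOP_DOWN, ColonyState

FIXTURE_KINDS = ("single_cell", "two_colony", "staircase", "ramp", "packed_cluster")


def _state_from_specs(specs, mode=MODE_TOP_DOWN):
    cells = []
    for i, (x, y, angle, hl, r, layer) in enumerate(specs):
        cells.append(Cell(id=i, body=CellBody(np.array([x, y]), angle, hl, r),
                          layer=layer))
    return ColonyState.from_cells(cells, step=0, mode=mode)


def single_cell(config: GrowthConfig | None = None) -> ColonyState:
    """One founder cell at the origin, angle 0."""
    g = config or GrowthConfig()
    hl = (g.birth_length - 2.0 * g.radius) / 2.0
    return _state_from_specs([(0.0, 0.0, 0.0, hl, g.radius, 1)])


def two_colony(d: float = 36.0, config: GrowthConfig | None = None) -> ColonyState:
    """Two founder cells separated by ``d`` um along x."""
    g = config or GrowthConfig()
    hl = (g.birth_length - 2.0 * g.radius) / 2.0
    return _state_from_specs([
        (-d / 2.0, 0.0, 0.0, hl, g.radius, 1),
        (d / 2.0, 0.0, 0.0, hl, g.radius, 1),
    ])


def staircase(k_layers: int = 3, band_width: float = 6.0,
              radius: float = 0.5) -> ColonyState:
    """Concentric-band colony whose section is an exact layer staircase.

    Horizontal cells tile the x-axis; the layer index climbs from 1 at the
    periphery to ``k_layers`` at the centre in bands of ``band_width`` um,
    so a section through the centroid shows plateaus at exactly 1, 2, ...,
    k cell diameters.
    """
    if k_layers < 1:
        raise ValueError("k_layers must be >= 1")
    hl = 0.75
    spacing = 2.0 * hl + 2.0 * radius  # cells touch end to end
    half_extent = k_layers * band_width
    specs = []
    x = -half_extent
    while x <= half_extent + 1e-9:
        band = min(int(abs(x) // band_width), k_layers - 1)
        layer = k_layers - band
        specs.append((x, 0.0, 0.0, hl, radius, layer))
        x += spacing
    return _state_from_specs(specs)


def ramp(n_bins: int = 40, slope_diameters: float = 0.1,
         diameter: float = 1.0) -> SectionProfile:
    """Section profile climbing ``slope_diameters`` per bin — no discrete jumps."""
    positions = np.arange(n_bins, dtype=float)
    heights = diameter * (1.0 + slope_diameters * np.arange(n_bins))
    return SectionProfile(positions=positions, heights=heights,
                          reference=diameter, diameter=diameter,
                          mode=MODE_TOP_DOWN)


def packed_cluster(n: int = 19, radius: float = 0.5,
                   compression: float = 0.05) -> list[CellBody]:
    """Hexagonally close-packed disc cluster with uniform compression.

    ``n`` must be a centred hexagonal number (1, 7, 19, 37, ...).  Discs
    (zero half-length capsules) sit on a hex lattice with spacing
    ``2 * radius * (1 - compression)``, so every neighbour pair overlaps
    by the same amount; the centre disc has the most contacts and, under a
    budgeted solve, retains the largest residual.
    """
    rings = 0
    total = 1
    while total < n:
        rings += 1
        total += 6 * rings
    if total != n:
        raise ValueError("n must be a centred hexagonal number (1, 7, 19, ...)")
    s = 2.0 * radius * (1.0 - compression)
    a1 = np.array([s, 0.0])
    a2 = np.array([s / 2.0, s * np.sqrt(3.0) / 2.0])
    bodies = []
    for i in range(-rings, rings + 1):
        for j in range(-rings, rings + 1):
            if max(abs(i), abs(j), abs(i + j)) <= rings:
                centre = i * a1 + j * a2
                bodies.append(CellBody(centre, 0.0, 0.0, radius))
    return bodies


def make_fixture(kind: str, **params):
    """Dispatch on fixture ``kind``; see the individual constructors."""
    factories = {
        "single_cell": single_cell,
        "two_colony": two_colony,
        "staircase": staircase,
        "ramp": ramp,
        "packed_cluster": packed_cluster,
    }
    try:
        factory = factories[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; available: {FIXTURE_KINDS}"
        ) from None
    return factory(**params)
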