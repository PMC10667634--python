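"""Single-cell growth, division and pressure bookkeeping.

Cells elongate asynchronously from both poles at exponentially distributed
random times.  Elongation is *pressure-dependent*: the mechanical pressure
on a cell (mean residual penetration left by the collision solver over a
short window) scales each elongation increment down towards a floor
``f_min`` — growth is delayed but never cancelled.  The withheld length is
banked and paid back once the pressure relaxes.  Division happens at a
per-cell sampled length threshold; daughters split the parent axis at its
midpoint and receive independently jittered orientations (asymmetric
division angles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CellBody, TWO_PI, elongate_axis, split_axis


@dataclass
class GrowthConfig:
    """Growth and division parameters.

    Defaults describe a typical rod-shaped bacterium at micrometre scale:
    radius 0.5 um, birth length 2 um, division around 4 um (+-10%).  Time
    is measured in engine steps; each pole fires on average every
    ``pole_interval`` steps and adds ``elongation_increment`` um of length
    (scaled down under pressure).
    """

    radius: float = 0.5
    birth_length: float = 2.0
    birth_jitter: float = 0.1
    division_length: float = 4.0
    division_jitter: float = 0.1
    elongation_increment: float = 0.1
    pole_interval: float = 20.0
    delay_threshold: float = 0.02   # P_delay: pressure (um) where delay starts
    delay_floor: float = 0.2        # f_min: minimum growth factor, > 0
    angle_jitter: float = 0.3       # theta_max: division angle noise (rad)
    pressure_window: int = 10       # W: steps averaged into the signal

    def validate(self) -> None:
        problems = []
        if self.radius <= 0:
            problems.append("radius must be > 0")
        if not 0 < self.delay_floor <= 1:
            problems.append("delay_floor must be in (0, 1]")
        if self.birth_length >= self.division_length:
            problems.append("birth_length must be < division_length")
        if self.elongation_increment <= 0:
            problems.append("elongation_increment must be > 0")
        if self.pole_interval <= 0:
            problems.append("pole_interval must be > 0")
        if self.delay_threshold <= 0:
            problems.append("delay_threshold must be > 0")
        if self.pressure_window < 1:
            problems.append("pressure_window must be >= 1")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class Cell:
    """Full agent state of one bacterium."""

    id: int
    body: CellBody
    layer: int = 1
    generation: int = 0
    birth_time: int = 0
    pole_next_growth: list = field(default_factory=lambda: [0, 0])
    division_length: float = 4.0
    pressure_window: list = field(default_factory=list)
    deferred_growth: float = 0.0


def pressure_signal(cell_or_window) -> float:
    """Mean of the recent residual-penetration readings; 0 when empty.

    Isolated cells never accumulate residuals, so their signal is 0.
    """
    window = (
        cell_or_window.pressure_window
        if isinstance(cell_or_window, Cell)
        else cell_or_window
    )
    if len(window) == 0:
        return 0.0
    return float(np.mean(window))


def growth_factor(pressure, config: GrowthConfig):
    """Pressure-to-growth scaling in ``[f_min, 1]``.

    1 below the delay threshold ``P_delay``, linearly decreasing to
    ``f_min`` at ``2 * P_delay``, constant ``f_min`` beyond; continuous and
    non-increasing.  Accepts scalars or arrays.
    """
    p = np.asarray(pressure, dtype=float)
    pd = config.delay_threshold
    frac = np.clip((p - pd) / pd, 0.0, 1.0)
    out = np.clip(1.0 - (1.0 - config.delay_floor) * frac,
                  config.delay_floor, 1.0)
    return float(out) if np.isscalar(pressure) else out


def apply_deferred(deferred: float, increment: float, factor: float,
                   f_min: float) -> tuple[float, float]:
    """One elongation event's actual growth under the delay law.

    The withheld fraction ``increment * (1 - factor)`` is banked.  Banked
    length is paid back at up to one increment per event, gated by how far
    the cell currently is from full delay, so a saturated cell elongates at
    exactly ``increment * f_min`` per event while a free cell catches up.
    Returns ``(actual_growth, new_deferred)``.
    """
    banked = deferred + increment * (1.0 - factor)
    relief = (factor - f_min) / (1.0 - f_min) if f_min < 1.0 else 1.0
    release = min(banked, increment) * relief
    return increment * factor + release, banked - release


def draw_pole_interval(rng: np.random.Generator, mean: float) -> int:
    """Exponential waiting time between pole firings, integerised, >= 1."""
    return max(1, int(round(rng.exponential(mean))))


def elongate(cell: Cell, now: int, pressure: float, config: GrowthConfig,
             rng: np.random.Generator) -> Cell:
    """Fire every due pole of ``cell`` (scheduled step <= ``now``).

    Each firing adds ``elongation_increment * growth_factor`` of length at
    that pole (far pole tip stays fixed) and reschedules the pole
    ``Exponential(pole_interval)`` steps ahead.  The cell is mutated in
    place and returned.
    """
    factor = growth_factor(pressure, config)
    for pole_idx, sign in ((0, -1.0), (1, 1.0)):
        if cell.pole_next_growth[pole_idx] <= now:
            actual, cell.deferred_growth = apply_deferred(
                cell.deferred_growth, config.elongation_increment, factor,
                config.delay_floor,
            )
            centroid, half = elongate_axis(
                cell.body.centroid, cell.body.angle, cell.body.half_length,
                sign, actual,
            )
            cell.body.centroid = centroid
            cell.body.half_length = half
            cell.pole_next_growth[pole_idx] = now + draw_pole_interval(
                rng, config.pole_interval
            )
    return cell


def sample_division_length(rng: np.random.Generator, config: GrowthConfig) -> float:
    return config.division_length * (
        1.0 + rng.uniform(-config.division_jitter, config.division_jitter)
    )


def maybe_divide(cell: Cell, now: int, config: GrowthConfig,
                 rng: np.random.Generator, next_id: int):
    """Divide iff total body length has reached the cell's threshold.

    Daughters split the parent axis at its midpoint (segment lengths sum
    exactly to the parent's), each with an independently jittered angle,
    fresh division threshold, fresh pole schedules and an empty pressure
    window; generation increments, layer is inherited.  Returns ``None``
    or ``(daughter_a, daughter_b)`` with ids ``next_id`` and
    ``next_id + 1``.
    """
    if cell.body.length < cell.division_length:
        return None
    (ca, ha), (cb, hb) = split_axis(
        cell.body.centroid, cell.body.angle, cell.body.half_length
    )
    jit = config.angle_jitter
    ang_a = (cell.body.angle + rng.uniform(-jit, jit)) % TWO_PI
    ang_b = (cell.body.angle + rng.uniform(-jit, jit)) % TWO_PI
    len_a = sample_division_length(rng, config)
    len_b = sample_division_length(rng, config)
    poles_a = [now + draw_pole_interval(rng, config.pole_interval) for _ in range(2)]
    poles_b = [now + draw_pole_interval(rng, config.pole_interval) for _ in range(2)]
    daughter_a = Cell(
        id=next_id,
        body=CellBody(ca, ang_a, ha, cell.body.radius),
        layer=cell.layer,
        generation=cell.generation + 1,
        birth_time=now,
        pole_next_growth=poles_a,
        division_length=len_a,
        pressure_window=[],
        deferred_growth=0.0,
    )
    daughter_b = Cell(
        id=next_id + 1,
        body=CellBody(cb, ang_b, hb, cell.body.radius),
        layer=cell.layer,
        generation=cell.generation + 1,
        birth_time=now,
        pole_next_growth=poles_b,
        division_length=len_b,
        pressure_window=[],
        deferred_growth=0.0,
    )
    return daughter_a, daughter_b


def interdivision_age(cell: Cell, now: int) -> int:
    """Steps since birth — the operational definition of cellular age."""
    if now < cell.birth_time:
        raise ValueError("now precedes the cell's birth")
    return now - cell.birth_time
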