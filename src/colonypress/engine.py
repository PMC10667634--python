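"""Simulation loop and experiment presets.

One engine step, in fixed order: (1) elongate every cell using the
previous step's pressure signals; (2) divisions; (3) budgeted collision
solve with the mode's pair eligibility; (4) vertical mode: quasi-static
gravity settling plus a re-solve — top-down mode: layer promotions;
(5) pressure/displacement window updates from the solver report;
(6) event logging.  A (config, seed) pair fully determines the run: all
randomness flows through one generator and per-cell draws are consumed in
ascending cell-id order.

Time is measured in engine steps.  No absolute-time calibration to hours
is attempted: the model reproduces orderings and geometry, not clock time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import cells as cm
from .cells import GrowthConfig
from .layering import PromotionRule, select_promotions
from .physics import (ANGULAR_COMPLIANCE, CONTACT_TOLERANCE, DEFAULT_BETA,
                      _solve_kernel, broadphase_pairs)
from .state import MODE_TOP_DOWN, MODE_VERTICAL, ColonyState

#: Surface-mobility presets: how long the solver may work per step.
#: Soft agar lets cells slide into collision-free space (large budget);
#: stiff agar pins them (small budget).
SURFACE_BUDGETS = {"soft": 500, "standard": 60, "stiff": 12}

#: Approximate agar percentages the presets correspond to.
SURFACE_AGAR = {"soft": 1.5, "standard": 3.0, "stiff": 5.0}

_AGAR_EXPONENT = 3.1


class ConfigError(ValueError):
    """Invalid simulation configuration, with named-field diagnostics."""


def mobility_to_budget(surface) -> int:
    """Map a surface label or agar percentage to a solver budget.

    Labels: soft (~1.5% agar) -> 500, standard -> 60, stiff (~5%) -> 12.
    Numeric percentages interpolate the same anchors with a power law, so
    the mapping is strictly decreasing in agar concentration.
    """
    if isinstance(surface, str):
        try:
            return SURFACE_BUDGETS[surface]
        except KeyError:
            raise ConfigError(
                f"surface: unknown label {surface!r}; expected one of "
                f"{sorted(SURFACE_BUDGETS)} or a positive agar percent"
            ) from None
    percent = float(surface)
    if percent <= 0:
        raise ConfigError("surface: agar percent must be > 0")
    return max(1, round(SURFACE_BUDGETS["soft"] * (percent / SURFACE_AGAR["soft"]) ** (-_AGAR_EXPONENT)))


@dataclass
class SimConfig:
    mode: str = MODE_TOP_DOWN
    seed: int = 0
    max_steps: int = 20000
    max_cells: int = 800
    solver_budget: int = 60
    beta: float = DEFAULT_BETA
    angular_compliance: float = ANGULAR_COMPLIANCE
    contact_tolerance: float = CONTACT_TOLERANCE
    gravity_step: float = 0.1
    settle_cycles: int = 3      # gravity drop/re-solve cycles per step (vertical)
    snapshot_every: int = 50
    surface: str | None = None          # optional label; overrides solver_budget
    initial_condition: str = "single"   # "single" | "two_colony"
    separation: float = 36.0            # founder spacing for two-colony runs (um)
    broadphase_margin: float = 1.0
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    promotion: PromotionRule = field(default_factory=PromotionRule)

    def __post_init__(self):
        if self.surface is not None:
            self.solver_budget = mobility_to_budget(self.surface)

    def validate(self) -> None:
        problems = []
        if self.mode not in (MODE_TOP_DOWN, MODE_VERTICAL):
            problems.append(f"mode: {self.mode!r} is not one of "
                            f"['{MODE_TOP_DOWN}', '{MODE_VERTICAL}']")
        if self.max_cells < 1:
            problems.append("max_cells: must be >= 1")
        if self.max_steps < 1:
            problems.append("max_steps: must be >= 1")
        if self.solver_budget < 0:
            problems.append("solver_budget: must be >= 0")
        if not 0 < self.beta <= 1:
            problems.append("beta: must be in (0, 1]")
        if self.gravity_step <= 0:
            problems.append("gravity_step: must be > 0")
        if self.settle_cycles < 1:
            problems.append("settle_cycles: must be >= 1")
        if self.snapshot_every < 1:
            problems.append("snapshot_every: must be >= 1")
        if self.initial_condition not in ("single", "two_colony"):
            problems.append("initial_condition: must be 'single' or 'two_colony'")
        try:
            self.growth.validate()
        except ValueError as exc:
            problems.append(f"growth: {exc}")
        try:
            self.promotion.validate()
        except ValueError as exc:
            problems.append(f"promotion: {exc}")
        if problems:
            raise ConfigError("; ".join(problems))


def vertical_section_config(seed=0, max_cells=400, surface="standard", **overrides):
    """Confocal-section preset: one cell on a substrate, gravity on."""
    return replace(SimConfig(mode=MODE_VERTICAL, seed=seed, max_cells=max_cells,
                             surface=surface), **overrides)


def top_down_config(seed=0, max_cells=800, surface="standard", **overrides):
    """Radial colony preset: substrate plane, discrete layer bookkeeping."""
    return replace(SimConfig(mode=MODE_TOP_DOWN, seed=seed, max_cells=max_cells,
                             surface=surface), **overrides)


def two_colony_config(seed=0, max_cells=1200, separation=36.0, surface="standard",
                      **overrides):
    """Two founder cells separated along x; colonies grow until they merge."""
    return replace(SimConfig(mode=MODE_TOP_DOWN, seed=seed, max_cells=max_cells,
                             surface=surface, initial_condition="two_colony",
                             separation=separation), **overrides)


@dataclass
class History:
    """Time-ordered snapshots plus the event log of a run."""

    config: SimConfig
    snapshots: list = field(default_factory=list)
    events: list = field(default_factory=list)  # (step, type, cell_id, x, y)
    truncated: bool = False
    first_offground_step: int | None = None
    merge_report: dict | None = None

    @property
    def final(self) -> ColonyState:
        return self.snapshots[-1]

    def promotion_steps(self):
        return [e[0] for e in self.events if e[1] == "promotion"]


class _Colony:
    """Mutable struct-of-arrays engine state."""

    def __init__(self, config: SimConfig):
        self.cfg = config
        g = config.growth
        self.W = g.pressure_window
        self.T = config.promotion.persistence
        self.step_no = 0
        n0 = 2 if config.initial_condition == "two_colony" else 1
        if config.initial_condition == "two_colony":
            xs = [-config.separation / 2.0, config.separation / 2.0]
        else:
            xs = [0.0]
        self.ids = np.arange(n0, dtype=np.int64)
        self.next_id = n0
        self.pos = np.zeros((n0, 2))
        self.pos[:, 0] = xs
        if config.mode == MODE_VERTICAL:
            self.pos[:, 1] = g.radius  # resting on the substrate
        self.ang = np.zeros(n0)
        self.hl = np.full(n0, (g.birth_length - 2.0 * g.radius) / 2.0)
        self.rad = np.full(n0, g.radius)
        self.layer = np.ones(n0, np.int64)
        self.gen = np.zeros(n0, np.int64)
        self.birth = np.zeros(n0, np.int64)
        self.divlen = np.zeros(n0)
        self.deferred = np.zeros(n0)
        self.pole_next = np.zeros((n0, 2), np.int64)
        self.ancestry = np.arange(n0, dtype=np.int64)
        self.pwin = np.zeros((n0, self.W))
        self.pwin_count = np.zeros(n0, np.int64)
        self.over_cnt = np.zeros(n0, np.int64)
        self.dwin = np.zeros((n0, self.T, 2))

    @property
    def n(self) -> int:
        return len(self.ids)

    def seed_founders(self, rng: np.random.Generator) -> None:
        for i in range(self.n):
            self.divlen[i] = cm.sample_division_length(rng, self.cfg.growth)
            self.pole_next[i, 0] = cm.draw_pole_interval(rng, self.cfg.growth.pole_interval)
            self.pole_next[i, 1] = cm.draw_pole_interval(rng, self.cfg.growth.pole_interval)

    def signals(self) -> np.ndarray:
        counts = np.maximum(self.pwin_count, 1)
        return self.pwin.sum(axis=1) / counts

    def snapshot(self) -> ColonyState:
        return ColonyState(
            step=self.step_no,
            ids=self.ids.copy(),
            pos=self.pos.copy(),
            angle=np.mod(self.ang, 2.0 * np.pi),
            half_length=self.hl.copy(),
            radius=self.rad.copy(),
            layer=self.layer.copy(),
            generation=self.gen.copy(),
            birth_step=self.birth.copy(),
            pressure=self.signals(),
            mode=self.cfg.mode,
            ancestry=self.ancestry.copy(),
        )

    def _append_rows(self, rows: dict) -> None:
        k = len(rows["ids"])
        self.ids = np.concatenate([self.ids, rows["ids"]])
        self.pos = np.vstack([self.pos, rows["pos"]])
        self.ang = np.concatenate([self.ang, rows["ang"]])
        self.hl = np.concatenate([self.hl, rows["hl"]])
        self.rad = np.concatenate([self.rad, rows["rad"]])
        self.layer = np.concatenate([self.layer, rows["layer"]])
        self.gen = np.concatenate([self.gen, rows["gen"]])
        self.birth = np.concatenate([self.birth, rows["birth"]])
        self.divlen = np.concatenate([self.divlen, rows["divlen"]])
        self.deferred = np.concatenate([self.deferred, np.zeros(k)])
        self.pole_next = np.vstack([self.pole_next, rows["pole_next"]])
        self.ancestry = np.concatenate([self.ancestry, rows["ancestry"]])
        self.pwin = np.vstack([self.pwin, np.zeros((k, self.W))])
        self.pwin_count = np.concatenate([self.pwin_count, np.zeros(k, np.int64)])
        self.over_cnt = np.concatenate([self.over_cnt, np.zeros(k, np.int64)])
        self.dwin = np.vstack([self.dwin, np.zeros((k, self.T, 2))])


def _elongate_all(col: _Colony, now: int, signals, rng) -> None:
    g = col.cfg.growth
    factors = cm.growth_factor(signals, g)
    order = np.argsort(col.ids, kind="stable")
    due_rows = order[(col.pole_next[order] <= now).any(axis=1)]
    for i in due_rows:
        ca, sa = np.cos(col.ang[i]), np.sin(col.ang[i])
        for pole_idx, sign in ((0, -1.0), (1, 1.0)):
            if col.pole_next[i, pole_idx] <= now:
                actual, col.deferred[i] = cm.apply_deferred(
                    col.deferred[i], g.elongation_increment, float(factors[i]),
                    g.delay_floor,
                )
                col.hl[i] += actual / 2.0
                col.pos[i, 0] += sign * ca * (actual / 2.0)
                col.pos[i, 1] += sign * sa * (actual / 2.0)
                col.pole_next[i, pole_idx] = now + cm.draw_pole_interval(
                    rng, g.pole_interval
                )


def _divide_all(col: _Colony, now: int, rng, events) -> None:
    g = col.cfg.growth
    lengths = 2.0 * col.hl + 2.0 * col.rad
    due = np.nonzero(lengths >= col.divlen)[0]
    if due.size == 0:
        return
    due = due[np.argsort(col.ids[due], kind="stable")]
    new = {k: [] for k in ("ids", "pos", "ang", "hl", "rad", "layer", "gen",
                           "birth", "divlen", "pole_next", "ancestry")}
    for i in due:
        u = np.array([np.cos(col.ang[i]), np.sin(col.ang[i])])
        c = col.pos[i].copy()
        h = col.hl[i] / 2.0
        jit = g.angle_jitter
        ang_a = col.ang[i] + rng.uniform(-jit, jit)
        ang_b = col.ang[i] + rng.uniform(-jit, jit)
        len_a = cm.sample_division_length(rng, g)
        len_b = cm.sample_division_length(rng, g)
        poles_a = [now + cm.draw_pole_interval(rng, g.pole_interval) for _ in range(2)]
        poles_b = [now + cm.draw_pole_interval(rng, g.pole_interval) for _ in range(2)]
        id_a, id_b = col.next_id, col.next_id + 1
        col.next_id += 2
        events.append((now, "division", int(col.ids[i]), float(c[0]), float(c[1])))
        gen_child = col.gen[i] + 1
        # Daughter a replaces the parent row; daughter b is appended.
        col.ids[i] = id_a
        col.pos[i] = c - u * h
        col.ang[i] = ang_a
        col.hl[i] = h
        col.gen[i] = gen_child
        col.birth[i] = now
        col.divlen[i] = len_a
        col.deferred[i] = 0.0
        col.pole_next[i] = poles_a
        col.pwin[i] = 0.0
        col.pwin_count[i] = 0
        col.over_cnt[i] = 0
        col.dwin[i] = 0.0
        new["ids"].append(id_b)
        new["pos"].append(c + u * h)
        new["ang"].append(ang_b)
        new["hl"].append(h)
        new["rad"].append(col.rad[i])
        new["layer"].append(col.layer[i])
        new["gen"].append(gen_child)
        new["birth"].append(now)
        new["divlen"].append(len_b)
        new["pole_next"].append(poles_b)
        new["ancestry"].append(col.ancestry[i])
    col._append_rows({
        "ids": np.array(new["ids"], np.int64),
        "pos": np.array(new["pos"]),
        "ang": np.array(new["ang"]),
        "hl": np.array(new["hl"]),
        "rad": np.array(new["rad"]),
        "layer": np.array(new["layer"], np.int64),
        "gen": np.array(new["gen"], np.int64),
        "birth": np.array(new["birth"], np.int64),
        "divlen": np.array(new["divlen"]),
        "pole_next": np.array(new["pole_next"], np.int64),
        "ancestry": np.array(new["ancestry"], np.int64),
    })


def _solve_and_measure(col: _Colony, vertical: bool):
    cfg = col.cfg
    layers = None if vertical else col.layer
    ii, jj = broadphase_pairs(col.pos, col.ang, col.hl, col.rad,
                              margin=cfg.broadphase_margin, layer=layers)
    pos_before = col.pos.copy()
    _solve_kernel(col.pos, col.ang, col.hl, col.rad, ii, jj,
                  cfg.solver_budget, cfg.beta, cfg.angular_compliance,
                  cfg.contact_tolerance, vertical)
    if vertical:
        for _ in range(max(1, cfg.settle_cycles)):
            col.pos[:, 1] -= cfg.gravity_step
            _, pen_pairs, ground_pen = _solve_kernel(
                col.pos, col.ang, col.hl, col.rad, ii, jj,
                cfg.solver_budget, cfg.beta, cfg.angular_compliance,
                cfg.contact_tolerance, True)
    else:
        _, pen_pairs, ground_pen = _solve_kernel(
            col.pos, col.ang, col.hl, col.rad, ii, jj,
            0, cfg.beta, cfg.angular_compliance, cfg.contact_tolerance, False)
    res = np.zeros(col.n)
    ncon = np.zeros(col.n, np.int64)
    hot = pen_pairs > 0.0
    if hot.any():
        np.add.at(res, ii[hot], pen_pairs[hot])
        np.add.at(res, jj[hot], pen_pairs[hot])
        np.add.at(ncon, ii[hot], 1)
        np.add.at(ncon, jj[hot], 1)
    # Substrate reaction (ground penetration) is not crowding: the pressure
    # signal counts only cell-cell residuals, so an uncrowded cell resting
    # on the substrate reads zero pressure.
    disp = col.pos - pos_before
    return res, ncon, disp, ii[hot], jj[hot]


def _engine_step(col: _Colony, rng, history: History) -> None:
    """Advance the colony by one step (see module docstring for order)."""
    cfg = col.cfg
    now = col.step_no + 1
    vertical = cfg.mode == MODE_VERTICAL
    signals_prev = col.signals()

    _elongate_all(col, now, signals_prev, rng)
    _divide_all(col, now, rng, history.events)
    res, ncon, disp, hot_i, hot_j = _solve_and_measure(col, vertical)

    if not vertical:
        net_disp = np.linalg.norm(col.dwin.sum(axis=1), axis=1)
        promo = select_promotions(signals_prev, col.over_cnt, net_disp, ncon,
                                  cfg.promotion)
        for i in promo:
            col.layer[i] += 1
            col.pwin[i] = 0.0
            col.pwin_count[i] = 0
            col.over_cnt[i] = 0
            col.dwin[i] = 0.0
            history.events.append((now, "promotion", int(col.ids[i]),
                                   float(col.pos[i, 0]), float(col.pos[i, 1])))
            if history.merge_report is not None:
                _classify_merge_promotion(
                    history.merge_report, now, float(col.pos[i, 0]),
                    int(col.ancestry[i]))

    # Window updates from this step's solver report.
    ptr = now % col.W
    col.pwin[:, ptr] = res
    col.pwin_count = np.minimum(col.pwin_count + 1, col.W)
    signal_now = col.signals()
    above = signal_now > cfg.promotion.promote_threshold
    col.over_cnt = np.where(above, col.over_cnt + 1, 0)
    col.dwin[:, now % col.T, :] = disp

    if vertical and history.first_offground_step is None:
        if (col.pos[:, 1] > 1.5 * 2.0 * col.rad.max()).any():
            history.first_offground_step = now

    if history.merge_report is not None and \
            history.merge_report["first_contact_step"] is None and hot_i.size:
        inter = col.ancestry[hot_i] != col.ancestry[hot_j]
        if inter.any():
            k = int(np.nonzero(inter)[0][0])
            i = hot_i[k]
            history.merge_report["first_contact_step"] = now
            history.events.append((now, "contact_first", int(col.ids[i]),
                                   float(col.pos[i, 0]), float(col.pos[i, 1])))
    col.step_no = now


def colony_from_state(state: ColonyState, config: SimConfig,
                      rng: np.random.Generator) -> "_Colony":
    """Rebuild a steppable colony from a snapshot.

    Growth clocks are not part of a snapshot; because pole waiting times
    are exponential (memoryless), resuming with fresh draws is
    statistically equivalent to having kept the clocks.  Division
    thresholds are re-sampled the same way.  Draws are consumed in
    ascending cell-id order.
    """
    col = _Colony(config)
    col.step_no = state.step
    col.ids = state.ids.copy()
    col.next_id = int(state.ids.max()) + 1 if state.n else 0
    col.pos = state.pos.copy()
    col.ang = state.angle.copy()
    col.hl = state.half_length.copy()
    col.rad = state.radius.copy()
    col.layer = state.layer.copy()
    col.gen = state.generation.copy()
    col.birth = state.birth_step.copy()
    col.divlen = np.full(state.n, config.growth.division_length)
    col.deferred = np.zeros(state.n)
    col.pole_next = np.zeros((state.n, 2), np.int64)
    col.ancestry = (state.ancestry.copy() if state.ancestry is not None
                    else np.zeros(state.n, np.int64))
    for i in np.argsort(col.ids, kind="stable"):
        col.divlen[i] = max(cm.sample_division_length(rng, config.growth),
                            2.0 * col.hl[i] + 2.0 * col.rad[i])
        col.pole_next[i, 0] = state.step + cm.draw_pole_interval(
            rng, config.growth.pole_interval)
        col.pole_next[i, 1] = state.step + cm.draw_pole_interval(
            rng, config.growth.pole_interval)
    col.pwin = np.zeros((state.n, col.W))
    col.pwin[:, 0] = state.pressure
    col.pwin_count = np.ones(state.n, np.int64)
    col.over_cnt = np.zeros(state.n, np.int64)
    col.dwin = np.zeros((state.n, col.T, 2))
    return col


def step(state: ColonyState, config: SimConfig, rng: np.random.Generator) -> ColonyState:
    """One engine step on an immutable snapshot; returns the new snapshot.

    Convenience wrapper for stepping arbitrary states; full runs should
    use :func:`run`, which keeps the rolling pressure and displacement
    windows across steps.
    """
    col = colony_from_state(state, config, rng)
    hist = History(config=config)
    _engine_step(col, rng, hist)
    return col.snapshot()


def _run(config: SimConfig, merge_tracking: bool = False) -> History:
    config.validate()
    rng = np.random.default_rng(config.seed)
    col = _Colony(config)
    col.seed_founders(rng)
    history = History(config=config)
    if merge_tracking:
        history.merge_report = {
            "first_contact_step": None,
            "centre_first_promotion": {0: None, 1: None},
            "intersection_first_promotion": None,
            "separation": config.separation,
        }
    history.snapshots.append(col.snapshot())
    while col.step_no < config.max_steps:
        _engine_step(col, rng, history)
        if col.step_no % config.snapshot_every == 0:
            history.snapshots.append(col.snapshot())
        if col.n > config.max_cells:
            history.truncated = True
            break
    if history.snapshots[-1].step != col.step_no:
        history.snapshots.append(col.snapshot())
    return history


def _classify_merge_promotion(report: dict, step_no: int, x: float,
                              side: int) -> None:
    """File one promotion event into the two-colony merge report."""
    if abs(x) <= report["separation"] / 4.0:
        if report["intersection_first_promotion"] is None:
            report["intersection_first_promotion"] = step_no
    elif report["centre_first_promotion"][side] is None:
        report["centre_first_promotion"][side] = step_no


def run(config: SimConfig) -> History:
    """Run a colony from its initial condition to max_steps or max_cells."""
    if config.initial_condition == "two_colony":
        return run_two_colony(config)
    return _run(config)


def run_two_colony(config: SimConfig, separation: float | None = None) -> History:
    """Two founders at (+-d/2, 0); history carries a merge report.

    The merge report records the step of first inter-colony contact, the
    first promotion in each colony's centre region, and the first
    promotion in the intersection region (within d/4 of the midline).
    """
    if config.mode != MODE_TOP_DOWN:
        raise ConfigError("mode: two-colony runs require top_down mode")
    if separation is not None:
        config = replace(config, separation=separation)
    if config.initial_condition != "two_colony":
        config = replace(config, initial_condition="two_colony")
    min_sep = 4.0 * config.growth.division_length
    if config.separation < min_sep:
        raise ConfigError(
            f"separation: {config.separation} um is below 4 cell lengths "
            f"({min_sep} um)")
    return _run(config, merge_tracking=True)
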