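"""Growth law, delayed elongation, division and age bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from colonypress.cells import (Cell, GrowthConfig, apply_deferred,
                               draw_pole_interval, elongate, growth_factor,
                               interdivision_age, maybe_divide, pressure_signal)
from colonypress.geometry import CellBody


@pytest.fixture
def config():
    return GrowthConfig()


def make_cell(length=3.0, angle=0.0, radius=0.5, cid=0):
    hl = (length - 2 * radius) / 2.0
    return Cell(id=cid, body=CellBody(np.array([0.0, 0.0]), angle, hl, radius),
                division_length=4.0)


class TestGrowthFactor:
    def test_free_growth_below_threshold(self, config):
        assert growth_factor(0.0, config) == 1.0
        assert growth_factor(config.delay_threshold, config) == 1.0

    def test_saturates_at_floor(self, config):
        assert growth_factor(2 * config.delay_threshold, config) == \
            pytest.approx(config.delay_floor)
        assert growth_factor(50.0, config) == pytest.approx(config.delay_floor)

    def test_linear_midpoint(self):
        cfg = GrowthConfig(delay_threshold=0.1, delay_floor=0.2)
        assert growth_factor(0.15, cfg) == pytest.approx(0.6)

    def test_non_increasing_and_bounded(self, config):
        p = np.linspace(0.0, 5 * config.delay_threshold, 400)
        f = growth_factor(p, config)
        assert (np.diff(f) <= 1e-12).all()
        assert f.min() >= config.delay_floor and f.max() <= 1.0


class TestPressureSignal:
    def test_empty_window_is_zero(self):
        assert pressure_signal([]) == 0.0
        assert pressure_signal([0.0, 0.0, 0.0]) == 0.0

    def test_window_mean(self):
        assert pressure_signal([0.2, 0.4]) == pytest.approx(0.3)


class TestDeferredGrowth:
    def test_saturated_cell_grows_at_exactly_floor_rate(self, config):
        dl, fmin = config.elongation_increment, config.delay_floor
        deferred = 0.0
        for _ in range(50):
            actual, deferred = apply_deferred(deferred, dl, fmin, fmin)
            assert actual == pytest.approx(dl * fmin)
        assert deferred > 0.0  # the withheld length is banked, not lost

    def test_free_cell_pays_back_at_most_one_increment_per_event(self, config):
        dl = config.elongation_increment
        actual, left = apply_deferred(5 * dl, dl, 1.0, config.delay_floor)
        assert actual == pytest.approx(2 * dl)
        assert left == pytest.approx(4 * dl)

    def test_no_pressure_no_banking(self, config):
        dl = config.elongation_increment
        actual, left = apply_deferred(0.0, dl, 1.0, config.delay_floor)
        assert actual == pytest.approx(dl)
        assert left == 0.0


class TestElongate:
    def test_pole_not_due_leaves_body_unchanged(self, config, rng):
        cell = make_cell()
        cell.pole_next_growth = [10, 10]
        before = cell.body.centroid.copy(), cell.body.half_length
        elongate(cell, now=5, pressure=0.0, config=config, rng=rng)
        assert cell.body.half_length == before[1]
        np.testing.assert_allclose(cell.body.centroid, before[0])

    def test_due_pole_grows_full_increment_with_far_tip_fixed(self, config, rng):
        cell = make_cell(angle=0.6)
        cell.pole_next_growth = [0, 99999]
        u = cell.body.direction
        far_tip = cell.body.centroid + u * (cell.body.half_length + cell.body.radius)
        length0 = cell.body.length
        elongate(cell, now=1, pressure=0.0, config=config, rng=rng)
        assert cell.body.length - length0 == pytest.approx(0.1, abs=1e-12)
        new_far = cell.body.centroid + cell.body.direction * (
            cell.body.half_length + cell.body.radius)
        np.testing.assert_allclose(new_far, far_tip, atol=1e-9)

    def test_rescheduling_mean_matches_pole_interval(self, rng):
        draws = [draw_pole_interval(rng, 20.0) for _ in range(10000)]
        assert 19.0 <= np.mean(draws) <= 21.0
        assert min(draws) >= 1


class TestDivision:
    def test_below_threshold_no_division(self, config, rng):
        cell = make_cell(length=3.0)
        assert maybe_divide(cell, 10, config, rng, next_id=5) is None

    def test_axis_length_conserved(self, config, rng):
        cell = make_cell(length=5.0)
        a, b = maybe_divide(cell, 10, config, rng, next_id=5)
        parent_axis = 2 * cell.body.half_length
        assert 2 * a.body.half_length + 2 * b.body.half_length == \
            pytest.approx(parent_axis, abs=1e-9)
        assert (a.id, b.id) == (5, 6)
        assert a.generation == b.generation == cell.generation + 1
        assert a.layer == cell.layer
        assert a.pressure_window == [] and a.birth_time == 10

    def test_daughter_angle_jitter_uniform(self, config, rng):
        devs = []
        for _ in range(10000):
            cell = make_cell(length=5.0, angle=1.0)
            a, b = maybe_divide(cell, 0, config, rng, next_id=1)
            devs.append((a.body.angle - 1.0 + np.pi) % (2 * np.pi) - np.pi)
        devs = np.asarray(devs)
        jit = config.angle_jitter
        assert abs(devs).max() <= jit + 1e-12
        p = stats.kstest(devs, stats.uniform(loc=-jit, scale=2 * jit).cdf).pvalue
        assert p > 0.01


class TestAge:
    def test_age_is_steps_since_birth(self):
        cell = make_cell()
        cell.birth_time = 100
        assert interdivision_age(cell, 100) == 0
        assert interdivision_age(cell, 250) == 150
        with pytest.raises(ValueError):
            interdivision_age(cell, 99)


def simulate_interdivision_time(config, pressure, seed, reps=60):
    """Steps from birth length to division threshold at fixed pressure."""
    rng = np.random.default_rng(seed)
    times = []
    for _ in range(reps):
        cell = make_cell(length=2.0)
        cell.division_length = config.division_length
        cell.pole_next_growth = [draw_pole_interval(rng, config.pole_interval)
                                 for _ in range(2)]
        now = 0
        while cell.body.length < cell.division_length and now < 30000:
            now += 1
            elongate(cell, now, pressure, config, rng)
        times.append(now)
    return float(np.mean(times))


def test_sustained_saturation_slows_division_by_inverse_floor():
    """Trapped cells at full delay divide ~1/f_min times slower than free."""
    config = GrowthConfig()
    free = simulate_interdivision_time(config, 0.0, seed=11)
    squeezed = simulate_interdivision_time(config, 10 * config.delay_threshold,
                                           seed=12)
    ratio = squeezed / free
    assert ratio >= 0.9 / config.delay_floor
    assert ratio == pytest.approx(1.0 / config.delay_floor, rel=0.15)


def test_free_growth_interdivision_constant_across_generations():
    """Without pressure the expected cycle time does not drift."""
    config = GrowthConfig()
    gen1 = simulate_interdivision_time(config, 0.0, seed=21)
    gen2 = simulate_interdivision_time(config, 0.0, seed=22)
    assert gen1 == pytest.approx(gen2, rel=0.1)
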