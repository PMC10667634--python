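"""Engine contracts: determinism, event accounting, presets, validation."""

import hashlib

import numpy as np
import pytest

from colonypress import engine
from colonypress.engine import ConfigError, SimConfig, mobility_to_budget
from colonypress.io import config_from_dict


def history_digest(history):
    h = hashlib.sha256()
    for snap in history.snapshots:
        for arr in (snap.ids, snap.pos, snap.angle, snap.half_length,
                    snap.layer, snap.generation, snap.birth_step, snap.pressure):
            h.update(np.ascontiguousarray(arr).tobytes())
    h.update(repr(history.events).encode())
    return h.hexdigest()


def small_run(seed=0, **kw):
    kw.setdefault("max_cells", 40)
    return engine.run(engine.top_down_config(seed=seed, **kw))


class TestDeterminism:
    def test_same_seed_bit_identical_history(self):
        assert history_digest(small_run(seed=3)) == history_digest(small_run(seed=3))

    def test_different_seeds_diverge(self):
        assert history_digest(small_run(seed=3)) != history_digest(small_run(seed=4))


class TestPopulationAccounting:
    def test_cell_count_non_decreasing_and_division_driven(self):
        history = small_run(seed=5)
        counts = [s.n for s in history.snapshots]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        divisions = sum(1 for e in history.events if e[1] == "division")
        assert history.final.n == 1 + divisions  # each division adds one cell

    def test_max_cells_one_stops_after_first_division(self):
        history = engine.run(engine.top_down_config(seed=0, max_cells=1))
        assert history.truncated
        assert history.final.n == 2

    def test_no_layer_demotion(self, topdown_runs):
        history = topdown_runs[0]
        seen = {}
        for snap in history.snapshots:
            for cid, layer in zip(snap.ids, snap.layer):
                assert layer >= seen.get(cid, 1)
                seen[cid] = layer

    def test_promotion_events_step_one_layer(self, topdown_runs):
        for history in topdown_runs[:3]:
            for ev in history.events:
                if ev[1] == "promotion":
                    assert ev[0] >= 1


class TestVerticalMode:
    def test_single_free_cell_step_grows_without_events(self):
        history = engine.run(engine.vertical_section_config(seed=0, max_cells=2,
                                                            max_steps=30))
        first = history.snapshots[0]
        assert first.n == 1
        assert not [e for e in history.events if e[0] <= 30 and e[1] != "division"]
        assert history.final.pressure.max() == 0.0

    def test_width_and_height_non_decreasing(self, vertical_runs):
        history = vertical_runs[0]
        widths, heights = [], []
        for snap in history.snapshots:
            reach = snap.half_length + snap.radius
            widths.append((snap.pos[:, 0] + reach).max() - (snap.pos[:, 0] - reach).min())
            heights.append(snap.pos[:, 1].max())
        assert all(b >= a - 1.0 for a, b in zip(widths, widths[1:]))
        assert max(heights) == pytest.approx(heights[-1], abs=2.0)

    def test_cells_stay_above_ground(self, vertical_runs):
        snap = vertical_runs[0].final
        low = snap.pos[:, 1] - (snap.half_length * np.abs(np.sin(snap.angle))
                                + snap.radius)
        assert low.min() >= -0.05


class TestStepWrapper:
    def test_single_snapshot_step_is_deterministic_and_quiet(self):
        from colonypress.fixtures import single_cell
        config = engine.top_down_config(seed=0, max_cells=10)
        state = single_cell()
        out1 = engine.step(state, config, np.random.default_rng(5))
        out2 = engine.step(state, config, np.random.default_rng(5))
        assert out1.step == state.step + 1
        assert out1.n == 1  # a lone founder neither divides nor feels pressure
        assert out1.pressure.max() == 0.0
        np.testing.assert_array_equal(out1.pos, out2.pos)


class TestMobility:
    def test_preset_table(self):
        assert mobility_to_budget("soft") == 500
        assert mobility_to_budget("standard") == 60
        assert mobility_to_budget("stiff") == 12

    def test_strictly_decreasing_in_agar_percent(self):
        # 0.5%-spaced grid: the finest resolution at which integer budgets
        # can still be strictly ordered at the stiff end of the range
        percents = np.linspace(1.0, 6.0, 11)
        budgets = [mobility_to_budget(p) for p in percents]
        assert all(b2 < b1 for b1, b2 in zip(budgets, budgets[1:]))

    def test_rejects_nonpositive_percent(self):
        with pytest.raises(ConfigError):
            mobility_to_budget(0.0)
        with pytest.raises(ConfigError):
            mobility_to_budget("granite")


class TestConfigValidation:
    def test_invalid_fields_named_in_diagnostics(self):
        config = SimConfig(mode="sideways", max_cells=0, beta=7.0)
        with pytest.raises(ConfigError) as err:
            config.validate()
        msg = str(err.value)
        assert "mode" in msg and "max_cells" in msg and "beta" in msg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigError, match="gravity_boost"):
            config_from_dict({"seed": 1, "gravity_boost": 2.0})

    def test_growth_validation_bubbles_up(self):
        raw = {"birth_length": 5.0, "division_length": 4.0}
        with pytest.raises(ConfigError, match="birth_length"):
            config_from_dict(raw)


class TestTwoColony:
    def test_too_small_separation_rejected(self):
        config = engine.two_colony_config(seed=0, separation=10.0)
        with pytest.raises(ConfigError, match="separation"):
            engine.run_two_colony(config)

    def test_distant_colonies_never_meet_in_short_run(self):
        config = engine.two_colony_config(seed=0, separation=200.0,
                                          max_cells=60)
        history = engine.run_two_colony(config)
        assert history.merge_report["first_contact_step"] is None
        assert history.merge_report["intersection_first_promotion"] is None

    def test_initial_state_has_two_founders_at_half_separation(self):
        config = engine.two_colony_config(seed=0, separation=36.0, max_cells=2)
        history = engine.run_two_colony(config)
        first = history.snapshots[0]
        assert first.n == 2
        np.testing.assert_allclose(sorted(first.pos[:, 0]), [-18.0, 18.0])
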