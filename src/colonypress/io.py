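"""Configuration files, snapshot/event CSV export and run manifests.

Config files are flat YAML key-value mappings; unknown keys are rejected
with field-level diagnostics.  Snapshots are plain CSV (one row per cell
per snapshot) written at full float precision so a reloaded state matches
the in-memory one field for field.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cells import GrowthConfig
from .engine import ConfigError, History, SimConfig
from .layering import PromotionRule
from .state import MODE_TOP_DOWN, ColonyState

SNAPSHOT_COLUMNS = [
    "step", "cell_id", "x", "y_or_z", "angle_rad", "length_um", "radius_um",
    "layer", "generation", "birth_step", "pressure_um",
]

EVENT_COLUMNS = ["step", "event_type", "cell_id", "x", "y"]

_TOP_KEYS = {
    "mode", "seed", "max_steps", "max_cells", "solver_budget", "beta",
    "angular_compliance", "contact_tolerance", "gravity_step", "settle_cycles",
    "snapshot_every", "surface", "initial_condition", "separation",
    "broadphase_margin",
}
_GROWTH_KEYS = {
    "radius", "birth_length", "birth_jitter", "division_length",
    "division_jitter", "elongation_increment", "pole_interval",
    "delay_threshold", "delay_floor", "angle_jitter", "pressure_window",
}
_PROMOTION_KEYS = {"promote_threshold", "persistence", "displacement_epsilon"}


def config_to_dict(config: SimConfig) -> dict:
    """Flatten a SimConfig into one YAML-ready key-value mapping."""
    out = {k: getattr(config, k) for k in sorted(_TOP_KEYS)}
    out.update({k: getattr(config.growth, k) for k in sorted(_GROWTH_KEYS)})
    out.update({k: getattr(config.promotion, k) for k in sorted(_PROMOTION_KEYS)})
    return out


def config_from_dict(raw: dict) -> SimConfig:
    unknown = set(raw) - _TOP_KEYS - _GROWTH_KEYS - _PROMOTION_KEYS
    if unknown:
        raise ConfigError(
            "unknown config keys: " + ", ".join(sorted(unknown)))
    growth = GrowthConfig(**{k: raw[k] for k in _GROWTH_KEYS if k in raw})
    promotion = PromotionRule(**{k: raw[k] for k in _PROMOTION_KEYS if k in raw})
    top = {k: raw[k] for k in _TOP_KEYS if k in raw}
    config = SimConfig(growth=growth, promotion=promotion, **top)
    config.validate()
    return config


def load_config(path) -> SimConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key-value mapping")
    return config_from_dict(raw)


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def _state_frame(state: ColonyState) -> pd.DataFrame:
    return pd.DataFrame({
        "step": np.full(state.n, state.step, dtype=np.int64),
        "cell_id": state.ids,
        "x": state.pos[:, 0],
        "y_or_z": state.pos[:, 1],
        "angle_rad": state.angle,
        "length_um": state.lengths,
        "radius_um": state.radius,
        "layer": state.layer,
        "generation": state.generation,
        "birth_step": state.birth_step,
        "pressure_um": state.pressure,
    })


def snapshots_to_csv(history_or_states, path) -> None:
    """Write snapshots as CSV, one row per cell per snapshot."""
    states = (history_or_states.snapshots
              if isinstance(history_or_states, History) else history_or_states)
    if isinstance(states, ColonyState):
        states = [states]
    frames = [_state_frame(s) for s in states]
    df = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=SNAPSHOT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def load_snapshots(path, mode: str = MODE_TOP_DOWN) -> list[ColonyState]:
    """Reload snapshot CSV into states (full float round trip)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SNAPSHOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot CSV missing columns: {sorted(missing)}")
    states = []
    for step_no, group in df.groupby("step", sort=True):
        rad = group["radius_um"].to_numpy()
        states.append(ColonyState(
            step=int(step_no),
            ids=group["cell_id"].to_numpy(np.int64),
            pos=np.column_stack([group["x"].to_numpy(), group["y_or_z"].to_numpy()]),
            angle=group["angle_rad"].to_numpy(),
            half_length=(group["length_um"].to_numpy() - 2.0 * rad) / 2.0,
            radius=rad,
            layer=group["layer"].to_numpy(np.int64),
            generation=group["generation"].to_numpy(np.int64),
            birth_step=group["birth_step"].to_numpy(np.int64),
            pressure=group["pressure_um"].to_numpy(),
            mode=mode,
        ))
    return states


def events_to_csv(history: History, path) -> None:
    df = pd.DataFrame(history.events, columns=EVENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def write_manifest(path, config: SimConfig, outputs: dict, history: History,
                   version: str) -> None:
    """JSON run manifest: config echo, seed, version, outputs, truncation."""
    manifest = {
        "config": config_to_dict(config),
        "seed": config.seed,
        "version": version,
        "start_step": history.snapshots[0].step if history.snapshots else 0,
        "end_step": history.final.step if history.snapshots else 0,
        "truncated": history.truncated,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    if history.merge_report is not None:
        manifest["merge_report"] = {
            "first_contact_step": history.merge_report["first_contact_step"],
            "centre_first_promotion": {
                str(k): v for k, v in
                history.merge_report["centre_first_promotion"].items()
            },
            "intersection_first_promotion":
                history.merge_report["intersection_first_promotion"],
            "separation": history.merge_report["separation"],
        }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def height_map_to_csv(xs, ys, H, path) -> None:
    """Gridded height field as tidy (x, y, height) CSV rows."""
    gx, gy = np.meshgrid(xs, ys)
    df = pd.DataFrame({"x": gx.ravel(), "y": gy.ravel(),
                       "height": np.asarray(H).ravel()})
    df.to_csv(path, index=False, float_format="%.17g")
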