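"""Matplotlib rendering of colony states.

Cells are drawn as to-scale capsule outlines coloured by age, generation,
pressure or layer.  Rendering is a visual aid only; every quantitative
claim in the package is asserted on numeric profiles, never on pixels.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PolyCollection

from .state import MODE_VERTICAL, ColonyState

COLOUR_QUANTITIES = ("age", "generation", "pressure", "layer")


def _capsule_polygon(centroid, angle, half_length, radius, n_arc=10):
    u = np.array([np.cos(angle), np.sin(angle)])
    tip_a = centroid + u * half_length
    tip_b = centroid - u * half_length
    phi = np.linspace(angle - np.pi / 2.0, angle + np.pi / 2.0, n_arc)
    arc_a = tip_a + radius * np.column_stack([np.cos(phi), np.sin(phi)])
    arc_b = tip_b + radius * np.column_stack([np.cos(phi + np.pi), np.sin(phi + np.pi)])
    return np.vstack([arc_a, arc_b])


def _values(state: ColonyState, colour_by: str) -> np.ndarray:
    if colour_by not in COLOUR_QUANTITIES:
        raise ValueError(
            f"colour_by must be one of {COLOUR_QUANTITIES}, got {colour_by!r}")
    return {
        "age": state.ages.astype(float),
        "generation": state.generation.astype(float),
        "pressure": state.pressure,
        "layer": state.layer.astype(float),
    }[colour_by]


def render_state(state: ColonyState, colour_by: str, output_path,
                 cmap: str = "viridis", dpi: int = 110) -> Path:
    """Draw one state to an image file; returns the path written."""
    output_path = Path(output_path)
    fig, ax = plt.subplots(figsize=(7, 6))
    if state.n == 0:
        warnings.warn("rendering an empty state: blank canvas")
        ax.set_axis_off()
    else:
        values = _values(state, colour_by)
        polys = [
            _capsule_polygon(state.pos[i], state.angle[i],
                             state.half_length[i], state.radius[i])
            for i in range(state.n)
        ]
        coll = PolyCollection(polys, array=values, cmap=cmap,
                              edgecolors="k", linewidths=0.2)
        ax.add_collection(coll)
        fig.colorbar(coll, ax=ax, label=colour_by)
        reach = state.half_length + state.radius
        lo = (state.pos - reach[:, None]).min(axis=0) - 1
        hi = (state.pos + reach[:, None]).max(axis=0) + 1
        ax.set_xlim(lo[0], hi[0])
        ax.set_ylim(lo[1] if state.mode != MODE_VERTICAL else 0.0, hi[1])
        ax.set_aspect("equal")
        ax.set_xlabel("x (um)")
        ax.set_ylabel("z (um)" if state.mode == MODE_VERTICAL else "y (um)")
    ax.set_title(f"step {state.step}, {state.n} cells")
    fig.savefig(output_path, dpi=dpi)
    plt.close(fig)
    return output_path


def render(state_or_history, colour_by: str, output_path) -> list[Path]:
    """Render a state, or one frame per snapshot of a history."""
    if isinstance(state_or_history, ColonyState):
        return [render_state(state_or_history, colour_by, output_path)]
    history = state_or_history
    output_path = Path(output_path)
    stem, suffix = output_path.stem, output_path.suffix or ".png"
    written = []
    for k, snap in enumerate(history.snapshots):
        frame = output_path.with_name(f"{stem}_{k:04d}{suffix}")
        written.append(render_state(snap, colour_by, frame))
    return written
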