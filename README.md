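# colonypress

Agent-based simulation of **pressure-dependent growth** in early
microcolonies of rod-shaped bacteria (e.g. *Pseudomonas putida* on an
agarose pad), for microbial biophysicists who want to test how far pure
mechanics goes in explaining 3D colony architecture.

Cells are 2D capsules that elongate stochastically from both poles and
divide with angle noise. The only coupling between cells is collision:
a position-based solver with a fixed per-step iteration budget *B*
resolves overlaps, and the overlap it cannot remove in time — the
per-cell **residual penetration** P — is the pressure signal. Growth is
delayed, never cancelled, by the factor

    f(P) = max(f_min, 1 − (1 − f_min) · (P − P_delay)/P_delay),   f(P ≤ P_delay) = 1

and a cell whose signal stays above a threshold while the solver fails to
move it sideways climbs onto the next discrete z-layer. That single
mechanism reproduces, with no nutrients or gene regulation:

* pyramid-shaped vertical cross-sections with a 1-cell-deep outer ring,
* discrete layer plateaus at ~2x and ~3x the monolayer height at the
  colony edge, but gradual height increments at the centre,
* radial gradients of cell age and pressure (old, squeezed centre),
* monolayer break times ordered by surface stiffness (the solver budget
  is the mobility proxy: soft agar B=500, standard 60, stiff 12),
* centre-before-intersection second-layer formation when two colonies
  merge.

## Worked example

```python
from colonypress import engine, metrics

history = engine.run(engine.vertical_section_config(seed=1, max_cells=400))
profile = metrics.section_profile(history.final, bin_width=1.0)
ratios, gradual = metrics.layer_ratios(profile)
print(f"monolayer reference: {profile.reference:.2f} um")
print({k: round(v, 2) for k, v in ratios.items()})
print(f"apex / monolayer: {profile.heights.max() / profile.reference:.1f}")
```

prints (seed 1):

```
monolayer reference: 1.00 um
{1: 1.0, 2: 1.98, 3: 3.0, 4: 4.05, 5: 5.02, 6: 6.0, 7: 7.19, 8: 8.05, 9: 9.08, 10: 10.06, 11: 11.03, 12: 11.86}
apex / monolayer: 11.9
```

The periphery of the simulated cross-section is an exact staircase of
1-, 2-, 3-cell-deep plateaus (height ratios 1, 2, 3 relative to the
single-cell reference), while the centre piles up gradually to an apex
many cell diameters high — the pyramid a confocal vertical section shows.

From the shell, the same run plus a rendering and tidy CSV outputs:

```bash
colonypress run --mode vertical_section --seed 1 --max-cells 400 \
    --out-dir out --render-by pressure
colonypress sweep --preset soft --preset standard --preset stiff \
    --seeds 10 --metric break_time --out sweep.csv
```

## Layout

| module | contents |
|---|---|
| `colonypress.geometry` | capsule bodies, segment-distance primitive |
| `colonypress.physics` | spatial-grid contact detection, budgeted positional solver, gravity settling |
| `colonypress.cells` | growth law, pressure-delayed elongation, division |
| `colonypress.layering` | layer eligibility, promotion rule, height maps, outer ring |
| `colonypress.engine` | simulation loop, presets, determinism, two-colony merge |
| `colonypress.metrics` | section profiles, layer ratios, discreteness, radial profiles, break time |
| `colonypress.io` / `cli` / `render` / `fixtures` | YAML configs, CSV snapshots, click CLI, matplotlib views, synthetic test states |

See `docs/methods.md` for the model description, parameter table and
limitations.
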