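"""Colony morphometrics.

Quantifies simulated colonies the way confocal sections and surface maps
quantify real ones: height profiles along a measuring line, discrete
layer-height ratios against the peripheral monolayer reference, the
step-like vs gradual character of layer transitions, radial profiles of
age/pressure/layer, monolayer break times and the age-pressure rank
correlation.  All functions are pure: they never mutate the state or
history they are given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .state import MODE_VERTICAL, ColonyState, top_envelope, top_layer_at_points


@dataclass
class SectionProfile:
    """Binned height along a measuring line through the colony."""

    positions: np.ndarray   # bin centres along the line (um)
    heights: np.ndarray     # height per bin (um), >= 0
    reference: float        # monolayer reference height (um)
    diameter: float         # cell diameter (um)
    mode: str
    empty: bool = False     # line missed the colony


@dataclass
class RadialProfile:
    """Per-annulus means of a cell quantity over normalised radius [0, 1]."""

    edges: np.ndarray       # bin edges, normalised radius
    means: np.ndarray       # nan where the annulus is empty
    counts: np.ndarray
    quantity: str


def _modal_reference(heights: np.ndarray, occupied: np.ndarray,
                     resolution: float = 0.05) -> float:
    """Monolayer reference: modal height of the outer 15% of occupied bins.

    The mode is taken per flank and the smaller flank wins, so a colony
    whose one edge has already doubled still references the true
    single-cell height of the other.
    """
    occ_idx = np.nonzero(occupied)[0]
    k = max(1, int(round(0.15 * occ_idx.size)))
    modes = []
    for outer in (occ_idx[:k], occ_idx[-k:]):
        vals = np.round(heights[outer] / resolution) * resolution
        uniq, counts = np.unique(vals, return_counts=True)
        modes.append(float(uniq[np.argmax(counts)]))
    return min(modes)


def section_profile(state: ColonyState, line=None, bin_width: float = 0.5) -> SectionProfile:
    """Height profile along a measuring line.

    Vertical-section mode: the line is the substrate axis and height is
    the top envelope of the capsule outlines.  Top-down mode: the line
    runs through the colony centroid (at angle ``line``, default 0) and
    height is (covering layer count) x cell diameter.  The monolayer
    reference is the modal height of the outer 15% of occupied bins —
    the periphery serves as the 1-cell-deep yardstick.
    """
    diam = state.diameter
    if state.n == 0:
        return SectionProfile(np.zeros(0), np.zeros(0), 0.0, diam, state.mode, True)
    if state.mode == MODE_VERTICAL:
        reach = state.half_length + state.radius
        lo = float((state.pos[:, 0] - reach).min())
        hi = float((state.pos[:, 0] + reach).max())
        xs = np.arange(lo, hi + bin_width, bin_width)
        heights = top_envelope(state, xs)
        positions = xs
    else:
        angle = 0.0 if line is None else float(line)
        u = np.array([np.cos(angle), np.sin(angle)])
        half_span = state.colony_radius + state.lengths.max()
        ts = np.arange(-half_span, half_span + bin_width, bin_width)
        pts = state.centroid + ts[:, None] * u
        heights = top_layer_at_points(state, pts) * diam
        positions = ts
    occupied = heights > 0
    if not occupied.any():
        warnings.warn("measuring line misses the colony; all-zero profile")
        return SectionProfile(positions, heights, 0.0, diam, state.mode, True)
    ref = _modal_reference(heights, occupied)
    return SectionProfile(positions, heights, ref, diam, state.mode)


def layer_ratios(profile: SectionProfile, tolerance_diameters: float = 0.25):
    """Median height ratio of each discrete layer plateau vs the monolayer.

    Occupied bins whose height lies within ``tolerance_diameters`` cell
    diameters of an integer multiple k of the reference are assigned to
    layer k; the ratio for layer k is the median of their heights divided
    by the reference.  Bins that fit no integer level are the *gradual*
    part of the colony (the pyramid core); their share of occupied bins is
    returned as ``gradual_fraction``.
    """
    heights = profile.heights[profile.heights > 0]
    if heights.size == 0 or profile.reference <= 0:
        return {}, 1.0
    k = np.maximum(np.round(heights / profile.reference).astype(int), 1)
    discrete = np.abs(heights - k * profile.reference) <= \
        tolerance_diameters * profile.diameter
    ratios = {}
    for level in np.unique(k[discrete]):
        sel = discrete & (k == level)
        ratios[int(level)] = float(np.median(heights[sel]) / profile.reference)
    gradual_fraction = 1.0 - discrete.mean()
    return ratios, float(gradual_fraction)


def transition_discreteness(profile: SectionProfile, region: str = "peripheral",
                            jump_diameters: float = 0.8, despeckle: int = 5):
    """Fraction of step-like height transitions in a profile region.

    ``region`` is 'peripheral' (outer 30% of occupied bins, both ends) or
    'central' (middle 30%).  Among all non-zero adjacent-bin height
    changes in the region, the fraction with magnitude >= 0.8 cell
    diameters counts as discrete jumps.  A ``despeckle``-bin median filter
    removes single-cell surface bumps first, so the statistic reflects
    plateau structure rather than envelope roughness (plateaus and linear
    ramps wider than the filter pass through unchanged).  Returns nan
    (with a warning) if fewer than 3 non-zero changes exist.
    """
    occ_idx = np.nonzero(profile.heights > 0)[0]
    if occ_idx.size < 4:
        warnings.warn("too few occupied bins for discreteness")
        return float("nan")
    h = profile.heights[occ_idx]
    if despeckle > 1:
        h = ndimage.median_filter(h, size=despeckle, mode="nearest")
    m = occ_idx.size
    k = max(2, int(round(0.3 * m)))
    if region == "peripheral":
        changes = np.concatenate([np.diff(h[:k]), np.diff(h[-k:])])
    elif region == "central":
        mid = m // 2
        half = max(1, k // 2)
        changes = np.diff(h[max(0, mid - half): mid + half])
    else:
        raise ValueError("region must be 'peripheral' or 'central'")
    nz = np.abs(changes) > 1e-9
    if nz.sum() < 3:
        warnings.warn("fewer than 3 non-zero height changes; undefined")
        return float("nan")
    jumps = np.abs(changes[nz]) >= jump_diameters * profile.diameter
    return float(jumps.mean())


def radial_profile(state: ColonyState, quantity: str = "age",
                   n_bins: int = 8) -> RadialProfile:
    """Per-annulus mean of a cell quantity vs normalised colony radius.

    ``quantity``: 'age' (current interdivision age, steps), 'pressure'
    (um), 'layer', or 'generation'.  Radii are normalised by the colony
    radius; empty annuli are flagged as nan, never interpolated.
    """
    if state.n < 50:
        warnings.warn("radial_profile on a small colony (< 50 cells)")
    values = {
        "age": state.ages.astype(float),
        "pressure": state.pressure,
        "layer": state.layer.astype(float),
        "generation": state.generation.astype(float),
    }[quantity]
    radius = state.colony_radius
    if radius <= 0:
        warnings.warn("degenerate colony; radial profile undefined")
        edges = np.linspace(0, 1, n_bins + 1)
        return RadialProfile(edges, np.full(n_bins, np.nan),
                             np.zeros(n_bins, int), quantity)
    r_norm = np.linalg.norm(state.pos - state.centroid, axis=1) / radius
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(r_norm, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(edges, means, counts, quantity)


def break_time(history):
    """Step at which the monolayer first breaks, or None if it never does.

    Top-down mode: the first promotion event.  Vertical-section mode: the
    first step at which any centroid rises above 1.5 cell diameters (a
    cell resting on another, not on the substrate).
    """
    promos = history.promotion_steps()
    if promos:
        return min(promos)
    return history.first_offground_step


def age_pressure_association(state: ColonyState) -> float:
    """Spearman rank correlation between interdivision age and pressure.

    Trapped central cells are both older (delayed growth) and under more
    pressure, so the delay mechanism predicts a positive association.
    Returns nan (with a warning) when either quantity is constant.
    """
    if state.n < 50:
        warnings.warn("age_pressure_association on a small colony (< 50 cells)")
    ages = state.ages.astype(float)
    press = state.pressure
    if np.ptp(ages) == 0 or np.ptp(press) == 0:
        warnings.warn("constant age or pressure vector; correlation undefined")
        return float("nan")
    rho = stats.spearmanr(ages, press).statistic
    return float(rho)
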