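"""Contact detection and budget-limited positional overlap resolution.

Cells are rigid 2D capsules.  Overlaps are resolved with a quasi-static
position-based (projection) scheme: each solver iteration detects all
penetrating pairs and translates the two bodies apart along the contact
normal by ``beta * penetration / 2`` each, with a small angular correction
proportional to the torque of the correction about the body centre.

The solver is given a fixed iteration *budget* per simulation step.  When
cell growth outruns the budget, penetrations remain at budget exhaustion;
that per-cell summed *residual penetration* is the mechanical pressure
signal used by the growth model.  A budget of 0 is pure measurement mode:
contacts are reported and nothing moves.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .geometry import TWO_PI, CellBody, segment_closest_points

#: Penetrations below this depth (um) count as resolved.
CONTACT_TOLERANCE = 1e-4

#: Default under-relaxation factor for positional corrections.
DEFAULT_BETA = 0.5

#: Angular correction per unit lever-weighted correction (rad per um^2).
ANGULAR_COMPLIANCE = 0.1


@dataclass
class Contact:
    """One pairwise overlap between two capsules."""

    id_a: int
    id_b: int
    penetration: float
    normal: np.ndarray  # unit vector pointing from b toward a
    point: np.ndarray   # contact location (um)


@dataclass
class SolverReport:
    """Outcome of a budgeted collision solve.

    ``residual_by_cell`` maps cell id to the summed penetration depth that
    the solver could not remove within its budget (0 for cells with no
    unresolved contact); this is the raw pressure reading.
    """

    residual_by_cell: dict = field(default_factory=dict)
    contacts_by_cell: dict = field(default_factory=dict)
    iterations_used: int = 0


# ---------------------------------------------------------------------------
# Broadphase: uniform spatial grid
# ---------------------------------------------------------------------------

def broadphase_pairs(pos, ang, hl, rad, margin=0.5, layer=None):
    """Candidate contact pairs from a uniform spatial grid.

    The grid cell size is the largest body reach (max cell length plus two
    radii) plus ``margin``, which guarantees any touching pair falls in the
    same or an adjacent grid cell.  Returns ``(i, j)`` index arrays with
    ``i < j``.  If ``layer`` is given, only same-layer pairs are kept
    (cells on different z-layers pass freely over one another).
    """
    n = pos.shape[0]
    if n < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    reach = hl + rad
    cell_size = float(2.0 * reach.max() + margin)
    keys = np.floor(pos / cell_size).astype(np.int64)
    grid = defaultdict(list)
    for idx in range(n):
        grid[(keys[idx, 0], keys[idx, 1])].append(idx)

    ii, jj = [], []
    half_stencil = ((0, 0), (1, 0), (0, 1), (1, 1), (1, -1))
    for (kx, ky), members in grid.items():
        for ox, oy in half_stencil:
            if ox == 0 and oy == 0:
                for a in range(len(members)):
                    for b in range(a + 1, len(members)):
                        ii.append(members[a])
                        jj.append(members[b])
            else:
                other = grid.get((kx + ox, ky + oy))
                if other:
                    for a in members:
                        for b in other:
                            ii.append(a)
                            jj.append(b)
    if not ii:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ii = np.asarray(ii, np.int64)
    jj = np.asarray(jj, np.int64)
    swap = ii > jj
    ii2 = np.where(swap, jj, ii)
    jj2 = np.where(swap, ii, jj)
    ii, jj = ii2, jj2

    # Prune pairs that cannot touch even at full extension.
    d = pos[ii] - pos[jj]
    limit = reach[ii] + reach[jj] + margin
    keep = np.einsum("ij,ij->i", d, d) <= limit * limit
    ii, jj = ii[keep], jj[keep]
    if layer is not None:
        keep = layer[ii] == layer[jj]
        ii, jj = ii[keep], jj[keep]
    return ii, jj


# ---------------------------------------------------------------------------
# Narrowphase + solver kernel (numba)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _seg_cp(p1x, p1y, q1x, q1y, p2x, p2y, q2x, q2y):
    """Closest points between two segments (scalar, numba)."""
    d1x = q1x - p1x
    d1y = q1y - p1y
    d2x = q2x - p2x
    d2y = q2y - p2y
    rx = p1x - p2x
    ry = p1y - p2y
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    f = d2x * rx + d2y * ry
    eps = 1e-12
    if a <= eps and e <= eps:
        s = 0.0
        t = 0.0
    elif a <= eps:
        s = 0.0
        t = min(max(f / e, 0.0), 1.0)
    else:
        c = d1x * rx + d1y * ry
        if e <= eps:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = d1x * d2x + d1y * d2y
            denom = a * e - b * b
            if denom > eps:
                s = min(max((b * f - c * e) / denom, 0.0), 1.0)
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)
    c1x = p1x + s * d1x
    c1y = p1y + s * d1y
    c2x = p2x + t * d2x
    c2y = p2y + t * d2y
    dx = c1x - c2x
    dy = c1y - c2y
    return math.sqrt(dx * dx + dy * dy), c1x, c1y, c2x, c2y


@njit(cache=True, fastmath=False)
def _solve_kernel(pos, ang, hl, rad, pi, pj, budget, beta, ang_k, tol, ground):
    """Budgeted projection solve.  Mutates pos/ang in place.

    Returns ``(iterations_used, pen_pairs, ground_pen)`` where
    ``pen_pairs`` holds the residual penetration of every candidate pair
    after the last iteration and ``ground_pen`` the residual ground-plane
    penetration per body (vertical mode only).
    """
    n = pos.shape[0]
    m = pi.shape[0]
    iterations = 0
    for _ in range(budget):
        dpx = np.zeros(n)
        dpy = np.zeros(n)
        da = np.zeros(n)
        maxpen = 0.0
        for k in range(m):
            i = pi[k]
            j = pj[k]
            uix = math.cos(ang[i]) * hl[i]
            uiy = math.sin(ang[i]) * hl[i]
            ujx = math.cos(ang[j]) * hl[j]
            ujy = math.sin(ang[j]) * hl[j]
            dist, c1x, c1y, c2x, c2y = _seg_cp(
                pos[i, 0] - uix, pos[i, 1] - uiy, pos[i, 0] + uix, pos[i, 1] + uiy,
                pos[j, 0] - ujx, pos[j, 1] - ujy, pos[j, 0] + ujx, pos[j, 1] + ujy,
            )
            pen = rad[i] + rad[j] - dist
            if pen > 0.0:
                if pen > maxpen:
                    maxpen = pen
                if dist > 1e-9:
                    nx = (c1x - c2x) / dist
                    ny = (c1y - c2y) / dist
                else:
                    nx = pos[i, 0] - pos[j, 0]
                    ny = pos[i, 1] - pos[j, 1]
                    dn = math.sqrt(nx * nx + ny * ny)
                    if dn > 1e-9:
                        nx /= dn
                        ny /= dn
                    else:
                        nx = -math.sin(ang[i])
                        ny = math.cos(ang[i])
                corr = 0.5 * beta * pen
                dpx[i] += corr * nx
                dpy[i] += corr * ny
                dpx[j] -= corr * nx
                dpy[j] -= corr * ny
                px = 0.5 * (c1x + c2x)
                py = 0.5 * (c1y + c2y)
                lx = px - pos[i, 0]
                ly = py - pos[i, 1]
                da[i] += ang_k * (lx * corr * ny - ly * corr * nx)
                lx = px - pos[j, 0]
                ly = py - pos[j, 1]
                da[j] += ang_k * (-lx * corr * ny + ly * corr * nx)
        if ground:
            for i in range(n):
                sa = math.sin(ang[i])
                zlow = pos[i, 1] - (hl[i] * abs(sa) + rad[i])
                if zlow < 0.0:
                    pen = -zlow
                    if pen > maxpen:
                        maxpen = pen
                    corr = beta * pen
                    dpy[i] += corr
                    # Torque about the centroid from the push at the lower
                    # axis endpoint flattens tilted cells onto the substrate.
                    s = -1.0 if sa > 0.0 else 1.0
                    da[i] += ang_k * (s * hl[i] * math.cos(ang[i]) * corr)
        if maxpen < tol:
            break
        iterations += 1
        for i in range(n):
            pos[i, 0] += dpx[i]
            pos[i, 1] += dpy[i]
            ang[i] += da[i]

    # Measurement pass: residual penetrations after budget exhaustion.
    pen_pairs = np.zeros(m)
    for k in range(m):
        i = pi[k]
        j = pj[k]
        uix = math.cos(ang[i]) * hl[i]
        uiy = math.sin(ang[i]) * hl[i]
        ujx = math.cos(ang[j]) * hl[j]
        ujy = math.sin(ang[j]) * hl[j]
        dist, _, _, _, _ = _seg_cp(
            pos[i, 0] - uix, pos[i, 1] - uiy, pos[i, 0] + uix, pos[i, 1] + uiy,
            pos[j, 0] - ujx, pos[j, 1] - ujy, pos[j, 0] + ujx, pos[j, 1] + ujy,
        )
        pen = rad[i] + rad[j] - dist
        if pen > 0.0:
            pen_pairs[k] = pen
    ground_pen = np.zeros(n)
    if ground:
        for i in range(n):
            zlow = pos[i, 1] - (hl[i] * abs(math.sin(ang[i])) + rad[i])
            if zlow < 0.0:
                ground_pen[i] = -zlow
    return iterations, pen_pairs, ground_pen


# ---------------------------------------------------------------------------
# Object-level API
# ---------------------------------------------------------------------------

def _bodies_to_arrays(bodies):
    n = len(bodies)
    pos = np.empty((n, 2))
    ang = np.empty(n)
    hl = np.empty(n)
    rad = np.empty(n)
    for k, b in enumerate(bodies):
        pos[k] = b.centroid
        ang[k] = b.angle
        hl[k] = b.half_length
        rad[k] = b.radius
    return pos, ang, hl, rad


def detect_contacts(bodies, ids=None, pair_filter=None, margin=0.5):
    """All penetrating capsule pairs, one :class:`Contact` per pair.

    ``pair_filter(id_a, id_b)`` restricts eligibility (e.g. same-layer
    collision in top-down mode).  Candidate pairs come from a uniform
    spatial grid, so cost is near-linear in cell count at bounded density.
    """
    if ids is None:
        ids = list(range(len(bodies)))
    if len(bodies) < 2:
        return []
    pos, ang, hl, rad = _bodies_to_arrays(bodies)
    ii, jj = broadphase_pairs(pos, ang, hl, rad, margin=margin)
    contacts = []
    if ii.size == 0:
        return contacts
    u = np.stack([np.cos(ang), np.sin(ang)], axis=1) * hl[:, None]
    dist, c1, c2 = segment_closest_points(
        pos[ii] - u[ii], pos[ii] + u[ii], pos[jj] - u[jj], pos[jj] + u[jj]
    )
    pen = rad[ii] + rad[jj] - dist
    for k in np.nonzero(pen > 0)[0]:
        a, b = int(ii[k]), int(jj[k])
        if pair_filter is not None and not pair_filter(ids[a], ids[b]):
            continue
        if dist[k] > 1e-9:
            normal = (c1[k] - c2[k]) / dist[k]
        else:
            delta = pos[a] - pos[b]
            nrm = np.linalg.norm(delta)
            if nrm > 1e-9:
                normal = delta / nrm
            else:
                normal = np.array([-np.sin(ang[a]), np.cos(ang[a])])
        contacts.append(
            Contact(ids[a], ids[b], float(pen[k]), normal, 0.5 * (c1[k] + c2[k]))
        )
    return contacts


def resolve_step(bodies, contacts, beta=DEFAULT_BETA, angular_compliance=ANGULAR_COMPLIANCE,
                 ids=None, apply=True):
    """One projection pass over ``contacts``.

    Each contact translates its two bodies apart along the contact normal
    by ``beta * penetration / 2`` apiece and adds an angular correction
    ``angular_compliance * cross(lever, correction)``.  Corrections from
    multiple contacts accumulate additively.  Returns ``(dpos, dangle)``
    arrays; bodies are updated in place unless ``apply=False``.
    """
    if ids is None:
        ids = list(range(len(bodies)))
    index = {cid: k for k, cid in enumerate(ids)}
    dpos = np.zeros((len(bodies), 2))
    dang = np.zeros(len(bodies))
    for c in contacts:
        a = index[c.id_a]
        b = index[c.id_b]
        corr = 0.5 * beta * c.penetration * c.normal
        dpos[a] += corr
        dpos[b] -= corr
        lever_a = c.point - bodies[a].centroid
        dang[a] += angular_compliance * float(lever_a[0] * corr[1] - lever_a[1] * corr[0])
        lever_b = c.point - bodies[b].centroid
        dang[b] += angular_compliance * float(-lever_b[0] * corr[1] + lever_b[1] * corr[0])
    if apply:
        for k, body in enumerate(bodies):
            body.centroid = body.centroid + dpos[k]
            body.angle = (body.angle + dang[k]) % TWO_PI
    return dpos, dang


def solve_collisions(bodies, budget, beta=DEFAULT_BETA, pair_filter=None,
                     ids=None, ground=False, tol=CONTACT_TOLERANCE,
                     angular_compliance=ANGULAR_COMPLIANCE, margin=0.5):
    """Iterate detect/resolve up to ``budget`` times; report residuals.

    Stops early once the deepest penetration drops below ``tol``.  With
    ``budget=0`` nothing moves (measurement mode) and the report carries
    the initial penetrations.  Bodies are mutated in place.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    if ids is None:
        ids = list(range(len(bodies)))
    report = SolverReport(
        residual_by_cell={cid: 0.0 for cid in ids},
        contacts_by_cell={cid: 0 for cid in ids},
        iterations_used=0,
    )
    if not bodies:
        return report
    pos, ang, hl, rad = _bodies_to_arrays(bodies)
    ii, jj = broadphase_pairs(pos, ang, hl, rad, margin=margin)
    if pair_filter is not None and ii.size:
        keep = np.fromiter(
            (pair_filter(ids[a], ids[b]) for a, b in zip(ii, jj)),
            dtype=bool, count=ii.size,
        )
        ii, jj = ii[keep], jj[keep]
    iters, pen_pairs, ground_pen = _solve_kernel(
        pos, ang, hl, rad, ii, jj, budget, beta, angular_compliance, tol, ground
    )
    report.iterations_used = int(iters)
    for k in range(ii.size):
        if pen_pairs[k] > 0.0:
            for idx in (int(ii[k]), int(jj[k])):
                report.residual_by_cell[ids[idx]] += float(pen_pairs[k])
                report.contacts_by_cell[ids[idx]] += 1
    if ground:
        for idx in range(len(bodies)):
            if ground_pen[idx] > 0.0:
                report.residual_by_cell[ids[idx]] += float(ground_pen[idx])
                report.contacts_by_cell[ids[idx]] += 1
    for k, body in enumerate(bodies):
        body.centroid = pos[k]
        body.angle = float(ang[k]) % TWO_PI
    return report


def settle_gravity(bodies, ground_level=0.0, step=0.1, budget=50,
                   beta=DEFAULT_BETA, tol=CONTACT_TOLERANCE,
                   angular_compliance=ANGULAR_COMPLIANCE):
    """Quasi-static gravity: drop every body by ``step``, then re-resolve.

    No velocities or inertia; colonies grow slowly enough that settling is
    a sequence of static rest states.  After resolution no body's lowest
    point lies below the ground plane (within the contact tolerance).
    Returns the :class:`SolverReport` of the post-drop resolution.
    """
    for body in bodies:
        body.centroid = body.centroid - np.array([0.0, step])
        if ground_level != 0.0:
            body.centroid[1] -= ground_level
    report = solve_collisions(bodies, budget, beta=beta, ground=True, tol=tol,
                              angular_compliance=angular_compliance)
    if ground_level != 0.0:
        for body in bodies:
            body.centroid[1] += ground_level
    return report
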