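"""Contact detection and the budgeted positional solver."""

import numpy as np
import pytest

from colonypress.fixtures import packed_cluster
from colonypress.geometry import CellBody, segment_closest_points
from colonypress.physics import (detect_contacts, resolve_step, settle_gravity,
                                 solve_collisions)


def random_bodies(rng, n, box=10.0):
    return [
        CellBody(rng.uniform(0, box, 2), rng.uniform(0, 2 * np.pi),
                 rng.uniform(0.0, 1.5), rng.uniform(0.3, 0.6))
        for _ in range(n)
    ]


def all_pairs_contacts(bodies):
    """O(n^2) oracle: every overlapping unordered pair."""
    out = set()
    for i in range(len(bodies)):
        for j in range(i + 1, len(bodies)):
            a, b = bodies[i], bodies[j]
            d, _, _ = segment_closest_points(*a.endpoints, *b.endpoints)
            if a.radius + b.radius - d[0] > 0:
                out.add((i, j))
    return out


def test_separated_parallel_capsules_no_contact():
    bodies = [CellBody(np.array([0.0, 0.0]), 0.0, 1.0, 0.4),
              CellBody(np.array([0.0, 2.0]), 0.0, 1.0, 0.4)]
    assert detect_contacts(bodies) == []


def test_coincident_capsules_penetration_is_radius_sum():
    bodies = [CellBody(np.array([0.0, 0.0]), 0.0, 1.0, 0.4),
              CellBody(np.array([0.0, 0.0]), 0.0, 1.0, 0.4)]
    contacts = detect_contacts(bodies)
    assert len(contacts) == 1
    assert contacts[0].penetration == pytest.approx(0.8)
    assert np.linalg.norm(contacts[0].normal) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_grid_broadphase_matches_all_pairs_oracle(seed, rng):
    rng = np.random.default_rng(seed)
    bodies = random_bodies(rng, 50)
    found = {(c.id_a, c.id_b) for c in detect_contacts(bodies)}
    assert found == all_pairs_contacts(bodies)


def test_contact_normals_are_unit_and_penetrations_consistent(rng):
    bodies = random_bodies(rng, 40)
    for c in detect_contacts(bodies):
        assert np.linalg.norm(c.normal) == pytest.approx(1.0, abs=1e-9)
        a, b = bodies[c.id_a], bodies[c.id_b]
        d, _, _ = segment_closest_points(*a.endpoints, *b.endpoints)
        assert c.penetration == pytest.approx(a.radius + b.radius - d[0], abs=1e-9)


def test_resolve_step_splits_penetration_symmetrically():
    bodies = [CellBody(np.array([0.0, 0.0]), 0.0, 0.0, 0.5),
              CellBody(np.array([0.8, 0.0]), 0.0, 0.0, 0.5)]
    contacts = detect_contacts(bodies)
    assert contacts[0].penetration == pytest.approx(0.2)
    dpos, _ = resolve_step(bodies, contacts, beta=1.0)
    assert np.linalg.norm(dpos[0]) == pytest.approx(0.1)
    assert np.linalg.norm(dpos[1]) == pytest.approx(0.1)
    np.testing.assert_allclose(dpos[0], -dpos[1], atol=1e-12)


def test_resolve_step_no_contacts_is_noop():
    bodies = [CellBody(np.array([0.0, 0.0]), 0.0, 1.0, 0.4)]
    dpos, dang = resolve_step(bodies, [], beta=1.0)
    assert not dpos.any() and not dang.any()


def test_mirror_squeeze_leaves_residual_without_lateral_motion():
    # middle disc squeezed by two mirror-image neighbours cannot translate
    bodies = [CellBody(np.array([-0.9, 0.0]), 0.0, 0.0, 0.5),
              CellBody(np.array([0.0, 0.0]), 0.0, 0.0, 0.5),
              CellBody(np.array([0.9, 0.0]), 0.0, 0.0, 0.5)]
    before = bodies[1].centroid.copy()
    report = solve_collisions(bodies, budget=3, beta=0.5)
    assert bodies[1].centroid[0] == pytest.approx(before[0], abs=1e-12)
    assert report.residual_by_cell[1] > 0.0


def test_free_pair_fully_separates_within_budget():
    bodies = [CellBody(np.array([0.0, 0.0]), 0.0, 1.0, 0.4),
              CellBody(np.array([0.5, 0.1]), 0.2, 1.0, 0.4)]
    report = solve_collisions(bodies, budget=50)
    assert max(report.residual_by_cell.values()) < 1e-3
    assert report.iterations_used <= 50


def test_budget_zero_is_measurement_mode():
    bodies = [CellBody(np.array([0.0, 0.0]), 0.0, 1.0, 0.4),
              CellBody(np.array([0.3, 0.0]), 0.0, 1.0, 0.4)]
    pen0 = detect_contacts(bodies)[0].penetration
    before = [b.centroid.copy() for b in bodies]
    report = solve_collisions(bodies, budget=0)
    assert report.iterations_used == 0
    for b, c in zip(bodies, before):
        np.testing.assert_allclose(b.centroid, c)
    assert report.residual_by_cell[0] == pytest.approx(pen0)


def test_compressed_cluster_centre_keeps_largest_residual():
    bodies = packed_cluster(19, compression=0.05)
    d0 = [np.linalg.norm(b.centroid) for b in bodies]
    centre, corner = int(np.argmin(d0)), int(np.argmax(d0))
    report = solve_collisions(bodies, budget=10)
    assert report.residual_by_cell[centre] > report.residual_by_cell[corner]


def test_solver_idempotent_on_contact_free_configuration():
    bodies = [CellBody(np.array([3.0 * i, 0.0]), 0.0, 1.0, 0.4) for i in range(5)]
    before = [b.centroid.copy() for b in bodies]
    report = solve_collisions(bodies, budget=100)
    assert all(v == 0.0 for v in report.residual_by_cell.values())
    for b, c in zip(bodies, before):
        np.testing.assert_allclose(b.centroid, c)


def test_displacement_bounded_by_budget_beta_penetration():
    bodies = packed_cluster(19, compression=0.05)
    pen0 = max(c.penetration for c in detect_contacts(bodies))
    before = np.array([b.centroid for b in bodies])
    budget, beta = 10, 0.5
    solve_collisions(bodies, budget=budget, beta=beta)
    moved = np.linalg.norm(np.array([b.centroid for b in bodies]) - before, axis=1)
    assert moved.max() <= budget * beta * pen0 + 1e-9


def test_residuals_nonnegative_and_zero_iff_no_contact(rng):
    bodies = random_bodies(rng, 30)
    report = solve_collisions(bodies, budget=5)
    contacts = detect_contacts(bodies)
    touched = set()
    for c in contacts:
        touched.update((c.id_a, c.id_b))
    for cid, res in report.residual_by_cell.items():
        assert res >= 0.0
        if res == 0.0:
            assert cid not in touched
        else:
            assert cid in touched


def test_settle_single_cell_rests_on_ground():
    bodies = [CellBody(np.array([0.0, 3.0]), 0.0, 1.0, 0.4)]
    for _ in range(40):
        settle_gravity(bodies, step=0.1)
    assert bodies[0].centroid[1] == pytest.approx(0.4, abs=1e-3)
    assert bodies[0].lowest_point() >= -1e-3


def test_settle_stacks_second_cell_on_first():
    bodies = [CellBody(np.array([0.0, 0.4]), 0.0, 1.0, 0.4),
              CellBody(np.array([0.0, 2.5]), 0.0, 1.0, 0.4)]
    for _ in range(40):
        settle_gravity(bodies, step=0.1)
    assert bodies[1].centroid[1] == pytest.approx(3 * 0.4, abs=0.1)
    assert bodies[0].centroid[1] == pytest.approx(0.4, abs=0.05)


def test_settle_empty_list_noop():
    assert settle_gravity([], step=0.1).residual_by_cell == {}
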