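"""Kinematic closure: sub-segment choice, bond angles, solver, bump check."""

import numpy as np
import pytest

from conftest import random_move
from kicloop.closure import (
    ATOM_RADII,
    BOND_ANGLE_MAX,
    BOND_ANGLE_MIN,
    KicMove,
    apply_move,
    bump_filter,
    choose_subsegment,
    sample_bond_angles,
    solve_closure,
)
from kicloop.geometry import (
    SegmentDefinition,
    bond_angle,
    build_coordinates,
    measure_internal,
    new_pose,
    normalize_angle,
)


class TestChooseSubsegment:
    def test_minimal_segment_is_forced(self):
        seg = SegmentDefinition(10, 12)
        mv = choose_subsegment(seg, np.random.default_rng(0))
        assert (mv.sub_start, mv.sub_end) == (10, 12)
        assert mv.pivots == (10, 11, 12)

    def test_pairs_are_uniform(self):
        seg = SegmentDefinition(1, 12)
        rng = np.random.default_rng(42)
        n_pairs = 55  # (start, end) pairs of length >= 3 in a 12-residue segment
        draws = 10 ** 5
        counts = {}
        for _ in range(draws):
            mv = choose_subsegment(seg, rng)
            counts[(mv.sub_start, mv.sub_end)] = counts.get(
                (mv.sub_start, mv.sub_end), 0) + 1
        assert len(counts) == n_pairs
        p = 1.0 / n_pairs
        se = np.sqrt(p * (1 - p) / draws)
        for c in counts.values():
            assert abs(c / draws - p) < 3 * se + 1e-12

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            KicMove(sub_start=5, sub_end=6)

    def test_even_length_middle_pivot_is_floor_midpoint(self):
        assert KicMove(sub_start=4, sub_end=9).pivots == (4, 6, 9)


class TestBondAngles:
    def test_varied_moments_match_uniform_distribution(self):
        rng = np.random.default_rng(0)
        mv = sample_bond_angles(KicMove(sub_start=1, sub_end=10 ** 6),
                                "varied", rng)
        draws = mv.theta
        assert draws.min() >= BOND_ANGLE_MIN
        assert draws.max() <= BOND_ANGLE_MAX
        width = BOND_ANGLE_MAX - BOND_ANGLE_MIN
        se = width / np.sqrt(12 * len(draws))
        assert abs(draws.mean() - (BOND_ANGLE_MIN + BOND_ANGLE_MAX) / 2) \
            < 3 * se

    def test_sampling_window_width(self):
        # the published variation is 2.48 degrees around the mean
        assert BOND_ANGLE_MAX - BOND_ANGLE_MIN == pytest.approx(2.48)

    def test_idealized_mode_has_zero_variance(self):
        mv = sample_bond_angles(KicMove(sub_start=1, sub_end=5), "idealized",
                                np.random.default_rng(0))
        assert np.ptp(mv.theta) == 0.0


class TestSolveClosure:
    def test_identity_closure_recovers_native_pivots(self, loop_pose):
        mv = KicMove(sub_start=5, sub_end=11)  # keep all internals
        sols = solve_closure(loop_pose, mv)
        assert sols
        s, m, e = mv.pivots
        native = np.array([loop_pose.phi[s - 1], loop_pose.psi[s - 1],
                           loop_pose.phi[m - 1], loop_pose.psi[m - 1],
                           loop_pose.phi[e - 1], loop_pose.psi[e - 1]])
        best = min(np.abs(normalize_angle(sol.pivot_torsions - native)).max()
                   for sol in sols)
        assert best < 1e-6

    def test_solutions_satisfy_pivot_bond_angle_constraints(self, loop_pose,
                                                            loop_segment):
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(100):
            mv = random_move(loop_pose, loop_segment, rng)
            for sol in solve_closure(loop_pose, mv):
                q = apply_move(loop_pose, mv, sol)
                for piv in mv.pivots:
                    i = piv - 1
                    theta = bond_angle(q.coords[i, 0], q.coords[i, 1],
                                       q.coords[i, 2])
                    assert abs(theta - mv.theta[piv - mv.sub_start]) < 1e-6
                checked += 1
        assert checked > 50

    def test_solution_count_bounded_by_polynomial_degree(self, loop_pose,
                                                         loop_segment):
        rng = np.random.default_rng(11)
        counts = [len(solve_closure(loop_pose,
                                    random_move(loop_pose, loop_segment, rng)))
                  for _ in range(300)]
        assert max(counts) <= 16
        assert any(c > 0 for c in counts)

    def test_degenerate_geometry_returns_empty_set(self, loop_pose):
        # impossible bond angles make the pivot triangle unclosable
        mv = KicMove(sub_start=5, sub_end=7)
        mv.phi[:] = 180.0
        mv.psi[:] = 180.0
        mv.omega[:] = 180.0
        mv.theta = np.full(3, 100.0)
        bad = loop_pose.copy()
        bad.coords[7:] += 100.0  # move the downstream anchor out of reach
        assert solve_closure(bad, mv) == []


class TestBumpFilter:
    def test_zero_overlap_factor_keeps_everything(self, loop_pose,
                                                  loop_segment):
        rng = np.random.default_rng(2)
        mv = random_move(loop_pose, loop_segment, rng)
        sols = solve_closure(loop_pose, mv)
        assert bump_filter(loop_pose, mv, sols, overlap_factor=0.0) == sols

    def test_atom_on_environment_sphere_is_rejected(self, loop_pose):
        mv = KicMove(sub_start=5, sub_end=11)
        sols = solve_closure(loop_pose, mv)  # identity closure
        assert sols
        clashed = loop_pose.copy()
        # on the first pivot's CA, which every solution keeps in place
        clashed.env_xyz = loop_pose.coords[4, 1][None, :].copy()
        clashed.env_radius = np.array([1.6])
        assert bump_filter(clashed, mv, sols, overlap_factor=0.01) == []

    def test_survival_threshold_arithmetic(self, loop_pose):
        """A sphere at distance d from one segment atom survives iff
        d^2 >= 0.36 (r1 + r2)^2."""
        mv = KicMove(sub_start=5, sub_end=11)
        sols = solve_closure(loop_pose, mv)
        sol = min(sols, key=lambda s: float(np.abs(normalize_angle(
            s.pivot_torsions[0] - loop_pose.phi[4]))))
        r_env = 1.5
        ca = sol.coords[3, 1]  # CA of residue 8
        all_xyz = loop_pose.coords.copy()
        all_xyz[4:11] = sol.coords
        all_xyz = all_xyz.reshape(-1, 3)
        # outward ray: away from the nearby atoms' centroid
        near = all_xyz[np.linalg.norm(all_xyz - ca, axis=1) < 6.0]
        ray = ca - near.mean(axis=0)
        ray /= np.linalg.norm(ray)
        rsum = ATOM_RADII["C"] + r_env
        for factor, survives in [(1.01, True), (0.99, False)]:
            d = np.sqrt(0.36) * rsum * factor
            pos = ca + d * ray
            # precondition: no atom other than this CA decides the outcome
            others = all_xyz[np.linalg.norm(all_xyz - ca, axis=1) > 1e-9]
            worst = np.linalg.norm(others - pos, axis=1).min()
            assert worst > np.sqrt(0.36) * (1.7 + r_env) * 1.05
            p = loop_pose.copy()
            p.env_xyz = pos[None, :]
            p.env_radius = np.array([r_env])
            kept = bump_filter(p, mv, [sol], overlap_factor=0.36)
            assert (kept == [sol]) is survives


class TestApplyMove:
    def test_locality_outside_subsegment_is_exact(self, loop_pose,
                                                  loop_segment):
        rng = np.random.default_rng(9)
        for _ in range(20):
            mv = random_move(loop_pose, loop_segment, rng)
            sols = solve_closure(loop_pose, mv)
            if not sols:
                continue
            q = apply_move(loop_pose, mv, sols[0])
            outside = [i for i in range(len(loop_pose))
                       if not (mv.sub_start - 1 <= i <= mv.sub_end - 1)]
            assert np.array_equal(q.coords[outside], loop_pose.coords[outside])

    def test_identity_solution_preserves_conformation(self, loop_pose):
        from kicloop.geometry import segment_rmsd

        mv = KicMove(sub_start=5, sub_end=11)
        sols = solve_closure(loop_pose, mv)
        s = mv.pivots[0]
        sol = min(sols, key=lambda x: float(np.abs(normalize_angle(
            x.pivot_torsions[0] - loop_pose.phi[s - 1]))))
        q = apply_move(loop_pose, mv, sol)
        assert segment_rmsd(q, loop_pose, SegmentDefinition(5, 11)) < 1e-6

    def test_chain_stays_closed(self, loop_pose, loop_segment):
        rng = np.random.default_rng(13)
        closed = 0
        for _ in range(30):
            mv = random_move(loop_pose, loop_segment, rng)
            sols = solve_closure(loop_pose, mv)
            if not sols:
                continue
            q = apply_move(loop_pose, mv, sols[int(rng.integers(len(sols)))])
            for i in range(len(q) - 1):
                gap = np.linalg.norm(q.coords[i + 1, 0] - q.coords[i, 2])
                assert abs(gap - q.bond_c_n[i]) < 1e-6
            closed += 1
        assert closed > 10

    def test_determinism_under_fixed_seed(self, loop_pose, loop_segment):
        def run(seed):
            rng = np.random.default_rng(seed)
            mv = random_move(loop_pose, loop_segment, rng)
            sols = solve_closure(loop_pose, mv)
            return mv, sols

        mv1, sols1 = run(21)
        mv2, sols2 = run(21)
        assert (mv1.sub_start, mv1.sub_end) == (mv2.sub_start, mv2.sub_end)
        assert np.array_equal(mv1.phi, mv2.phi)
        assert len(sols1) == len(sols2)
        for a, b in zip(sols1, sols2):
            assert np.array_equal(a.pivot_torsions, b.pivot_torsions)
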