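"""Monte-Carlo protocol: Metropolis, trials, minimisation, trajectories."""

import numpy as np
import pytest

from kicloop.closure import KicMove
from kicloop.energy import EnergyWeights
from kicloop.geometry import SegmentDefinition, segment_rmsd
from kicloop.priors import classify_bin
from kicloop.protocol import (
    ProtocolConfig,
    _minimize,
    _propose,
    kic_trial,
    metropolis_accept,
    minimize_segment,
    run_ensemble,
    run_trajectory,
)
from kicloop.taboo import native_bin_vector
from kicloop.energy import score


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(d, 1.0, rng)
                   for d in (-5.0, -0.1, 0.0))

    def test_half_acceptance_at_kt_ln2(self):
        rng = np.random.default_rng(1)
        kT = 1.3
        n = 10 ** 5
        acc = sum(metropolis_accept(kT * np.log(2.0), kT, rng)
                  for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(acc / n - 0.5) < 3 * se

    def test_huge_barrier_never_accepted(self):
        rng = np.random.default_rng(2)
        assert not any(metropolis_accept(1e4, 1.0, rng) for _ in range(1000))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, np.random.default_rng(0))


class TestProtocolConfig:
    def test_ngk_preset_combines_four_strategies(self):
        cfg = ProtocolConfig.ngk()
        assert (cfg.rama2b, cfg.omega_sampling, cfg.ramp_fa_rep,
                cfg.ramp_rama) == (True,) * 4
        assert not cfg.taboo

    def test_legacy_preset_uses_three_outer_cycles(self):
        cfg = ProtocolConfig.legacy()
        assert cfg.n_outer == 3 and not (cfg.ramp_fa_rep or cfg.ramp_rama)

    def test_taboo_and_torsion_restricted_conflict(self):
        with pytest.raises(ValueError):
            ProtocolConfig(taboo=True, torsion_restricted=True)


class TestProposals:
    def test_torsion_restricted_proposals_stay_in_native_bins(
            self, small_fixture, tables):
        fx = small_fixture
        bins = native_bin_vector(fx.native, fx.segment)
        cfg = ProtocolConfig(torsion_restricted=True)
        rng = np.random.default_rng(3)
        for _ in range(30):
            mv = KicMove(sub_start=fx.segment.start, sub_end=fx.segment.end)
            mv = _propose(fx.native, mv, cfg, tables, rng, None, bins,
                          fx.segment)
            pivots = set(mv.pivots)
            for resi in fx.segment.residues():
                if resi in pivots:
                    continue
                k = resi - mv.sub_start
                pos = resi - fx.segment.start
                assert classify_bin(mv.phi[k], mv.psi[k]) == bins[pos].upper()

    def test_planar_mode_proposes_only_trans_omegas(self, small_fixture,
                                                    tables):
        fx = small_fixture
        cfg = ProtocolConfig()  # omega sampling off
        rng = np.random.default_rng(4)
        mv = KicMove(sub_start=fx.segment.start, sub_end=fx.segment.end)
        mv = _propose(fx.native, mv, cfg, tables, rng, None, None, fx.segment)
        assert np.all(mv.omega == 180.0)


class TestKicTrial:
    def test_exhausted_attempt_budget_leaves_pose_unchanged(
            self, small_fixture, tables):
        fx = small_fixture
        blocked = fx.native.copy()
        # a wall of overlapping spheres right on the segment: nothing passes
        blocked.env_xyz = fx.native.coords[
            fx.segment.start - 1:fx.segment.end, 1].copy()
        blocked.env_radius = np.full(fx.segment.length, 10.0)
        cfg = ProtocolConfig(max_closure_attempts=5)
        w = EnergyWeights()
        pose, accepted, attempts, _ = kic_trial(
            blocked, fx.segment, cfg, w, tables, np.random.default_rng(0))
        assert not accepted
        assert attempts == 5
        assert np.array_equal(pose.coords, blocked.coords)

    def test_accepted_trial_changes_only_segment_atoms(self, small_fixture,
                                                       tables):
        fx = small_fixture
        cfg = ProtocolConfig(minimize_steps=0)
        w = EnergyWeights()
        rng = np.random.default_rng(5)
        seg = fx.segment
        pose = fx.native
        changed = False
        for _ in range(20):
            new, accepted, _, _ = kic_trial(pose, seg, cfg, w, tables, rng)
            if accepted:
                outside = [i for i in range(len(pose))
                           if not (seg.start - 1 <= i <= seg.end - 1)]
                assert np.array_equal(new.coords[outside],
                                      pose.coords[outside])
                changed = True
                pose = new
        assert changed


class TestMinimize:
    def test_score_never_increases(self, small_fixture, tables):
        fx = small_fixture
        w = EnergyWeights()
        rng = np.random.default_rng(6)
        pose = fx.start
        sc = score(pose, fx.segment, w, tables)
        for _ in range(10):
            pose2, sc2 = _minimize(pose, sc, fx.segment, w, tables, rng,
                                   steps=3, overlap_factor=0.36)
            assert sc2 <= sc + 1e-12
            pose, sc = pose2, sc2
        assert sc == pytest.approx(score(pose, fx.segment, w, tables))

    def test_chain_stays_closed_after_minimisation(self, small_fixture,
                                                   tables):
        fx = small_fixture
        rng = np.random.default_rng(7)
        pose = minimize_segment(fx.native, fx.segment, EnergyWeights(),
                                tables, rng, steps=10)
        for i in range(len(pose) - 1):
            gap = np.linalg.norm(pose.coords[i + 1, 0] - pose.coords[i, 2])
            assert abs(gap - pose.bond_c_n[i]) < 1e-4


@pytest.fixture()
def quick_cfg():
    return ProtocolConfig(n_outer=2, inner_per_residue=1,
                          max_closure_attempts=200, minimize_steps=1)


class TestTrajectory:

    def test_trial_bookkeeping(self, small_fixture, quick_cfg, tables):
        fx = small_fixture
        res = run_trajectory(fx.start, fx.native, fx.segment, quick_cfg,
                             np.random.default_rng(0), tables)
        # log length = n_outer * inner_per_residue * segment length
        assert len(res.accept_log) == 2 * 1 * fx.segment.length
        assert res.best_score <= res.final_score + 1e-12

    def test_determinism_under_fixed_seed(self, small_fixture, quick_cfg,
                                          tables):
        fx = small_fixture
        a = run_trajectory(fx.start, fx.native, fx.segment, quick_cfg,
                           np.random.default_rng(9), tables)
        b = run_trajectory(fx.start, fx.native, fx.segment, quick_cfg,
                           np.random.default_rng(9), tables)
        assert a.best_score == b.best_score
        assert np.array_equal(a.best_pose.coords, b.best_pose.coords)
        assert a.accept_log == b.accept_log

    def test_reported_model_is_lowest_scoring(self, small_fixture, quick_cfg,
                                              tables):
        fx = small_fixture
        res = run_trajectory(fx.start, fx.native, fx.segment, quick_cfg,
                             np.random.default_rng(11), tables)
        from kicloop.energy import configure_ramp

        full, _ = configure_ramp(n_outer=quick_cfg.n_outer)
        assert res.best_score == pytest.approx(
            score(res.best_pose, fx.segment, full, tables))


class TestEnsemble:
    def test_models_table_and_rmsd_round_trip(self, small_fixture, tables,
                                              tmp_path):
        import pandas as pd

        from kicloop.pdbio import read_pdb

        fx = small_fixture
        cfg = ProtocolConfig(n_outer=1, inner_per_residue=1, n_models=3,
                             max_closure_attempts=200, minimize_steps=1,
                             seed=2)
        results = run_ensemble(fx.start, fx.native, fx.segment, cfg, tables,
                               out_dir=tmp_path)
        assert len(results) == 3
        df = pd.read_csv(tmp_path / "scores.tsv", sep="\t")
        assert len(df) == 3
        for _, row in df.iterrows():
            if row["failed"]:
                continue
            model = read_pdb(tmp_path / f"{row['model_id']}.pdb")
            # PDB coordinates carry 3 decimals
            r = segment_rmsd(model, fx.native, fx.segment)
            assert r == pytest.approx(row["rmsd"], abs=5e-3)
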