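"""Ramachandran tables, torsion bins and omega sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kicloop.priors import (
    BINS,
    CIS_RATE,
    GRID_RESOLUTION,
    NCELL,
    OMEGA_SD,
    OMEGA_TRANS_MEAN,
    RamaTable,
    Tables,
    Rama2bTable,
    bin_probability,
    classify_bin,
    load_table,
    rama_energy,
    sample_bin_restricted,
    sample_omega,
    sample_phi_psi,
    sample_phi_psi_rama2b,
    save_table,
)


class TestClassifyBin:
    @pytest.mark.parametrize("phi,psi,expected", [
        (-60, -45, "A"),
        (-120, 140, "B"),
        (60, 40, "G"),
        (100, 170, "E"),
        (0, 50, "A"),        # boundary: phi <= 0 and psi <= 50
        (0, 50.0001, "B"),
        (0, -130, "A"),
        (0, -130.0001, "B"),
        (0.0001, 90, "G"),
        (0.0001, 90.0001, "E"),
    ])
    def test_printed_bin_conditions(self, phi, psi, expected):
        assert classify_bin(phi, psi) == expected

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.floats(-720, 720, allow_nan=False),
           st.floats(-720, 720, allow_nan=False))
    def test_bins_partition_the_torus(self, phi, psi):
        assert classify_bin(phi, psi) in BINS


def single_cell_table(i=10, j=20):
    grid = np.zeros((NCELL, NCELL))
    grid[i, j] = 1.0
    return Tables(rama=RamaTable({"general": grid}), rama2b=Rama2bTable({}))


class TestSamplePhiPsi:
    def test_single_cell_table_draws_inside_that_cell(self):
        t = single_cell_table(4, 40)
        rng = np.random.default_rng(0)
        lo_phi = -180 + 4 * GRID_RESOLUTION
        lo_psi = -180 + 40 * GRID_RESOLUTION
        for _ in range(200):
            phi, psi = sample_phi_psi("A", t, rng)
            assert lo_phi <= phi <= lo_phi + GRID_RESOLUTION
            assert lo_psi <= psi <= lo_psi + GRID_RESOLUTION

    def test_cell_frequencies_pass_chi_square(self, tables):
        from scipy.stats import chisquare

        rng = np.random.default_rng(1)
        n = 10 ** 6
        grid = tables.rama.grid("general")
        cdf = tables.rama.cdf("general")
        draws = np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right")
        counts = np.bincount(np.minimum(draws, grid.size - 1),
                             minlength=grid.size).astype(float)
        mask = grid.ravel() * n >= 5  # chi-square validity
        stat, p = chisquare(counts[mask],
                            grid.ravel()[mask] / grid.ravel()[mask].sum() * counts[mask].sum())
        assert p > 0.01

    def test_bin_marginals_match_summed_masses(self, tables):
        rng = np.random.default_rng(2)
        n = 10 ** 5
        hits = {b: 0 for b in BINS}
        for _ in range(n):
            phi, psi = sample_phi_psi("A", tables, rng)
            hits[classify_bin(phi, psi)] += 1
        for b in BINS:
            p = bin_probability("A", b, tables)
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(hits[b] / n - p) < 3 * se + 1e-4

    def test_unknown_class_raises(self, tables):
        with pytest.raises(KeyError):
            Tables(rama=RamaTable({}), rama2b=Rama2bTable({})).rama.grid("general")


class TestRama2b:
    def test_identical_sides_match_single_grid_sampling(self, tables):
        g = tables.rama.grid("general").copy()
        t = Tables(rama=RamaTable({"general": g.copy()}),
                   rama2b=Rama2bTable({("general", "general", "left"): g.copy(),
                                       ("general", "general", "right"): g.copy()}))
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        a = [sample_phi_psi_rama2b("A", "S", "L", t, rng1) for _ in range(50)]
        # the side choice consumes one uniform; replay with the same stream
        b = []
        for _ in range(50):
            rng2.integers(2)
            b.append(tuple(np.round(sample_phi_psi("A", t, rng2), 12)))
        assert [tuple(np.round(x, 12)) for x in a] == b

    def test_disjoint_supports_split_evenly(self):
        left = np.zeros((NCELL, NCELL))
        left[5, 5] = 1.0   # phi < 0 half
        right = np.zeros((NCELL, NCELL))
        right[NCELL - 5, 5] = 1.0  # phi > 0 half
        t = Tables(rama=RamaTable({"general": left + right}),
                   rama2b=Rama2bTable({("general", "general", "left"): left,
                                       ("general", "general", "right"): right}))
        rng = np.random.default_rng(3)
        n = 10 ** 5
        left_hits = sum(sample_phi_psi_rama2b("A", "S", "L", t, rng)[0] < 0
                        for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(left_hits / n - 0.5) < 3 * se

    def test_chain_terminus_uses_the_other_side(self):
        left = np.zeros((NCELL, NCELL))
        left[5, 5] = 1.0
        right = np.zeros((NCELL, NCELL))
        right[NCELL - 5, 5] = 1.0
        t = Tables(rama=RamaTable({"general": left + right}),
                   rama2b=Rama2bTable({("general", "general", "left"): left,
                                       ("general", "general", "right"): right}))
        rng = np.random.default_rng(4)
        for _ in range(50):
            phi, _ = sample_phi_psi_rama2b("A", None, "L", t, rng)
            assert phi > 0  # only the right-neighbour grid exists

    def test_missing_entries_fall_back_to_standard(self, tables, caplog):
        t = Tables(rama=tables.rama, rama2b=Rama2bTable({}))
        rng = np.random.default_rng(6)
        with caplog.at_level("WARNING"):
            phi, psi = sample_phi_psi_rama2b("A", "S", "L", t, rng)
        assert "falling back" in caplog.text


class TestBinProbability:
    def test_bin_masses_partition_unity(self, tables):
        total = sum(bin_probability("A", b, tables) for b in BINS)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_rama2b_identical_sides_equal_standard(self, tables):
        g = tables.rama.grid("general")
        t = Tables(rama=tables.rama,
                   rama2b=Rama2bTable({("general", "general", "left"): g,
                                       ("general", "general", "right"): g}))
        for b in BINS:
            assert bin_probability("A", b, t, mode="rama2b",
                                   left_aa="S", right_aa="L") == \
                pytest.approx(bin_probability("A", b, t))

    def test_two_cell_toy_grid(self):
        grid = np.zeros((NCELL, NCELL))
        grid[5, 20] = 0.7    # phi < 0, psi in A range -> bin A
        grid[5, 2] = 0.3     # phi < 0, psi < -130 -> bin B
        t = Tables(rama=RamaTable({"general": grid}), rama2b=Rama2bTable({}))
        assert bin_probability("A", "A", t) == pytest.approx(0.7)
        assert bin_probability("A", "B", t) == pytest.approx(0.3)

    def test_rama2b_takes_minimum_of_sides(self):
        a_cell = np.zeros((NCELL, NCELL))
        a_cell[5, 20] = 1.0
        mixed = np.zeros((NCELL, NCELL))
        mixed[5, 20] = 0.4
        mixed[5, 2] = 0.6
        t = Tables(rama=RamaTable({"general": a_cell}),
                   rama2b=Rama2bTable({("general", "general", "left"): a_cell,
                                       ("general", "general", "right"): mixed}))
        assert bin_probability("A", "A", t, mode="rama2b", left_aa="S",
                               right_aa="L") == pytest.approx(0.4)


class TestBinRestricted:
    @pytest.mark.parametrize("bin_", list(BINS))
    def test_draws_always_reclassify_to_the_bin(self, tables, bin_):
        rng = np.random.default_rng(7)
        for _ in range(25_000):
            phi, psi = sample_bin_restricted("A", bin_, tables, rng)
            assert classify_bin(phi, psi) == bin_

    def test_within_bin_frequencies_match_renormalised_grid(self, tables):
        from scipy.stats import chisquare

        rng = np.random.default_rng(8)
        n = 10 ** 5
        cdf = tables.rama.bin_cdf("glycine", "G")
        pmf = np.diff(np.concatenate([[0.0], cdf]))
        draws = np.searchsorted(cdf, rng.random(n) * cdf[-1], "right")
        counts = np.bincount(np.minimum(draws, len(pmf) - 1),
                             minlength=len(pmf)).astype(float)
        mask = pmf * n >= 5
        stat, p = chisquare(counts[mask],
                            pmf[mask] / pmf[mask].sum() * counts[mask].sum())
        assert p > 0.01

    def test_zero_mass_bin_raises_with_names(self):
        grid = np.zeros((NCELL, NCELL))
        grid[5, 20] = 1.0  # all mass in bin A
        t = Tables(rama=RamaTable({"general": grid}), rama2b=Rama2bTable({}))
        with pytest.raises(ValueError, match="E.*general|general.*E"):
            sample_bin_restricted("A", "E", t, np.random.default_rng(0))


class TestSampleOmega:
    def test_planar_mode_returns_exactly_180(self):
        rng = np.random.default_rng(0)
        assert all(sample_omega(False, "planar", rng) == 180.0
                   for _ in range(10))

    def test_trans_gaussian_moments(self):
        rng = np.random.default_rng(1)
        n = 10 ** 6
        draws = np.array([sample_omega(False, "sampled", rng)
                          for _ in range(n)])
        draws = np.where(draws < 0, draws + 360.0, draws)  # unwrap near 180
        se_mean = OMEGA_SD / np.sqrt(n)
        se_sd = OMEGA_SD / np.sqrt(2 * n)
        assert abs(draws.mean() - OMEGA_TRANS_MEAN) < 3 * se_mean
        assert abs(draws.std(ddof=1) - OMEGA_SD) < 3 * se_sd

    def test_pre_proline_cis_rate(self):
        rng = np.random.default_rng(2)
        n = 10 ** 7
        # vectorised replica of the per-draw branch for speed
        cis = rng.random(n) < CIS_RATE
        values = np.where(cis, rng.normal(0.0, OMEGA_SD, n),
                          rng.normal(OMEGA_TRANS_MEAN, OMEGA_SD, n))
        frac = np.mean(np.abs(values) < 90.0)
        # 99% binomial CI around 1e-4
        half = 2.576 * np.sqrt(CIS_RATE * (1 - CIS_RATE) / n)
        assert abs(frac - CIS_RATE) < half
        # and the scalar sampler produces cis values at all
        hits = sum(abs(sample_omega(True, "sampled", rng)) < 90
                   for _ in range(200_000))
        assert 0 <= hits <= 200  # loose sanity bound


class TestRamaEnergy:
    def test_modal_cell_has_minimal_energy(self, tables):
        grid = tables.rama.grid("general")
        i, j = np.unravel_index(np.argmax(grid), grid.shape)
        phi = -180 + (i + 0.5) * GRID_RESOLUTION
        psi = -180 + (j + 0.5) * GRID_RESOLUTION
        e_mode = rama_energy("A", phi, psi, tables)
        rng = np.random.default_rng(3)
        for _ in range(200):
            p, s = rng.uniform(-180, 180, 2)
            assert rama_energy("A", p, s, tables) >= e_mode - 1e-12

    def test_uniform_grid_gives_constant_energy(self):
        t = Tables(rama=RamaTable({"general": np.ones((NCELL, NCELL))}),
                   rama2b=Rama2bTable({}))
        vals = {rama_energy("A", p, s, t)
                for p in (-170, -50, 30, 110) for s in (-120, 0, 160)}
        assert len(vals) == 1

    def test_toy_two_cell_energy_gap_is_ln9(self):
        grid = np.zeros((NCELL, NCELL))
        grid[5, 20] = 0.9
        grid[5, 2] = 0.1
        t = Tables(rama=RamaTable({"general": grid}), rama2b=Rama2bTable({}))
        lo = rama_energy("A", -180 + 5.5 * GRID_RESOLUTION,
                         -180 + 20.5 * GRID_RESOLUTION, t)
        hi = rama_energy("A", -180 + 5.5 * GRID_RESOLUTION,
                         -180 + 2.5 * GRID_RESOLUTION, t)
        assert hi - lo == pytest.approx(np.log(9.0), abs=1e-6)


class TestTableIO:
    def test_round_trip(self, tables, tmp_path):
        path = tmp_path / "rama.tsv"
        save_table(tables.rama, path)
        loaded = load_table(path)
        for cls, grid in tables.rama.grids.items():
            assert np.allclose(loaded.grid(cls), grid, atol=1e-12)
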