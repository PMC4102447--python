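"""Umbrella sampling, window seeding and the WHAM solver."""

import numpy as np
import pytest

from bindfe import (CoordinateCV, DoubleWellPotential, HarmonicPotential,
                    LangevinParams, Profile1D, Trajectory, UmbrellaWindow,
                    UnstitchableLadderError, WindowLadder, harmonic_bias,
                    make_ladder, pmf_depth, run_umbrella,
                    seed_windows_from_path, wham)


class TestHarmonicBias:
    def test_values_and_symmetry(self):
        w = UmbrellaWindow(cv="r", center=10.0, k=5.0)
        assert harmonic_bias(10.0, w) == 0.0
        # k = 5, displacement 0.5 Å → (5/2)·0.25 = 0.625 kcal/mol
        assert harmonic_bias(10.5, w) == pytest.approx(0.625)
        assert harmonic_bias(9.3, w) == harmonic_bias(10.7, w)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(cv="r", center=0.0, k=-1.0)


class TestLadders:
    def test_paper_default_window_counts(self):
        assert len(make_ladder("r", 5.0, 25.0, 0.5, 5.0)) == 41
        assert len(make_ladder("rmsd", 0.0, 3.0, 0.5, 0.01)) == 7
        assert len(make_ladder("rmsd", 0.0, 5.0, 0.5, 0.01)) == 11

    def test_centers_strictly_increasing(self):
        with pytest.raises(ValueError):
            WindowLadder(windows=[UmbrellaWindow("r", 1.0, 1.0),
                                  UmbrellaWindow("r", 1.0, 1.0)], spacing=0.5)


class TestSeeding:
    def _traj(self, values):
        values = np.asarray(values, dtype=float)
        return Trajectory(times=np.arange(len(values), dtype=float) + 1.0,
                          coordinates=values[:, None],
                          cv_values={"r": values})

    def test_exact_hits_selected(self):
        traj = self._traj([5.0, 5.5, 6.0, 6.5])
        seeds = seed_windows_from_path(traj, [5.0, 6.0], cv_name="r")
        assert seeds[0][0] == 5.0 and seeds[1][0] == 6.0

    def test_nearest_and_earliest_tie(self):
        traj = self._traj([5.0, 6.0, 5.0, 7.0])
        # 5.5 is equidistant from frames 0 (5.0) and 1 (6.0): earliest wins
        seeds = seed_windows_from_path(traj, [5.5], cv_name="r")
        assert seeds[0][0] == 5.0
        seeds = seed_windows_from_path(traj, [6.8], cv_name="r")
        assert seeds[0][0] == 7.0

    def test_41_centers_give_41_seeds(self):
        traj = self._traj(np.linspace(5.0, 25.0, 200))
        centers = make_ladder("r", 5.0, 25.0, 0.5, 5.0).centers
        assert len(seed_windows_from_path(traj, centers, cv_name="r")) == 41

    def test_center_outside_range_rejected(self):
        traj = self._traj([5.0, 6.0])
        with pytest.raises(ValueError, match="outside"):
            seed_windows_from_path(traj, [8.0], cv_name="r")


class TestRunUmbrella:
    def test_flat_potential_window_variance(self, conditions):
        # per-window variance ≈ kB·T/k = 0.1232 Å² at k = 5
        pot = HarmonicPotential(k=[0.0], center=[0.0])
        ladder = make_ladder("x", -1.0, 1.0, 0.5, 5.0)
        params = LangevinParams(timestep=0.01, n_steps=200_000, seed=3,
                                save_stride=5)
        run_umbrella(pot, CoordinateCV("x", 0), ladder, params, conditions)
        for w in ladder.windows:
            assert float(np.var(w.samples)) == pytest.approx(
                conditions.kt / 5.0, rel=0.10)
            assert float(np.mean(w.samples)) == pytest.approx(w.center, abs=0.05)

    def test_neighbor_histogram_overlap(self, conditions):
        pot = DoubleWellPotential(barrier=5.0, half_separation=1.5)
        ladder = make_ladder("x", -2.0, 2.0, 0.2, 15.0)
        params = LangevinParams(timestep=0.01, n_steps=100_000, seed=5,
                                save_stride=5)
        run_umbrella(pot, CoordinateCV("x", 0), ladder, params, conditions)
        edges = np.linspace(-2.5, 2.5, 101)
        dens = [np.histogram(w.samples, bins=edges, density=True)[0]
                for w in ladder.windows]
        width = edges[1] - edges[0]
        for a, b in zip(dens, dens[1:]):
            overlap = float(np.minimum(a, b).sum() * width)
            assert overlap >= 0.05

    def test_identical_seeds_identical_samples(self, conditions):
        pot = HarmonicPotential(k=[1.0], center=[0.0])
        params = LangevinParams(n_steps=20_000, seed=8, save_stride=10)
        l1 = make_ladder("x", -1.0, 1.0, 1.0, 2.0)
        l2 = make_ladder("x", -1.0, 1.0, 1.0, 2.0)
        run_umbrella(pot, CoordinateCV("x", 0), l1, params, conditions)
        run_umbrella(pot, CoordinateCV("x", 0), l2, params, conditions)
        for a, b in zip(l1.windows, l2.windows):
            assert np.array_equal(a.samples, b.samples)


class TestWham:
    def _window_with(self, samples, center=0.0, k=0.0):
        return UmbrellaWindow(cv="x", center=center, k=k,
                              samples=np.asarray(samples, dtype=float))

    def test_zero_bias_limit_equals_boltzmann_inversion(self, conditions, rng):
        samples = rng.normal(0.0, 1.0, size=20_000)
        ladder = WindowLadder(windows=[self._window_with(samples)], spacing=1.0)
        res = wham(ladder, conditions, bin_count=40)
        lo = float(np.quantile(samples, 5e-4))
        hi = float(np.quantile(samples, 1 - 5e-4))
        hist, _ = np.histogram(samples, bins=np.linspace(lo, hi, 41))
        direct = -conditions.kt * np.log(hist[hist > 0])
        direct -= direct.min()
        assert np.allclose(res.pmf.free_energy, direct, atol=1e-10)

    def test_uniform_single_window_flat(self, conditions, rng):
        samples = rng.uniform(0.0, 1.0, size=100_000)
        ladder = WindowLadder(windows=[self._window_with(samples)], spacing=1.0)
        res = wham(ladder, conditions, bin_count=20)
        assert float(res.pmf.free_energy.max()) < 0.05

    def test_flat_potential_recovered_flat(self, conditions):
        pot = HarmonicPotential(k=[0.0], center=[0.0])
        ladder = make_ladder("x", -2.0, 2.0, 0.4, 5.0)
        params = LangevinParams(timestep=0.01, n_steps=300_000, seed=13,
                                save_stride=5)
        run_umbrella(pot, CoordinateCV("x", 0), ladder, params, conditions)
        res = wham(ladder, conditions, bin_count=100,
                   bin_range=(-2.0, 2.0))
        assert res.converged
        assert float(res.pmf.free_energy.max()) <= 0.1

    def test_window_permutation_invariance(self, conditions):
        pot = DoubleWellPotential(barrier=3.0, half_separation=1.5)
        ladder = make_ladder("x", -2.0, 2.0, 0.25, 12.0)
        params = LangevinParams(timestep=0.01, n_steps=60_000, seed=17,
                                save_stride=5)
        run_umbrella(pot, CoordinateCV("x", 0), ladder, params, conditions)
        res1 = wham(ladder, conditions, bin_count=80, bin_range=(-2.0, 2.0))
        perm = WindowLadder(windows=ladder.windows[:], spacing=ladder.spacing)
        order = np.random.default_rng(0).permutation(len(perm.windows))
        perm_windows = [perm.windows[i] for i in order]
        shuffled = WindowLadder.__new__(WindowLadder)
        shuffled.windows = perm_windows
        shuffled.spacing = ladder.spacing
        res2 = wham(shuffled, conditions, bin_count=80, bin_range=(-2.0, 2.0))
        assert np.allclose(res1.pmf.free_energy, res2.pmf.free_energy,
                           atol=1e-8)

    def test_disconnected_ladder_rejected(self, conditions, rng):
        w1 = self._window_with(rng.normal(0.0, 0.05, 5000), center=0.0, k=50.0)
        w2 = self._window_with(rng.normal(5.0, 0.05, 5000), center=5.0, k=50.0)
        ladder = WindowLadder(windows=[w1, w2], spacing=5.0)
        with pytest.raises(UnstitchableLadderError):
            wham(ladder, conditions, bin_count=100, bin_range=(-0.5, 5.5))


class TestBlockUncertainty:
    def test_block_errors_are_small_and_positive(self, conditions):
        from bindfe import wham_block_uncertainty

        pot = DoubleWellPotential(barrier=3.0, half_separation=1.5)
        ladder = make_ladder("x", -2.0, 2.0, 0.25, 12.0)
        params = LangevinParams(timestep=0.01, n_steps=120_000, seed=29,
                                save_stride=5)
        run_umbrella(pot, CoordinateCV("x", 0), ladder, params, conditions)
        prof = wham_block_uncertainty(ladder, conditions, n_blocks=4,
                                      bin_count=80, bin_range=(-2.0, 2.0))
        assert prof.uncertainty is not None
        assert prof.uncertainty.shape == prof.free_energy.shape
        assert np.all(prof.uncertainty >= 0)
        assert float(np.median(prof.uncertainty)) < 0.3


class TestPmfDepth:
    def test_flat_and_constructed_well(self):
        rc = np.linspace(0.0, 20.0, 201)
        flat = Profile1D(rc, np.zeros_like(rc))
        assert pmf_depth(flat, (0, 5), (15, 20)) == 0.0
        fe = 10.0 - 10.0 * np.exp(-0.5 * ((rc - 2.0) / 0.5) ** 2)
        well = Profile1D(rc, fe)
        assert pmf_depth(well, (0, 5), (15, 20)) == pytest.approx(10.0, abs=1e-6)

    def test_empty_range_rejected(self):
        prof = Profile1D(np.linspace(0, 1, 11), np.zeros(11))
        with pytest.raises(ValueError):
            pmf_depth(prof, (5.0, 6.0), (0.0, 1.0))
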