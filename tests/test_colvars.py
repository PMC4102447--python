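"""Collective variables: frozen geometric examples and isometry invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from bindfe import (OutOfPathError, angle, com_distance, dihedral,
                    funnel_radial, make_path_frames, msd, path_progress,
                    population_histogram, rmsd)

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


def _random_isometry(seed: int):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(scale=5.0, size=3)
    return lambda p: p @ rot.T + shift


class TestComDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ([(0, 0, 0)], [(3, 4, 0)], 5.0),                      # 3-4-5 triangle
        ([(1, 2, 3)], [(1, 2, 3)], 0.0),                      # identity
    ])
    def test_unit_mass_examples(self, a, b, expected):
        assert com_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_mass_weighted_centroid(self):
        # masses (1, 3) at x=0 and x=4 → centroid x=3, equal to the point (3,0,0)
        d = com_distance([(0, 0, 0), (4, 0, 0)], [(3, 0, 0)], masses_a=[1, 3])
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_errors(self):
        a, b = [(0, 0, 0), (1, 1, 0)], [(5, 2, 1)]
        assert com_distance(a, b) == com_distance(b, a)
        with pytest.raises(ValueError):
            com_distance([], b)
        with pytest.raises(ValueError):
            com_distance(a, b, masses_a=[0.0, 0.0])

    def test_gradient_matches_central_differences(self, rng):
        pts_a = rng.normal(size=(3, 3))
        pts_b = rng.normal(size=(2, 3)) + 5.0
        masses = np.array([1.0, 2.0, 0.5])
        d, grad = com_distance(pts_a, pts_b, masses_a=masses,
                               return_gradient=True)
        h = 1e-6
        for i in range(3):
            for j in range(3):
                p = pts_a.copy(); p[i, j] += h
                m = pts_a.copy(); m[i, j] -= h
                num = (com_distance(p, pts_b, masses_a=masses)
                       - com_distance(m, pts_b, masses_a=masses)) / (2 * h)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestAngle:
    @pytest.mark.parametrize("p1,p2,p3,expected", [
        ((1, 0, 0), (0, 0, 0), (-1, 0, 0), 180.0),
        ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (0, 0, 0), (1, 1, 0), 45.0),
    ])
    def test_examples(self, p1, p2, p3, expected):
        assert angle(p1, p2, p3) == pytest.approx(expected, abs=1e-10)

    def test_zero_arm_rejected(self):
        with pytest.raises(ValueError):
            angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        iso = _random_isometry(seed)
        pts = np.random.default_rng(seed + 1).normal(size=(3, 3)) * 3
        moved = iso(pts)
        assert angle(*moved) == pytest.approx(angle(*pts), abs=1e-8)


class TestDihedral:
    def test_trans_and_cis(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == \
            pytest.approx(180.0, abs=1e-10)
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == \
            pytest.approx(0.0, abs=1e-10)

    def test_sign_convention_plus_90(self):
        # fixed by the IUPAC convention (clockwise positive viewed along b2)
        phi = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1))
        assert phi == pytest.approx(90.0, abs=1e-10)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @given(st.integers(0, 10_000))
    def test_wrapped_range_and_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 2
        try:
            phi = dihedral(*pts)
        except ValueError:
            return
        assert -180.0 < phi <= 180.0
        iso = _random_isometry(seed)
        assert dihedral(*iso(pts)) == pytest.approx(phi, abs=1e-7)


class TestMsd:
    def test_identity_translation_and_mixed(self):
        a = np.array([(0.0, 0, 0), (1, 1, 0)])
        assert msd(a, a) == 0.0
        b = a + np.array([1.0, 0, 0])
        assert msd(a, b) == pytest.approx(1.0)
        assert rmsd(a, b) == pytest.approx(1.0)
        # displacements of 1 Å and 3 Å → (1+9)/2 = 5 Å²
        c = a + np.array([(1.0, 0, 0), (3.0, 0, 0)]).reshape(2, 3) * np.array([[1], [1]])
        c = np.array([(1.0, 0, 0), (4.0, 1, 0)])
        assert msd(a, c) == pytest.approx(5.0)

    def test_mismatched_counts(self):
        with pytest.raises(ValueError):
            msd(np.zeros((2, 3)), np.zeros((3, 3)))

    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 5, 3))
        iso = _random_isometry(seed)
        assert msd(iso(a), iso(b)) == pytest.approx(msd(a, b), rel=1e-9)


class TestPathProgress:
    def setup_method(self):
        self.ref = make_path_frames(7, 1.0)

    def test_endpoints_near_milestones(self):
        # at λ = 2.3/spacing the one-sided neighbour weight e^{-2.3} biases
        # the endpoints inward by ≈0.09·spacing (analytic), interior frames
        # are symmetric and land within 5% of their milestone
        s0 = path_progress(self.ref.frames[0], self.ref)
        s6 = path_progress(self.ref.frames[6], self.ref)
        assert s0 == pytest.approx(0.0, abs=0.1)
        assert s6 == pytest.approx(6.0, abs=0.1)
        for i in range(1, 6):
            si = path_progress(self.ref.frames[i], self.ref)
            assert si == pytest.approx(float(i), abs=0.05)

    def test_monotone_along_interpolation(self):
        a, b = self.ref.frames[0], self.ref.frames[-1]
        ts = np.linspace(0, 1, 61)
        vals = [path_progress(a + t * (b - a), self.ref) for t in ts]
        assert np.all(np.diff(vals) > 0)

    def test_off_path_raises(self):
        far = self.ref.frames[0] + 100.0
        with pytest.raises(OutOfPathError):
            path_progress(far, self.ref)


class TestFunnelRadial:
    def test_examples(self):
        assert funnel_radial((5, 0, 0), (0, 0, 0), (1, 0, 0)) == 0.0
        assert funnel_radial((2, 3, 4), (0, 0, 0), (1, 0, 0)) == pytest.approx(5.0)
        # invariance under translation along the axis
        assert funnel_radial((9, 3, 4), (0, 0, 0), (1, 0, 0)) == pytest.approx(5.0)

    def test_axis_validation(self):
        with pytest.raises(ValueError):
            funnel_radial((1, 1, 1), (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError):
            funnel_radial((1, 1, 1), (0, 0, 0), (2, 0, 0))

    def test_gradient(self):
        d, g = funnel_radial((2.0, 3.0, 4.0), (0, 0, 0), (1, 0, 0),
                             return_gradient=True)
        assert np.allclose(g, [0.0, 0.6, 0.8])


class TestPopulationHistogram:
    def test_counts_conserved_and_density_normalised(self, rng):
        vals = rng.uniform(0.0, 1.0, size=1000)
        h = population_histogram(vals, 0.1, normalize=True)
        assert h.counts.sum() == 1000
        widths = np.diff(h.bin_edges)
        assert float(np.sum(h.normalized_density * widths)) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_grid_exact(self):
        vals = (np.arange(1000) + 0.5) / 1000.0  # 100 values per 0.1-wide bin
        h = population_histogram(vals, 0.1)
        assert h.counts.sum() == 1000
        # exact up to float-representability of the bin boundaries
        assert np.all(np.abs(h.counts - 100) <= 1)

    def test_constant_series_single_occupied_bin(self):
        h = population_histogram(np.full(50, 3.7), 0.5)
        assert (h.counts > 0).sum() == 1
        assert h.counts.max() == 50

    def test_circular_wrap_shares_bin(self):
        h = population_histogram([-179.0, 179.0], 5.0, circular=True)
        assert (h.counts > 0).sum() == 1

    def test_errors(self):
        with pytest.raises(ValueError):
            population_histogram([], 0.1)
        with pytest.raises(ValueError):
            population_histogram([1.0], -0.1)
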