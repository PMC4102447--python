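"""Woo–Roux assembly: restraint integrals, S*/I*, K_bind and the report."""

import math

import numpy as np
import pytest

from bindfe import (AssemblyReport, FreeEnergySurface, FunnelSpec,
                    HarmonicRestraint, Profile1D, RestraintComponents,
                    SimulationConditions, SystemResult, TruncatedSupportError,
                    build_report, bulk_orientation_dg, dg_bind_meta,
                    dg_bind_us, dg_off, funnel_correction, i_star, k_bind,
                    min_free_energy_path, residence_time_ratio,
                    restraint_dg_from_pmf, s_star)

WT = RestraintComponents(conf_site=0.073, conf_bulk=1.639, orient_alpha=0.410,
                         orient_beta=0.892, orient_gamma=0.210,
                         orient_bulk=7.135, trans_theta=0.355,
                         trans_Theta=0.162, s_star=9.834, i_star=1.98e17)
MUT = RestraintComponents(conf_site=0.323, conf_bulk=1.772, orient_alpha=0.617,
                          orient_beta=0.520, orient_gamma=0.389,
                          orient_bulk=7.230, trans_theta=0.214,
                          trans_Theta=0.165, s_star=8.950, i_star=4.44e12)


class TestRestraintDg:
    def test_zero_restraint_is_zero(self, conditions):
        pmf = Profile1D(np.linspace(0, 10, 501), np.zeros(501))
        assert restraint_dg_from_pmf(pmf, HarmonicRestraint(5.0, 0.0),
                                     conditions) == 0.0

    def test_flat_pmf_matches_gaussian_closed_form(self, conditions):
        # ΔG = −kT·ln( sqrt(2π·kT/k) / L ) for a flat PMF of length L
        L, k = 10.0, 2.0
        pmf = Profile1D(np.linspace(0, L, 4001), np.zeros(4001))
        dg = restraint_dg_from_pmf(pmf, HarmonicRestraint(L / 2, k), conditions)
        closed = -conditions.kt * math.log(
            math.sqrt(2 * math.pi * conditions.kt / k) / L)
        assert dg == pytest.approx(closed, abs=1e-6)

    def test_restraint_on_deep_narrow_minimum_costs_nothing(self, conditions):
        rc = np.linspace(-2, 2, 2001)
        pmf = Profile1D(rc, 0.5 * 50.0 * rc**2)  # stiff well at the centre
        dg = restraint_dg_from_pmf(pmf, HarmonicRestraint(0.0, 0.1), conditions)
        assert 0.0 <= dg < 0.01

    def test_truncated_support_rejected(self, conditions):
        pmf = Profile1D(np.linspace(0, 1, 101), np.zeros(101))
        with pytest.raises(TruncatedSupportError):
            restraint_dg_from_pmf(pmf, HarmonicRestraint(0.5, 0.5), conditions)

    def test_gauge_invariance(self, conditions):
        rc = np.linspace(-3, 3, 1001)
        pmf = Profile1D(rc, 0.5 * 3.0 * rc**2)
        shifted = Profile1D(rc, pmf.free_energy + 17.3)
        r = HarmonicRestraint(0.0, 1.0)
        assert restraint_dg_from_pmf(pmf, r, conditions) == pytest.approx(
            restraint_dg_from_pmf(shifted, r, conditions), abs=1e-12)


class TestBulkOrientation:
    def test_zero_restraints_zero(self, conditions):
        z = HarmonicRestraint(0.0, 0.0)
        assert bulk_orientation_dg(z, z, z, conditions) == pytest.approx(0.0, abs=1e-5)

    def test_monotone_in_stiffness(self, conditions):
        vals = []
        for k in (0.001, 0.01, 0.1):
            r = HarmonicRestraint(90.0, k)
            rp = HarmonicRestraint(0.0, k, periodic=True)
            vals.append(bulk_orientation_dg(r, rp, rp, conditions))
        assert vals[0] < vals[1] < vals[2]

    def test_separable_10_degree_width_closed_form(self, conditions):
        # k chosen so each angle has Gaussian width 10°
        sigma = 10.0
        k = conditions.kt / sigma**2
        alpha0 = 90.0
        r_a = HarmonicRestraint(alpha0, k)
        r_b = HarmonicRestraint(30.0, k, periodic=True)
        r_g = HarmonicRestraint(-60.0, k, periodic=True)
        dg = bulk_orientation_dg(r_a, r_b, r_g, conditions)
        s_rad = math.radians(sigma)
        closed = -conditions.kt * math.log(
            (math.sin(math.radians(alpha0)) * math.sqrt(2 * math.pi) * s_rad / 2.0)
            * (math.sqrt(2 * math.pi) * s_rad / (2 * math.pi)) ** 2
        )
        assert dg == pytest.approx(closed, abs=0.01)


class TestSStar:
    def test_zero_restraints_full_sphere(self, conditions):
        z = HarmonicRestraint(0.0, 0.0)
        assert s_star(z, z, 10.0, conditions) == pytest.approx(
            4 * math.pi * 100.0, rel=1e-6)

    def test_stiff_limit_matches_laplace_approximation(self, conditions):
        theta0, k = 70.0, 0.15  # ~2° width
        r_t = HarmonicRestraint(theta0, k)
        r_T = HarmonicRestraint(0.0, k, periodic=True)
        val = s_star(r_t, r_T, 24.0, conditions, n_points=8001)
        k_rad = k * (180.0 / math.pi) ** 2
        laplace = 24.0**2 * math.sin(math.radians(theta0)) \
            * 2 * math.pi * conditions.kt / k_rad
        assert val == pytest.approx(laplace, rel=0.01)

    def test_monotone_decreasing_in_k(self, conditions):
        vals = [s_star(HarmonicRestraint(90.0, k),
                       HarmonicRestraint(0.0, k, periodic=True), 10.0,
                       conditions)
                for k in (0.001, 0.01, 0.1)]
        assert vals[0] > vals[1] > vals[2]

    def test_bad_r_star(self, conditions):
        z = HarmonicRestraint(0.0, 0.0)
        with pytest.raises(ValueError):
            s_star(z, z, -1.0, conditions)


class TestIStar:
    def _square_well(self, depth, lo=5.0, hi=6.0):
        rc = np.linspace(0.0, 26.0, 5201)
        w = np.where((rc >= lo) & (rc <= hi), -depth, 0.0)
        return Profile1D(rc, w)

    def test_flat_profile_returns_site_length(self, conditions):
        rc = np.linspace(0.0, 26.0, 2601)
        prof = Profile1D(rc, np.zeros_like(rc))
        assert i_star(prof, (5.0, 9.0), conditions) == pytest.approx(4.0, rel=1e-9)

    def test_square_well_matches_closed_form(self, conditions):
        # depth 24.96 kcal/mol over 1 Å at 310 K → e^{24.96·β} ≈ 3.9e17 Å,
        # the order of magnitude of the published wild-type I*
        prof = self._square_well(24.96)
        val = i_star(prof, (5.0, 6.0), conditions)
        closed = math.exp(24.96 * conditions.beta) * 1.0
        assert val == pytest.approx(closed, rel=1e-3)
        assert 1e17 < val < 1e18

    def test_monotone_in_depth_and_gauge_invariant(self, conditions):
        a = i_star(self._square_well(10.0), (5.0, 6.0), conditions)
        b = i_star(self._square_well(12.0), (5.0, 6.0), conditions)
        assert b > a
        shifted = self._square_well(10.0)
        shifted = Profile1D(shifted.rc, shifted.free_energy + 3.0)
        assert i_star(shifted, (5.0, 6.0), conditions) == pytest.approx(a, rel=1e-12)

    def test_missing_plateau_rejected(self, conditions):
        rc = np.linspace(0.0, 26.0, 1001)
        prof = Profile1D(rc, -0.5 * rc)  # sloped everywhere
        with pytest.raises(ValueError, match="plateau"):
            i_star(prof, (5.0, 6.0), conditions)


class TestKBindAndStandardState:
    def test_published_wild_type_column(self, conditions):
        assert k_bind(WT, conditions) == pytest.approx(3.85e13, rel=0.02)
        assert dg_bind_us(k_bind(WT, conditions), conditions) == pytest.approx(
            -14.70, abs=0.02)

    def test_published_mutant_column(self, conditions):
        assert k_bind(MUT, conditions) == pytest.approx(6.64e8, rel=0.02)
        assert dg_bind_us(k_bind(MUT, conditions), conditions) == pytest.approx(
            -7.95, abs=0.02)

    def test_zero_restraints_reduce_to_s_times_i(self, conditions):
        comp = RestraintComponents(0, 0, 0, 0, 0, 0, 0, 0, s_star=7.0,
                                   i_star=3.0)
        assert k_bind(comp, conditions) == pytest.approx(21.0, rel=1e-12)

    def test_standard_state_identity(self, conditions):
        assert dg_bind_us(1661.0, conditions) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            dg_bind_us(-1.0, conditions)


class TestDgBindMeta:
    def test_correction_magnitude_at_r15(self, conditions):
        # |kB·T·ln(π·15²·C°)| = 0.526 kcal/mol; the correction weakens binding
        # because π·225 Å²·Å < 1661 Å³
        corr = funnel_correction(FunnelSpec(radius=15.0), conditions)
        assert corr == pytest.approx(0.526, abs=5e-4)
        assert corr > 0

    def test_zero_depth_gives_correction_only(self, conditions):
        rc = np.linspace(0.0, 20.0, 201)
        prof = Profile1D(rc, np.zeros_like(rc))
        funnel = FunnelSpec(radius=15.0)
        assert dg_bind_meta(prof, funnel, (0, 5), (15, 20), conditions) == \
            pytest.approx(funnel_correction(funnel, conditions))


class TestMinFreeEnergyPath:
    def test_hand_enumerated_grid(self):
        fe = np.array([[3.0, 1.0, 2.0],
                       [0.5, 4.0, 0.5],   # tie → lowest CV2 index
                       [2.0, 2.0, 0.0]])
        fes = FreeEnergySurface(axes=[np.arange(3.0), np.arange(3.0)],
                                free_energy=fe,
                                visited=np.ones((3, 3), dtype=bool))
        prof = min_free_energy_path(fes)
        assert np.allclose(prof.free_energy, [1.0, 0.5, 0.0])

    def test_constant_in_cv2_equals_any_slice(self):
        col = np.array([2.0, 0.0, 1.0, 3.0])
        fe = np.tile(col[:, None], (1, 5))
        fes = FreeEnergySurface(axes=[np.arange(4.0), np.arange(5.0)],
                                free_energy=fe,
                                visited=np.ones((4, 5), dtype=bool))
        prof = min_free_energy_path(fes)
        assert np.allclose(prof.free_energy, col - col.min())

    def test_additive_shift_invariance(self):
        rng = np.random.default_rng(5)
        fe = rng.uniform(0, 5, size=(6, 4))
        vis = np.ones((6, 4), dtype=bool)
        axes = [np.arange(6.0), np.arange(4.0)]
        p1 = min_free_energy_path(FreeEnergySurface(axes, fe, vis))
        p2 = min_free_energy_path(FreeEnergySurface(axes, fe + 11.0, vis))
        assert np.allclose(p1.free_energy, p2.free_energy)

    def test_unvisited_column_rejected_unless_trimmed(self):
        fe = np.zeros((3, 2))
        vis = np.ones((3, 2), dtype=bool)
        vis[0] = False
        fes = FreeEnergySurface([np.arange(3.0), np.arange(2.0)], fe, vis)
        with pytest.raises(ValueError):
            min_free_energy_path(fes)
        prof = min_free_energy_path(fes, trim_unvisited=True)
        assert prof.rc.size == 2


class TestDgOffAndResidence:
    def test_monotone_profile_gives_plateau_height(self):
        rc = np.linspace(0, 20, 201)
        prof = Profile1D(rc, 7.0 * (1 - np.exp(-rc / 2.0)))
        assert dg_off(prof, (0.0, 5.0)) == pytest.approx(7.0, abs=0.01)

    def test_barrier_height_12_10(self):
        rc = np.linspace(0, 20, 401)
        fe = 12.10 * np.exp(-0.5 * ((rc - 6.0) / 1.0) ** 2) \
            + 4.0 * (1 - np.exp(-rc / 3.0)) * 0.0
        prof = Profile1D(rc, fe)
        assert dg_off(prof, (0.0, 3.0)) == pytest.approx(12.10, abs=1e-6)

    def test_flat_profile_zero(self):
        prof = Profile1D(np.linspace(0, 10, 101), np.zeros(101))
        assert dg_off(prof, (0.0, 5.0)) == 0.0

    def test_residence_ratio_examples(self, conditions):
        assert residence_time_ratio(5.0, 5.0, conditions) == 1.0
        r = residence_time_ratio(12.10, 5.53, conditions)
        assert r == pytest.approx(math.exp(6.57 * conditions.beta), rel=1e-12)
        assert r == pytest.approx(4.3e4, rel=0.01)
        assert r * residence_time_ratio(5.53, 12.10, conditions) == \
            pytest.approx(1.0, rel=1e-12)


class TestReport:
    def _systems(self, conditions):
        a = SystemResult.from_components("WT", WT, conditions,
                                         separation_pmf=-24.96, dg_off=12.10,
                                         dg_bind_meta=-10.14)
        b = SystemResult.from_components("G2032R", MUT, conditions,
                                         separation_pmf=-18.32, dg_off=5.53,
                                         dg_bind_meta=-5.91)
        return a, b

    def test_published_ddg_conventions(self, conditions):
        report = build_report(*self._systems(conditions))
        # restraint rows print (mutant − WT); total rows print (WT − mutant)
        assert report.ddg["conf_site"] == pytest.approx(0.250, abs=1e-9)
        assert report.ddg["orient_beta"] == pytest.approx(-0.372, abs=1e-9)
        assert report.ddg["separation_pmf"] == pytest.approx(-6.64, abs=1e-9)
        assert report.ddg["dg_bind_us"] == pytest.approx(-6.75, abs=0.03)
        assert report.ddg["dg_off"] == pytest.approx(6.57, abs=1e-9)
        assert report.ddg["dg_bind_meta"] == pytest.approx(-4.23, abs=1e-9)

    def test_identical_systems_all_zero(self, conditions):
        a = SystemResult.from_components("A", WT, conditions,
                                         separation_pmf=-24.96, dg_off=12.1)
        b = SystemResult.from_components("B", WT, conditions,
                                         separation_pmf=-24.96, dg_off=12.1)
        report = build_report(a, b)
        assert all(abs(v) < 1e-12 for v in report.ddg.values())

    def test_keyvalue_roundtrip_lossless(self, conditions, tmp_path):
        from bindfe.fileio import read_keyvalues, write_keyvalues

        report = build_report(*self._systems(conditions))
        path = tmp_path / "report.txt"
        write_keyvalues(path, report.to_keyvalues())
        back = AssemblyReport.from_keyvalues(read_keyvalues(path))
        assert back.system_a.k_bind == report.system_a.k_bind
        assert back.system_b.dg_bind_us == report.system_b.dg_bind_us
        assert back.ddg == report.ddg
        assert "k_bind" in report.to_text()
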