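"""Forward reflectivity model, density profiles and the GA fitter."""

import copy

import numpy as np
import pytest

import slbfet as sf
from slbfet.reflectometry import critical_q

from oracles import tm_reflectivity


class TestWavelength:
    @pytest.mark.parametrize("energy, wavelength", [
        (16.2, 0.76534),        # the beamline energy used for the SLB
        (12.39842, 1.0),
        (8.048, 1.5406),        # Cu K-alpha
    ])
    def test_conversion(self, energy, wavelength):
        assert sf.energy_to_wavelength(energy) == pytest.approx(
            wavelength, rel=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sf.energy_to_wavelength(0.0)


class TestBuildProfile:
    def test_zero_roughness_is_step_profile(self, slb_stack):
        stack = copy.deepcopy(slb_stack)
        for s in stack.slabs:
            s.roughness_A = 0.0
        stack.substrate_roughness_A = 0.0
        z = np.linspace(-20.0, 70.0, 1801)
        prof = sf.build_profile(stack, z)
        # inside the first tail slab (z in (8, 22)) density is exactly 0.30
        sel = (z > 8.01) & (z < 21.99)
        assert np.allclose(prof.rho_e[sel], 0.30)
        assert np.allclose(prof.rho_e[z < -0.01], 0.66)

    def test_single_interface_midpoint(self):
        stack = sf.SlabStack(substrate=sf.Medium(0.66), slabs=[],
                             ambient=sf.Medium(0.334),
                             substrate_roughness_A=3.0)
        z = np.linspace(-40.0, 40.0, 1601)
        prof = sf.build_profile(stack, z)
        mid = np.interp(0.0, prof.z_A, prof.rho_e)
        assert mid == pytest.approx(0.5 * (0.66 + 0.334), rel=1e-9)

    def test_excess_electrons_roughness_independent(self, slb_stack):
        """The integral of rho - rho_ambient is conserved under smoothing."""
        z = np.linspace(-60.0, 110.0, 4001)
        totals = []
        for rough in (1.5, 3.0, 6.0):
            stack = copy.deepcopy(slb_stack)
            for s in stack.slabs:
                s.roughness_A = rough
            stack.substrate_roughness_A = rough
            prof = sf.build_profile(stack, z)
            totals.append(np.trapezoid(prof.rho_e - stack.ambient.rho_e, z))
        assert np.allclose(totals, totals[0], rtol=1e-9)

    def test_grid_must_cover_stack(self, slb_stack):
        with pytest.raises(ValueError, match="cover"):
            sf.build_profile(slb_stack, np.linspace(0.0, 30.0, 100))


class TestReflectivity:
    def test_bare_interface_equals_fresnel_closed_form(self):
        stack = sf.SlabStack(substrate=sf.Medium(0.66), slabs=[],
                             ambient=sf.Medium(0.334),
                             substrate_roughness_A=0.0)
        q = np.linspace(0.005, 0.7, 300)
        assert np.allclose(sf.reflectivity(stack, q),
                           sf.fresnel_reflectivity(0.66, 0.334, q),
                           rtol=0, atol=1e-14)

    def test_total_reflection_below_critical_edge(self):
        stack = sf.SlabStack(substrate=sf.Medium(0.66), slabs=[],
                             ambient=sf.Medium(0.334),
                             substrate_roughness_A=0.0)
        qc = critical_q(0.66, 0.334)
        q = np.linspace(0.1 * qc, 0.99 * qc, 60)
        R = sf.reflectivity(stack, q)
        assert np.allclose(R, 1.0, atol=1e-12)

    def test_large_q_fresnel_decay(self):
        stack = sf.SlabStack(substrate=sf.Medium(0.66), slabs=[],
                             ambient=sf.Medium(0.334),
                             substrate_roughness_A=0.0)
        qc = critical_q(0.66, 0.334)
        q = np.array([0.4, 0.6])
        assert np.allclose(sf.reflectivity(stack, q), (qc / (2 * q)) ** 4,
                           rtol=5e-3)

    def test_contrast_free_slabs_reduce_to_bare_substrate(self, slb_stack):
        """Slabs at the ambient density are invisible: R equals the bare
        substrate/ambient Fresnel curve."""
        stack = copy.deepcopy(slb_stack)
        for s in stack.slabs:
            s.rho_e = stack.ambient.rho_e
            s.roughness_A = 0.0
        stack.substrate_roughness_A = 0.0
        q = np.linspace(0.01, 0.6, 200)
        assert np.allclose(sf.reflectivity(stack, q),
                           sf.fresnel_reflectivity(0.66, 0.334, q),
                           rtol=1e-10)

    def test_matches_transfer_matrix_oracle_spot_checks(self, slb_avidin_stack):
        q = np.linspace(0.01, 0.7, 150)
        a = sf.reflectivity(slb_avidin_stack, q)
        b = tm_reflectivity(slb_avidin_stack, q)
        assert np.max(np.abs(a - b) / b) < 1e-10

    def test_rejects_nonpositive_q(self, slb_stack):
        with pytest.raises(ValueError):
            sf.reflectivity(slb_stack, np.array([0.0, 0.1]))


class TestFitReflectivity:
    def test_rejects_all_fixed_template(self, slb_stack):
        curve = sf.gen_reflectivity(slb_stack, np.linspace(0.02, 0.5, 50),
                                    sf.NoiseSpec(reflectivity_relative_sigma=0))
        with pytest.raises(ValueError, match="free"):
            sf.fit_reflectivity(curve, slb_stack, free={})

    def test_deterministic_under_fixed_seed(self, slb_stack):
        curve = sf.gen_reflectivity(slb_stack, np.linspace(0.02, 0.5, 80),
                                    sf.NoiseSpec(seed=5))
        free = {"slabs[1].thickness_A": (10.0, 18.0)}
        ga = sf.GAConfig(population=16, generations=10, seed=11, polish=False)
        fit1 = sf.fit_reflectivity(curve, copy.deepcopy(slb_stack), free, ga)
        fit2 = sf.fit_reflectivity(curve, copy.deepcopy(slb_stack), free, ga)
        assert fit1.params == fit2.params
        assert fit1.generations_log == fit2.generations_log

    def test_recovers_two_free_parameters(self, slb_stack):
        curve = sf.gen_reflectivity(slb_stack, np.linspace(0.02, 0.6, 150),
                                    sf.NoiseSpec(reflectivity_relative_sigma=0))
        free = {"slabs[1].thickness_A": (10.0, 18.0),
                "slabs[0].rho_e": (0.35, 0.55)}
        ga = sf.GAConfig(population=32, generations=40, seed=2)
        fit = sf.fit_reflectivity(curve, copy.deepcopy(slb_stack), free, ga)
        assert fit.params["slabs[1].thickness_A"] == pytest.approx(14.0, rel=0.02)
        assert fit.params["slabs[0].rho_e"] == pytest.approx(0.45, rel=0.02)

    def test_nine_slab_fit_reaches_noise_floor(self, slb_avidin_stack):
        """SLB+avidin template fitted to its own 2%-noise curve: chi2/N < 1.5."""
        q = np.linspace(0.02, 0.6, 200)
        curve = sf.gen_reflectivity(
            slb_avidin_stack, q,
            sf.NoiseSpec(reflectivity_relative_sigma=0.02, seed=9))
        free = {}
        for i in (5, 6, 7, 8):   # the four added avidin/hydration slabs
            s = slb_avidin_stack.slabs[i]
            free[f"slabs[{i}].thickness_A"] = (0.7 * s.thickness_A,
                                               1.3 * s.thickness_A)
            free[f"slabs[{i}].rho_e"] = (0.7 * s.rho_e, 1.3 * s.rho_e)
        ga = sf.GAConfig(population=64, generations=60, seed=4)
        fit = sf.fit_reflectivity(curve, copy.deepcopy(slb_avidin_stack),
                                  free, ga)
        assert fit.chi2_reduced < 1.5


class TestDensityDifference:
    def test_identical_profiles_give_zero(self):
        z = np.linspace(0, 50, 101)
        p = sf.DensityProfile(z_A=z, rho_e=np.sin(z / 10) ** 2)
        d = sf.density_difference(p, p)
        assert np.allclose(d.rho_e, 0.0)

    def test_constant_offset(self):
        z = np.linspace(0, 50, 101)
        a = sf.DensityProfile(z_A=z, rho_e=np.full_like(z, 0.4))
        b = sf.DensityProfile(z_A=z, rho_e=np.full_like(z, 0.3))
        assert np.allclose(sf.density_difference(a, b).rho_e, 0.1)

    def test_antisymmetry_on_mismatched_grids(self):
        za, zb = np.linspace(0, 50, 101), np.linspace(-5, 48, 77)
        a = sf.DensityProfile(z_A=za, rho_e=0.3 + 0.1 * np.cos(za / 7))
        b = sf.DensityProfile(z_A=zb, rho_e=0.3 + 0.05 * np.sin(zb / 5))
        d1, d2 = sf.density_difference(a, b), sf.density_difference(b, a)
        assert np.allclose(d1.rho_e, -d2.rho_e)
        assert np.allclose(d1.z_A, d2.z_A)

    def test_disjoint_ranges_rejected(self):
        a = sf.DensityProfile(z_A=np.linspace(0, 10, 11),
                              rho_e=np.zeros(11))
        b = sf.DensityProfile(z_A=np.linspace(20, 30, 11),
                              rho_e=np.zeros(11))
        with pytest.raises(ValueError, match="overlap"):
            sf.density_difference(a, b)
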