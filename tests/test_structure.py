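"""Structural solver: gradients, inflation, prestress inversion, dynamics."""

import numpy as np
import pytest

from tonosim.geometry import CornealTopography, EyeMeshConfig, build_meridian
from tonosim.materials import OgdenMaterial, default_regional_map
from tonosim.structure import (MMHG_TO_MPA, FluidCavity, SolverError,
                               cavity_pressure, compute_stress_free,
                               inflate_static, newmark_step, shell_from_eye,
                               step_dynamic)

from conftest import make_sphere_shell


class TestFluidCavity:
    def test_reference_volume_gives_reference_pressure(self):
        cav = FluidCavity(P_ref=15.0, V_ref=6000.0)
        assert cavity_pressure(cav, 6000.0) == 15.0

    def test_bulk_modulus_conversion(self):
        # ppm volume deficit at K = 2200 MPa -> 2.2e-3 MPa = 16.50 mmHg
        cav = FluidCavity(P_ref=10.0, V_ref=1000.0, K=2200.0)
        dp = cavity_pressure(cav, 1000.0 * (1 - 1e-6)) - 10.0
        assert dp == pytest.approx(2.2e-3 / MMHG_TO_MPA, rel=1e-9)
        assert dp == pytest.approx(16.50, abs=0.01)

    def test_incompressible_pressure_source_limit(self):
        cav = FluidCavity(P_ref=12.0, V_ref=1000.0, K=0.0)
        for v in (500.0, 1000.0, 1500.0):
            assert cavity_pressure(cav, v) == 12.0


class TestGradientConsistency:
    def test_internal_force_is_energy_gradient(self):
        sh = make_sphere_shell(n=16, mu=0.05, alpha=110.0)
        rng = np.random.default_rng(3)
        x = sh.X0 + 0.01 * rng.standard_normal(sh.X0.shape)
        f = sh.internal_force(x)
        h = 1e-6
        fd = np.empty_like(f)
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd[i] = (sh.elastic_energy(xp) - sh.elastic_energy(xm)) / (2 * h)
        assert np.max(np.abs(f - fd)) <= 1e-5 * max(np.max(np.abs(fd)), 1.0)

    def test_volume_gradient_matches_finite_differences(self):
        sh = make_sphere_shell(n=12)
        rng = np.random.default_rng(5)
        x = sh.X0 + 0.05 * rng.standard_normal(sh.X0.shape)
        g = sh.volume_grad(x)
        h = 1e-6
        fd = np.array([(sh.volume(_bump(x, i, h)) - sh.volume(_bump(x, i, -h)))
                       / (2 * h) for i in range(len(x))])
        assert np.max(np.abs(g - fd)) <= 1e-6 * np.max(np.abs(fd))


def _bump(x, i, h):
    y = x.copy()
    y[i] += h
    return y


class TestStaticInflation:
    def test_zero_iop_means_zero_displacement(self):
        sh = make_sphere_shell(n=24)
        st = inflate_static(sh, 0.0)
        assert np.allclose(st.x, sh.X0)

    def test_thin_sphere_matches_laplace_law(self):
        # R = 10 mm, t = 0.5 mm, small-strain neo-Hookean, P = 2 kPa
        sh = make_sphere_shell(n=60, R=10.0, t=0.5, mu=1.0, alpha=2.0)
        P = 2e-3  # MPa
        st = inflate_static(sh, P / MMHG_TO_MPA)
        s_mer, s_hoop = sh.membrane_stress(st.x)
        R_def = np.mean(np.hypot(st.x[0::2], st.x[1::2]))
        laplace = P * R_def / (2 * 0.5)
        mean_stress = 0.5 * (np.mean(s_mer) + np.mean(s_hoop))
        assert mean_stress == pytest.approx(laplace, rel=0.05)

    def test_apical_rise_monotone_in_iop(self):
        mer = build_meridian(CornealTopography(), EyeMeshConfig())
        sh = shell_from_eye(mer, default_regional_map())
        z10 = inflate_static(sh, 10.0).x[1]
        z20 = inflate_static(sh, 20.0).x[1]
        assert z20 > z10 > sh.X0[1]

    def test_displacement_decreases_with_stiffness(self):
        mer = build_meridian(CornealTopography(), EyeMeshConfig())
        disp = []
        for mu in (0.0422, 0.1082):
            sh = shell_from_eye(mer, default_regional_map(mu))
            disp.append(np.max(np.abs(inflate_static(sh, 20.0).x - sh.X0)))
        assert disp[0] > disp[1]


class TestStressFree:
    def test_zero_iop_returns_measured_mesh(self):
        sh = make_sphere_shell(n=24)
        out, st, n_it = compute_stress_free(sh, 0.0)
        assert n_it == 0
        assert np.array_equal(out.X0, sh.X0)

    def test_default_eye_round_trip_below_tolerance(self):
        mer = build_meridian(CornealTopography(), EyeMeshConfig())
        sh = shell_from_eye(mer, default_regional_map())
        sf, st, n_it = compute_stress_free(sh, 15.0)
        assert np.max(np.abs(st.x - sh.X0)) < 1e-3
        assert n_it <= 25

    @pytest.mark.parametrize("iop,mu", [(10.0, 0.0422), (25.0, 0.1082)])
    def test_iteration_count_bounded_over_parameter_ranges(self, iop, mu):
        mer = build_meridian(CornealTopography(), EyeMeshConfig())
        sh = shell_from_eye(mer, default_regional_map(mu), prestress_mmhg=iop)
        _, _, n_it = compute_stress_free(sh, iop)
        assert n_it <= 25


class TestDynamics:
    def test_equilibrium_is_preserved_under_zero_load(self):
        sh = make_sphere_shell(n=24, mu=0.5, alpha=110.0)
        st = inflate_static(sh, 15.0)
        cav = FluidCavity(P_ref=15.0, V_ref=st.cavity_v)
        nxt = step_dynamic(sh, st, 0.1, cav, np.zeros_like(st.x))
        assert np.max(np.abs(nxt.x - st.x)) < 1e-9

    def test_single_mass_oscillator_second_order_convergence(self):
        # m x'' + k x = 0, x(0)=1: Newmark beta=1/4 gamma=1/2 is 2nd order
        m, k = 2.0, 5.0
        omega = np.sqrt(k / m)
        T = 3.0
        errs = []
        for dt in (0.02, 0.01, 0.005):
            x = np.array([1.0])
            v = np.zeros(1)
            a = np.array([-k / m])
            mass = np.array([m])
            free = np.array([0])
            g = lambda xx: k * xx
            t = 0.0
            while t < T - 1e-12:
                x, v, a, _, ok = newmark_step(x, v, a, dt, mass, g,
                                              np.zeros(1), free, tol=1e-10)
                assert ok
                t += dt
            errs.append(abs(x[0] - np.cos(omega * T)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.2)

    def test_impulse_energy_constant_after_pulse(self):
        # impulsive pressure pulse; with damping off the post-pulse total
        # energy (kinetic + strain + cavity) drifts < 1 %
        sh = make_sphere_shell(n=40, mu=0.5, alpha=110.0)
        st = inflate_static(sh, 15.0)
        cav = FluidCavity(P_ref=15.0, V_ref=st.cavity_v)
        el0 = sh.elastic_energy(st.x)
        dt, energies = 0.05, []
        p_seg = np.full(12, 5e-4)
        for kstep in range(80):
            t = kstep * dt
            f_ext = sh.pressure_force(st.x, p_seg) if t < 1.0 else np.zeros_like(st.x)
            st = step_dynamic(sh, st, dt, cav, f_ext)
            dV = st.cavity_v - cav.V_ref
            ucav = -cav.P_ref * MMHG_TO_MPA * dV + 0.5 * cav.K / cav.V_ref * dV**2
            kin = 0.5 * float(st.v @ (sh.mass * st.v))
            energies.append((t + dt, kin + (sh.elastic_energy(st.x) - el0) + ucav))
        e = np.array(energies)
        post = e[e[:, 0] > 1.0 + dt, 1]
        assert (post.max() - post.min()) / post.mean() < 0.01

    def test_nonpositive_dt_rejected(self):
        sh = make_sphere_shell(n=12)
        st = inflate_static(sh, 0.0)
        cav = FluidCavity(P_ref=0.0, V_ref=st.cavity_v)
        with pytest.raises(ValueError):
            step_dynamic(sh, st, 0.0, cav, np.zeros_like(st.x))
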