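"""Axisymmetric structural solver for the eye shell.

The eye wall is solved as an axisymmetric meridian shell: nonlinear
membrane response from the incompressible plane-stress Ogden law, plus a
discrete-Kirchhoff bending surrogate (meridional hinge stiffness and a
hoop-curvature penalty) that regularises applanation and dimpling.  The
intraocular fluids are a lumped fluid cavity whose pressure follows the
enclosed volume through a bulk modulus.  The module provides

* static inflation to a target IOP (Newton with load ramping),
* stress-free (prestress) inversion by fixed-point iteration,
* one implicit Newmark step of the damped equations of motion.

Internal units: mm, ms, g, N, MPa (1 mm/ms = 1 m/s; 1 MPa mm^3 = 1 mJ).
Pressures cross the interface in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MeridianGeometry
from .materials import RegionalMaterialMap

__all__ = [
    "FluidCavity",
    "StructuralState",
    "MeridianShell",
    "SolverError",
    "cavity_pressure",
    "inflate_static",
    "compute_stress_free",
    "newmark_step",
    "step_dynamic",
]

MMHG_TO_MPA = 133.322e-6


class SolverError(RuntimeError):
    """Newton or fixed-point iteration failed to converge."""


@dataclass(frozen=True)
class FluidCavity:
    """Lumped fluid cavity representing the intraocular contents.

    P = P_ref + K (V_ref - V) / V_ref  (converted to mmHg at the interface):
    a nearly incompressible fluid (default bulk modulus 2.2e3 MPa, water)
    filling the globe at reference pressure P_ref (the IOP) and volume V_ref.
    """

    P_ref: float            # mmHg
    V_ref: float            # mm^3
    K: float = 2.2e3        # MPa
    rho_fluid: float = 1000.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.K < 0 or self.V_ref <= 0:
            raise ValueError("cavity requires K >= 0 and V_ref > 0")


def cavity_pressure(cav: FluidCavity, V: float) -> float:
    """Cavity pressure (mmHg) at current volume V (mm^3)."""
    if V <= 0:
        raise ValueError("cavity volume must be positive")
    return cav.P_ref + cav.K * (cav.V_ref - V) / cav.V_ref / MMHG_TO_MPA


@dataclass
class StructuralState:
    """Nodal kinematics plus cavity state at one instant."""

    x: np.ndarray          # interleaved (r0, z0, r1, z1, ...), mm
    v: np.ndarray          # mm/ms
    a: np.ndarray          # mm/ms^2
    t: float               # ms
    cavity_p: float        # mmHg
    cavity_v: float        # mm^3


class MeridianShell:
    """Discretised axisymmetric shell with reference (stress-free) geometry.

    The reference midsurface is ``X0`` (interleaved r, z).  Boundary
    conditions follow the eye model: on-axis nodes are fixed radially
    (axisymmetry, which also pins the poles in X and Y), and the equator
    node is fixed axially to remove rigid-body motion in Z.
    """

    def __init__(self, r, z, thickness, materials, equator_index,
                 rho_tissue=1.062e-3, bending_scale=1.0,
                 prestress_mmhg: float = 0.0, tangent_bending: float = 0.0):
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        self.n = len(r)
        self.thickness = np.asarray(thickness, dtype=float)
        if len(self.thickness) == self.n:  # nodal -> segment mid values
            self.t0 = 0.5 * (self.thickness[:-1] + self.thickness[1:])
        else:
            self.t0 = self.thickness
        self.equator_index = int(equator_index)
        self.rho = rho_tissue
        self.bending_scale = float(bending_scale)
        self.prestress_mmhg = float(prestress_mmhg)
        self.tangent_bending = float(tangent_bending)

        # segment material terms: list of (mu_seg, alpha_seg) arrays
        nseg = self.n - 1
        if isinstance(materials, (list, tuple)) and not hasattr(materials[0], "mu"):
            raise TypeError("materials must be per-segment OgdenMaterial list")
        mats = list(materials)
        if len(mats) != nseg:
            raise ValueError("need one material per segment")
        nterm = max(m.order for m in mats)
        self.mu_terms = np.zeros((nterm, nseg))
        self.alpha_terms = np.ones((nterm, nseg))
        for j, m in enumerate(mats):
            for i in range(m.order):
                self.mu_terms[i, j] = m.mu[i]
                self.alpha_terms[i, j] = m.alpha[i]
        self.mu0 = np.array([m.shear_modulus for m in mats])

        X0 = np.empty(2 * self.n)
        X0[0::2] = r
        X0[1::2] = z
        self._fixed = np.zeros(2 * self.n, dtype=bool)
        self._fixed[0] = True                       # apex on axis
        self._fixed[2 * (self.n - 1)] = True        # posterior pole on axis
        self._fixed[2 * self.equator_index + 1] = True  # equator z
        self.free = np.flatnonzero(~self._fixed)
        self.set_reference(X0)

    # -- reference state ---------------------------------------------------
    def set_reference(self, X0: np.ndarray) -> None:
        """(Re)build all reference quantities from coordinates X0."""
        self.X0 = np.asarray(X0, dtype=float).copy()
        r, z = self.X0[0::2], self.X0[1::2]
        dr, dz = np.diff(r), np.diff(z)
        self.L0 = np.hypot(dr, dz)
        if np.any(self.L0 <= 0):
            raise ValueError("degenerate meridian segment")
        self.rbar0 = 0.5 * (r[:-1] + r[1:])
        self.A0 = 2.0 * np.pi * np.maximum(self.rbar0, 1e-9) * self.L0
        self.V0 = self.A0 * self.t0          # reference volume per segment
        tau0 = np.arctan2(dz, dr)
        self.tau0 = tau0
        self.kth0 = -np.sin(tau0) / np.maximum(self.rbar0, 1e-9)
        self.psi0 = np.diff(tau0)
        # bending modulus per segment: B = E_b t^3 / 9 (nu = 1/2) with the
        # incremental modulus about the prestressed state, E_b = 3 mu0 +
        # alpha * sigma_pre -- a strongly strain-stiffening material bends
        # about its pressurised configuration with the tension-stiffened
        # tangent modulus, not the small-strain one.  sigma_pre is the
        # Laplace membrane prestress P rho_theta / (2 t) from the local
        # hoop radius of curvature.
        E_b = 3.0 * self.mu0
        if self.prestress_mmhg > 0.0 and self.tangent_bending > 0.0:
            with np.errstate(divide="ignore"):
                rho_th = np.where(np.abs(self.kth0) > 1e-12,
                                  1.0 / np.abs(self.kth0), 0.0)
            rho_th[rho_th == 0.0] = np.max(rho_th)
            sigma_pre = (self.prestress_mmhg * MMHG_TO_MPA * rho_th
                         / (2.0 * self.t0))
            alpha_max = self.alpha_terms.max(axis=0)
            E_b = E_b + self.tangent_bending * alpha_max * sigma_pre
        self.B = self.bending_scale * E_b * self.t0**3 / 9.0
        Bn = 0.5 * (self.B[:-1] + self.B[1:])
        ln = 0.5 * (self.L0[:-1] + self.L0[1:])
        rn = r[1:-1]
        self.k_hinge = Bn / ln * 2.0 * np.pi * np.maximum(rn, 1e-9)
        # pole hinges (mirror symmetry at the axis)
        self.k_pole0 = 4.0 * self.B[0] / self.L0[0] * 2.0 * np.pi * self.rbar0[0]
        self.k_pole1 = 4.0 * self.B[-1] / self.L0[-1] * 2.0 * np.pi * self.rbar0[-1]
        # lumped nodal mass (g)
        mseg = self.rho * self.V0
        m = np.zeros(self.n)
        m[:-1] += 0.5 * mseg
        m[1:] += 0.5 * mseg
        self.mass = np.repeat(m, 2)

    def with_reference(self, X0: np.ndarray) -> "MeridianShell":
        import copy
        sh = copy.copy(self)
        sh.set_reference(X0)
        return sh

    # -- kinematic helpers (batched over leading axes) ---------------------
    @staticmethod
    def _rz(x):
        return x[..., 0::2], x[..., 1::2]

    def _segment_state(self, x):
        r, z = self._rz(x)
        dr = r[..., 1:] - r[..., :-1]
        dz = z[..., 1:] - z[..., :-1]
        L = np.sqrt(dr * dr + dz * dz)
        lam_s = L / self.L0
        lam_t = (r[..., :-1] + r[..., 1:]) / (2.0 * np.maximum(self.rbar0, 1e-9))
        return r, z, dr, dz, L, lam_s, lam_t

    # -- energies ----------------------------------------------------------
    def elastic_energy(self, x) -> float | np.ndarray:
        r, z, dr, dz, L, lam_s, lam_t = self._segment_state(x)
        w = np.zeros_like(lam_s)
        for mu, a in zip(self.mu_terms, self.alpha_terms):
            w = w + 2.0 * mu / a**2 * (
                lam_s**a + lam_t**a + (lam_s * lam_t) ** (-a) - 3.0)
        e = np.sum(w * self.V0, axis=-1)
        # bending
        tau = np.arctan2(dz, dr)
        kth = -np.sin(tau) / np.maximum(0.5 * (r[..., :-1] + r[..., 1:]), 1e-9)
        e = e + np.sum(0.5 * self.B * (kth - self.kth0) ** 2 * self.A0, axis=-1)
        psi = tau[..., 1:] - tau[..., :-1]
        e = e + np.sum(0.5 * self.k_hinge * (psi - self.psi0) ** 2, axis=-1)
        e = e + 0.5 * self.k_pole0 * (tau[..., 0] - self.tau0[0]) ** 2
        e = e + 0.5 * self.k_pole1 * (tau[..., -1] - self.tau0[-1]) ** 2
        return e

    def membrane_stress(self, x):
        """Principal Cauchy membrane stresses (sigma_s, sigma_theta), MPa."""
        *_, lam_s, lam_t = self._segment_state(x)
        s1 = np.zeros_like(lam_s)
        s2 = np.zeros_like(lam_t)
        for mu, a in zip(self.mu_terms, self.alpha_terms):
            l3a = (lam_s * lam_t) ** (-a)
            s1 = s1 + 2.0 * mu / a * (lam_s**a - l3a)
            s2 = s2 + 2.0 * mu / a * (lam_t**a - l3a)
        return s1, s2

    # -- forces ------------------------------------------------------------
    def internal_force(self, x) -> np.ndarray:
        """Gradient of the elastic energy w.r.t. nodal coordinates (N)."""
        r, z, dr, dz, L, lam_s, lam_t = self._segment_state(x)
        f = np.zeros_like(x)
        fr = f[..., 0::2]
        fz = f[..., 1::2]

        dwds = np.zeros_like(lam_s)
        dwdt = np.zeros_like(lam_t)
        for mu, a in zip(self.mu_terms, self.alpha_terms):
            l3a = (lam_s * lam_t) ** (-a)
            dwds = dwds + 2.0 * mu / a * (lam_s ** (a - 1.0) - l3a / lam_s)
            dwdt = dwdt + 2.0 * mu / a * (lam_t ** (a - 1.0) - l3a / lam_t)
        ur, uz = dr / L, dz / L
        cs = self.V0 * dwds / self.L0
        ct = self.V0 * dwdt / (2.0 * np.maximum(self.rbar0, 1e-9))
        fr[..., :-1] += -cs * ur + ct
        fr[..., 1:] += cs * ur + ct
        fz[..., :-1] += -cs * uz
        fz[..., 1:] += cs * uz

        # hoop-curvature bending
        tau = np.arctan2(dz, dr)
        rbar = 0.5 * (r[..., :-1] + r[..., 1:])
        rb = np.maximum(rbar, 1e-9)
        kth = -np.sin(tau) / rb
        dEdk = self.B * (kth - self.kth0) * self.A0
        dk_dtau = -np.cos(tau) / rb
        dk_drbar = np.sin(tau) / rb**2
        # tau derivatives: d tau/d dr = -dz/L^2, d tau/d dz = dr/L^2
        gtau = dEdk * dk_dtau
        L2 = L * L
        fr[..., :-1] += gtau * (dz / L2) + 0.5 * dEdk * dk_drbar
        fr[..., 1:] += -gtau * (dz / L2) + 0.5 * dEdk * dk_drbar
        fz[..., :-1] += -gtau * (dr / L2)
        fz[..., 1:] += gtau * (dr / L2)

        # meridional hinges (interior nodes) + pole hinges
        psi = tau[..., 1:] - tau[..., :-1]
        m_h = self.k_hinge * (psi - self.psi0)     # dE/dpsi
        # dE/dtau_j gets +m from hinge j (psi_j = tau_j - tau_{j-1}) ...
        gt = np.zeros_like(tau)
        gt[..., 1:] += m_h
        gt[..., :-1] -= m_h
        gt[..., 0] += self.k_pole0 * (tau[..., 0] - self.tau0[0])
        gt[..., -1] += self.k_pole1 * (tau[..., -1] - self.tau0[-1])
        fr[..., :-1] += gt * (dz / L2)
        fr[..., 1:] += -gt * (dz / L2)
        fz[..., :-1] += -gt * (dr / L2)
        fz[..., 1:] += gt * (dr / L2)
        return f

    # -- cavity geometry ---------------------------------------------------
    def volume(self, x) -> float | np.ndarray:
        """Enclosed volume of the revolved meridian (mm^3)."""
        r, z = self._rz(x)
        r1, r2 = r[..., :-1], r[..., 1:]
        return np.sum(np.pi / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)
                      * (z[..., :-1] - z[..., 1:]), axis=-1)

    def volume_grad(self, x) -> np.ndarray:
        r, z = self._rz(x)
        r1, r2 = r[..., :-1], r[..., 1:]
        dzj = z[..., :-1] - z[..., 1:]
        g = np.zeros_like(x)
        gr = g[..., 0::2]
        gz = g[..., 1::2]
        gr[..., :-1] += np.pi / 3.0 * (2.0 * r1 + r2) * dzj
        gr[..., 1:] += np.pi / 3.0 * (r1 + 2.0 * r2) * dzj
        s = np.pi / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)
        gz[..., :-1] += s
        gz[..., 1:] -= s
        return g

    # -- external loads ----------------------------------------------------
    def pressure_force(self, x, p_seg: np.ndarray) -> np.ndarray:
        """Consistent nodal force from gauge pressure p_seg (MPa) applied on
        the first ``len(p_seg)`` meridian segments, pushing inward along the
        current outward normal (follower load)."""
        m = len(p_seg)
        r, z = self._rz(x)
        dr = r[..., 1:m + 1] - r[..., :m]
        dz = z[..., 1:m + 1] - z[..., :m]
        L = np.sqrt(dr * dr + dz * dz)
        r1, r2 = r[..., :m], r[..., 1:m + 1]
        # outward normal (-dz, dr)/L; consistent (radius-weighted) nodal
        # lumping of the frustum load: node weights (r1/3 + r2/6) and
        # (r1/6 + r2/3) of the 2 pi L total
        c = -p_seg * 2.0 * np.pi * L
        w1 = r1 / 3.0 + r2 / 6.0
        w2 = r1 / 6.0 + r2 / 3.0
        nR, nZ = -dz / L, dr / L
        f = np.zeros_like(x)
        f[..., 0:2 * m:2] += c * w1 * nR
        f[..., 2:2 * (m + 1):2] += c * w2 * nR
        f[..., 1:2 * m + 1:2] += c * w1 * nZ
        f[..., 3:2 * (m + 1) + 1:2] += c * w2 * nZ
        return f

    # -- residuals and Jacobians -------------------------------------------
    def static_residual(self, x, P_mpa: float, f_ext=None) -> np.ndarray:
        """f_int - P dV/dx - f_ext (full-vector)."""
        g = self.internal_force(x) - P_mpa * self.volume_grad(x)
        if f_ext is not None:
            g = g - f_ext
        return g

    def cavity_residual(self, x, cav: FluidCavity, f_ext=None) -> np.ndarray:
        V = self.volume(x)
        P = cav.P_ref * MMHG_TO_MPA + cav.K * (cav.V_ref - V) / cav.V_ref
        g = self.internal_force(x) - np.asarray(P)[..., None] * self.volume_grad(x)
        if f_ext is not None:
            g = g - f_ext
        return g

    def fd_jacobian(self, x, res_fn, h: float = 1e-7) -> np.ndarray:
        """Forward-difference Jacobian of ``res_fn`` on the free dofs."""
        free = self.free
        base = res_fn(x)[free]
        X = np.repeat(x[None, :], len(free), axis=0)
        X[np.arange(len(free)), free] += h
        G = res_fn(X)[:, free]
        return (G - base[None, :]).T / h

    def embed(self, xf: np.ndarray, xref: np.ndarray) -> np.ndarray:
        x = xref.copy()
        x[self.free] = xf
        return x


# ---------------------------------------------------------------------------
# static analyses
# ---------------------------------------------------------------------------

def _newton(shell: MeridianShell, x0: np.ndarray, res_fn, tol: float,
            max_iter: int = 60) -> np.ndarray:
    """Damped Newton on the free dofs with backtracking line search."""
    x = x0.copy()
    g = res_fn(x)[shell.free]
    norm = float(np.max(np.abs(g)))
    for _ in range(max_iter):
        if norm < tol:
            return x
        J = shell.fd_jacobian(x, res_fn)
        try:
            dx = np.linalg.solve(J, -g)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular tangent (residual {norm:.3e})") from exc
        step = 1.0
        for _ls in range(12):
            xt = x.copy()
            xt[shell.free] += step * dx
            gt = res_fn(xt)[shell.free]
            nt = float(np.max(np.abs(gt)))
            if np.isfinite(nt) and nt < norm * (1.0 - 1e-4 * step) + tol:
                x, g, norm = xt, gt, nt
                break
            step *= 0.5
        else:
            raise SolverError(f"line search stalled (residual {norm:.3e})")
    raise SolverError(f"Newton did not converge (residual {norm:.3e}, tol {tol:.1e})")


def _force_tolerance(shell: MeridianShell, P_mpa: float) -> float:
    scale = max(abs(P_mpa), 1e-4) * float(np.max(shell.A0))
    return max(1e-10, 1e-7 * scale)


def inflate_static(shell: MeridianShell, iop_mmhg: float,
                   n_ramp: int = 4, x0: np.ndarray | None = None) -> StructuralState:
    """Inflate the shell from its (stress-free) reference to a target IOP.

    Pressure-controlled Newton solve with load ramping; returns the
    equilibrium state with the cavity initialised at (IOP, V_equilibrium).
    """
    P = iop_mmhg * MMHG_TO_MPA
    x = shell.X0.copy() if x0 is None else x0.copy()
    if iop_mmhg != 0.0:
        for frac in np.linspace(1.0 / n_ramp, 1.0, n_ramp):
            Pf = P * frac
            x = _newton(shell, x, lambda xx: shell.static_residual(xx, Pf),
                        _force_tolerance(shell, Pf))
    V = float(shell.volume(x))
    return StructuralState(x=x, v=np.zeros_like(x), a=np.zeros_like(x),
                           t=0.0, cavity_p=float(iop_mmhg), cavity_v=V)


def compute_stress_free(shell: MeridianShell, iop_mmhg: float,
                        tol_geo: float = 1e-3, max_iter: int = 50,
                        relax: float = 1.0):
    """Stress-free (prestress) inversion of a measured, pressurised geometry.

    Fixed-point iteration X <- X - relax * (inflate(X, IOP) - X_measured);
    returns ``(stress_free_shell, inflated_state, n_iterations)``.  The
    returned inflated state reproduces the measured geometry within
    ``tol_geo`` (mm, max nodal error).
    """
    x_meas = shell.X0.copy()
    if iop_mmhg == 0.0:
        st = inflate_static(shell, 0.0)
        return shell, st, 0
    X = x_meas.copy()
    trial = shell
    prev = np.inf
    grow = 0
    x_warm = None
    for it in range(1, max_iter + 1):
        trial = shell.with_reference(X)
        st = inflate_static(trial, iop_mmhg, x0=x_warm)
        x_warm = st.x
        d = st.x - x_meas
        res = float(np.max(np.abs(d)))
        if res < tol_geo:
            return trial, st, it
        grow = grow + 1 if res > prev else 0
        if grow >= 3:
            raise SolverError(
                f"stress-free iteration diverging (residual {res:.3e} mm)")
        prev = res
        X = X - relax * d
    raise SolverError(
        f"stress-free iteration did not reach {tol_geo} mm in {max_iter} steps")


# ---------------------------------------------------------------------------
# implicit dynamics
# ---------------------------------------------------------------------------

def newmark_step(x_n, v_n, a_n, dt, mass, g_fn, f_ext, free,
                 damping=None, beta: float = 0.25, gamma: float = 0.5,
                 jac_fn=None, tol: float = 1e-9, max_iter: int = 25):
    """One implicit Newmark step of  M a + C v + g(x) = f_ext.

    ``mass`` is the lumped (diagonal) mass; ``g_fn(x)`` the static residual
    (internal minus conservative external forces); ``f_ext`` the remaining
    external force vector held over the step; ``free`` the free-dof index.
    Returns (x, v, a, n_newton, converged).
    """
    inv_bdt2 = 1.0 / (beta * dt * dt)
    c_v = gamma / (beta * dt)

    def kinematics(x):
        a = (x - x_n) * inv_bdt2 - v_n / (beta * dt) - (0.5 / beta - 1.0) * a_n
        v = v_n + dt * ((1.0 - gamma) * a_n + gamma * a)
        return v, a

    def residual(x):
        v, a = kinematics(x)
        r = mass * a + g_fn(x) - f_ext
        if damping is not None:
            r = r + damping @ v if damping.ndim == 2 else r + damping * v
        return r

    x = x_n.copy()
    r = residual(x)[free]
    norm = float(np.max(np.abs(r)))
    J = None
    for it in range(max_iter):
        if norm < tol:
            v, a = kinematics(x)
            return x, v, a, it, True
        if J is None or it % 4 == 3:
            if jac_fn is not None:
                K = jac_fn(x)
            else:
                K = _fd_static_jacobian(g_fn, x, free)
            J = K + np.diag(mass[free]) * inv_bdt2
            if damping is not None:
                J = J + (damping[np.ix_(free, free)] if damping.ndim == 2
                         else np.diag(damping[free])) * c_v
        try:
            dx = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            return x, *kinematics(x), it, False
        step = 1.0
        for _ in range(10):
            xt = x.copy()
            xt[free] += step * dx
            rt = residual(xt)[free]
            nt = float(np.max(np.abs(rt)))
            if np.isfinite(nt) and nt < norm:
                x, r, norm = xt, rt, nt
                break
            step *= 0.5
        else:
            J = None  # refresh Jacobian and retry once
            if it > max_iter - 3:
                break
    v, a = kinematics(x)
    return x, v, a, max_iter, norm < tol


def _fd_static_jacobian(g_fn, x, free, h: float = 1e-7):
    base = g_fn(x)[free]
    X = np.repeat(x[None, :], len(free), axis=0)
    X[np.arange(len(free)), free] += h
    G = g_fn(X)[:, free]
    return (G - base[None, :]).T / h


def step_dynamic(shell: MeridianShell, state: StructuralState, dt: float,
                 cav: FluidCavity, f_ext: np.ndarray,
                 damping=None, tol: float | None = None) -> StructuralState:
    """Advance the shell by one implicit Newmark step under ``f_ext``.

    ``f_ext`` is the surface-load nodal force vector (held constant over
    the step, staggered coupling); the cavity force is treated implicitly.
    Raises SolverError on non-convergence (the caller adapts dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g_fn = lambda x: shell.cavity_residual(x, cav)
    if tol is None:
        tol = _force_tolerance(shell, cav.P_ref * MMHG_TO_MPA)
    x, v, a, n_it, ok = newmark_step(
        state.x, state.v, state.a, dt, shell.mass, g_fn, f_ext,
        shell.free, damping=damping, tol=tol)
    if not ok:
        raise SolverError(f"Newmark Newton stalled at dt={dt} ms")
    V = float(shell.volume(x))
    return StructuralState(x=x, v=v, a=a, t=state.t + dt,
                           cavity_p=cavity_pressure(cav, V), cavity_v=V)


def shell_from_eye(mer: MeridianGeometry, matmap: RegionalMaterialMap,
                   bending_scale: float = 0.5, prestress_mmhg: float = 0.0,
                   tangent_bending: float = 0.0) -> MeridianShell:
    """Build the solver shell from an eye meridian: midsurface coordinates
    (anterior surface offset inward by half the wall thickness) and the
    per-segment regional Ogden materials."""
    r, z, t = mer.r, mer.z, mer.thickness
    dr = np.gradient(r)
    dz = np.gradient(z)
    L = np.hypot(dr, dz)
    n_r, n_z = dz / L, -dr / L
    if n_z[0] < 0:
        n_r, n_z = -n_r, -n_z
    n_r[0], n_z[0] = 0.0, 1.0
    n_r[-1], n_z[-1] = 0.0, -1.0
    rm = r - 0.5 * t * n_r
    zm = z - 0.5 * t * n_z
    rm[0] = 0.0
    rm[-1] = 0.0
    mats = [matmap[reg] for reg in mer.region]
    rho = mats[0].rho_tissue * 1e-6  # kg/m^3 -> g/mm^3
    return MeridianShell(rm, zm, t, mats, mer.equator_index,
                         rho_tissue=rho, bending_scale=bending_scale,
                         prestress_mmhg=prestress_mmhg,
                         tangent_bending=tangent_bending)
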