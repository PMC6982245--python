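"""Reduced-order impinging-jet surface-pressure model.

The air puff of a non-contact tonometer is a short round jet (orifice
diameter 2.4 mm, standoff 11 mm, peak exit velocity 167.8 m/s over a 30 ms
span) impinging on the cornea.  Instead of resolving the turbulent flow,
this module closes the surface load with classical impinging-jet theory:

* temporal profile -- a smooth half-sine-squared ramp peaking at 16 ms;
* centerline closure -- full stagnation (dynamic) pressure while the
  surface lies inside the potential core, inverse-square decay beyond it;
* spatial shape -- a Gaussian stagnation bell plus a negative (suction)
  annulus produced by the accelerating radial wall jet;
* deformation feedback -- in coupled mode the standoff grows with apex
  retreat and the stagnation pressure is attenuated by the central
  concavity of the deformed profile (the dimple shelters the stagnation
  point), which is the fluid-structure interaction surrogate.

The closure coefficients ``c_w`` (bell width), ``c_s`` (suction strength)
and ``c_f`` (concavity feedback) are frozen calibration constants of the
model configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "JetConfig",
    "SurfacePressureField",
    "nozzle_velocity",
    "reynolds",
    "core_length",
    "stagnation_pressure",
    "surface_pressure_field",
]

PA_TO_MMHG = 1.0 / 133.322


@dataclass(frozen=True)
class JetConfig:
    """Air-jet parameters (mm / ms / m/s / Pa units at the interface).

    ``theta_core`` and ``theta_outer`` are the potential-core contraction
    and outer spreading half-angles of a round jet; ``c_w``, ``c_s`` and
    ``c_f`` are the calibrated closure coefficients (see module docstring).
    """

    D: float = 2.4               # orifice diameter, mm
    H: float = 11.0              # standoff distance, mm
    V_max: float = 167.8         # peak nozzle velocity, m/s
    T: float = 30.0              # puff span, ms
    t_peak: float = 16.0         # time of peak velocity, ms
    rho_air: float = 1.204       # kg/m^3
    mu_air: float = 1.83e-5      # Pa s
    theta_core: float = 5.0      # deg
    theta_outer: float = 8.5     # deg
    c_w: float = 0.555           # bell-width factor (calibrated)
    c_s: float = 0.15            # annulus suction coefficient
    c_f: float = 0.142           # deformation-feedback coefficient (calibrated)

    def __post_init__(self) -> None:
        for name in ("D", "H", "V_max", "T", "t_peak", "rho_air", "mu_air",
                     "theta_core", "theta_outer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"jet parameter {name} must be positive")
        if self.t_peak >= self.T:
            raise ValueError("t_peak must be earlier than the puff span T")

    def with_coefficients(self, **kw) -> "JetConfig":
        return replace(self, **kw)


def nozzle_velocity(cfg: JetConfig, t) -> float | np.ndarray:
    """Nozzle exit velocity (m/s) at time t (ms).

    Half-sine-squared ramp: rises from 0 to V_max at t_peak, decays
    symmetrically to 0 at T, and stays 0 afterwards; C1-continuous.
    """
    t = np.asarray(t, dtype=float)
    up = cfg.V_max * np.sin(np.pi * t / (2.0 * cfg.t_peak)) ** 2
    down = cfg.V_max * np.sin(
        np.pi * (cfg.T - t) / (2.0 * (cfg.T - cfg.t_peak))) ** 2
    v = np.where(t <= cfg.t_peak, up, np.where(t < cfg.T, down, 0.0))
    v = np.where(t < 0, 0.0, v)
    return float(v) if v.ndim == 0 else v


def reynolds(cfg: JetConfig, V: float) -> float:
    """Jet Reynolds number rho V D / mu for nozzle velocity V (m/s)."""
    if V < 0:
        raise ValueError("velocity must be >= 0")
    return cfg.rho_air * V * (cfg.D * 1e-3) / cfg.mu_air


def core_length(cfg: JetConfig) -> float:
    """Potential-core length (mm): the orifice radius over tan(theta_core)."""
    return (cfg.D / 2.0) / np.tan(np.radians(cfg.theta_core))


def stagnation_pressure(cfg: JetConfig, V: float, z_eff: float) -> float:
    """Centerline stagnation gauge pressure (Pa) at distance z_eff (mm).

    Full dynamic pressure q = rho V^2 / 2 while the surface is inside the
    potential core (z_eff <= core length), with inverse-square centerline
    decay beyond it.
    """
    if z_eff <= 0:
        raise ValueError("effective distance must be positive")
    q = 0.5 * cfg.rho_air * V * V
    Lc = core_length(cfg)
    return float(q * min(1.0, (Lc / z_eff) ** 2))


@dataclass
class SurfacePressureField:
    """Gauge pressure (Pa) along the meridian at one instant."""

    s: np.ndarray         # arc length from the apex, mm
    pressure: np.ndarray  # Pa
    t: float              # ms
    mode: str             # "rigid" | "coupled"
    q_apex: float         # centerline stagnation pressure actually applied, Pa

    def apex_pressure_mmhg(self) -> float:
        return float(self.pressure[0]) * PA_TO_MMHG


def _suction_lobe(s: np.ndarray, b: float) -> np.ndarray:
    """Normalized annular suction shape: peaks at s = b*sqrt(2), 0 at 0 and inf."""
    x2 = (s / b) ** 2 / 2.0
    return x2 * np.exp(1.0 - x2)


def central_concavity(s: np.ndarray, w: np.ndarray, D: float,
                      s_ref: float = 2.5) -> float:
    """Non-dimensional central concavity of an inward-displacement profile.

    ``w`` is the inward normal displacement sampled at arc lengths ``s``;
    the concavity is the excess apex indentation over the rim of the
    central region (s_ref, mm), normalized by the orifice diameter.  Zero
    for convex (undeformed) profiles.
    """
    w_ref = float(np.interp(s_ref, s, w))
    return max(0.0, (float(w[0]) - w_ref) / D)


def surface_pressure_field(cfg: JetConfig, s, t: float, mode: str = "rigid",
                           apex_displacement: float = 0.0,
                           concavity: float = 0.0) -> SurfacePressureField:
    """Surface gauge-pressure distribution along the meridian arc length.

    P(s) = q_eff exp(-(s/b)^2) - c_s q_eff g(s; b) with the bell width
    b = c_w (D/2 + z_eff tan(theta_outer)).  In rigid mode z_eff = H and
    the feedback terms are ignored.  In coupled mode z_eff = H + apex
    displacement (the apex retreats from the nozzle) and q_eff is further
    attenuated by 1/(1 + c_f * concavity).
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite surface coordinates")
    if mode not in ("rigid", "coupled"):
        raise ValueError("mode must be 'rigid' or 'coupled'")
    V = nozzle_velocity(cfg, t)
    if mode == "rigid":
        z_eff = cfg.H
        q_eff = stagnation_pressure(cfg, V, z_eff)
    else:
        z_eff = cfg.H + max(0.0, apex_displacement)
        q_eff = stagnation_pressure(cfg, V, z_eff) / (1.0 + cfg.c_f * max(0.0, concavity))
    b = cfg.c_w * (cfg.D / 2.0 + z_eff * np.tan(np.radians(cfg.theta_outer)))
    p = q_eff * (np.exp(-(s / b) ** 2) - cfg.c_s * _suction_lobe(s, b))
    return SurfacePressureField(s=s, pressure=p, t=float(t), mode=mode,
                                q_apex=float(q_eff))
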