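"""Dynamic corneal response (DCR) parameter extraction.

From a simulated deformation trace this module extracts the metrics a
non-contact tonometer reports: first-applanation time/length/velocity and
pressure (A1, AP1), highest-concavity time/amplitude and peak distance
(HC, PD), and the stiffness parameter at highest concavity

    SP-HC = (AP1 - IOP) / (HC deformation - A1 deformation).

Applanation is detected on the anterior meridian profile: the applanated
zone is the central chord over which the profile deviates from a flat
chord by no more than ``tau_flat`` (10 um by default).  Because the flat
span peaks exactly when the central curvature passes through zero, A1 is
taken as the first local maximum of the flat-span length during the
inward phase; the device's internal definition is proprietary, so this
operational definition is versioned here and can be swapped without
touching the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .coupling import SimulationTrace

__all__ = [
    "DCRRecord",
    "ApplanationResult",
    "detect_applanation",
    "highest_concavity",
    "stiffness_parameter",
    "extract_dcr",
]


@dataclass
class DCRRecord:
    """The nine dynamic corneal response parameters."""

    A1_time: float        # ms
    A1_length: float      # mm
    A1_velocity: float    # m/s (numerically equal to mm/ms)
    HC_time: float        # ms
    peak_distance: float  # mm
    A1_def_amp: float     # mm
    HC_def_amp: float     # mm
    AP1: float            # mmHg
    SP_HC: float          # (AP1 - IOP) / (HC_def - A1_def)

    def as_dict(self) -> dict:
        return {
            "A1 Time (ms)": self.A1_time,
            "A1 Length (mm)": self.A1_length,
            "A1 Velocity (mm/s)": self.A1_velocity,
            "HC Time (ms)": self.HC_time,
            "Peak Distance (mm)": self.peak_distance,
            "A1 Def. Amp. (mm)": self.A1_def_amp,
            "HC Def. Amp. (mm)": self.HC_def_amp,
            "AP1 (mmHg)": self.AP1,
            "SP-HC": self.SP_HC,
        }


@dataclass
class ApplanationResult:
    found: bool
    A1_time: float = np.nan
    A1_length: float = np.nan
    A1_velocity: float = np.nan
    A1_def_amp: float = np.nan
    AP1: float = np.nan


def _flat_span(r: np.ndarray, z: np.ndarray, tau: float, s_max: float,
               dr: float = 0.02) -> float:
    """Chord length of the central applanated zone of one profile.

    Largest 2*r1 such that the profile height varies by at most ``tau``
    over [0, r1]; by axial symmetry the flat chord is horizontal and spans
    [-r1, r1].
    """
    m = r <= s_max + 0.5
    spl = CubicSpline(r[m], z[m])
    rr = np.arange(0.0, min(s_max, r[m][-1]), dr)
    zz = spl(rr)
    hi = np.maximum.accumulate(zz)
    lo = np.minimum.accumulate(zz)
    bad = np.flatnonzero(hi - lo > tau)
    r1 = rr[-1] if len(bad) == 0 else rr[max(bad[0] - 1, 0)]
    return 2.0 * r1


def flat_span_history(trace: SimulationTrace, tau_flat: float = 0.010,
                      s_max: float = 4.0) -> np.ndarray:
    """Applanated-chord length (mm) at every trace sample."""
    return np.array([
        _flat_span(trace.prof_r[i], trace.prof_z[i], tau_flat, s_max)
        for i in range(len(trace.t))
    ])


def detect_applanation(trace: SimulationTrace, tau_flat: float = 0.010,
                       s_max: float = 4.0, min_length: float = 1.0
                       ) -> ApplanationResult:
    """First-applanation metrics from a deformation trace.

    A1 is the first local maximum of the applanated-chord length that
    exceeds ``min_length`` mm during the inward phase.  Returns an
    explicit not-found result for traces that never applanate (e.g. a
    zero-strength jet).
    """
    spans = flat_span_history(trace, tau_flat, s_max)
    i_hc = int(np.argmax(trace.apex_disp))
    if trace.apex_disp[i_hc] <= 1e-6:
        return ApplanationResult(found=False)
    # the flat span peaks when the central curvature passes through zero;
    # restrict to the inward phase so the outgoing applanation is excluded
    inward = spans[:i_hc + 1]
    if inward.max() < min_length:
        return ApplanationResult(found=False)
    idx = int(np.argmax(inward))
    t = trace.t
    vel = trace.meta.get("apex_velocity")
    if vel is None:
        vel = np.gradient(trace.apex_disp, t)
    return ApplanationResult(
        found=True,
        A1_time=float(t[idx]),
        A1_length=float(spans[idx]),
        A1_velocity=float(vel[idx]),
        A1_def_amp=float(trace.apex_disp[idx]),
        AP1=float(trace.apex_p[idx]),
    )


def highest_concavity(trace: SimulationTrace):
    """(HC_time, HC_def_amp, peak_distance) at maximum apical indentation.

    HC_time is refined by parabolic interpolation through the discrete
    maximum; the peak distance is the span between the two crests flanking
    the central concavity of the deformed profile (NaN and a degenerate
    flag if the profile has no central concavity).
    """
    d = trace.apex_disp
    i = int(np.argmax(d))
    if i == 0 or i == len(d) - 1:
        return float(trace.t[i]), float(d[i]), np.nan, True
    # parabolic vertex through (i-1, i, i+1)
    y0, y1, y2 = d[i - 1], d[i], d[i + 1]
    denom = y0 - 2 * y1 + y2
    off = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    dt = trace.t[1] - trace.t[0]
    hc_time = float(trace.t[i] + np.clip(off, -1, 1) * dt)
    hc_def = float(y1 - 0.25 * (y0 - y2) * np.clip(off, -1, 1))

    r, z = trace.prof_r[i], trace.prof_z[i]
    spl = CubicSpline(r, z)
    rr = np.linspace(0.0, r[-1], 600)
    zz = spl(rr)
    imax = [j for j in range(1, len(rr) - 1)
            if zz[j] >= zz[j - 1] and zz[j] > zz[j + 1]]
    degenerate = len(imax) == 0 or zz[0] >= zz[imax[0]]
    pd = 2.0 * rr[imax[0]] if not degenerate else np.nan
    return hc_time, hc_def, pd, degenerate


def stiffness_parameter(AP1: float, IOP: float, HC_def: float,
                        A1_def: float) -> float:
    """SP-HC = (AP1 - IOP) / (HC_def - A1_def)."""
    if HC_def == A1_def:
        raise ZeroDivisionError(
            "SP-HC undefined: HC and A1 deformation amplitudes coincide")
    return (AP1 - IOP) / (HC_def - A1_def)


def extract_dcr(trace: SimulationTrace, iop: float, **kw) -> DCRRecord | None:
    """All nine DCR parameters from a trace, or None if no applanation."""
    a1 = detect_applanation(trace, **kw)
    if not a1.found:
        return None
    hc_time, hc_def, pd, _deg = highest_concavity(trace)
    sp = stiffness_parameter(a1.AP1, iop, hc_def, a1.A1_def_amp)
    return DCRRecord(
        A1_time=a1.A1_time, A1_length=a1.A1_length, A1_velocity=a1.A1_velocity,
        HC_time=hc_time, peak_distance=pd, A1_def_amp=a1.A1_def_amp,
        HC_def_amp=hc_def, AP1=a1.AP1, SP_HC=sp)
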