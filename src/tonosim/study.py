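"""Parametric study driver and statistics.

Reproduces the structure of the published parametric study: a sampled
design over intraocular pressure (IOP), central corneal thickness (CCT),
corneal stiffness coefficient (mu) and corneal radius (R); one coupled
air-puff simulation per model; descriptive statistics of the inputs and
the nine DCR outputs; and Pearson correlation with two-tailed Student-t
significance for every input/output pair.  A truncated-normal generator
emulates the summary statistics of clinical CCT/IOP/age datasets for
exercising the comparison code (no real patient data are consumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .coupling import CouplingConfig, build_eye, run_pair, run_simulation
from .dcr import extract_dcr
from .geometry import CornealTopography
from .jet import JetConfig
from .materials import default_regional_map

__all__ = [
    "StudyDesign",
    "CorrelationTable",
    "generate_design",
    "run_study",
    "pearson_r",
    "correlation_matrix",
    "summarize",
    "synthesize_clinical",
    "trace_rmse",
    "calibration_decrease",
    "INPUT_COLUMNS",
    "OUTPUT_COLUMNS",
]

#: Parameter ranges of the parametric study (min, max).
DEFAULT_RANGES = {
    "IOP (mmHg)": (10.0, 25.0),
    "CCT (µm)": (445.0, 645.0),
    "µ": (0.0422, 0.1082),
    "R (mm)": (7.4, 8.4),
}

INPUT_COLUMNS = list(DEFAULT_RANGES)
OUTPUT_COLUMNS = [
    "A1 Time (ms)", "A1 Length (mm)", "A1 Velocity (mm/s)", "HC Time (ms)",
    "Peak Distance (mm)", "A1 Def. Amp. (mm)", "HC Def. Amp. (mm)",
    "AP1 (mmHg)", "SP-HC",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampled design over the four model inputs."""

    n: int = 110
    scheme: str = "latin-hypercube"   # or "grid"
    seed: int = 0
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("design needs n >= 4 models")
        if self.scheme not in ("latin-hypercube", "grid"):
            raise ValueError("scheme must be 'latin-hypercube' or 'grid'")
        for k, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid range for {k}: ({lo}, {hi})")


def generate_design(design: StudyDesign) -> pd.DataFrame:
    """Sample the input design; seeded and reproducible.

    Latin-hypercube sampling by default; 'grid' produces the corners-first
    full factorial truncated to n (useful for corner tests).
    """
    lo = np.array([v[0] for v in design.ranges.values()])
    hi = np.array([v[1] for v in design.ranges.values()])
    d = len(lo)
    if design.scheme == "latin-hypercube":
        u = qmc.LatinHypercube(d=d, seed=design.seed).random(design.n)
    else:
        m = int(np.ceil(design.n ** (1.0 / d)))
        axes = [np.linspace(0, 1, m) for _ in range(d)]
        u = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, d)[:design.n]
    return pd.DataFrame(lo + u * (hi - lo), columns=list(design.ranges))


def _build_and_run(iop, cct, mu, R, cc: CouplingConfig | None = None,
                   jet: JetConfig | None = None):
    topo = CornealTopography(R_anterior=R, CCT=cct)
    eye = build_eye(topo, materials=default_regional_map(mu), iop=iop)
    trace = run_simulation(eye, jet, cc)
    return eye, trace


def run_study(design: StudyDesign, cc: CouplingConfig | None = None,
              jet: JetConfig | None = None, progress: bool = False
              ) -> pd.DataFrame:
    """Run one coupled simulation per design row and extract DCR metrics.

    Failed rows are recorded with ``failed=True`` and NaN outputs; the
    sweep never aborts.  Rows are independent of execution order.
    """
    rows = generate_design(design)
    out = []
    it = rows.iterrows()
    if progress:
        from tqdm import tqdm
        it = tqdm(it, total=len(rows))
    for _, row in it:
        rec = dict(row)
        try:
            eye, trace = _build_and_run(row["IOP (mmHg)"], row["CCT (µm)"],
                                        row["µ"], row["R (mm)"], cc, jet)
            dcr = extract_dcr(trace, row["IOP (mmHg)"])
            if dcr is None:
                raise RuntimeError("no applanation detected")
            rec.update(dcr.as_dict())
            rec["failed"] = False
        except Exception as exc:  # noqa: BLE001 - per-row isolation
            rec.update({c: np.nan for c in OUTPUT_COLUMNS})
            rec["failed"] = True
            rec["error"] = f"{type(exc).__name__}: {exc}"
        out.append(rec)
    return pd.DataFrame(out)


def pearson_r(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with two-tailed Student-t significance.

    t = r sqrt((n-2)/(1-r^2)) follows a t distribution with n-2 degrees of
    freedom under the null of no correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


@dataclass
class CorrelationTable:
    """Pearson r and two-tailed p per (input, output) pair."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for inp in self.r.index:
            rows.append(pd.Series(self.r.loc[inp], name=f"{inp} r"))
            rows.append(pd.Series(self.p.loc[inp], name=f"{inp} p"))
        return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> CorrelationTable:
    """Correlations of every input against every DCR output."""
    ok = table[~table.get("failed", False).astype(bool)] if "failed" in table else table
    if len(ok) < 10:
        raise ValueError("need at least 10 successful rows for correlations")
    r = pd.DataFrame(index=INPUT_COLUMNS, columns=OUTPUT_COLUMNS, dtype=float)
    p = pd.DataFrame(index=INPUT_COLUMNS, columns=OUTPUT_COLUMNS, dtype=float)
    n = len(ok)
    for i in INPUT_COLUMNS:
        for o in OUTPUT_COLUMNS:
            r.loc[i, o], p.loc[i, o], n = pearson_r(ok[i], ok[o])
    return CorrelationTable(r=r, p=p, n=n)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/min/max per column in the published table's column order."""
    if len(table) == 0:
        raise ValueError("empty study table")
    cols = [c for c in INPUT_COLUMNS + OUTPUT_COLUMNS if c in table.columns]
    ok = table[~table.get("failed", False).astype(bool)] if "failed" in table else table
    return pd.DataFrame({
        "Mean": ok[cols].mean(),
        "Std. Deviation": ok[cols].std(ddof=1),
        "Minimum": ok[cols].min(),
        "Maximum": ok[cols].max(),
    })


def synthesize_clinical(stats_spec: dict, n: int, seed: int) -> pd.DataFrame:
    """Synthetic clinical-like dataset from printed summary statistics.

    ``stats_spec`` maps a column name to (mean, sd, lo, hi); each column is
    drawn independently from a truncated normal matching the given moments
    within sampling error and clipped to the printed range.  This is a
    synthetic stand-in fixture for device exports, not patient data.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for col, (mean, sd, lo, hi) in stats_spec.items():
        a, b = (lo - mean) / sd, (hi - mean) / sd
        out[col] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                       size=n, random_state=rng)
    return pd.DataFrame(out)


def trace_rmse(t_a, d_a, t_b, d_b) -> float:
    """RMSE (mm) between two apical-displacement traces.

    The second trace is resampled onto the overlap of the two time
    supports; disjoint supports are a data error.
    """
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    lo, hi = max(t_a[0], t_b[0]), min(t_a[-1], t_b[-1])
    if hi <= lo:
        raise ValueError("traces have disjoint time supports")
    m = (t_a >= lo) & (t_a <= hi)
    db = np.interp(t_a[m], t_b, np.asarray(d_b, dtype=float))
    da = np.asarray(d_a, dtype=float)[m]
    return float(np.sqrt(np.mean((da - db) ** 2)))


def calibration_decrease(n: int = 10, seed: int = 0,
                         jet: JetConfig | None = None,
                         cc: CouplingConfig | None = None):
    """Mean rigid-to-coupled peak apex-pressure decrease (%) over a sweep.

    Builds ``n`` eye models spanning the parametric ranges (seeded Latin
    hypercube), runs each in rigid and coupled mode with identical jet
    settings, and averages the per-model relative decrease in peak apex
    pressure -- the fluid-structure attenuation statistic.
    Returns (mean %, per-model array).
    """
    rows = generate_design(StudyDesign(n=n, seed=seed))
    dec = []
    for _, row in rows.iterrows():
        topo = CornealTopography(R_anterior=row["R (mm)"], CCT=row["CCT (µm)"])
        eye = build_eye(topo, materials=default_regional_map(row["µ"]),
                        iop=row["IOP (mmHg)"])
        _, _, d = run_pair(eye, jet, cc)
        dec.append(d)
    dec = np.asarray(dec)
    return float(dec.mean()), dec
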