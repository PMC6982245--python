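"""Configuration schema, readers/writers and reproducibility plumbing.

Run configurations are structured text (YAML) with explicitly unit-tagged
keys (``iop_mmHg``, ``CCT_um``, ``V_max_m_per_s`` ...).  Unknown keys are
rejected with an error naming the offending key, so an untagged quantity
(e.g. plain ``iop``) cannot slip through in the wrong unit.  A single
global seed fans out to per-purpose child seeds by stable hashing, and
``write_outputs`` emits a manifest (config hash + seed + version) from
which a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .coupling import CouplingConfig
from .geometry import CornealTopography, EyeMeshConfig
from .jet import JetConfig
from .materials import default_regional_map
from .study import DEFAULT_RANGES, StudyDesign

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "write_outputs", "child_seed"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TopographySection(_Base):
    R_anterior_mm: float = 7.8
    Q: float = -0.25
    CCT_um: float = 545.0
    peripheral_thickness_ratio: float = 1.18
    elevation_map_csv: str | None = None


class MeshSection(_Base):
    corneal_rings: int = 15
    scleral_rings: int = 35
    sectors: int = 100
    layers: int = 2
    scleral_radius_mm: float = 11.5
    limbus_angle_deg: float = 40.0


class MaterialsSection(_Base):
    mu_MPa: float = 0.0712
    alpha: float = 110.0
    limbus_factor: float = 0.8
    anterior_sclera_factor: float = 3.0
    equatorial_sclera_factor: float = 3.5
    posterior_sclera_factor: float = 4.0


class EyeSection(_Base):
    topography: TopographySection = TopographySection()
    mesh: MeshSection = MeshSection()
    materials: MaterialsSection = MaterialsSection()
    iop_mmHg: float = 15.0


class JetSection(_Base):
    D_mm: float = 2.4
    standoff_mm: float = 11.0
    V_max_m_per_s: float = 167.8
    T_ms: float = 30.0
    t_peak_ms: float = 16.0
    rho_air_kg_per_m3: float = 1.204
    mu_air_Pa_s: float = 1.83e-5
    theta_core_deg: float = 5.0
    theta_outer_deg: float = 8.5
    c_w: float = 0.555
    c_s: float = 0.15
    c_f: float = 0.142


class CouplingSection(_Base):
    dt_init_ms: float = 0.05
    dt_min_ms: float = 1e-4
    dt_max_ms: float = 0.1
    motion_limit: float = 0.45
    sample_interval_ms: float = 0.231
    mode: str = "coupled"
    air_layers: int = 12
    damping_alpha_ms: float = 1e-5


class StudySection(_Base):
    n: int = 110
    scheme: str = "latin-hypercube"
    iop_range_mmHg: tuple[float, float] = DEFAULT_RANGES["IOP (mmHg)"]
    cct_range_um: tuple[float, float] = DEFAULT_RANGES["CCT (µm)"]
    mu_range_MPa: tuple[float, float] = DEFAULT_RANGES["µ"]
    r_range_mm: tuple[float, float] = DEFAULT_RANGES["R (mm)"]


class RunConfig(_Base):
    """Validated, fully defaulted run configuration."""

    eye: EyeSection = EyeSection()
    jet: JetSection = JetSection()
    coupling: CouplingSection = CouplingSection()
    study: StudySection = StudySection()
    seed: int = 0
    output_dir: str = "out"

    # -- object builders ---------------------------------------------------
    def topography(self) -> CornealTopography:
        t = self.eye.topography
        emap = None
        if t.elevation_map_csv:
            import pandas as pd
            df = pd.read_csv(t.elevation_map_csv)
            cols = [df["r_mm"].to_numpy(), df["z_mm"].to_numpy()]
            if "thickness_um" in df.columns:
                cols.append(df["thickness_um"].to_numpy())
            emap = tuple(cols)
        return CornealTopography(
            R_anterior=t.R_anterior_mm, Q=t.Q, CCT=t.CCT_um,
            peripheral_thickness_ratio=t.peripheral_thickness_ratio,
            elevation_map=emap)

    def mesh_config(self) -> EyeMeshConfig:
        m = self.eye.mesh
        return EyeMeshConfig(corneal_rings=m.corneal_rings,
                             scleral_rings=m.scleral_rings, sectors=m.sectors,
                             layers=m.layers, scleral_radius=m.scleral_radius_mm,
                             limbus_angle=m.limbus_angle_deg)

    def material_map(self):
        m = self.eye.materials
        return default_regional_map(
            mu_cornea=m.mu_MPa, alpha=m.alpha,
            factors={"limbus": m.limbus_factor,
                     "anterior_sclera": m.anterior_sclera_factor,
                     "equatorial_sclera": m.equatorial_sclera_factor,
                     "posterior_sclera": m.posterior_sclera_factor})

    def jet_config(self) -> JetConfig:
        j = self.jet
        return JetConfig(D=j.D_mm, H=j.standoff_mm, V_max=j.V_max_m_per_s,
                         T=j.T_ms, t_peak=j.t_peak_ms,
                         rho_air=j.rho_air_kg_per_m3, mu_air=j.mu_air_Pa_s,
                         theta_core=j.theta_core_deg,
                         theta_outer=j.theta_outer_deg,
                         c_w=j.c_w, c_s=j.c_s, c_f=j.c_f)

    def coupling_config(self, mode: str | None = None) -> CouplingConfig:
        c = self.coupling
        return CouplingConfig(dt_init=c.dt_init_ms, dt_min=c.dt_min_ms,
                              dt_max=c.dt_max_ms, motion_limit=c.motion_limit,
                              sample_interval=c.sample_interval_ms,
                              mode=mode or c.mode, air_layers=c.air_layers,
                              damping_alpha=c.damping_alpha_ms)

    def study_design(self, n: int | None = None, seed: int | None = None
                     ) -> StudyDesign:
        s = self.study
        ranges = {"IOP (mmHg)": tuple(s.iop_range_mmHg),
                  "CCT (µm)": tuple(s.cct_range_um),
                  "µ": tuple(s.mu_range_MPa),
                  "R (mm)": tuple(s.r_range_mm)}
        return StudyDesign(n=n or s.n, scheme=s.scheme,
                           seed=child_seed(self.seed if seed is None else seed,
                                           "study-design"),
                           ranges=ranges)

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()),
                              sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()[:16]


def child_seed(seed: int, purpose: str) -> int:
    """Stable per-purpose child seed derived from the global seed (< 2^31)."""
    h = hashlib.sha256(f"{seed}:{purpose}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (defaults filled in)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            if err["type"] == "extra_forbidden":
                msgs.append(f"unknown key '{loc}' (keys are unit-tagged, "
                            "e.g. iop_mmHg, CCT_um, V_max_m_per_s)")
            else:
                msgs.append(f"{loc}: {err['msg']}")
        raise ConfigError("; ".join(msgs)) from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(cfg.canonical_yaml())


def _write_artifact(name: str, obj, outdir: Path) -> str:
    import pandas as pd
    p = outdir / name
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(p, index=name.endswith("_indexed.csv"))
    elif isinstance(obj, (dict, list)):
        p.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    elif isinstance(obj, str):
        p.write_text(obj)
    else:
        raise TypeError(f"cannot serialise artifact {name!r} of {type(obj)}")
    return name


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def write_outputs(artifacts: dict, outdir, cfg: RunConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write artifacts plus a reproducibility manifest; returns the manifest.

    ``artifacts`` maps file names (csv for DataFrames, json for dicts) to
    objects.  The manifest records the config hash, seed and package
    version; re-running with the same config and seed reproduces the
    outputs bit-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = [_write_artifact(name, obj, outdir) for name, obj in artifacts.items()]
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash() if cfg is not None else None,
        "seed": seed if seed is not None else (cfg.seed if cfg else None),
        "files": sorted(files),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def trace_frame(trace):
    """Summary trace as a DataFrame with the canonical column set."""
    return trace.to_frame()
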