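"""Parametric eye geometry and meshing.

The anterior cornea is a conic section (apical radius ``R_anterior``,
asphericity ``Q``); the sclera is an idealised spherical segment joined at
the limbus.  The full eye is meshed as rings x sectors x through-thickness
layers of wedge/hexahedral cells carrying one of five region labels
(cornea, limbus, anterior/equatorial/posterior sclera).  An axisymmetric
meridian extraction feeds the structural solver, and the air domain above
the cornea is built by projecting the anterior-surface nodes toward the
nozzle plane with a single similar-triangles scale factor.

Coordinates are millimetres.  Z is the anterior-posterior axis with the
corneal apex at maximum Z; the apex sits at z = 0 and the globe extends to
negative z.  Angles are degrees at interfaces, radians internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "CornealTopography",
    "EyeMeshConfig",
    "EyeMesh",
    "AirDomainMesh",
    "MeridianGeometry",
    "build_anterior_surface",
    "build_meridian",
    "build_eye_mesh",
    "enclosed_volume",
    "signed_volume",
    "project_air_domain",
    "write_vtk",
]

MMHG_TO_MPA = 133.322e-6  # 1 mmHg in MPa

#: Region boundaries as thresholds on the normalized meridional angle
#: (degrees from the anterior pole; the cornea occupies [0, limbus_angle]
#: by construction and the scleral arc is mapped onto [limbus_angle, 180]).
REGION_THRESHOLDS = ((40.0, "cornea"),
                     (50.0, "limbus"),
                     (90.0, "anterior_sclera"),
                     (135.0, "equatorial_sclera"),
                     (180.0, "posterior_sclera"))


class GeometryError(ValueError):
    """Invalid or inconsistent geometric input."""


class ConfigError(ValueError):
    """Invalid mesh/model configuration."""


@dataclass(frozen=True)
class CornealTopography:
    """Anterior corneal shape and thickness profile.

    Parameters
    ----------
    R_anterior : float
        Apical radius of curvature, mm.
    Q : float
        Conic asphericity (0 sphere, <0 prolate ellipse).
    CCT : float
        Central corneal thickness, micrometres.
    peripheral_thickness_ratio : float
        Limbal/central thickness ratio (>= 1).
    elevation_map : tuple of arrays, optional
        ``(r_mm, z_mm)`` radial grid of anterior sagittal heights replacing
        the parametric conic (patient-specific path), plus optionally a
        third ``thickness_um`` array.
    """

    R_anterior: float = 7.8
    Q: float = -0.25
    CCT: float = 545.0
    peripheral_thickness_ratio: float = 1.18
    elevation_map: tuple | None = None

    def __post_init__(self) -> None:
        if self.R_anterior <= 0:
            raise GeometryError("R_anterior must be positive")
        if self.CCT <= 0:
            raise GeometryError("CCT must be positive")
        if self.peripheral_thickness_ratio < 1.0:
            raise GeometryError("peripheral_thickness_ratio must be >= 1")
        if self.elevation_map is not None:
            r = np.asarray(self.elevation_map[0], dtype=float)
            if r.ndim != 1 or len(r) < 3 or np.any(np.diff(r) <= 0):
                raise GeometryError(
                    "elevation map radii must be strictly increasing "
                    "(single-valued in radius)")


@dataclass(frozen=True)
class EyeMeshConfig:
    """Ring/sector/layer mesh resolution and idealised scleral dimensions."""

    corneal_rings: int = 15
    scleral_rings: int = 35
    sectors: int = 100
    layers: int = 2
    scleral_radius: float = 11.5
    limbus_angle: float = 40.0

    def __post_init__(self) -> None:
        if self.corneal_rings < 2 or self.scleral_rings < 2:
            raise ConfigError("need at least 2 rings in cornea and sclera")
        if self.sectors < 3:
            raise ConfigError("sectors must be >= 3")
        if self.layers < 1:
            raise ConfigError("layers must be >= 1")
        if not 0 < self.limbus_angle < 90:
            raise ConfigError("limbus_angle must be in (0, 90) degrees")
        if self.scleral_radius <= 0:
            raise ConfigError("scleral_radius must be positive")


def build_anterior_surface(topo: CornealTopography, r) -> float | np.ndarray:
    """Sagittal height z(r) of the anterior corneal surface, mm.

    For the parametric conic:  z = r^2 / (R + sqrt(R^2 - (1+Q) r^2)),
    i.e. the depth below the apex at radial distance r.  z(0) = 0 and
    dz/dr(0) = 0.  When an elevation map is present it takes precedence
    and is interpolated with a clamped cubic spline.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r < 0):
        raise GeometryError("radial coordinate must be >= 0")
    if topo.elevation_map is not None:
        rg = np.asarray(topo.elevation_map[0], dtype=float)
        zg = np.asarray(topo.elevation_map[1], dtype=float)
        if np.any(r > rg[-1] + 1e-12):
            raise GeometryError("radius outside elevation-map support")
        spl = CubicSpline(rg, zg, bc_type=((1, 0.0), "not-a-knot"))
        z = spl(np.clip(r, rg[0], rg[-1]))
    else:
        R, Q = topo.R_anterior, topo.Q
        disc = R * R - (1.0 + Q) * r * r
        if np.any(disc < 0):
            raise GeometryError(
                "radius outside the conic's domain: (1+Q) r^2 must be < R^2")
        z = r * r / (R + np.sqrt(disc))
    return float(z[0]) if scalar else z


def _region_of(theta_deg: float) -> str:
    for thr, name in REGION_THRESHOLDS:
        if theta_deg <= thr + 1e-9:
            return name
    return "posterior_sclera"


@dataclass
class MeridianGeometry:
    """Axisymmetric meridian of the anterior (outer) eye surface.

    Arrays run from the corneal apex (index 0, on-axis) to the posterior
    pole (last index, on-axis).  ``thickness`` is the local wall thickness
    (mm) at each node, ``theta_norm`` the normalized meridional angle
    (degrees) and ``region`` the material-region label per segment.
    """

    r: np.ndarray
    z: np.ndarray
    thickness: np.ndarray
    theta_norm: np.ndarray
    region: list
    n_corneal: int          # number of corneal segments
    equator_index: int      # meridian node closest to the globe equator

    @property
    def n_segments(self) -> int:
        return len(self.r) - 1

    def arc_length(self) -> np.ndarray:
        """Cumulative arc length from the apex along the meridian, mm."""
        ds = np.hypot(np.diff(self.r), np.diff(self.z))
        return np.concatenate([[0.0], np.cumsum(ds)])


# Scleral thickness profile (mm) vs normalized position through the scleral
# arc: limbal 0.8, thinnest near the equator 0.45, posterior pole 1.0 --
# average anatomical values.
_SCLERA_T = np.array([[0.0, 0.80], [0.45, 0.45], [1.0, 1.00]])


def build_meridian(topo: CornealTopography, cfg: EyeMeshConfig) -> MeridianGeometry:
    """Construct the meridian polyline of the anterior surface.

    Corneal nodes are spaced uniformly in the meridional angle about the
    apical centre of curvature up to ``limbus_angle``; scleral nodes
    uniformly in angle about the scleral centre from the junction to the
    posterior pole.
    """
    R, Rs = topo.R_anterior, cfg.scleral_radius
    phi_l = np.radians(cfg.limbus_angle)
    phi = np.linspace(0.0, phi_l, cfg.corneal_rings + 1)
    r_c = R * np.sin(phi)
    if topo.elevation_map is not None:
        rmax = float(np.asarray(topo.elevation_map[0])[-1])
        if r_c[-1] > rmax:
            r_c = r_c * (rmax / r_c[-1])
    z_c = -build_anterior_surface(topo, r_c)

    r_l, z_l = r_c[-1], z_c[-1]
    if r_l >= Rs:
        raise GeometryError("corneal rim wider than the scleral sphere")
    z_centre = z_l - np.sqrt(Rs * Rs - r_l * r_l)
    psi_l = np.arcsin(r_l / Rs)
    psi = np.linspace(psi_l, np.pi, cfg.scleral_rings + 1)[1:]
    r_s = Rs * np.sin(psi)
    z_s = z_centre + Rs * np.cos(psi)

    r = np.concatenate([r_c, r_s])
    z = np.concatenate([z_c, z_s])
    r[0] = 0.0
    r[-1] = 0.0

    # normalized meridional angle: cornea -> [0, limbus_angle],
    # scleral arc -> [limbus_angle, 180]
    th_c = np.degrees(phi)
    th_s = cfg.limbus_angle + (psi - psi_l) / (np.pi - psi_l) * (180.0 - cfg.limbus_angle)
    theta = np.concatenate([th_c, th_s])

    # thickness: corneal CCT -> peripheral at limbus, then scleral profile
    cct = topo.CCT * 1e-3
    if topo.elevation_map is not None and len(topo.elevation_map) > 2:
        tg = np.asarray(topo.elevation_map[2], dtype=float) * 1e-3
        rg = np.asarray(topo.elevation_map[0], dtype=float)
        t_c = np.interp(r_c, rg, tg)
    else:
        t_c = cct * (1.0 + (topo.peripheral_thickness_ratio - 1.0) * (phi / phi_l) ** 2)
    xi = (psi - psi_l) / (np.pi - psi_l)
    t_s = np.interp(xi, _SCLERA_T[:, 0], _SCLERA_T[:, 1])
    # blend the limbal junction so thickness is continuous
    t_s = t_s + (t_c[-1] - t_s[0]) * np.exp(-xi / 0.08)
    thickness = np.concatenate([t_c, t_s])

    region = [_region_of(0.5 * (theta[j] + theta[j + 1]))
              for j in range(len(r) - 1)]
    equator_index = int(np.argmax(r))
    return MeridianGeometry(r=r, z=z, thickness=thickness, theta_norm=theta,
                            region=region, n_corneal=cfg.corneal_rings,
                            equator_index=equator_index)


@dataclass
class EyeMesh:
    """Full 3-D ring/sector/layer mesh of the eye wall.

    ``cells`` is a list of (cell_type, connectivity) with cell_type
    "wedge" (6 nodes) or "hexahedron" (8 nodes); ``cell_regions`` carries
    one region label per cell.  Node sets index into ``nodes``.
    """

    nodes: np.ndarray
    cells: list
    cell_regions: list
    node_sets: dict
    meridian: MeridianGeometry
    config: EyeMeshConfig
    topo: CornealTopography

    @property
    def n_elements(self) -> int:
        return len(self.cells)

    def surface_facets(self, surface: str = "inner") -> np.ndarray:
        """Triangulated closed surface (outer or inner wall), (m, 3) indices."""
        return self._surfaces[surface]

    _surfaces: dict = field(default_factory=dict)


def _surface_node_ids(j: int, k: int, n_mer: int, sectors: int) -> int:
    """Node id within one layer-surface for meridian position j, sector k."""
    if j == 0:
        return 0
    if j == n_mer - 1:
        return 1 + (n_mer - 2) * sectors
    return 1 + (j - 1) * sectors + (k % sectors)


def _triangulate_surface(n_mer: int, sectors: int, offset: int, flip: bool) -> np.ndarray:
    """Triangles of one revolved layer-surface (closed, consistently oriented)."""
    tris = []
    nid = lambda j, k: offset + _surface_node_ids(j, k, n_mer, sectors)
    for k in range(sectors):
        tris.append([nid(0, 0), nid(1, k), nid(1, k + 1)])
    for j in range(1, n_mer - 2):
        for k in range(sectors):
            a, b = nid(j, k), nid(j, k + 1)
            c, d = nid(j + 1, k + 1), nid(j + 1, k)
            tris.append([a, b, c])
            tris.append([a, c, d])
    for k in range(sectors):
        tris.append([nid(n_mer - 1, 0), nid(n_mer - 2, k + 1), nid(n_mer - 2, k)])
    tris = np.asarray(tris, dtype=int)
    if flip:
        tris = tris[:, ::-1]
    return tris


def build_eye_mesh(topo: CornealTopography, cfg: EyeMeshConfig) -> EyeMesh:
    """Build the 3-D eye-wall mesh.

    Element count is exactly ``(corneal_rings + scleral_rings) * sectors *
    layers``; the outer surface is the anterior topography and inner
    surfaces are offset inward along the local meridian normal by the local
    wall thickness, so the apex thickness equals CCT.
    """
    mer = build_meridian(topo, cfg)
    n_mer = len(mer.r)
    sectors, layers = cfg.sectors, cfg.layers

    # outward meridian normals (in the r-z plane)
    dr = np.gradient(mer.r)
    dz = np.gradient(mer.z)
    L = np.hypot(dr, dz)
    n_r, n_z = dz / L, -dr / L
    # orient outward: at the apex the outward normal is +z
    if n_z[0] < 0:
        n_r, n_z = -n_r, -n_z
    n_r[0], n_z[0] = 0.0, 1.0
    n_r[-1], n_z[-1] = 0.0, -1.0

    npl = 2 + (n_mer - 2) * sectors  # nodes per layer-surface
    ang = 2.0 * np.pi * np.arange(sectors) / sectors
    nodes = np.empty(((layers + 1) * npl, 3))
    for l in range(layers + 1):
        f = l / layers
        rr = mer.r - f * mer.thickness * n_r
        zz = mer.z - f * mer.thickness * n_z
        base = l * npl
        nodes[base] = (0.0, 0.0, zz[0])
        for j in range(1, n_mer - 1):
            ids = base + 1 + (j - 1) * sectors
            nodes[ids:ids + sectors, 0] = rr[j] * np.cos(ang)
            nodes[ids:ids + sectors, 1] = rr[j] * np.sin(ang)
            nodes[ids:ids + sectors, 2] = zz[j]
        nodes[base + npl - 1] = (0.0, 0.0, zz[-1])

    cells, regions = [], []
    for l in range(layers):
        top, bot = l * npl, (l + 1) * npl
        for j in range(n_mer - 1):
            reg = mer.region[j]
            for k in range(sectors):
                if j == 0:
                    conn = [top + _surface_node_ids(0, 0, n_mer, sectors),
                            top + _surface_node_ids(1, k, n_mer, sectors),
                            top + _surface_node_ids(1, k + 1, n_mer, sectors),
                            bot + _surface_node_ids(0, 0, n_mer, sectors),
                            bot + _surface_node_ids(1, k, n_mer, sectors),
                            bot + _surface_node_ids(1, k + 1, n_mer, sectors)]
                    cells.append(("wedge", conn))
                elif j == n_mer - 2:
                    conn = [top + _surface_node_ids(n_mer - 1, 0, n_mer, sectors),
                            top + _surface_node_ids(j, k + 1, n_mer, sectors),
                            top + _surface_node_ids(j, k, n_mer, sectors),
                            bot + _surface_node_ids(n_mer - 1, 0, n_mer, sectors),
                            bot + _surface_node_ids(j, k + 1, n_mer, sectors),
                            bot + _surface_node_ids(j, k, n_mer, sectors)]
                    cells.append(("wedge", conn))
                else:
                    conn = [top + _surface_node_ids(j, k, n_mer, sectors),
                            top + _surface_node_ids(j, k + 1, n_mer, sectors),
                            top + _surface_node_ids(j + 1, k + 1, n_mer, sectors),
                            top + _surface_node_ids(j + 1, k, n_mer, sectors),
                            bot + _surface_node_ids(j, k, n_mer, sectors),
                            bot + _surface_node_ids(j, k + 1, n_mer, sectors),
                            bot + _surface_node_ids(j + 1, k + 1, n_mer, sectors),
                            bot + _surface_node_ids(j + 1, k, n_mer, sectors)]
                    cells.append(("hexahedron", conn))
                regions.append(reg)

    anterior = np.arange(npl)
    eq_j = mer.equator_index
    eq_base = 1 + (eq_j - 1) * sectors
    node_sets = {
        "anterior_surface": anterior,
        "anterior_pole": np.array([0]),
        "posterior_pole": np.array([npl - 1]),
        "equator": np.arange(eq_base, eq_base + sectors),
    }
    mesh = EyeMesh(nodes=nodes, cells=cells, cell_regions=regions,
                   node_sets=node_sets, meridian=mer, config=cfg, topo=topo)
    mesh._surfaces = {
        "outer": _triangulate_surface(n_mer, sectors, 0, flip=False),
        "inner": _triangulate_surface(n_mer, sectors, layers * npl, flip=True),
    }
    return mesh


def signed_volume(vertices: np.ndarray, faces: np.ndarray,
                  check_closed: bool = True) -> float:
    """Signed enclosed volume of a triangulated surface (divergence theorem).

    Positive for outward-oriented closed surfaces.  Raises GeometryError if
    the surface is not closed (an edge not shared by exactly two facets).
    """
    faces = np.asarray(faces, dtype=int)
    if check_closed:
        edges = np.sort(np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                                        faces[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts != 2):
            raise GeometryError("surface is not closed (open or non-manifold edges)")
    v = np.asarray(vertices, dtype=float)
    a, b, c = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
    return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)


def enclosed_volume(mesh: EyeMesh) -> float:
    """Volume of the fluid cavity enclosed by the inner wall surface, mm^3."""
    vol = signed_volume(mesh.nodes, mesh.surface_facets("inner"))
    if vol <= 0:
        raise GeometryError("inner surface is inverted or degenerate")
    return vol


@dataclass
class AirDomainMesh:
    """Layered node grid between the anterior surface and the nozzle plane.

    Layer 0 coincides node-for-node (same numbering) with the selected
    anterior-surface nodes of the eye mesh; the top layer lies in the plane
    z = apex + standoff with radial coordinates shrunk toward the jet axis
    by one global similar-triangles factor.
    """

    nodes: np.ndarray          # (layers+1, n_surf, 3)
    surface_node_ids: np.ndarray
    scale: float
    standoff: float

    @property
    def n_layers(self) -> int:
        return self.nodes.shape[0] - 1


def project_air_domain(mesh: EyeMesh, standoff: float = 11.0,
                       layers: int = 12, scale: float | None = None,
                       scleral_ring: float = 4.0) -> AirDomainMesh:
    """Project the air domain from the anterior surface by similar triangles.

    The footprint covers the cornea plus ``scleral_ring`` mm of scleral arc
    (the fluid-structure interface of the jet model).  ``scale`` is the
    nozzle-plane footprint factor; by default the nozzle-plane footprint
    shrinks the surface footprint to the 1.2 mm orifice radius.
    """
    if standoff <= 0:
        raise ConfigError("standoff must be positive")
    if layers < 1:
        raise ConfigError("air domain needs at least 1 layer")
    mer = mesh.meridian
    s = mer.arc_length()
    s_limbus = s[mer.n_corneal]
    j_max = int(np.searchsorted(s, s_limbus + scleral_ring))
    j_max = min(j_max, len(s) - 2)

    sectors = mesh.config.sectors
    n_mer = len(mer.r)
    ids = [0]
    for j in range(1, j_max + 1):
        base = 1 + (j - 1) * sectors
        ids.extend(range(base, base + sectors))
    ids = np.asarray(ids, dtype=int)

    surf = mesh.nodes[ids]
    z_apex = mesh.nodes[0, 2]
    if standoff <= float(z_apex - surf[:, 2].min()):
        raise ConfigError("standoff must exceed the corneal sagittal depth")
    r_foot = float(np.hypot(surf[:, 0], surf[:, 1]).max())
    if scale is None:
        scale = min(1.0, 1.2 / r_foot)

    top = np.empty_like(surf)
    top[:, 0] = surf[:, 0] * scale
    top[:, 1] = surf[:, 1] * scale
    top[:, 2] = z_apex + standoff
    grid = np.empty((layers + 1, len(ids), 3))
    for l in range(layers + 1):
        f = l / layers
        grid[l] = (1.0 - f) * surf + f * top
    return AirDomainMesh(nodes=grid, surface_node_ids=ids, scale=float(scale),
                         standoff=float(standoff))


_VTK_TYPE = {"wedge": 13, "hexahedron": 12}
_REGION_ID = {name: i for i, (_, name) in enumerate(REGION_THRESHOLDS)}


def write_vtk(mesh: EyeMesh, path) -> None:
    """Write the eye mesh as legacy ASCII VTK with a cell region-tag field."""
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write("tonosim eye mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {len(mesh.nodes)} double\n")
    np.savetxt(buf, mesh.nodes, fmt="%.9g")
    total = sum(len(c[1]) + 1 for c in mesh.cells)
    buf.write(f"CELLS {len(mesh.cells)} {total}\n")
    for ctype, conn in mesh.cells:
        buf.write(str(len(conn)) + " " + " ".join(map(str, conn)) + "\n")
    buf.write(f"CELL_TYPES {len(mesh.cells)}\n")
    for ctype, _ in mesh.cells:
        buf.write(f"{_VTK_TYPE[ctype]}\n")
    buf.write(f"CELL_DATA {len(mesh.cells)}\n")
    buf.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
    for reg in mesh.cell_regions:
        buf.write(f"{_REGION_ID[reg]}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
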