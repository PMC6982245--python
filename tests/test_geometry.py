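"""Eye geometry: conic surface, mesh topology, volume, air projection."""

import numpy as np
import pytest
from scipy.optimize import brentq

from tonosim.geometry import (AirDomainMesh, ConfigError, CornealTopography,
                              EyeMeshConfig, GeometryError,
                              build_anterior_surface, build_eye_mesh,
                              build_meridian, enclosed_volume,
                              project_air_domain, signed_volume, write_vtk)


class TestAnteriorSurface:
    def test_apex_height_and_slope(self):
        topo = CornealTopography(R_anterior=7.8, Q=0.0)
        assert build_anterior_surface(topo, 0.0) == 0.0
        assert build_anterior_surface(topo, 1e-6) == pytest.approx(0.0, abs=1e-9)

    def test_sphere_reaches_equator(self):
        topo = CornealTopography(R_anterior=7.8, Q=0.0)
        assert build_anterior_surface(topo, 7.8) == pytest.approx(7.8, rel=1e-12)

    def test_aspheric_value_against_implicit_conic_root(self):
        # oracle: solve r^2 = 2 R z - (1+Q) z^2 for z numerically
        R, Q, r = 7.8, -0.3, 3.0
        z_oracle = brentq(lambda z: 2 * R * z - (1 + Q) * z**2 - r * r, 0.0, R)
        topo = CornealTopography(R_anterior=R, Q=Q)
        assert build_anterior_surface(topo, r) == pytest.approx(z_oracle, rel=1e-12)

    def test_out_of_domain_radius_raises(self):
        topo = CornealTopography(R_anterior=7.8, Q=0.5)
        with pytest.raises(GeometryError):
            build_anterior_surface(topo, 7.8)

    def test_elevation_map_reproduced_at_grid_radii(self):
        rg = np.linspace(0, 5.5, 23)
        zg = rg**2 / (7.7 + np.sqrt(7.7**2 - 0.8 * rg**2))
        topo = CornealTopography(elevation_map=(rg, zg))
        assert np.max(np.abs(build_anterior_surface(topo, rg) - zg)) <= 1e-9

    def test_elevation_map_must_be_single_valued(self):
        with pytest.raises(GeometryError):
            CornealTopography(elevation_map=([0.0, 1.0, 0.5], [0.0, 0.1, 0.2]))


class TestEyeMesh:
    @pytest.mark.parametrize("rings_c,rings_s,sectors,layers,expected", [
        (15, 35, 100, 2, 10000),   # the default published element count
        (15, 35, 24, 1, 1200),
        (4, 6, 12, 3, 360),
    ])
    def test_element_count_formula(self, rings_c, rings_s, sectors, layers, expected):
        cfg = EyeMeshConfig(corneal_rings=rings_c, scleral_rings=rings_s,
                            sectors=sectors, layers=layers)
        mesh = build_eye_mesh(CornealTopography(), cfg)
        assert mesh.n_elements == expected == (rings_c + rings_s) * sectors * layers

    def test_degenerate_sectors_rejected(self):
        with pytest.raises(ConfigError):
            EyeMeshConfig(sectors=2)
        with pytest.raises(GeometryError):
            CornealTopography(CCT=-10.0)

    def test_surfaces_are_closed_with_euler_characteristic_two(self):
        mesh = build_eye_mesh(CornealTopography(),
                              EyeMeshConfig(sectors=24, layers=1))
        for name in ("outer", "inner"):
            faces = mesh.surface_facets(name)
            verts = np.unique(faces)
            edges = np.unique(np.sort(np.concatenate(
                [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1),
                axis=0)
            chi = len(verts) - len(edges) + len(faces)
            assert chi == 2

    def test_every_element_has_one_of_five_regions(self):
        mesh = build_eye_mesh(CornealTopography(), EyeMeshConfig(sectors=12))
        assert set(mesh.cell_regions) == {
            "cornea", "limbus", "anterior_sclera", "equatorial_sclera",
            "posterior_sclera"}

    def test_apex_thickness_equals_cct(self):
        cfg = EyeMeshConfig(sectors=12)
        for cct in (445.0, 645.0):
            mesh = build_eye_mesh(CornealTopography(CCT=cct), cfg)
            npl = len(mesh.nodes) // (cfg.layers + 1)
            apex_out = mesh.nodes[0, 2]
            apex_in = mesh.nodes[cfg.layers * npl, 2]
            assert apex_out - apex_in == pytest.approx(cct * 1e-3, rel=1e-9)


class TestEnclosedVolume:
    @staticmethod
    def _tri_sphere(r=10.0, n=60):
        th = np.linspace(0, np.pi, n + 1)
        ph = np.linspace(0, 2 * np.pi, 2 * n, endpoint=False)
        # build via a revolved band triangulation around the polar axis
        verts = [(0, 0, r)]
        for t in th[1:-1]:
            for p in ph:
                verts.append((r * np.sin(t) * np.cos(p),
                              r * np.sin(t) * np.sin(p), r * np.cos(t)))
        verts.append((0, 0, -r))
        m = len(ph)
        faces = []
        for k in range(m):
            faces.append([0, 1 + k, 1 + (k + 1) % m])
        for i in range(n - 2):
            a = 1 + i * m
            b = 1 + (i + 1) * m
            for k in range(m):
                k2 = (k + 1) % m
                faces.append([a + k, b + k, b + k2])
                faces.append([a + k, b + k2, a + k2])
        last = len(verts) - 1
        a = 1 + (n - 2) * m
        for k in range(m):
            faces.append([last, a + (k + 1) % m, a + k])
        return np.array(verts), np.array(faces)

    def test_sphere_volume_within_half_percent(self):
        v, f = self._tri_sphere()
        assert len(f) >= 5000
        assert signed_volume(v, f) == pytest.approx(4 / 3 * np.pi * 1000, rel=5e-3)

    def test_translation_invariance(self):
        v, f = self._tri_sphere(n=24)
        assert signed_volume(v + [5, 5, 5], f) == pytest.approx(
            signed_volume(v, f), rel=1e-12)

    def test_open_surface_raises(self):
        v, f = self._tri_sphere(n=24)
        with pytest.raises(GeometryError):
            signed_volume(v, f[:-1])

    def test_cavity_volume_decreases_with_cct(self):
        cfg = EyeMeshConfig(sectors=16)
        vols = [enclosed_volume(build_eye_mesh(CornealTopography(CCT=c), cfg))
                for c in (445.0, 545.0, 645.0)]
        assert vols[0] > vols[1] > vols[2]


class TestAirDomain:
    def test_apex_projects_straight_up(self):
        mesh = build_eye_mesh(CornealTopography(), EyeMeshConfig(sectors=16))
        air = project_air_domain(mesh, standoff=11.0, layers=6)
        apex = mesh.nodes[0]
        top_apex = air.nodes[-1, 0]
        assert top_apex == pytest.approx([0.0, 0.0, apex[2] + 11.0], abs=1e-12)

    def test_single_similar_triangles_scale(self):
        mesh = build_eye_mesh(CornealTopography(), EyeMeshConfig(sectors=16))
        air = project_air_domain(mesh, layers=4)
        surf = air.nodes[0]
        top = air.nodes[-1]
        r_s = np.hypot(surf[:, 0], surf[:, 1])
        r_t = np.hypot(top[:, 0], top[:, 1])
        m = r_s > 1e-9
        ratios = r_t[m] / r_s[m]
        assert 0.0 < air.scale <= 1.0
        assert np.allclose(ratios, air.scale, rtol=1e-12)

    def test_layer0_nodes_and_count(self):
        mesh = build_eye_mesh(CornealTopography(), EyeMeshConfig(sectors=16))
        air = project_air_domain(mesh, layers=5)
        # layer 0 is bitwise-identical to the referenced surface nodes
        assert np.array_equal(air.nodes[0], mesh.nodes[air.surface_node_ids])
        assert air.nodes.shape == (6, len(air.surface_node_ids), 3)
        with pytest.raises(ConfigError):
            project_air_domain(mesh, standoff=-1.0)


def test_vtk_export_round_figures(tmp_path):
    mesh = build_eye_mesh(CornealTopography(), EyeMeshConfig(sectors=12, layers=1))
    out = tmp_path / "eye.vtk"
    write_vtk(mesh, out)
    text = out.read_text().splitlines()
    assert text[0].startswith("# vtk DataFile")
    assert f"POINTS {len(mesh.nodes)} double" in text
    assert any(line.startswith(f"CELLS {mesh.n_elements} ") for line in text)


def test_meridian_arc_length_monotone_and_regions_ordered():
    mer = build_meridian(CornealTopography(), EyeMeshConfig())
    s = mer.arc_length()
    assert np.all(np.diff(s) > 0)
    # the five regions appear in anatomical order along the meridian
    order = []
    for reg in mer.region:
        if not order or order[-1] != reg:
            order.append(reg)
    assert order == ["cornea", "limbus", "anterior_sclera",
                     "equatorial_sclera", "posterior_sclera"]
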