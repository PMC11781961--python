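"""Parametric vein/sinus/leaflet geometry and meshing."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from venavalve import geometry as geo


class TestParams:
    def test_table_defaults(self, table_params):
        p = table_params
        assert (p.l, p.d, p.tw) == (3.2, 0.691, 0.020)
        assert (p.lv, p.tv, p.ls, p.ts) == (0.500, 0.020, 1.000, 0.015)

    @pytest.mark.parametrize("kw", [
        dict(d=-1.0), dict(lv=1.5), dict(ls=4.0), dict(g=0.1),
        dict(sinus_bulge_ratio=0.9), dict(sinus_bulge_ratio=2.5),
    ])
    def test_invariants_rejected(self, kw):
        with pytest.raises(ValueError):
            geo.GeometryParams(**kw)

    def test_truncation_keeps_valve_centred(self, table_params):
        t = table_params.truncated(3.0)
        assert t.l == 3.0
        assert t.valve_top == pytest.approx(1.75)


class TestLeafletMidsurface:
    def test_commissures_on_wall_for_all_depths(self, table_params):
        p = table_params
        rin = float(geo.inner_radius(p, p.valve_top))
        for s in (0.0, 1.0):
            for t in (0.0, 0.5, 1.0):
                pt = geo.leaflet_midsurface(p, s, t)
                assert np.hypot(pt[0], pt[1]) == pytest.approx(rin,
                                                               abs=1e-12)

    def test_free_edge_midpoint_at_half_gap(self, table_params):
        p = table_params
        pt = geo.leaflet_midsurface(p, 0.5, 1.0)
        assert pt[0] == pytest.approx(p.g / 2, abs=1e-12)
        assert pt[1] == pytest.approx(0.0, abs=1e-12)
        pt2 = geo.leaflet_midsurface(p, 0.5, 1.0, side=-1)
        assert pt2[0] == pytest.approx(-p.g / 2, abs=1e-12)

    def test_axial_extent_equals_valve_depth(self, table_params):
        p = table_params
        s, t = np.meshgrid(np.linspace(0, 1, 401), np.linspace(0, 1, 41))
        pts = geo.leaflet_midsurface(p, s, t)
        extent = p.valve_top - pts[..., 2].min()
        assert extent == pytest.approx(p.lv, abs=1e-6)

    def test_domain_errors(self, table_params):
        with pytest.raises(geo.ParameterDomainError):
            geo.leaflet_midsurface(table_params, -0.1, 0.5)
        with pytest.raises(geo.ParameterDomainError):
            geo.leaflet_midsurface(table_params, 0.5, 1.2)


class TestMeshBuild:
    def test_end_lumen_diameter(self, coarse_mesh, table_params):
        res = coarse_mesh.meta["resolution"]
        end = coarse_mesh.meta["wall_ids"][0, :, 0]
        r = np.hypot(*coarse_mesh.X[end, :2].T)
        assert 2 * r.mean() == pytest.approx(table_params.d, abs=res / 2)

    def test_wall_volume_thin_shell_estimate(self, coarse_mesh,
                                             table_params):
        p = table_params
        plain_len = p.l - p.ls
        expect = np.pi * p.d * p.tw * plain_len
        got = coarse_mesh.region_volume("wall")
        assert got == pytest.approx(expect, rel=0.05)

    def test_free_edge_gap_by_construction(self, table_params):
        p = geo.GeometryParams(g=0.01)
        m = geo.build_structural_mesh(p, resolution=0.11)
        e1, e2 = m.free_edges
        dmin = cdist(m.X[e1], m.X[e2]).min()
        assert dmin == pytest.approx(0.01, abs=1e-9)

    def test_mirror_symmetry(self, coarse_mesh):
        X = coarse_mesh.X
        refl = X * np.array([-1.0, 1.0, 1.0])
        d, _ = cKDTree(X).query(refl)
        assert d.max() < 1e-9

    def test_conformal_junctions(self, coarse_mesh):
        """Attachment nodes belong to elements of >= 2 regions."""
        m = coarse_mesh
        regions_of_node = {}
        for tet, reg in zip(m.elements, m.region):
            for n in tet:
                regions_of_node.setdefault(int(n), set()).add(int(reg))
        leaf = geo.REGION_ID["leaflet"]
        leaf_nodes = {int(n) for tet, reg in zip(m.elements, m.region)
                      if reg == leaf for n in tet}
        shared = [n for n in leaf_nodes if len(regions_of_node[n]) >= 2]
        assert len(shared) > 0
        # every shared node also appears in wall or sinus elements
        for n in shared:
            assert regions_of_node[n] - {leaf}

    def test_no_orphans_and_positive_volumes(self, coarse_mesh):
        rep = geo.mesh_quality_report(coarse_mesh)
        assert rep["n_orphan_nodes"] == 0
        assert rep["min_volume"] > 0

    def test_refinement_volume_convergence(self, table_params):
        vols = {}
        for res in (0.06, 0.03):
            m = geo.build_structural_mesh(table_params, res)
            vols[res] = {
                "total": m.total_volume(),
                "wall": m.region_volume("wall"),
                "sinus": m.region_volume("sinus"),
            }
        for key in vols[0.06]:
            change = abs(vols[0.03][key] - vols[0.06][key]) / vols[0.06][key]
            assert change < 0.01, f"{key} changed {change:.2%} on halving"

    def test_too_coarse_resolution_rejected(self, table_params):
        with pytest.raises(geo.MeshingError):
            geo.build_structural_mesh(table_params, resolution=0.5)

    def test_fixed_end_rings_at_tube_ends(self, coarse_mesh):
        z = coarse_mesh.X[coarse_mesh.fixed_nodes, 2]
        assert np.all((z < 1e-9) | (z > coarse_mesh.params.l - 1e-9))


class TestQualityReport:
    def test_single_regular_tetrahedron(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                      [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]])
        mesh = geo.StructuralMesh(
            X=X, elements=np.array([[0, 1, 2, 3]]),
            region=np.array([0], dtype=np.int8),
            fixed_nodes=np.array([], dtype=int), free_edges=(),
            params=geo.GeometryParams(), meta={})
        rep = geo.mesh_quality_report(mesh)
        assert rep["n_elements"] == 1
        assert rep["min_volume"] > 0
        assert rep["worst_aspect_ratio"] == pytest.approx(
            rep["worst_aspect_ratio"])

    def test_inverted_element_reported_with_id(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        mesh = geo.StructuralMesh(
            X=X, elements=np.array([[0, 2, 1, 3]]),    # negative volume
            region=np.array([0], dtype=np.int8),
            fixed_nodes=np.array([], dtype=int), free_edges=(),
            params=geo.GeometryParams(), meta={})
        with pytest.raises(geo.InvertedElementError) as exc:
            geo.mesh_quality_report(mesh)
        assert 0 in exc.value.element_ids

    def test_element_count_order_of_magnitude_at_study_resolution(
            self, table_params):
        """At the in-plane resolution matching the reference element
        budget, the count lands within a factor 2 of 74,294."""
        m = geo.build_structural_mesh(table_params.truncated(3.0), 0.03)
        assert 74294 / 2 <= m.n_elements <= 74294 * 2
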