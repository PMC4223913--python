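"""Mesh generation, model geometry and configuration handling."""

import dataclasses

import numpy as np
import pytest

import ocuvib as ov
from ocuvib import fem
from ocuvib.materials import ConfigurationError
from ocuvib.mesh import MeshError, build_mapped_block, merge_meshes
from ocuvib.models import WeakZone, apply_weak_zone, corneal_centroid_angles


class TestMappedBlocks:
    def test_rectangular_block_counts_and_edge_sets(self):
        def xfun(u, v):
            return np.stack([u, 2 * v], axis=-1)

        mesh = build_mapped_block(xfun, 3, 2, order=8, region="solid")
        assert mesh.n_elements == 6
        # serendipity lattice: (2*3+1)*(2*2+1) minus 6 element centres
        assert mesh.n_nodes == 7 * 5 - 6
        assert len(mesh.edge_sets["v0"]) == 3
        assert len(mesh.edge_sets["u1"]) == 2
        mesh.validate()

    def test_inverted_mapping_fails_validation(self):
        def xfun(u, v):
            return np.stack([1.0 - u, v], axis=-1)  # negative orientation

        mesh = build_mapped_block(xfun, 2, 2, order=4)
        with pytest.raises(MeshError):
            mesh.validate()

    def test_merge_fuses_shared_boundary_nodes(self):
        def block(z0):
            def xfun(u, v):
                return np.stack([u, z0 + v], axis=-1)

            return xfun

        a = build_mapped_block(block(0.0), 2, 2, order=4, region="a")
        b = build_mapped_block(block(1.0), 2, 2, order=4, region="b")
        merged = merge_meshes(a, b)
        assert merged.n_nodes == a.n_nodes + b.n_nodes - 3  # 3 shared nodes
        merged.validate()


class TestFlapModel:
    def test_default_flap_has_54_clamped_elements(self, flap_model):
        mesh = flap_model.mesh
        assert mesh.n_elements == 54
        rim = np.unique(
            np.concatenate(
                [mesh.edge_nodes(e, le) for e, le in mesh.edge_sets["u1"]]
            )
        )
        sd = flap_model.dof.sdofs(rim)
        assert flap_model.fixed[sd].all()

    def test_refinement_quadruples_element_count(self):
        m = ov.build_flap(ov.FlapConfig(refine=2))
        assert m.mesh.n_elements == 4 * 54

    def test_zero_prestress_state_is_exactly_zero(self):
        m = ov.build_flap(ov.FlapConfig(prestress_kpa=0.0))
        assert m.prestress.is_zero()
        Kg = fem.assemble_geometric_stiffness(m.mesh, m.prestress, m.dof)
        assert Kg.nnz == 0

    def test_mesh_regeneration_is_deterministic(self):
        a = ov.build_flap(ov.FlapConfig())
        b = ov.build_flap(ov.FlapConfig())
        assert np.array_equal(a.mesh.nodes, b.mesh.nodes)
        assert np.array_equal(a.mesh.elements, b.mesh.elements)


class TestGlobeModel:
    def test_region_element_counts_match_reference_within_10_percent(self, globe_model):
        mesh = globe_model.mesh
        expected = {
            "cornea-anterior": 40,
            "cornea-posterior": 40,
            "limbus": 12,
            "sclera": 182,
            "fluid": 1234,
        }
        for region, n in expected.items():
            count = int((mesh.region == region).sum())
            assert abs(count - n) <= 0.1 * n, (region, count)

    def test_globe_mesh_is_valid_and_deterministic(self, globe_model):
        globe_model.mesh.validate()
        again = ov.build_globe(ov.GlobeConfig())
        assert np.array_equal(globe_model.mesh.nodes, again.mesh.nodes)

    def test_zero_iop_gives_zero_prestress(self):
        m = ov.build_globe(ov.GlobeConfig(iop_kpa=0.0))
        assert m.prestress.is_zero()

    def test_static_iop_solve_pushes_apex_outward(self):
        m = ov.build_globe(ov.GlobeConfig(prestress_mode="static"))
        uz = m.static_displacement[2 * m.dof.s_of_node[m.probe_node] + 1]
        assert uz > 0.0

    def test_anterior_posterior_moduli_partition_corneal_thickness(self, globe_model):
        mats = globe_model.materials
        assert mats["cornea-anterior"].E == pytest.approx(24.8e3)
        assert mats["cornea-posterior"].E == pytest.approx(19.8e3)
        n_ant = (globe_model.mesh.region == "cornea-anterior").sum()
        n_post = (globe_model.mesh.region == "cornea-posterior").sum()
        assert n_ant == n_post  # equal-thickness layers

    def test_geometric_consistency_checks(self):
        with pytest.raises(ConfigurationError):
            ov.GlobeConfig(posterior_curvature_mm=7.0)  # must be < anterior
        with pytest.raises(ConfigurationError):
            ov.GlobeConfig(corneal_diameter_mm=20.0)  # exceeds sclera
        with pytest.raises(ConfigurationError):
            ov.GlobeConfig(iop_kpa=-1.0)

    def test_fsi_edges_touch_exactly_the_wetted_surface(self, globe_model):
        mesh = globe_model.mesh
        assert len(mesh.fsi_edges) == 137  # one edge per shell column
        for e, le in mesh.fsi_edges:
            assert mesh.region[e] != "fluid"


class TestWeakZones:
    def test_central_zone_selects_only_apex_region(self, globe_model):
        elems, theta = corneal_centroid_angles(globe_model)
        weak = apply_weak_zone(globe_model, WeakZone(70.0, 90.0, 2.48))
        changed = np.flatnonzero(weak.e_scale != 1.0)
        assert changed.size > 0
        assert set(changed).issubset(set(elems))
        assert theta[np.isin(elems, changed)].min() >= 70.0

    def test_peripheral_zone_leaves_apex_untouched(self, globe_model):
        weak = apply_weak_zone(globe_model, WeakZone(50.0, 70.0, 2.48))
        changed = np.flatnonzero(weak.e_scale != 1.0)
        elems, theta = corneal_centroid_angles(globe_model)
        touched_theta = theta[np.isin(elems, changed)]
        assert changed.size > 0
        assert touched_theta.max() <= 70.0

    def test_zone_missing_the_cornea_raises(self, globe_model):
        with pytest.raises(ConfigurationError):
            apply_weak_zone(globe_model, WeakZone(0.0, 10.0, 2.48))

    def test_noop_weakening_reproduces_the_model_bitwise(self):
        # with equal layer moduli a "reduction" to the nominal value is a
        # no-op: identical scale factors, bitwise identical response
        cfg = ov.GlobeConfig(E_anterior_kpa=24.8, E_posterior_kpa=24.8)
        base = ov.build_globe(cfg)
        weak = apply_weak_zone(base, WeakZone(70.0, 90.0, 24.8))
        assert np.all(weak.e_scale == 1.0)
        f = 137.0
        u0 = base.solve(f).u
        u1 = weak.solve(f).u
        assert np.array_equal(u0, u1)

    def test_invalid_zone_angles_rejected(self):
        with pytest.raises(ConfigurationError):
            WeakZone(80.0, 70.0, 2.48)
        with pytest.raises(ConfigurationError):
            WeakZone(0.0, 95.0, 2.48)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        from ocuvib.io import load_config, save_config

        cfg = ov.GlobeConfig(E_anterior_kpa=30.0)
        path = tmp_path / "globe.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert back == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        from ocuvib.io import load_config

        path = tmp_path / "bad.yaml"
        path.write_text("kind: flap\nbananas: 3\n")
        with pytest.raises(ConfigurationError):
            load_config(path)

    def test_gmsh_export_is_readable_text(self, tmp_path, flap_model):
        from ocuvib.io import export_gmsh

        path = tmp_path / "flap.msh"
        export_gmsh(flap_model.mesh, path)
        text = path.read_text()
        assert text.startswith("$MeshFormat")
        assert f"$Nodes\n{flap_model.mesh.n_nodes}" in text
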