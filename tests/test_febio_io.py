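"""Deck writing/parsing, fixation constraints, and solver log ingestion."""

import numpy as np
import pytest
from lxml import etree

from tenodesis_fe.errors import FebParseError, FebValidationError
from tenodesis_fe.febio_io import (FEModelSpec, MeshDomain, RigidBody,
                                   node_fixation_actions, parse_feb,
                                   read_element_stresses, read_kinematics,
                                   specs_equal, write_feb)
from tenodesis_fe.loading_protocols import build_protocol
from tenodesis_fe.materials import GraftMaterial, TIMRParams
from tenodesis_fe.mesh_geometry import box_tet_mesh
from tenodesis_fe.synthetic_fixtures import random_model_spec


class TestWriteParse:
    def test_minimal_spec_is_wellformed_xml(self, tmp_path):
        spec = FEModelSpec(rigid_bodies=[RigidBody("femur")])
        path = tmp_path / "minimal.feb"
        write_feb(spec, path)
        root = etree.parse(str(path)).getroot()
        assert root.tag == "febio_spec"
        assert root.find("Module") is not None
        assert root.find("Globals") is not None

    def test_node_count_conservation(self, tmp_path):
        mesh = box_tet_mesh((4, 4, 4), 1.0, name="graft")  # 125 nodes
        spec = FEModelSpec(
            materials=[GraftMaterial("m", TIMRParams(c1=1.0))],
            domains=[MeshDomain("graft", mesh, "m")])
        path = tmp_path / "graft.feb"
        write_feb(spec, path)
        root = etree.parse(str(path)).getroot()
        nodes = root.find("Mesh").find("Nodes")
        assert len(nodes.findall("node")) == len(mesh.nodes)
        elems = root.find("Mesh").find("Elements")
        assert len(elems.findall("elem")) == len(mesh.elements)

    @pytest.mark.parametrize("seed", range(12))
    def test_round_trip_on_random_specs(self, tmp_path, seed):
        spec = random_model_spec(seed)
        path = tmp_path / f"rt_{seed}.feb"
        write_feb(spec, path)
        assert specs_equal(spec, parse_feb(path))

    def test_prestrain_round_trip(self, tmp_path):
        """Two ligaments with distinct prestrain stretches survive a
        write/parse cycle; a stretch of exactly 1 leaves the deck without
        prestrain data."""
        m1 = box_tet_mesh((2, 2, 2), 1.0, name="acl")
        m2 = box_tet_mesh((2, 2, 2), 1.0, name="mcl")
        from tenodesis_fe.materials import PreStrainSpec
        spec = FEModelSpec(
            materials=[
                GraftMaterial("acl_m", TIMRParams(c1=1.0),
                              prestrain=PreStrainSpec(1.03)),
                GraftMaterial("mcl_m", TIMRParams(c1=1.0),
                              prestrain=PreStrainSpec(1.01))],
            domains=[MeshDomain("acl", m1, "acl_m"),
                     MeshDomain("mcl", m2, "mcl_m")])
        path = tmp_path / "ps.feb"
        write_feb(spec, path)
        back = parse_feb(path)
        stretches = sorted(m.prestrain.stretch for m in back.materials)
        assert stretches == [1.01, 1.03]

        spec.materials[0].prestrain = PreStrainSpec(1.0)
        spec.materials[1].prestrain = None
        write_feb(spec, path)
        root = etree.parse(str(path)).getroot()
        assert root.find("MeshData") is None

    def test_validation_lists_all_violations(self, tmp_path):
        mesh = box_tet_mesh((2, 2, 2), 1.0)
        spec = FEModelSpec(
            domains=[MeshDomain("g", mesh, "missing_material")])
        spec.contacts.append(__import__(
            "tenodesis_fe.febio_io", fromlist=["ContactPair"]).ContactPair(
            "c", "no_surf_a", "no_surf_b"))
        with pytest.raises(FebValidationError) as exc:
            write_feb(spec, tmp_path / "bad.feb")
        assert len(exc.value.violations) == 3

    def test_truncated_file_raises_parse_error(self, tmp_path):
        spec = random_model_spec(1)
        path = tmp_path / "full.feb"
        write_feb(spec, path)
        text = path.read_text()
        (tmp_path / "cut.feb").write_text(text[:len(text) // 2])
        with pytest.raises(FebParseError):
            parse_feb(tmp_path / "cut.feb")

    def test_unknown_section_preserved_with_warning(self, tmp_path):
        spec = FEModelSpec(rigid_bodies=[RigidBody("femur")])
        path = tmp_path / "extra.feb"
        write_feb(spec, path)
        root = etree.parse(str(path)).getroot()
        etree.SubElement(root, "Output").append(etree.Element("plotfile"))
        etree.ElementTree(root).write(str(path))
        with pytest.warns(UserWarning, match="Output"):
            back = parse_feb(path)
        assert len(back.extra_sections) == 1

    def test_family_decks_differ_only_in_documented_sections(self, tmp_path,
                                                             small_phantom_spec):
        """Deck families share the skeleton; surgical families add graft
        domains, extra steps and fixation constraints only."""
        from tenodesis_fe.assembly import build_phantom_model

        def sections(surgery, **kw):
            spec = build_phantom_model(surgery, phantom=small_phantom_spec,
                                       **kw)
            p = tmp_path / f"{surgery}.feb"
            write_feb(spec, p)
            root = etree.parse(str(p)).getroot()
            return root

        injured = sections("injured")
        aclr = sections("aclr", aclr_tension=80.0)
        both = sections("aclr_let", aclr_tension=80.0, let_tension=40.0)
        for root in (injured, aclr, both):
            # the common skeleton is identical across families
            assert etree.tostring(root.find("Globals")) == \
                etree.tostring(injured.find("Globals"))
        assert len(injured.find("Step").findall("step")) == 2
        assert len(aclr.find("Step").findall("step")) == 5
        assert len(both.find("Step").findall("step")) == 7
        names = {d.get("name") for d in both.find("MeshDomains")}
        assert names == {"aclr_graft", "let_graft"}


class TestNodeFixation:
    def _spec(self):
        mesh = box_tet_mesh((2, 2, 2), 1.0, name="graft")
        mesh.node_sets["aclr_graft_free_end"] = np.array([0, 1])
        mesh.node_sets["aclr_tunnel_fixation_nodes"] = np.array([0, 1])
        plan = build_protocol("aclr", aclr_tension=80.0)
        return FEModelSpec(
            materials=[GraftMaterial("m", TIMRParams(c1=1.0))],
            rigid_bodies=[RigidBody("femur"), RigidBody("tibia")],
            domains=[MeshDomain("graft", mesh, "m")], plan=plan)

    def test_constraint_active_from_fixation_step_onward(self, tmp_path):
        spec = self._spec()
        path = tmp_path / "fix.feb"
        write_feb(spec, path)
        root = etree.parse(str(path)).getroot()
        steps = root.find("Step").findall("step")
        active = ["Constraints" in [c.tag for c in s] for s in steps]
        # fixation happens in step 3 of 5 (index 2)
        assert active == [False, False, True, True, True]

    def test_missing_node_set_rejected(self):
        spec = self._spec()
        with pytest.raises(FebValidationError):
            node_fixation_actions(spec, "not_a_set", "tibia", "prestrain")

    def test_two_fixations_have_distinct_activation_steps(self, tmp_path):
        spec = self._spec()
        spec.domains[0].mesh.node_sets["femoral_end"] = np.array([2, 3])
        node_fixation_actions(spec, "femoral_end", "femur", "prestrain")
        path = tmp_path / "two.feb"
        write_feb(spec, path)
        back = parse_feb(path)
        activations = {f.node_set: i
                       for i, st in enumerate(back.plan.steps)
                       for f in st.node_fixations}
        assert activations["femoral_end"] == 0
        assert activations["aclr_tunnel_fixation_nodes"] == 2


KIN_CSV = """time,body,x,y,z,qw,qx,qy,qz
0.0,femur,0.0,0.0,25.0,1.0,0.0,0.0,0.0
1.0,femur,0.1,-0.5,25.0,0.9961947,0.0871557,0.0,0.0
2.0,femur,0.2,-1.0,25.0,0.9848078,0.1736482,0.0,0.0
"""


class TestSolverLogs:
    def test_kinematics_exact_values(self, tmp_path):
        p = tmp_path / "kin.csv"
        p.write_text(KIN_CSV)
        kin = read_kinematics(p)
        assert len(kin.times) == 3
        np.testing.assert_allclose(kin.positions[1], [0.1, -0.5, 25.0])
        np.testing.assert_allclose(np.linalg.norm(kin.quaternions, axis=1),
                                   1.0, atol=1e-12)

    def test_decreasing_time_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(KIN_CSV.replace("2.0,femur", "0.5,femur"))
        with pytest.raises(FebParseError):
            read_kinematics(p)

    def test_small_quaternion_drift_renormalized(self, tmp_path):
        p = tmp_path / "drift.csv"
        p.write_text(KIN_CSV.replace("1.0,0.0,0.0,0.0",
                                     "1.00000001,0.0,0.0,0.0"))
        kin = read_kinematics(p)
        assert np.linalg.norm(kin.quaternions[0]) == pytest.approx(1.0,
                                                                   abs=1e-12)

    def test_large_quaternion_drift_rejected(self, tmp_path):
        p = tmp_path / "drift2.csv"
        p.write_text(KIN_CSV.replace("1.0,0.0,0.0,0.0",
                                     "1.1,0.0,0.0,0.0"))
        with pytest.raises(FebParseError):
            read_kinematics(p)

    def _stress_csv(self, tmp_path):
        rows = ["step,element,cx,cy,cz,von_mises"]
        for step in (1, 2):
            for e in range(10):
                rows.append(f"{step},{e},{e},0.0,0.0,{1.0 + e + 10 * step}")
        p = tmp_path / "stress.csv"
        p.write_text("\n".join(rows) + "\n")
        return p

    def test_restriction_to_element_set(self, tmp_path):
        p = self._stress_csv(tmp_path)
        recs = read_element_stresses(p, {1, 3, 5, 7})
        assert len(recs) == 8  # 4 elements x 2 steps
        assert {r.element_id for r in recs} == {1, 3, 5, 7}
        steps = [r.step for r in recs]
        assert steps == sorted(steps)

    def test_negative_stress_rejected(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("step,element,cx,cy,cz,von_mises\n1,0,0,0,0,-1.0\n")
        with pytest.raises(FebParseError):
            read_element_stresses(p, {0})

    def test_unknown_element_set_rejected(self, tmp_path):
        p = self._stress_csv(tmp_path)
        with pytest.raises(FebParseError):
            read_element_stresses(p, {99, 100})
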