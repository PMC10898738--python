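"""Assemble complete phantom-knee model specs for each surgical family.

Composes the phantom geometry, graft sweeping, constitutive defaults, the
cylindrical-joint chain, contact, and the per-surgery step plan into an
exportable :class:`~tenodesis_fe.febio_io.FEModelSpec`.  The four families
mirror the study designs: the injured knee (no ACL), the healthy knee
(native ACL), standalone single-bundle reconstruction, and reconstruction
combined with lateral extra-articular tenodesis.

Default graft parameters are synthetic stand-ins on the stiffness scale of
tendon tissue (documented in the methods note); they are configuration, not
measurements.
"""

from __future__ import annotations

import numpy as np

from .febio_io import (ContactPair, CylindricalJoint, FEModelSpec,
                       MeshDomain, RigidBody, node_fixation_actions)
from .loading_protocols import PSProfile, build_protocol
from .materials import GraftMaterial, PreStrainSpec, TIMRParams
from .mesh_geometry import box_tet_mesh, sweep_graft
from .synthetic_fixtures import PhantomSpec, make_phantom_knee

__all__ = ["SEMITENDINOSUS_LIKE", "ITB_LIKE", "build_phantom_model"]

# synthetic stand-in constitutive defaults (MPa / dimensionless)
SEMITENDINOSUS_LIKE = TIMRParams(c1=2.0, c2=0.5, c3=0.8, c4=40.0, c5=400.0,
                                 lambda_star=1.045)
ITB_LIKE = TIMRParams(c1=1.5, c2=0.3, c3=0.5, c4=45.0, c5=250.0,
                      lambda_star=1.05)
ACL_LIKE = TIMRParams(c1=1.95, c2=0.0, c3=0.0139, c4=116.22, c5=535.04,
                      lambda_star=1.046)

_JOINT_AXES = [((0.0, 0.0, 2.5), (1.0, 0.0, 0.0)),
               ((0.0, 0.0, 2.5), (0.0, 1.0, 0.0)),
               ((0.0, 0.0, 2.5), (0.0, 0.0, 1.0))]


def build_phantom_model(surgery: str, aclr_tension: float | None = None,
                        let_tension: float | None = None,
                        phantom: PhantomSpec | None = None,
                        profile: PSProfile | None = None,
                        acl_prestrain: float = 1.03,
                        aclr_fixation_deg: float = 25.0,
                        let_fixation_deg: float = 30.0) -> FEModelSpec:
    """Build a complete exportable model spec on the phantom knee.

    The bones are rigid bodies joined by the three-cylindrical-joint chain;
    grafts are swept volumetric domains with free-end and tunnel node sets
    wired into the step plan's pretension loads and fixation actions.
    """
    phantom_spec = phantom or PhantomSpec()
    knee = make_phantom_knee(phantom_spec)
    plan = build_protocol(surgery, aclr_tension=aclr_tension,
                          let_tension=let_tension,
                          aclr_fixation_deg=aclr_fixation_deg,
                          let_fixation_deg=let_fixation_deg,
                          profile=profile)
    spec = FEModelSpec(plan=plan)
    spec.rigid_bodies = [RigidBody("femur", center_of_mass=(0.0, 0.0, 25.0)),
                         RigidBody("tibia", center_of_mass=(0.0, 0.0, -20.0))]
    spec.joints = [CylindricalJoint(f"knee_joint_{i + 1}", "femur", "tibia",
                                    origin=o, axis=a)
                   for i, (o, a) in enumerate(_JOINT_AXES)]

    if surgery == "native":
        gap = knee.femur.nodes[:, 2].min()
        acl = box_tet_mesh((8.0, 8.0, gap + 4.0), phantom_spec.edge_length,
                           origin=(-4.0, -4.0, -2.0), name="acl")
        mat = GraftMaterial("acl_material", ACL_LIKE,
                            prestrain=PreStrainSpec(acl_prestrain))
        spec.materials.append(mat)
        spec.domains.append(MeshDomain("acl", acl, "acl_material"))

    if surgery in ("aclr", "aclr_let"):
        graft = sweep_graft(knee.aclr_trajectory, name="aclr_graft")
        graft.node_sets["aclr_graft_free_end"] = \
            graft.node_sets["proximal_end"].copy()
        graft.node_sets["aclr_tunnel_fixation_nodes"] = \
            graft.node_sets["proximal_end"].copy()
        spec.materials.append(GraftMaterial("aclr_graft_material",
                                            SEMITENDINOSUS_LIKE))
        spec.domains.append(MeshDomain("aclr_graft", graft,
                                       "aclr_graft_material"))
        spec.surfaces["aclr_graft_surface"] = \
            ("aclr_graft", _local_boundary(graft))
        # femoral end is anchored from the start
        node_fixation_actions(spec, "aclr_graft::distal_end", "femur",
                              "prestrain")

    if surgery == "aclr_let":
        strap = sweep_graft(knee.let_trajectory, name="let_graft")
        strap.node_sets["let_graft_free_end"] = \
            strap.node_sets["distal_end"].copy()
        strap.node_sets["let_tunnel_fixation_nodes"] = \
            strap.node_sets["distal_end"].copy()
        spec.materials.append(GraftMaterial("let_graft_material", ITB_LIKE))
        spec.domains.append(MeshDomain("let_graft", strap,
                                       "let_graft_material"))
        spec.surfaces["let_graft_surface"] = \
            ("let_graft", _local_boundary(strap))
        spec.contacts.append(ContactPair("let_vs_aclr",
                                         primary="let_graft_surface",
                                         secondary="aclr_graft_surface"))
        # tibial end of the strap is fixed with the tibia from the start
        node_fixation_actions(spec, "let_graft::proximal_end", "tibia",
                              "prestrain")

    spec.validate()
    return spec


def _local_boundary(mesh):
    faces = mesh.boundary_faces()
    return np.asarray(faces, dtype=int)
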