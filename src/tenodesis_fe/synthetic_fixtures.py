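"""Synthetic inputs for exercising the full pipeline without downloads.

Real subject geometry (segmented MRI bone surfaces) is deliberately not
required anywhere: phantom knees built from geometric primitives carry the
same labeling (plateau landmarks, tunnel cylinders, graft trajectories) as
a segmented knee would, so every geometric, export, and analysis operation
runs end to end on them.  Kinematics traces are generated with programmed
external-rotation and posterior-translation content so the analysis
pipeline can be verified closed-loop; uniaxial stress-strain data is
generated from known constitutive parameters for the same reason.

All randomness flows through one ``numpy.random.Generator`` seeded
explicitly; fixtures are byte-reproducible from (spec, seed).

``table1_fixture`` packages the published pretension summary table
(ten best combined ACLR-LET rows and nine standalone ACLR rows) for the
ranking and stress-comparison operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import KinematicsTrace, make_results_table
from .errors import GeometryError, MaterialError
from .materials import StressStrainData, TIMRParams, uniaxial_cauchy_stress
from .mesh_geometry import (Cylinder, LabeledSurfaceMesh, LabeledTetMesh,
                            PlateauLandmarks, TrajectoryPolyline,
                            box_tet_mesh)
from .loading_protocols import QuaternionSample

__all__ = [
    "PhantomSpec",
    "PhantomKnee",
    "make_phantom_knee",
    "make_flexion_quaternions",
    "make_kinematics",
    "make_uniaxial_data",
    "table1_fixture",
]


@dataclass
class PhantomSpec:
    """Primitive phantom knee: two boxes standing in for femur and tibia.

    Lengths in mm.  The tunnel dimensions follow the surgical defaults: a
    4 mm radius single-bundle graft, a 5 mm diameter lateral femoral tunnel
    for the tenodesis, and a 10 mm wide iliotibial-band strap.
    """

    femur_size: tuple = (40.0, 40.0, 40.0)
    tibia_size: tuple = (40.0, 40.0, 40.0)
    plateau_width: float = 40.0
    edge_length: float = 1.0
    aclr_graft_radius: float = 4.0
    aclr_tunnel_radius: float = 4.5
    let_tunnel_radius: float = 2.5
    itb_strap_width: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if min(*self.femur_size, *self.tibia_size, self.plateau_width,
               self.edge_length) <= 0:
            raise GeometryError("phantom dimensions must be positive")


@dataclass
class PhantomKnee:
    femur: LabeledTetMesh
    tibia: LabeledTetMesh
    femur_surface: LabeledSurfaceMesh
    landmarks: PlateauLandmarks
    aclr_tunnel: Cylinder
    let_tunnel: Cylinder
    aclr_trajectory: TrajectoryPolyline
    let_trajectory: TrajectoryPolyline


def make_phantom_knee(spec: PhantomSpec | None = None) -> PhantomKnee:
    """Build the phantom knee: tibia below z=0, femur above a 5 mm joint
    gap, plateau aspects on the tibial top face separated by the requested
    width along x (medial at -x).

    Raises :class:`GeometryError` when the mesh resolution leaves fewer
    than ~10 tetrahedra across the smallest tunnel diameter (two tets per
    structured cell along a line, so cell edge must not exceed d/5).
    """
    spec = spec or PhantomSpec()
    d_min = 2.0 * min(spec.aclr_tunnel_radius, spec.let_tunnel_radius)
    tets_across = 2.0 * d_min / spec.edge_length
    if tets_across < 10.0:
        raise GeometryError(
            f"resolution too coarse to drill a {d_min:g} mm tunnel: "
            f"~{tets_across:.0f} tetrahedra across the diameter (< 10)")

    fs, ts = np.asarray(spec.femur_size), np.asarray(spec.tibia_size)
    gap = 5.0
    tibia = box_tet_mesh(ts, spec.edge_length,
                         origin=(-ts[0] / 2, -ts[1] / 2, -ts[2]),
                         name="tibia")
    femur = box_tet_mesh(fs, spec.edge_length,
                         origin=(-fs[0] / 2, -fs[1] / 2, gap),
                         name="femur")
    femur_surface = femur.surface(name="femur_surface")

    w = spec.plateau_width
    landmarks = PlateauLandmarks(medial=(-w / 2, 0.0, 0.0),
                                 lateral=(w / 2, 0.0, 0.0))

    # single-bundle tunnel: oblique through the joint, entering the tibial
    # plateau and exiting the lateral femoral cortex
    aclr_dir = np.array([0.3, 0.0, 1.0])
    aclr_dir /= np.linalg.norm(aclr_dir)
    aclr_origin = np.array([-ts[0] / 8, 0.0, -0.75 * ts[2]])
    aclr_tunnel = Cylinder(origin=aclr_origin, direction=aclr_dir,
                           radius=spec.aclr_tunnel_radius, length=np.inf)
    # lateral femoral tunnel for the tenodesis, pierced along x
    let_z = gap + 0.5 * fs[2]
    let_tunnel = Cylinder(origin=(-fs[0], fs[1] / 8, let_z),
                          direction=(1.0, 0.0, 0.0),
                          radius=spec.let_tunnel_radius, length=np.inf)

    graft_len = 0.75 * ts[2] + gap + 0.75 * fs[2]
    aclr_trajectory = TrajectoryPolyline(
        points=[aclr_origin, aclr_origin + 0.5 * graft_len * aclr_dir,
                aclr_origin + graft_len * aclr_dir],
        radius=spec.aclr_graft_radius)
    # the strap runs from the anterolateral tibia up the lateral side, then
    # turns into the femoral tunnel along a quarter-arc (gentle bends keep
    # the swept cross-sections from inverting)
    x0, y2 = fs[0] / 2 + 4.0, fs[1] / 8
    r_arc = 0.5 * let_z
    phi = np.deg2rad(np.linspace(0.0, 90.0, 5))
    arc = np.column_stack([x0 - r_arc + r_arc * np.cos(phi),
                           np.full_like(phi, y2),
                           let_z - r_arc + r_arc * np.sin(phi)])
    let_points = np.vstack([[(w / 2, fs[1] / 5, -ts[2] / 2),
                             (w / 2 + 4.0, 0.15 * fs[1], 0.0)],
                            arc, [(0.0, y2, let_z)]])
    let_trajectory = TrajectoryPolyline(points=let_points,
                                        width=spec.itb_strap_width)
    return PhantomKnee(femur=femur, tibia=tibia, femur_surface=femur_surface,
                       landmarks=landmarks, aclr_tunnel=aclr_tunnel,
                       let_tunnel=let_tunnel,
                       aclr_trajectory=aclr_trajectory,
                       let_trajectory=let_trajectory)


def make_flexion_quaternions(axis=(1.0, 0.0, 0.0),
                             angles_deg=None) -> list[QuaternionSample]:
    """Flexion-sampled femoral orientations: rotations about a fixed axis
    at 0-90 degrees in 10 degree steps (the forward-simulation sampling)."""
    axis = np.asarray(axis, dtype=float).reshape(3)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise GeometryError("flexion axis must be unit-norm")
    if angles_deg is None:
        angles_deg = np.arange(0.0, 91.0, 10.0)
    out = []
    for a in angles_deg:
        half = np.deg2rad(a) / 2.0
        q = np.concatenate([[np.cos(half)], np.sin(half) * axis])
        if q[0] < 0:
            q = -q
        out.append(QuaternionSample(float(a), tuple(q)))
    return out


def _scaled_logistic(angles, center, k):
    """Logistic rescaled to exactly [0, 1] over the sampled angle range."""
    s = 1.0 / (1.0 + np.exp(-k * (angles - center)))
    return (s - s[0]) / (s[-1] - s[0])


def make_kinematics(etr_amplitude_deg: float, ptt_amplitude_mm: float,
                    transition_center_deg: float = 25.0,
                    noise_sd: float = 0.0, seed: int = 0,
                    flexion_deg=None, lfp=(0.0, 0.0, 0.0)) -> KinematicsTrace:
    """Synthetic pivot-shift reduction kinematics with programmed content.

    ETR and LFP-referenced PTT follow logistic transitions of exactly the
    stated amplitudes (the logistic is rescaled to span [0, amplitude] over
    the sampled flexion range) centered at ``transition_center_deg``, plus
    seeded additive Gaussian noise on both channels.  The femoral rotation
    is applied about the tibial long axis through the LFP point, so the
    rotation itself leaves the LFP in place and the programmed translation
    alone carries the PTT signal.
    """
    if etr_amplitude_deg < 0 or ptt_amplitude_mm < 0:
        raise GeometryError("amplitudes must be >= 0")
    if noise_sd < 0:
        raise MaterialError("noise sd must be >= 0")
    if flexion_deg is None:
        flexion_deg = np.arange(0.0, 40.0 + 0.25, 0.5)
    flexion_deg = np.asarray(flexion_deg, dtype=float)
    rng = np.random.default_rng(seed)
    k = np.log(19.0) / 5.0
    s = _scaled_logistic(flexion_deg, transition_center_deg, k)

    etr = etr_amplitude_deg * s + (rng.normal(0.0, noise_sd, len(s))
                                   if noise_sd else 0.0)
    ptt = ptt_amplitude_mm * s + (rng.normal(0.0, noise_sd, len(s))
                                  if noise_sd else 0.0)
    lfp = np.asarray(lfp, dtype=float).reshape(3)

    # femoral internal rotation = -ETR about +z (ETR external positive)
    g = np.deg2rad(-etr)
    cz, sz = np.cos(g), np.sin(g)
    R = np.zeros((len(s), 3, 3))
    R[:, 0, 0], R[:, 0, 1] = cz, -sz
    R[:, 1, 0], R[:, 1, 1] = sz, cz
    R[:, 2, 2] = 1.0
    # rotate about the axis through the LFP, then translate posteriorly
    t = lfp - np.einsum("nij,j->ni", R, lfp)
    t[:, 1] -= ptt  # posterior = -y
    return KinematicsTrace(flexion_deg=flexion_deg, rotations=R,
                           translations=t)


def make_uniaxial_data(params: TIMRParams, n_points: int = 40,
                       noise_fraction: float = 0.0, seed: int = 0,
                       stretch_max: float = 1.10,
                       label: str = "synthetic") -> StressStrainData:
    """Uniaxial stress-strain data from known constitutive parameters with
    multiplicative Gaussian noise."""
    if n_points < 5:
        raise MaterialError("need at least 5 points")
    if noise_fraction < 0:
        raise MaterialError("noise fraction must be >= 0")
    lam = np.linspace(1.0, stretch_max, n_points)
    sig = np.asarray(uniaxial_cauchy_stress(params, lam))
    if noise_fraction:
        rng = np.random.default_rng(seed)
        sig = sig * (1.0 + noise_fraction * rng.standard_normal(n_points))
    return StressStrainData(lam, sig, label=label)


# published pretension summary: (ACLR N, LET N, ETR MAE deg, PTT MAE mm,
# peri-tunnel max von Mises MPa)
_TABLE1_COMBINED = [
    (80, 5, 0.659, 1.017, 21.734),
    (60, 5, 0.691, 1.128, 20.022),
    (70, 5, 0.701, 1.075, 21.083),
    (110, 5, 0.707, 0.772, 23.382),
    (90, 5, 0.717, 0.957, 22.334),
    (120, 5, 0.745, 0.782, 23.831),
    (100, 5, 0.763, 0.901, 22.892),
    (40, 5, 0.821, 1.257, 18.442),
    (90, 10, 0.826, 0.712, 21.493),
    (50, 5, 0.846, 1.258, 19.455),
]
_TABLE1_STANDALONE = [
    (120, None, 1.188, 0.781, 26.471),
    (110, None, 1.203, 0.876, 25.774),
    (100, None, 1.217, 0.973, 25.542),
    (90, None, 1.233, 1.067, 25.143),
    (80, None, 1.191, 1.156, 24.763),
    (70, None, 1.275, 1.299, 24.331),
    (60, None, 1.352, 1.436, 23.791),
    (50, None, 1.435, 1.575, 23.313),
    (40, None, 1.583, 1.742, 22.485),
]


def random_model_spec(seed: int):
    """A small randomized but valid model spec (deck round-trip fuzzing).

    Draws the surgical family, graft tensions, constitutive parameters,
    prestrain, joint axes, contact settings and spring bundles from a
    seeded generator; meshes are small random boxes carrying the node sets
    the chosen protocol references.
    """
    from .febio_io import (ContactPair, CylindricalJoint, FEModelSpec,
                           MeshDomain, RigidBody, SpringBundle)
    from .loading_protocols import build_protocol
    from .materials import GraftMaterial, PreStrainSpec, SpringCurve

    rng = np.random.default_rng(seed)
    surgery = ["native", "injured", "aclr", "aclr_let"][int(rng.integers(4))]
    aclr_t = float(rng.uniform(40, 120)) if surgery in ("aclr", "aclr_let") \
        else None
    let_t = float(rng.uniform(5, 60)) if surgery == "aclr_let" else None
    plan = build_protocol(surgery, aclr_tension=aclr_t, let_tension=let_t)

    spec = FEModelSpec(plan=plan)
    spec.rigid_bodies = [
        RigidBody("femur", center_of_mass=tuple(rng.normal(size=3) * 10)),
        RigidBody("tibia", center_of_mass=tuple(rng.normal(size=3) * 10))]
    for i in range(int(rng.integers(1, 4))):
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        spec.joints.append(CylindricalJoint(f"joint_{i}", "femur", "tibia",
                                            origin=tuple(rng.normal(size=3)
                                                         * 5),
                                            axis=tuple(ax)))

    n_dom = int(rng.integers(1, 3))
    for d in range(n_dom):
        size = rng.uniform(2.0, 5.0, size=3)
        mesh = box_tet_mesh(tuple(size), float(rng.uniform(1.0, 2.0)),
                            origin=tuple(rng.normal(size=3) * 10),
                            name=f"domain_{d}")
        n = len(mesh.nodes)
        mesh.node_sets["random_set"] = np.sort(rng.choice(
            n, size=min(4, n), replace=False))
        params = TIMRParams(c1=float(rng.uniform(0.5, 5)),
                            c2=float(rng.uniform(0, 2)),
                            c3=float(rng.uniform(0, 2)),
                            c4=float(rng.uniform(10, 80)),
                            c5=float(rng.uniform(50, 800)),
                            lambda_star=float(rng.uniform(1.02, 1.1)))
        prestrain = PreStrainSpec(float(rng.uniform(1.0, 1.05))) \
            if rng.random() < 0.5 else None
        spec.materials.append(GraftMaterial(f"material_{d}", params,
                                            prestrain=prestrain))
        spec.domains.append(MeshDomain(f"domain_{d}", mesh, f"material_{d}"))
        spec.surfaces[f"surface_{d}"] = (f"domain_{d}",
                                         mesh.boundary_faces())
    # wire the node sets the protocol references into the first domain
    first = spec.domains[0].mesh
    needed = []
    if surgery in ("aclr", "aclr_let"):
        needed += ["aclr_graft_free_end", "aclr_tunnel_fixation_nodes"]
    if surgery == "aclr_let":
        needed += ["let_graft_free_end", "let_tunnel_fixation_nodes"]
    for s in needed:
        first.node_sets[s] = np.sort(rng.choice(
            len(first.nodes), size=min(3, len(first.nodes)), replace=False))
    if n_dom == 2:
        spec.contacts.append(ContactPair(
            "contact_0", "surface_0", "surface_1",
            penalty=float(rng.uniform(10, 500)),
            tolerance=float(rng.uniform(0.001, 0.1)),
            augmented_lagrangian=bool(rng.random() < 0.5),
            search_tol=float(rng.uniform(0.001, 0.1))))
    if rng.random() < 0.5:
        k = int(rng.integers(1, 4))
        pairs = rng.integers(0, len(first.nodes), size=(k, 2))
        disp = np.sort(rng.uniform(0.5, 10.0, size=3))
        curve = SpringCurve(np.concatenate([[0.0], disp]),
                            np.concatenate([[0.0],
                                            np.sort(rng.uniform(1, 100,
                                                                size=3))]))
        spec.springs.append(SpringBundle("pcl_springs", "domain_0", pairs,
                                         curve))
    return spec


def table1_fixture():
    """The published pretension summary table.

    Returns ``(combined, standalone)`` results tables: the ten best
    (ACLR, LET) pretension pairs of the combined surgery and the nine
    standalone ACLR tensions, each with ETR MAE (deg), lateral-compartment
    PTT MAE (mm), and peri-tunnel max von Mises stress (MPa).
    """
    return (make_results_table(_TABLE1_COMBINED),
            make_results_table(_TABLE1_STANDALONE))
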