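"""Load curves and multi-step simulation protocols.

Covers the pivot-shift loading profile, graft-pretension direction via
quaternion SLERP over flexion-sampled femoral orientations, ramp tension
curves, and the per-surgery step sequences (native / injured knee, single
bundle ACL reconstruction, and ACL reconstruction combined with lateral
extra-articular tenodesis).

Pivot-shift sign conventions: the anterior-posterior femoral force is
negative posterior, positive anterior.  It sweeps from -amplitude to
+amplitude through a logistic centered at the sigmoid center (default 25
degrees of knee flexion); varus and internal torques rise from zero to their
amplitudes through the same logistic; the compression force is constant.
The logistic rate is chosen so the 5 % -> 95 % transition spans exactly the
configured flexion band (default 20-30 degrees, giving k = ln(19)/5 per
degree).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ProtocolError

__all__ = [
    "LoadCurve",
    "PSProfile",
    "PSLoads",
    "QuaternionSample",
    "Step",
    "StepLoad",
    "NodeFixation",
    "StepPlan",
    "TensionGrid",
    "ps_loads_at",
    "ps_load_curves",
    "slerp",
    "pretension_force",
    "build_protocol",
    "tension_grid",
]

DOFS = ("x", "y", "z", "Rx", "Ry", "Rz")  # x=medial-lateral, y=anterior-
# posterior, z=long axis; Rx is the flexion axis.


@dataclass
class LoadCurve:
    """Ordered (abscissa, value) controller curve.

    ``abscissa`` is either simulation pseudo-time ("time") or knee flexion
    angle in degrees ("flexion_deg"); interpolation is "linear" or "step".
    """

    points: np.ndarray
    abscissa: str = "time"
    interpolation: str = "linear"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 2:
            raise ProtocolError("load curve needs at least 2 points")
        if np.any(np.diff(self.points[:, 0]) <= 0):
            raise ProtocolError("load curve abscissae must be strictly increasing")
        if self.abscissa not in ("time", "flexion_deg"):
            raise ProtocolError(f"unknown abscissa semantic '{self.abscissa}'")
        if self.interpolation not in ("linear", "step"):
            raise ProtocolError(f"unknown interpolation '{self.interpolation}'")

    def value(self, x) -> np.ndarray | float:
        xs, ys = self.points[:, 0], self.points[:, 1]
        if self.interpolation == "linear":
            out = np.interp(x, xs, ys)
        else:
            idx = np.clip(np.searchsorted(xs, x, side="right") - 1, 0, len(ys) - 1)
            out = ys[idx]
        return out


class PSLoads(NamedTuple):
    ap_force: float        # N, posterior negative
    varus_torque: float    # N*m
    internal_torque: float  # N*m
    compression: float     # N


@dataclass
class PSProfile:
    """Pivot-shift loading profile parameters (defaults from the reduction
    style profile: 25 N AP force, 7 N*m varus, 5 N*m internal torque, 20 N
    compression, sigmoid transition across 20-30 degrees centered at 25)."""

    ap_amplitude: float = 25.0
    varus_amplitude: float = 7.0
    internal_amplitude: float = 5.0
    compression: float = 20.0
    subluxation_threshold: float = 10.0
    sigmoid_center: float = 25.0
    sigmoid_span: tuple = (20.0, 30.0)
    flexion_range: tuple = (0.0, 40.0)

    def __post_init__(self):
        lo, hi = self.sigmoid_span
        if not (lo < self.sigmoid_center < hi):
            raise ProtocolError("sigmoid center must lie strictly inside its span")
        for a in (self.ap_amplitude, self.varus_amplitude,
                  self.internal_amplitude, self.compression):
            if a < 0:
                raise ProtocolError("load amplitudes must be >= 0")

    @property
    def rate(self) -> float:
        """Logistic rate (per degree): 5 % -> 95 % across the span."""
        lo, hi = self.sigmoid_span
        return 2.0 * np.log(19.0) / (hi - lo)

    def logistic(self, flexion) -> np.ndarray | float:
        z = self.rate * (np.asarray(flexion, dtype=float) - self.sigmoid_center)
        return 1.0 / (1.0 + np.exp(-z))


def ps_loads_at(profile: PSProfile, flexion: float) -> PSLoads:
    """Pivot-shift loads at a flexion angle inside the profile's range."""
    lo, hi = profile.flexion_range
    if not (lo <= flexion <= hi):
        raise ProtocolError(
            f"flexion {flexion} deg outside profile range [{lo}, {hi}]")
    s = float(profile.logistic(flexion))
    return PSLoads(ap_force=profile.ap_amplitude * (2.0 * s - 1.0),
                   varus_torque=profile.varus_amplitude * s,
                   internal_torque=profile.internal_amplitude * s,
                   compression=profile.compression)


def ps_load_curves(profile: PSProfile, step_deg: float = 1.0) -> dict:
    """Sample the profile into flexion-indexed load curves for deck export."""
    lo, hi = profile.flexion_range
    ang = np.arange(lo, hi + 0.5 * step_deg, step_deg)
    s = profile.logistic(ang)
    return {
        "ps_ap_force": LoadCurve(np.column_stack([ang, profile.ap_amplitude * (2 * s - 1)]),
                                 abscissa="flexion_deg"),
        "ps_varus_torque": LoadCurve(np.column_stack([ang, profile.varus_amplitude * s]),
                                     abscissa="flexion_deg"),
        "ps_internal_torque": LoadCurve(np.column_stack([ang, profile.internal_amplitude * s]),
                                        abscissa="flexion_deg"),
        "ps_compression": LoadCurve(np.column_stack([ang, np.full_like(ang, profile.compression)]),
                                    abscissa="flexion_deg"),
    }


# ---------------------------------------------------------------------------
# quaternions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuaternionSample:
    """Femoral orientation relative to the tibia at a flexion angle.

    Quaternion in scalar-first (w, x, y, z) order, unit norm.
    """

    angle_deg: float
    quaternion: tuple

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float).reshape(4)
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ProtocolError("quaternion sample must be unit-norm")
        object.__setattr__(self, "quaternion", tuple(q))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.quaternion)


def slerp(q0, q1, t: float) -> np.ndarray:
    """Spherical linear interpolation between unit quaternions (w, x, y, z).

    Shortest-path: ``q1`` is negated when the dot product is negative
    (quaternion double cover).  Near-parallel inputs fall back to normalized
    linear interpolation.  The result is unit-norm.
    """
    q0 = np.asarray(q0, dtype=float).reshape(4)
    q1 = np.asarray(q1, dtype=float).reshape(4)
    n0, n1 = np.linalg.norm(q0), np.linalg.norm(q1)
    if n0 < 1e-12 or n1 < 1e-12:
        raise ProtocolError("cannot slerp a zero-norm quaternion")
    q0, q1 = q0 / n0, q1 / n1
    dot = float(q0 @ q1)
    if dot < 0.0:
        q1, dot = -q1, -dot
    if dot > 1.0 - 1e-12:
        out = (1.0 - t) * q0 + t * q1
        return out / np.linalg.norm(out)
    theta = np.arccos(np.clip(dot, -1.0, 1.0))
    s = np.sin(theta)
    out = (np.sin((1.0 - t) * theta) * q0 + np.sin(t * theta) * q1) / s
    return out / np.linalg.norm(out)


def _quat_to_matrix(q_wxyz: np.ndarray) -> np.ndarray:
    w, x, y, z = q_wxyz
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def pretension_force(samples, fixation_angle_deg: float, tunnel_axis,
                     magnitude: float) -> np.ndarray:
    """Graft pretension force vector at a fixation angle.

    The femoral orientation at the fixation angle is obtained by SLERP
    between the two flexion samples bracketing it; the resulting rotation is
    applied to the tunnel axis and the direction scaled by the force
    magnitude.  The output norm equals ``magnitude`` exactly.
    """
    axis = np.asarray(tunnel_axis, dtype=float).reshape(3)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ProtocolError("tunnel axis must be unit-norm")
    samples = sorted(samples, key=lambda s: s.angle_deg)
    angles = np.array([s.angle_deg for s in samples])
    if not (angles[0] <= fixation_angle_deg <= angles[-1]):
        raise ProtocolError(
            f"fixation angle {fixation_angle_deg} outside sampled range "
            f"[{angles[0]}, {angles[-1]}]")
    j = int(np.searchsorted(angles, fixation_angle_deg, side="right"))
    if fixation_angle_deg == angles[j - 1]:
        q = samples[j - 1].as_array()
    else:
        lo, hi = samples[j - 1], samples[j]
        t = (fixation_angle_deg - lo.angle_deg) / (hi.angle_deg - lo.angle_deg)
        q = slerp(lo.as_array(), hi.as_array(), t)
    if magnitude == 0.0:
        return np.zeros(3)
    d = _quat_to_matrix(q) @ axis
    return magnitude * d / np.linalg.norm(d)


# ---------------------------------------------------------------------------
# step plans
# ---------------------------------------------------------------------------


@dataclass
class StepLoad:
    """A load curve driving one DoF of a rigid body during a step."""

    body: str
    dof: str
    curve: str
    scale: float = 1.0


@dataclass
class NodeFixation:
    """Fix a graft node set to a rigid body from this step onward."""

    node_set: str
    rigid_body: str


@dataclass
class Step:
    name: str
    duration: float = 1.0
    rigid_dofs: dict = field(default_factory=dict)  # body -> dof -> state
    loads: list = field(default_factory=list)
    node_fixations: list = field(default_factory=list)

    def dof_state(self, body: str, dof: str):
        return self.rigid_dofs.get(body, {}).get(dof, "free")


@dataclass
class StepPlan:
    """Ordered simulation steps plus the load curves they reference."""

    steps: list
    curves: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.steps and self.steps[0].name != "prestrain":
            raise ProtocolError("the prestrain step must come first")
        names = {}
        for st in self.steps:
            for ld in st.loads:
                if ld.curve not in self.curves:
                    names.setdefault(st.name, []).append(ld.curve)
            for dd in st.rigid_dofs.values():
                for state in dd.values():
                    if (isinstance(state, tuple) and state[0] == "prescribed"
                            and state[1] not in self.curves):
                        names.setdefault(st.name, []).append(state[1])
        if names:
            raise ProtocolError(f"steps reference unknown load curves: {names}")

    def step_names(self):
        return [s.name for s in self.steps]

    def to_json(self, path):
        def enc(st):
            return {"name": st.name, "duration": st.duration,
                    "rigid_dofs": {b: {d: (list(s) if isinstance(s, tuple) else s)
                                       for d, s in dd.items()}
                                   for b, dd in st.rigid_dofs.items()},
                    "loads": [vars(l) for l in st.loads],
                    "node_fixations": [vars(f) for f in st.node_fixations]}

        d = {"steps": [enc(s) for s in self.steps],
             "curves": {k: {"points": c.points.tolist(), "abscissa": c.abscissa,
                            "interpolation": c.interpolation}
                        for k, c in self.curves.items()}}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        steps = []
        for sd in d["steps"]:
            steps.append(Step(
                name=sd["name"], duration=sd["duration"],
                rigid_dofs={b: {k: (tuple(v) if isinstance(v, list) else v)
                                for k, v in dd.items()}
                            for b, dd in sd["rigid_dofs"].items()},
                loads=[StepLoad(**l) for l in sd["loads"]],
                node_fixations=[NodeFixation(**f) for f in sd["node_fixations"]]))
        curves = {k: LoadCurve(np.asarray(c["points"]), abscissa=c["abscissa"],
                               interpolation=c["interpolation"])
                  for k, c in d["curves"].items()}
        return cls(steps=steps, curves=curves)


_FIX_ALL = {d: "fixed" for d in DOFS}


def _ramp(peak: float) -> LoadCurve:
    return LoadCurve([[0.0, 0.0], [1.0, peak]])


def build_protocol(surgery: str, aclr_tension: float | None = None,
                   let_tension: float | None = None,
                   aclr_fixation_deg: float = 25.0,
                   let_fixation_deg: float = 30.0,
                   profile: PSProfile | None = None) -> StepPlan:
    """Build the per-surgery simulation step sequence.

    native / injured: (1) ligament prestrain, (2) pivot shift -- 2 steps.
    aclr: prestrain, flexion to the graft fixation angle, graft pretension +
    fixation, return to full extension (0 degrees), pivot shift -- 5 steps.
    aclr_let: the LET flexion and fixation steps are inserted right after
    the ACLR fixation step (tenodesis is performed after the
    reconstruction) -- 7 steps.

    The tibia is fixed in all DoFs throughout.  During graft fixation steps
    the femur is fixed in the anterior-posterior and medial-lateral
    translations and the internal-external rotation, with flexion
    prescribed; during the pivot shift the femur is free and driven by the
    profile's load curves.
    """
    if surgery not in ("native", "injured", "aclr", "aclr_let"):
        raise ProtocolError(f"unknown surgery '{surgery}'")
    profile = profile or PSProfile()
    has_aclr = surgery in ("aclr", "aclr_let")
    has_let = surgery == "aclr_let"
    if let_tension is not None and not has_let:
        raise ProtocolError("LET tension given for a surgery without LET")
    if has_aclr and (aclr_tension is None or aclr_tension <= 0):
        raise ProtocolError("ACLR surgery requires a positive graft tension")
    if has_let and (let_tension is None or let_tension <= 0):
        raise ProtocolError("combined surgery requires a positive LET tension")
    for ang in ((aclr_fixation_deg,) if has_aclr else ()) + \
            ((let_fixation_deg,) if has_let else ()):
        if not (0.0 < ang < 90.0):
            raise ProtocolError("fixation angles must lie in (0, 90) degrees")

    curves = dict(ps_load_curves(profile))
    tibia = {"tibia": dict(_FIX_ALL)}

    def fixation_dofs(flexion_curve):
        return {**tibia,
                "femur": {"x": "fixed", "y": "fixed", "Rz": "fixed",
                          "Rx": ("prescribed", flexion_curve)}}

    steps = [Step("prestrain", rigid_dofs={**tibia, "femur": dict(_FIX_ALL)})]

    if has_aclr:
        curves["aclr_flexion_ramp"] = _ramp(np.deg2rad(aclr_fixation_deg))
        curves["aclr_tension_ramp"] = _ramp(aclr_tension)
        steps.append(Step("aclr_flexion",
                          rigid_dofs=fixation_dofs("aclr_flexion_ramp")))
        steps.append(Step(
            "aclr_fixation",
            rigid_dofs=fixation_dofs("aclr_flexion_ramp"),
            loads=[StepLoad("aclr_graft_free_end", "axial",
                            "aclr_tension_ramp")],
            node_fixations=[NodeFixation("aclr_tunnel_fixation_nodes",
                                         "tibia")]))
    if has_let:
        curves["let_flexion_ramp"] = _ramp(np.deg2rad(let_fixation_deg))
        curves["let_tension_ramp"] = _ramp(let_tension)
        steps.append(Step("let_flexion",
                          rigid_dofs=fixation_dofs("let_flexion_ramp")))
        steps.append(Step(
            "let_fixation",
            rigid_dofs=fixation_dofs("let_flexion_ramp"),
            loads=[StepLoad("let_graft_free_end", "axial", "let_tension_ramp")],
            node_fixations=[NodeFixation("let_tunnel_fixation_nodes",
                                         "femur")]))
    if has_aclr:
        curves["extension_ramp"] = LoadCurve([[0.0, 1.0], [1.0, 0.0]])
        steps.append(Step("extension",
                          rigid_dofs=fixation_dofs("extension_ramp")))

    steps.append(Step(
        "pivot_shift",
        rigid_dofs={**tibia, "femur": {d: "free" for d in DOFS}},
        loads=[StepLoad("femur", "y", "ps_ap_force"),
               StepLoad("femur", "Ry", "ps_varus_torque"),
               StepLoad("femur", "Rz", "ps_internal_torque"),
               StepLoad("femur", "z", "ps_compression", scale=-1.0)]))
    return StepPlan(steps=steps, curves=curves)


# ---------------------------------------------------------------------------
# tension grids
# ---------------------------------------------------------------------------


@dataclass
class TensionGrid:
    """Cartesian grid of (ACLR tension, LET tension) pairs, both in newtons,
    ACLR ascending in the outer loop, LET ascending in the inner loop."""

    aclr_values: np.ndarray
    let_values: np.ndarray

    def __post_init__(self):
        self.aclr_values = np.asarray(self.aclr_values, dtype=float)
        self.let_values = np.asarray(self.let_values, dtype=float)
        if np.any(self.aclr_values <= 0) or np.any(self.let_values <= 0):
            raise ProtocolError("all tensions must be positive")

    @property
    def pairs(self) -> np.ndarray:
        a, l = np.meshgrid(self.aclr_values, self.let_values, indexing="ij")
        return np.column_stack([a.ravel(), l.ravel()])

    def __len__(self):
        return len(self.aclr_values) * len(self.let_values)


def _axis_values(lo: float, hi: float, step: float, label: str) -> np.ndarray:
    if step <= 0 or hi < lo:
        raise ProtocolError(f"{label}: invalid range or step")
    n = (hi - lo) / step
    if abs(n - round(n)) > 1e-9:
        raise ProtocolError(f"{label}: step {step} does not divide [{lo}, {hi}]")
    return lo + step * np.arange(int(round(n)) + 1)


def tension_grid(aclr_center: float = 80.0, aclr_fraction: float = 0.5,
                 aclr_step: float = 10.0, let_min: float = 5.0,
                 let_max: float = 60.0, let_step: float = 5.0) -> TensionGrid:
    """Sensitivity-analysis grid of graft pretension pairs.

    Defaults: ACLR 80 N +/- 50 % in 10 N steps (40-120 N, 9 values) crossed
    with LET 5-60 N in 5 N steps (12 values) -> 108 pairs.  A finer 5 N ACLR
    step gives the 204-pair grid.
    """
    lo = aclr_center * (1.0 - aclr_fraction)
    hi = aclr_center * (1.0 + aclr_fraction)
    return TensionGrid(_axis_values(lo, hi, aclr_step, "aclr"),
                       _axis_values(let_min, let_max, let_step, "let"))
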