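"""FEBio model deck assembly, export, and solver-log ingestion.

:class:`FEModelSpec` collects everything a knee surgery simulation needs --
constitutive materials with optional in-situ prestrain, tetrahedral mesh
domains, rigid bones, the cylindrical-joint chain, sliding-elastic contact
pairs, spring bundles, and the multi-step loading protocol -- and
:func:`write_feb` serializes it as an FEBio spec-3.0 XML deck (mm-N-MPa
units).  :func:`parse_feb` inverts the writer on decks it produced, which
backs the round-trip validation suite.  Solver kinematics and element
stress logs are read from structured CSV text.

The writer validates referential integrity before touching the filesystem
and reports every violation at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

from .errors import FebParseError, FebValidationError
from .loading_protocols import (LoadCurve, NodeFixation, Step, StepLoad,
                                StepPlan)
from .materials import GraftMaterial, PreStrainSpec, SpringCurve, TIMRParams
from .mesh_geometry import LabeledTetMesh

__all__ = [
    "RigidBody",
    "MeshDomain",
    "CylindricalJoint",
    "ContactPair",
    "SpringBundle",
    "FEModelSpec",
    "RigidBodyKinematics",
    "ElementStressRecord",
    "write_feb",
    "parse_feb",
    "node_fixation_actions",
    "read_kinematics",
    "read_element_stresses",
    "specs_equal",
]

FEB_VERSION = "3.0"


@dataclass
class RigidBody:
    name: str
    center_of_mass: tuple = (0.0, 0.0, 0.0)
    density: float = 1e-6  # tonne/mm^3 scale irrelevant for quasi-statics


@dataclass
class MeshDomain:
    name: str
    mesh: LabeledTetMesh
    material: str


@dataclass
class CylindricalJoint:
    """One joint of the four-link tibiofemoral kinematic chain."""

    name: str
    body_a: str
    body_b: str
    origin: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (1.0, 0.0, 0.0)


@dataclass
class ContactPair:
    """Sliding-elastic contact between two named surfaces."""

    name: str
    primary: str
    secondary: str
    penalty: float = 100.0
    tolerance: float = 0.01
    augmented_lagrangian: bool = False
    search_tol: float = 0.01


@dataclass
class SpringBundle:
    """Nonlinear tension-only springs between node pairs of one domain."""

    name: str
    domain: str
    pairs: np.ndarray  # (k, 2) local node indices
    curve: SpringCurve

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)


@dataclass
class FEModelSpec:
    materials: list = field(default_factory=list)      # GraftMaterial
    rigid_bodies: list = field(default_factory=list)   # RigidBody
    domains: list = field(default_factory=list)        # MeshDomain
    surfaces: dict = field(default_factory=dict)       # name -> (domain, faces)
    joints: list = field(default_factory=list)         # CylindricalJoint
    contacts: list = field(default_factory=list)       # ContactPair
    springs: list = field(default_factory=list)        # SpringBundle
    plan: StepPlan | None = None
    extra_sections: list = field(default_factory=list)  # opaque parsed blocks

    # ------------------------------------------------------------------
    def material_names(self):
        return [m.name for m in self.materials]

    def rigid_names(self):
        return [r.name for r in self.rigid_bodies]

    def node_set_names(self):
        return {f"{d.name}::{s}" for d in self.domains for s in d.mesh.node_sets} | \
            {s for d in self.domains for s in d.mesh.node_sets}

    def validate(self):
        """Referential integrity; raises :class:`FebValidationError` listing
        every violation."""
        v = []
        mats = self.material_names()
        rigids = self.rigid_names()
        if len(set(mats)) != len(mats):
            v.append("duplicate material names")
        if len(set(rigids)) != len(rigids):
            v.append("duplicate rigid body names")
        dom_names = [d.name for d in self.domains]
        if len(set(dom_names)) != len(dom_names):
            v.append("duplicate domain names")
        for d in self.domains:
            if d.material not in mats:
                v.append(f"domain '{d.name}' bound to unknown material "
                         f"'{d.material}'")
        for sname, (dom, faces) in self.surfaces.items():
            if dom not in dom_names:
                v.append(f"surface '{sname}' references unknown domain '{dom}'")
        for c in self.contacts:
            for s in (c.primary, c.secondary):
                if s not in self.surfaces:
                    v.append(f"contact '{c.name}' references unknown surface "
                             f"'{s}'")
        for j in self.joints:
            for b in (j.body_a, j.body_b):
                if b not in rigids:
                    v.append(f"joint '{j.name}' references unknown rigid body "
                             f"'{b}'")
        for sp in self.springs:
            if sp.domain not in dom_names:
                v.append(f"spring bundle '{sp.name}' references unknown "
                         f"domain '{sp.domain}'")
        if self.plan is not None:
            node_sets = self.node_set_names()
            for st in self.plan.steps:
                for fx in st.node_fixations:
                    if fx.node_set not in node_sets:
                        v.append(f"step '{st.name}' fixes unknown node set "
                                 f"'{fx.node_set}'")
                    if fx.rigid_body not in rigids:
                        v.append(f"step '{st.name}' fixes nodes to unknown "
                                 f"rigid body '{fx.rigid_body}'")
                for ld in st.loads:
                    if ld.body not in rigids and ld.body not in node_sets:
                        v.append(f"step '{st.name}' loads unknown target "
                                 f"'{ld.body}'")
        if v:
            raise FebValidationError(v)


def node_fixation_actions(spec: FEModelSpec, node_set: str, rigid_body: str,
                          step: int | str) -> Step:
    """Register a graft-fixation action: from the given step onward the node
    set moves rigidly with ``rigid_body``.

    Returns the updated step.  The constraint is emitted as active in the
    fixation step and every later step, and absent from earlier steps.
    """
    if node_set not in spec.node_set_names():
        raise FebValidationError([f"unknown node set '{node_set}'"])
    if rigid_body not in spec.rigid_names():
        raise FebValidationError([f"unknown rigid body '{rigid_body}'"])
    if spec.plan is None:
        raise FebValidationError(["spec has no step plan"])
    if isinstance(step, str):
        idx = spec.plan.step_names().index(step)
    else:
        idx = step
    st = spec.plan.steps[idx]
    st.node_fixations.append(NodeFixation(node_set, rigid_body))
    return st


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_G = "%.17g"


def _fmt3(x):
    return ",".join(_G % v for v in np.asarray(x, dtype=float).reshape(-1))


def _sub(parent, tag, text=None, **attrs):
    e = etree.SubElement(parent, tag, {k: str(v) for k, v in attrs.items()})
    if text is not None:
        e.text = text if isinstance(text, str) else _G % text
    return e


def write_feb(spec: FEModelSpec, path) -> None:
    """Write the model as a solver-ready FEBio spec-3.0 XML deck.

    Node and element ids are 1-based and contiguous per domain (a single
    running counter across domains).  Prestrain element data is emitted for
    every domain bound to a material carrying a prestrain stretch different
    from 1 (a stretch of exactly 1 is the reference state and leaves the
    deck untouched).
    """
    spec.validate()
    root = etree.Element("febio_spec", version=FEB_VERSION)
    _sub(root, "Module", type="solid")
    glob = _sub(root, "Globals")
    const = _sub(glob, "Constants")
    for k in ("T", "R", "Fc"):
        _sub(const, k, "0")

    # materials -------------------------------------------------------
    mat_el = _sub(root, "Material")
    mat_ids = {}
    mid = 0
    for m in spec.materials:
        mid += 1
        mat_ids[m.name] = mid
        p: TIMRParams = m.params
        me = _sub(mat_el, "material", id=mid, name=m.name,
                  type="trans iso Mooney-Rivlin")
        for tag, val in (("c1", p.c1), ("c2", p.c2), ("c3", p.c3),
                         ("c4", p.c4), ("c5", p.c5),
                         ("lam_max", p.lambda_star), ("k", p.K)):
            _sub(me, tag, val)
        _sub(me, "fiber", _fmt3(m.fiber_axis), type="vector")
        if m.prestrain is not None and m.prestrain.stretch != 1.0:
            _sub(me, "prestrain_stretch", m.prestrain.stretch)
    for r in spec.rigid_bodies:
        mid += 1
        mat_ids[r.name] = mid
        me = _sub(mat_el, "material", id=mid, name=r.name, type="rigid body")
        _sub(me, "density", r.density)
        _sub(me, "center_of_mass", _fmt3(r.center_of_mass))

    # mesh ------------------------------------------------------------
    mesh_el = _sub(root, "Mesh")
    node_offset = {}
    elem_offset = {}
    nid = 0
    for d in spec.domains:
        node_offset[d.name] = nid
        nodes = _sub(mesh_el, "Nodes", name=f"{d.name}_nodes")
        for i, xyz in enumerate(d.mesh.nodes, start=1):
            _sub(nodes, "node", _fmt3(xyz), id=nid + i)
        nid += len(d.mesh.nodes)
    eid = 0
    for d in spec.domains:
        elem_offset[d.name] = eid
        els = _sub(mesh_el, "Elements", type="tet4", name=d.name)
        off = node_offset[d.name]
        for i, conn in enumerate(d.mesh.elements, start=1):
            _sub(els, "elem", ",".join(str(off + c + 1) for c in conn),
                 id=eid + i)
        eid += len(d.mesh.elements)
    for d in spec.domains:
        off = node_offset[d.name]
        for sname, idx in sorted(d.mesh.node_sets.items()):
            ns = _sub(mesh_el, "NodeSet", name=f"{d.name}::{sname}")
            for i in idx:
                _sub(ns, "n", id=off + int(i) + 1)
    for sname, (dom, faces) in spec.surfaces.items():
        off = node_offset[dom]
        surf = _sub(mesh_el, "Surface", name=sname, domain=dom)
        for i, f in enumerate(np.asarray(faces, dtype=int).reshape(-1, 3),
                              start=1):
            _sub(surf, "tri3", ",".join(str(off + c + 1) for c in f), id=i)
    for c in spec.contacts:
        sp = _sub(mesh_el, "SurfacePair", name=c.name)
        _sub(sp, "primary", c.primary)
        _sub(sp, "secondary", c.secondary)
    for s in spec.springs:
        off = node_offset[s.domain]
        ds = _sub(mesh_el, "DiscreteSet", name=s.name, domain=s.domain)
        for a, b in s.pairs:
            _sub(ds, "delem", f"{off + a + 1},{off + b + 1}")

    dom_el = _sub(root, "MeshDomains")
    for d in spec.domains:
        _sub(dom_el, "SolidDomain", name=d.name, mat=d.material)

    prestrained = [d for d in spec.domains
                   for m in spec.materials
                   if m.name == d.material and m.prestrain is not None
                   and m.prestrain.stretch != 1.0]
    if prestrained:
        md = _sub(root, "MeshData")
        for d in prestrained:
            m = next(m for m in spec.materials if m.name == d.material)
            ed = _sub(md, "ElementData", var="prestrain_stretch",
                      elem_set=d.name)
            for i in range(1, len(d.mesh.elements) + 1):
                _sub(ed, "e", m.prestrain.stretch, lid=i)

    if spec.joints:
        rig = _sub(root, "Rigid")
        for j in spec.joints:
            je = _sub(rig, "rigid_connector", name=j.name,
                      type="rigid cylindrical joint")
            _sub(je, "body_a", str(mat_ids[j.body_a]))
            _sub(je, "body_b", str(mat_ids[j.body_b]))
            _sub(je, "joint_origin", _fmt3(j.origin))
            _sub(je, "joint_axis", _fmt3(j.axis))

    if spec.contacts:
        ct = _sub(root, "Contact")
        for c in spec.contacts:
            ce = _sub(ct, "contact", type="sliding-elastic", name=c.name,
                      surface_pair=c.name)
            _sub(ce, "penalty", c.penalty)
            _sub(ce, "tolerance", c.tolerance)
            _sub(ce, "laugon", "1" if c.augmented_lagrangian else "0")
            _sub(ce, "search_tol", c.search_tol)

    if spec.springs:
        disc = _sub(root, "Discrete")
        for i, sp in enumerate(spec.springs, start=1):
            dm = _sub(disc, "discrete_material", id=i, name=f"{sp.name}_mat",
                      type="nonlinear spring")
            pts = _sub(dm, "points")
            for x, fval in zip(sp.curve.displacements, sp.curve.forces):
                _sub(pts, "point", f"{_G % x},{_G % fval}")
            _sub(disc, "discrete", discrete_set=sp.name, dmat=i)

    # load controllers ------------------------------------------------
    plan = spec.plan
    if plan is not None and plan.curves:
        ld = _sub(root, "LoadData")
        curve_ids = {}
        for i, (name, curve) in enumerate(sorted(plan.curves.items()),
                                          start=1):
            curve_ids[name] = i
            lc = _sub(ld, "load_controller", id=i, name=name,
                      type="loadcurve", abscissa=curve.abscissa)
            _sub(lc, "interpolate", curve.interpolation.upper())
            pts = _sub(lc, "points")
            for x, y in curve.points:
                _sub(pts, "point", f"{_G % x},{_G % y}")
    else:
        curve_ids = {}

    # steps -----------------------------------------------------------
    if plan is not None:
        node_sets_global = spec.node_set_names()
        steps_el = _sub(root, "Step")
        active_fix = []
        for si, st in enumerate(plan.steps, start=1):
            active_fix.extend(st.node_fixations)
            se = _sub(steps_el, "step", id=si, name=st.name)
            ctrl = _sub(se, "Control")
            _sub(ctrl, "analysis", "STATIC")
            _sub(ctrl, "time_steps", "10")
            _sub(ctrl, "step_size", st.duration / 10.0)
            rig = _sub(se, "Rigid")
            for body in sorted(st.rigid_dofs):
                fixed = [d for d, s_ in st.rigid_dofs[body].items()
                         if s_ == "fixed"]
                if fixed:
                    rc = _sub(rig, "rigid_constraint",
                              name=f"{st.name}_{body}_fix", type="fix")
                    _sub(rc, "rb", str(mat_ids[body]))
                    _sub(rc, "dofs", ",".join(sorted(fixed)))
                for dof, s_ in sorted(st.rigid_dofs[body].items()):
                    if isinstance(s_, tuple) and s_[0] == "prescribed":
                        rc = _sub(rig, "rigid_constraint",
                                  name=f"{st.name}_{body}_{dof}",
                                  type="prescribe")
                        _sub(rc, "rb", str(mat_ids[body]))
                        _sub(rc, "dof", dof)
                        _sub(rc, "value", "1", lc=curve_ids[s_[1]])
            loads_rigid = [l for l in st.loads if l.body in mat_ids]
            loads_nodal = [l for l in st.loads if l.body in node_sets_global
                           and l.body not in mat_ids]
            for l in loads_rigid:
                rc = _sub(rig, "rigid_constraint",
                          name=f"{st.name}_{l.body}_{l.dof}_load",
                          type="force")
                _sub(rc, "rb", str(mat_ids[l.body]))
                _sub(rc, "dof", l.dof)
                _sub(rc, "value", l.scale, lc=curve_ids[l.curve])
            if loads_nodal:
                le = _sub(se, "Loads")
                for l in loads_nodal:
                    nl = _sub(le, "nodal_load", name=f"{st.name}_{l.body}",
                              node_set=l.body, dof=l.dof)
                    _sub(nl, "scale", l.scale, lc=curve_ids[l.curve])
            if active_fix:
                cons = _sub(se, "Constraints")
                for fx in active_fix:
                    ce = _sub(cons, "constraint", type="node-rigid",
                              name=f"{fx.node_set}_to_{fx.rigid_body}",
                              node_set=fx.node_set)
                    _sub(ce, "rb", str(mat_ids[fx.rigid_body]))

    tree = etree.ElementTree(root)
    etree.indent(tree, space=" ")
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_KNOWN = {"Module", "Globals", "Material", "Mesh", "MeshDomains", "MeshData",
          "Rigid", "Contact", "Discrete", "LoadData", "Step"}


def _floats(text):
    return np.array([float(t) for t in text.replace(",", " ").split()])


def parse_feb(path) -> FEModelSpec:
    """Parse a deck produced by :func:`write_feb` back into a spec.

    Unknown top-level sections are preserved opaquely in
    ``spec.extra_sections`` with a warning.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FebParseError(f"malformed deck: {exc}") from exc
    root = tree.getroot()
    if root.tag != "febio_spec":
        raise FebParseError("not an FEBio deck")
    if root.get("version") != FEB_VERSION:
        raise FebParseError(
            f"unsupported spec version {root.get('version')!r}")

    spec = FEModelSpec()
    mat_by_id = {}

    for sec in root:
        if sec.tag not in _KNOWN:
            warnings.warn(f"preserving unknown deck section <{sec.tag}>")
            spec.extra_sections.append(etree.tostring(sec))

    mat_sec = root.find("Material")
    if mat_sec is not None:
        for me in mat_sec.findall("material"):
            mid = int(me.get("id"))
            name = me.get("name")
            if me.get("type") == "rigid body":
                rb = RigidBody(
                    name=name,
                    center_of_mass=tuple(_floats(me.findtext("center_of_mass"))),
                    density=float(me.findtext("density")))
                spec.rigid_bodies.append(rb)
            else:
                params = TIMRParams(
                    c1=float(me.findtext("c1")), c2=float(me.findtext("c2")),
                    c3=float(me.findtext("c3")), c4=float(me.findtext("c4")),
                    c5=float(me.findtext("c5")),
                    lambda_star=float(me.findtext("lam_max")),
                    K=float(me.findtext("k")))
                ps = me.findtext("prestrain_stretch")
                fib = me.find("fiber")
                spec.materials.append(GraftMaterial(
                    name=name, params=params,
                    prestrain=PreStrainSpec(float(ps)) if ps else None,
                    fiber_axis=tuple(_floats(fib.text))))
            mat_by_id[mid] = name

    # mesh ------------------------------------------------------------
    mesh_sec = root.find("Mesh")
    dom_sec = root.find("MeshDomains")
    dom_mats = {}
    if dom_sec is not None:
        for de in dom_sec.findall("SolidDomain"):
            dom_mats[de.get("name")] = de.get("mat")
    node_blocks = {}
    global_nodes = []
    if mesh_sec is not None:
        for ne in mesh_sec.findall("Nodes"):
            name = ne.get("name").removesuffix("_nodes")
            coords = np.array([_floats(n.text) for n in ne.findall("node")])
            node_blocks[name] = (len(global_nodes), len(coords))
            global_nodes.extend(coords)
        global_nodes = np.array(global_nodes) if global_nodes else \
            np.zeros((0, 3))
        meshes = {}
        for ee in mesh_sec.findall("Elements"):
            name = ee.get("name")
            off, cnt = node_blocks[name]
            conn = np.array([[int(t) for t in e.text.split(",")]
                             for e in ee.findall("elem")], dtype=int) - 1 - off
            meshes[name] = LabeledTetMesh(
                global_nodes[off:off + cnt], conn, name=name)
        for ns in mesh_sec.findall("NodeSet"):
            full = ns.get("name")
            dom, _, sname = full.partition("::")
            off, _cnt = node_blocks[dom]
            ids = np.array([int(n.get("id")) for n in ns.findall("n")],
                           dtype=int) - 1 - off
            meshes[dom].node_sets[sname] = ids
        for d_name, mesh in meshes.items():
            spec.domains.append(MeshDomain(name=d_name, mesh=mesh,
                                           material=dom_mats.get(d_name, "")))
        for se in mesh_sec.findall("Surface"):
            dom = se.get("domain")
            off, _cnt = node_blocks[dom]
            faces = np.array([[int(t) for t in f.text.split(",")]
                              for f in se.findall("tri3")], dtype=int) - 1 - off
            spec.surfaces[se.get("name")] = (dom, faces)
        discrete_sets = {}
        for ds in mesh_sec.findall("DiscreteSet"):
            dom = ds.get("domain")
            off, _cnt = node_blocks[dom]
            pairs = np.array([[int(t) for t in d.text.split(",")]
                              for d in ds.findall("delem")], dtype=int) - 1 - off
            discrete_sets[ds.get("name")] = (dom, pairs)

    # prestrain element data is redundant with the material record; the
    # parser checks consistency rather than storing it separately
    md = root.find("MeshData")
    if md is not None:
        for ed in md.findall("ElementData"):
            dname = ed.get("elem_set")
            mat = next((m for m in spec.materials
                        if m.name == dom_mats.get(dname)), None)
            vals = {float(e.text) for e in ed.findall("e")}
            if mat is None or mat.prestrain is None or \
                    vals != {mat.prestrain.stretch}:
                raise FebParseError(
                    f"inconsistent prestrain element data for '{dname}'")

    rig_sec = root.find("Rigid")
    if rig_sec is not None:
        for je in rig_sec.findall("rigid_connector"):
            spec.joints.append(CylindricalJoint(
                name=je.get("name"),
                body_a=mat_by_id[int(je.findtext("body_a"))],
                body_b=mat_by_id[int(je.findtext("body_b"))],
                origin=tuple(_floats(je.findtext("joint_origin"))),
                axis=tuple(_floats(je.findtext("joint_axis")))))

    ct = root.find("Contact")
    if ct is not None:
        for ce in ct.findall("contact"):
            pair = mesh_sec.xpath(f"SurfacePair[@name='{ce.get('name')}']")[0]
            spec.contacts.append(ContactPair(
                name=ce.get("name"),
                primary=pair.findtext("primary"),
                secondary=pair.findtext("secondary"),
                penalty=float(ce.findtext("penalty")),
                tolerance=float(ce.findtext("tolerance")),
                augmented_lagrangian=ce.findtext("laugon") == "1",
                search_tol=float(ce.findtext("search_tol"))))

    disc = root.find("Discrete")
    if disc is not None:
        dmats = {}
        for dm in disc.findall("discrete_material"):
            pts = np.array([[float(t) for t in p.text.split(",")]
                            for p in dm.find("points").findall("point")])
            dmats[dm.get("id")] = SpringCurve(pts[:, 0], pts[:, 1])
        for de in disc.findall("discrete"):
            sname = de.get("discrete_set")
            dom, pairs = discrete_sets[sname]
            spec.springs.append(SpringBundle(
                name=sname, domain=dom, pairs=pairs,
                curve=dmats[de.get("dmat")]))

    # load controllers + steps ---------------------------------------
    curves = {}
    ld = root.find("LoadData")
    if ld is not None:
        for lc in ld.findall("load_controller"):
            pts = np.array([[float(t) for t in p.text.split(",")]
                            for p in lc.find("points").findall("point")])
            curves[lc.get("name")] = LoadCurve(
                pts, abscissa=lc.get("abscissa", "time"),
                interpolation=lc.findtext("interpolate").lower())
    curve_by_id = {}
    if ld is not None:
        curve_by_id = {lc.get("id"): lc.get("name")
                       for lc in ld.findall("load_controller")}

    steps_sec = root.find("Step")
    if steps_sec is not None:
        steps = []
        seen_fix = set()
        node_set_local = {f"{d.name}::{s}" for d in spec.domains
                          for s in d.mesh.node_sets} | \
            {s for d in spec.domains for s in d.mesh.node_sets}
        for se in steps_sec.findall("step"):
            st = Step(name=se.get("name"),
                      duration=float(se.find("Control").findtext("step_size"))
                      * 10.0)
            rig = se.find("Rigid")
            if rig is not None:
                for rc in rig.findall("rigid_constraint"):
                    body = mat_by_id[int(rc.findtext("rb"))]
                    kind = rc.get("type")
                    dd = st.rigid_dofs.setdefault(body, {})
                    if kind == "fix":
                        for dof in rc.findtext("dofs").split(","):
                            dd[dof] = "fixed"
                    elif kind == "prescribe":
                        lc = rc.find("value").get("lc")
                        dd[rc.findtext("dof")] = ("prescribed",
                                                  curve_by_id[lc])
                    elif kind == "force":
                        ve = rc.find("value")
                        st.loads.append(StepLoad(
                            body=body, dof=rc.findtext("dof"),
                            curve=curve_by_id[ve.get("lc")],
                            scale=float(ve.text)))
            le = se.find("Loads")
            if le is not None:
                for nl in le.findall("nodal_load"):
                    sc = nl.find("scale")
                    st.loads.append(StepLoad(
                        body=nl.get("node_set"), dof=nl.get("dof"),
                        curve=curve_by_id[sc.get("lc")],
                        scale=float(sc.text)))
            cons = se.find("Constraints")
            if cons is not None:
                for ce in cons.findall("constraint"):
                    key = (ce.get("node_set"),
                           mat_by_id[int(ce.findtext("rb"))])
                    if key not in seen_fix:  # first appearance = activation
                        seen_fix.add(key)
                        st.node_fixations.append(NodeFixation(*key))
            steps.append(st)
        spec.plan = StepPlan(steps=steps, curves=curves)
        _ = node_set_local
    elif curves:
        spec.plan = StepPlan(steps=[], curves=curves)
    return spec


# ---------------------------------------------------------------------------
# equality (round-trip support)
# ---------------------------------------------------------------------------


def specs_equal(a: FEModelSpec, b: FEModelSpec, tol: float = 1e-9) -> bool:
    """Semantic equality of two model specs to a coordinate tolerance.

    Rigid DoF states are compared through their effective value (a DoF not
    mentioned is free), so a deck round trip that drops explicit "free"
    entries still compares equal.
    """
    def close(x, y):
        return np.allclose(np.asarray(x, float), np.asarray(y, float),
                           atol=tol, rtol=0)

    if sorted(a.material_names()) != sorted(b.material_names()):
        return False
    bm = {m.name: m for m in b.materials}
    for m in a.materials:
        o = bm[m.name]
        if not close(m.params.as_array(), o.params.as_array()):
            return False
        if not close(m.params.K, o.params.K):
            return False
        pa = m.prestrain.stretch if m.prestrain else 1.0
        pb = o.prestrain.stretch if o.prestrain else 1.0
        if not close(pa, pb) or not close(m.fiber_axis, o.fiber_axis):
            return False
    if sorted(a.rigid_names()) != sorted(b.rigid_names()):
        return False
    br = {r.name: r for r in b.rigid_bodies}
    for r in a.rigid_bodies:
        o = br[r.name]
        if not close(r.center_of_mass, o.center_of_mass) or \
                not close(r.density, o.density):
            return False
    if sorted(d.name for d in a.domains) != sorted(d.name for d in b.domains):
        return False
    bd = {d.name: d for d in b.domains}
    for d in a.domains:
        o = bd[d.name]
        if d.material != o.material or \
                not close(d.mesh.nodes, o.mesh.nodes) or \
                not np.array_equal(d.mesh.elements, o.mesh.elements):
            return False
        if sorted(d.mesh.node_sets) != sorted(o.mesh.node_sets):
            return False
        for s in d.mesh.node_sets:
            if not np.array_equal(np.sort(d.mesh.node_sets[s]),
                                  np.sort(o.mesh.node_sets[s])):
                return False
    if sorted(a.surfaces) != sorted(b.surfaces):
        return False
    for s in a.surfaces:
        da, fa = a.surfaces[s]
        db, fb = b.surfaces[s]
        if da != db or not np.array_equal(np.asarray(fa), np.asarray(fb)):
            return False
    if len(a.joints) != len(b.joints) or len(a.contacts) != len(b.contacts) \
            or len(a.springs) != len(b.springs):
        return False
    for ja, jb in zip(a.joints, b.joints):
        if ja.name != jb.name or {ja.body_a, ja.body_b} != \
                {jb.body_a, jb.body_b} or not close(ja.origin, jb.origin) \
                or not close(ja.axis, jb.axis):
            return False
    for ca, cb in zip(a.contacts, b.contacts):
        if (ca.name, ca.primary, ca.secondary,
                ca.augmented_lagrangian) != \
                (cb.name, cb.primary, cb.secondary, cb.augmented_lagrangian):
            return False
        if not close([ca.penalty, ca.tolerance, ca.search_tol],
                     [cb.penalty, cb.tolerance, cb.search_tol]):
            return False
    for sa, sb in zip(a.springs, b.springs):
        if sa.name != sb.name or sa.domain != sb.domain or \
                not np.array_equal(sa.pairs, sb.pairs) or \
                not close(sa.curve.displacements, sb.curve.displacements) or \
                not close(sa.curve.forces, sb.curve.forces):
            return False
    pa, pb = a.plan, b.plan
    if (pa is None) != (pb is None):
        return False
    if pa is not None:
        if sorted(pa.curves) != sorted(pb.curves):
            return False
        for cname in pa.curves:
            ca, cb = pa.curves[cname], pb.curves[cname]
            if ca.abscissa != cb.abscissa or \
                    ca.interpolation != cb.interpolation or \
                    not close(ca.points, cb.points):
                return False
        if len(pa.steps) != len(pb.steps):
            return False
        bodies = set(a.rigid_names()) | set(b.rigid_names())
        for sa, sb in zip(pa.steps, pb.steps):
            if sa.name != sb.name or not close(sa.duration, sb.duration):
                return False
            for body in bodies | set(sa.rigid_dofs) | set(sb.rigid_dofs):
                for dof in ("x", "y", "z", "Rx", "Ry", "Rz"):
                    if sa.dof_state(body, dof) != sb.dof_state(body, dof):
                        return False
            la = sorted((l.body, l.dof, l.curve, l.scale) for l in sa.loads)
            lb = sorted((l.body, l.dof, l.curve, l.scale) for l in sb.loads)
            if la != lb:
                return False
            fa = sorted((f.node_set, f.rigid_body)
                        for f in sa.node_fixations)
            fb = sorted((f.node_set, f.rigid_body)
                        for f in sb.node_fixations)
            if fa != fb:
                return False
    return True


# ---------------------------------------------------------------------------
# solver logs
# ---------------------------------------------------------------------------


@dataclass
class RigidBodyKinematics:
    """Per-output-step rigid-body poses from a solver kinematics log."""

    times: np.ndarray
    bodies: np.ndarray
    positions: np.ndarray    # (n, 3) mm
    quaternions: np.ndarray  # (n, 4) scalar-first, unit

    def for_body(self, body):
        m = self.bodies == body
        return RigidBodyKinematics(self.times[m], self.bodies[m],
                                   self.positions[m], self.quaternions[m])


@dataclass(frozen=True)
class ElementStressRecord:
    element_id: int
    centroid: tuple
    von_mises: float  # MPa
    step: int


def read_kinematics(path) -> RigidBodyKinematics:
    """Read a kinematics CSV log: time, body, x, y, z, qw, qx, qy, qz.

    Quaternions drifting from unit norm by less than 1e-6 are renormalized
    silently; larger drift is an error, as are decreasing times (per body).
    """
    df = pd.read_csv(path)
    required = ["time", "body", "x", "y", "z", "qw", "qx", "qy", "qz"]
    if list(df.columns[:9]) != required:
        raise FebParseError(
            f"kinematics log must have columns {required}")
    quats = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(quats, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(norms - 1.0)))
        raise FebParseError(
            f"quaternion at record {bad} drifts from unit norm by "
            f"{abs(norms[bad] - 1.0):.2e}")
    quats = quats / norms[:, None]
    for body, grp in df.groupby("body"):
        if np.any(np.diff(grp["time"].to_numpy(dtype=float)) < 0):
            raise FebParseError(f"times decrease for body {body!r}")
    return RigidBodyKinematics(
        times=df["time"].to_numpy(dtype=float),
        bodies=df["body"].to_numpy(),
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        quaternions=quats)


def read_element_stresses(path, element_set) -> list[ElementStressRecord]:
    """Read an element stress CSV log (step, element, cx, cy, cz, von_mises)
    restricted to the given element ids, grouped by step and ordered."""
    ids = set(int(i) for i in element_set)
    if not ids:
        raise FebParseError("empty element set")
    df = pd.read_csv(path)
    required = ["step", "element", "cx", "cy", "cz", "von_mises"]
    if list(df.columns[:6]) != required:
        raise FebParseError(f"stress log must have columns {required}")
    if np.any(df["von_mises"].to_numpy(dtype=float) < 0):
        raise FebParseError("negative von Mises stress in log")
    known = set(df["element"].astype(int))
    missing = ids - known
    if missing == ids:
        raise FebParseError(
            f"element set not present in log (ids {sorted(ids)[:5]}...)")
    df = df[df["element"].astype(int).isin(ids)]
    df = df.sort_values(["step", "element"], kind="stable")
    return [ElementStressRecord(element_id=int(r.element),
                                centroid=(r.cx, r.cy, r.cz),
                                von_mises=float(r.von_mises),
                                step=int(r.step))
            for r in df.itertuples()]
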