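"""Synthetic parametric intervertebral-disc meshes, fiber frames and mesh I/O.

The disc planform is a superellipse |x/a|^p + |y/b|^p = 1 (x lateral,
y anterior-posterior, z cranial-caudal) extruded between two endplates.
Unequal anterior/posterior heights produce wedging, a skew offset shears the
cranial endplate against the caudal one, and the outer wall carries a gentle
parabolic outward bulge.  The nucleus pulposus occupies a central, similar
superellipse whose area is a configurable fraction of the planform.
Degeneration presets (none / moderate / severe) map to reduced heights plus
increasing wedge and skew, emulating the narrowed and skewed geometries of
degenerated discs.

Meshing strategy: the planform is covered by a 2D Delaunay triangulation of
perimeter-graded concentric rings (with a small seeded jitter on interior
points), then extruded layer by layer through the wedge/skew/bulge mapping;
each triangular prism is split into three tetrahedra with the min-vertex-
index diagonal rule, which is conforming across shared faces and produces
no slivers.  Per-element collagen fiber pairs at +/-phi are aligned with the
local circumferential tangent; the characteristic length used by the
explicit time step is the minimum tet altitude l_c = 3 V / A_max.

Mesh I/O supports Gmsh MSH 4.1 (ASCII) and legacy VTK, with region labels
and fiber vectors carried as cell data.  Internal coordinates are meters;
files are written in millimeters (the convention of both formats in this
domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay
from scipy.special import gamma as _gamma

from .constitutive import FiberPair
from .errors import MeshingError, UnsupportedElementError

__all__ = [
    "SegmentSpec",
    "TetMesh",
    "FiberFrame",
    "generate_segment",
    "assign_fiber_frames",
    "characteristic_length",
    "read_mesh",
    "write_mesh",
]

MM = 1.0e-3  # mm -> m

AF, NP_REGION = 0, 1
_REGION_NAMES = {AF: "AF", NP_REGION: "NP"}


# --------------------------------------------------------------------------
# specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """Parametric description of a synthetic disc segment (lengths in mm)."""

    lateral_radius: float = 26.0
    ap_radius: float = 18.0
    anterior_height: float = 12.0
    posterior_height: float = 9.0
    skew: float = 0.0
    nucleus_fraction: float = 0.40
    nucleus_offset: float = 0.0
    element_size: float = 1.4
    exponent: float = 2.5
    bulge: float = 0.05
    fiber_angle_deg: float = 30.0

    def __post_init__(self):
        for name in ("lateral_radius", "ap_radius", "anterior_height",
                     "posterior_height", "element_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.nucleus_fraction < 0.8:
            raise ValueError("nucleus_fraction must lie in (0, 0.8)")
        if self.exponent < 1.5:
            raise ValueError("superellipse exponent below 1.5 loses convexity")

    @classmethod
    def preset(cls, name: str, element_size: float = 1.4) -> "SegmentSpec":
        """Degeneration presets: height loss plus wedge/skew growth."""
        table = {
            "none": dict(anterior_height=12.0, posterior_height=9.0, skew=0.0),
            "moderate": dict(anterior_height=9.0, posterior_height=6.0, skew=1.5),
            "severe": dict(anterior_height=6.0, posterior_height=3.2, skew=3.0),
        }
        if name not in table:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(table)}")
        return cls(element_size=element_size, **table[name])

    @property
    def mean_height(self) -> float:
        return 0.5 * (self.anterior_height + self.posterior_height)

    @property
    def min_height(self) -> float:
        return min(self.anterior_height, self.posterior_height)

    def planform_area(self) -> float:
        """Superellipse area 4ab Gamma(1+1/p)^2 / Gamma(1+2/p), mm^2."""
        p = self.exponent
        return (4.0 * self.lateral_radius * self.ap_radius
                * _gamma(1.0 + 1.0 / p) ** 2 / _gamma(1.0 + 2.0 / p))

    def analytic_volume(self) -> float:
        """Exact solid volume in mm^3.

        The wedge term integrates to zero over the symmetric planform and the
        skew shear is volume-preserving, leaving the barrel-bulge quadrature
        V = A * h_mean * (1 + 4 beta/3 + 8 beta^2/15).
        """
        beta = self.bulge
        return self.planform_area() * self.mean_height * (
            1.0 + 4.0 * beta / 3.0 + 8.0 * beta**2 / 15.0
        )


# --------------------------------------------------------------------------
# mesh container
# --------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Linear tetrahedral mesh of a disc (coordinates in meters).

    region is 0 for annulus (AF), 1 for nucleus (NP).  AF elements carry the
    unit reference fiber pair (M1, M2) and the local frame (e1 circumferential
    tangent, e2 local axial, e3 outward radial); NP rows are NaN.
    """

    nodes: np.ndarray          # (n, 3) m
    tets: np.ndarray           # (m, 4) int, 0-based, positive volume
    region: np.ndarray         # (m,) int8
    cranial_nodes: np.ndarray  # node indices tied to the upper vertebra
    caudal_nodes: np.ndarray   # node indices tied to the lower vertebra
    M1: np.ndarray = None      # (m, 3)
    M2: np.ndarray = None
    lc: np.ndarray = None      # (m,) m
    frame_e1: np.ndarray = None
    frame_e2: np.ndarray = None
    frame_e3: np.ndarray = None
    basis: np.ndarray = field(default_factory=lambda: np.eye(3))
    spec: SegmentSpec | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    @property
    def af_mask(self) -> np.ndarray:
        return self.region == AF

    @property
    def np_mask(self) -> np.ndarray:
        return self.region == NP_REGION

    def volumes(self) -> np.ndarray:
        """Signed tet volumes (m^3); positive for a valid mesh."""
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d) / 6.0

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def fiber_pairs(self) -> FiberPair:
        """FiberPair view over the AF elements."""
        m = self.af_mask
        return FiberPair(M1=self.M1[m], M2=self.M2[m])


@dataclass
class FiberFrame:
    """Local orthonormal basis of an AF element and the rotation to it.

    e1: circumferential tangent, e2: local axial, e3: outward radial.
    """

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """Q_R with columns (e1, e2, e3): maps local to global components."""
        return np.stack([self.e1, self.e2, self.e3], axis=-1)

    @property
    def euler_angles(self) -> np.ndarray:
        """Intrinsic z-x-z Euler angles of Q_R, radians."""
        from scipy.spatial.transform import Rotation

        return Rotation.from_matrix(self.rotation).as_euler("ZXZ")


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _superellipse_boundary(psi, a, b, p):
    c, s = np.cos(psi), np.sin(psi)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / p)
    y = b * np.sign(s) * np.abs(s) ** (2.0 / p)
    return x, y


def _superellipse_perimeter(a, b, p, n=2048):
    psi = np.linspace(0, 2 * np.pi, n, endpoint=True)
    x, y = _superellipse_boundary(psi, a, b, p)
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def _height_at(y_plan, spec: SegmentSpec):
    """Wedged height field, linear in the AP coordinate of the planform."""
    hm = spec.mean_height
    dh = spec.anterior_height - spec.posterior_height
    return hm + 0.5 * dh * (y_plan / spec.ap_radius)


def _bulge_scale(z_frac, beta):
    return 1.0 + 4.0 * beta * z_frac * (1.0 - z_frac)


def generate_segment(spec: SegmentSpec, seed: int = 0) -> TetMesh:
    """Generate a tetrahedral mesh of the parametric disc.

    Deterministic for a fixed (spec, seed): the seed drives only the small
    interior-node jitter that breaks the structured lattice's degeneracies.
    Raises :class:`MeshingError` when the element size exceeds the smallest
    disc dimension (thin severe-preset geometries).
    """
    size = spec.element_size
    if size > spec.min_height:
        raise MeshingError(
            f"element size {size} mm exceeds the minimum disc height "
            f"{spec.min_height} mm; refine the mesh or thicken the disc"
        )
    a, b, p = spec.lateral_radius, spec.ap_radius, spec.exponent
    n_rings = max(3, int(round(np.sqrt(a * b) / size)))
    n_theta = max(12, int(round(_superellipse_perimeter(a, b, p) / size)))
    n_layers = max(2, int(round(spec.mean_height / size)))

    rng = np.random.default_rng(seed)

    # planform point cloud: axis node plus perimeter-graded concentric rings
    plan = [(0.0, 0.0)]
    boundary_ring = []
    for i in range(1, n_rings + 1):
        s = i / n_rings
        n_i = max(6, int(round(n_theta * s)))
        psi = 2.0 * np.pi * (np.arange(n_i) + 0.5 * (i % 2)) / n_i
        bx, by = _superellipse_boundary(psi, a, b, p)
        base = len(plan)
        plan.extend(zip(s * bx, s * by))
        if i == n_rings:
            boundary_ring = list(range(base, base + n_i))
    plan = np.asarray(plan)
    n_plan = len(plan)
    inner = np.ones(n_plan, dtype=bool)
    inner[boundary_ring] = False
    # small seeded in-plane jitter on interior planform points breaks the
    # lattice symmetry; the same planform is reused for every layer so the
    # extruded prism columns stay vertical
    plan[inner] += (0.10 * size) * rng.uniform(-1.0, 1.0, size=(int(inner.sum()), 2))

    tri2d = Delaunay(plan)
    tris = np.asarray(tri2d.simplices, dtype=np.int64)
    # orient counterclockwise
    e1 = plan[tris[:, 1]] - plan[tris[:, 0]]
    e2 = plan[tris[:, 2]] - plan[tris[:, 0]]
    area2 = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    flip = area2 < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    # extrude the planform through the wedge/skew/bulge mapping
    pts = np.empty(((n_layers + 1) * n_plan, 3))
    for k in range(n_layers + 1):
        zf = k / n_layers
        rho = _bulge_scale(zf, spec.bulge)
        h = _height_at(plan[:, 1], spec)
        sl = slice(k * n_plan, (k + 1) * n_plan)
        pts[sl, 0] = rho * plan[:, 0]
        pts[sl, 1] = rho * plan[:, 1] + spec.skew * (zf - 0.5)
        pts[sl, 2] = (zf - 0.5) * h
    caudal = np.arange(n_plan)
    cranial = np.arange(n_layers * n_plan, (n_layers + 1) * n_plan)

    # each triangle x layer prism splits into 3 tets; diagonals follow the
    # global min-vertex rule, which is conforming across shared quad faces
    tets = []
    tri_of_tet = []
    for k in range(n_layers):
        lo, hi = k * n_plan, (k + 1) * n_plan
        for it, (ta, tb, tc) in enumerate(tris):
            bot = (lo + ta, lo + tb, lo + tc)
            top = (hi + ta, hi + tb, hi + tc)
            v = bot + top
            r = int(np.argmin(bot))  # smallest planform index leads
            i0, i1, i2 = r, (r + 1) % 3, (r + 2) % 3
            v0, v1, v2 = v[i0], v[i1], v[i2]
            v3, v4, v5 = v[i0 + 3], v[i1 + 3], v[i2 + 3]
            if min(v1, v5) < min(v2, v4):
                new = [(v0, v1, v2, v5), (v0, v1, v5, v4), (v0, v4, v5, v3)]
            else:
                new = [(v0, v1, v2, v4), (v0, v4, v2, v5), (v0, v4, v5, v3)]
            tets.extend(new)
            tri_of_tet.extend([it] * 3)
    tets = np.asarray(tets, dtype=np.int64)
    tri_of_tet = np.asarray(tri_of_tet)
    d = pts[tets[:, 1:]] - pts[tets[:, :1]]
    vol = np.linalg.det(d) / 6.0
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    vol = np.abs(vol)
    if np.any(vol <= 0):
        raise MeshingError("degenerate prism decomposition (zero-volume tet)")

    # region label per planform triangle: columns are uniformly AF or NP
    tri_cen = plan[tris].mean(axis=1)
    s_np = np.sqrt(spec.nucleus_fraction)  # area fraction -> radius fraction
    s_tri = (np.abs(tri_cen[:, 0] / a) ** p
             + np.abs((tri_cen[:, 1] - spec.nucleus_offset) / b) ** p) ** (1.0 / p)
    region = np.where(s_tri[tri_of_tet] < s_np, NP_REGION, AF)
    # region-major element ordering (AF block then NP block) keeps the
    # on-disk Gmsh entity blocks aligned with the in-memory order
    order = np.argsort(region, kind="stable")
    tets, region = tets[order], region[order]

    mesh = TetMesh(
        nodes=pts * MM,
        tets=tets,
        region=region.astype(np.int8),
        cranial_nodes=np.asarray(cranial, dtype=np.int64),
        caudal_nodes=np.asarray(caudal, dtype=np.int64),
        spec=spec,
    )
    if mesh.n_elements == 0 or not np.any(mesh.af_mask) or not np.any(mesh.np_mask):
        raise MeshingError("generated mesh does not contain both AF and NP regions")
    assign_fiber_frames(mesh, phi_deg=spec.fiber_angle_deg)
    mesh.lc = characteristic_length(mesh)
    return mesh


def assign_fiber_frames(mesh: TetMesh, phi_deg: float = 30.0,
                        spec: SegmentSpec | None = None) -> TetMesh:
    """Attach +/-phi fiber pairs and local frames to every AF element.

    The circumferential tangent e1 at each element centroid is taken along
    the level superellipse through that point (gradient of the planform
    implicit function gives the outward radial e3; e1 = e_z x e3; e2 = e_z).
    Fibers follow M1,2 = cos(phi) e1 +/- sin(phi) e2, i.e. they lie in the
    (e1, e2) plane at +/-phi about the transverse plane span(e1, e3).
    """
    spec = spec or mesh.spec
    cen = mesh.centroids() / MM  # mm
    if spec is None:
        a = float(np.max(np.abs(mesh.nodes[:, 0]))) / MM
        b = float(np.max(np.abs(mesh.nodes[:, 1]))) / MM
        p = 2.0
    else:
        a, b, p = spec.lateral_radius, spec.ap_radius, spec.exponent

    x, y = cen[:, 0], cen[:, 1]
    r_inplane = np.hypot(x / a, y / b)
    af = mesh.af_mask
    if np.any(r_inplane[af] < 1e-9):
        raise MeshingError("AF element centroid lies on the disc axis; "
                           "circumferential tangent undefined")
    # gradient of (|x/a|^p + |y/b|^p): outward in-plane normal
    gx = p * np.sign(x) * np.abs(x / a) ** (p - 1.0) / a
    gy = p * np.sign(y) * np.abs(y / b) ** (p - 1.0) / b
    g = np.stack([gx, gy, np.zeros_like(gx)], axis=1)
    nrm = np.linalg.norm(g, axis=1)
    nrm[nrm < 1e-30] = 1.0
    e3 = g / nrm[:, None]
    ez = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(np.broadcast_to(ez, e3.shape), e3)
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(e3, e1)

    phi = np.deg2rad(phi_deg)
    M1 = np.cos(phi) * e1 + np.sin(phi) * e2
    M2 = np.cos(phi) * e1 - np.sin(phi) * e2

    m = mesh.n_elements
    mesh.M1 = np.full((m, 3), np.nan)
    mesh.M2 = np.full((m, 3), np.nan)
    mesh.frame_e1 = np.full((m, 3), np.nan)
    mesh.frame_e2 = np.full((m, 3), np.nan)
    mesh.frame_e3 = np.full((m, 3), np.nan)
    mesh.M1[af] = M1[af]
    mesh.M2[af] = M2[af]
    mesh.frame_e1[af] = e1[af]
    mesh.frame_e2[af] = e2[af]
    mesh.frame_e3[af] = e3[af]
    return mesh


def characteristic_length(mesh: TetMesh) -> np.ndarray:
    """Minimum-altitude characteristic length l_c = 3 V / A_max per element."""
    return tet_min_altitude(mesh.nodes, mesh.tets)


def tet_min_altitude(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    x = nodes[tets]
    d = x[:, 1:] - x[:, :1]
    vol = np.linalg.det(d) / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise MeshingError(f"degenerate element {bad}: volume {vol[bad]}")
    faces = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    areas = np.stack([
        0.5 * np.linalg.norm(
            np.cross(x[:, f[1]] - x[:, f[0]], x[:, f[2]] - x[:, f[0]]), axis=1)
        for f in faces
    ], axis=1)
    return 3.0 * vol / areas.max(axis=1)


# --------------------------------------------------------------------------
# mesh I/O
# --------------------------------------------------------------------------

def write_mesh(mesh: TetMesh, path) -> None:
    """Write a mesh to Gmsh MSH 4.1 (.msh) or legacy VTK (.vtk), in mm."""
    path = Path(path)
    if path.suffix == ".msh":
        _write_msh(mesh, path)
    elif path.suffix == ".vtk":
        _write_vtk(mesh, path)
    else:
        raise MeshingError(f"unsupported mesh format {path.suffix!r}")


def read_mesh(path) -> TetMesh:
    """Read a mesh written by :func:`write_mesh` (coordinates in mm on disk)."""
    path = Path(path)
    if path.suffix == ".msh":
        return _read_msh(path)
    if path.suffix == ".vtk":
        return _read_vtk(path)
    raise MeshingError(f"unsupported mesh format {path.suffix!r}")


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def _interface_labels(mesh: TetMesh) -> np.ndarray:
    lab = np.zeros(mesh.n_nodes, dtype=np.int64)
    lab[mesh.caudal_nodes] = 1
    lab[mesh.cranial_nodes] = 2
    return lab


def _cell_data_arrays(mesh: TetMesh):
    m = mesh.n_elements
    M1 = mesh.M1 if mesh.M1 is not None else np.full((m, 3), np.nan)
    M2 = mesh.M2 if mesh.M2 is not None else np.full((m, 3), np.nan)
    lc = mesh.lc if mesh.lc is not None else np.zeros(m)
    return M1, M2, lc / MM


def _write_msh(mesh: TetMesh, path: Path) -> None:
    nodes_mm = mesh.nodes / MM
    lab = _interface_labels(mesh)
    M1, M2, lc_mm = _cell_data_arrays(mesh)
    n, m = mesh.n_nodes, mesh.n_elements
    blocks = [(tag + 1, np.flatnonzero(mesh.region == tag)) for tag in (AF, NP_REGION)]
    blocks = [(t, idx) for t, idx in blocks if len(idx)]

    out = []
    out.append("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
    out.append("$PhysicalNames\n2\n")
    out.append('3 1 "AF"\n3 2 "NP"\n')
    out.append("$EndPhysicalNames\n")
    # two discrete volume entities carrying the physical region tags
    out.append("$Entities\n0 0 0 2\n")
    lo = nodes_mm.min(axis=0)
    hi = nodes_mm.max(axis=0)
    for tag in (1, 2):
        out.append(
            f"{tag} {_fmt(lo[0])} {_fmt(lo[1])} {_fmt(lo[2])} "
            f"{_fmt(hi[0])} {_fmt(hi[1])} {_fmt(hi[2])} 1 {tag} 0\n"
        )
    out.append("$EndEntities\n")
    out.append(f"$Nodes\n1 {n} 1 {n}\n")
    out.append(f"3 1 0 {n}\n")
    out.extend(f"{i + 1}\n" for i in range(n))
    out.extend(f"{_fmt(x)} {_fmt(y)} {_fmt(z)}\n" for x, y, z in nodes_mm)
    out.append("$EndNodes\n")
    out.append(f"$Elements\n{len(blocks)} {m} 1 {m}\n")
    eid = 1
    for tag, idx in blocks:
        out.append(f"3 {tag} 4 {len(idx)}\n")
        for e in idx:
            a_, b_, c_, d_ = mesh.tets[e] + 1
            out.append(f"{eid} {a_} {b_} {c_} {d_}\n")
            eid += 1
    out.append("$EndElements\n")

    def element_data(name, arr, ncomp):
        out.append("$ElementData\n1\n")
        out.append(f'"{name}"\n0\n3\n0\n{ncomp}\n{m}\n')
        eid = 1
        for _, idx in blocks:
            for e in idx:
                if ncomp == 1:
                    out.append(f"{eid} {_fmt(arr[e])}\n")
                else:
                    out.append(f"{eid} " + " ".join(_fmt(v) for v in arr[e]) + "\n")
                eid += 1
        out.append("$EndElementData\n")

    element_data("M1", M1, 3)
    element_data("M2", M2, 3)
    element_data("lc", lc_mm, 1)
    out.append("$NodeData\n1\n")
    out.append(f'"interface"\n0\n3\n0\n1\n{n}\n')
    out.extend(f"{i + 1} {lab[i]}\n" for i in range(n))
    out.append("$EndNodeData\n")
    path.write_text("".join(out))


def _read_msh(path: Path) -> TetMesh:
    lines = path.read_text().splitlines()
    i = 0

    def until(tag):
        nonlocal i
        while i < len(lines) and lines[i].strip() != tag:
            i += 1
        if i == len(lines):
            raise MeshingError(f"malformed MSH file: missing {tag}")
        i += 1

    until("$MeshFormat")
    version = lines[i].split()[0]
    if not version.startswith("4"):
        raise MeshingError(f"unsupported MSH version {version}")

    until("$Nodes")
    nblocks, n_total = (int(v) for v in lines[i].split()[:2])
    i += 1
    coords = np.empty((n_total, 3))
    ids = np.empty(n_total, dtype=np.int64)
    pos = 0
    for _ in range(nblocks):
        nb = int(lines[i].split()[3])
        i += 1
        for j in range(nb):
            ids[pos + j] = int(lines[i + j])
        i += nb
        for j in range(nb):
            coords[pos + j] = [float(v) for v in lines[i + j].split()[:3]]
        i += nb
        pos += nb
    order = np.argsort(ids)
    coords = coords[order]
    id_to_row = {int(ids[o]) + 0: r for r, o in enumerate(order)}

    until("$Elements")
    eblocks, m_total = (int(v) for v in lines[i].split()[:2])
    i += 1
    tets = np.empty((m_total, 4), dtype=np.int64)
    region = np.empty(m_total, dtype=np.int8)
    pos = 0
    for _ in range(eblocks):
        dim, etag, etype, ne = (int(v) for v in lines[i].split())
        i += 1
        if etype != 4:
            raise UnsupportedElementError(
                f"MSH element type {etype} is not a linear tetrahedron"
            )
        for j in range(ne):
            parts = lines[i + j].split()
            tets[pos + j] = [id_to_row[int(v)] for v in parts[1:5]]
            region[pos + j] = etag - 1
        i += ne
        pos += ne

    m = m_total
    M1 = np.full((m, 3), np.nan)
    M2 = np.full((m, 3), np.nan)
    lc_mm = np.zeros(m)
    lab = np.zeros(n_total, dtype=np.int64)
    while True:
        found = None
        for tag in ("$ElementData", "$NodeData"):
            j = i
            while j < len(lines) and lines[j].strip() != tag:
                j += 1
            if j < len(lines) and (found is None or j < found[1]):
                found = (tag, j)
        if found is None:
            break
        tag, i = found
        i += 1
        i += 1  # numStringTags (=1)
        name = lines[i].strip().strip('"')
        i += 1
        i += int(lines[i]) + 1  # real tags
        nint = int(lines[i])
        i += 1
        ncomp = int(lines[i + 1])
        count = int(lines[i + 2])
        i += nint
        rows = lines[i:i + count]
        i += count
        if tag == "$ElementData":
            data = np.array([[float(v) for v in r.split()[1:1 + ncomp]] for r in rows])
            if name == "M1":
                M1 = data
            elif name == "M2":
                M2 = data
            elif name == "lc":
                lc_mm = data[:, 0]
        else:
            for r in rows:
                a_, b_ = r.split()
                lab[id_to_row[int(a_)]] = int(float(b_))

    return TetMesh(
        nodes=coords * MM,
        tets=tets,
        region=region,
        cranial_nodes=np.flatnonzero(lab == 2),
        caudal_nodes=np.flatnonzero(lab == 1),
        M1=M1,
        M2=M2,
        lc=lc_mm * MM,
    )


def _write_vtk(mesh: TetMesh, path: Path) -> None:
    nodes_mm = mesh.nodes / MM
    lab = _interface_labels(mesh)
    M1, M2, lc_mm = _cell_data_arrays(mesh)
    n, m = mesh.n_nodes, mesh.n_elements
    out = [
        "# vtk DataFile Version 3.0\n",
        "discfem tetrahedral mesh\n",
        "ASCII\n",
        "DATASET UNSTRUCTURED_GRID\n",
        f"POINTS {n} double\n",
    ]
    out.extend(f"{_fmt(x)} {_fmt(y)} {_fmt(z)}\n" for x, y, z in nodes_mm)
    out.append(f"CELLS {m} {5 * m}\n")
    out.extend("4 " + " ".join(str(v) for v in t) + "\n" for t in mesh.tets)
    out.append(f"CELL_TYPES {m}\n")
    out.extend("10\n" for _ in range(m))
    out.append(f"CELL_DATA {m}\n")
    out.append("SCALARS region int 1\nLOOKUP_TABLE default\n")
    out.extend(f"{int(r)}\n" for r in mesh.region)
    out.append("SCALARS lc double 1\nLOOKUP_TABLE default\n")
    out.extend(f"{_fmt(v)}\n" for v in lc_mm)
    out.append("VECTORS M1 double\n")
    out.extend(f"{_fmt(a)} {_fmt(b)} {_fmt(c)}\n" for a, b, c in M1)
    out.append("VECTORS M2 double\n")
    out.extend(f"{_fmt(a)} {_fmt(b)} {_fmt(c)}\n" for a, b, c in M2)
    out.append(f"POINT_DATA {n}\n")
    out.append("SCALARS interface int 1\nLOOKUP_TABLE default\n")
    out.extend(f"{int(v)}\n" for v in lab)
    path.write_text("".join(out))


def _read_vtk(path: Path) -> TetMesh:
    tok = path.read_text().split("\n")
    i = 0

    def seek(prefix):
        nonlocal i
        while i < len(tok) and not tok[i].startswith(prefix):
            i += 1
        if i == len(tok):
            raise MeshingError(f"malformed VTK file: missing {prefix}")

    seek("POINTS")
    n = int(tok[i].split()[1])
    coords = np.array([[float(v) for v in tok[i + 1 + j].split()] for j in range(n)])
    i += n + 1
    seek("CELLS")
    m = int(tok[i].split()[1])
    tets = np.empty((m, 4), dtype=np.int64)
    for j in range(m):
        parts = tok[i + 1 + j].split()
        if parts[0] != "4":
            raise UnsupportedElementError(
                f"VTK cell with {parts[0]} vertices is not a linear tetrahedron"
            )
        tets[j] = [int(v) for v in parts[1:5]]
    i += m + 1
    seek("CELL_TYPES")
    for j in range(m):
        if tok[i + 1 + j].strip() != "10":
            raise UnsupportedElementError(
                f"VTK cell type {tok[i + 1 + j].strip()} is not VTK_TETRA"
            )
    i += m + 1

    region = np.zeros(m, dtype=np.int8)
    lc_mm = np.zeros(m)
    M1 = np.full((m, 3), np.nan)
    M2 = np.full((m, 3), np.nan)
    lab = np.zeros(n, dtype=np.int64)
    while i < len(tok):
        line = tok[i]
        if line.startswith("SCALARS region"):
            region = np.array([int(tok[i + 2 + j]) for j in range(m)], dtype=np.int8)
            i += m + 2
        elif line.startswith("SCALARS lc"):
            lc_mm = np.array([float(tok[i + 2 + j]) for j in range(m)])
            i += m + 2
        elif line.startswith("VECTORS M1"):
            M1 = np.array([[float(v) for v in tok[i + 1 + j].split()] for j in range(m)])
            i += m + 1
        elif line.startswith("VECTORS M2"):
            M2 = np.array([[float(v) for v in tok[i + 1 + j].split()] for j in range(m)])
            i += m + 1
        elif line.startswith("SCALARS interface"):
            lab = np.array([int(tok[i + 2 + j]) for j in range(n)])
            i += n + 2
        else:
            i += 1

    return TetMesh(
        nodes=coords * MM,
        tets=tets,
        region=region,
        cranial_nodes=np.flatnonzero(lab == 2),
        caudal_nodes=np.flatnonzero(lab == 1),
        M1=M1,
        M2=M2,
        lc=lc_mm * MM,
    )
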