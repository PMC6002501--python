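"""Structured graded tetrahedral meshing of the electrode-in-box geometry.

A tensor-product grid is laid down whose tick planes contain every material
interface (substrate faces, contact faces, seam planes, current-audit box),
then each hexahedral cell is subdivided into six conforming tetrahedra
(Kuhn subdivision).  Grading concentrates resolution at the thin contact
domains (25 um through-thickness, two to three element layers) and relaxes
geometrically toward the grounded walls.

Internal insulating surfaces ("workplane" seams between contacts, and the
substrate-medium interface when the electrode block is modelled as platinum)
are represented as mesh *cracks*: vertices on the surface are duplicated so
that elements on the two sides reference distinct copies, which represents a
perfect insulator exactly.  Each crack can later be re-tied (condition of
continuity) without re-meshing, so one mesh serves every boundary-condition
case of a geometry family.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import GeometryModel, GeometryError

__all__ = [
    "ResolutionProfile",
    "FacetSet",
    "TaggedMesh",
    "mesh_model",
    "tie_vertex_map",
    "region_element_components",
    "write_msh",
    "write_vtu",
]

# crack names; a case activates a subset of these as perfect insulators
CRACK_SUBSTRATE_MEDIUM = "substrate_medium"
CRACK_WORKPLANE = "workplane"

AXON_SAMPLE_HEIGHTS = (0.05, 0.75, 2.0)  # mm above the contact plane
# current-audit box beyond the contact; 0.5 mm keeps the audit surface clear
# of the contact-edge fringe where the recovered flux is noisy
AUDIT_MARGIN = 0.5


@dataclass(frozen=True)
class ResolutionProfile:
    """Target edge lengths (mm) controlling the graded grid.

    ``h_plane`` is the in-plane edge over the electrode footprint, ``h_wall``
    the coarsest edge at the box walls, ``h_z`` the vertical edge just above
    the contact plane and ``growth`` the linear growth rate of edge length
    with distance from the refined core.  ``contact_layers`` sets the minimum
    number of element layers through the 25 um contact thickness.
    """

    name: str = "default"
    h_plane: float = 0.55
    h_wall: float = 1.7
    h_z: float = 0.08
    growth: float = 0.7
    contact_layers: int = 2
    # extra refinement where the threshold physics lives: in-plane over the
    # contact footprint, and vertically through the closest axon plane
    h_contact: float = 0.18
    h_z_near: float = 0.028

    def scaled(self, factor: float, name: str) -> "ResolutionProfile":
        """Uniformly scale linear target sizes (element count ~ factor^-3)."""
        return ResolutionProfile(
            name=name,
            h_plane=self.h_plane * factor,
            h_wall=self.h_wall * factor,
            h_z=self.h_z * factor,
            growth=self.growth,
            contact_layers=self.contact_layers,
            h_contact=self.h_contact * factor,
            h_z_near=self.h_z_near * factor,
        )


_PROFILES = {
    # "tiny" exists for exactness properties (source-model equivalences,
    # superposition identities) that hold at any resolution
    "tiny": ResolutionProfile(name="tiny", h_plane=0.7, h_wall=5.0,
                              h_z=0.15, growth=1.3, contact_layers=2,
                              h_contact=0.5, h_z_near=0.1),
    "coarse": ResolutionProfile(name="coarse", h_plane=0.5, h_wall=4.0,
                                h_z=0.1, growth=0.9, contact_layers=2,
                                h_contact=0.35, h_z_near=0.05),
    "default": ResolutionProfile(name="default"),
    # "fine" targets ~2.5x the element count of "default" (linear scale
    # chosen so the realised tetrahedron count lands there, since the
    # interface-mandated tick planes do not scale)
    "fine": ResolutionProfile(name="default").scaled(0.69, "fine"),
    # flux-verification profile: resolution weighted toward the grounded
    # walls and the contact fringe, where direct current integrals converge
    "audit": ResolutionProfile(name="audit", h_plane=0.5, h_wall=1.0,
                               h_z=0.08, growth=0.5, contact_layers=2,
                               h_contact=0.3, h_z_near=0.08),
}


def resolution_profile(name_or_profile) -> ResolutionProfile:
    if isinstance(name_or_profile, ResolutionProfile):
        return name_or_profile
    try:
        return _PROFILES[name_or_profile]
    except KeyError:
        raise ValueError(f"unknown resolution profile {name_or_profile!r}") from None


@dataclass
class FacetSet:
    """Oriented triangle set: vertex triples, owning element, unit normals, areas."""

    tri: np.ndarray     # (k,3) int32, vertex ids consistent with `elem`'s copies
    elem: np.ndarray    # (k,) int64
    normal: np.ndarray  # (k,3) float64, orientation defined by the tag
    area: np.ndarray    # (k,) float64

    def total_area(self) -> float:
        return float(self.area.sum())


@dataclass
class TaggedMesh:
    """Tetrahedral mesh with region tags, facet tags and crack bookkeeping."""

    points: np.ndarray                  # (n,3) mm
    tets: np.ndarray                    # (m,4) int32
    region: np.ndarray                  # (m,) int16
    region_names: Dict[int, str]
    facet_sets: Dict[str, FacetSet]
    # crack bookkeeping -------------------------------------------------
    vertex_origin: np.ndarray           # (n,) int32; copies point at originals
    crack_bridges: np.ndarray           # (b,3) int32 rows (copy_i, copy_j, crack_id)
    crack_names: Dict[int, str]
    geometry_hash: str = ""
    resolution: str = "default"
    contact_model: str = "thin"         # "thin" | "no_thin"
    # y >= 0 half-domain with a symmetry (natural) plane at y = 0; valid
    # for source configurations that are mirror-symmetric in y
    symmetric_y: bool = False
    # structured-grid metadata for O(log n) point location
    ticks: Tuple[np.ndarray, np.ndarray, np.ndarray] = None
    n_cells: Tuple[int, int, int] = None

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def region_id(self, name: str) -> int:
        for k, v in self.region_names.items():
            if v == name:
                return k
        raise KeyError(name)

    def element_volumes(self) -> np.ndarray:
        p = self.points[self.tets]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0

    def region_volumes(self) -> Dict[str, float]:
        vols = self.element_volumes()
        return {name: float(vols[self.region == rid].sum())
                for rid, name in self.region_names.items()}

    def candidate_elements(self, xyz: np.ndarray) -> np.ndarray:
        """Element ids of the six tets of the hex cell containing each point.

        Points exactly on tick planes are assigned to the lower cell, clipped
        into range so boundary points remain locatable.
        """
        xyz = np.atleast_2d(xyz)
        nh = int(np.prod(self.n_cells))
        idx = []
        for ax in range(3):
            i = np.searchsorted(self.ticks[ax], xyz[:, ax], side="right") - 1
            idx.append(np.clip(i, 0, self.n_cells[ax] - 1))
        hexid = (idx[0] * self.n_cells[1] + idx[1]) * self.n_cells[2] + idx[2]
        return hexid[:, None] + nh * np.arange(6)[None, :]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.points, self.tets, self.region):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


# --------------------------------------------------------------------------
# tick generation
# --------------------------------------------------------------------------

def _fill_interval(a: float, b: float, ha: float, hb: float) -> np.ndarray:
    """Interior ticks of [a, b] with edge sizes grading linearly ha -> hb."""
    length = b - a
    n = max(1, int(np.ceil(2.0 * length / (ha + hb))))
    # spacing proportional to linear interpolation of h between the ends
    w = ha + (hb - ha) * (np.arange(n) + 0.5) / n
    w = w / w.sum()
    return a + length * np.cumsum(w)[:-1]


def _axis_ticks(mandatory: Sequence[float], size_fn, tol: float = 1e-9) -> np.ndarray:
    m = np.unique(np.round(np.asarray(sorted(mandatory), dtype=float), 12))
    out = [m[0]]
    for a, b in zip(m[:-1], m[1:]):
        if b - a < tol:
            continue
        out.extend(_fill_interval(a, b, size_fn(a), size_fn(b)).tolist())
        out.append(b)
    return np.asarray(out)


def _size_fn(cores, h_coarse: float, growth: float):
    """Size field: finest of several graded cores ((lo, hi), h_fine)."""

    def h(t: float) -> float:
        best = h_coarse
        for (c0, c1), hf in cores:
            d = max(c0 - t, t - c1, 0.0)
            best = min(best, float(np.clip(hf + growth * d, hf, h_coarse)))
        return best

    return h


def _build_ticks(geom: GeometryModel, prof: ResolutionProfile,
                 contact_model: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    e = geom.box.bounds
    el = geom.electrode
    sub = geom.substrate_box

    man_x = {e[0], e[1], sub[0], sub[1]}
    man_y = {e[2], e[3], sub[2], sub[3]}
    man_z = {e[4], e[5], sub[4], sub[5]}
    for (ax, c) in geom.seam_planes:
        (man_x if ax == "x" else man_y).add(c)
    for b in geom.contact_boxes:
        man_x.update((b[0], b[1], b[0] - AUDIT_MARGIN, b[1] + AUDIT_MARGIN))
        man_y.update((b[2], b[3], b[2] - AUDIT_MARGIN, b[3] + AUDIT_MARGIN))
        man_z.update((b[5] + AUDIT_MARGIN,))
        if contact_model == "thin":
            man_z.update((b[4], b[5]))
            # guarantee the requested number of layers through the thickness
            man_z.update(np.linspace(b[4], b[5], prof.contact_layers + 1).tolist())
        else:
            man_z.add(0.5 * (sub[4] + sub[5]))   # keep two layers in the sheet
    man_z.add(sub[4] - AUDIT_MARGIN)
    man_z.update(AXON_SAMPLE_HEIGHTS)

    m = 0.35  # mm, halo of contact-zone refinement
    cx = ((min(b[0] for b in geom.contact_boxes) - m,
           max(b[1] for b in geom.contact_boxes) + m), prof.h_contact)
    cy = ((min(b[2] for b in geom.contact_boxes) - m,
           max(b[3] for b in geom.contact_boxes) + m), prof.h_contact)
    hx = _size_fn([((sub[0], sub[1]), prof.h_plane), cx],
                  prof.h_wall, prof.growth)
    hy = _size_fn([((sub[2], sub[3]), prof.h_plane), cy],
                  prof.h_wall, prof.growth)
    # vertical: fine through the sheet, finest through the closest axon plane
    hz = _size_fn([((sub[4] - 0.05, 0.12), prof.h_z),
                   ((-0.03, 0.16), prof.h_z_near)],
                  prof.h_wall, prof.growth)
    return (_axis_ticks(man_x, hx), _axis_ticks(man_y, hy),
            _axis_ticks(man_z, hz))


# --------------------------------------------------------------------------
# hex grid -> Kuhn tetrahedra
# --------------------------------------------------------------------------

_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _grid_tets(nx: int, ny: int, nz: int) -> np.ndarray:
    """Six conforming tetrahedra per hex cell, translation-invariant pattern."""

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    base = (ii * (ny + 1) + jj) * (nz + 1) + kk
    base = base.ravel()
    step = np.array([ (ny + 1) * (nz + 1), (nz + 1), 1 ])  # +x, +y, +z strides
    tets = []
    for p in _KUHN_PERMS:
        v0 = base
        v1 = v0 + step[p[0]]
        v2 = v1 + step[p[1]]
        v3 = v2 + step[p[2]]
        tets.append(np.stack([v0, v1, v2, v3], axis=1))
    return np.concatenate(tets, axis=0).astype(np.int32)


def _orient_positive(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = points[tets]
    det = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                    np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    flip = det < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return tets


# --------------------------------------------------------------------------
# region and face classification
# --------------------------------------------------------------------------

def _in_box(c: np.ndarray, b) -> np.ndarray:
    return ((c[:, 0] > b[0]) & (c[:, 0] < b[1]) & (c[:, 1] > b[2])
            & (c[:, 1] < b[3]) & (c[:, 2] > b[4]) & (c[:, 2] < b[5]))


_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _element_faces(tets: np.ndarray) -> np.ndarray:
    """(m,4,3) local faces, outward-oriented for positively oriented tets."""
    return tets[:, _FACE_LOCAL]


def _face_key(faces: np.ndarray) -> np.ndarray:
    return np.sort(faces, axis=-1)


def mesh_model(geometry: GeometryModel, resolution="default", *,
               contact_model: str = "thin",
               symmetric_y: bool = False) -> TaggedMesh:
    """Mesh the solid model into a :class:`TaggedMesh`.

    ``contact_model="no_thin"`` omits the thin contact volumes: the contact
    footprint becomes a tagged rectangle (``contact_k_active_rect``) on the
    substrate surface, used with a boundary current source.
    ``symmetric_y`` meshes only the y >= 0 half with a natural (zero normal
    current) symmetry plane at y = 0, exact for y-mirror-symmetric source
    configurations; the solver restores full-model current bookkeeping.
    The result is deterministic for a given geometry and profile.
    """
    prof = resolution_profile(resolution)
    if contact_model not in ("thin", "no_thin"):
        raise ValueError(f"unknown contact model {contact_model!r}")
    if contact_model == "no_thin" and geometry.electrode.contact_profile != "flush":
        raise GeometryError("no_thin contact model requires flush contacts")

    tx, ty, tz = _build_ticks(geometry, prof, contact_model)
    if symmetric_y:
        if any(ax == "y" for ax, _ in geometry.seam_planes):
            raise GeometryError(
                "y-symmetric meshing cannot split a y workplane seam")
        ty = np.concatenate([[0.0], ty[ty > 1e-12]])
    X, Y, Z = np.meshgrid(tx, ty, tz, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    nx, ny, nz = len(tx) - 1, len(ty) - 1, len(tz) - 1
    tets = _orient_positive(points, _grid_tets(nx, ny, nz))

    # ---- region tags ---------------------------------------------------
    cent = points[tets].mean(axis=1)
    region = np.zeros(len(tets), dtype=np.int16)           # 0 = medium
    region_names = {0: "medium", 1: "substrate"}
    region[_in_box(cent, geometry.substrate_box)] = 1
    if contact_model == "thin":
        for k, b in enumerate(geometry.contact_boxes):
            rid = 2 + k
            region_names[rid] = f"contact_{k}"
            region[_in_box(cent, b)] = rid

    mesh = TaggedMesh(
        points=points, tets=tets, region=region, region_names=region_names,
        facet_sets={}, vertex_origin=np.arange(len(points), dtype=np.int32),
        crack_bridges=np.zeros((0, 3), dtype=np.int32), crack_names={},
        geometry_hash=hashlib.sha256(
            geometry.to_yaml().encode() + prof.name.encode()
            + contact_model.encode()).hexdigest(),
        resolution=prof.name, contact_model=contact_model,
        symmetric_y=symmetric_y,
        ticks=(tx, ty, tz), n_cells=(nx, ny, nz),
    )
    _classify_and_crack(mesh, geometry)
    return mesh


def _classify_and_crack(mesh: TaggedMesh, geom: GeometryModel) -> None:
    points, tets, region = mesh.points, mesh.tets, mesh.region
    m = len(tets)
    faces = _element_faces(tets).reshape(-1, 3)            # (4m,3) outward
    keys = _face_key(faces)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    sk = keys[order]
    same = np.all(sk[1:] == sk[:-1], axis=1)
    # pair up shared faces
    pair_start = np.flatnonzero(same)
    is_paired = np.zeros(len(order), dtype=bool)
    is_paired[pair_start] = True
    is_paired[pair_start + 1] = True
    face_elem = order // 4

    # ---- boundary facets (outer ground) --------------------------------
    bidx = order[~is_paired]
    btris = faces[bidx]
    belem = face_elem[~is_paired]
    e = geom.box.bounds
    c = points[btris].mean(axis=1)
    tol = 1e-9
    on_wall = (
        (np.abs(c[:, 0] - e[0]) < tol) | (np.abs(c[:, 0] - e[1]) < tol)
        | (np.abs(c[:, 1] - e[2]) < tol) | (np.abs(c[:, 1] - e[3]) < tol)
        | (np.abs(c[:, 2] - e[4]) < tol) | (np.abs(c[:, 2] - e[5]) < tol)
    )
    mesh.facet_sets["outer_ground"] = _make_facet_set(
        points, btris[on_wall], belem[on_wall], flip_to=None)

    # ---- interior interface facets -------------------------------------
    iA = order[pair_start]          # one side
    iB = order[pair_start + 1]      # other side
    eA, eB = face_elem[pair_start], face_elem[pair_start + 1]
    rA, rB = region[eA], region[eB]
    diff = rA != rB

    crack_faces: List[np.ndarray] = []   # vertex-triples (sorted) per crack
    crack_ids: List[int] = []
    mesh.crack_names = {0: CRACK_SUBSTRATE_MEDIUM, 1: CRACK_WORKPLANE}

    def add_set(name, mask, side_elems, side_faceidx, flip_to=None):
        mesh.facet_sets[name] = _make_facet_set(
            points, faces[side_faceidx[mask]], side_elems[mask], flip_to=flip_to)

    sub_id = mesh.region_id("substrate")
    med_id = mesh.region_id("medium")

    # substrate-medium interface (medium side and substrate side)
    sm = diff & (((rA == sub_id) & (rB == med_id)) | ((rA == med_id) & (rB == sub_id)))
    med_side_elem = np.where(region[eA] == med_id, eA, eB)
    med_side_face = np.where(region[eA] == med_id, iA, iB)
    sub_side_elem = np.where(region[eA] == sub_id, eA, eB)
    sub_side_face = np.where(region[eA] == sub_id, iA, iB)

    # contact-medium interfaces (exposed faces) per contact
    active_rects = {}
    if mesh.contact_model == "thin":
        for k in range(geom.electrode.n_contacts):
            cid = mesh.region_id(f"contact_{k}")
            cm = diff & (((rA == cid) & (rB == med_id)) | ((rA == med_id) & (rB == cid)))
            cm_med_elem = np.where(region[eA] == med_id, eA, eB)
            cm_med_face = np.where(region[eA] == med_id, iA, iB)
            # normal points out of the contact, i.e. into the medium: the
            # medium-side face as stored is outward for the medium element,
            # i.e. pointing into the contact, so flip.
            add_set(f"contact_{k}_exposed", cm, cm_med_elem, cm_med_face,
                    flip_to="reverse")
    else:
        # tag the active rectangles on the substrate surface by footprint
        fc = points[faces].mean(axis=1)
        for k, b in enumerate(geom.contact_boxes):
            rect = (sm & (np.abs(fc[med_side_face][:, 2] - 0.0) < 1e-9)
                    & (fc[med_side_face][:, 0] > b[0]) & (fc[med_side_face][:, 0] < b[1])
                    & (fc[med_side_face][:, 1] > b[2]) & (fc[med_side_face][:, 1] < b[3]))
            active_rects[k] = rect
            add_set(f"contact_{k}_active_rect", rect, med_side_elem, med_side_face,
                    flip_to="reverse")
        # active rectangles stay coupled (condition of continuity): current
        # injected there feeds both the medium and the electrode block
        rect_any = np.zeros_like(sm)
        for rmask in active_rects.values():
            rect_any |= rmask
        sm = sm & ~rect_any

    add_set("substrate_medium_medium_side", sm, med_side_elem, med_side_face)
    add_set("substrate_medium_substrate_side", sm, sub_side_elem, sub_side_face)
    crack_faces.append(_face_key(faces[med_side_face[sm]]))
    crack_ids.append(0)

    # workplane seam: substrate-substrate faces lying in seam planes
    ss = (~diff) & (rA == sub_id)
    fcen = points[faces[iA]].mean(axis=1)
    seam = np.zeros_like(ss)
    for ax, coord in geom.seam_planes:
        col = 0 if ax == "x" else 1
        # a seam plane passing through a contact volume is a geometry error
        for b in geom.contact_boxes:
            lo, hi = (b[0], b[1]) if ax == "x" else (b[2], b[3])
            if lo < coord < hi:
                raise GeometryError("workplane seam intersects a contact volume")
        seam |= ss & (np.abs(fcen[:, col] - coord) < 1e-9)
    # seam facets: pick side-A element, orient normal toward the +axis
    add_set("workplane_seam", seam, eA, iA, flip_to="+axis")
    crack_faces.append(_face_key(faces[iA[seam]]))
    crack_ids.append(1)

    # contact-substrate interfaces kept under continuity; tag for completeness
    if mesh.contact_model == "thin":
        for k in range(geom.electrode.n_contacts):
            cid = mesh.region_id(f"contact_{k}")
            cs = diff & (((rA == cid) & (rB == sub_id)) | ((rA == sub_id) & (rB == cid)))
            cs_elem = np.where(region[eA] == cid, eA, eB)
            cs_face = np.where(region[eA] == cid, iA, iB)
            add_set(f"contact_{k}_substrate_interface", cs, cs_elem, cs_face)

    _apply_cracks(mesh, crack_faces, crack_ids)


def _make_facet_set(points, tris, elems, flip_to=None) -> FacetSet:
    tris = np.ascontiguousarray(tris, dtype=np.int32)
    elems = np.ascontiguousarray(elems, dtype=np.int64)
    p = points[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area2 = np.linalg.norm(n, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat = n / area2[:, None]
    if flip_to == "reverse":
        nhat = -nhat
        tris = tris[:, ::-1]
    elif flip_to == "+axis":
        # orient along the dominant positive axis direction
        dom = np.argmax(np.abs(nhat), axis=1)
        sign = np.sign(nhat[np.arange(len(nhat)), dom])
        flip = sign < 0
        nhat[flip] *= -1
        tris[flip] = tris[flip, ::-1]
    return FacetSet(tri=tris, elem=elems, normal=nhat, area=area2 / 2.0)


# --------------------------------------------------------------------------
# cracking (vertex duplication) and re-tying
# --------------------------------------------------------------------------

def _apply_cracks(mesh: TaggedMesh, crack_faces: List[np.ndarray],
                  crack_ids: List[int]) -> None:
    """Duplicate vertices on crack surfaces; record bridges for re-tying.

    For every vertex on a crack surface, its incident elements are grouped by
    face-adjacency that does not pass through a crack face; each group gets
    its own vertex copy.  A "bridge" records which copies a given crack face
    separates, so a continuity condition can merge them again at solve time.
    """
    if all(len(cf) == 0 for cf in crack_faces):
        return
    tets = mesh.tets
    # face(sorted tri) -> crack id
    crack_map: Dict[bytes, int] = {}
    for cf, cid in zip(crack_faces, crack_ids):
        for row in cf:
            crack_map[row.tobytes()] = cid

    crack_verts = np.unique(np.concatenate(
        [cf.ravel() for cf in crack_faces if len(cf)]))
    vset = set(crack_verts.tolist())

    # incident elements per crack vertex
    incid: Dict[int, List[int]] = {v: [] for v in vset}
    for e_idx, tet in enumerate(tets):
        for v in tet:
            if v in vset:
                incid[int(v)].append(e_idx)

    new_points: List[np.ndarray] = []
    new_origin: List[int] = []
    bridges: List[Tuple[int, int, int]] = []
    next_id = mesh.n_points
    tets_new = tets.copy()

    for v in crack_verts.tolist():
        elems = incid[v]
        # local face adjacency among incident elements
        facemap: Dict[bytes, List[int]] = {}
        for le, e_idx in enumerate(elems):
            tet = tets[e_idx]
            for f in range(4):
                tri = tet[_FACE_LOCAL[f]]
                if v in tri:
                    facemap.setdefault(np.sort(tri).astype(np.int32).tobytes(),
                                       []).append(le)
        nloc = len(elems)
        parent = list(range(nloc))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        shared_crack_faces = []
        for key, les in facemap.items():
            if len(les) == 2:
                cid = crack_map.get(key)
                if cid is None:
                    ra, rb = find(les[0]), find(les[1])
                    if ra != rb:
                        parent[ra] = rb
                else:
                    shared_crack_faces.append((les[0], les[1], cid))
        groups: Dict[int, List[int]] = {}
        for le in range(nloc):
            groups.setdefault(find(le), []).append(le)
        if len(groups) == 1:
            continue
        roots = sorted(groups)
        # group containing the lowest element index keeps the original vertex
        vid_of_root = {}
        for gi, r in enumerate(roots):
            if gi == 0:
                vid_of_root[r] = v
            else:
                vid_of_root[r] = next_id
                new_points.append(mesh.points[v])
                new_origin.append(v)
                next_id += 1
        for r, les in groups.items():
            vid = vid_of_root[r]
            if vid == v:
                continue
            for le in les:
                e_idx = elems[le]
                tets_new[e_idx, tets_new[e_idx] == v] = vid
        for (la, lb, cid) in shared_crack_faces:
            va, vb = vid_of_root[find(la)], vid_of_root[find(lb)]
            if va != vb:
                bridges.append((va, vb, cid))

    if new_points:
        mesh.points = np.vstack([mesh.points, np.array(new_points)])
        mesh.vertex_origin = np.concatenate(
            [mesh.vertex_origin, np.array(new_origin, dtype=np.int32)])
        mesh.tets = tets_new
        mesh.crack_bridges = np.array(sorted(set(bridges)), dtype=np.int32)
        _refresh_facet_vertices(mesh)


def _refresh_facet_vertices(mesh: TaggedMesh) -> None:
    """Rewrite facet-set vertex ids to the copies used by the owning element."""
    for fs in mesh.facet_sets.values():
        if len(fs.tri) == 0:
            continue
        tri = fs.tri
        owner = mesh.tets[fs.elem]                       # (k,4) current ids
        owner_orig = mesh.vertex_origin[owner]           # (k,4) original ids
        tri_orig = mesh.vertex_origin[tri]
        out = tri.copy()
        for c in range(3):
            match = owner_orig == tri_orig[:, c][:, None]
            sel = np.argmax(match, axis=1)
            has = match.any(axis=1)
            out[has, c] = owner[has, sel[has]]
        fs.tri = out


def tie_vertex_map(mesh: TaggedMesh,
                   active_cracks: Sequence[str] = ()) -> np.ndarray:
    """Vertex representative map for a given set of *insulating* cracks.

    Copies separated only by inactive cracks (condition of continuity) are
    merged back to one representative; active cracks stay electrically open.
    Returns an (n_points,) array mapping every vertex to its representative.
    """
    active_ids = {cid for cid, name in mesh.crack_names.items()
                  if name in active_cracks}
    unknown = set(active_cracks) - set(mesh.crack_names.values())
    if unknown:
        raise ValueError(f"unknown crack name(s): {sorted(unknown)}")
    n = mesh.n_points
    parent = np.arange(n, dtype=np.int64)

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    for va, vb, cid in mesh.crack_bridges:
        if cid not in active_ids:
            ra, rb = find(int(va)), find(int(vb))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    for i in range(n):
        parent[i] = find(i)
    return parent


def region_element_components(mesh: TaggedMesh, region_name: str,
                              active_cracks: Sequence[str] = ()) -> int:
    """Number of connected components of a region's element graph.

    Adjacency passes through shared faces except faces of active cracks
    (after cracking, elements across an open crack share no face at all, so
    it suffices to count components of the cracked connectivity).
    """
    rep = tie_vertex_map(mesh, active_cracks)
    rid = mesh.region_id(region_name)
    elems = np.flatnonzero(mesh.region == rid)
    tets = rep[mesh.tets[elems]]
    faces = _face_key(tets[:, _FACE_LOCAL].reshape(-1, 3))
    keys = [row.tobytes() for row in faces]
    fmap: Dict[bytes, List[int]] = {}
    for fi, key in enumerate(keys):
        fmap.setdefault(key, []).append(fi // 4)
    rows, cols = [], []
    for les in fmap.values():
        if len(les) == 2:
            rows.append(les[0]); cols.append(les[1])
    g = coo_matrix((np.ones(len(rows)), (rows, cols)),
                   shape=(len(elems), len(elems)))
    ncomp, _ = connected_components(g, directed=False)
    return int(ncomp)


# --------------------------------------------------------------------------
# text exporters (Gmsh MSH 4.1 and VTU)
# --------------------------------------------------------------------------

def write_msh(mesh: TaggedMesh, path: str) -> None:
    """Write the volume mesh as ASCII Gmsh MSH v4.1 (one entity per region)."""
    rids = sorted(mesh.region_names)
    with open(path, "w") as f:
        f.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n%d\n" % len(rids))
        for rid in rids:
            f.write('3 %d "%s"\n' % (rid + 1, mesh.region_names[rid]))
        f.write("$EndPhysicalNames\n")
        f.write("$Entities\n0 0 0 %d\n" % len(rids))
        for rid in rids:
            f.write("%d 0 0 0 0 0 0 1 %d 0\n" % (rid + 1, rid + 1))
        f.write("$EndEntities\n")
        n = mesh.n_points
        f.write("$Nodes\n1 %d 1 %d\n3 1 0 %d\n" % (n, n, n))
        for i in range(1, n + 1):
            f.write("%d\n" % i)
        for p in mesh.points:
            f.write("%.12g %.12g %.12g\n" % (p[0], p[1], p[2]))
        f.write("$EndNodes\n")
        f.write("$Elements\n%d %d 1 %d\n" % (len(rids), mesh.n_elements,
                                             mesh.n_elements))
        eid = 1
        for rid in rids:
            idx = np.flatnonzero(mesh.region == rid)
            f.write("3 %d 4 %d\n" % (rid + 1, len(idx)))
            for e in idx:
                t = mesh.tets[e] + 1
                f.write("%d %d %d %d %d\n" % (eid, t[0], t[1], t[2], t[3]))
                eid += 1
        f.write("$EndElements\n")


def write_vtu(mesh: TaggedMesh, path: str,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write an ASCII VTK XML unstructured grid with optional fields."""
    n, m = mesh.n_points, mesh.n_elements

    def arr(f, name, data, comps):
        f.write('<DataArray type="Float64" Name="%s" '
                'NumberOfComponents="%d" format="ascii">\n' % (name, comps))
        np.savetxt(f, np.asarray(data).reshape(-1, comps), fmt="%.9g")
        f.write("</DataArray>\n")

    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n'
                '<VTKFile type="UnstructuredGrid" version="0.1" '
                'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        f.write('<Piece NumberOfPoints="%d" NumberOfCells="%d">\n' % (n, m))
        f.write("<Points>\n")
        arr(f, "Points", mesh.points, 3)
        f.write("</Points>\n<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        np.savetxt(f, mesh.tets, fmt="%d")
        f.write('</DataArray>\n<DataArray type="Int64" Name="offsets" '
                'format="ascii">\n')
        np.savetxt(f, 4 * np.arange(1, m + 1), fmt="%d")
        f.write('</DataArray>\n<DataArray type="UInt8" Name="types" '
                'format="ascii">\n')
        np.savetxt(f, np.full(m, 10, dtype=np.uint8), fmt="%d")
        f.write("</DataArray>\n</Cells>\n")
        f.write("<PointData>\n")
        for name, data in (point_data or {}).items():
            arr(f, name, data, 1 if np.asarray(data).ndim == 1 else
                np.asarray(data).shape[1])
        f.write("</PointData>\n<CellData>\n")
        cd = dict(cell_data or {})
        cd.setdefault("region", mesh.region.astype(float))
        for name, data in cd.items():
            arr(f, name, data, 1 if np.asarray(data).ndim == 1 else
                np.asarray(data).shape[1])
        f.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
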