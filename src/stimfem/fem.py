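"""Quasi-static volume-conductor finite element solver.

Solves the conduction problem div(sigma grad V) = 0 on a tagged tetrahedral
mesh with Lagrange P1 or (default) P2 elements, under the four current-source
representations compared in this package:

* ``pcs`` - point current source: a shape-function-weighted delta load at an
  exact coordinate inside a conductive domain;
* ``bcs`` - boundary current source: uniform inward normal current density
  I / exposed_area as Neumann data on the exposed contact facets;
* ``ep``  - electric potential source: Dirichlet V = 1 V on the contact
  surface, rescaled exactly (linearity) so the delivered current matches the
  target;
* ``fp``  - floating potential: all exposed-surface degrees of freedom tied
  to one auxiliary unknown (exactly isopotential) delivering a prescribed
  net current.

Inactive contacts carry either a condition of continuity (floating, no
constraint) or a ground (Dirichlet 0).  Insulating surfaces (substrate-medium
boundary and the internal workplane between contacts) are mesh cracks that a
case activates or re-ties; see :mod:`stimfem.mesh`.

Lengths on the mesh are millimetres; assembly converts to SI metres, so
potentials are volts and currents amperes (reported in milliamperes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TaggedMesh, tie_vertex_map

__all__ = [
    "MaterialLibrary",
    "ContactSource",
    "SourceConfiguration",
    "FieldSolution",
    "ConfigurationError",
    "SolverError",
    "FemOperator",
    "assemble",
    "solve_case",
]

MM = 1e-3  # mesh unit in metres


class ConfigurationError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaterialLibrary:
    """Isotropic conductivities (S/m) of the model materials."""

    sigma_sil: float = 1e-12
    sigma_medium: float = 0.2
    sigma_pt: float = 9.43e6

    def __post_init__(self):
        if min(self.sigma_sil, self.sigma_medium, self.sigma_pt) <= 0:
            raise ConfigurationError("conductivities must be positive")

    def check_conditioning(self, sigmas: Sequence[float]) -> None:
        ratio = min(sigmas) / max(sigmas)
        if ratio < 1e-12:
            warnings.warn(
                "conductivity ratio %.1e is below safe conditioning limits "
                "(~1e-6 recommended); consider the platinum_insulated_with_seams "
                "substrate scheme" % ratio, RuntimeWarning, stacklevel=3)


SUBSTRATE_SCHEMES = (
    "silicone", "silicone_insulated", "medium_insulated",
    "platinum_insulated_with_seams",
)


@dataclass(frozen=True)
class ContactSource:
    """Source assignment for one contact.

    ``model`` is one of pcs/bcs/ep/fp/inactive_floating/inactive_grounded;
    ``amplitude_mA`` is the prescribed (or, for ep, target) current.
    """

    model: str = "inactive_floating"
    amplitude_mA: float = 0.0

    def __post_init__(self):
        if self.model not in ("pcs", "bcs", "ep", "fp",
                              "inactive_floating", "inactive_grounded"):
            raise ConfigurationError(f"unknown source model {self.model!r}")


@dataclass(frozen=True)
class SourceConfiguration:
    """Per-contact sources plus the substrate scheme of a solve case."""

    sources: Tuple[ContactSource, ...]
    substrate_scheme: str = "silicone"
    contact_conductivity: str = "pt"      # "pt" | "substrate" (thin contact model)

    def __post_init__(self):
        if self.substrate_scheme not in SUBSTRATE_SCHEMES:
            raise ConfigurationError(
                f"unknown substrate scheme {self.substrate_scheme!r}")
        if self.contact_conductivity not in ("pt", "substrate"):
            raise ConfigurationError("contact_conductivity must be pt|substrate")

    def active_cracks(self) -> Tuple[str, ...]:
        return {
            "silicone": (),
            "silicone_insulated": ("substrate_medium",),
            "medium_insulated": ("substrate_medium",),
            "platinum_insulated_with_seams": ("substrate_medium", "workplane"),
        }[self.substrate_scheme]

    def region_sigma(self, mesh: TaggedMesh,
                     materials: MaterialLibrary) -> Dict[str, float]:
        sub = {
            "silicone": materials.sigma_sil,
            "silicone_insulated": materials.sigma_sil,
            "medium_insulated": materials.sigma_medium,
            "platinum_insulated_with_seams": materials.sigma_pt,
        }[self.substrate_scheme]
        out = {"medium": materials.sigma_medium, "substrate": sub}
        for name in mesh.region_names.values():
            if name.startswith("contact_"):
                out[name] = (materials.sigma_pt
                             if self.contact_conductivity == "pt" else sub)
        return out


# --------------------------------------------------------------------------
# P1 / P2 reference elements
# --------------------------------------------------------------------------

_EDGE_LOCAL = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])

# Keast 4-point degree-2 rule on the tetrahedron (barycentric, weight 1/4)
_TET_Q = np.array([
    [0.5854101966249685, 0.1381966011250105, 0.1381966011250105, 0.1381966011250105],
    [0.1381966011250105, 0.5854101966249685, 0.1381966011250105, 0.1381966011250105],
    [0.1381966011250105, 0.1381966011250105, 0.5854101966249685, 0.1381966011250105],
    [0.1381966011250105, 0.1381966011250105, 0.1381966011250105, 0.5854101966249685],
])
_TET_W = np.full(4, 0.25)

# 6-point degree-4 rule on the triangle
_TRI_Q = np.array([
    [0.816847572980459, 0.091576213509771, 0.091576213509771],
    [0.091576213509771, 0.816847572980459, 0.091576213509771],
    [0.091576213509771, 0.091576213509771, 0.816847572980459],
    [0.108103018168070, 0.445948490915965, 0.445948490915965],
    [0.445948490915965, 0.108103018168070, 0.445948490915965],
    [0.445948490915965, 0.445948490915965, 0.108103018168070],
])
_TRI_W = np.array([0.109951743655322] * 3 + [0.223381589678011] * 3)


def p2_basis(lam: np.ndarray) -> np.ndarray:
    """P2 basis values at barycentric points; dof order [v0..v3, e01..e23]."""
    lam = np.atleast_2d(lam)
    vals = [lam[:, i] * (2 * lam[:, i] - 1) for i in range(4)]
    vals += [4 * lam[:, a] * lam[:, b] for a, b in _EDGE_LOCAL]
    return np.stack(vals, axis=-1)


def p2_grad(lam: np.ndarray, G: np.ndarray) -> np.ndarray:
    """P2 basis gradients; ``G`` is (m,4,3) barycentric gradients.

    ``lam``: (q,4).  Returns (q,m,10,3).
    """
    lam = np.atleast_2d(lam)
    q = lam.shape[0]
    m = G.shape[0]
    out = np.empty((q, m, 10, 3))
    for i in range(4):
        out[:, :, i, :] = (4 * lam[:, i] - 1)[:, None, None] * G[None, :, i, :]
    for k, (a, b) in enumerate(_EDGE_LOCAL):
        out[:, :, 4 + k, :] = 4 * (lam[:, b][:, None, None] * G[None, :, a, :]
                                   + lam[:, a][:, None, None] * G[None, :, b, :])
    return out


# --------------------------------------------------------------------------
# operator assembly
# --------------------------------------------------------------------------

@dataclass
class FemOperator:
    """Mesh-bound discrete conduction operator (material-independent parts).

    Holds the degree-of-freedom numbering, per-element geometric stiffness
    blocks and the facet degree-of-freedom tables; material-weighted global
    matrices are produced per case by :meth:`stiffness`.
    """

    mesh: TaggedMesh
    order: int = 2
    n_vert: int = 0
    edges: np.ndarray = None              # (ne,2) raw vertex pairs, sorted
    _edge_keys: np.ndarray = None
    tet_dofs: np.ndarray = None           # (m, 4 or 10)
    n_dofs: int = 0

    def __post_init__(self):
        mesh = self.mesh
        self.n_vert = mesh.n_points
        tets = mesh.tets.astype(np.int64)
        if self.order == 2:
            e = np.sort(tets[:, _EDGE_LOCAL].reshape(-1, 2), axis=1)
            keys = e[:, 0] * self.n_vert + e[:, 1]
            ukeys, inv = np.unique(keys, return_inverse=True)
            self._edge_keys = ukeys
            self.edges = np.column_stack([ukeys // self.n_vert,
                                          ukeys % self.n_vert]).astype(np.int64)
            edofs = self.n_vert + inv.reshape(-1, 6)
            self.tet_dofs = np.concatenate([tets, edofs], axis=1)
            self.n_dofs = self.n_vert + len(ukeys)
        elif self.order == 1:
            self.tet_dofs = tets
            self.n_dofs = self.n_vert
        else:
            raise ConfigurationError("element order must be 1 or 2")
        self._G, self._vol = self._geometry()

    # barycentric gradients and volumes ---------------------------------
    def _geometry(self):
        p = self.mesh.points[self.mesh.tets] * MM          # (m,4,3) metres
        J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0],
                      p[:, 3] - p[:, 0]], axis=1)          # (m,3,3) rows=edges
        detJ = np.linalg.det(J)
        vol = detJ / 6.0
        Jinv = np.linalg.inv(J)                            # columns map
        Gv = np.transpose(Jinv, (0, 2, 1))                 # (m,3,3): grads of l1..l3
        G = np.empty((len(vol), 4, 3))
        G[:, 1:, :] = Gv
        G[:, 0, :] = -Gv.sum(axis=1)
        return G, vol

    def stiffness(self, region_sigma: Dict[str, float]) -> sp.csr_matrix:
        """Material-weighted global stiffness matrix on the raw DOFs.

        Element matrices are streamed in chunks rather than stored: the
        10x10 blocks of a fine mesh would otherwise dominate memory.
        """
        names = self.mesh.region_names
        missing = [n for n in names.values() if n not in region_sigma]
        if missing:
            raise ConfigurationError(f"no conductivity for region(s) {missing}")
        sig = np.zeros(max(names) + 1)
        for rid, nm in names.items():
            sig[rid] = region_sigma[nm]
        w = sig[self.mesh.region] * self._vol
        nd = self.tet_dofs.shape[1]
        m = len(w)
        K = sp.csr_matrix((self.n_dofs, self.n_dofs))
        chunk = max(1, 200000 // 1)
        for start in range(0, m, chunk):
            sl = slice(start, min(start + chunk, m))
            G = self._G[sl]
            if self.order == 1:
                ke = np.einsum("mid,mjd,m->mij", G, G, w[sl])
            else:
                ke = np.zeros((G.shape[0], 10, 10))
                for q in range(len(_TET_W)):
                    B = p2_grad(_TET_Q[q:q + 1], G)[0]     # (mc,10,3)
                    ke += _TET_W[q] * np.einsum("mid,mjd->mij", B, B)
                ke *= w[sl, None, None]
            dofs = self.tet_dofs[sl]
            rows = np.repeat(dofs, nd, axis=1).ravel()
            cols = np.tile(dofs, (1, nd)).ravel()
            Kc = sp.coo_matrix((ke.ravel(), (rows, cols)),
                               shape=(self.n_dofs, self.n_dofs)).tocsr()
            Kc.sum_duplicates()
            K = K + Kc
        return K

    # facet DOF helpers ---------------------------------------------------
    def edge_dof(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keys = lo.astype(np.int64) * self.n_vert + hi
        idx = np.searchsorted(self._edge_keys, keys)
        if np.any(self._edge_keys[np.clip(idx, 0, len(self._edge_keys) - 1)]
                  != keys):
            raise KeyError("edge not present in mesh")
        return self.n_vert + idx

    def facet_dofs(self, tri: np.ndarray) -> np.ndarray:
        """DOFs of each facet: (k, 3) for P1, (k, 6) for P2."""
        if self.order == 1:
            return tri.astype(np.int64)
        e = [self.edge_dof(tri[:, a], tri[:, b])
             for a, b in ((0, 1), (1, 2), (0, 2))]
        return np.column_stack([tri.astype(np.int64)] + e)

    def facet_set_dofs(self, name: str) -> np.ndarray:
        fs = self.mesh.facet_sets[name]
        if len(fs.tri) == 0:
            return np.zeros(0, dtype=np.int64)
        return np.unique(self.facet_dofs(fs.tri).ravel())

    def facet_basis(self, tri: np.ndarray):
        """Trace basis values at the triangle quadrature points: (q, nb)."""
        if self.order == 1:
            return _TRI_Q, _TRI_W
        lam = _TRI_Q
        vals = [lam[:, i] * (2 * lam[:, i] - 1) for i in range(3)]
        vals += [4 * lam[:, 0] * lam[:, 1], 4 * lam[:, 1] * lam[:, 2],
                 4 * lam[:, 0] * lam[:, 2]]
        return np.stack(vals, axis=-1), _TRI_W

    @property
    def dof_coords(self) -> np.ndarray:
        """Coordinates (mm) of every raw DOF (vertices, then edge midpoints)."""
        if getattr(self, "_dof_coords", None) is None:
            pts = self.mesh.points
            if self.order == 1:
                self._dof_coords = pts
            else:
                mid = 0.5 * (pts[self.edges[:, 0]] + pts[self.edges[:, 1]])
                self._dof_coords = np.vstack([pts, mid])
        return self._dof_coords

    # point evaluation ----------------------------------------------------
    def locate(self, xyz: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Containing element and barycentric coordinates for each point."""
        xyz = np.atleast_2d(xyz)
        cand = self.mesh.candidate_elements(xyz)           # (n,6)
        n = len(xyz)
        elem = np.full(n, -1, dtype=np.int64)
        lam = np.zeros((n, 4))
        p = self.mesh.points * MM
        x = xyz * MM
        for c in range(cand.shape[1]):
            todo = elem < 0
            if not todo.any():
                break
            e = cand[todo, c]
            verts = p[self.mesh.tets[e]]
            T = np.stack([verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0],
                          verts[:, 3] - verts[:, 0]], axis=2)
            rhs = x[todo] - verts[:, 0]
            sol = np.linalg.solve(T, rhs[..., None])[..., 0]
            l0 = 1 - sol.sum(axis=1)
            lm = np.column_stack([l0, sol])
            ok = np.all(lm > -1e-9, axis=1)
            idx = np.flatnonzero(todo)[ok]
            elem[idx] = e[ok]
            lam[idx] = lm[ok]
        if np.any(elem < 0):
            raise ValueError("point(s) outside the mesh")
        return elem, lam

    def eval_at(self, V: np.ndarray, xyz: np.ndarray) -> np.ndarray:
        elem, lam = self.locate(xyz)
        if self.order == 1:
            N = lam
        else:
            N = p2_basis(lam)
        return np.einsum("pi,pi->p", N, V[self.tet_dofs[elem]])


def assemble(mesh: TaggedMesh, materials: MaterialLibrary,
             config: SourceConfiguration, order: int = 2,
             operator: Optional[FemOperator] = None
             ) -> Tuple[FemOperator, sp.csr_matrix, Dict[str, float]]:
    """Build the stiffness operator for a case; the operator is reusable."""
    op = operator if operator is not None else FemOperator(mesh, order=order)
    sigma = config.region_sigma(mesh, materials)
    materials.check_conditioning(list(sigma.values()))
    return op, op.stiffness(sigma), sigma


# --------------------------------------------------------------------------
# solution container
# --------------------------------------------------------------------------

@dataclass
class FieldSolution:
    """Nodal potentials plus the bookkeeping needed for current audits."""

    mesh: TaggedMesh
    operator: FemOperator
    V: np.ndarray                       # raw-DOF potentials (volts)
    residual: np.ndarray                # K_raw V - f_raw (amperes)
    load: np.ndarray                    # f_raw (amperes)
    region_sigma: Dict[str, float]
    config: Optional[SourceConfiguration]
    diagnostics: Dict[str, float] = dfield(default_factory=dict)
    contact_summary: Dict[int, Dict[str, float]] = dfield(default_factory=dict)

    def sample(self, xyz: np.ndarray) -> np.ndarray:
        return self.operator.eval_at(self.V, xyz)

    def contact_surface_potentials(self, k: int) -> np.ndarray:
        name = (f"contact_{k}_exposed" if f"contact_{k}_exposed"
                in self.mesh.facet_sets else f"contact_{k}_active_rect")
        dofs = self.operator.facet_set_dofs(name)
        return self.V[dofs]

    def scaled(self, factor: float) -> "FieldSolution":
        out = FieldSolution(
            mesh=self.mesh, operator=self.operator, V=self.V * factor,
            residual=self.residual * factor, load=self.load * factor,
            region_sigma=self.region_sigma, config=self.config,
            diagnostics=dict(self.diagnostics),
            contact_summary={k: {kk: vv * factor for kk, vv in d.items()}
                             for k, d in self.contact_summary.items()},
        )
        return out


# --------------------------------------------------------------------------
# case solve
# --------------------------------------------------------------------------

def _dof_representatives(op: FemOperator, vrep: np.ndarray,
                         fp_groups: List[np.ndarray]) -> np.ndarray:
    """Raw-DOF -> representative map from crack ties and floating-potential ties."""
    rep = np.arange(op.n_dofs, dtype=np.int64)
    rep[:op.n_vert] = vrep
    if op.order == 2:
        a = vrep[op.edges[:, 0]]
        b = vrep[op.edges[:, 1]]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keys = lo * op.n_dofs + hi
        ukeys, first = np.unique(keys, return_index=True)
        inv = np.searchsorted(ukeys, keys)
        rep[op.n_vert:] = op.n_vert + first[inv]
    for dofs in fp_groups:
        r = np.unique(rep[dofs])
        master = r[0]
        mask = np.isin(rep, r)
        rep[mask] = master
    return rep


def contact_exposed_name(mesh: TaggedMesh, k: int) -> str:
    name = f"contact_{k}_exposed"
    if name in mesh.facet_sets:
        return name
    return f"contact_{k}_active_rect"


def pcs_location(mesh: TaggedMesh, geom, k: int) -> np.ndarray:
    """Centre of the contact volume (the study's point-source position)."""
    b = geom.contact_boxes[k]
    return np.array([(b[0] + b[1]) / 2, (b[2] + b[3]) / 2, (b[4] + b[5]) / 2])


def solve_case(mesh: TaggedMesh, materials: MaterialLibrary,
               config: SourceConfiguration, *, geometry=None,
               order: int = 2, operator: Optional[FemOperator] = None,
               pcs_points: Optional[Dict[int, np.ndarray]] = None,
               extra_dirichlet: Optional[Dict[int, float]] = None,
               system_cache: Optional[Dict] = None,
               solver_rtol: Optional[float] = None,
               ) -> FieldSolution:
    """Assemble, constrain and solve one source configuration.

    ``geometry`` (a :class:`~stimfem.geometry.GeometryModel`) is required
    when a point current source is used so the source can be placed at the
    contact-volume centre; explicit coordinates may be given instead via
    ``pcs_points``.  EP sources are solved at 1 V and rescaled exactly to
    their target current.
    """
    op, K, sigma = assemble(mesh, materials, config, order=order,
                            operator=operator)
    n = op.n_dofs
    f = np.zeros(n)

    # --- ground and Dirichlet sets --------------------------------------
    if "outer_ground" not in mesh.facet_sets or \
            len(mesh.facet_sets["outer_ground"].tri) == 0:
        raise ConfigurationError("grounded outer boundary is required")
    dirichlet: Dict[int, float] = {}
    for d in op.facet_set_dofs("outer_ground"):
        dirichlet[int(d)] = 0.0

    fp_groups: List[np.ndarray] = []
    fp_currents: List[float] = []
    ep_contacts: List[Tuple[int, float]] = []

    for k, src in enumerate(config.sources):
        dofs = op.facet_set_dofs(contact_exposed_name(mesh, k))
        # in a y-symmetric half model, half of each prescribed current flows
        # through the modelled half; measured currents are doubled back
        amp_A = src.amplitude_mA * 1e-3 / symmetry_factor(mesh)
        if src.model == "pcs":
            if pcs_points and k in pcs_points:
                loc = np.asarray(pcs_points[k], dtype=float)
            else:
                if geometry is None:
                    raise ConfigurationError(
                        "pcs requires geometry or explicit pcs_points")
                loc = pcs_location(mesh, geometry, k)
            elem, lam = op.locate(loc[None, :])
            rname = mesh.region_names[int(mesh.region[elem[0]])]
            if sigma[rname] < materials.sigma_medium:
                raise ConfigurationError(
                    "point current source must be embedded in a conductor "
                    f"(landed in {rname}, sigma={sigma[rname]:g} S/m)")
            N = lam if op.order == 1 else p2_basis(lam)
            f[op.tet_dofs[elem[0]]] += amp_A * N[0]
        elif src.model == "bcs":
            fs = mesh.facet_sets[contact_exposed_name(mesh, k)]
            area = fs.total_area()
            if area <= 0:
                raise ConfigurationError("boundary current source on zero area")
            J = amp_A / (area * MM**2)                     # A/m^2 inward
            Nq, Wq = op.facet_basis(fs.tri)
            fd = op.facet_dofs(fs.tri)                     # (kf, nb)
            load = (fs.area[:, None] * MM**2) * (Wq @ Nq)[None, :] * J
            np.add.at(f, fd.ravel(), load.ravel())
        elif src.model == "ep":
            # EP rescaling compares against full-model delivered current
            ep_contacts.append((k, src.amplitude_mA * 1e-3))
            for d in dofs:
                if int(d) in dirichlet and dirichlet[int(d)] != 1.0:
                    raise ConfigurationError(
                        "conflicting Dirichlet data on shared vertices")
                dirichlet[int(d)] = 1.0
        elif src.model == "fp":
            fp_groups.append(dofs)
            fp_currents.append(amp_A)
        elif src.model == "inactive_grounded":
            for d in dofs:
                prev = dirichlet.get(int(d))
                if prev is not None and prev != 0.0:
                    raise ConfigurationError(
                        "conflicting Dirichlet data on shared vertices")
                dirichlet[int(d)] = 0.0
        # inactive_floating: condition of continuity -> nothing to do

    if extra_dirichlet:
        dirichlet.update(extra_dirichlet)

    # --- reduction: crack ties + FP ties ---------------------------------
    cache_key = None
    if system_cache is not None:
        fp_sig = tuple((len(d), int(d[0]), int(d[-1])) for d in fp_groups)
        dir_sig = hash(frozenset(dirichlet.items()))
        cache_key = (config.substrate_scheme, config.contact_conductivity,
                     dir_sig, fp_sig, order, solver_rtol)
    if cache_key is not None and cache_key in system_cache:
        sysd = system_cache[cache_key]
    else:
        vrep = tie_vertex_map(mesh, config.active_cracks())
        rep = _dof_representatives(op, vrep, fp_groups)
        used, red = np.unique(rep, return_inverse=True)
        n_red = len(used)
        R = sp.coo_matrix((np.ones(n), (np.arange(n), red)),
                          shape=(n, n_red)).tocsr()
        Kr = (R.T @ K @ R).tocsr()
        g = np.zeros(n_red)
        is_dir = np.zeros(n_red, dtype=bool)
        for d, val in dirichlet.items():
            rd = red[d]
            if is_dir[rd] and g[rd] != val:
                raise ConfigurationError(
                    "conflicting Dirichlet data on shared vertices")
            is_dir[rd] = True
            g[rd] = val
        free = np.flatnonzero(~is_dir)
        fixed = np.flatnonzero(is_dir)
        Kff = Kr[free][:, free].tocsc()
        rhs_fix = Kr[free][:, fixed] @ g[fixed]
        if op.order == 2 and Kff.shape[0] >= 30000:
            # two-level preconditioned CG: the vertex (P1) subspace plus
            # the conductivity-cluster constants are solved directly, the
            # quadratic remainder is Chebyshev-smoothed
            Pr = sp.coo_matrix(
                (np.concatenate([np.ones(op.n_vert),
                                 np.full(2 * (n - op.n_vert), 0.5)]),
                 (np.concatenate([np.arange(op.n_vert),
                                  np.arange(op.n_vert, n),
                                  np.arange(op.n_vert, n)]),
                  np.concatenate([np.arange(op.n_vert),
                                  op.edges[:, 0], op.edges[:, 1]]))),
                shape=(n, op.n_vert)).tocsr()
            P_red = (R.T @ Pr @ R[:op.n_vert, :]).tocsr()
            vert_red = np.unique(red[np.arange(op.n_vert)])
            col_free = np.flatnonzero(~is_dir[vert_red])
            Pf = P_red[free][:, vert_red[col_free]]
            Z = _cluster_indicators(op, mesh, sigma, materials, Kr, red,
                                    rep, free)
            solver = _make_spd_solver(Kff, coords=op.dof_coords[used[free]],
                                      P=Pf, Z=Z,
                                      **({"rtol": solver_rtol}
                                         if solver_rtol else {}))
        else:
            solver = _make_spd_solver(Kff, coords=op.dof_coords[used[free]],
                                      **({"rtol": solver_rtol}
                                         if solver_rtol else {}))
        sysd = dict(R=R, red=red, free=free, g=g, rhs_fix=rhs_fix,
                    solver=solver)
        if cache_key is not None:
            system_cache[cache_key] = sysd

    R, red, free, g, rhs_fix, solver = (
        sysd["R"], sysd["red"], sysd["free"], sysd["g"], sysd["rhs_fix"],
        sysd["solver"])
    fr = R.T @ f
    for dofs, amp_A in zip(fp_groups, fp_currents):
        fr[red[dofs[0]]] += amp_A
    rhs = fr[free] - rhs_fix
    x, n_iter = solver(rhs)
    if not np.all(np.isfinite(x)):
        raise SolverError("solver produced non-finite potentials")
    sol_red = g.copy()
    sol_red[free] = x
    V = sol_red[red]

    residual = K @ V - f
    r_red = R.T @ residual
    rel_res = float(np.linalg.norm(r_red[free])
                    / max(np.linalg.norm(fr), 1e-300))
    sol = FieldSolution(mesh=mesh, operator=op, V=V, residual=residual,
                        load=f, region_sigma=sigma, config=config,
                        diagnostics={"rel_residual": rel_res,
                                     "iterations": float(n_iter),
                                     "n_dofs": float(len(free))})

    # --- EP exact rescaling ----------------------------------------------
    if ep_contacts:
        if len(ep_contacts) == 1 and all(
                s.model in ("ep", "inactive_floating", "inactive_grounded")
                for s in config.sources):
            k, target_A = ep_contacts[0]
            delivered = ground_current(sol)                # amperes
            if target_A != 0.0:
                sol = sol.scaled(target_A / delivered)
        # multi-EP (simultaneous bipolar) solves are returned unscaled; the
        # caller calibrates per-contact voltages beforehand.

    _summarise_contacts(sol)
    return sol


def _nested_dissection(coords: np.ndarray, A: sp.csr_matrix,
                       leaf: int = 512) -> np.ndarray:
    """Geometric nested-dissection ordering for the structured-grid graph.

    Recursive bisection at the median coordinate of the longest axis; the
    separator is the set of left-side DOFs adjacent to the right side.
    Median-of-coordinate (not median-of-count) keeps separators in the
    coarsely meshed far field, which is what makes the fill-in small on
    these strongly graded grids.
    """
    import sys
    indptr, indices = A.indptr, A.indices
    n = len(coords)
    order = np.empty(n, dtype=np.int64)
    pos = [0]
    inright = np.zeros(A.shape[0], dtype=bool)

    def emit(idx):
        order[pos[0]:pos[0] + len(idx)] = idx
        pos[0] += len(idx)

    def rec(idx):
        if len(idx) <= leaf:
            emit(idx)
            return
        c = coords[idx]
        ax = int(np.argmax(c.max(axis=0) - c.min(axis=0)))
        med = np.median(c[:, ax])
        lm = c[:, ax] <= med
        left, right = idx[lm], idx[~lm]
        if len(left) == 0 or len(right) == 0:
            emit(idx)
            return
        inright[right] = True
        st = indptr[left]
        ln = indptr[left + 1] - st
        flat = (np.repeat(st, ln) + np.arange(ln.sum())
                - np.repeat(np.cumsum(ln) - ln, ln))
        nbr_right = inright[indices[flat]]
        seg = np.zeros(len(left) + 1, dtype=np.int64)
        np.cumsum(ln, out=seg[1:])
        has_right = np.add.reduceat(nbr_right, seg[:-1]) > 0
        has_right[ln == 0] = False
        inright[right] = False
        rec(left[~has_right])
        rec(right)
        emit(left[has_right])

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        rec(np.arange(n, dtype=np.int64))
    finally:
        sys.setrecursionlimit(old)
    return order


def _direct_factor(K: sp.csc_matrix, coords: Optional[np.ndarray]):
    """SuperLU factorisation, geometrically nested-dissection ordered."""
    if coords is not None:
        perm = _nested_dissection(coords, K.tocsr())
        Kp = K[perm][:, perm].tocsc()
        spec = "NATURAL"
    else:
        perm = None
        Kp = K.tocsc()
        spec = "MMD_AT_PLUS_A"
    try:
        lu = spla.splu(Kp, permc_spec=spec, options=dict(SymmetricMode=True))
    except RuntimeError as exc:   # pragma: no cover - singular systems
        raise SolverError(f"direct solve failed: {exc}") from exc

    def solve(b):
        if perm is None:
            return lu.solve(b)
        xp = lu.solve(b[perm])
        out = np.empty_like(xp)
        out[perm] = xp
        return out

    return solve


def _cluster_indicators(op: FemOperator, mesh: TaggedMesh,
                        sigma: Dict[str, float], materials: MaterialLibrary,
                        Kr: sp.csr_matrix, red: np.ndarray, rep: np.ndarray,
                        free: np.ndarray) -> Optional[np.ndarray]:
    """Indicator vectors of high/low-conductivity clusters on the free DOFs.

    After symmetric diagonal scaling the stiffness matrix retains a handful
    of near-null modes: the constants over each connected platinum component
    and over each floating silicone block.  Deflating them through the
    preconditioner's coarse space is what makes conjugate gradients work at
    a conductivity contrast of ~1e19.
    """
    from scipy.sparse.csgraph import connected_components
    sig_of_rid = np.zeros(max(mesh.region_names) + 1)
    for rid, nm in mesh.region_names.items():
        sig_of_rid[rid] = sigma[nm]
    sig_el = sig_of_rid[mesh.region]
    smax = np.zeros(op.n_dofs)
    np.maximum.at(smax, op.tet_dofs.ravel(),
                  np.repeat(sig_el, op.tet_dofs.shape[1]))
    n_red = Kr.shape[0]
    smax_red = np.zeros(n_red)
    np.maximum.at(smax_red, red[rep], smax)
    freepos = -np.ones(n_red, dtype=np.int64)
    freepos[free] = np.arange(len(free))
    smed = materials.sigma_medium
    cols = []
    for mask in (smax_red > 100 * smed, smax_red < smed / 100):
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        ncmp, lab = connected_components(Kr[idx][:, idx], directed=False)
        for c in range(ncmp):
            fp = freepos[idx[lab == c]]
            fp = fp[fp >= 0]
            if len(fp):
                z = np.zeros(len(free))
                z[fp] = 1.0
                cols.append(z)
    return np.column_stack(cols) if cols else None


def _make_spd_solver(Kff: sp.csc_matrix,
                     coords: Optional[np.ndarray] = None,
                     P: Optional[sp.csr_matrix] = None,
                     Z: Optional[np.ndarray] = None,
                     rtol: float = 1e-8, maxiter: int = 1200):
    """Reusable solver for a symmetric positive-definite reduced system.

    The system is symmetrically diagonal-scaled (conditioning guard for the
    ~1e19 silicone-to-platinum conductivity ratio).  Without a prolongation
    ``P`` it is factorised directly with SuperLU under a geometric
    nested-dissection ordering.  With ``P`` (quadratic elements) it is
    solved by conjugate gradients with a symmetric two-level V(1,1)
    preconditioner: Chebyshev(4) smoothing plus an exact solve of the
    Galerkin-projected vertex subproblem, whose basis is augmented with the
    conductivity-cluster indicator vectors ``Z`` (near-null-space
    deflation).  Returns ``solve(rhs) -> (x, n_iterations)``.
    """
    d = Kff.diagonal()
    if np.any(d <= 0):
        raise SolverError("non-positive diagonal: singular or disconnected system")
    s = 1.0 / np.sqrt(d)
    S = sp.diags(s)
    Ks = (S @ Kff @ S).tocsr()

    if P is None:
        direct = _direct_factor(Ks.tocsc(), coords)

        def solve_direct(rhs):
            rs = rhs * s
            xs = direct(rs)
            xs += direct(rs - Ks @ xs)     # one refinement step
            return xs * s, 0

        return solve_direct

    Paug = (S @ P).tocsr()
    if Z is not None:
        Paug = sp.hstack([Paug, sp.csr_matrix(Z / s[:, None])]).tocsr()
    A1 = (Paug.T @ Ks @ Paug).tocsc()
    coarse = _direct_factor(A1, None)

    # deterministic power iteration for the spectral bound of the smoother
    x = np.cos(np.arange(Ks.shape[0], dtype=float))
    for _ in range(20):
        x = Ks @ x
        x /= np.linalg.norm(x)
    lmax = float(x @ (Ks @ x)) * 1.05
    lo, hi = 0.03 * lmax, lmax
    theta, delta = (hi + lo) / 2, (hi - lo) / 2
    sig1 = theta / delta

    def smooth(r):
        rho = 1.0 / sig1
        dvec = r / theta
        z = dvec.copy()
        res = r - Ks @ z
        for _ in range(3):
            rho_new = 1.0 / (2 * sig1 - rho)
            dvec = rho_new * rho * dvec + (2 * rho_new / delta) * res
            z = z + dvec
            res = res - Ks @ dvec
            rho = rho_new
        return z

    def precond(r):
        r = np.asarray(r, dtype=float)
        z1 = smooth(r)
        r1 = r - Ks @ z1
        z2 = z1 + Paug @ coarse(Paug.T @ r1)
        r2 = r - Ks @ z2
        return z2 + smooth(r2)

    M = spla.LinearOperator(Ks.shape, matvec=precond, dtype=float)

    def solve_cg(rhs):
        rs = rhs * s
        it = [0]

        def cb(_):
            it[0] += 1

        xs, info = spla.cg(Ks, rs, rtol=rtol, maxiter=maxiter, M=M,
                           callback=cb)
        if info != 0:
            raise SolverError(f"conjugate gradients failed to converge "
                              f"(info={info}, iterations={it[0]})")
        return xs * s, it[0]

    return solve_cg


def symmetry_factor(mesh: TaggedMesh) -> float:
    """Current multiplier restoring full-model semantics (2 for half models)."""
    return 2.0 if getattr(mesh, "symmetric_y", False) else 1.0


def ground_current(sol: FieldSolution) -> float:
    """Net current (A) leaving through the grounded outer boundary (reaction).

    The constrained-row residual at a ground DOF equals minus the current
    leaving the domain there, by the weak form with J = -sigma*grad V.
    Reported on the full-model scale.
    """
    dofs = sol.operator.facet_set_dofs("outer_ground")
    return float(-sol.residual[dofs].sum()) * symmetry_factor(sol.mesh)


def _summarise_contacts(sol: FieldSolution) -> None:
    mesh = sol.mesh
    n_contacts = sum(1 for nm in mesh.facet_sets
                     if nm.startswith("contact_") and
                     (nm.endswith("_exposed") or nm.endswith("_active_rect")))
    for k in range(n_contacts):
        v = sol.contact_surface_potentials(k)
        if len(v) == 0:
            continue
        sol.contact_summary[k] = {
            "mean_V": float(v.mean()),
            "min_V": float(v.min()),
            "max_V": float(v.max()),
        }
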