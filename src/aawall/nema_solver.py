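"""Inverse membrane equilibrium: wall stress from geometry and pressure alone.

A pressurized thin-walled vessel imaged in its deformed configuration is
statically determinate: the in-plane Cauchy stress follows from the
equilibrium equations and the applied load, with no constitutive material
model.  On each flat triangle with covariant basis ``g_1, g_2`` (metric
determinant ``g``), membrane equilibrium reads

    (1/sqrt(g)) * d/dxi^beta ( sqrt(g) h sigma^{alpha beta} g_alpha ) + p n = 0

with uniform thickness ``h``, intraluminal pressure ``p`` applied outwards
along the surface normal ``n``, and ``sigma^{alpha beta}`` the in-plane
Cauchy components in the local contravariant basis.

Discretization: three stress unknowns per vertex, expressed in a
vertex-local orthonormal tangent frame, interpolated linearly over each
element (each nodal 2x2 surface tensor is promoted to its Cartesian 3x3
form, and the element field is the linear blend of the three corner
tensors).  Galerkin testing with hat functions in each Cartesian direction
yields one 3-vector equilibrium equation per vertex; rows at the fixed
proximal/distal rings are removed, since reaction tractions there are not
solved for.  The system is linear in the stress unknowns for a fixed
deformed geometry and is solved by regularized least squares inside a
Newton loop (which therefore converges in a single step).

Because equilibrium rows are removed at the fixed rings, the discrete
system is underdetermined: it admits self-equilibrated stress fields
(and, on equal-order nodal interpolation, spurious oscillatory near-null
modes).  The solver selects the physically smooth solution by penalizing,
for every mesh edge, the difference between the two nodal stress tensors
after parallel transport (rotating one vertex tangent plane onto the
other).  Laplace-type fields — isotropic tension on a sphere, hoop
tension on a cylinder — are covariantly constant under this transport, so
the penalty selects among equilibrium solutions while leaving such fields
essentially unbiased.

Geometry is in mm, pressure is supplied in mmHg, and every reported
stress is in N/cm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh_builder import SurfaceMesh

__all__ = [
    "ElementFrame",
    "MembraneProblem",
    "StressField",
    "BiomechParams",
    "element_frame",
    "pressure_to_stress_units",
    "assemble_system",
    "assemble_residual",
    "solve_membrane_stress",
    "biomech_params",
    "element_distance_to_nodes",
]

MMHG_TO_N_PER_CM2 = 133.322e-4  # 1 mmHg = 133.322 Pa = 133.322e-4 N/cm^2


def pressure_to_stress_units(p_mmhg: float) -> float:
    """Convert pressure from mmHg to N/cm^2 (the reporting unit for stress)."""
    if p_mmhg < 0:
        raise ValueError("pressure must be non-negative")
    return p_mmhg * MMHG_TO_N_PER_CM2


@dataclass
class ElementFrame:
    """Covariant surface basis of one flat triangle.

    ``g_1 = v1 - v0`` and ``g_2 = v2 - v0`` map the reference triangle
    {(0,0), (1,0), (0,1)} onto the element; the metric is
    ``g_ab = g_a . g_b`` with determinant ``g = (2 * area)^2``.
    """

    g1: np.ndarray
    g2: np.ndarray
    normal: np.ndarray
    metric: np.ndarray       # (2, 2)
    g_det: float

    @property
    def dual_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Contravariant basis vectors g^1, g^2 (g^a . g_b = delta^a_b)."""
        inv = np.linalg.inv(self.metric)
        return (inv[0, 0] * self.g1 + inv[0, 1] * self.g2,
                inv[1, 0] * self.g1 + inv[1, 1] * self.g2)


def element_frame(verts: np.ndarray) -> ElementFrame:
    """Local covariant basis, metric and outward normal of one triangle."""
    v = np.asarray(verts, dtype=float)
    if v.shape != (3, 3):
        raise ValueError("verts must be a (3, 3) array of triangle vertices")
    g1 = v[1] - v[0]
    g2 = v[2] - v[0]
    cross = np.cross(g1, g2)
    nrm = np.linalg.norm(cross)
    if nrm <= 1e-14:
        raise ValueError("degenerate (zero-area) triangle")
    metric = np.array([[g1 @ g1, g1 @ g2], [g1 @ g2, g2 @ g2]])
    return ElementFrame(g1=g1, g2=g2, normal=cross / nrm, metric=metric,
                        g_det=float(np.linalg.det(metric)))


@dataclass
class MembraneProblem:
    """A pressurized membrane with fixed end rings.

    Defaults are the physiological reference load used throughout the
    package: 1.5 mm uniform wall thickness and 93.3 mmHg mean arterial
    pressure.
    """

    mesh: SurfaceMesh
    thickness_mm: float = 1.5
    pressure_mmhg: float = 93.3
    fixed_nodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        if self.pressure_mmhg < 0:
            raise ValueError("pressure must be non-negative")
        if self.fixed_nodes is None:
            if len(self.mesh.proximal_ring) == 0 or len(self.mesh.distal_ring) == 0:
                raise ValueError(
                    "mesh must carry proximal and distal boundary rings "
                    "(or pass fixed_nodes explicitly)")
            self.fixed_nodes = np.union1d(self.mesh.proximal_ring,
                                          self.mesh.distal_ring)
        else:
            self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=int))
        if self.fixed_nodes.size and (self.fixed_nodes.min() < 0 or
                                      self.fixed_nodes.max() >= self.mesh.n_vertices):
            raise ValueError("fixed_nodes out of vertex range")


@dataclass
class StressField:
    """Per-element Cauchy stress of a solved membrane problem (N/cm^2)."""

    sigma_contra: np.ndarray     # (F, 3): sigma^11, sigma^22, sigma^12 in local bases
    sigma1: np.ndarray           # (F,) first (max) principal stress
    sigma2: np.ndarray           # (F,) second principal stress
    areas: np.ndarray            # (F,) element areas, mm^2
    near_boundary: np.ndarray    # (F,) True where the element touches a fixed node
    centroids: np.ndarray        # (F, 3) mm
    iterations: int = 1
    residual: float = 0.0


# ---------------------------------------------------------------------------
# assembly


def _vertex_frames(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal tangent frame (e1, e2) and unit normal per vertex.

    Normals are area-weighted averages of incident face normals; e1 is a
    deterministic tangent (projection of a global axis least aligned with
    the normal) and e2 completes the right-handed triad.
    """
    normals_f, areas = mesh.face_normals_and_areas()
    vn = np.zeros((mesh.n_vertices, 3))
    w = (normals_f * areas[:, None])
    for k in range(3):
        np.add.at(vn, mesh.triangles[:, k], w)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms == 0] = 1.0
    vn /= norms[:, None]

    # pick per-vertex the global axis least aligned with the normal
    axes = np.eye(3)
    pick = np.argmin(np.abs(vn), axis=1)
    a = axes[pick]
    e1 = a - (np.einsum("ij,ij->i", a, vn))[:, None] * vn
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(vn, e1)
    return e1, e2, vn


def _hat_gradients(mesh: SurfaceMesh):
    """Surface gradients of the three hat functions per element, plus geometry."""
    v = mesh.vertices
    t = mesh.triangles
    v0, v1, v2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    cross = np.cross(v1 - v0, v2 - v0)
    two_a = np.linalg.norm(cross, axis=1)
    if np.any(two_a <= 1e-14):
        raise ValueError("degenerate triangle in mesh")
    n = cross / two_a[:, None]
    areas = two_a / 2.0
    grads = np.stack([
        np.cross(n, v2 - v1) / two_a[:, None],
        np.cross(n, v0 - v2) / two_a[:, None],
        np.cross(n, v1 - v0) / two_a[:, None],
    ], axis=1)  # (F, 3 slots, 3 xyz)
    return grads, n, areas


def _basis_tensors(e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """Per-vertex Cartesian forms of the three stress dof basis tensors.

    Dof order per vertex: (s11, s22, s12) in the vertex tangent frame.
    Returns (N, 3 dofs, 3, 3).
    """
    t11 = np.einsum("ni,nj->nij", e1, e1)
    t22 = np.einsum("ni,nj->nij", e2, e2)
    t12 = np.einsum("ni,nj->nij", e1, e2) + np.einsum("ni,nj->nij", e2, e1)
    return np.stack([t11, t22, t12], axis=1)


def assemble_system(problem: MembraneProblem):
    """Assemble the free-node equilibrium system ``A s = b``.

    Rows: 3 Cartesian equilibrium equations per non-fixed vertex.
    Columns: 3 stress dofs per vertex (fixed vertices keep their dofs —
    only their equations are removed).  Returns ``(A, b, meta)`` where
    meta carries the per-vertex frames for later stress recovery.
    """
    mesh = problem.mesh
    nv = mesh.n_vertices
    tri = mesh.triangles
    h = problem.thickness_mm
    p = pressure_to_stress_units(problem.pressure_mmhg)

    e1, e2, vn = _vertex_frames(mesh)
    bten = _basis_tensors(e1, e2)               # (N, 3, 3, 3)
    grads, n_f, areas = _hat_gradients(mesh)    # (F,3,3), (F,3), (F,)

    rows, cols, vals = [], [], []
    coef = (h * areas / 3.0)
    for i_slot in range(3):          # test (equation) vertex slot
        gi = grads[:, i_slot, :]     # (F, 3)
        test_nodes = tri[:, i_slot]
        for v_slot in range(3):      # trial (dof) vertex slot
            trial_nodes = tri[:, v_slot]
            tm = bten[trial_nodes]   # (F, 3 dofs, 3, 3)
            # block[f, k, m] = coef * (T_m gi)_k
            block = coef[:, None, None] * np.einsum("fmkl,fl->fkm", tm, gi)
            fidx = np.arange(len(tri))
            r = (3 * test_nodes[:, None, None]
                 + np.arange(3)[None, :, None]).repeat(3, axis=2)
            c = (3 * trial_nodes[:, None, None]
                 + np.arange(3)[None, None, :]).repeat(3, axis=1)
            rows.append(r.ravel())
            cols.append(c.ravel())
            vals.append(block.ravel())

    A_full = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * nv, 3 * nv)).tocsr()

    b_full = np.zeros(3 * nv)
    load = (p * areas / 3.0)[:, None] * n_f     # (F, 3)
    for i_slot in range(3):
        np.add.at(b_full.reshape(nv, 3), tri[:, i_slot], load)

    free = np.setdiff1d(np.arange(nv), problem.fixed_nodes)
    free_rows = (3 * free[:, None] + np.arange(3)[None, :]).ravel()
    meta = dict(e1=e1, e2=e2, vertex_normals=vn, free=free,
                grads=grads, face_normals=n_f, areas=areas)
    return A_full[free_rows], b_full[free_rows], meta


def _transport_smoothness(mesh: SurfaceMesh, e1: np.ndarray, e2: np.ndarray,
                          vn: np.ndarray) -> sp.csr_matrix:
    """Edge-difference operator on parallel-transported nodal stress tensors.

    For each mesh edge (u, v), six rows measure the Cartesian components
    of ``R_uv T_u R_uv^T - T_v``, where ``R_uv`` is the minimal rotation
    taking the vertex normal at u onto the one at v.  Off-diagonal
    components carry weight sqrt(2) so the row block is the Frobenius
    seminorm of the transported tensor difference.
    """
    bten = _basis_tensors(e1, e2)
    edges = np.unique(mesh.edges(), axis=0)
    u, v = edges[:, 0], edges[:, 1]
    ne = len(edges)
    nu, nv = vn[u], vn[v]
    c = np.einsum("ei,ei->e", nu, nv)
    k = np.cross(nu, nv)
    s2 = np.einsum("ei,ei->e", k, k)
    K = np.zeros((ne, 3, 3))
    K[:, 0, 1] = -k[:, 2]
    K[:, 0, 2] = k[:, 1]
    K[:, 1, 0] = k[:, 2]
    K[:, 1, 2] = -k[:, 0]
    K[:, 2, 0] = -k[:, 1]
    K[:, 2, 1] = k[:, 0]
    # Rodrigues: R = I + K + K^2 (1 - c)/|k|^2; identity when normals align
    fac = np.where(s2 > 1e-16, (1 - c) / np.maximum(s2, 1e-16), 0.0)
    R = np.eye(3)[None] + K + fac[:, None, None] * np.einsum("eij,ejk->eik", K, K)
    btu = np.einsum("eij,emjk,elk->emil", R, bten[u], R)
    btv = bten[v]
    comps = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    rows, cols, vals = [], [], []
    for comp, (i, j) in enumerate(comps):
        w = np.sqrt(2.0) if i != j else 1.0
        for sgn, nodes, bt in ((1.0, u, btu[:, :, i, j]), (-1.0, v, btv[:, :, i, j])):
            r = (np.arange(ne) * 6 + comp)[:, None].repeat(3, axis=1)
            cidx = 3 * nodes[:, None] + np.arange(3)[None, :]
            rows.append(r.ravel())
            cols.append(cidx.ravel())
            vals.append((sgn * w * bt).ravel())
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(6 * ne, 3 * mesh.n_vertices)).tocsr()


def assemble_residual(problem: MembraneProblem, dofs: np.ndarray) -> np.ndarray:
    """Equilibrium residual at the free nodes for a given nodal stress state.

    ``dofs`` is length ``3 * n_vertices``, ordered (s11, s22, s12) per
    vertex in the vertex tangent frames.
    """
    if len(dofs) != 3 * problem.mesh.n_vertices:
        raise ValueError(
            f"expected {3 * problem.mesh.n_vertices} dofs, got {len(dofs)}")
    A, b, _ = assemble_system(problem)
    return A @ np.asarray(dofs, dtype=float) - b


# ---------------------------------------------------------------------------
# solve


def solve_membrane_stress(problem: MembraneProblem, tol: float = 1e-8,
                          max_iter: int = 100, tikhonov: float = 1e-10,
                          smoothing: float = 1.0) -> StressField:
    """Solve for the element Cauchy stress field of a pressurized membrane.

    Minimizes ``|A s - b|^2 + lam |R s|^2`` where ``A s = b`` is the
    assembled equilibrium system and ``R`` the parallel-transport
    edge-difference operator (see :func:`_transport_smoothness`);
    ``smoothing`` sets ``lam`` relative to the natural scales of the two
    operators, and a tiny Tikhonov term guards exact rank deficiency.
    Newton iteration on the regularized normal equations; because the
    system is linear in the stress unknowns for fixed geometry, one step
    reaches the optimum and later steps only confirm stationarity.
    Convergence is declared when the projected gradient drops below
    ``tol`` relative to the load; otherwise an error carrying the final
    residual is raised.
    """
    A, b, meta = assemble_system(problem)
    n_dof = A.shape[1]
    AtA = (A.T @ A).tocsc()
    Atb = A.T @ b
    scale = AtA.diagonal().mean() if AtA.nnz else 1.0
    # Tikhonov on the Frobenius norm of the nodal tensors (shear counts
    # twice), which is frame-invariant — a plain dof-norm would make the
    # solution depend on the arbitrary vertex frame orientation
    frob_w = sp.diags(np.tile([1.0, 1.0, 2.0], n_dof // 3), format="csc")
    reg = AtA + tikhonov * scale * frob_w
    if smoothing > 0:
        R = _transport_smoothness(problem.mesh, meta["e1"], meta["e2"],
                                  meta["vertex_normals"])
        RtR = (R.T @ R).tocsc()
        r_scale = RtR.diagonal().mean() if RtR.nnz else 1.0
        reg = reg + (smoothing * scale / r_scale) * RtR

    # Newton step + iterative refinement on the factorized normal matrix;
    # iterate until the projected gradient stagnates at machine level
    s = np.zeros(n_dof)
    b_norm = max(np.linalg.norm(Atb), 1e-300)
    solve = spla.factorized(reg)
    it = 0
    prev = np.inf
    for it in range(1, max_iter + 1):
        grad = reg @ s - Atb
        rel_grad = float(np.linalg.norm(grad) / b_norm)
        if rel_grad < 1e-14 or rel_grad >= 0.5 * prev:
            break
        prev = rel_grad
        s = s - solve(grad)
    rel_grad = float(np.linalg.norm(reg @ s - Atb) / b_norm)
    if rel_grad >= tol:
        raise RuntimeError(
            f"membrane solve did not converge: relative gradient {rel_grad:.3e} "
            f"after {it} iterations")
    residual = float(np.linalg.norm(A @ s - b) / max(np.linalg.norm(b), 1e-300))

    return _recover_stress(problem, s, meta, iterations=it, residual=residual)


def _recover_stress(problem: MembraneProblem, s: np.ndarray, meta: dict,
                    iterations: int, residual: float) -> StressField:
    """Centroid stress per element from the nodal solution."""
    mesh = problem.mesh
    tri = mesh.triangles
    bten = _basis_tensors(meta["e1"], meta["e2"])       # (N, 3, 3, 3)
    s_nodes = s.reshape(-1, 3)
    # nodal Cartesian tensors, then the element centroid value of the
    # linear interpolant = mean of the three corner tensors
    T_nodes = np.einsum("nm,nmij->nij", s_nodes, bten)  # (N, 3, 3)
    T_c = T_nodes[tri].mean(axis=1)                     # (F, 3, 3)

    v = mesh.vertices
    v0, v1, v2 = v[tri[:, 0]], v[tri[:, 1]], v[tri[:, 2]]
    g1 = v1 - v0
    g2 = v2 - v0
    cross = np.cross(g1, g2)
    two_a = np.linalg.norm(cross, axis=1)
    n = cross / two_a[:, None]

    # orthonormal element frame for physical components
    eh1 = g1 / np.linalg.norm(g1, axis=1)[:, None]
    eh2 = np.cross(n, eh1)
    m11 = np.einsum("fi,fij,fj->f", eh1, T_c, eh1)
    m22 = np.einsum("fi,fij,fj->f", eh2, T_c, eh2)
    m12 = np.einsum("fi,fij,fj->f", eh1, T_c, eh2)
    tr = m11 + m22
    disc = np.sqrt(np.maximum(((m11 - m22) / 2.0) ** 2 + m12 ** 2, 0.0))
    sigma1 = tr / 2.0 + disc
    sigma2 = tr / 2.0 - disc

    # contravariant components in the element covariant basis
    g11 = np.einsum("fi,fi->f", g1, g1)
    g22 = np.einsum("fi,fi->f", g2, g2)
    g12 = np.einsum("fi,fi->f", g1, g2)
    det = g11 * g22 - g12 ** 2
    # dual basis vectors
    d1 = (g22[:, None] * g1 - g12[:, None] * g2) / det[:, None]
    d2 = (-g12[:, None] * g1 + g11[:, None] * g2) / det[:, None]
    s11 = np.einsum("fi,fij,fj->f", d1, T_c, d1)
    s22 = np.einsum("fi,fij,fj->f", d2, T_c, d2)
    s12 = np.einsum("fi,fij,fj->f", d1, T_c, d2)

    fixed = np.zeros(mesh.n_vertices, dtype=bool)
    fixed[problem.fixed_nodes] = True
    near_boundary = fixed[tri].any(axis=1)

    return StressField(
        sigma_contra=np.column_stack([s11, s22, s12]),
        sigma1=sigma1, sigma2=sigma2,
        areas=two_a / 2.0,
        near_boundary=near_boundary,
        centroids=(v0 + v1 + v2) / 3.0,
        iterations=iterations,
        residual=residual,
    )


def element_distance_to_nodes(mesh: SurfaceMesh, nodes) -> np.ndarray:
    """Per-element graph distance (in vertex rings) from a node set.

    Breadth-first over the vertex adjacency; an element's distance is the
    minimum over its three vertices.  Used to identify elements far
    enough from the fixed rings for boundary effects to have decayed.
    """
    from collections import defaultdict, deque

    adj = defaultdict(set)
    for a, b, c in mesh.triangles:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    dist = {int(v): 0 for v in np.asarray(nodes, dtype=int)}
    queue = deque(dist)
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return np.array([min(dist.get(a, np.inf), dist.get(b, np.inf),
                         dist.get(c, np.inf)) for a, b, c in mesh.triangles])


# ---------------------------------------------------------------------------
# biomechanical summary parameters


@dataclass
class BiomechParams:
    """The five wall-stress summary parameters, in N/cm^2."""

    peak_wall_stress: float
    p99: float
    p75: float
    mean_stress: float
    saws: float

    def as_dict(self) -> dict[str, float]:
        return dict(peak_wall_stress=self.peak_wall_stress, p99=self.p99,
                    p75=self.p75, mean_stress=self.mean_stress, saws=self.saws)


def _weighted_percentile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(q / 100.0, cw, x))


def biomech_params(fld: StressField, area_weighted_percentiles: bool = False) -> BiomechParams:
    """Summary parameters of the first principal stress field.

    Peak is the element maximum; the 99th/75th percentiles and the mean
    are unweighted over elements by default; SAWS (spatially averaged wall
    stress) is always the area-weighted mean.  Set
    ``area_weighted_percentiles`` to weight the percentiles and mean by
    element area as well.
    """
    s1 = np.asarray(fld.sigma1, dtype=float)
    a = np.asarray(fld.areas, dtype=float)
    if s1.size == 0:
        raise ValueError("empty stress field")
    saws = float((s1 * a).sum() / a.sum())
    if area_weighted_percentiles:
        p99 = _weighted_percentile(s1, a, 99.0)
        p75 = _weighted_percentile(s1, a, 75.0)
        mean = saws
    else:
        p99 = float(np.percentile(s1, 99.0))
        p75 = float(np.percentile(s1, 75.0))
        mean = float(s1.mean())
    return BiomechParams(peak_wall_stress=float(s1.max()), p99=p99, p75=p75,
                         mean_stress=mean, saws=saws)
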