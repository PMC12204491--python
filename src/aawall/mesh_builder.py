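"""Surface mesh construction from stacked contours, and diameter profiles.

A vessel wall segmented slice-by-slice becomes a stack of closed planar
contours at known z positions (slice index times slice spacing).  Lofting
resamples every contour to a common circumferential count, aligns ring
start points, and connects adjacent rings with triangle strips, producing
an open tube: a manifold with exactly two boundary loops (Euler
characteristic 0), outward-oriented, with the first ring tagged proximal
and the last distal.

The maximum-diameter surrogate used clinically is the hydraulic diameter
``D_h = 4 A / P`` of each cross-section (area over perimeter; equal to the
geometric diameter for a circle), tracked per slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .contour_ops import Contour, polygon_area, polygon_perimeter, resample_contour

__all__ = [
    "SurfaceMesh",
    "DiameterProfile",
    "hydraulic_diameter",
    "max_hydraulic_diameter",
    "loft_contours",
    "mask_to_contour_stack",
    "write_mesh",
    "read_mesh",
    "mesh_to_json",
    "mesh_from_json",
]


@dataclass
class SurfaceMesh:
    """Oriented triangulated open-tube surface with tagged end rings."""

    vertices: np.ndarray            # (V, 3) mm
    triangles: np.ndarray           # (F, 3) vertex indices
    proximal_ring: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    distal_ring: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        self.proximal_ring = np.asarray(self.proximal_ring, dtype=int).ravel()
        self.distal_ring = np.asarray(self.distal_ring, dtype=int).ravel()

    # -- topology -----------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.triangles)

    def edges(self) -> np.ndarray:
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.sort(e, axis=1)

    def n_edges(self) -> int:
        return len(np.unique(self.edges(), axis=0))

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges() + self.n_faces

    def boundary_edges(self) -> np.ndarray:
        """Directed boundary edges, in the orientation induced by the faces."""
        t = self.triangles
        directed = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        und = np.sort(directed, axis=1)
        _, inv, counts = np.unique(und, axis=0, return_inverse=True,
                                   return_counts=True)
        return directed[counts[inv] == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Vertex loops of the boundary, each as an ordered index array."""
        edges = self.boundary_edges()
        nxt = {int(a): int(b) for a, b in edges}
        loops = []
        remaining = set(nxt)
        while remaining:
            start = min(remaining)
            loop = [start]
            cur = nxt[start]
            remaining.discard(start)
            while cur != start:
                loop.append(cur)
                remaining.discard(cur)
                cur = nxt[cur]
            loops.append(np.array(loop, dtype=int))
        return loops

    # -- geometry -----------------------------------------------------------
    def face_normals_and_areas(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norms = np.linalg.norm(cross, axis=1)
        areas = norms / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cross / norms[:, None]
        return normals, areas

    def area(self) -> float:
        return float(self.face_normals_and_areas()[1].sum())

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def capped_signed_volume(self) -> float:
        """Signed volume after fanning caps onto both boundary loops.

        Positive for an outward-oriented tube; used to verify (and fix)
        global orientation.
        """
        v = self.vertices
        faces = [self.triangles]
        extra_vertices = [v]
        next_idx = len(v)
        for edge_loop in self._boundary_edge_loops():
            centroid = v[np.unique(edge_loop)].mean(axis=0)
            extra_vertices.append(centroid[None, :])
            # cap triangle traverses each boundary edge in reverse
            cap = np.column_stack([
                np.full(len(edge_loop), next_idx),
                edge_loop[:, 1], edge_loop[:, 0]])
            faces.append(cap)
            next_idx += 1
        vv = np.vstack(extra_vertices)
        ff = np.vstack(faces)
        a, b, c = vv[ff[:, 0]], vv[ff[:, 1]], vv[ff[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def _boundary_edge_loops(self) -> list[np.ndarray]:
        edges = self.boundary_edges()
        nxt = {int(a): (int(a), int(b)) for a, b in edges}
        loops = []
        remaining = set(nxt)
        while remaining:
            start = min(remaining)
            loop = []
            cur = start
            while True:
                a, b = nxt[cur]
                loop.append((a, b))
                remaining.discard(cur)
                cur = b
                if cur == start:
                    break
            loops.append(np.array(loop, dtype=int))
        return loops

    def validate(self) -> None:
        """Raise unless this is a clean open tube."""
        und = self.edges()
        _, counts = np.unique(und, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise ValueError("non-manifold edge (shared by >2 faces)")
        n_loops = len(self.boundary_loops())
        if n_loops != 2:
            raise ValueError(f"expected 2 boundary loops, found {n_loops}")
        if self.euler_characteristic() != 0:
            raise ValueError(
                f"Euler characteristic {self.euler_characteristic()} != 0")
        _, areas = self.face_normals_and_areas()
        if np.any(areas <= 0) or np.any(~np.isfinite(areas)):
            raise ValueError("degenerate (zero-area) triangle present")
        if self.capped_signed_volume() <= 0:
            raise ValueError("mesh is inward-oriented")


@dataclass
class DiameterProfile:
    """Per-slice hydraulic diameter along the vessel."""

    diameters: np.ndarray
    slice_indices: np.ndarray
    z: np.ndarray

    @property
    def max_diameter(self) -> float:
        return float(np.max(self.diameters))

    @property
    def argmax_slice(self) -> int:
        return int(self.slice_indices[int(np.argmax(self.diameters))])


def hydraulic_diameter(contour: Contour) -> float:
    """D_h = 4 A / P of one cross-section, in mm."""
    a = abs(polygon_area(contour.points))
    per = polygon_perimeter(contour.points)
    if per <= 0 or a <= 1e-9 * per ** 2:
        raise ValueError("degenerate contour: zero or near-zero enclosed area")
    return 4.0 * a / per


def max_hydraulic_diameter(contours: list[Contour]) -> DiameterProfile:
    """Hydraulic-diameter profile over a contour stack, with its maximum."""
    if not contours:
        raise ValueError("need at least one contour")
    ordered = sorted(contours, key=lambda c: c.z)
    d = np.array([hydraulic_diameter(c) for c in ordered])
    return DiameterProfile(
        diameters=d,
        slice_indices=np.array([c.slice_index for c in ordered]),
        z=np.array([c.z for c in ordered]),
    )


def _best_ring_offset(prev_ring: np.ndarray, ring: np.ndarray) -> int:
    """Cyclic shift of `ring` minimizing summed chord length to `prev_ring`."""
    n = len(ring)
    best, best_cost = 0, np.inf
    for k in range(n):
        cost = np.linalg.norm(np.roll(ring, -k, axis=0) - prev_ring, axis=1).sum()
        if cost < best_cost:
            best, best_cost = k, cost
    return best


def loft_contours(contours: list[Contour], n_circ: int = 64) -> SurfaceMesh:
    """Loft a stack of contours into an oriented open-tube triangle mesh.

    Each contour is arc-length resampled to ``n_circ`` points with the
    shared start-point convention; each subsequent ring is additionally
    rotated to minimize summed inter-ring chord length, which prevents
    strip twist on tortuous centerlines.  Each adjacent ring pair yields
    ``2 * n_circ`` triangles, quads split along their shorter diagonal.
    """
    if n_circ < 8:
        raise ValueError("need n_circ >= 8")
    if len(contours) < 2:
        raise ValueError("need at least 2 contours to loft")
    ordered = sorted(contours, key=lambda c: c.z)
    zs = np.array([c.z for c in ordered])
    if np.any(np.diff(zs) <= 0):
        raise ValueError("contours must lie on distinct z positions")

    rings = []
    for c in ordered:
        rc = resample_contour(c, n_circ)
        rings.append(np.column_stack([rc.points, np.full(n_circ, rc.z)]))
    for j in range(1, len(rings)):
        k = _best_ring_offset(rings[j - 1][:, :2], rings[j][:, :2])
        rings[j] = np.roll(rings[j], -k, axis=0)

    vertices = np.vstack(rings)
    faces = []
    for j in range(len(rings) - 1):
        lo = j * n_circ
        hi = (j + 1) * n_circ
        for i in range(n_circ):
            i2 = (i + 1) % n_circ
            a, b = lo + i, lo + i2
            c_, d = hi + i2, hi + i
            # split the quad (a, b, c_, d) along its shorter diagonal
            if (np.linalg.norm(vertices[a] - vertices[c_])
                    <= np.linalg.norm(vertices[b] - vertices[d])):
                faces.append((a, b, c_))
                faces.append((a, c_, d))
            else:
                faces.append((a, b, d))
                faces.append((b, c_, d))
    mesh = SurfaceMesh(
        vertices=vertices,
        triangles=np.array(faces, dtype=int),
        proximal_ring=np.arange(n_circ),
        distal_ring=np.arange((len(rings) - 1) * n_circ, len(rings) * n_circ),
    )
    if mesh.capped_signed_volume() < 0:
        mesh.triangles = mesh.triangles[:, ::-1]
    mesh.validate()
    return mesh


def mask_to_contour_stack(volume, min_area_px: float = 2.0,
                          largest_only: bool = True) -> list[Contour]:
    """Extract one contour per slice of a MaskVolume (largest component)."""
    from .contour_ops import mask_to_contours

    dz = volume.slice_spacing
    out = []
    for k in range(volume.shape[0]):
        cs = mask_to_contours(volume.voxels[k], pixel_size=volume.pixel_size,
                              slice_index=k, z=k * dz,
                              min_area_px=min_area_px, largest_only=largest_only)
        if cs:
            out.extend(cs if not largest_only else cs[:1])
    return out


# ---------------------------------------------------------------------------
# I/O (PLY / STL via trimesh; JSON exchange keeps the boundary tags)

def write_mesh(mesh: SurfaceMesh, path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    tm.export(str(path))


def read_mesh(path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def mesh_to_json(mesh: SurfaceMesh, path) -> None:
    payload = dict(vertices=mesh.vertices.tolist(),
                   triangles=mesh.triangles.tolist(),
                   proximal_ring=mesh.proximal_ring.tolist(),
                   distal_ring=mesh.distal_ring.tolist())
    with open(path, "w") as fh:
        json.dump(payload, fh)


def mesh_from_json(path) -> SurfaceMesh:
    with open(path) as fh:
        d = json.load(fh)
    return SurfaceMesh(np.asarray(d["vertices"]), np.asarray(d["triangles"]),
                       np.asarray(d["proximal_ring"]),
                       np.asarray(d["distal_ring"]))
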