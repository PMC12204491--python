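"""Synthetic fixtures: analytic membrane meshes and fusiform vessel phantoms.

Clinical CTA exams cannot ship with the package, so every downstream
module is exercised on phantoms with closed-form geometry:

* icosphere (optionally cut to an equatorial band with two boundary rings)
  and open cylinder meshes, for validating the membrane solver against the
  Laplace law;
* fusiform aneurysm phantoms — a tube whose radius follows a Gaussian
  bulge, ``r(z) = R0 + dR * exp(-(z - z0)^2 / (2 s^2))`` — voxelized to
  ground-truth masks and CTA-like grayscale volumes with additive Gaussian
  noise and optional bright streaks mimicking metal artifacts (e.g. spinal
  screws) that break naive thresholding.

Cross-sections are circular by design so that every geometric quantity
(radius profile, hydraulic diameter, surface area) has an analytic value
to test against.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .contour_ops import Contour
from .mesh_builder import SurfaceMesh, loft_contours
from .volume import MaskVolume

__all__ = [
    "FusiformSpec",
    "make_sphere_mesh",
    "make_cylinder_mesh",
    "make_fusiform_phantom",
    "phantom_dataset",
]


@dataclass
class FusiformSpec:
    """Parameters of a fusiform AAA phantom.

    Defaults describe a surveillance-sized aneurysm: a 10 mm baseline
    aortic radius bulging to 25 mm (5 cm maximum diameter) over a 100 mm
    segment, imaged at 1 mm in-plane resolution and 2 mm slice spacing.
    """

    R0: float = 10.0            # baseline radius, mm
    dR: float = 15.0            # bulge amplitude, mm
    z0: float | None = None     # bulge centre, mm (default mid-length)
    s: float = 15.0             # bulge width (Gaussian sigma), mm
    L: float = 100.0            # segment length, mm
    offset: float = 0.0         # centerline lateral offset amplitude, mm
    pixel_size: tuple[float, float] = (1.0, 1.0)
    slice_spacing: float = 2.0
    noise_sigma: float = 0.05   # image noise std, on a [0, 1] intensity scale
    n_artifacts: int = 0        # bright streak count
    seed: int = 0
    grid_shape: tuple[int, int] | None = None   # (rows, cols); auto if None

    def __post_init__(self) -> None:
        if self.R0 <= 0 or self.L <= 0 or self.s <= 0 or self.dR < 0:
            raise ValueError("need R0, L, s > 0 and dR >= 0")
        if self.z0 is None:
            self.z0 = self.L / 2.0

    def radius(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.R0 + self.dR * np.exp(-((z - self.z0) ** 2) / (2 * self.s ** 2))

    def centerline(self, z) -> np.ndarray:
        """Centre (x, y) of the cross-section at height z (mm)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        dx_off = self.offset * np.sin(np.pi * z / self.L)
        cx, cy = self._grid_centre()
        return np.column_stack([cx + dx_off, np.full(len(z), cy)])

    def _auto_shape(self) -> tuple[int, int]:
        dx, dy = self.pixel_size
        r_max = self.R0 + self.dR + abs(self.offset)
        w = int(np.ceil(2 * (r_max + 4.0) / dx))
        h = int(np.ceil(2 * (r_max + 4.0) / dy))
        return (h, w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid_shape if self.grid_shape is not None else self._auto_shape()

    def _grid_centre(self) -> tuple[float, float]:
        h, w = self.shape
        return (w * self.pixel_size[0] / 2.0, h * self.pixel_size[1] / 2.0)


# ---------------------------------------------------------------------------
# analytic meshes


def make_sphere_mesh(R: float = 25.0, subdivisions: int = 3,
                     band: float | None = None) -> SurfaceMesh:
    """Icosphere of radius R (mm); optionally cut to an equatorial band.

    ``band`` keeps only faces whose vertices satisfy ``|z| <= band * R``,
    leaving two polar-cap openings whose boundary rings serve as the fixed
    ends of a membrane problem.  Without a band the closed sphere is
    returned (no boundary rings).
    """
    import trimesh

    if R <= 0:
        raise ValueError("R must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=R)
    vertices = np.asarray(ico.vertices)
    faces = np.asarray(ico.faces)
    if band is None:
        return SurfaceMesh(vertices, faces)

    keep = np.all(np.abs(vertices[:, 2])[faces] <= band * R, axis=1)
    faces = faces[keep]
    used = np.unique(faces)
    remap = -np.ones(len(vertices), dtype=int)
    remap[used] = np.arange(len(used))
    mesh = SurfaceMesh(vertices[used], remap[faces])
    loops = mesh.boundary_loops()
    if len(loops) != 2:
        raise ValueError(f"band cut produced {len(loops)} boundary loops; "
                         "use a band fraction that clears both poles")
    z_mean = [mesh.vertices[l, 2].mean() for l in loops]
    lo, hi = (0, 1) if z_mean[0] < z_mean[1] else (1, 0)
    mesh.proximal_ring = loops[lo]
    mesh.distal_ring = loops[hi]
    return mesh


def make_cylinder_mesh(R: float = 10.0, L: float = 100.0, n_circ: int = 64,
                       n_len: int = 40) -> SurfaceMesh:
    """Open cylindrical tube along z with tagged end rings.

    ``n_circ * (n_len + 1)`` vertices; every vertex sits exactly at radius
    R from the axis.
    """
    if min(R, L) <= 0 or n_circ < 8 or n_len < 1:
        raise ValueError("need R, L > 0, n_circ >= 8, n_len >= 1")
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    ring = np.column_stack([R * np.cos(theta), R * np.sin(theta)])
    contours = [Contour(ring.copy(), slice_index=j, z=j * L / n_len)
                for j in range(n_len + 1)]
    return loft_contours(contours, n_circ=n_circ)


# ---------------------------------------------------------------------------
# fusiform phantom


def fusiform_contours(spec: FusiformSpec, n_pts: int = 128) -> list[Contour]:
    """Analytic (non-voxel) cross-section contours of the phantom."""
    n_slices = int(round(spec.L / spec.slice_spacing)) + 1
    zs = np.arange(n_slices) * spec.slice_spacing
    centres = spec.centerline(zs)
    radii = spec.radius(zs)
    theta = 2 * np.pi * np.arange(n_pts) / n_pts
    out = []
    for k, (c, r, z) in enumerate(zip(centres, radii, zs)):
        pts = np.column_stack([c[0] + r * np.cos(theta), c[1] + r * np.sin(theta)])
        out.append(Contour(pts, slice_index=k, z=float(z)))
    return out


def fusiform_mesh(spec: FusiformSpec, n_circ: int = 64) -> SurfaceMesh:
    """Lofted analytic surface of the phantom."""
    return loft_contours(fusiform_contours(spec, n_pts=max(n_circ, 128)),
                         n_circ=n_circ)


def make_fusiform_phantom(spec: FusiformSpec):
    """Voxelize a fusiform phantom.

    Returns ``(image, mask, info)``: a CTA-like float image volume on a
    [0, 1]-ish intensity scale (foreground 0.8, background 0.2, Gaussian
    noise, optional streak artifacts), the ground-truth MaskVolume, and an
    analytic record with the radius profile and the location of the
    maximum radius.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    dx, dy = spec.pixel_size
    n_slices = int(round(spec.L / spec.slice_spacing)) + 1
    zs = np.arange(n_slices) * spec.slice_spacing
    radii = spec.radius(zs)
    centres = spec.centerline(zs)

    if (centres[:, 0] - radii < 0).any() or (centres[:, 0] + radii > w * dx).any() \
            or (centres[:, 1] - radii < 0).any() or (centres[:, 1] + radii > h * dy).any():
        raise ValueError("phantom radius exceeds the voxel grid extent")

    xc = (np.arange(w) + 0.5) * dx
    yc = (np.arange(h) + 0.5) * dy
    X, Y = np.meshgrid(xc, yc)
    mask = np.zeros((n_slices, h, w), dtype=np.uint8)
    for k in range(n_slices):
        inside = (X - centres[k, 0]) ** 2 + (Y - centres[k, 1]) ** 2 <= radii[k] ** 2
        mask[k] = inside

    image = 0.2 + 0.6 * mask.astype(np.float64)
    for _ in range(spec.n_artifacts):
        k = int(rng.integers(0, n_slices))
        streak = _streak(h, w, dx, dy, centres[k], radii[k], rng)
        image[k] += streak
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)

    k_max = int(np.argmax(radii))
    info = dict(radii=radii, z=zs, r_max=float(radii[k_max]),
                z_at_max=float(zs[k_max]), slice_at_max=k_max,
                centres=centres)
    mask_vol = MaskVolume(mask, pixel_size=spec.pixel_size,
                          slice_spacing=spec.slice_spacing)
    return image, mask_vol, info


def _streak(h, w, dx, dy, centre, radius, rng) -> np.ndarray:
    """A blurred bright line segment crossing the vessel wall."""
    theta = rng.uniform(0, 2 * np.pi)
    # chord through a point near the wall, random direction
    px = centre[0] + radius * np.cos(theta)
    py = centre[1] + radius * np.sin(theta)
    phi = rng.uniform(0, np.pi)
    d = np.array([np.cos(phi), np.sin(phi)])
    canvas = np.zeros((h, w))
    ts = np.linspace(-max(h * dy, w * dx), max(h * dy, w * dx), 4 * max(h, w))
    pts = np.array([px, py]) + ts[:, None] * d
    cols = (pts[:, 0] / dx - 0.5).round().astype(int)
    rows = (pts[:, 1] / dy - 0.5).round().astype(int)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    canvas[rows[ok], cols[ok]] = 1.0
    return ndimage.gaussian_filter(canvas, 1.0)


def phantom_dataset(n: int, seed: int = 0, patch_size: int = 64,
                    spec_ranges: dict | None = None):
    """A reproducible (image patch, mask patch) training set.

    Draws phantoms with randomized fusiform parameters and crops
    ``patch_size`` windows, roughly half centred on the wall boundary and
    half away from it (vessel interior or background), so a segmentation
    model sees both edge and homogeneous content.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    ranges = dict(R0=(8.0, 12.0), dR=(6.0, 16.0), s=(10.0, 20.0),
                  noise_sigma=(0.03, 0.07), offset=(0.0, 4.0))
    if spec_ranges:
        ranges.update(spec_ranges)

    images, masks = [], []
    n_phantoms = max(1, n // 40)
    per = int(np.ceil(n / n_phantoms))
    for ph in range(n_phantoms):
        spec = FusiformSpec(
            R0=rng.uniform(*ranges["R0"]), dR=rng.uniform(*ranges["dR"]),
            s=rng.uniform(*ranges["s"]), offset=rng.uniform(*ranges["offset"]),
            noise_sigma=rng.uniform(*ranges["noise_sigma"]),
            n_artifacts=int(rng.integers(0, 3)),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        # enlarge the field of view so off-wall patches see pure background,
        # giving the ~50/50 boundary / homogeneous patch mix
        h0, w0 = spec.shape
        spec.grid_shape = (h0 + 2 * patch_size, w0 + 2 * patch_size)
        img, msk, _ = make_fusiform_phantom(spec)
        h, w = img.shape[1:]
        pad_h = max(0, patch_size - h)
        pad_w = max(0, patch_size - w)
        if pad_h or pad_w:
            img = np.pad(img, ((0, 0), (0, pad_h), (0, pad_w)))
            m = np.pad(msk.voxels, ((0, 0), (0, pad_h), (0, pad_w)))
        else:
            m = msk.voxels
        h, w = img.shape[1:]
        for j in range(per):
            if len(images) >= n:
                break
            k = int(rng.integers(0, img.shape[0]))
            on_boundary = (j % 2 == 0)
            r0, c0 = _patch_origin(m[k], patch_size, on_boundary, rng)
            images.append(img[k, r0:r0 + patch_size, c0:c0 + patch_size].copy())
            masks.append(m[k, r0:r0 + patch_size, c0:c0 + patch_size].copy())
    return np.stack(images), np.stack(masks).astype(np.uint8)


def _patch_origin(mask2d, patch, on_boundary, rng):
    h, w = mask2d.shape
    max_r, max_c = h - patch, w - patch
    if max_r <= 0 and max_c <= 0:
        return 0, 0
    edges = np.argwhere(ndimage.binary_dilation(mask2d) ^
                        ndimage.binary_erosion(mask2d))
    if on_boundary and len(edges):
        r, c = edges[int(rng.integers(0, len(edges)))]
        r0 = int(np.clip(r - patch // 2, 0, max(max_r, 0)))
        c0 = int(np.clip(c - patch // 2, 0, max(max_c, 0)))
        return r0, c0
    return (int(rng.integers(0, max(max_r, 0) + 1)),
            int(rng.integers(0, max(max_c, 0) + 1)))
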