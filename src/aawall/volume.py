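"""Binary mask volumes with physical voxel spacing.

The segmentation representation shared across the package: a 3D binary
array indexed ``(slice, row, col)`` together with the in-plane pixel size
``(dx, dy)`` and the slice spacing ``dz``, all in millimetres.  Volumes can
be read and written as NIfTI (``.nii``/``.nii.gz``) or as a directory of
per-slice PNG/TIFF images with a JSON sidecar holding the spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class MaskVolume:
    """A binary voxel volume with anisotropic physical spacing.

    Parameters
    ----------
    voxels
        3D array ``(slice, row, col)``; any nonzero value is foreground.
    pixel_size
        In-plane spacing ``(dx, dy)`` in mm: ``dx`` along columns (x),
        ``dy`` along rows (y).
    slice_spacing
        Distance between consecutive slices ``dz`` in mm.
    """

    voxels: np.ndarray
    pixel_size: tuple[float, float] = (1.0, 1.0)
    slice_spacing: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError(f"voxels must be 3D (slice, row, col); got shape {v.shape}")
        self.voxels = (v != 0).astype(np.uint8)
        dx, dy = (float(s) for s in self.pixel_size)
        dz = float(self.slice_spacing)
        if dx <= 0 or dy <= 0 or dz <= 0:
            raise ValueError("pixel_size and slice_spacing must be positive")
        self.pixel_size = (dx, dy)
        self.slice_spacing = dz

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Spacing ordered like the array axes: (dz, dy, dx)."""
        return (self.slice_spacing, self.pixel_size[1], self.pixel_size[0])

    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def same_grid(self, other: "MaskVolume", atol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_zyx, other.spacing_zyx, atol=atol
        )


def save_nifti(volume: MaskVolume | np.ndarray, path: str | Path,
               pixel_size=(1.0, 1.0), slice_spacing=1.0) -> None:
    """Write a volume as NIfTI; spacing goes into the affine diagonal."""
    import nibabel as nib

    if isinstance(volume, MaskVolume):
        data = volume.voxels
        dx, dy = volume.pixel_size
        dz = volume.slice_spacing
    else:
        data = np.asarray(volume)
        dx, dy = pixel_size
        dz = slice_spacing
    # nibabel convention: fastest axis first -> store as (x, y, z)
    arr = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.uint8), affine), str(path))


def load_nifti(path: str | Path) -> MaskVolume:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(arr, (2, 1, 0))  # back to (slice, row, col)
    return MaskVolume(data, pixel_size=(float(zooms[0]), float(zooms[1])),
                      slice_spacing=float(zooms[2]))


def save_image_volume(volume: np.ndarray, path: str | Path,
                      pixel_size=(1.0, 1.0), slice_spacing=1.0) -> None:
    """Write a grayscale (float) image volume as NIfTI without binarizing."""
    import nibabel as nib

    arr = np.ascontiguousarray(np.transpose(np.asarray(volume, dtype=np.float32), (2, 1, 0)))
    affine = np.diag([pixel_size[0], pixel_size[1], slice_spacing, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_image_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float], float]:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()[:3]
    return (np.transpose(arr, (2, 1, 0)),
            (float(zooms[0]), float(zooms[1])), float(zooms[2]))


def save_slice_stack(volume: MaskVolume, directory: str | Path, fmt: str = "png") -> None:
    """Write one image per slice plus a ``spacing.json`` sidecar."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, sl in enumerate(volume.voxels):
        iio.imwrite(directory / f"slice_{i:04d}.{fmt}", (sl * 255).astype(np.uint8))
    sidecar = {
        "pixel_size_mm": list(volume.pixel_size),
        "slice_spacing_mm": volume.slice_spacing,
    }
    (directory / "spacing.json").write_text(json.dumps(sidecar, indent=2))


def load_slice_stack(directory: str | Path) -> MaskVolume:
    import imageio.v3 as iio

    directory = Path(directory)
    sidecar_path = directory / "spacing.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"spacing sidecar missing: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in {".png", ".tif", ".tiff"})
    if not files:
        raise FileNotFoundError(f"no slice images in {directory}")
    slices = [np.asarray(iio.imread(p)) for p in files]
    vol = np.stack([(s > 127) if s.dtype == np.uint8 else (s > 0) for s in slices])
    return MaskVolume(vol, pixel_size=tuple(sidecar["pixel_size_mm"]),
                      slice_spacing=float(sidecar["slice_spacing_mm"]))
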