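"""Shared voxel-grid data model, geometry rasterization and NIfTI I/O.

All modules share one spatial convention: world coordinates in millimetres,
axis order (x, y, z), and the voxel-*center* convention — ``origin`` is the
world position of the center of voxel index (0, 0, 0).  Volumes are stored on
disk as NIfTI-1 (32-bit float, RAS-aligned diagonal affine) with a JSON
sidecar of identical basename carrying the non-spatial metadata (quantity,
nuclide, time stamp) that NIfTI itself cannot hold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "VolumeImage",
    "VoiMask",
    "GeometrySpec",
    "QUANTITIES",
    "rasterize_geometry",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "mask_stats",
]

#: Recognised physical quantities for a :class:`VolumeImage`.
QUANTITIES = (
    "activity_conc_Bq_per_ml",
    "counts",
    "density_g_per_ml",
    "mu_per_mm",
    "dose_Gy",
    "dose_Sv_RBE",
    "suv",
    "tia_MBq_h",
)


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z); each entry >= 1.
    spacing : tuple of float
        Voxel pitch in mm along (x, y, z); each entry > 0.
    origin : tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be >= 1 in every axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0 in every axis, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate arrays (mm) of every voxel center, shape = grid shape."""
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2), indexing="ij"
        )

    @classmethod
    def centered(
        cls, shape: tuple[int, int, int], spacing: tuple[float, float, float]
    ) -> "VoxelGrid":
        """Grid whose world origin (0,0,0) is at the volume center."""
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return cls(shape, spacing, origin)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class VolumeImage:
    """A 3-D scalar field on a :class:`VoxelGrid` with a physical quantity tag."""

    grid: VoxelGrid
    values: np.ndarray
    quantity: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.quantity in (
            "activity_conc_Bq_per_ml",
            "density_g_per_ml",
            "mu_per_mm",
        ) and np.any(self.values < 0):
            raise ValueError(f"{self.quantity} values must be >= 0")

    def copy_with(self, values: np.ndarray, quantity: str | None = None,
                  meta: dict | None = None) -> "VolumeImage":
        return VolumeImage(
            self.grid,
            values,
            self.quantity if quantity is None else quantity,
            dict(self.meta) if meta is None else meta,
        )


@dataclass
class VoiMask:
    """Integer label map (0 = background) with a label -> name table."""

    grid: VoxelGrid
    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if tuple(self.labels.shape) != self.grid.shape:
            raise ValueError("labels shape does not match grid shape")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise KeyError(f"no VOI named {name!r}")

    def indicator(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class GeometrySpec:
    """Analytic solid used to rasterize phantom compartments and VOIs.

    kind 'sphere': size = (radius,); 'cylinder' (axis along z):
    size = (radius, height); 'ellipsoid': size = (a, b, c) semi-axes. All mm.
    """

    kind: str
    center: tuple[float, float, float]
    size: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cylinder", "ellipsoid"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        n_expected = {"sphere": 1, "cylinder": 2, "ellipsoid": 3}[self.kind]
        if len(self.size) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} size parameter(s)")
        if any(s <= 0 for s in self.size):
            raise ValueError("all size parameters must be > 0")

    def analytic_volume_ml(self) -> float:
        if self.kind == "sphere":
            (r,) = self.size
            return 4.0 / 3.0 * np.pi * r**3 / 1000.0
        if self.kind == "cylinder":
            r, h = self.size
            return np.pi * r**2 * h / 1000.0
        a, b, c = self.size
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        if self.kind == "sphere":
            (r,) = self.size
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        if self.kind == "cylinder":
            r, h = self.size
            radial = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
            return radial & (np.abs(z - cz) <= h / 2.0)
        a, b, c = self.size
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


def rasterize_geometry(spec: GeometrySpec, grid: VoxelGrid, name: str = "voi") -> VoiMask:
    """Binary mask of voxels whose centers lie inside the solid.

    Voxel membership is by center inclusion (no partial-volume weighting), so
    the rasterized volume converges to the analytic volume as spacing -> 0.

    Raises
    ------
    ValueError
        If the solid contains no voxel center (geometry outside the grid).
    """
    x, y, z = grid.meshgrid()
    inside = spec.contains(x, y, z)
    if not inside.any():
        raise ValueError("geometry lies entirely outside the grid (empty mask)")
    return VoiMask(grid, inside.astype(np.int16), {1: name})


# ---------------------------------------------------------------------------
# NIfTI round trip

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_volume(path: str | Path, image: VolumeImage) -> None:
    """Write a volume as float32 NIfTI-1 plus a JSON metadata sidecar."""
    path = Path(path)
    data = image.values.astype(np.float32)
    img = nib.Nifti1Image(data, image.grid.affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    sidecar = {
        "quantity": image.quantity,
        "meta": image.meta,
        # NIfTI headers hold geometry in float32; the sidecar keeps it exact
        "spacing_mm": list(image.grid.spacing),
        "origin_mm": list(image.grid.origin),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_volume(path: str | Path) -> VolumeImage:
    path = Path(path)
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("non-diagonal affine: volume was not written by save_volume")
    spacing = tuple(np.diag(aff[:3, :3]).astype(float))
    if any(s <= 0 for s in spacing):
        raise ValueError("negative or zero spacing in affine")
    origin = tuple(aff[:3, 3].astype(float))
    values = np.asarray(img.dataobj, dtype=np.float32).astype(np.float64)
    quantity, meta = "counts", {}
    sc = _sidecar_path(path)
    if sc.exists():
        record = json.loads(sc.read_text())
        quantity = record.get("quantity", quantity)
        meta = record.get("meta", {})
        spacing = tuple(record.get("spacing_mm", spacing))
        origin = tuple(record.get("origin_mm", origin))
    grid = VoxelGrid(values.shape, spacing, origin)
    return VolumeImage(grid, values, quantity, meta)


def save_mask(path: str | Path, mask: VoiMask) -> None:
    path = Path(path)
    img = nib.Nifti1Image(mask.labels.astype(np.int16), mask.grid.affine())
    nib.save(img, str(path))
    sidecar = {
        "names": {str(k): v for k, v in mask.names.items()},
        "spacing_mm": list(mask.grid.spacing),
        "origin_mm": list(mask.grid.origin),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_mask(path: str | Path) -> VoiMask:
    path = Path(path)
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(np.diag(aff[:3, :3]).astype(float))
    origin = tuple(aff[:3, 3].astype(float))
    labels = np.asarray(img.dataobj).astype(np.int32)
    names: dict[int, str] = {}
    sc = _sidecar_path(path)
    if sc.exists():
        record = json.loads(sc.read_text())
        names = {int(k): v for k, v in record["names"].items()}
        spacing = tuple(record.get("spacing_mm", spacing))
        origin = tuple(record.get("origin_mm", origin))
    grid = VoxelGrid(labels.shape, spacing, origin)
    return VoiMask(grid, labels, names)


def mask_stats(image: VolumeImage, mask: VoiMask, label: int) -> dict:
    """Mean / sample-sd / max of the image over one label, plus VOI volume.

    ``volume_ml`` is voxel count times voxel volume (center-inclusion masks).
    """
    if image.grid != mask.grid:
        raise ValueError("image and mask grids differ")
    sel = image.values[mask.labels == label]
    if sel.size == 0:
        raise ValueError(f"label {label} not present in mask")
    return {
        "mean": float(sel.mean()),
        "sd": float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
        "max": float(sel.max()),
        "volume_ml": float(sel.size * mask.grid.voxel_volume_ml),
        "n_voxels": int(sel.size),
    }
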