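"""Digital twin of the cylinder quality-control phantom.

The physical phantom is a 3.5 l water cylinder with three fillable inserts of
approximately 200, 45 and 20 ml (kidney-, salivary-gland- and lesion-sized
targets for PSMA therapy) filled at a foreground-to-background concentration
ratio of 6.4:1.  The high-count (HC) condition carries a total activity of
about 4.5 MBq; the low-count (LC) condition emulates the clinical count level
by dividing the acquisition time per view by 30.  Five 100-ml rod-shaped
background VOIs placed between and around the inserts provide the noise
reference for SNR and background-recovery measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GeometrySpec, VoiMask, VolumeImage, VoxelGrid

__all__ = [
    "PhantomSpec",
    "GroundTruthRecord",
    "default_phantom_spec",
    "build_cylinder_phantom",
    "decay_evolve",
]

WATER_DENSITY_G_PER_ML = 1.0

#: Insert radii (mm) for the nominal 200 / 45 / 20 ml sphere volumes.
def _sphere_radius_mm(volume_ml: float) -> float:
    return (volume_ml * 1000.0 * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class GroundTruthRecord:
    """Generator-side truth against which recovery is tested."""

    voi: dict[str, dict] = field(default_factory=dict)
    global_info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"voi": self.voi, "global": self.global_info}


@dataclass(frozen=True)
class PhantomSpec:
    body: GeometrySpec
    background_conc_Bq_per_ml: float
    inserts: tuple[tuple[GeometrySpec, float, str], ...]
    background_rods: tuple[GeometrySpec, ...] = ()
    count_mode: str = "HC"
    lc_time_factor: float = 30.0

    def __post_init__(self) -> None:
        if self.background_conc_Bq_per_ml < 0:
            raise ValueError("background concentration must be >= 0")
        if any(conc < 0 for _, conc, _ in self.inserts):
            raise ValueError("insert concentrations must be >= 0")
        if self.count_mode not in ("HC", "LC"):
            raise ValueError("count_mode must be 'HC' or 'LC'")
        if self.lc_time_factor <= 0:
            raise ValueError("lc_time_factor must be > 0")

    @property
    def time_factor(self) -> float:
        """Acquisition-time divisor implied by the count mode."""
        return 1.0 if self.count_mode == "HC" else self.lc_time_factor


def default_phantom_spec(count_mode: str = "HC",
                         background_conc_Bq_per_ml: float = 900.0,
                         contrast: float = 6.4) -> PhantomSpec:
    """The cylinder phantom at its measured fill.

    Background about 0.9 kBq/ml with inserts at 6.4:1 gives a total activity
    of ~4.5 MBq for the 3.5 l body — the high-count condition; the low-count
    condition keeps the same fill and divides acquisition time by 30.

    Layout: a 101 mm x 110 mm water cylinder; sphere inserts of 200/45/20 ml
    at 120 deg spacing; five 100-ml background rods (17.84 mm x 100 mm)
    between and around the inserts, clear of every insert.
    """
    body = GeometrySpec("cylinder", (0.0, 0.0, 0.0), (101.0, 110.0))
    fg = contrast * background_conc_Bq_per_ml

    def polar(r: float, angle_deg: float) -> tuple[float, float, float]:
        a = np.deg2rad(angle_deg)
        return (r * np.cos(a), r * np.sin(a), 0.0)

    inserts = (
        (GeometrySpec("sphere", polar(50.0, 0.0), (_sphere_radius_mm(200.0),)),
         fg, "insert_200ml"),
        (GeometrySpec("sphere", polar(55.0, 120.0), (_sphere_radius_mm(45.0),)),
         fg, "insert_45ml"),
        (GeometrySpec("sphere", polar(60.0, 240.0), (_sphere_radius_mm(20.0),)),
         fg, "insert_20ml"),
    )
    rod_r = np.sqrt(100.0 * 1000.0 / (np.pi * 100.0))  # 100 ml at 100 mm length
    rods = tuple(
        GeometrySpec("cylinder", polar(radius, ang), (rod_r, 100.0))
        for radius, ang in ((60.0, 60.0), (60.0, 180.0), (60.0, 300.0),
                            (78.0, 150.0), (78.0, 210.0))
    )
    return PhantomSpec(body, background_conc_Bq_per_ml, inserts, rods, count_mode)


def build_cylinder_phantom(
    spec: PhantomSpec, grid: VoxelGrid
) -> tuple[VolumeImage, VolumeImage, VoiMask, GroundTruthRecord]:
    """Rasterize the phantom: activity map, density map, VOI mask, truth.

    Mask labels: inserts first (1..n), then the background rods; every label
    is named.  Raises if any two inserts overlap on the grid.
    """
    x, y, z = grid.meshgrid()
    body_in = spec.body.contains(x, y, z)
    if not body_in.any():
        raise ValueError("phantom body lies outside the grid")

    activity = np.where(body_in, spec.background_conc_Bq_per_ml, 0.0)
    density = np.where(body_in, WATER_DENSITY_G_PER_ML, 0.0)
    labels = np.zeros(grid.shape, dtype=np.int16)
    names: dict[int, str] = {}
    truth = GroundTruthRecord()

    occupied = np.zeros(grid.shape, dtype=bool)
    for i, (geom, conc, name) in enumerate(spec.inserts, start=1):
        inside = geom.contains(x, y, z)
        if not inside.any():
            raise ValueError(f"insert {name!r} lies outside the grid")
        if (inside & occupied).any():
            raise ValueError(f"insert {name!r} overlaps another insert")
        if (inside & ~body_in).any():
            raise ValueError(f"insert {name!r} extends outside the body")
        occupied |= inside
        activity[inside] = conc
        labels[inside] = i
        names[i] = name
        truth.voi[name] = {
            "concentration_Bq_per_ml": conc,
            "volume_ml": float(inside.sum() * grid.voxel_volume_ml),
            "analytic_volume_ml": geom.analytic_volume_ml(),
        }

    for j, rod in enumerate(spec.background_rods, start=1):
        lab = len(spec.inserts) + j
        inside = rod.contains(x, y, z) & body_in & ~occupied
        if not inside.any():
            raise ValueError(f"background rod {j} lies outside the body")
        labels[inside] = lab
        names[lab] = f"bg_rod_{j}"

    total_MBq = float(activity.sum() * grid.voxel_volume_ml * 1e-6)
    truth.global_info = {
        "background_conc_Bq_per_ml": spec.background_conc_Bq_per_ml,
        "contrast": (spec.inserts[0][1] / spec.background_conc_Bq_per_ml
                     if spec.background_conc_Bq_per_ml > 0 else None),
        "total_activity_MBq": total_MBq,
        "count_mode": spec.count_mode,
        "time_factor": spec.time_factor,
    }
    act_img = VolumeImage(grid, activity, "activity_conc_Bq_per_ml",
                          {"source": "phantom", "count_mode": spec.count_mode})
    den_img = VolumeImage(grid, density, "density_g_per_ml")
    return act_img, den_img, VoiMask(grid, labels, names), truth


def decay_evolve(
    image: VolumeImage,
    mask: VoiMask,
    half_life_h: dict[str, float],
    dt_h: float,
) -> VolumeImage:
    """Mono-exponential evolution: scale each voxel by 2^(-dt / T_eff of its VOI).

    ``half_life_h`` maps VOI names (plus the key ``"background"`` for label 0)
    to effective half-lives in hours.  A negative half-life expresses growing
    uptake (activity doubling over ``|T|``), used for the increasing-uptake
    lesions that single-time-point dosimetry must exclude.
    """
    if image.grid != mask.grid:
        raise ValueError("image and mask grids differ")
    if "background" not in half_life_h:
        raise ValueError("missing 'background' half-life entry")
    factor = np.empty(image.grid.shape)
    t_bg = half_life_h["background"]
    if t_bg == 0:
        raise ValueError("half-life entries must be nonzero")
    factor[:] = 2.0 ** (-dt_h / t_bg)
    for lab, name in mask.names.items():
        if name not in half_life_h:
            raise ValueError(f"missing half-life for VOI {name!r}")
        t = half_life_h[name]
        if t == 0:
            raise ValueError("half-life entries must be nonzero")
        factor[mask.labels == lab] = 2.0 ** (-dt_h / t)
    return image.copy_with(image.values * factor,
                           meta={**image.meta, "decay_evolved_h": dt_h})
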