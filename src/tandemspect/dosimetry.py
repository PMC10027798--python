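"""Single-time-point voxel dosimetry for tandem Lu-177 / Ac-225 therapy.

Kinetics are mono-exponential per VOI: a two-point fit to the 24 h / 48 h
Lu-177 uptake yields the VOI effective half-life; assuming equal biological
pharmacokinetics of the two labelled compounds, the Lu-177 biological
clearance is combined with the Ac-225 physical half-life to obtain the Ac-225
effective half-life.  The time-integrated activity of each voxel in a VOI is

    TIA(x) = A(x, t*) * exp(ln2 * t* / T_half) * T_half / ln2,

i.e. the 0-to-infinity integral of the mono-exponential through the uptake
A(x, t*) at the reference time t* (about 24 h).  Absorbed dose maps follow by
convolution with an energy-conserving voxel S-value (VSV) kernel, voxel-wise
CT-density weighting, and RBE weighting (5 for the alpha chain, 1 for the
beta emitter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .grid import VoiMask, VolumeImage, VoxelGrid
from .nuclides import NuclideSpec, get_nuclide

__all__ = [
    "VoiKinetics",
    "VsvKernel",
    "decay_correct",
    "fit_two_point_half_life",
    "convert_effective_half_life",
    "voxel_tia",
    "build_vsv_kernel",
    "apply_vsv",
    "density_weight",
    "rbe_weight",
    "voi_dose_report",
]

LN2 = np.log(2.0)
MEV_TO_J = 1.602176634e-13
SOFT_TISSUE_DENSITY_G_PER_ML = 1.04


@dataclass
class VoiKinetics:
    """Per-VOI uptake at the reference time plus the fitted effective half-life."""

    name: str
    a_ref: float  # uptake at the reference time (same unit as the fit inputs)
    t_ref_h: float
    half_life_h: float | None  # None when the fit is excluded
    excluded: bool = False
    points: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.excluded and (self.half_life_h is None or self.half_life_h <= 0):
            raise ValueError("valid kinetics require a positive half-life")


def decay_correct(value: float | np.ndarray, dt_h: float,
                  half_life_h: float) -> float | np.ndarray:
    """Correct a measurement for physical decay over ``dt_h``: value * 2^(dt/T)."""
    if half_life_h <= 0:
        raise ValueError("half-life must be > 0")
    return value * 2.0 ** (dt_h / half_life_h)


def fit_two_point_half_life(a1: float, t1_h: float, a2: float,
                            t2_h: float, name: str = "voi") -> VoiKinetics:
    """Mono-exponential two-point fit of the effective half-life.

    When the later uptake is not lower than the earlier one the VOI cannot be
    described by a decaying mono-exponential and is flagged ``excluded``
    (such lesions are dropped from single-time-point dosimetry).
    """
    if t2_h <= t1_h:
        raise ValueError("t2 must be later than t1")
    if a1 <= 0 or a2 <= 0:
        raise ValueError("activities must be > 0")
    if a2 >= a1:
        return VoiKinetics(name, a1, t1_h, None, excluded=True,
                           points=((t1_h, a1), (t2_h, a2)))
    t_half = (t2_h - t1_h) * LN2 / np.log(a1 / a2)
    return VoiKinetics(name, a1, t1_h, float(t_half),
                       points=((t1_h, a1), (t2_h, a2)))


def convert_effective_half_life(
    t_eff_h: float,
    from_nuclide: NuclideSpec | str,
    to_nuclide: NuclideSpec | str,
) -> float:
    """Map an effective half-life between nuclides sharing one biological clearance.

    1/T_eff = 1/T_phys + 1/T_bio; the biological component is kept and
    recombined with the target nuclide's physical half-life.  T_eff equal to
    the source physical half-life (no biological clearance) maps to the
    target physical half-life.
    """
    src = get_nuclide(from_nuclide)
    dst = get_nuclide(to_nuclide)
    if t_eff_h <= 0:
        raise ValueError("effective half-life must be > 0")
    if t_eff_h > src.half_life_h * (1 + 1e-12):
        raise ValueError(
            f"T_eff {t_eff_h} h exceeds the {src.name} physical half-life "
            f"{src.half_life_h:.1f} h (negative biological clearance)"
        )
    inv_bio = max(1.0 / t_eff_h - 1.0 / src.half_life_h, 0.0)
    return 1.0 / (inv_bio + 1.0 / dst.half_life_h)


def voxel_tia(
    activity: VolumeImage,
    mask: VoiMask,
    half_life_h: dict[str, float],
    t_ref_h: float,
) -> VolumeImage:
    """Voxel time-integrated activity map [MBq h per ml].

    Applies TIA(x) = A(x,t*) * exp(ln2 t*/T) * T/ln2 with the VOI-specific
    effective half-life of the voxel's VOI; label 0 uses the ``"background"``
    entry.  Input activity is Bq/ml at the reference time.
    """
    if activity.grid != mask.grid:
        raise ValueError("activity and mask grids differ")
    if activity.quantity != "activity_conc_Bq_per_ml":
        raise ValueError("voxel_tia expects an activity concentration map")
    if "background" not in half_life_h:
        raise ValueError("missing 'background' half-life entry")

    def integral_factor(t_half: float) -> float:
        if t_half <= 0:
            raise ValueError("half-life entries must be > 0")
        return float(np.exp(LN2 * t_ref_h / t_half) * t_half / LN2)

    factor = np.full(activity.grid.shape, integral_factor(half_life_h["background"]))
    for lab, name in mask.names.items():
        if name not in half_life_h:
            raise ValueError(f"missing half-life for VOI {name!r}")
        factor[mask.labels == lab] = integral_factor(half_life_h[name])
    tia = activity.values * factor * 1e-6  # Bq h/ml -> MBq h/ml
    return VolumeImage(activity.grid, tia, "tia_MBq_h",
                       {**activity.meta, "t_ref_h": t_ref_h})


@dataclass
class VsvKernel:
    """Voxel S-value kernel: absorbed dose [Gy] per decay in the source voxel.

    Energy conservation holds by construction:
    sum(kernel) * voxel mass = locally deposited energy per decay (J).
    """

    nuclide: str
    spacing_mm: tuple[float, float, float]
    kernel: np.ndarray
    reference_density_g_per_ml: float = 1.0

    @property
    def self_s_Gy_per_decay(self) -> float:
        c = tuple(s // 2 for s in self.kernel.shape)
        return float(self.kernel[c])

    def energy_per_decay_J(self) -> float:
        mass_kg = float(np.prod(self.spacing_mm)) / 1000.0 \
            * self.reference_density_g_per_ml * 1e-3
        return float(self.kernel.sum() * mass_kg)


def build_vsv_kernel(
    nuclide: NuclideSpec | str,
    grid: VoxelGrid,
    beta_range_mm: float = 0.6,
    reference_density_g_per_ml: float = 1.0,
) -> VsvKernel:
    """Energy-conserving analytic dose kernel on the image voxel lattice.

    Ac-225 (full local deposition of the alpha chain): a single-voxel kernel —
    the charged-particle ranges are far below the voxel size.  Lu-177: the
    mean beta energy split between the source voxel and an exponential shell
    of scale ``beta_range_mm``; the self-fraction tends to 1 as the voxel
    grows, and total energy is conserved exactly at any voxel size.
    """
    nuc = get_nuclide(nuclide)
    sp = grid.spacing
    if max(sp) / min(sp) > 1.5:
        raise ValueError("voxel spacing too anisotropic for an isotropic kernel")
    mass_kg = float(np.prod(sp)) / 1000.0 * reference_density_g_per_ml * 1e-3
    e_j = nuc.energy_per_decay_MeV * MEV_TO_J

    if nuc.name == "Ac-225":
        kernel = np.array([[[e_j / mass_kg]]])
    else:
        r_vox = max(1, int(np.ceil(5.0 * beta_range_mm / min(sp))))
        ax = [np.arange(-r_vox, r_vox + 1) * s for s in sp]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        w = np.exp(-r / beta_range_mm)
        w /= w.sum()
        kernel = e_j * w / mass_kg
    return VsvKernel(nuc.name, sp, kernel, reference_density_g_per_ml)


def apply_vsv(tia: VolumeImage, kernel: VsvKernel) -> VolumeImage:
    """Soft-tissue absorbed dose map [Gy]: decays-per-voxel convolved with the VSV."""
    if tia.quantity != "tia_MBq_h":
        raise ValueError("apply_vsv expects a TIA map")
    if not np.allclose(tia.grid.spacing, kernel.spacing_mm):
        raise ValueError("TIA and kernel voxel spacings differ")
    decays = tia.values * 1e6 * 3600.0 * tia.grid.voxel_volume_ml  # MBq h/ml -> decays
    if kernel.kernel.size == 1:
        dose = decays * float(kernel.kernel.ravel()[0])
    else:
        dose = scipy.signal.fftconvolve(decays, kernel.kernel, mode="same")
        np.maximum(dose, 0.0, out=dose)  # FFT round-off can dip below zero
    return VolumeImage(tia.grid, dose, "dose_Gy",
                       {**tia.meta, "nuclide": kernel.nuclide})


def density_weight(dose: VolumeImage, density: VolumeImage,
                   rho_soft_g_per_ml: float = SOFT_TISSUE_DENSITY_G_PER_ML,
                   ) -> VolumeImage:
    """Rescale a soft-tissue dose map by the local density: dose * rho_soft / rho."""
    if dose.grid != density.grid:
        raise ValueError("dose and density grids differ")
    rho = density.values
    bad = (rho <= 0) & (dose.values > 0)
    if bad.any():
        raise ValueError("zero density under nonzero dose")
    out = np.zeros_like(dose.values)
    ok = rho > 0
    out[ok] = dose.values[ok] * rho_soft_g_per_ml / rho[ok]
    return dose.copy_with(out, meta={**dose.meta, "density_weighted": True})


def rbe_weight(dose: VolumeImage, nuclide: NuclideSpec | str) -> VolumeImage:
    """RBE-weighted dose [Sv_RBE] = RBE x absorbed dose [Gy]."""
    nuc = get_nuclide(nuclide)
    if dose.quantity != "dose_Gy":
        raise ValueError("rbe_weight expects an absorbed dose map in Gy")
    return VolumeImage(dose.grid, dose.values * nuc.rbe, "dose_Sv_RBE",
                       {**dose.meta, "rbe": nuc.rbe, "nuclide": nuc.name})


def voi_dose_report(
    dose_Gy: VolumeImage,
    mask: VoiMask,
    administered_MBq: float,
    nuclide: NuclideSpec | str,
    half_life_h: dict[str, float] | None = None,
    labels: list[int] | None = None,
) -> pd.DataFrame:
    """Per-VOI mean absorbed and RBE-weighted dose, normalized to administration.

    The per-administration column follows the field's reporting convention:
    Sv_RBE per MBq for the alpha emitter (few-MBq administrations), Sv_RBE
    per GBq for Lu-177.
    """
    if administered_MBq <= 0:
        raise ValueError("administered activity must be > 0")
    nuc = get_nuclide(nuclide)
    per_gbq = nuc.rbe == 1.0  # Lu-177 convention
    rows = []
    for lab in sorted(labels if labels is not None else mask.names):
        if lab not in mask.names:
            raise ValueError(f"label {lab} not present in mask")
        name = mask.names[lab]
        sel = dose_Gy.values[mask.labels == lab]
        if sel.size == 0:
            raise ValueError(f"VOI {name!r} is empty")
        mean_gy = float(sel.mean())
        mean_sv = mean_gy * nuc.rbe
        denom = administered_MBq / 1000.0 if per_gbq else administered_MBq
        rows.append({
            "voi": name,
            "nuclide": nuc.name,
            "volume_ml": float(sel.size * mask.grid.voxel_volume_ml),
            "mean_dose_Gy": mean_gy,
            "mean_dose_Sv_RBE": mean_sv,
            "dose_per_admin": mean_sv / denom,
            "dose_per_admin_unit": (
                f"Sv_RBE={nuc.rbe:g}/GBq" if per_gbq else f"Sv_RBE={nuc.rbe:g}/MBq"),
            "half_life_h": (half_life_h or {}).get(name, np.nan),
        })
    return pd.DataFrame(rows)
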