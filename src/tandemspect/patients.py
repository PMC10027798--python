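"""Synthetic tandem-therapy patients with known ground truth.

Each patient mimics the imaged cohort: simultaneous administration of about
1000 MBq of the Lu-177-labelled and 8 MBq of the Ac-225-labelled PSMA ligand,
imaged at 24 h (both isotopes, the Ac-225 chain via its Bi-213 440 keV gamma)
and at 48 h (Lu-177 only).  Kidney and lesion SUVs, lesion volumes and
effective half-lives are drawn from the printed cohort statistics; the
Ac-225 SUV of each structure is generated as a paired ratio on its Lu-177
SUV so the two isotopes stay strongly correlated, as observed clinically.
A fraction of lesions is generated with *increasing* 24-to-48 h uptake;
these are the cases a decaying mono-exponential cannot fit and which
single-time-point dosimetry must detect and exclude.

SUV convention (both for generation and measurement): SUV = concentration
divided by decay-corrected injected activity per gram of body mass, tissue
density 1 g/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosimetry import LN2, MEV_TO_J, convert_effective_half_life
from .grid import GeometrySpec, VoiMask, VolumeImage, VoxelGrid
from .nuclides import AC225, LU177
from .phantom import GroundTruthRecord

__all__ = ["SyntheticPatientSpec", "build_synthetic_patient", "analytic_voi_dose"]


@dataclass(frozen=True)
class SyntheticPatientSpec:
    """Cohort-level generator parameters (means and sds of the printed statistics)."""

    n_lesions: int = 3
    kidney_suv_lu177: tuple[float, float] = (2.1, 0.9)
    kidney_suv_ac225: tuple[float, float] = (2.5, 0.8)
    lesion_suv_lu177: tuple[float, float] = (2.1, 1.5)
    lesion_suv_ac225: tuple[float, float] = (1.8, 1.1)
    #: sd of the paired Ac/Lu SUV ratio around the ratio of the means
    kidney_ratio_sd: float = 0.23
    lesion_ratio_sd: float = 0.32
    kidney_half_life_h: tuple[float, float] = (31.0, 17.0)   # Lu-177 effective
    lesion_half_life_h: tuple[float, float] = (51.0, 39.0)   # Lu-177 effective
    lesion_volume_ml: tuple[float, float] = (21.0, 13.0)
    injected_MBq: dict = field(default_factory=lambda: {"lu177": 1000.0, "ac225": 8.0})
    body_weight_kg: float = 80.0
    p_increasing_uptake: float = 7.0 / 26.0
    background_suv: float = 0.3
    background_half_life_h: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        for mean, sd in (self.kidney_suv_lu177, self.kidney_suv_ac225,
                         self.lesion_suv_lu177, self.lesion_suv_ac225,
                         self.kidney_half_life_h, self.lesion_half_life_h,
                         self.lesion_volume_ml):
            if mean <= 0:
                raise ValueError("distribution means must be > 0")
            if sd < 0:
                raise ValueError("distribution sds must be >= 0")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if not (0.0 <= self.p_increasing_uptake <= 1.0):
            raise ValueError("p_increasing_uptake must lie in [0, 1]")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = 1e-6) -> float:
    """Positive-truncated normal draw (resampling); degenerate at sd = 0."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    raise RuntimeError("truncated normal sampling failed")


def _lognormal_matched(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Log-normal draw moment-matched to (mean, sd); degenerate at sd = 0."""
    if sd == 0:
        return mean
    s2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(s2)))


def _suv_to_conc(suv: float, injected_MBq: float, weight_kg: float,
                 t_h: float, half_life_h: float) -> float:
    """Bq/ml at scan time t for a given SUV (decay-corrected convention, rho=1)."""
    injected_bq = injected_MBq * 1e6 * 2.0 ** (-t_h / half_life_h)
    return suv * injected_bq / (weight_kg * 1000.0)


def analytic_voi_dose(conc24_Bq_per_ml: float, t_eff_h: float,
                      energy_MeV: float, t_ref_h: float = 24.0,
                      density_g_per_ml: float = 1.0) -> float:
    """Closed-form local-deposition absorbed dose [Gy] for a uniform VOI.

    TIA density (decays/ml) times energy per decay over the mass of a ml —
    the independent truth the imaging-plus-dosimetry chain must recover.
    """
    tia_bq_h = conc24_Bq_per_ml * np.exp(LN2 * t_ref_h / t_eff_h) * t_eff_h / LN2
    decays_per_ml = tia_bq_h * 3600.0
    return decays_per_ml * energy_MeV * MEV_TO_J / (density_g_per_ml * 1e-3)


def _place_lesions(rng: np.random.Generator, n: int, radii: list[float],
                   torso_r: float, torso_h: float,
                   blocked: list[tuple[np.ndarray, float]],
                   max_tries: int = 500) -> list[np.ndarray]:
    centers: list[np.ndarray] = []
    for i in range(n):
        r_i = radii[i]
        for attempt in range(max_tries):
            rad = rng.uniform(0, torso_r - r_i - 2.0)
            ang = rng.uniform(0, 2 * np.pi)
            zmax = torso_h / 2.0 - r_i - 2.0
            c = np.array([rad * np.cos(ang), rad * np.sin(ang),
                          rng.uniform(-zmax, zmax)])
            ok = all(np.linalg.norm(c - bc) > r_i + br + 2.0
                     for bc, br in blocked)
            ok = ok and all(
                np.linalg.norm(c - pc) > r_i + radii[j] + 2.0
                for j, pc in enumerate(centers))
            if ok:
                centers.append(c)
                blocked = blocked  # kidneys stay blocked for later lesions
                break
        else:
            raise RuntimeError(
                f"could not place lesion {i + 1} without overlap "
                f"after {max_tries} tries")
    return centers


def build_synthetic_patient(
    spec: SyntheticPatientSpec, grid: VoxelGrid
) -> tuple[dict[str, VolumeImage], VolumeImage, VoiMask, GroundTruthRecord]:
    """Generate one tandem patient on the grid.

    Returns activity maps keyed ``lu177_24h``, ``lu177_48h``, ``ac225_24h``
    (Bq/ml at the respective scan times), a water-equivalent density map, the
    VOI mask (two kidneys, lesions, torso background), and the ground-truth
    record with per-VOI SUVs, concentrations, half-lives and analytic doses.
    """
    rng = np.random.default_rng(spec.seed)
    fov = [s * n for s, n in zip(grid.spacing, grid.shape)]
    torso_r = min(0.44 * min(fov[0], fov[1]), 150.0)
    torso_h = 0.92 * fov[2]
    torso = GeometrySpec("cylinder", (0.0, 0.0, 0.0), (torso_r, torso_h))

    # two kidney ellipsoids, posterior-lateral, clipped to the torso
    kax = (min(28.0, 0.35 * torso_r), min(18.0, 0.25 * torso_r),
           min(42.0, 0.4 * torso_h / 2.0))
    kx = 0.55 * torso_r
    kidneys = [
        ("kidney_left", GeometrySpec("ellipsoid", (kx, -0.2 * torso_r, 0.0), kax)),
        ("kidney_right", GeometrySpec("ellipsoid", (-kx, -0.2 * torso_r, 0.0), kax)),
    ]

    # --- draws -------------------------------------------------------------
    ratio_k_mean = spec.kidney_suv_ac225[0] / spec.kidney_suv_lu177[0] - 1.0
    ratio_l_mean = spec.lesion_suv_ac225[0] / spec.lesion_suv_lu177[0] - 1.0

    def paired_suvs(lu_dist, ratio_mean, ratio_sd):
        suv_lu = _truncated_normal(rng, *lu_dist)
        r = rng.normal(ratio_mean, ratio_sd) if ratio_sd > 0 else ratio_mean
        suv_ac = max(suv_lu * (1.0 + r), 1e-3)
        return suv_lu, suv_ac

    voi_geoms: list[tuple[str, GeometrySpec]] = list(kidneys)
    voi_params: dict[str, dict] = {}
    for name, _ in kidneys:
        suv_lu, suv_ac = paired_suvs(spec.kidney_suv_lu177,
                                     ratio_k_mean, spec.kidney_ratio_sd)
        t_eff = min(_lognormal_matched(rng, *spec.kidney_half_life_h),
                    0.98 * LU177.half_life_h)
        voi_params[name] = {"suv_lu": suv_lu, "suv_ac": suv_ac,
                            "t_eff_lu_h": t_eff, "increasing": False,
                            "kind": "kidney"}

    lesion_radii = []
    lesion_names = []
    for i in range(spec.n_lesions):
        vol = _truncated_normal(rng, *spec.lesion_volume_ml, lo=1.0)
        r_mm = (vol * 1000.0 * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        lesion_radii.append(r_mm)
        name = f"lesion_{i + 1}"
        lesion_names.append(name)
        suv_lu, suv_ac = paired_suvs(spec.lesion_suv_lu177,
                                     ratio_l_mean, spec.lesion_ratio_sd)
        increasing = bool(rng.uniform() < spec.p_increasing_uptake)
        t_eff = min(_lognormal_matched(rng, *spec.lesion_half_life_h),
                    0.98 * LU177.half_life_h)
        voi_params[name] = {"suv_lu": suv_lu, "suv_ac": suv_ac,
                            "t_eff_lu_h": t_eff, "increasing": increasing,
                            "kind": "lesion"}

    blocked = [(np.asarray(g.center), max(g.size)) for _, g in kidneys]
    centers = _place_lesions(rng, spec.n_lesions, lesion_radii,
                             torso_r, torso_h, blocked)
    for name, c, r in zip(lesion_names, centers, lesion_radii):
        voi_geoms.append((name, GeometrySpec("sphere", tuple(c), (r,))))

    # --- rasterize ---------------------------------------------------------
    x, y, z = grid.meshgrid()
    torso_in = torso.contains(x, y, z)
    labels = np.zeros(grid.shape, dtype=np.int16)
    names: dict[int, str] = {}
    for lab, (name, geom) in enumerate(voi_geoms, start=1):
        inside = geom.contains(x, y, z) & torso_in
        if not inside.any():
            raise ValueError(f"VOI {name!r} lies outside the grid")
        labels[inside] = lab
        names[lab] = name
    body_label = len(voi_geoms) + 1
    labels[torso_in & (labels == 0)] = body_label
    names[body_label] = "body"

    density = VolumeImage(grid, np.where(torso_in, 1.0, 0.0), "density_g_per_ml")

    # --- concentrations ----------------------------------------------------
    inj_lu = spec.injected_MBq["lu177"]
    inj_ac = spec.injected_MBq["ac225"]
    w = spec.body_weight_kg
    bg24_lu = _suv_to_conc(spec.background_suv, inj_lu, w, 24.0, LU177.half_life_h)
    bg24_ac = _suv_to_conc(spec.background_suv, inj_ac, w, 24.0, AC225.half_life_h)

    lu24 = np.where(torso_in, bg24_lu, 0.0)
    lu48 = np.where(torso_in,
                    bg24_lu * 2.0 ** (-24.0 / spec.background_half_life_h), 0.0)
    ac24 = np.where(torso_in, bg24_ac, 0.0)

    truth = GroundTruthRecord(global_info={
        "seed": spec.seed,
        "injected_MBq": dict(spec.injected_MBq),
        "body_weight_kg": w,
        "background_suv": spec.background_suv,
        "background_half_life_h": spec.background_half_life_h,
    })
    for lab, name in names.items():
        if name == "body":
            continue
        p = voi_params[name]
        sel = labels == lab
        c_lu24 = _suv_to_conc(p["suv_lu"], inj_lu, w, 24.0, LU177.half_life_h)
        c_ac24 = _suv_to_conc(p["suv_ac"], inj_ac, w, 24.0, AC225.half_life_h)
        t_lu = p["t_eff_lu_h"]
        if p["increasing"]:
            # growing uptake between 24 h and 48 h: no decaying fit exists
            c_lu48 = c_lu24 * 2.0 ** (24.0 / t_lu)
            t_ac = None
        else:
            c_lu48 = c_lu24 * 2.0 ** (-24.0 / t_lu)
            t_ac = convert_effective_half_life(t_lu, LU177, AC225)
        lu24[sel] = c_lu24
        lu48[sel] = c_lu48
        ac24[sel] = c_ac24
        entry = {
            "kind": p["kind"],
            "volume_ml": float(sel.sum() * grid.voxel_volume_ml),
            "suv_lu177": p["suv_lu"],
            "suv_ac225": p["suv_ac"],
            "conc_lu177_24h_Bq_per_ml": c_lu24,
            "conc_lu177_48h_Bq_per_ml": c_lu48,
            "conc_ac225_24h_Bq_per_ml": c_ac24,
            "t_eff_lu177_h": t_lu if not p["increasing"] else None,
            "t_eff_ac225_h": t_ac,
            "increasing_uptake": p["increasing"],
        }
        if not p["increasing"]:
            entry["dose_Gy_lu177"] = analytic_voi_dose(
                c_lu24, t_lu, LU177.energy_per_decay_MeV)
            entry["dose_Gy_ac225"] = analytic_voi_dose(
                c_ac24, t_ac, AC225.energy_per_decay_MeV)
            entry["dose_per_admin_lu177_Sv_per_GBq"] = (
                entry["dose_Gy_lu177"] * LU177.rbe / (inj_lu / 1000.0))
            entry["dose_per_admin_ac225_Sv_per_MBq"] = (
                entry["dose_Gy_ac225"] * AC225.rbe / inj_ac)
        truth.voi[name] = entry

    def img(vals, nuclide, t_h):
        return VolumeImage(grid, vals, "activity_conc_Bq_per_ml",
                           {"nuclide": nuclide, "time_h": t_h, "seed": spec.seed})

    maps = {
        "lu177_24h": img(lu24, "Lu-177", 24.0),
        "lu177_48h": img(lu48, "Lu-177", 48.0),
        "ac225_24h": img(ac24, "Ac-225", 24.0),
    }
    return maps, density, VoiMask(grid, labels, names), truth
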