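"""End-to-end study orchestration: phantom figure-of-merit and tandem-patient runs.

A single validated :class:`RunConfig` (YAML-serializable) drives each study;
every output carries the config hash and the seed, and reruns with the same
config are byte-identical.  The phantom study simulates the high-count and
low-count cylinder acquisitions at 440 keV, reconstructs with 60 all-view
MLEM iterations, and tabulates recovery coefficients and SNR against
iteration number and post-filter width.  The tandem-patient study generates
synthetic patients, images them at 24 h (both isotopes) and 48 h (Lu-177),
harmonizes image quality, segments lesions, fits single-time-point kinetics
and produces per-VOI RBE-weighted dose reports with recovery errors against
the generator truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dosimetry import (
    apply_vsv,
    build_vsv_kernel,
    convert_effective_half_life,
    density_weight,
    fit_two_point_half_life,
    voi_dose_report,
    voxel_tia,
)
from .grid import VoiMask, VolumeImage, VoxelGrid, save_volume
from .metrics import gaussian_post_filter, isocontour_voi, match_snr_fwhm, \
    recovery_coefficient, snr, suv_map
from .nuclides import AC225, LU177
from .patients import SyntheticPatientSpec, build_synthetic_patient
from .phantom import build_cylinder_phantom, default_phantom_spec
from .projector import (
    AC225_WINDOWS,
    LU177_WINDOWS,
    AcquisitionGeometry,
    PsfStack,
    add_poisson_noise,
    analytic_psf_stack,
    emulate_scatter_windows,
    forward_project,
    mu_map_from_density,
)
from .recon import (
    AC225_PROTOCOL,
    LU177_PROTOCOL,
    CalibrationFactor,
    calibrate_to_concentration,
    dew_scatter_estimate,
    osem_reconstruct,
    tew_scatter_estimate,
)

__all__ = ["RunConfig", "run_phantom_study", "run_tandem_patient_study"]

log = logging.getLogger("tandemspect")


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; defaults are the clinical protocol values."""

    study: str = "phantom"  # phantom | tandem_patient
    grid_shape: tuple[int, int, int] = (96, 96, 64)
    grid_spacing_mm: tuple[float, float, float] = (4.7952, 4.7952, 4.7952)
    seed: int = 1
    # acquisition (24 h combined protocol): 16 views/head x 2 heads, 3.5 min
    n_views_per_head: int = 16
    heads: int = 2
    time_per_view_s: float = 210.0
    radius_mm: float = 250.0
    # Lu-177 48 h protocol: 64 views/head at 5 s
    n_views_per_head_48h: int = 64
    time_per_view_s_48h: float = 5.0
    sensitivity_cps_per_MBq: dict = field(
        default_factory=lambda: {"lu177": 7.0, "ac225": 22.7})
    scatter_fraction: dict = field(
        default_factory=lambda: {"lu177": 0.3, "ac225": 0.5})
    scatter_blur_fwhm_mm: float = 80.0
    psf_lu177: dict = field(default_factory=lambda: {
        "regime": "gaussian", "intrinsic_fwhm_mm": 4.0, "slope": 0.09})
    psf_ac225: dict = field(default_factory=lambda: {
        "regime": "high_energy", "intrinsic_fwhm_mm": 4.0, "slope": 0.09,
        "penetration_fraction": 0.25, "arm_decay_mm": 40.0})
    iterations_ac225: int = 60
    iterations_lu177: int = 20
    checkpoint_every: int = 10
    filter_candidates_mm: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0)
    # harmonization: Ac fixed, Lu searched
    harmonization_ac_fwhm_mm: float = 30.0
    harmonization_lu_candidates_mm: tuple[float, ...] = (
        20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)
    isocontour_fraction: float = 0.8
    # phantom study
    phantom_background_Bq_per_ml: float = 900.0
    phantom_contrast: float = 6.4
    lc_time_factor: float = 30.0
    count_modes: tuple[str, ...] = ("HC", "LC")
    # patient study
    n_patients: int = 1
    imaging_mode: str = "ideal"  # ideal | realistic
    patient: dict = field(default_factory=dict)  # SyntheticPatientSpec overrides
    background_half_life_h: float = 25.0
    rho_soft_g_per_ml: float = 1.04

    def __post_init__(self) -> None:
        if self.study not in ("phantom", "tandem_patient"):
            raise ValueError(f"unknown study kind {self.study!r}")
        if self.imaging_mode not in ("ideal", "realistic"):
            raise ValueError("imaging_mode must be 'ideal' or 'realistic'")
        if self.iterations_ac225 < 1 or self.iterations_lu177 < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0 < self.isocontour_fraction < 1):
            raise ValueError("isocontour fraction must lie in (0, 1)")
        if self.lc_time_factor <= 0:
            raise ValueError("lc_time_factor must be > 0")
        if not self.count_modes or set(self.count_modes) - {"HC", "LC"}:
            raise ValueError("count_modes must be a non-empty subset of HC/LC")
        VoxelGrid(self.grid_shape, self.grid_spacing_mm)  # validates
        for key in ("lu177", "ac225"):
            if self.sensitivity_cps_per_MBq[key] <= 0:
                raise ValueError("sensitivities must be > 0")
            if self.scatter_fraction[key] < 0:
                raise ValueError("scatter fractions must be >= 0")

    # -- serialization ------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "grid_spacing_mm", "filter_candidates_mm",
                    "harmonization_lu_candidates_mm", "count_modes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    # -- derived objects ----------------------------------------------------
    def make_grid(self) -> VoxelGrid:
        return VoxelGrid.centered(self.grid_shape, self.grid_spacing_mm)

    def geometry(self, protocol_48h: bool = False) -> AcquisitionGeometry:
        pitch = (self.grid_spacing_mm[0], self.grid_spacing_mm[2])
        if protocol_48h:
            return AcquisitionGeometry(self.n_views_per_head_48h, self.heads,
                                       360.0, self.radius_mm,
                                       self.time_per_view_s_48h, pitch)
        return AcquisitionGeometry(self.n_views_per_head, self.heads, 360.0,
                                   self.radius_mm, self.time_per_view_s, pitch)

    def psf(self, nuclide: str) -> PsfStack:
        params = dict(self.psf_lu177 if nuclide == "lu177" else self.psf_ac225)
        pitch = (self.grid_spacing_mm[0], self.grid_spacing_mm[2])
        return analytic_psf_stack(pitch_mm=pitch, **params)


def _write_outputs(out_dir: Path, config: RunConfig, tables: dict[str, pd.DataFrame],
                   volumes: dict[str, VolumeImage], extra: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    (out_dir / "run.json").write_text(json.dumps({**stamp, **extra}, indent=1,
                                                 default=float))
    for name, df in tables.items():
        df = df.copy()
        df["config_hash"] = stamp["config_hash"]
        df["seed"] = stamp["seed"]
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.10g")
    for name, vol in volumes.items():
        save_volume(out_dir / f"{name}.nii.gz", vol)


# ---------------------------------------------------------------------------
# Phantom study

def run_phantom_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """HC + LC cylinder-phantom study at 440 keV: simulate, reconstruct, tabulate.

    Returns a bundle with the figure-of-merit table (rows: count mode, VOI,
    iteration checkpoint, filter; columns RC and SNR), reconstructed volumes
    and the ground truth.
    """
    if config.study != "phantom":
        raise ValueError("config.study must be 'phantom'")
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    grid = config.make_grid()
    spec = default_phantom_spec("HC", config.phantom_background_Bq_per_ml,
                                config.phantom_contrast)
    activity, density, mask, truth = build_cylinder_phantom(spec, grid)
    log.info("phantom: total activity %.3f MBq",
             truth.global_info["total_activity_MBq"])

    geom = config.geometry()
    mu = mu_map_from_density(density, 440.0)
    psf = config.psf("ac225")
    sens = config.sensitivity_cps_per_MBq["ac225"]
    primary = forward_project(activity, mu, psf, geom, sens, nuclide="ac225")
    emu = emulate_scatter_windows(primary, AC225_WINDOWS,
                                  config.scatter_fraction["ac225"],
                                  config.scatter_blur_fwhm_mm)
    cal = CalibrationFactor("ac225", sens)
    protocol = replace(AC225_PROTOCOL, iterations=config.iterations_ac225)
    checkpoints = tuple(range(config.checkpoint_every,
                              config.iterations_ac225 + 1,
                              config.checkpoint_every))

    insert_names = [n for n in mask.names.values() if n.startswith("insert")]
    bg_labels = [lab for lab, n in mask.names.items() if n.startswith("bg_rod")]
    fg_conc = config.phantom_contrast * config.phantom_background_Bq_per_ml

    rows = []
    volumes: dict[str, VolumeImage] = {}
    mode_runs = {"HC": (1.0, rng_seeds[:2]),
                 "LC": (config.lc_time_factor, rng_seeds[2:])}
    for mode in config.count_modes:
        time_factor, seed_pair = mode_runs[mode]
        peak = add_poisson_noise(emu["photopeak"], int(seed_pair[0]), time_factor)
        lower = add_poisson_noise(emu["lower"], int(seed_pair[1]), time_factor)
        scatter = dew_scatter_estimate(lower, AC225_WINDOWS)
        log.info("%s: %d photopeak counts", mode, int(peak.total_counts()))
        final, saved = osem_reconstruct(peak, scatter, mu, psf, protocol, grid,
                                        checkpoints=checkpoints)
        for it, img in sorted({**saved, config.iterations_ac225: final}.items()):
            conc = calibrate_to_concentration(img, cal)
            for fw in config.filter_candidates_mm:
                filt = gaussian_post_filter(conc, fw)
                for name in insert_names:
                    lab = mask.label_of(name)
                    rows.append({
                        "count_mode": mode, "iteration": it, "fwhm_mm": fw,
                        "voi": name,
                        "rc": recovery_coefficient(filt, mask, lab, fg_conc),
                        "snr": snr(filt, mask, lab, bg_labels),
                    })
                bg_mean = np.mean([filt.values[mask.labels == b].mean()
                                   for b in bg_labels])
                rows.append({
                    "count_mode": mode, "iteration": it, "fwhm_mm": fw,
                    "voi": "background",
                    "rc": float(bg_mean / config.phantom_background_Bq_per_ml),
                    "snr": np.nan,
                })
        volumes[f"recon_{mode.lower()}"] = calibrate_to_concentration(final, cal)

    table = pd.DataFrame(rows)
    bundle = {"fom": table, "mask": mask, "truth": truth, "volumes": volumes,
              "activity": activity}
    if out_dir is not None:
        _write_outputs(Path(out_dir), config, {"phantom_fom": table},
                       {**volumes, "activity_truth": activity},
                       {"truth": truth.to_dict()})
    return bundle


# ---------------------------------------------------------------------------
# Tandem patient study

def _image_patient(config: RunConfig, maps: dict[str, VolumeImage],
                   density: VolumeImage, seeds: np.ndarray) -> dict[str, VolumeImage]:
    """Measured (reconstructed, calibrated) concentration maps per acquisition.

    ``ideal`` mode is the perfect-imaging limit (no PSF, scatter, noise, and
    exact attenuation correction): the measured maps equal the true ones.
    """
    if config.imaging_mode == "ideal":
        return {k: v.copy_with(v.values.copy()) for k, v in maps.items()}
    grid = maps["lu177_24h"].grid
    out = {}
    specs = {
        "lu177_24h": ("lu177", 208.0, LU177_WINDOWS, False),
        "lu177_48h": ("lu177", 208.0, LU177_WINDOWS, True),
        "ac225_24h": ("ac225", 440.0, AC225_WINDOWS, False),
    }
    for i, (key, (nuc, energy, windows, is48)) in enumerate(specs.items()):
        geom = config.geometry(protocol_48h=is48)
        mu = mu_map_from_density(density, energy)
        psf = config.psf(nuc)
        sens = config.sensitivity_cps_per_MBq[nuc]
        primary = forward_project(maps[key], mu, psf, geom, sens, nuclide=nuc)
        emu = emulate_scatter_windows(windows=windows, primary=primary,
                                     scatter_fraction=config.scatter_fraction[nuc],
                                     blur_fwhm_mm=config.scatter_blur_fwhm_mm)
        peak = add_poisson_noise(emu["photopeak"], int(seeds[3 * i]))
        if nuc == "lu177":
            low = add_poisson_noise(emu["lower"], int(seeds[3 * i + 1]))
            up = add_poisson_noise(emu["upper"], int(seeds[3 * i + 2]))
            scatter = tew_scatter_estimate(low, up, windows)
            protocol = replace(LU177_PROTOCOL, iterations=config.iterations_lu177)
            if geom.total_views % 16 != 0:
                protocol = replace(protocol, projections_per_subset=0)
        else:
            low = add_poisson_noise(emu["lower"], int(seeds[3 * i + 1]))
            scatter = dew_scatter_estimate(low, windows)
            protocol = replace(AC225_PROTOCOL, iterations=config.iterations_ac225)
        rec = osem_reconstruct(peak, scatter, mu, psf, protocol, grid)
        conc = calibrate_to_concentration(rec, CalibrationFactor(nuc, sens))
        out[key] = conc.copy_with(conc.values, meta={**maps[key].meta,
                                                     **conc.meta})
    return out


def run_tandem_patient_study(config: RunConfig,
                             out_dir: str | Path | None = None) -> dict:
    """Synthetic tandem-therapy cohort: image, harmonize, fit, dose, compare.

    Per patient: generate ground truth; acquire/reconstruct Lu-177 at 24 h and
    48 h and the Ac-225 chain at 24 h; harmonize SNR (Ac fixed filter, Lu
    searched); segment lesions by isocontour; compute SUVs; fit the two-point
    Lu-177 effective half-life per VOI (excluding increasing-uptake lesions);
    convert half-lives to Ac-225; integrate TIA; apply the VSV kernel, density
    and RBE weighting; report per-VOI doses and recovery errors vs truth.
    """
    if config.study != "tandem_patient":
        raise ValueError("config.study must be 'tandem_patient'")
    grid = config.make_grid()
    base_patient = dict(config.patient)
    master = np.random.SeedSequence(config.seed)
    cohort_rows = []
    dose_tables = []
    bundles = []

    for ip, child in enumerate(master.spawn(config.n_patients), start=1):
        seeds = child.generate_state(16) % (2**31)
        pspec = SyntheticPatientSpec(**{**base_patient, "seed": int(seeds[0])})
        maps, density, mask, truth = build_synthetic_patient(pspec, grid)
        measured = _image_patient(config, maps, density, seeds[1:])
        inj = truth.global_info["injected_MBq"]
        weight = truth.global_info["body_weight_kg"]
        body_label = mask.label_of("body")
        voi_labels = {lab: n for lab, n in mask.names.items() if n != "body"}
        kidney_labels = [lab for lab, n in voi_labels.items()
                         if n.startswith("kidney")]

        # --- harmonization (realistic imaging only) ------------------------
        if config.imaging_mode == "realistic":
            harm = match_snr_fwhm(
                measured["lu177_24h"], measured["ac225_24h"], mask,
                kidney_labels[0], [body_label],
                list(config.harmonization_lu_candidates_mm),
                fwhm_b_mm=config.harmonization_ac_fwhm_mm)
            lu_fwhm = harm.chosen_fwhm_mm
            ac_fwhm = config.harmonization_ac_fwhm_mm
        else:
            harm = None
            lu_fwhm = ac_fwhm = 0.0
        lu24 = gaussian_post_filter(measured["lu177_24h"], lu_fwhm)
        lu48 = gaussian_post_filter(measured["lu177_48h"], lu_fwhm)
        ac24 = gaussian_post_filter(measured["ac225_24h"], ac_fwhm)

        # --- per-VOI uptake and kinetics -----------------------------------
        suv_lu_img = suv_map(lu24, inj["lu177"], weight, 24.0, LU177)
        suv_ac_img = suv_map(ac24, inj["ac225"], weight, 24.0, AC225)
        half_life_lu = {"background": config.background_half_life_h,
                        "body": config.background_half_life_h}
        half_life_ac = {"background": convert_effective_half_life(
            config.background_half_life_h, LU177, AC225)}
        half_life_ac["body"] = half_life_ac["background"]
        n_excluded = 0
        for lab, name in voi_labels.items():
            sel = mask.labels == lab
            is_lesion = truth.voi[name]["kind"] == "lesion"
            if is_lesion:
                # lesion uptake on the harmonized images via 80 % isocontour
                seed_vox = tuple(int(np.mean(ax)) for ax in np.where(sel))
                iso = isocontour_voi(ac24, seed_vox, config.isocontour_fraction,
                                     name=name)
                suv_ac_meas = float(suv_ac_img.values[iso.labels == 1].mean())
                iso_lu = isocontour_voi(lu24, seed_vox, config.isocontour_fraction,
                                        name=name)
                suv_lu_meas = float(suv_lu_img.values[iso_lu.labels == 1].mean())
                seg_volume = float(iso.labels.sum() * grid.voxel_volume_ml)
            else:
                suv_ac_meas = float(suv_ac_img.values[sel].mean())
                suv_lu_meas = float(suv_lu_img.values[sel].mean())
                seg_volume = float(sel.sum() * grid.voxel_volume_ml)

            a24 = float(lu24.values[sel].mean())
            a48 = float(lu48.values[sel].mean())
            kin = fit_two_point_half_life(a24, 24.0, a48, 48.0, name)
            if kin.excluded:
                n_excluded += 1
                t_lu = t_ac = None
            else:
                t_lu = kin.half_life_h
                t_ac = convert_effective_half_life(t_lu, LU177, AC225)
                half_life_lu[name] = t_lu
                half_life_ac[name] = t_ac

            tv = truth.voi[name]
            cohort_rows.append({
                "patient": ip, "voi": name, "kind": tv["kind"],
                "segmented_volume_ml": seg_volume,
                "true_volume_ml": tv["volume_ml"],
                "suv_lu177": suv_lu_meas, "suv_lu177_true": tv["suv_lu177"],
                "suv_ac225": suv_ac_meas, "suv_ac225_true": tv["suv_ac225"],
                "t_eff_lu177_h": t_lu, "t_eff_lu177_true_h": tv["t_eff_lu177_h"],
                "t_eff_ac225_h": t_ac, "t_eff_ac225_true_h": tv["t_eff_ac225_h"],
                "excluded": kin.excluded,
                "harmonized_fwhm_lu_mm": lu_fwhm,
                "harmonized_fwhm_ac_mm": ac_fwhm,
            })

        # --- dosimetry ------------------------------------------------------
        evaluable = [lab for lab, n in voi_labels.items() if n in half_life_lu]
        for nuc_key, nuc, act_img, hl in (
            ("lu177", LU177, lu24, half_life_lu),
            ("ac225", AC225, ac24, half_life_ac),
        ):
            # excluded lesions carry no fitted half-life; their voxels fall
            # back to the background default (their dose rows are dropped)
            tia_hl = {**{n: hl["background"] for n in mask.names.values()}, **hl}
            tia = voxel_tia(act_img, mask, tia_hl, 24.0)
            kernel = build_vsv_kernel(nuc, grid)
            raw = apply_vsv(tia, kernel)
            # kernel spill-out past the body edge deposits in air; discard it
            raw = raw.copy_with(np.where(density.values > 0, raw.values, 0.0))
            # the density reference of the weighting must match the density
            # the kernel was derived for, else a constant bias enters
            dose = density_weight(raw, density, kernel.reference_density_g_per_ml)
            report = voi_dose_report(dose, mask, inj[nuc_key], nuc,
                                     half_life_h=hl, labels=evaluable)
            report.insert(0, "patient", ip)
            truth_dpa = {
                n: truth.voi[n].get(
                    "dose_per_admin_lu177_Sv_per_GBq" if nuc_key == "lu177"
                    else "dose_per_admin_ac225_Sv_per_MBq")
                for n in report.voi
            }
            report["dose_per_admin_true"] = report.voi.map(truth_dpa)
            dose_tables.append(report)

        bundles.append({"patient": ip, "truth": truth, "mask": mask,
                        "measured": measured, "harmonization": harm,
                        "n_excluded": n_excluded})
        log.info("patient %d: %d VOIs, %d excluded lesions",
                 ip, len(voi_labels), n_excluded)

    cohort = pd.DataFrame(cohort_rows)
    doses = pd.concat(dose_tables, ignore_index=True) if dose_tables else \
        pd.DataFrame()
    out = {"cohort": cohort, "doses": doses, "patients": bundles}
    if out_dir is not None:
        _write_outputs(Path(out_dir), config,
                       {"cohort": cohort, "doses": doses}, {},
                       {"n_patients": config.n_patients,
                        "imaging_mode": config.imaging_mode})
    return out
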