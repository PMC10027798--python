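"""Image figures of merit and cross-isotope harmonization.

Recovery coefficient (RC) = mean measured concentration in the CT-truth VOI
over the true concentration; SNR = insert mean over the pooled voxel sd of
the background rod VOIs.  Harmonization searches a grid of Gaussian
post-filter widths on one image for the closest SNR match to the other —
the procedure used to make the noisy 440 keV Ac-225 chain image and the
Lu-177 image visually and quantitatively comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label

from .grid import VoiMask, VolumeImage
from .nuclides import get_nuclide

__all__ = [
    "FilterSpec",
    "HarmonizationResult",
    "gaussian_post_filter",
    "recovery_coefficient",
    "snr",
    "match_snr_fwhm",
    "isocontour_voi",
    "suv_map",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class FilterSpec:
    fwhm_mm: float
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm must be >= 0")
        if self.kind != "gaussian":
            raise ValueError("only gaussian filters are supported")


@dataclass
class HarmonizationResult:
    chosen_fwhm_mm: float
    reference_snr: float
    table: pd.DataFrame  # columns: fwhm_mm, snr
    voi_name: str


def gaussian_post_filter(image: VolumeImage, f: FilterSpec | float) -> VolumeImage:
    """Separable Gaussian post-filter, sigma = FWHM/2.3548 per axis in mm.

    Reflective borders keep the global sum preserved (to 1e-6 relative);
    FWHM 0 is the identity.
    """
    if not isinstance(f, FilterSpec):
        f = FilterSpec(float(f))
    if f.fwhm_mm == 0:
        return image.copy_with(image.values.copy())
    sigma_vox = [f.fwhm_mm * FWHM_TO_SIGMA / s for s in image.grid.spacing]
    out = gaussian_filter(image.values, sigma_vox, mode="reflect")
    return image.copy_with(out, meta={**image.meta, "post_filter_fwhm_mm": f.fwhm_mm})


def recovery_coefficient(image: VolumeImage, mask: VoiMask, label: int,
                         truth_conc_Bq_per_ml: float) -> float:
    """RC = mean measured concentration in the truth-geometry VOI / truth."""
    if truth_conc_Bq_per_ml <= 0:
        raise ValueError("truth concentration must be > 0")
    if image.grid != mask.grid:
        raise ValueError("image and mask grids differ")
    sel = image.values[mask.labels == label]
    if sel.size == 0:
        raise ValueError(f"label {label} not present")
    return float(sel.mean() / truth_conc_Bq_per_ml)


def snr(image: VolumeImage, mask: VoiMask, insert_label: int,
        background_labels: list[int]) -> float:
    """SNR = insert mean / sd of the pooled background-VOI voxels."""
    if not background_labels:
        raise ValueError("background labels must be non-empty")
    if image.grid != mask.grid:
        raise ValueError("image and mask grids differ")
    ins = image.values[mask.labels == insert_label]
    if ins.size == 0:
        raise ValueError(f"insert label {insert_label} not present")
    bg = image.values[np.isin(mask.labels, background_labels)]
    if bg.size < 2:
        raise ValueError("background VOIs too small")
    sd = float(bg.std(ddof=1))
    if sd == 0:
        raise ValueError("background sd is zero; SNR undefined")
    return float(ins.mean() / sd)


def match_snr_fwhm(
    image_a: VolumeImage,
    image_b: VolumeImage,
    mask: VoiMask,
    insert_label: int,
    background_labels: list[int],
    candidates_fwhm_mm: list[float],
    fwhm_b_mm: float = 0.0,
) -> HarmonizationResult:
    """Choose the filter width for image A whose VOI SNR best matches image B.

    Image B is filtered at the fixed ``fwhm_b_mm`` first; ties between
    candidates break toward the smaller width.
    """
    if not candidates_fwhm_mm:
        raise ValueError("candidate list must be non-empty")
    ref = snr(gaussian_post_filter(image_b, fwhm_b_mm), mask,
              insert_label, background_labels)
    rows = []
    for f in sorted(candidates_fwhm_mm):
        s = snr(gaussian_post_filter(image_a, f), mask,
                insert_label, background_labels)
        rows.append({"fwhm_mm": f, "snr": s})
    table = pd.DataFrame(rows)
    best = table.loc[(table.snr - ref).abs().idxmin()]  # idxmin: first = smallest
    return HarmonizationResult(float(best.fwhm_mm), float(ref), table,
                               mask.names.get(insert_label, str(insert_label)))


def isocontour_voi(image: VolumeImage, seed_voxel: tuple[int, int, int],
                   threshold_fraction: float = 0.8,
                   name: str = "isocontour") -> VoiMask:
    """Isocontour VOI at a fraction of the local maximum reached from a seed.

    Hill-climbs (26-neighborhood) from the seed to a local maximum, thresholds
    the image at ``fraction x max``, and keeps the connected component
    (26-connectivity) containing that maximum.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold fraction must lie in (0, 1)")
    vals = image.values
    if vals.max() == vals.min():
        raise ValueError("flat image: isocontour undefined")
    idx = tuple(int(i) for i in seed_voxel)
    if any(not (0 <= i < s) for i, s in zip(idx, vals.shape)):
        raise ValueError("seed outside image")
    # hill-climb to the local max
    while True:
        lo = tuple(max(i - 1, 0) for i in idx)
        hi = tuple(min(i + 2, s) for i, s in zip(idx, vals.shape))
        patch = vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        best = np.unravel_index(np.argmax(patch), patch.shape)
        nxt = tuple(l + b for l, b in zip(lo, best))
        if vals[nxt] <= vals[idx]:
            break
        idx = nxt
    thr = threshold_fraction * vals[idx]
    above = vals >= thr
    comps = cc_label(above, connectivity=3)
    sel = comps == comps[idx]
    return VoiMask(image.grid, sel.astype(np.int16), {1: name})


def suv_map(conc: VolumeImage, injected_MBq: float, weight_kg: float,
            reference_time_h: float, nuclide) -> VolumeImage:
    """SUV = concentration / (decay-corrected injected activity per g body mass).

    The injected activity is decayed to the scan time with the nuclide's
    physical half-life; tissue density 1 g/ml.
    """
    if injected_MBq <= 0 or weight_kg <= 0:
        raise ValueError("injected activity and weight must be > 0")
    if conc.quantity != "activity_conc_Bq_per_ml":
        raise ValueError("suv_map expects an activity concentration image")
    nuc = get_nuclide(nuclide)
    injected_bq = injected_MBq * 1e6 * nuc.decay_factor(reference_time_h)
    denom = injected_bq / (weight_kg * 1000.0)
    return VolumeImage(conc.grid, conc.values / denom, "suv",
                       {**conc.meta, "nuclide": nuc.name,
                        "reference_time_h": reference_time_h})
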