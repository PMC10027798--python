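"""SPECT forward model: attenuated, collimator-blurred, energy-windowed projections.

The projector is rotation-based: for each view the activity volume is rotated
(bilinear, about the scanner axis z) so the detector lies along +y, attenuated
cumulatively toward the detector, each constant-distance plane is convolved
with the point-spread-function (PSF) kernel for its source-to-collimator
distance, and the planes are summed.  Rotation is realized as a sparse matrix
so the adjoint used by MLEM is the exact transpose of the forward operator;
the plane convolutions use centrosymmetric kernels and are therefore
self-adjoint, which makes forward/adjoint an exact pair to rounding error.

The collimator-detector response comes in two regimes: an isotropic
distance-dependent Gaussian (Lu-177, 208 keV) and a "high-energy" model for
the 440 keV Bi-213 gamma in which a fraction of the counts is diverted into
exponentially decaying star arms, emulating the anisotropic septal
penetration of a hexagonal-bore high-energy collimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft
import scipy.sparse as sp

from .grid import VolumeImage, VoxelGrid

__all__ = [
    "EnergyWindow",
    "EnergyWindowSet",
    "AcquisitionGeometry",
    "PsfStack",
    "ProjectionSet",
    "LU177_WINDOWS",
    "AC225_WINDOWS",
    "mu_map_from_density",
    "water_mass_attenuation",
    "analytic_psf_stack",
    "SpectProjector",
    "forward_project",
    "emulate_scatter_windows",
    "default_scatter_model",
    "add_poisson_noise",
    "crosstalk_fraction",
]

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548


# ---------------------------------------------------------------------------
# Energy windows

@dataclass(frozen=True)
class EnergyWindow:
    center_keV: float
    frac_width: float
    tag: str = "photopeak"  # photopeak | lower | upper

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_width < 1.0):
            raise ValueError("fractional width must lie in (0, 1)")

    @property
    def width_keV(self) -> float:
        return self.center_keV * self.frac_width

    @property
    def bounds_keV(self) -> tuple[float, float]:
        half = self.width_keV / 2.0
        return (self.center_keV - half, self.center_keV + half)

    def contains(self, energy_keV: float) -> bool:
        lo, hi = self.bounds_keV
        return lo <= energy_keV <= hi


@dataclass(frozen=True)
class EnergyWindowSet:
    photopeak: EnergyWindow
    scatter: tuple[EnergyWindow, ...] = ()

    def __post_init__(self) -> None:
        wins = (self.photopeak,) + tuple(self.scatter)
        bounds = sorted(w.bounds_keV for w in wins)
        for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
            if lo2 < hi1 - 1e-9:
                raise ValueError("energy windows overlap")

    def scatter_window(self, tag: str) -> EnergyWindow:
        for w in self.scatter:
            if w.tag == tag:
                return w
        raise KeyError(f"no scatter window tagged {tag!r}")


#: Lu-177: 208 keV photopeak (15 %), lower 170 keV (15 %) / upper 240 keV (10 %).
LU177_WINDOWS = EnergyWindowSet(
    photopeak=EnergyWindow(208.0, 0.15),
    scatter=(EnergyWindow(170.0, 0.15, "lower"), EnergyWindow(240.0, 0.10, "upper")),
)

#: Ac-225 chain: 440 keV photopeak (20 % total width) with one adjacent lower
#: scatter window of the same absolute width as 10 % of 440 keV.
AC225_WINDOWS = EnergyWindowSet(
    photopeak=EnergyWindow(440.0, 0.20),
    scatter=(EnergyWindow(374.0, 44.0 / 374.0, "lower"),),
)


# ---------------------------------------------------------------------------
# Acquisition geometry

@dataclass(frozen=True)
class AcquisitionGeometry:
    """Circular-orbit step-and-shoot acquisition.

    ``n_views`` counts the views of a single head; total views are
    ``n_views * heads``, spread evenly over ``angular_span_deg``.
    """

    n_views: int = 16
    heads: int = 2
    angular_span_deg: float = 360.0
    radius_mm: float = 250.0
    time_per_view_s: float = 210.0
    det_pitch_mm: tuple[float, float] = (4.7952, 4.7952)

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.time_per_view_s <= 0:
            raise ValueError("time per view must be > 0")

    @property
    def total_views(self) -> int:
        return self.n_views * self.heads

    def view_angles_deg(self) -> np.ndarray:
        return np.arange(self.total_views) * self.angular_span_deg / self.total_views


@dataclass
class ProjectionSet:
    """Per-view 2-D count arrays plus everything needed to reproduce them."""

    views: np.ndarray  # (n_views_total, nx, nz)
    geometry: AcquisitionGeometry
    window: str = "photopeak"
    nuclide: str = ""
    noisy: bool = False
    seed: int | None = None
    time_factor: float = 1.0  # acquisition time divisor (low-count emulation)

    def __post_init__(self) -> None:
        self.views = np.asarray(self.views, dtype=np.float64)
        if self.views.ndim != 3:
            raise ValueError("views must be (n_views, nx, nz)")
        if self.views.shape[0] != self.geometry.total_views:
            raise ValueError("view count does not match geometry")
        if np.any(self.views < 0):
            raise ValueError("counts must be >= 0")

    def total_counts(self) -> float:
        return float(self.views.sum())


# ---------------------------------------------------------------------------
# Attenuation

# Water mass attenuation coefficients mu/rho [cm^2/g] (NIST, total with
# coherent scattering), log-log interpolated between entries.
_WATER_MU_RHO = np.array([
    [60.0, 0.2059],
    [80.0, 0.1837],
    [100.0, 0.1707],
    [150.0, 0.1505],
    [200.0, 0.1370],
    [300.0, 0.1186],
    [400.0, 0.1061],
    [500.0, 0.09687],
    [600.0, 0.08956],
    [800.0, 0.07865],
    [1000.0, 0.07072],
])


def water_mass_attenuation(energy_keV: float) -> float:
    """Water mass attenuation coefficient [cm^2/g] at ``energy_keV``."""
    e = _WATER_MU_RHO[:, 0]
    if not (e[0] <= energy_keV <= e[-1]):
        raise ValueError(
            f"energy {energy_keV} keV outside attenuation table [{e[0]}, {e[-1]}]"
        )
    return float(np.exp(np.interp(np.log(energy_keV), np.log(e),
                                  np.log(_WATER_MU_RHO[:, 1]))))


def mu_map_from_density(density: VolumeImage, energy_keV: float) -> VolumeImage:
    """Linear attenuation map [mm^-1]: density times the water mu/rho value.

    Tissue is treated as water of the local density, the standard soft-tissue
    approximation for CT-based attenuation correction at these energies.
    """
    mu_rho_mm = water_mass_attenuation(energy_keV) / 10.0  # cm^2/g -> mm^2/mg? no:
    # mu/rho [cm^2/g] * rho [g/cm^3] = mu [cm^-1]; density is g/ml = g/cm^3,
    # so mu [mm^-1] = mu/rho * density / 10.
    mu = density.values * mu_rho_mm
    return density.copy_with(mu, quantity="mu_per_mm",
                             meta={**density.meta, "energy_keV": energy_keV})


# ---------------------------------------------------------------------------
# PSF stack

@dataclass
class PsfStack:
    """Ordered 2-D collimator-detector response kernels by source distance."""

    distances_mm: np.ndarray
    kernels: list[np.ndarray]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=np.float64)
        if len(self.kernels) != self.distances_mm.size:
            raise ValueError("one kernel per distance required")

    def kernel_for(self, distance_mm: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.distances_mm - distance_mm)))
        return self.kernels[idx]

    def index_for(self, distance_mm: float) -> int:
        return int(np.argmin(np.abs(self.distances_mm - distance_mm)))

    @classmethod
    def delta(cls, pitch_mm: tuple[float, float] = (4.7952, 4.7952)) -> "PsfStack":
        """Ideal collimator: a single identity kernel at every distance."""
        return cls(np.array([0.0]), [np.ones((1, 1))], {"regime": "delta"})


def _star_arm_kernel(xx: np.ndarray, zz: np.ndarray, n_arm_pairs: int,
                     decay_mm: float, cross_sigma_mm: float) -> np.ndarray:
    """Star of 2*n_arm_pairs exponential arms with Gaussian cross profile."""
    r = np.hypot(xx, zz)
    phi = np.arctan2(zz, xx)
    arms = np.zeros_like(r)
    for i in range(2 * n_arm_pairs):
        angle = i * np.pi / n_arm_pairs
        # perpendicular distance from the ray through the origin at `angle`
        perp = np.abs(-np.sin(angle) * xx + np.cos(angle) * zz)
        along = np.cos(angle) * xx + np.sin(angle) * zz
        ray = (along > 0) & (r > 0)
        arms += np.where(
            ray,
            np.exp(-r / decay_mm) * np.exp(-0.5 * (perp / cross_sigma_mm) ** 2),
            0.0,
        )
    return arms


def analytic_psf_stack(
    regime: str = "gaussian",
    intrinsic_fwhm_mm: float = 4.0,
    slope: float = 0.09,
    penetration_fraction: float = 0.0,
    n_arm_pairs: int = 3,
    arm_decay_mm: float = 40.0,
    n_planes: int = 150,
    max_distance_mm: float = 600.0,
    pitch_mm: tuple[float, float] = (4.7952, 4.7952),
    max_kernel_radius_mm: float = 130.0,
) -> PsfStack:
    """Analytic collimator-detector response stack.

    ``gaussian``: isotropic Gaussians, FWHM(d) = sqrt(intrinsic^2 + (slope*d)^2).
    ``high_energy``: the same Gaussian core carrying (1 - p) of the counts plus
    ``2 * n_arm_pairs`` exponential-decay star arms (hexagonal collimator
    symmetry) carrying fraction ``p = penetration_fraction``.

    Every kernel is normalized to unit sum and symmetrized, so the stack
    conserves counts and the projector's plane convolutions are self-adjoint.
    """
    if regime not in ("gaussian", "high_energy"):
        raise ValueError(f"unknown PSF regime {regime!r}")
    if intrinsic_fwhm_mm <= 0 or slope <= 0 or arm_decay_mm <= 0:
        raise ValueError("PSF model parameters must be positive")
    if not (0.0 <= penetration_fraction < 1.0):
        raise ValueError("penetration fraction must lie in [0, 1)")
    p = penetration_fraction if regime == "high_energy" else 0.0

    distances = np.linspace(0.0, max_distance_mm, n_planes)
    fwhm = np.sqrt(intrinsic_fwhm_mm**2 + (slope * distances) ** 2)
    max_sigma = fwhm.max() * GAUSS_FWHM_TO_SIGMA
    radius_mm = 4.0 * max_sigma
    if p > 0:
        radius_mm = max(radius_mm, min(3.5 * arm_decay_mm, max_kernel_radius_mm))
    nx = int(np.ceil(radius_mm / pitch_mm[0]))
    nz = int(np.ceil(radius_mm / pitch_mm[1]))
    x = (np.arange(-nx, nx + 1)) * pitch_mm[0]
    z = (np.arange(-nz, nz + 1)) * pitch_mm[1]
    xx, zz = np.meshgrid(x, z, indexing="ij")
    rsq = xx**2 + zz**2

    kernels = []
    for d, f in zip(distances, fwhm):
        sigma = f * GAUSS_FWHM_TO_SIGMA
        core = np.exp(-0.5 * rsq / sigma**2)
        core /= core.sum()
        if p > 0:
            arms = _star_arm_kernel(xx, zz, n_arm_pairs, arm_decay_mm,
                                    cross_sigma_mm=max(sigma, pitch_mm[0]))
            # remove the near-origin part already covered by the core
            arm_sum = arms.sum()
            if arm_sum > 0:
                k = (1.0 - p) * core + p * arms / arm_sum
            else:
                k = core
        else:
            k = core
        k = 0.5 * (k + k[::-1, ::-1])  # enforce exact centrosymmetry
        k /= k.sum()
        kernels.append(k)
    return PsfStack(distances, kernels, {
        "regime": regime,
        "intrinsic_fwhm_mm": intrinsic_fwhm_mm,
        "slope": slope,
        "penetration_fraction": p,
        "n_arm_pairs": n_arm_pairs,
        "arm_decay_mm": arm_decay_mm,
    })


# ---------------------------------------------------------------------------
# Projector

def _rotation_matrix(grid: VoxelGrid, angle_deg: float) -> sp.csr_matrix:
    """Sparse bilinear in-plane rotation operator about the world z-axis.

    Maps a flattened (nx*ny) transaxial plane to its rotated counterpart by
    gathering from the 4 bilinear neighbours; samples falling outside the grid
    contribute zero (zero padding), keeping the operator linear with an exact
    transpose.
    """
    nx, ny = grid.shape[0], grid.shape[1]
    xc = grid.axis_coords(0)
    yc = grid.axis_coords(1)
    xo, yo = np.meshgrid(xc, yc, indexing="ij")
    th = np.deg2rad(angle_deg)
    # source point: rotate the output sample back by -angle
    xs = np.cos(th) * xo - np.sin(th) * yo
    ys = np.sin(th) * xo + np.cos(th) * yo
    fx = (xs - grid.origin[0]) / grid.spacing[0]
    fy = (ys - grid.origin[1]) / grid.spacing[1]
    i0 = np.floor(fx).astype(np.int64)
    j0 = np.floor(fy).astype(np.int64)
    tx = fx - i0
    ty = fy - j0

    rows, cols, vals = [], [], []
    out_idx = np.arange(nx * ny)
    for di, wx in ((0, 1.0 - tx), (1, tx)):
        for dj, wy in ((0, 1.0 - ty), (1, ty)):
            ii = i0 + di
            jj = j0 + dj
            ok = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny)
            w = (wx * wy).ravel()
            okf = ok.ravel() & (w > 0)
            rows.append(out_idx[okf])
            cols.append((ii * ny + jj).ravel()[okf])
            vals.append(w[okf])
    mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    )
    return mat


class _PlaneConvolver:
    """Batched per-plane 2-D convolution with distance-indexed kernels.

    Works on volumes in rotated-frame layout (nx, ny, nz): plane j (all x, z
    at depth y_j) is convolved with the PSF kernel for its distance to the
    collimator.  FFT-based; kernels are centered so the operation is exactly
    self-adjoint for centrosymmetric kernels.
    """

    def __init__(self, grid: VoxelGrid, psf: PsfStack, radius_mm: float):
        nx, ny, nz = grid.shape
        self.trivial = all(k.shape == (1, 1) for k in psf.kernels)
        if self.trivial:
            return
        kx = max(k.shape[0] for k in psf.kernels)
        kz = max(k.shape[1] for k in psf.kernels)
        self.px = scipy.fft.next_fast_len(nx + kx - 1)
        self.pz = scipy.fft.next_fast_len(nz + kz - 1)
        self.nx, self.nz = nx, nz
        yc = grid.axis_coords(1)
        dist = radius_mm - yc  # source-to-collimator distance per depth plane
        kidx = [psf.index_for(d) for d in dist]
        # pre-transform one kernel per used stack index, then map planes to it
        used = sorted(set(kidx))
        kf = {}
        for u in used:
            k = psf.kernels[u]
            kpad = np.zeros((self.px, self.pz))
            kpad[: k.shape[0], : k.shape[1]] = k
            kpad = np.roll(kpad, (-(k.shape[0] // 2), -(k.shape[1] // 2)), axis=(0, 1))
            kf[u] = scipy.fft.rfft2(kpad)
        self.kf_planes = np.stack([kf[i] for i in kidx])  # (ny, px, pz//2+1)

    def apply(self, vol: np.ndarray) -> np.ndarray:
        """vol: (nx, ny, nz) in the rotated frame -> same shape, blurred."""
        if self.trivial:
            return vol
        planes = np.moveaxis(vol, 1, 0)  # (ny, nx, nz)
        pf = scipy.fft.rfft2(planes, s=(self.px, self.pz))
        out = scipy.fft.irfft2(pf * self.kf_planes, s=(self.px, self.pz))
        out = out[:, : self.nx, : self.nz]
        return np.ascontiguousarray(np.moveaxis(out, 0, 1))


class SpectProjector:
    """Linear SPECT system operator A and its exact adjoint A^T.

    Forward maps an activity volume (Bq/ml) to expected counts per detector
    pixel per view.  The overall scale is
    ``counts = (Bq/ml -> MBq per voxel) * sensitivity [cps/MBq] * time [s]``;
    with no attenuation and a delta PSF, each view's total equals
    total activity [MBq] x sensitivity x time per view.
    """

    def __init__(
        self,
        grid: VoxelGrid,
        geometry: AcquisitionGeometry,
        psf: PsfStack | None = None,
        mu: VolumeImage | None = None,
        sensitivity_cps_per_MBq: float = 1.0,
    ):
        self.grid = grid
        self.geometry = geometry
        self.psf = psf if psf is not None else PsfStack.delta()
        self.sensitivity = float(sensitivity_cps_per_MBq)
        self.angles = geometry.view_angles_deg()
        self._rot = [_rotation_matrix(grid, a) for a in self.angles]
        self._conv = _PlaneConvolver(grid, self.psf, geometry.radius_mm)
        self._att: list[np.ndarray] | None = None
        if mu is not None:
            self.set_attenuation(mu)
        # Bq/ml -> MBq per voxel, times cps/MBq, times s  =>  counts
        self.scale = (
            grid.voxel_volume_ml * 1e-6 * self.sensitivity * geometry.time_per_view_s
        )

    # -- helpers ------------------------------------------------------------
    def _rotate(self, vol: np.ndarray, i_view: int, adjoint: bool = False) -> np.ndarray:
        """In-plane rotation into (forward) / out of (adjoint) the view frame.

        The forward direction uses the *splat* (transpose of the bilinear
        gather): it conserves total activity exactly, so view totals do not
        depend on object position.  The adjoint is then the gather, keeping
        forward/adjoint an exact transpose pair.
        """
        nx, ny, nz = self.grid.shape
        flat = vol.reshape(nx * ny, nz)
        m = self._rot[i_view]
        out = (m @ flat) if adjoint else (m.T @ flat)
        return out.reshape(nx, ny, nz)

    def _rotate_field(self, vol: np.ndarray, i_view: int) -> np.ndarray:
        """Value-interpolating (gather) rotation for non-emission fields (mu)."""
        nx, ny, nz = self.grid.shape
        out = self._rot[i_view] @ vol.reshape(nx * ny, nz)
        return out.reshape(nx, ny, nz)

    def set_attenuation(self, mu: VolumeImage | None) -> None:
        """Precompute per-view voxel-to-detector attenuation factors."""
        if mu is None:
            self._att = None
            return
        if mu.grid != self.grid:
            raise ValueError("mu grid does not match projector grid")
        dy = self.grid.spacing[1]
        att = []
        for i in range(len(self.angles)):
            mu_rot = self._rotate_field(mu.values, i)
            # detector at +y: path integral from voxel center to the far y edge,
            # counting half of the voxel's own mu (midpoint convention)
            s = np.cumsum(mu_rot[:, ::-1, :], axis=1)[:, ::-1, :]
            att.append(np.exp(-dy * (s - 0.5 * mu_rot)))
        self._att = att

    # -- operator -----------------------------------------------------------
    def forward(self, activity: np.ndarray) -> np.ndarray:
        """Expected counts, shape (n_views_total, nx, nz)."""
        if tuple(activity.shape) != self.grid.shape:
            raise ValueError("activity shape does not match projector grid")
        views = np.empty(
            (len(self.angles), self.grid.shape[0], self.grid.shape[2]))
        for i in range(len(self.angles)):
            vol = self._rotate(activity, i)
            if self._att is not None:
                vol = vol * self._att[i]
            vol = self._conv.apply(vol)
            views[i] = vol.sum(axis=1)
        return views * self.scale

    def adjoint(self, views: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`forward`."""
        nx, ny, nz = self.grid.shape
        if views.shape != (len(self.angles), nx, nz):
            raise ValueError("views shape does not match geometry")
        out = np.zeros(self.grid.shape)
        for i in range(len(self.angles)):
            vol = np.broadcast_to(views[i][:, None, :], (nx, ny, nz)).copy()
            vol = self._conv.apply(vol)
            if self._att is not None:
                vol = vol * self._att[i]
            out += self._rotate(vol, i, adjoint=True)
        return out * self.scale

    def forward_subset(self, activity: np.ndarray, view_idx: np.ndarray) -> np.ndarray:
        full = np.empty((len(view_idx), self.grid.shape[0], self.grid.shape[2]))
        for n, i in enumerate(view_idx):
            vol = self._rotate(activity, i)
            if self._att is not None:
                vol = vol * self._att[i]
            vol = self._conv.apply(vol)
            full[n] = vol.sum(axis=1)
        return full * self.scale

    def adjoint_subset(self, views: np.ndarray, view_idx: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.grid.shape
        out = np.zeros(self.grid.shape)
        for n, i in enumerate(view_idx):
            vol = np.broadcast_to(views[n][:, None, :], (nx, ny, nz)).copy()
            vol = self._conv.apply(vol)
            if self._att is not None:
                vol = vol * self._att[i]
            out += self._rotate(vol, i, adjoint=True)
        return out * self.scale


def forward_project(
    activity: VolumeImage,
    mu: VolumeImage | None,
    psf: PsfStack,
    geometry: AcquisitionGeometry,
    sensitivity_cps_per_MBq: float,
    nuclide: str = "",
    window: str = "photopeak",
) -> ProjectionSet:
    """Noiseless expected projection counts of an activity map [Bq/ml]."""
    if mu is not None and mu.grid != activity.grid:
        raise ValueError("activity and mu grids differ")
    proj = SpectProjector(activity.grid, geometry, psf, mu, sensitivity_cps_per_MBq)
    views = proj.forward(activity.values)
    np.maximum(views, 0.0, out=views)  # clip FFT round-off below zero
    return ProjectionSet(views, geometry, window=window, nuclide=nuclide, noisy=False)


# ---------------------------------------------------------------------------
# Scatter emulation

def _broad_blur(views: np.ndarray, fwhm_mm: float,
                pitch: tuple[float, float]) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    sigma = (0.0, fwhm_mm * GAUSS_FWHM_TO_SIGMA / pitch[0],
             fwhm_mm * GAUSS_FWHM_TO_SIGMA / pitch[1])
    return gaussian_filter(views, sigma, mode="constant")


def default_scatter_model(windows: EnergyWindowSet,
                          scatter_fraction: float,
                          blur_fwhm_mm: float = 80.0) -> dict:
    """Window fractions that make the TEW/DEW estimate exact by construction.

    Each scatter window receives ``scatter_fraction * w_window / w_peak`` of
    the blurred component, which inverts the window-based scatter formula
    S = (C_l/w_l + C_u/w_u) * w_p/2 (one term per available window) exactly.
    """
    if scatter_fraction < 0:
        raise ValueError("scatter fraction must be >= 0")
    w_p = windows.photopeak.width_keV
    n = len(windows.scatter)
    # each window contributes s_f/n to the estimate: (g_w / w_w) * w_p / 2 = s_f / n
    fractions = {
        w.tag: scatter_fraction * 2.0 * w.width_keV / (n * w_p)
        for w in windows.scatter
    }
    return {
        "scatter_fraction": scatter_fraction,
        "blur_fwhm_mm": blur_fwhm_mm,
        "window_fractions": fractions,
    }


def emulate_scatter_windows(
    primary: ProjectionSet,
    windows: EnergyWindowSet,
    scatter_fraction: float,
    blur_fwhm_mm: float = 80.0,
    window_fractions: dict[str, float] | None = None,
) -> dict[str, ProjectionSet]:
    """Parametric scatter emulation around a noiseless primary projection.

    The measured photopeak window is ``primary + s_f * B(primary)`` where B is
    a broad Gaussian blur; each adjacent scatter window records its configured
    fraction of the same blurred component.  With the fractions from
    :func:`default_scatter_model` the window-based scatter estimate recovers
    the injected scatter exactly in expectation.
    Returns a dict with the photopeak under key ``"photopeak"`` and each
    scatter window under its tag.
    """
    if primary.noisy:
        raise ValueError("scatter emulation requires the noiseless primary")
    if scatter_fraction < 0:
        raise ValueError("scatter fraction must be >= 0")
    if window_fractions is None:
        window_fractions = default_scatter_model(
            windows, scatter_fraction, blur_fwhm_mm)["window_fractions"]
    if any(f < 0 for f in window_fractions.values()):
        raise ValueError("window fractions must be >= 0")
    blurred = _broad_blur(primary.views, blur_fwhm_mm, primary.geometry.det_pitch_mm)
    out = {
        "photopeak": replace(primary,
                             views=primary.views + scatter_fraction * blurred)
    }
    for w in windows.scatter:
        out[w.tag] = replace(primary, views=window_fractions[w.tag] * blurred,
                             window=w.tag)
    return out


# ---------------------------------------------------------------------------
# Counting noise

def add_poisson_noise(p: ProjectionSet, seed: int,
                      time_factor: float = 1.0) -> ProjectionSet:
    """Independent Poisson counting noise per pixel.

    ``time_factor > 1`` emulates a shorter acquisition: the expected counts
    are divided by it before drawing (low-count protocols trade acquisition
    time per view, not sensitivity).
    """
    if time_factor <= 0:
        raise ValueError("time_factor must be > 0")
    rng = np.random.default_rng(seed)
    lam = p.views / time_factor
    noisy = rng.poisson(lam).astype(np.float64)
    return replace(p, views=noisy, noisy=True, seed=seed, time_factor=time_factor)


# ---------------------------------------------------------------------------
# Crosstalk

def crosstalk_fraction(
    window: EnergyWindow,
    contaminant: tuple[float, tuple[tuple[float, float], ...]],
    signal: tuple[float, tuple[tuple[float, float], ...]],
) -> float:
    """Fraction of window counts contributed by a contaminating nuclide.

    Each nuclide is (activity, photon emissions); emission lines falling
    inside the window contribute activity x probability.  Detection
    efficiency is taken equal for lines inside one window (they are within a
    few percent in energy), so the fraction is purely emission-weighted.
    """
    def rate(activity: float, emissions) -> float:
        return activity * sum(p for e, p in emissions if window.contains(e))

    c = rate(*contaminant)
    s = rate(*signal)
    if c + s == 0:
        raise ValueError("no emission of either nuclide falls in the window")
    return c / (c + s)
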