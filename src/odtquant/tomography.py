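"""Fourier-diffraction-theorem tomographic reconstruction.

Each retrieved field contributes its 2D Rytov-phase spectrum to one Ewald
cap of the 3D scattering-potential spectrum, offset by the illumination
wavevector.  Overlapping contributions are averaged by accumulated hit
counts (nearest-voxel gridding).  The limited illumination and detection
apertures leave an empty cone of axial frequencies (the missing cone),
which a Gerchberg–Papoulis alternating-projection loop fills in by
enforcing non-negativity of the RI contrast in real space and data
consistency on the covered spectrum samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from numpy.fft import fft2, fftfreq, fftn, fftshift, ifftn, ifftshift
from scipy import ndimage

from .holography import (
    ComplexField,
    Hologram,
    IlluminationScheme,
    retrieve_field,
    to_rytov,
)
from .optics import DensityModel, OpticalConfig, RITomogram

__all__ = [
    "KSpaceVolume",
    "PrecisionReport",
    "ReconstructionSettings",
    "map_fields_to_spectrum",
    "invert_spectrum",
    "regularize_missing_cone",
    "reconstruct",
    "reconstruct_from_fields",
    "precision_report",
]


@dataclass
class KSpaceVolume:
    """Accumulated scattering-potential spectrum and per-voxel hit counts.

    ``spectrum`` holds the *sum* of contributions in fftshifted (origin at
    the central index) layout; divide by ``weights`` where positive to get
    the averaged spectrum.
    """

    spectrum: np.ndarray  # 3D complex, fftshifted layout
    weights: np.ndarray  # 3D float hit counts
    voxel_size_um: tuple[float, float, float]

    def averaged(self) -> np.ndarray:
        out = np.zeros_like(self.spectrum)
        hit = self.weights > 0
        out[hit] = self.spectrum[hit] / self.weights[hit]
        return out


@dataclass
class PrecisionReport:
    """Voxelwise standard error of repeated tomograms and its density scale."""

    se_map: np.ndarray  # RI units
    mean_se_in_mask: float  # RI units
    density_se_mg_ml: float  # mean_se / alpha
    n_repeats: int


@dataclass(frozen=True)
class ReconstructionSettings:
    """Pipeline knobs for :func:`reconstruct`."""

    approximation: str = "rytov"
    n_iter: int = 100  # Gerchberg–Papoulis iterations; 0 disables
    grid_shape: tuple[int, int, int] | None = None  # default from field extent
    support: str | None = None  # None or "auto" (shrinkwrap-style support)


# ---------------------------------------------------------------------------
# k-space mapping
# ---------------------------------------------------------------------------

def map_fields_to_spectrum(
    fields: list[ComplexField],
    scheme: IlluminationScheme,
    config: OpticalConfig | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    approximation: str = "rytov",
) -> KSpaceVolume:
    """Grid every field's Rytov spectrum onto its Ewald cap.

    The inverse of the forward sampling: for each transverse frequency q of
    the normalized field, the contribution

        F̂(K − k_i) = (2 K_z / i Δz) · ψ̂(q),   K_z = sqrt(k_m² − |q + k_i,t|²)

    is added at the nearest spectrum voxel, and the hit count incremented.
    Frequencies outside the detection NA, evanescent components, and samples
    falling off the grid are dropped.
    """
    config = config or OpticalConfig()
    if len(fields) != len(scheme):
        raise ValueError("one field per illumination angle required")
    ny, nx = fields[0].values.shape
    dy, dx = fields[0].pixel_size_um
    dz, dy_obj, dx_obj = config.voxel_size_um
    if grid_shape is None:
        # object grid spans the detector field of view at the config voxel size
        grid_shape = (
            int(round(ny * dy / dy_obj)),
            int(round(ny * dy / dy_obj)),
            int(round(nx * dx / dx_obj)),
        )
    shape = tuple(grid_shape)

    k_m = config.k_medium_um
    k0 = 2 * math.pi / config.wavelength_um
    qy = 2 * math.pi * fftfreq(ny, dy)
    qx = 2 * math.pi * fftfreq(nx, dx)
    QY, QX = np.meshgrid(qy, qx, indexing="ij")
    dkz = 2 * math.pi / (shape[0] * dz)
    dky = 2 * math.pi / (shape[1] * dy_obj)
    dkx = 2 * math.pi / (shape[2] * dx_obj)

    spectrum = np.zeros(shape, dtype=np.complex128)
    weights = np.zeros(shape, dtype=np.float64)

    for fld, s in zip(fields, scheme):
        if fld.values.shape != (ny, nx):
            raise ValueError("all fields must share one grid")
        ki = k_m * np.asarray(s, dtype=np.float64)
        if approximation == "rytov":
            psi = to_rytov(fld)
        else:
            psi = fld.values - 1.0
        PSI = fft2(ifftshift(psi))
        KY = QY + ki[1]
        KX = QX + ki[2]
        KT2 = KY**2 + KX**2
        KZ = np.sqrt(np.clip(k_m**2 - KT2, 0.0, None))
        valid = KT2 <= min(k0 * config.na_detection, k_m * (1 - 1e-9)) ** 2
        iz = np.rint((KZ - ki[0]) / dkz).astype(int) + shape[0] // 2
        iy = np.rint(QY / dky).astype(int) + shape[1] // 2
        ix = np.rint(QX / dkx).astype(int) + shape[2] // 2
        inside = (
            valid
            & (iz >= 0) & (iz < shape[0])
            & (iy >= 0) & (iy < shape[1])
            & (ix >= 0) & (ix < shape[2])
        )
        # inverse of the forward weight: F̂_DFT3 = −2i Kz (dA_det / dV_obj) ψ̂
        factor = (dy * dx) / (dz * dy_obj * dx_obj)
        vals = (2.0 * KZ[inside] * factor / 1j) * PSI[inside]
        np.add.at(spectrum, (iz[inside], iy[inside], ix[inside]), vals)
        np.add.at(weights, (iz[inside], iy[inside], ix[inside]), 1.0)

    return KSpaceVolume(spectrum, weights, (dz, dy_obj, dx_obj))


def invert_spectrum(
    kvol: KSpaceVolume, config: OpticalConfig | None = None
) -> RITomogram:
    """Inverse 3D transform of the averaged spectrum, converted to RI.

    The scattering potential f = k0²(n² − n_m²) yields
    n = sqrt(n_m² + f/k0²); uncovered spectrum voxels stay zero, so the
    result is the band-limited estimate with the missing cone unfilled.
    """
    config = config or OpticalConfig()
    if not np.any(kvol.weights > 0):
        raise ValueError("empty k-space coverage: no field contributed")
    avg = kvol.averaged()
    f = fftshift(ifftn(ifftshift(avg))).real
    k0 = 2 * math.pi / config.wavelength_um
    n_sq = np.clip(config.medium_ri**2 + f / k0**2, 0.0, None)
    return RITomogram(np.sqrt(n_sq), kvol.voxel_size_um, config.medium_ri)


def estimate_support(
    tomogram: RITomogram, smooth_sigma_vox: float = 1.0, closing_iter: int = 2
) -> np.ndarray:
    """Object support estimated from a (typically unregularized) tomogram.

    Otsu's threshold on the smoothed RI map followed by binary closing; the
    smeared halo of the band-limited estimate makes this a generous superset
    of the true object.
    """
    from skimage.filters import threshold_otsu  # local import: keep module light

    sm = ndimage.gaussian_filter(tomogram.values, smooth_sigma_vox)
    if sm.max() - sm.min() < 1e-9:
        return np.ones(tomogram.shape, dtype=bool)
    mask = sm > threshold_otsu(sm)
    if closing_iter > 0:
        mask = ndimage.binary_closing(mask, iterations=closing_iter)
    return mask


def regularize_missing_cone(
    tomogram: RITomogram,
    kvol: KSpaceVolume,
    config: OpticalConfig | None = None,
    n_iter: int = 100,
    floor: float | None = None,
    support: np.ndarray | str | None = None,
) -> RITomogram:
    """Gerchberg–Papoulis missing-cone regularization.

    Alternates between (a) resetting the covered spectrum samples to their
    measured values and (b) real-space constraints: RI clipped at ``floor``
    (default: the medium RI, i.e. non-negative contrast) and, optionally,
    zero contrast outside an object ``support`` (a boolean volume, or
    ``"auto"`` to estimate one from the input via :func:`estimate_support`).

    Without a support the loop ends on the k-space projection, so covered
    samples of the returned tomogram match the measurement exactly.  With a
    support the loop ends on the real-space projection instead — the
    support constraint is what pulls smeared halo mass back into thin
    object regions, at the price of a small departure from the measured
    samples.
    """
    config = config or OpticalConfig()
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if n_iter == 0:
        return tomogram
    floor = config.medium_ri if floor is None else floor
    k0 = 2 * math.pi / config.wavelength_um
    f_floor = k0**2 * (floor**2 - config.medium_ri**2)

    if isinstance(support, str):
        if support != "auto":
            raise ValueError("support must be None, 'auto', or a boolean volume")
        support = estimate_support(tomogram)
    elif support is not None:
        support = np.asarray(support, dtype=bool)
        if support.shape != tomogram.shape:
            raise ValueError("support must match the tomogram grid")

    measured = ifftshift(kvol.averaged())
    covered = ifftshift(kvol.weights) > 0
    f = k0**2 * (tomogram.values**2 - config.medium_ri**2)
    for it in range(n_iter):
        F = fftn(ifftshift(f))
        F[covered] = measured[covered]
        f = fftshift(ifftn(F)).real
        if support is not None:
            f = np.clip(f, f_floor, None)
            f[~support] = 0.0
        elif it < n_iter - 1:
            f = np.clip(f, f_floor, None)
    n_sq = np.clip(config.medium_ri**2 + f / k0**2, 0.0, None)
    return RITomogram(np.sqrt(n_sq), tomogram.voxel_size_um, config.medium_ri)


# ---------------------------------------------------------------------------
# pipeline composition
# ---------------------------------------------------------------------------

def reconstruct_from_fields(
    fields: list[ComplexField],
    scheme: IlluminationScheme,
    config: OpticalConfig | None = None,
    settings: ReconstructionSettings | None = None,
) -> tuple[RITomogram, KSpaceVolume]:
    """Map retrieved fields to k-space, invert, and regularize."""
    config = config or OpticalConfig()
    settings = settings or ReconstructionSettings()
    kvol = map_fields_to_spectrum(
        fields, scheme, config, settings.grid_shape, settings.approximation
    )
    tomo = invert_spectrum(kvol, config)
    if settings.n_iter > 0:
        tomo = regularize_missing_cone(
            tomo, kvol, config, settings.n_iter, support=settings.support
        )
    return tomo, kvol


def reconstruct(
    holograms: list[Hologram],
    backgrounds: list[Hologram] | Hologram,
    scheme: IlluminationScheme,
    config: OpticalConfig | None = None,
    settings: ReconstructionSettings | None = None,
) -> RITomogram:
    """Full deterministic pipeline: retrieval → Rytov → mapping → inversion
    → missing-cone regularization.

    ``backgrounds`` may be a single sample-free hologram (shared reference)
    or one per angle.
    """
    config = config or OpticalConfig()
    if isinstance(backgrounds, Hologram):
        backgrounds = [backgrounds] * len(holograms)
    if len(holograms) != len(scheme) or len(backgrounds) != len(holograms):
        raise ValueError("need one hologram (and background) per angle")
    fields = []
    for holo, bg, s in zip(holograms, backgrounds, scheme):
        fld = retrieve_field(holo, bg, config)
        fld.illumination = np.asarray(s)
        fields.append(fld)
    tomo, _ = reconstruct_from_fields(fields, scheme, config, settings)
    return tomo


# ---------------------------------------------------------------------------
# precision characterization
# ---------------------------------------------------------------------------

def precision_report(
    repeats: list[RITomogram],
    mask: np.ndarray,
    model: DensityModel | None = None,
) -> PrecisionReport:
    """Standard error of a tomogram time series, averaged within a mask.

    Per-voxel SE = sample standard deviation (ddof=1) over the N repeats
    divided by sqrt(N); the mask-averaged SE converts to a mass-density
    precision through the RI increment: SE_rho = SE_RI / alpha (in mg/mL).
    """
    model = model or DensityModel()
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeated tomograms")
    shape = repeats[0].shape
    if any(r.shape != shape for r in repeats) or np.asarray(mask).shape != shape:
        raise ValueError("repeats and mask must share one grid")
    stack = np.stack([r.values for r in repeats])
    se = stack.std(axis=0, ddof=1) / math.sqrt(len(repeats))
    mask = np.asarray(mask, dtype=bool)
    mean_se = float(se[mask].mean()) if mask.any() else float(se.mean())
    density_se = mean_se / model.alpha_ml_per_g * 1e3
    return PrecisionReport(se, mean_se, density_se, len(repeats))
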