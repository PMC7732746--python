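"""Angle-scanned off-axis holography: forward scattering simulation,
hologram synthesis, and Fourier-transform field retrieval.

Conventions
-----------
Arrays are indexed (z, y, x) for volumes and (y, x) for detector planes.
Real-space arrays place the object/field origin at the central index
``N // 2``; the matching discrete Fourier transforms are
``A = fft(ifftshift(a))`` and ``a = fftshift(ifft(A))`` with angular
frequencies ``2π · fftfreq(N, d)`` (rad/µm).

Fields are stored in the *common-path* (lab-frame-normalized) convention:
the illumination plane wave is divided out, so an empty medium gives the
unit field 1 + 0i for every tilt.  The first-order scattering models are

    Born:  u = 1 + u_s,       Rytov:  u = exp(ψ),  ψ = u_s,

where ``u_s`` is the normalized first-Born scattered field obtained by
sampling the 3D spectrum of the scattering potential
``f = k₀²(n² − n_m²)`` on the Ewald cap selected by the illumination:

    û_s(q) = (i Δz / 2 K_z) · F̂(K − k_i),   K = (q + k_i,t, K_z),
    K_z = sqrt(k_m² − |q + k_i,t|²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2, ifftshift
from scipy import ndimage
from skimage.restoration import unwrap_phase

from .optics import OpticalConfig, RITomogram

__all__ = [
    "IlluminationScheme",
    "ComplexField",
    "Hologram",
    "SidebandSeparationError",
    "generate_angles",
    "forward_scatter",
    "synthesize_hologram",
    "retrieve_field",
    "to_rytov",
    "scattering_potential",
]


class SidebandSeparationError(ValueError):
    """The +1-order sideband cannot be separated from the DC term."""


@dataclass(frozen=True)
class IlluminationScheme:
    """A set of unit illumination directions in (z, y, x) component order.

    Directions propagate toward +z; the transverse sine is bounded by
    NA_ill / n_m.
    """

    directions: np.ndarray  # (n_angles, 3), rows (sz, sy, sx)

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=np.float64)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be (n, 3)")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions must be unit vectors")
        object.__setattr__(self, "directions", d)

    def __len__(self) -> int:
        return self.directions.shape[0]

    def __iter__(self):
        return iter(self.directions)


@dataclass
class ComplexField:
    """Detection-plane complex field, normalized to unit empty-medium field."""

    values: np.ndarray  # (ny, nx) complex
    pixel_size_um: tuple[float, float]  # (dy, dx)
    illumination: np.ndarray | None = None  # (sz, sy, sx) unit vector

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("field must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


@dataclass
class Hologram:
    """Off-axis interferogram with a known carrier frequency."""

    intensity: np.ndarray  # (ny, nx), >= 0
    carrier_cyc_px: tuple[float, float]  # (cy, cx) cycles/pixel
    pixel_size_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")


# ---------------------------------------------------------------------------
# illumination schemes
# ---------------------------------------------------------------------------

def generate_angles(
    scheme: str = "circular",
    n_angles: int | None = None,
    config: OpticalConfig | None = None,
    seed: int = 0,
    tilt_fraction: float = 0.95,
) -> IlluminationScheme:
    """Generate an illumination scan within the condenser NA cone.

    ``circular``: normal incidence plus a ring at ``tilt_fraction`` of the
    maximal tilt (the classic galvanometer circle scan).  ``spiral``: a
    Fermat spiral filling the cone, better axial-frequency diversity.
    Both are deterministic for a fixed seed (the seed only rotates the
    azimuthal starting phase).
    """
    config = config or OpticalConfig()
    n = config.n_angles if n_angles is None else int(n_angles)
    if n < 1:
        raise ValueError("n_angles must be >= 1")
    s_max = config.max_illumination_sine
    if not (0 < tilt_fraction <= 1):
        raise ValueError("tilt requested beyond the illumination NA cone")
    rng = np.random.default_rng(seed)
    phi0 = float(rng.uniform(0, 2 * math.pi))

    sines = np.zeros(n)
    phis = np.zeros(n)
    if scheme == "circular":
        sines[1:] = tilt_fraction * s_max
        phis[1:] = phi0 + 2 * math.pi * np.arange(n - 1) / max(n - 1, 1)
    elif scheme == "spiral":
        golden = math.pi * (3 - math.sqrt(5))
        idx = np.arange(n)
        sines = tilt_fraction * s_max * np.sqrt(idx / max(n - 1, 1))
        phis = phi0 + golden * idx
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    sz = np.sqrt(1.0 - sines**2)
    sy = sines * np.sin(phis)
    sx = sines * np.cos(phis)
    return IlluminationScheme(np.column_stack([sz, sy, sx]))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def scattering_potential(tomogram: RITomogram, wavelength_um: float) -> np.ndarray:
    """f = k0² (n² − n_m²), rad²/µm²."""
    k0 = 2 * math.pi / wavelength_um
    return k0**2 * (tomogram.values**2 - tomogram.medium_ri**2)


def _potential_spectrum(tomogram: RITomogram, config: OpticalConfig) -> np.ndarray:
    f = scattering_potential(tomogram, config.wavelength_um)
    return fftshift(np.fft.fftn(ifftshift(f)))


def forward_scatter(
    tomogram: RITomogram,
    illumination: np.ndarray,
    config: OpticalConfig | None = None,
    approximation: str = "rytov",
    detector_oversample: int = 1,
    _spectrum_cache: np.ndarray | None = None,
) -> ComplexField:
    """First-order scattered field at the mid-plane of the object grid.

    Samples the scattering-potential spectrum on the Ewald cap for the given
    illumination (trilinear interpolation), applies the diffraction-theorem
    weight i/(2 K_z), restricts to the detection NA passband, and returns
    the normalized total field (see module docstring for the approximation
    forms).

    ``detector_oversample`` > 1 emulates a camera sampled finer than the
    object grid (as a magnified detection arm provides): the field is
    computed on a grid ``oversample×`` finer in-plane, which lets an
    off-axis carrier separate the full NA passband from the DC term.
    ``_spectrum_cache`` lets callers reuse the 3D FFT across angles.
    """
    config = config or OpticalConfig()
    if approximation not in ("rytov", "born"):
        raise ValueError("approximation must be 'rytov' or 'born'")
    if not np.all(np.isfinite(tomogram.values)):
        raise ValueError("tomogram contains non-finite values")
    s = np.asarray(illumination, dtype=np.float64)
    F3 = _potential_spectrum(tomogram, config) if _spectrum_cache is None else _spectrum_cache

    nz, ny_obj, nx_obj = tomogram.shape
    dz, dy_obj, dx_obj = tomogram.voxel_size_um
    os_ = int(detector_oversample)
    if os_ < 1:
        raise ValueError("detector_oversample must be >= 1")
    ny, nx = ny_obj * os_, nx_obj * os_
    dy, dx = dy_obj / os_, dx_obj / os_
    k_m = config.k_medium_um
    k0 = 2 * math.pi / config.wavelength_um
    ki = k_m * s  # (kiz, kiy, kix)
    if math.hypot(s[1], s[2]) > config.max_illumination_sine + 1e-9:
        raise ValueError("illumination tilt beyond the condenser NA cone")

    qy = 2 * math.pi * fftfreq(ny, dy)
    qx = 2 * math.pi * fftfreq(nx, dx)
    QY, QX = np.meshgrid(qy, qx, indexing="ij")
    KY = QY + ki[1]
    KX = QX + ki[2]
    KT2 = KY**2 + KX**2
    valid = KT2 <= min(k0 * config.na_detection, k_m * (1 - 1e-9)) ** 2
    KZ = np.sqrt(np.clip(k_m**2 - KT2, 0.0, None))

    # fractional indices into the fftshifted 3D spectrum (object grid)
    dkz = 2 * math.pi / (nz * dz)
    dky = 2 * math.pi / (ny_obj * dy_obj)
    dkx = 2 * math.pi / (nx_obj * dx_obj)
    iz = (KZ - ki[0]) / dkz + nz // 2
    iy = QY / dky + ny_obj // 2
    ix = QX / dkx + nx_obj // 2
    inside = (
        valid
        & (iz >= 0) & (iz <= nz - 1)
        & (iy >= 0) & (iy <= ny_obj - 1)
        & (ix >= 0) & (ix <= nx_obj - 1)
    )
    coords = np.stack([iz[inside], iy[inside], ix[inside]])
    samp_re = ndimage.map_coordinates(F3.real, coords, order=1, mode="constant")
    samp_im = ndimage.map_coordinates(F3.imag, coords, order=1, mode="constant")
    # S = Û_cont / (detector pixel area), Û_cont = (i/2Kz) F̂_cont,
    # F̂_cont = object voxel volume × DFT3(f)
    factor = (dz * dy_obj * dx_obj) / (dy * dx)
    S = np.zeros((ny, nx), dtype=np.complex128)
    S[inside] = (1j * factor / (2.0 * KZ[inside])) * (samp_re + 1j * samp_im)

    u_s = fftshift(ifft2(S))
    if approximation == "born":
        u = 1.0 + u_s
    else:
        u = np.exp(u_s)
    return ComplexField(u, (dy, dx), s)


def forward_scatter_stack(
    tomogram: RITomogram,
    scheme: IlluminationScheme,
    config: OpticalConfig | None = None,
    approximation: str = "rytov",
    detector_oversample: int = 1,
) -> list[ComplexField]:
    """Forward-scatter all angles, sharing the 3D spectrum FFT."""
    config = config or OpticalConfig()
    F3 = _potential_spectrum(tomogram, config)
    return [
        forward_scatter(
            tomogram, s, config, approximation, detector_oversample, _spectrum_cache=F3
        )
        for s in scheme
    ]


# ---------------------------------------------------------------------------
# hologram synthesis and retrieval
# ---------------------------------------------------------------------------

def synthesize_hologram(
    field: ComplexField,
    carrier_cyc_px: tuple[float, float] = (0.25, 0.25),
    reference_amplitude: float = 2.0,
    noise_gaussian_sigma: float = 0.0,
    noise_poisson_scale: float = 0.0,
    seed: int | None = None,
) -> Hologram:
    """Interfere the field with a tilted reference beam.

    intensity = |u + R exp(i 2π c · x)|², with optional Poisson shot noise
    (``noise_poisson_scale`` photons per intensity unit) and additive
    Gaussian read noise; negative values are clipped at 0.
    """
    cy, cx = carrier_cyc_px
    if abs(cy) > 0.5 or abs(cx) > 0.5:
        raise ValueError("carrier beyond Nyquist (|c| must be <= 0.5 cycles/px)")
    if reference_amplitude <= 0:
        raise ValueError("reference amplitude must be positive")
    ny, nx = field.values.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    ref = reference_amplitude * np.exp(2j * math.pi * (cy * yy + cx * xx))
    intensity = np.abs(field.values + ref) ** 2
    rng = np.random.default_rng(seed)
    if noise_poisson_scale > 0:
        intensity = rng.poisson(intensity * noise_poisson_scale) / noise_poisson_scale
    if noise_gaussian_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_gaussian_sigma, intensity.shape)
    return Hologram(np.clip(intensity, 0.0, None), (cy, cx), field.pixel_size_um)


def _crop_sideband(holo: Hologram, na_radius_px: float) -> np.ndarray:
    """Demodulate the +1-order sideband; returns the complex field R·u*."""
    ny, nx = holo.intensity.shape
    cy, cx = holo.carrier_cyc_px
    shift_y = int(round(cy * ny))
    shift_x = int(round(cx * nx))
    dist_px = math.hypot(shift_y, shift_x)
    if dist_px < 2:
        raise SidebandSeparationError(
            f"carrier shift {dist_px:.1f} px cannot be separated from the DC term"
        )
    # remove the mean before transforming: the DC delta of |u|² + R² would
    # otherwise leak into a crop circle that extends up to the carrier offset
    spec = fft2(holo.intensity - holo.intensity.mean())
    # recenter the +1 order onto zero frequency (circular shift is exact on
    # the periodic spectrum; sub-integer carrier residuals cancel in the
    # background normalization)
    spec = np.roll(spec, (-shift_y, -shift_x), axis=(0, 1))
    fy = fftfreq(ny) * ny
    fx = fftfreq(nx) * nx
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    radius = min(dist_px, na_radius_px)
    spec[FY**2 + FX**2 > radius**2] = 0.0
    return ifft2(spec)


def retrieve_field(
    holo: Hologram,
    background_holo: Hologram,
    config: OpticalConfig | None = None,
) -> ComplexField:
    """Fourier-transform field retrieval with background normalization.

    Crops the +1-order sideband of both the sample and the background
    hologram (crop radius = min(carrier offset, detection-NA band radius)),
    recenters, inverse-transforms, and divides sample by background.  The
    division removes the carrier, the reference amplitude, and any static
    reference-arm aberrations, leaving the normalized sample field with unit
    background amplitude.
    """
    config = config or OpticalConfig()
    if holo.carrier_cyc_px != background_holo.carrier_cyc_px:
        raise ValueError("sample and background holograms must share the carrier")
    ny, nx = holo.intensity.shape
    dy, dx = holo.pixel_size_um
    na_radius_px = config.na_detection * dx * nx / config.wavelength_um
    s1 = _crop_sideband(holo, na_radius_px)
    b1 = _crop_sideband(background_holo, na_radius_px)
    if np.any(np.abs(b1) == 0):
        raise SidebandSeparationError("background sideband has zero amplitude")
    # each crop yields R·u*; the ratio is u_sample* / u_background*
    u = np.conj(s1 / b1)
    return ComplexField(u, holo.pixel_size_um)


def to_rytov(field: ComplexField) -> np.ndarray:
    """Complex Rytov phase ψ = ln|u| + i · unwrap(arg u).

    The unwrapped phase is anchored so that the field-of-view border (taken
    to be empty medium, u ≈ 1) has zero mean phase modulo 2π, making ψ = 0
    wherever u = 1.
    """
    u = field.values
    amp = np.abs(u)
    if np.any(amp == 0):
        raise ValueError("zero amplitude: Rytov phase is singular")
    phase = unwrap_phase(np.angle(u))
    border = np.concatenate([phase[0, :], phase[-1, :], phase[:, 0], phase[:, -1]])
    offset = 2 * math.pi * round(float(np.median(border)) / (2 * math.pi))
    return np.log(amp) + 1j * (phase - offset)
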