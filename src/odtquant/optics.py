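"""Optical constants, the refractive-index ↔ mass-density model, and
closed-form system characteristics.

The physical model used throughout the package is the linear relation

    n(x, y, z) = n_m + alpha * rho(x, y, z)

between the refractive index ``n`` of a biological sample, the refractive
index ``n_m`` of the surrounding medium, and the local dry-mass density
``rho``.  ``alpha`` is the refractive-index increment (dn/dc), close to
0.190 mL/g for protein and nucleic acid.  All unit conversions are
centralized here: wavelengths are carried in nm, voxel sizes in µm,
densities in mg/mL, dry mass in pg, pressure in Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GAS_CONSTANT",
    "NONNEG_RI_TOL",
    "OpticalConfig",
    "DensityModel",
    "RITomogram",
    "ri_to_density",
    "density_to_ri",
    "theoretical_resolution",
    "osmotic_pressure",
]

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Tolerance (RI units) below the medium RI that reconstructed tomograms may
#: reach after non-negativity regularization; see RITomogram.check_nonneg.
NONNEG_RI_TOL = 1e-4


@dataclass(frozen=True)
class OpticalConfig:
    """Instrument parameters of the tomographic microscope.

    Defaults describe a Mach-Zehnder off-axis holographic setup with a
    532 nm laser, a 1.2-NA water-immersion detection objective, a 1.0-NA
    illumination condenser, and a dual-axis galvanometer scanning 150
    incident angles.
    """

    wavelength_nm: float = 532.0
    na_detection: float = 1.2
    na_illumination: float = 1.0
    medium_ri: float = 1.3370
    n_angles: int = 150
    voxel_size_um: tuple[float, float, float] = (0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not (self.wavelength_nm > 0):
            raise ValueError("wavelength must be positive")
        if self.na_detection <= 0 or self.na_illumination <= 0:
            raise ValueError("numerical apertures must be positive")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_um must be three positive lengths")
        object.__setattr__(self, "voxel_size_um", vs)

    # -- derived quantities ------------------------------------------------
    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def k_medium_um(self) -> float:
        """Angular wavenumber in the immersion medium, rad/µm."""
        return 2.0 * math.pi * self.medium_ri / self.wavelength_um

    @property
    def max_illumination_sine(self) -> float:
        """sin of the steepest illumination tilt inside the medium."""
        return self.na_illumination / self.medium_ri

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_config_dict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OpticalConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            wavelength_nm=d["wavelength_nm"],
            na_detection=d["na_detection"],
            na_illumination=d["na_illumination"],
            medium_ri=d["medium_ri"],
            n_angles=d["n_angles"],
            voxel_size_um=tuple(d["voxel_size_um"]),
        )


def _config_dict(config: "OpticalConfig") -> dict:
    d = asdict(config)
    d["voxel_size_um"] = list(d["voxel_size_um"])
    return d


@dataclass(frozen=True)
class DensityModel:
    """Refractive-index increment model linking RI excess to mass density.

    ``alpha_ml_per_g`` is dn/dc for protein and nucleic acid; the lipid
    range covers phospholipid-rich material (membranes), whose lower
    increment means densities of membrane-rich regions computed with the
    protein increment are underestimates.
    """

    alpha_ml_per_g: float = 0.190
    alpha_lipid_range: tuple[float, float] = (0.135, 0.138)

    def __post_init__(self) -> None:
        if not (self.alpha_ml_per_g > 0):
            raise ValueError("alpha must be positive")
        lo, hi = self.alpha_lipid_range
        if lo > hi:
            raise ValueError("alpha_lipid_range must be ordered (low, high)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "alpha_ml_per_g": self.alpha_ml_per_g,
                    "alpha_lipid_range": list(self.alpha_lipid_range),
                }
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DensityModel":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            alpha_ml_per_g=d["alpha_ml_per_g"],
            alpha_lipid_range=tuple(d.get("alpha_lipid_range", (0.135, 0.138))),
        )


@dataclass
class RITomogram:
    """A 3D refractive-index map on a regular voxel grid.

    ``values`` is indexed (z, y, x); ``voxel_size_um`` gives the physical
    spacing per axis in the same order.
    """

    values: np.ndarray
    voxel_size_um: tuple[float, float, float]
    medium_ri: float = 1.3370

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tomogram contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel sizes must be positive")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def delta_n(self) -> np.ndarray:
        """RI excess over the medium."""
        return self.values - self.medium_ri

    def check_nonneg(self, tol: float = NONNEG_RI_TOL) -> bool:
        """True when no voxel dips more than ``tol`` below the medium RI."""
        return bool(np.all(self.values >= self.medium_ri - tol))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def ri_to_density(
    mean_ri: float | np.ndarray,
    config: OpticalConfig | None = None,
    model: DensityModel | None = None,
) -> float | np.ndarray:
    """Convert refractive index to dry-mass density in mg/mL.

    Inverts n = n_m + alpha * rho.  With alpha in mL/g, (n - n_m)/alpha
    is in g/mL; the result is returned in mg/mL.
    """
    config = config or OpticalConfig()
    model = model or DensityModel()
    ri = np.asarray(mean_ri, dtype=np.float64)
    if not np.all(np.isfinite(ri)):
        raise ValueError("mean_ri must be finite")
    rho = (ri - config.medium_ri) / model.alpha_ml_per_g * 1e3
    return float(rho) if np.isscalar(mean_ri) else rho


def density_to_ri(
    density_mg_ml: float | np.ndarray,
    config: OpticalConfig | None = None,
    model: DensityModel | None = None,
) -> float | np.ndarray:
    """Inverse of :func:`ri_to_density`: n = n_m + alpha * rho."""
    config = config or OpticalConfig()
    model = model or DensityModel()
    rho = np.asarray(density_mg_ml, dtype=np.float64)
    if not np.all(np.isfinite(rho)):
        raise ValueError("density must be finite")
    ri = config.medium_ri + model.alpha_ml_per_g * rho * 1e-3
    return float(ri) if np.isscalar(density_mg_ml) else ri


def theoretical_resolution(config: OpticalConfig | None = None) -> tuple[float, float]:
    """Diffraction-limited lateral and axial resolution of the system, in nm.

    Lateral: the synthetic-aperture band limit spans transverse spatial
    frequencies up to (NA_det + NA_ill)/λ, giving a half-period resolution

        d_lat = λ / (2 (NA_det + NA_ill)).

    Axial: the accessible axial frequency support is the sum of the sagittal
    heights of the detection and illumination Ewald caps,

        Δk_z = (n_m/λ) [(1 − cos θ_det) + (1 − cos θ_ill)],
        sin θ_i = NA_i / n_m,

    and the axial resolution is its inverse, d_ax = 1/Δk_z.  The two
    conventions (half-period laterally, full-period axially) are the standard
    pair for limited-angle transmission tomography.
    """
    config = config or OpticalConfig()
    lam = config.wavelength_nm
    n_m = config.medium_ri
    if config.na_detection >= n_m or config.na_illumination >= n_m:
        raise ValueError("NA must be smaller than the medium RI for angle mapping")
    lateral = lam / (2.0 * (config.na_detection + config.na_illumination))
    cos_det = math.sqrt(1.0 - (config.na_detection / n_m) ** 2)
    cos_ill = math.sqrt(1.0 - (config.na_illumination / n_m) ** 2)
    axial = lam / (n_m * ((1.0 - cos_det) + (1.0 - cos_ill)))
    return lateral, axial


def osmotic_pressure(
    density_mg_ml: float,
    temperature_k: float,
    molecular_weight_g_mol: float,
) -> float:
    """Van't Hoff osmotic pressure Π = ρ R T / M, in Pa.

    ``density_mg_ml`` is the solute mass density (1 mg/mL = 1 kg/m³),
    ``molecular_weight_g_mol`` the solute molar mass.
    """
    if not (density_mg_ml > 0 and temperature_k > 0 and molecular_weight_g_mol > 0):
        raise ValueError("density, temperature, and molecular weight must be positive")
    rho_kg_m3 = density_mg_ml  # 1 mg/mL == 1 kg/m^3
    m_kg_mol = molecular_weight_g_mol * 1e-3
    return rho_kg_m3 / m_kg_mol * GAS_CONSTANT * temperature_k
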