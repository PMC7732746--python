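"""Synthetic cell phantoms with known compartment densities.

This module is the stand-in for raw microscope data: it builds 3D
refractive-index tomograms of adherent-cell-like objects whose compartment
geometry and mass densities are known exactly, together with matched
epi-fluorescence channels (cell-cycle reporters and a nucleolar marker) and
repeated bead tomograms for precision calibration.

The default densities are chosen so that the phantom's compartment mean RI
values match the control HeLa population means (cytoplasm 1.3538,
nucleoplasm 1.3528; nucleoli 58% denser than nucleoplasm; perinuclear
cytoplasm denser than bulk cytoplasm such that nucleoplasm is about 10.8%
less dense than the shell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .masks import CompartmentMasks, COMPARTMENTS
from .optics import DensityModel, OpticalConfig, RITomogram, density_to_ri

__all__ = [
    "CellGeometry",
    "CompartmentDensities",
    "PhantomTruth",
    "FluorescenceStack",
    "make_cell_phantom",
    "make_population",
    "make_bead_stack",
    "render_fluorescence",
    "default_config",
]

#: 1 mg/mL integrated over 1 µm³ is 1e-3 pg.
PG_PER_MGML_UM3 = 1e-3

#: Cell-cycle phases in progression order.
PHASES = ("G1", "earlyS", "SG2")

# Per-phase FUCCI reporter levels (arbitrary units): mKO2 is high in G1,
# both reporters present in early S, mAG1 high in S/G2.
_FUCCI_LEVELS = {
    "G1": {"mKO2": 1.0, "mAG1": 0.05},
    "earlyS": {"mKO2": 0.75, "mAG1": 0.75},
    "SG2": {"mKO2": 0.05, "mAG1": 1.0},
}


def default_config() -> OpticalConfig:
    """Desk-scale grid: 0.25 µm isotropic voxels (128³ covers 32 µm)."""
    return OpticalConfig(voxel_size_um=(0.25, 0.25, 0.25))


@dataclass(frozen=True)
class CellGeometry:
    """Ellipsoidal cell/nucleus geometry with spherical nucleoli.

    Lengths in µm; centers are offsets from the grid center in (z, y, x)
    order.  The default emulates a spread adherent cell ("fried egg"): an
    oblate cell body whose nuclear bulge spans essentially the full local
    cell height — the apical/basal cytoplasmic layers over the nucleus of a
    flat interphase cell are thinner than the axial resolution and are
    omitted rather than voxelized as an unresolvable film.
    """

    cell_axes: tuple[float, float, float] = (4.5, 9.0, 10.0)  # (z, y, x) semi-axes
    cell_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    nucleus_axes: tuple[float, float, float] = (4.49, 5.0, 5.5)
    nucleus_center: tuple[float, float, float] = (0.0, 0.0, -0.5)
    nucleoli: tuple[tuple[tuple[float, float, float], float], ...] = (
        ((0.3, 1.6, 0.8), 1.8),
        ((-0.4, -2.0, -2.2), 1.4),
    )
    jitter_seed: int = 0

    def validate(self) -> None:
        """Check containment invariants analytically."""
        cz, cy, cx = self.nucleus_center
        # nucleus inside cell: sample the nucleus surface, test the cell
        # implicit function (sufficient at this sampling for smooth shapes)
        th = np.linspace(0, np.pi, 41)
        ph = np.linspace(0, 2 * np.pi, 81)
        T, P = np.meshgrid(th, ph, indexing="ij")
        az, ay, ax = self.nucleus_axes
        z = cz + az * np.cos(T) + self.cell_center[0] * 0
        y = cy + ay * np.sin(T) * np.cos(P)
        x = cx + ax * np.sin(T) * np.sin(P)
        bz, by, bx = self.cell_axes
        oz, oy, ox = self.cell_center
        if np.any(
            ((z - oz) / bz) ** 2 + ((y - oy) / by) ** 2 + ((x - ox) / bx) ** 2 > 1.0
        ):
            raise ValueError("nucleus is not fully inside the cell")
        for (nz, ny, nx), r in self.nucleoli:
            # nucleolus inside nucleus (centers relative to the nucleus):
            # conservative bound — shrink each nucleus semi-axis by r

            if any(a <= r for a in self.nucleus_axes):
                raise ValueError("nucleolus larger than nucleus semi-axis")
            sz, sy, sx = (az - r), (ay - r), (ax - r)
            if ((nz - 0) / sz) ** 2 + ((ny - 0) / sy) ** 2 + ((nx - 0) / sx) ** 2 > 1.0:
                raise ValueError("nucleolus is not fully inside the nucleus")
        for i, ((z1, y1, x1), r1) in enumerate(self.nucleoli):
            for (z2, y2, x2), r2 in self.nucleoli[i + 1 :]:
                if np.hypot(np.hypot(z1 - z2, y1 - y2), x1 - x2) < r1 + r2:
                    raise ValueError("nucleoli overlap")

    def scaled(self, volume_factor: float) -> "CellGeometry":
        """Scale all linear dimensions by volume_factor ** (1/3)."""
        s = float(volume_factor) ** (1.0 / 3.0)
        return CellGeometry(
            cell_axes=tuple(a * s for a in self.cell_axes),
            cell_center=self.cell_center,
            nucleus_axes=tuple(a * s for a in self.nucleus_axes),
            nucleus_center=tuple(c * s for c in self.nucleus_center),
            nucleoli=tuple(
                (tuple(c * s for c in ctr), r * s) for ctr, r in self.nucleoli
            ),
            jitter_seed=self.jitter_seed,
        )


@dataclass(frozen=True)
class CompartmentDensities:
    """Ground-truth dry-mass densities, mg/mL.

    Defaults reproduce the control HeLa compartment RI means under
    n = n_m + alpha * rho with n_m = 1.3370, alpha = 0.190 mL/g:
    cytoplasm 88.42 mg/mL (RI 1.3538), nucleoplasm 83.16 mg/mL (RI 1.3528),
    nucleoli 1.58 × nucleoplasm, perinuclear shell ≈ 4.8 mg/mL above bulk
    cytoplasm (shell ≈ 12% denser than nucleoplasm).
    """

    cytoplasm: float = 88.42105263157895
    perinuclear_excess: float = 4.8
    nucleoplasm: float = 83.15789473684211
    nucleoli: float = 131.38947368421052  # 1.58 * nucleoplasm

    def __post_init__(self) -> None:
        for name in ("cytoplasm", "perinuclear_excess", "nucleoplasm", "nucleoli"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "cytoplasm": self.cytoplasm,
            "perinuclear": self.cytoplasm + self.perinuclear_excess,
            "nucleoplasm": self.nucleoplasm,
            "nucleoli": self.nucleoli,
        }


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside each phantom tomogram."""

    masks: CompartmentMasks
    densities: CompartmentDensities
    phase_label: str = "G1"
    volumes_um3: dict[str, float] = field(default_factory=dict)
    dry_masses_pg: dict[str, float] = field(default_factory=dict)


@dataclass
class FluorescenceStack:
    """Co-registered fluorescence channels on the tomogram grid."""

    channels: dict[str, np.ndarray]
    psf_sigma_um: float
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, ch in self.channels.items():
            ch = np.asarray(ch, dtype=np.float64)
            if np.any(ch < 0):
                raise ValueError(f"channel {name} has negative intensities")
            self.channels[name] = ch


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------

def _grid_coords(shape, voxel_size):
    """Physical (z, y, x) coordinate arrays, origin at the grid center."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_mask(coords, center, semi_axes):
    z, y, x = coords
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def _sphere_mask(coords, center, radius):
    return _ellipsoid_mask(coords, center, (radius, radius, radius))


def perinuclear_shell_mask(nucleus, thickness_um, voxel_size_um):
    """Voxels within ``thickness_um`` outside the nucleus (anisotropy-aware)."""
    dist = ndimage.distance_transform_edt(~nucleus, sampling=voxel_size_um)
    return (dist <= thickness_um) & ~nucleus


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def make_cell_phantom(
    geometry: CellGeometry | None = None,
    densities: CompartmentDensities | None = None,
    config: OpticalConfig | None = None,
    model: DensityModel | None = None,
    shape: tuple[int, int, int] = (128, 128, 128),
    shell_thickness_um: float = 2.0,
    boundary_sigma_um: float = 0.0,
) -> tuple[RITomogram, PhantomTruth]:
    """Voxelize a cell phantom and return its RI tomogram plus ground truth.

    Outside the cell the RI equals the medium RI exactly; inside, each
    compartment carries n_m + alpha * rho(compartment).  The perinuclear
    density excess is painted into the 2-µm shell around the nucleus so that
    a downstream shell segmentation recovers an elevated density.  With
    ``boundary_sigma_um`` > 0 the RI field is smoothed to emulate a soft
    compartment boundary (truth masks stay hard).
    """
    geometry = geometry or CellGeometry()
    densities = densities or CompartmentDensities()
    config = config or default_config()
    model = model or DensityModel()
    geometry.validate()

    coords = _grid_coords(shape, config.voxel_size_um)
    cell = _ellipsoid_mask(coords, geometry.cell_center, geometry.cell_axes)
    nucleus = _ellipsoid_mask(coords, geometry.nucleus_center, geometry.nucleus_axes)
    nucleus &= cell
    nucleoli = np.zeros(shape, dtype=bool)
    nz, ny, nx = geometry.nucleus_center
    for (cz, cy, cx), r in geometry.nucleoli:
        nucleoli |= _sphere_mask(coords, (nz + cz, ny + cy, nx + cx), r)
    nucleoli &= nucleus
    shell = perinuclear_shell_mask(nucleus, shell_thickness_um, config.voxel_size_um)
    masks = CompartmentMasks.from_primary(cell, nucleus, nucleoli, shell)
    masks.validate()

    rho = np.zeros(shape, dtype=np.float64)
    rho[masks.cytoplasm] = densities.cytoplasm
    rho[masks.perinuclear] = densities.cytoplasm + densities.perinuclear_excess
    rho[masks.nucleoplasm] = densities.nucleoplasm
    rho[masks.nucleoli] = densities.nucleoli
    if boundary_sigma_um > 0:
        sig = [boundary_sigma_um / v for v in config.voxel_size_um]
        rho = ndimage.gaussian_filter(rho, sig)
    ri = density_to_ri(rho, config, model)
    tomo = RITomogram(ri, config.voxel_size_um, config.medium_ri)

    voxvol = tomo.voxel_volume_um3
    volumes = {name: float(m.sum()) * voxvol for name, m in masks.as_dict().items()}
    dens = densities.as_dict()
    dens["cell"] = None  # aggregate below
    dry = {}
    for name, m in masks.as_dict().items():
        dry[name] = float(np.sum(rho[m])) * voxvol * PG_PER_MGML_UM3
    dry["nucleus"] = dry["nucleoplasm"] + dry["nucleoli"]
    dry["cell"] = dry["cytoplasm"] + dry["nucleus"]
    truth = PhantomTruth(
        masks=masks, densities=densities, volumes_um3=volumes, dry_masses_pg=dry
    )
    return tomo, truth


def render_fluorescence(
    truth: PhantomTruth,
    psf_sigma_um: float = 0.3,
    voxel_size_um: tuple[float, float, float] = (0.25, 0.25, 0.25),
    noise_gaussian_sigma: float = 0.0,
    noise_poisson_scale: float = 0.0,
    seed: int | None = None,
) -> FluorescenceStack:
    """Render FUCCI (mKO2/mAG1), nucleolar-GFP, and Hoechst channels.

    Each channel is the indicator of the relevant truth mask scaled by the
    phase-dependent reporter level, blurred with a Gaussian PSF, with
    optional Poisson(scale * signal)/scale shot noise plus additive Gaussian
    read noise.  psf_sigma = 0 with no noise returns the scaled binary masks.
    """
    if psf_sigma_um < 0:
        raise ValueError("psf_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    levels = _FUCCI_LEVELS[truth.phase_label]
    base = {
        "mKO2": truth.masks.nucleus.astype(np.float64) * levels["mKO2"],
        "mAG1": truth.masks.nucleus.astype(np.float64) * levels["mAG1"],
        "GFP_nucleoli": truth.masks.nucleoli.astype(np.float64),
        "Hoechst": truth.masks.nucleus.astype(np.float64),
    }
    channels = {}
    for name, ch in base.items():
        if psf_sigma_um > 0:
            sig = [psf_sigma_um / v for v in voxel_size_um]
            ch = ndimage.gaussian_filter(ch, sig)
        if noise_poisson_scale > 0:
            ch = rng.poisson(ch * noise_poisson_scale) / noise_poisson_scale
        if noise_gaussian_sigma > 0:
            ch = ch + rng.normal(0.0, noise_gaussian_sigma, ch.shape)
        channels[name] = np.clip(ch, 0.0, None)
    return FluorescenceStack(channels, psf_sigma_um, tuple(voxel_size_um))


def make_population(
    n_cells: int,
    phase_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    growth_factor: float = 2.0,
    seed: int = 0,
    geometry: CellGeometry | None = None,
    densities: CompartmentDensities | None = None,
    config: OpticalConfig | None = None,
    model: DensityModel | None = None,
    shape: tuple[int, int, int] = (128, 128, 128),
    psf_sigma_um: float = 0.3,
    size_jitter: float = 0.0,
) -> list[tuple[RITomogram, PhantomTruth, FluorescenceStack]]:
    """Generate a population of single-cell phantoms across the cell cycle.

    Compartment volumes (and hence dry masses) scale by a factor
    interpolating 1 → ``growth_factor`` across G1 → early S → S/G2 while
    densities are held fixed, emulating the twofold volume/mass growth at
    constant density over the cycle.  One top-level seed fans out to one
    child seed per cell via ``np.random.SeedSequence.spawn``, so any subset
    is reproducible.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    mix = np.asarray(phase_mix, dtype=float)
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
        raise ValueError("phase_mix must be non-negative and sum to 1")
    geometry = geometry or CellGeometry()
    densities = densities or CompartmentDensities()
    config = config or default_config()
    model = model or DensityModel()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cells + 1)
    rng = np.random.default_rng(children[0])
    phases = rng.choice(len(PHASES), size=n_cells, p=mix)
    vol_factors = {"G1": 1.0, "earlyS": (1.0 + growth_factor) / 2.0, "SG2": growth_factor}

    out = []
    for i in range(n_cells):
        phase = PHASES[phases[i]]
        cell_rng = np.random.default_rng(children[i + 1])
        factor = vol_factors[phase]
        if size_jitter > 0:
            factor *= float(np.exp(cell_rng.normal(0.0, size_jitter)))
        geo = geometry.scaled(factor)
        tomo, truth = make_cell_phantom(geo, densities, config, model, shape)
        truth.phase_label = phase
        fluo_seed = int(cell_rng.integers(0, 2**31 - 1))
        fluo = render_fluorescence(
            truth, psf_sigma_um, config.voxel_size_um, seed=fluo_seed
        )
        out.append((tomo, truth, fluo))
    return out


def make_bead_stack(
    n_repeats: int = 10,
    bead_ri: float = 1.4350,
    medium_ri: float = 1.3665,
    noise_sigma: float = 1.31e-4,
    seed: int = 0,
    bead_radius_um: float = 2.5,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_um: tuple[float, float, float] = (0.25, 0.25, 0.25),
) -> tuple[list[RITomogram], np.ndarray]:
    """Repeated tomograms of a silica bead in sucrose for precision calibration.

    Emulates a time series of tomograms of the same field of view: one bead
    phantom plus i.i.d. Gaussian voxel noise of standard deviation
    ``noise_sigma`` (RI units) per repeat.  The default medium RI 1.3665
    corresponds to 0.7 M sucrose at 532 nm.  Returns the repeats and the
    bead mask.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    coords = _grid_coords(shape, voxel_size_um)
    bead = _sphere_mask(coords, (0.0, 0.0, 0.0), bead_radius_um)
    base = np.full(shape, medium_ri, dtype=np.float64)
    base[bead] = bead_ri
    repeats = []
    for _ in range(n_repeats):
        noisy = base + rng.normal(0.0, noise_sigma, shape) if noise_sigma > 0 else base.copy()
        repeats.append(RITomogram(noisy, tuple(voxel_size_um), medium_ri))
    return repeats, bead
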