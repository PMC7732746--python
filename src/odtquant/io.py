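"""File formats: 32-bit float TIFF for tomograms and SE maps, 16-bit TIFF
for masks/labels, HDF5 for hologram stacks and phantom ground truth, CSV
for per-cell tables, YAML for configs and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .holography import ComplexField, Hologram, IlluminationScheme
from .masks import COMPARTMENTS, CompartmentMasks
from .optics import DensityModel, OpticalConfig, RITomogram
from .phantom import CompartmentDensities, FluorescenceStack, PhantomTruth
from .quantify import CellRecord
from .stats import GroupComparison
from .tomography import PrecisionReport

__all__ = [
    "save_tomogram",
    "load_tomogram",
    "save_masks",
    "load_masks",
    "save_phantom",
    "load_phantom",
    "save_hologram_stack",
    "load_hologram_stack",
    "save_precision",
    "records_to_dataframe",
    "save_cell_table",
    "comparisons_to_dataframe",
    "RunManifest",
]


def _config_yaml(config: OpticalConfig) -> str:
    d = asdict(config)
    d["voxel_size_um"] = list(d["voxel_size_um"])
    return yaml.safe_dump(d)


def _config_from_yaml(text: str) -> OpticalConfig:
    d = yaml.safe_load(text)
    d["voxel_size_um"] = tuple(d["voxel_size_um"])
    return OpticalConfig(**d)


# ---------------------------------------------------------------------------
# tomograms
# ---------------------------------------------------------------------------

def save_tomogram(tomogram: RITomogram, path: str | Path) -> Path:
    """Write a tomogram as a float32 TIFF stack with an HDF5 sidecar.

    The sidecar (same stem, ``.h5``) carries the voxel size and medium RI;
    the TIFF alone is ImageJ-readable with correct spacing.
    """
    path = Path(path)
    dz, dy, dx = tomogram.voxel_size_um
    tifffile.imwrite(
        path,
        tomogram.values.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um"},
    )
    with h5py.File(path.with_suffix(".h5"), "w") as h5:
        h5.attrs["voxel_size_um"] = tomogram.voxel_size_um
        h5.attrs["medium_ri"] = tomogram.medium_ri
    return path


def load_tomogram(path: str | Path) -> RITomogram:
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    sidecar = path.with_suffix(".h5")
    if sidecar.exists():
        with h5py.File(sidecar, "r") as h5:
            voxel = tuple(float(v) for v in h5.attrs["voxel_size_um"])
            medium = float(h5.attrs["medium_ri"])
    else:  # fall back to ImageJ metadata; assume the default medium
        with tifffile.TiffFile(path) as tif:
            meta = tif.imagej_metadata or {}
            dz = float(meta.get("spacing", 1.0))
            res = tif.pages[0].tags.get("XResolution")
            dx = 1.0 / (res.value[0] / res.value[1]) if res else 1.0
        voxel = (dz, dx, dx)
        medium = OpticalConfig().medium_ri
    return RITomogram(values, voxel, medium)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def save_masks(masks: CompartmentMasks, path: str | Path) -> Path:
    """Write compartment masks as one 16-bit multi-page TIFF per compartment
    plane order (cell, cytoplasm, perinuclear, nucleus, nucleoplasm,
    nucleoli)."""
    path = Path(path)
    stack = np.stack(
        [getattr(masks, name).astype(np.uint16) for name in COMPARTMENTS]
    )
    tifffile.imwrite(path, stack, metadata={"axes": "CZYX"})
    return path


def load_masks(path: str | Path) -> CompartmentMasks:
    stack = tifffile.imread(path).astype(bool)
    return CompartmentMasks(**{name: stack[i] for i, name in enumerate(COMPARTMENTS)})


# ---------------------------------------------------------------------------
# phantom datasets
# ---------------------------------------------------------------------------

def save_phantom(
    out_dir: str | Path,
    tomogram: RITomogram,
    truth: PhantomTruth,
    fluorescence: FluorescenceStack | None = None,
    config: OpticalConfig | None = None,
    stem: str = "phantom",
) -> Path:
    """Write one phantom as TIFF (RI, fluorescence) plus an HDF5 sidecar
    holding truth masks, densities, phase label, and the optical config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_tomogram(tomogram, out_dir / f"{stem}_ri.tif")
    h5_path = out_dir / f"{stem}_truth.h5"
    with h5py.File(h5_path, "w") as h5:
        g = h5.create_group("masks")
        for name in COMPARTMENTS:
            g.create_dataset(name, data=getattr(truth.masks, name), compression="gzip")
        h5.attrs["phase_label"] = truth.phase_label
        h5.attrs["densities_mg_ml"] = json.dumps(truth.densities.as_dict())
        h5.attrs["volumes_um3"] = json.dumps(truth.volumes_um3)
        h5.attrs["dry_masses_pg"] = json.dumps(truth.dry_masses_pg)
        if config is not None:
            h5.attrs["config_yaml"] = _config_yaml(config)
    if fluorescence is not None:
        names = sorted(fluorescence.channels)
        stack = np.stack([fluorescence.channels[n] for n in names]).astype(np.float32)
        tifffile.imwrite(
            out_dir / f"{stem}_fluo.tif",
            stack,
            metadata={"axes": "CZYX", "channel_names": names},
        )
        with h5py.File(h5_path, "a") as h5:
            h5.attrs["fluo_channels"] = json.dumps(names)
            h5.attrs["psf_sigma_um"] = fluorescence.psf_sigma_um
    return out_dir


def load_phantom(
    out_dir: str | Path, stem: str = "phantom"
) -> tuple[RITomogram, PhantomTruth, FluorescenceStack | None, OpticalConfig | None]:
    out_dir = Path(out_dir)
    tomo = load_tomogram(out_dir / f"{stem}_ri.tif")
    with h5py.File(out_dir / f"{stem}_truth.h5", "r") as h5:
        masks = CompartmentMasks(**{n: h5["masks"][n][()] for n in COMPARTMENTS})
        dens = json.loads(h5.attrs["densities_mg_ml"])
        truth = PhantomTruth(
            masks=masks,
            densities=CompartmentDensities(
                cytoplasm=dens["cytoplasm"],
                perinuclear_excess=dens["perinuclear"] - dens["cytoplasm"],
                nucleoplasm=dens["nucleoplasm"],
                nucleoli=dens["nucleoli"],
            ),
            phase_label=str(h5.attrs["phase_label"]),
            volumes_um3=json.loads(h5.attrs["volumes_um3"]),
            dry_masses_pg=json.loads(h5.attrs["dry_masses_pg"]),
        )
        config = (
            _config_from_yaml(h5.attrs["config_yaml"])
            if "config_yaml" in h5.attrs
            else None
        )
        channels = (
            json.loads(h5.attrs["fluo_channels"]) if "fluo_channels" in h5.attrs else None
        )
        psf = float(h5.attrs.get("psf_sigma_um", 0.0))
    fluo = None
    fluo_path = out_dir / f"{stem}_fluo.tif"
    if channels and fluo_path.exists():
        stack = tifffile.imread(fluo_path).astype(np.float64)
        fluo = FluorescenceStack(
            dict(zip(channels, stack)), psf, tomo.voxel_size_um
        )
    return tomo, truth, fluo, config


# ---------------------------------------------------------------------------
# holograms
# ---------------------------------------------------------------------------

def save_hologram_stack(
    path: str | Path,
    holograms: list[Hologram],
    background: Hologram,
    scheme: IlluminationScheme,
    config: OpticalConfig,
) -> Path:
    """One HDF5 file: /holograms (angle-major), /background, /angles,
    carrier and pixel size and config as attributes."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset(
            "holograms",
            data=np.stack([h.intensity for h in holograms]).astype(np.float32),
            compression="gzip",
        )
        h5.create_dataset("background", data=background.intensity.astype(np.float32))
        h5.create_dataset("angles", data=scheme.directions)
        h5.attrs["carrier_cyc_px"] = holograms[0].carrier_cyc_px
        h5.attrs["pixel_size_um"] = holograms[0].pixel_size_um
        h5.attrs["config_yaml"] = _config_yaml(config)
    return path


def load_hologram_stack(
    path: str | Path,
) -> tuple[list[Hologram], Hologram, IlluminationScheme, OpticalConfig]:
    with h5py.File(path, "r") as h5:
        carrier = tuple(float(c) for c in h5.attrs["carrier_cyc_px"])
        pixel = tuple(float(p) for p in h5.attrs["pixel_size_um"])
        holos = [
            Hologram(frame.astype(np.float64), carrier, pixel)
            for frame in h5["holograms"][()]
        ]
        background = Hologram(h5["background"][()].astype(np.float64), carrier, pixel)
        scheme = IlluminationScheme(h5["angles"][()])
        config = _config_from_yaml(h5.attrs["config_yaml"])
    return holos, background, scheme, config


# ---------------------------------------------------------------------------
# tables and reports
# ---------------------------------------------------------------------------

def records_to_dataframe(records: list[CellRecord]) -> pd.DataFrame:
    """One row per cell × compartment, ratios repeated per cell."""
    rows = []
    for rec in records:
        for comp, st in rec.stats.items():
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "phase": rec.phase,
                    "compartment": comp,
                    "mean_ri": st.mean_ri,
                    "density_mg_ml": st.density_mg_ml,
                    "volume_um3": st.volume_um3,
                    "dry_mass_pg": st.dry_mass_pg,
                    "surface_area_um2": st.surface_area_um2,
                    "sphericity": st.sphericity,
                    **{f"ratio_{k.replace('/', '_over_')}": v for k, v in rec.ratios.items()},
                }
            )
    return pd.DataFrame(rows)


def save_cell_table(records: list[CellRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_dataframe(records).to_csv(path, index=False)
    return path


def comparisons_to_dataframe(comparisons: dict[str, GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": name,
                "test": c.test_name,
                "n_a": c.n[0],
                "n_b": c.n[1],
                "statistic": c.statistic,
                "p_value": c.p_value,
                "stars": c.stars,
                "normality_p_a": c.normality_p[0],
                "normality_p_b": c.normality_p[1],
            }
            for name, c in comparisons.items()
        ]
    )


def save_precision(report: PrecisionReport, out_dir: str | Path) -> Path:
    """SE map as float32 TIFF plus a YAML summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "se_map.tif", report.se_map.astype(np.float32))
    (out_dir / "precision.yaml").write_text(
        yaml.safe_dump(
            {
                "mean_se_ri": report.mean_se_in_mask,
                "density_se_mg_ml": report.density_se_mg_ml,
                "n_repeats": report.n_repeats,
            }
        )
    )
    return out_dir


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    config_yaml: str
    tool_version: str
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, **outputs: str | Path) -> None:
        self.stages.append(
            {
                "name": name,
                "outputs": {
                    key: {"path": str(p), "sha256": _sha256(Path(p))}
                    for key, p in outputs.items()
                },
            }
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            yaml.safe_dump(
                {
                    "seed": self.seed,
                    "tool_version": self.tool_version,
                    "config": yaml.safe_load(self.config_yaml),
                    "stages": self.stages,
                }
            )
        )
        return path
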