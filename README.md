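# odtquant

Optical diffraction tomography (ODT) measures the 3D refractive index (RI)
of living cells without labels. Because the RI of biological material is
linearly tied to its dry-mass concentration,

&nbsp;&nbsp;&nbsp;&nbsp; *n*(x, y, z) = *n*<sub>m</sub> + α · ρ(x, y, z),

with medium RI *n*<sub>m</sub> ≈ 1.3370 and RI increment α ≈ 0.190 mL/g for
protein and nucleic acid, an RI tomogram is simultaneously a quantitative
map of mass density ρ in mg/mL. `odtquant` implements the complete
computational chain that turns angle-scanned off-axis holograms into
per-organelle physical quantities — and, because raw microscope data are
bulky, it also implements the *inverse* of the measurement: a synthetic
phantom generator that builds cells with known compartment densities so
every stage can be exercised and validated at desk scale.

The pipeline, mirroring a Mach-Zehnder ODT microscope with a dual-axis
galvanometer (λ = 532 nm, NA<sub>det</sub> = 1.2, NA<sub>ill</sub> = 1.0,
150 illumination angles):

1. **phantom** — adherent-cell phantoms (cytoplasm, 2-µm perinuclear
   shell, nucleoplasm, nucleoli) with ground-truth masks and densities;
   FUCCI cell-cycle fluorescence; silica-bead calibration series.
2. **holography** — first-order (Born/Rytov) forward scattering, off-axis
   hologram synthesis, Fourier-transform field retrieval with background
   normalization, 2D phase unwrapping.
3. **tomography** — Fourier-diffraction-theorem mapping of each field onto
   its Ewald cap, inversion to RI, Gerchberg–Papoulis missing-cone
   regularization (non-negativity, optional object support), precision
   (standard-error) characterization from repeated tomograms.
4. **segmentation** — Otsu + watershed cells, fluorescence-correlated
   nuclei, perinuclear shell by anisotropy-aware 2-µm dilation,
   intra-nuclear Otsu nucleoli, FUCCI phase gating.
5. **quantify** — per-compartment mean RI, density, voxel-count volume,
   dry-mass integral, isosurface sphericity Ψ = π<sup>1/3</sup>(6V)<sup>2/3</sup>/A,
   and the density ratios ρ<sub>np</sub>/ρ<sub>c</sub>,
   ρ<sub>np</sub>/ρ<sub>pc</sub>, ρ<sub>nl</sub>/ρ<sub>np</sub>.
6. **stats** — Shapiro-Wilk-gated two-tailed t / Mann-Whitney comparisons
   with the ∗ *p* < 0.01, ∗∗ *p* < 0.001, ∗∗∗ *p* < 0.0001 convention.

## Worked example

```python
from odtquant import (OpticalConfig, make_cell_phantom, render_fluorescence,
                      segment_cell_compartments, cell_record)

config = OpticalConfig(voxel_size_um=(0.25, 0.25, 0.25))
tomo, truth = make_cell_phantom(config=config)          # 128³ phantom
fluo = render_fluorescence(truth, 0.3, config.voxel_size_um, seed=0)
masks = segment_cell_compartments(tomo, fluo)           # full cascade
rec = cell_record(tomo, masks, config=config)
print({k: round(v, 3) for k, v in rec.ratios.items()})
```

prints

```
{'rho_np/rho_c': 0.916, 'rho_np/rho_pc': 0.895, 'rho_nl/rho_np': 1.579}
```

meaning the phantom's nucleoplasm is measured 8.4% less dense than the
whole cytoplasm (10.5% less than the membrane-rich perinuclear shell),
while its nucleoli are 58% denser than the surrounding nucleoplasm — the
ratios the phantom was built to carry. `examples/` holds one short script
per capability (optics constants, hologram simulation and retrieval,
sphere reconstruction, segmentation + quantification, precision
calibration, population statistics); each prints the numbers it computes
and what they mean.

A thin CLI wraps the same library calls:

```bash
odtquant simulate --n-cells 2 --seed 1 --out run/
odtquant reconstruct --holograms run/cell000_holograms.h5 --out run/rec.tif
odtquant analyze --phantom-dir run/ --out run/analysis/
odtquant calibrate --out run/calibration/
```

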