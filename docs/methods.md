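# Methods

## Physical model

A cell immersed in medium of refractive index *n*<sub>m</sub> perturbs a
plane wave according to the scalar Helmholtz equation with scattering
potential *f* = k₀²(*n*² − *n*<sub>m</sub>²), k₀ = 2π/λ. The package links
RI to dry-mass density through the linear increment model
*n* = *n*<sub>m</sub> + αρ. Defaults: λ = 532 nm, *n*<sub>m</sub> = 1.3370,
α = 0.190 mL/g (protein/nucleic acid). Because phospholipid has a lower
increment (0.135–0.138 mL/g), densities of membrane-rich regions computed
with the protein increment are conservative underestimates;
`DensityModel.alpha_lipid_range` supports recomputing a compartment under
the lipid increment for sensitivity reporting.

Closed-form system characteristics: the lateral resolution is the
half-period of the synthetic-aperture band limit,
d<sub>lat</sub> = λ/(2(NA<sub>det</sub> + NA<sub>ill</sub>)); the axial
resolution is the inverse of the summed sagittal heights of the detection
and illumination Ewald caps,
d<sub>ax</sub> = λ/(*n*<sub>m</sub>[(1 − cos θ<sub>det</sub>) + (1 − cos θ<sub>ill</sub>)]),
sin θᵢ = NAᵢ/*n*<sub>m</sub>. This is the one pair of standard conventions
that reproduces both instrument values (121 nm, 444 nm) at the stated
apertures; both formulas are implemented side by side in
`optics.theoretical_resolution`.

## Forward model and field retrieval

`forward_scatter` samples the 3D spectrum of *f* on the Ewald cap selected
by the illumination direction (trilinear interpolation), applies the
diffraction-theorem weight i/(2K<sub>z</sub>), restricts to the detection
NA, and returns the field normalized by the incident plane wave
(common-path convention: empty medium ⇒ 1 + 0i for every tilt). Under the
Rytov option (the default — cell-scale phase delays of 2–3 rad exceed the
Born validity range) the returned field is exp(ψ) with ψ equal to the
normalized first-order scattered field; `to_rytov` inverts this with
quality-guided 2D phase unwrapping, anchored to zero at the empty border.

Holograms are |u + R·exp(i2πc·x)|² with carrier c = (0.25, 0.25)
cycles/px and reference amplitude 2. Retrieval crops the +1-order sideband
(radius = min(carrier offset, NA band radius); the mean intensity is
subtracted first so the DC delta cannot leak into a crop that reaches it),
recenters by the integer carrier shift, inverse transforms, and divides by
the identically processed background hologram — removing carrier,
reference amplitude, and static aberrations, including any sub-pixel
carrier residual.

Detector sampling: holograms are synthesized on a grid
`detector_oversample`× finer than the object grid (default 2 in the
pipeline experiments). This emulates the magnified detection arm of the
real instrument, whose camera oversamples the NA passband; at matched
sampling an off-axis carrier cannot separate the full passband from the
DC term.

## Tomographic reconstruction

`map_fields_to_spectrum` inverts the forward sampling: each field's
ψ-spectrum is placed on its Ewald cap at the nearest spectrum voxel
(nearest-voxel gridding — the documented accuracy/speed trade-off; no
Kaiser-Bessel regridding), overlapping hits averaged by accumulated
counts. `invert_spectrum` inverse-transforms and converts
*f* → *n* = √(*n*<sub>m</sub>² + *f*/k₀²). The unsampled cone of axial
frequencies (missing cone) causes axial elongation and systematic
underestimation of Δ*n* — about −25% for the mean inside a weak sphere at
these apertures — which `regularize_missing_cone` mitigates by
Gerchberg–Papoulis alternating projections: data consistency on covered
spectrum samples against non-negative contrast (*n* ≥ *n*<sub>m</sub>),
optionally plus an object-support projection (support estimated
shrinkwrap-style by Otsu + closing of the unregularized estimate). The
support constraint is what pulls halo mass back into thin cytoplasmic
regions; without it the loop converges with the thin skirt of an adherent
cell several percent low. Without a support the loop ends on the k-space
projection (covered samples exactly data-consistent up to the Hermitian
symmetrization inherent in producing a real RI map); with a support it
ends on the real-space projection.

Iteration counts: 100 iterations recover a weak sphere's mean to < 5%;
the single-cell recovery experiment uses 500 support-constrained
iterations, the mid-range of the 300–800 window over which the segmented
density ratios hold steady at truth (convergence measured on the phantom
benchmark).

## Phantom design

The default geometry is a spread adherent cell: an oblate ellipsoidal body
(semi-axes 4.5 × 9 × 10 µm) whose nuclear bulge spans essentially the full
local cell height, a thin tapering cytoplasmic skirt, two spherical
nucleoli (radii 1.8 and 1.4 µm), and a 2-µm perinuclear shell carrying a
+4.8 mg/mL density excess by default (emulating the ER/Golgi-rich zone).
The apical/basal cytoplasmic films over the nucleus of a flat interphase
cell are thinner than the axial resolution; the phantom omits them rather
than voxelizing an unresolvable sub-voxel layer whose mass no
limited-angle reconstruction could localize. Compartment boundaries are
hard by default (a Gaussian transition of configurable width is
available); voxels outside the cell are exactly *n*<sub>m</sub>. Default
densities reproduce the control-population compartment RI means
(cytoplasm 1.3538 → 88.42 mg/mL, nucleoplasm 1.3528 → 83.16 mg/mL,
nucleoli 1.58 × nucleoplasm).

The population generator scales all linear dimensions by the cube root of
a volume factor interpolating 1 → 2 across G1 → early S → S/G2 at fixed
densities, so volume and dry mass double over the cycle while density is
constant by construction. FUCCI reporter levels are phase-separable
(mKO2-high in G1, both in early S, mAG1-high in S/G2); any monotone gate
recovers the phase, and the default gate is per-channel Otsu over the
population of per-cell means. One top-level seed fans out to per-cell
child seeds via `numpy.random.SeedSequence.spawn`, so subsets reproduce.

What the phantoms do *not* emulate: subcellular texture (ER, mitochondria),
soft compartment boundaries, inter-angle drift, photobleaching, camera
MTF, speckle. Passing tests therefore demonstrate correctness of the
computational chain under the stated noise models, not robustness to every
artifact of real acquisitions.

## Segmentation

Cells: Otsu threshold on the 1-voxel-smoothed RI map, distance-transform
watershed seeded at maxima ≥ 4 µm apart, minimum cell volume 50 µm³,
border-touching cells excluded by default. Nuclei: Otsu on the 3D
fluorescence (mKO2 + mAG1, or a named channel); components assigned to the
cell of maximal overlap and clipped to it; an `extend2d` mode thresholds
the axial projection instead for 2D-only acquisitions (the 3D mode is the
default because it is the one that reaches Dice > 0.95 against truth on
oblate cells). Perinuclear shell: Euclidean distance transform with
per-axis voxel sizes (anisotropy-aware), thickness 2 µm, clipped to the
cell. Nucleoli: Otsu restricted to intra-nuclear RI, accepted only when
the class means separate by ≥ 3 pooled within-class standard deviations
(pure noise separates by ≈ 1.4, real nucleoli by ≫ 3), minimum volume
2 µm³. All cascade outputs satisfy the mask algebra (nucleoplasm =
nucleus \ nucleoli, cytoplasm = cell \ nucleus, shell ⊆ cytoplasm) by
construction and are validated after every run.

## Quantification

Volume is voxel count × voxel volume; dry mass integrates the per-voxel
density over the mask (1 mg/mL·µm³ = 10⁻³ pg), not mean × volume, so mass
additivity over partitions is exact. Surface area comes from a
marching-cubes isosurface at the 0.5 level of the one-voxel-Gaussian-
smoothed mask: voxel-face counting would overestimate area by tens of
percent and bias Ψ low, while the smoothed mesh reproduces Ψ = 1 for
digital spheres (r = 20 voxels) within 2%. The smoothing rounds sharp
edges, so for a digital cube the mesh Ψ sits ~4% above the closed-form
0.806; the closed form itself is tested exactly and the mesh against a 5%
bound. The statistics report "cytoplasm" including the perinuclear shell
(it is part of the cytoplasm); a flag restricts to cytoplasm-minus-shell.

## Statistics

Normality is gated by Shapiro-Wilk at 0.05 (the gate level is a documented
default). Two-tailed t-test when both groups pass — Welch's
unequal-variance form by default, since group variances differ in
practice; a flag restores the pooled form — otherwise the two-tailed
Mann-Whitney U. Stars: ∗ *p* < 0.01, ∗∗ *p* < 0.001, ∗∗∗ *p* < 0.0001,
boundary values taking the weaker label. Means ± SE are reported for
normal-passing samples, means alone otherwise. No multiple-testing
correction is applied.

## Numerical conventions and degenerate inputs

Real-space arrays put the object origin at the central index; transforms
are `fft(ifftshift(·))` / `fftshift(ifft(·))` with angular frequencies
2π·fftfreq. Evanescent components and samples beyond the object grid's
Nyquist are dropped during mapping. Reconstructed tomograms may dip up to
1 × 10⁻⁴ RI below *n*<sub>m</sub> (band-limit ripple after the final
data-consistency projection); the `RITomogram.check_nonneg` tolerance
encodes this. Degenerate inputs fail loudly: unimodal histograms yield
empty segmentations with warnings, empty masks and sub-minimal sample
sizes raise, carrier/sideband overlap raises a dedicated separation error.

## Desk-scale problem sizes

Tests and experiments run on 128³ grids at 0.25 µm voxels with 60-angle
scans (the instrument's 150 angles and 0.121 µm sampling remain the
configuration defaults). At this scale the end-to-end recovery experiment
reconstructs, segments, and quantifies a cell in about two minutes on one
CPU, and recovers ρ_np/ρ_c within 0.01 and ρ_nl/ρ_np within 0.03 of the
phantom truth. The per-cell ratio biases that remain are boundary
partial-volume effects of limited-angle tomography and are discussed above.

## Known limitations

Single scattering only (first Born/Rytov); no regridding kernels; the
Gerchberg–Papoulis loop is the only missing-cone treatment; nuclei
require a fluorescence channel (no RI-only nuclear segmentation); no
mitotic-cell handling or time-lapse tracking; absolute osmolarity
inference is out of scope (only the Van't Hoff conversion is provided).
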