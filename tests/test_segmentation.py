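"""Segmentation cascade: cells, nuclei, shell, nucleoli, phase calls."""

import warnings

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from odtquant import (
    CellGeometry,
    OpticalConfig,
    RITomogram,
    assign_nuclei,
    classify_cell_cycle,
    make_cell_phantom,
    perinuclear_shell,
    render_fluorescence,
    segment_cell_compartments,
    segment_cells,
    segment_nucleoli,
    validate_masks,
)
from odtquant.phantom import FluorescenceStack


def _two_spheres_tomogram(config, centers, radius_um=5.0, dn=0.017, n=128):
    ax = (np.arange(n) - (n - 1) / 2) * config.voxel_size_um[0]
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    vals = np.full((n, n, n), config.medium_ri)
    for cz, cy, cx in centers:
        vals[(z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= radius_um**2] += dn
    return RITomogram(vals, config.voxel_size_um, config.medium_ri)


class TestSegmentCells:
    def test_two_disjoint_cells(self, config):
        tomo = _two_spheres_tomogram(config, [(0, 0, -7.5), (0, 0, 7.5)])
        labels = segment_cells(tomo)
        assert labels.max() == 2

    def test_two_touching_cells_split_by_watershed(self, config):
        # overlapping spheres joined by a thin neck
        tomo = _two_spheres_tomogram(config, [(0, 0, -4.6), (0, 0, 4.6)])
        labels = segment_cells(tomo)
        assert labels.max() == 2

    def test_background_only_gives_no_cells(self, config):
        vals = np.full((48, 48, 48), config.medium_ri)
        tomo = RITomogram(vals, config.voxel_size_um, config.medium_ri)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = segment_cells(tomo)
        assert labels.max() == 0

    def test_border_cells_excluded(self, config):
        tomo = _two_spheres_tomogram(config, [(0, 0, 13.0)])  # pokes out of FOV
        labels = segment_cells(tomo, exclude_border=True)
        assert labels.max() == 0


class TestAssignNuclei:
    def test_noiseless_phantom_dice(self, config, phantom):
        tomo, truth = phantom
        fluo = render_fluorescence(truth, 0.3, config.voxel_size_um)
        labels = segment_cells(tomo)
        nuclei = assign_nuclei(labels, fluo)
        _, dice = validate_masks(nuclei[1], truth.masks.nucleus)
        assert dice > 0.95

    def test_no_signal_gives_empty_and_warns(self, config, phantom):
        tomo, truth = phantom
        labels = segment_cells(tomo)
        flat = FluorescenceStack(
            {"mKO2": np.zeros(tomo.shape), "mAG1": np.zeros(tomo.shape)},
            0.3,
            config.voxel_size_um,
        )
        with pytest.warns(UserWarning):
            nuclei = assign_nuclei(labels, flat)
        assert not nuclei[1].any()

    def test_nucleus_clipped_to_cell(self, config, phantom):
        tomo, truth = phantom
        fluo = render_fluorescence(truth, 0.8, config.voxel_size_um)  # heavy blur
        labels = segment_cells(tomo)
        nuclei = assign_nuclei(labels, fluo)
        assert not np.any(nuclei[1] & (labels != 1))


class TestPerinuclearShell:
    def test_spherical_shell_volume_analytic(self):
        # r = 5 µm nucleus, 2 µm shell: V = 4π/3 (7³ − 5³) = 913.0 µm³
        n, vox = 96, 0.2
        ax = (np.arange(n) - (n - 1) / 2) * vox
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        nucleus = z**2 + y**2 + x**2 <= 5.0**2
        shell = perinuclear_shell(nucleus, (vox, vox, vox), thickness_um=2.0)
        vol = shell.sum() * vox**3
        assert vol == pytest.approx(4 / 3 * np.pi * (7**3 - 5**3), rel=0.05)

    def test_empty_nucleus_gives_empty_shell(self):
        empty = np.zeros((16, 16, 16), bool)
        assert not perinuclear_shell(empty, (0.25,) * 3).any()

    def test_shell_disjoint_from_nucleus(self, phantom):
        _, truth = phantom
        shell = perinuclear_shell(truth.masks.nucleus, (0.25,) * 3)
        assert not np.any(shell & truth.masks.nucleus)

    def test_anisotropic_voxels_give_physical_thickness(self):
        # coarse axial voxels must not inflate the axial shell extent
        n = 64
        nucleus = np.zeros((n, n, n), bool)
        ax = (np.arange(n) - (n - 1) / 2)
        z, y, x = np.meshgrid(ax * 0.5, ax * 0.25, ax * 0.25, indexing="ij")
        nucleus[z**2 + y**2 + x**2 <= 4.0**2] = True
        shell = perinuclear_shell(nucleus, (0.5, 0.25, 0.25), thickness_um=2.0)
        zc = np.where(shell.any(axis=(1, 2)))[0]
        yc = np.where(shell.any(axis=(0, 2)))[0]
        z_extent = (zc.max() - zc.min() + 1) * 0.5
        y_extent = (yc.max() - yc.min() + 1) * 0.25
        assert z_extent == pytest.approx(y_extent, abs=1.0)


class TestSegmentNucleoli:
    def test_two_nucleoli_recovered(self, config, phantom):
        tomo, truth = phantom
        from scipy import ndimage

        nucleoli = segment_nucleoli(tomo, truth.masks.nucleus)
        _, n_comp = ndimage.label(nucleoli)
        assert n_comp == 2
        tpr, _ = validate_masks(nucleoli, truth.masks.nucleoli)
        assert tpr >= 0.99

    def test_uniform_nucleus_gives_empty(self, config):
        geo = CellGeometry(nucleoli=())
        tomo, truth = make_cell_phantom(geo, config=config, shape=(64, 64, 64))
        with pytest.warns(UserWarning):
            nucleoli = segment_nucleoli(tomo, truth.masks.nucleus)
        assert not nucleoli.any()

    def test_noise_only_nucleus_gates_as_unimodal(self, config):
        rng = np.random.default_rng(0)
        vals = np.full((48, 48, 48), 1.353) + rng.normal(0, 5e-4, (48, 48, 48))
        tomo = RITomogram(vals, config.voxel_size_um, config.medium_ri)
        nucleus = np.zeros((48, 48, 48), bool)
        nucleus[8:40, 8:40, 8:40] = True
        with pytest.warns(UserWarning):
            nucleoli = segment_nucleoli(tomo, nucleus)
        assert not nucleoli.any()

    def test_empty_nucleus_rejected(self, config, phantom):
        tomo, _ = phantom
        with pytest.raises(ValueError):
            segment_nucleoli(tomo, np.zeros(tomo.shape, bool))


class TestCellCycleGate:
    @pytest.mark.parametrize(
        "mko2, mag1, label",
        [
            (1.0, 0.02, "G1"),
            (0.8, 0.8, "earlyS"),
            (0.02, 1.0, "SG2"),
            (0.01, 0.01, "unclassified"),
        ],
    )
    def test_gate_rule(self, mko2, mag1, label):
        phase = classify_cell_cycle(mko2, mag1, gates=(0.1, 0.1))
        assert phase.label == label

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            classify_cell_cycle(-1.0, 0.5, gates=(0.1, 0.1))


class TestValidateMasks:
    def test_perfect_prediction(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:6, 2:6, 2:6] = True
        assert validate_masks(m, m) == (1.0, 1.0)

    def test_empty_prediction(self):
        t = np.ones((4, 4, 4), bool)
        tpr, dice = validate_masks(np.zeros_like(t), t)
        assert tpr == 0.0 and dice == 0.0

    def test_half_overlap_exact(self):
        t = np.zeros((4, 4, 8), bool)
        t[..., :4] = True
        p = np.zeros_like(t)
        p[..., 2:6] = True  # half inside truth, same size
        tpr, dice = validate_masks(p, t)
        assert tpr == 0.5 and dice == 0.5

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            validate_masks(np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool))


class TestCascade:
    def test_otsu_separates_two_delta_histogram(self):
        vals = np.concatenate([np.full(600, 1.337), np.full(400, 1.354)])
        thr = threshold_otsu(vals)
        assert 1.337 < thr < 1.354

    @pytest.mark.parametrize("jitter", [0, 1, 2])
    def test_cascade_invariants_and_fidelity(self, config, jitter):
        rng = np.random.default_rng(jitter)
        scale = float(np.exp(rng.normal(0, 0.05)))
        geo = CellGeometry().scaled(scale)
        tomo, truth = make_cell_phantom(geo, config=config, shape=(128, 128, 128))
        fluo = render_fluorescence(truth, 0.3, config.voxel_size_um, seed=jitter)
        masks = segment_cell_compartments(tomo, fluo)
        masks.validate()
        for name in ("cell", "nucleus", "nucleoplasm", "nucleoli", "perinuclear"):
            _, dice = validate_masks(getattr(masks, name), getattr(truth.masks, name))
            assert dice > 0.9, name

    def test_cascade_deterministic(self, config, phantom):
        tomo, truth = phantom
        fluo = render_fluorescence(truth, 0.3, config.voxel_size_um, seed=0)
        a = segment_cell_compartments(tomo, fluo)
        b = segment_cell_compartments(tomo, fluo)
        for name in ("cell", "nucleus", "nucleoli"):
            assert np.array_equal(getattr(a, name), getattr(b, name))
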