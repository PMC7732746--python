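"""Compartment segmentation cascade.

The cascade mirrors the measurement workflow: cells are separated from the
medium by Otsu thresholding of the RI map and split into individuals by a
distance-transform-seeded watershed; nuclei come from the co-registered
fluorescence channels; the perinuclear cytoplasm is the 2-µm shell obtained
by physical-distance dilation of the nucleus mask; nucleoli are segmented by
a second Otsu threshold restricted to intra-nuclear RI values.  Cell-cycle
phase is assigned from the mean FUCCI reporter intensities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

from .masks import CompartmentMasks
from .optics import RITomogram
from .phantom import FluorescenceStack, perinuclear_shell_mask

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentMasks",
    "CellCyclePhase",
    "segment_cells",
    "assign_nuclei",
    "perinuclear_shell",
    "segment_nucleoli",
    "classify_cell_cycle",
    "validate_masks",
    "segment_cell_compartments",
    "otsu_gates",
]

#: Default minimum object volumes, µm³ (plumbing choices; small debris and
#: single-voxel noise below these are discarded).
MIN_CELL_VOLUME_UM3 = 50.0
MIN_NUCLEOLUS_VOLUME_UM3 = 2.0

#: A restricted Otsu split is considered bimodal only when the class means
#: are separated by at least this many pooled within-class standard
#: deviations; pure noise splits at ~1.4 and true nucleoli far above.
BIMODALITY_MIN_SEPARATION = 3.0


@dataclass(frozen=True)
class CellCyclePhase:
    """FUCCI-derived cell-cycle call for one cell."""

    label: str  # G1 | earlyS | SG2 | unclassified
    mko2_mean: float
    mag1_mean: float


def _voxel_volume(voxel_size_um) -> float:
    return float(np.prod(voxel_size_um))


def segment_cells(
    tomogram: RITomogram,
    min_volume_um3: float = MIN_CELL_VOLUME_UM3,
    exclude_border: bool = True,
    smooth_sigma_vox: float = 1.0,
) -> np.ndarray:
    """Label individual cells in an RI tomogram.

    Otsu's threshold on the (lightly smoothed) RI map separates cell from
    medium; touching cells are split by a watershed on the negated Euclidean
    distance transform, seeded at distance maxima at least 4 µm apart.
    Returns an integer label map (0 = background).  Cells touching the
    lateral field-of-view border are dropped when ``exclude_border``.
    """
    vals = ndimage.gaussian_filter(tomogram.values, smooth_sigma_vox)
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-6:
        warnings.warn("tomogram histogram is unimodal; no cells found")
        return np.zeros(tomogram.shape, dtype=np.int32)
    thr = threshold_otsu(vals)
    fg = vals > thr
    if not fg.any() or fg.all():
        warnings.warn("Otsu threshold produced no foreground/background split")
        return np.zeros(tomogram.shape, dtype=np.int32)

    dist = ndimage.distance_transform_edt(fg, sampling=tomogram.voxel_size_um)
    min_sep_vox = max(1, int(round(4.0 / max(tomogram.voxel_size_um))))
    peaks = peak_local_max(
        dist, labels=fg, min_distance=min_sep_vox, exclude_border=False
    )
    markers = np.zeros(tomogram.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(fg)
    labels = watershed(-dist, markers, mask=fg)

    voxvol = _voxel_volume(tomogram.voxel_size_um)
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if m.sum() * voxvol < min_volume_um3:
            continue
        if exclude_border:
            if (
                m[:, 0, :].any()
                or m[:, -1, :].any()
                or m[:, :, 0].any()
                or m[:, :, -1].any()
            ):
                logger.info("cell %d touches the field-of-view border; excluded", lab)
                continue
        out[m] = next_id
        next_id += 1
    return out


def assign_nuclei(
    cell_labels: np.ndarray,
    fluorescence: FluorescenceStack,
    channel: str | None = None,
    mode: str = "3d",
) -> dict[int, np.ndarray]:
    """Segment nuclei from fluorescence and assign each to a cell.

    The nuclear channel (sum of mKO2 + mAG1 unless ``channel`` names one) is
    Otsu-thresholded; connected components are assigned to the cell label
    with maximal overlap, and every nucleus is clipped to its cell mask.
    ``mode='extend2d'`` thresholds the axial maximum projection instead and
    extends the 2D mask along z before clipping (for setups where only 2D
    epi-fluorescence is available).
    """
    if channel is not None:
        nuc = fluorescence.channels[channel]
    else:
        nuc = fluorescence.channels.get("mKO2", 0) + fluorescence.channels.get("mAG1", 0)
        if np.isscalar(nuc):
            raise ValueError("no nuclear channel available")
    nuc = np.asarray(nuc, dtype=np.float64)

    out: dict[int, np.ndarray] = {}
    n_cells = int(cell_labels.max())
    if nuc.max() - nuc.min() < 1e-12:
        warnings.warn("no fluorescence signal; nuclei left empty")
        for lab in range(1, n_cells + 1):
            out[lab] = np.zeros(cell_labels.shape, dtype=bool)
        return out

    if mode == "extend2d":
        proj = nuc.max(axis=0) if nuc.ndim == 3 else nuc
        mask2d = proj > threshold_otsu(proj)
        mask = np.broadcast_to(mask2d, cell_labels.shape).copy()
    elif mode == "3d":
        if nuc.ndim == 2:
            mask = np.broadcast_to(nuc > threshold_otsu(nuc), cell_labels.shape).copy()
        else:
            mask = nuc > threshold_otsu(nuc)
    else:
        raise ValueError("mode must be '3d' or 'extend2d'")

    comps, n_comp = ndimage.label(mask)
    for lab in range(1, n_cells + 1):
        out[lab] = np.zeros(cell_labels.shape, dtype=bool)
    for comp in range(1, n_comp + 1):
        cm = comps == comp
        overlap_labels, counts = np.unique(cell_labels[cm], return_counts=True)
        inside = overlap_labels > 0
        if not inside.any():
            continue
        best = int(overlap_labels[inside][np.argmax(counts[inside])])
        if (overlap_labels > 0).sum() > 1:
            logger.info(
                "nucleus component %d straddles cells %s; assigned to %d",
                comp,
                overlap_labels[inside].tolist(),
                best,
            )
        out[best] |= cm & (cell_labels == best)
    return out


def perinuclear_shell(
    nucleus_mask: np.ndarray,
    voxel_size_um,
    thickness_um: float = 2.0,
    cell_mask: np.ndarray | None = None,
) -> np.ndarray:
    """The perinuclear cytoplasm: all voxels within ``thickness_um`` of the
    nucleus surface, outside the nucleus, clipped to the cell.

    Dilation by physical distance uses the anisotropy-aware Euclidean
    distance transform, so coarser axial voxels still give a 2-µm shell.
    """
    if thickness_um <= 0:
        raise ValueError("shell thickness must be positive")
    nucleus_mask = np.asarray(nucleus_mask, bool)
    if not nucleus_mask.any():
        return np.zeros_like(nucleus_mask)
    shell = perinuclear_shell_mask(nucleus_mask, thickness_um, voxel_size_um)
    if cell_mask is not None:
        shell &= np.asarray(cell_mask, bool)
    return shell


def segment_nucleoli(
    tomogram: RITomogram,
    nucleus_mask: np.ndarray,
    min_volume_um3: float = MIN_NUCLEOLUS_VOLUME_UM3,
    min_separation: float = BIMODALITY_MIN_SEPARATION,
) -> np.ndarray:
    """Nucleoli = upper Otsu class of the RI values inside the nucleus.

    A bimodality gate rejects near-unimodal intra-nuclear histograms (Otsu
    always splits, even pure noise): the split is kept only when the class
    means are separated by ``min_separation`` pooled within-class standard
    deviations.  Components smaller than ``min_volume_um3`` are dropped.
    """
    nucleus_mask = np.asarray(nucleus_mask, bool)
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    vals = tomogram.values[nucleus_mask]
    if vals.max() - vals.min() < 1e-12:
        warnings.warn("uniform intra-nuclear RI; no nucleoli")
        return np.zeros_like(nucleus_mask)
    thr = threshold_otsu(vals)
    hi = vals > thr
    lo = ~hi
    if not hi.any() or not lo.any():
        warnings.warn("degenerate intra-nuclear split; no nucleoli")
        return np.zeros_like(nucleus_mask)
    pooled_sd = np.sqrt(
        (np.var(vals[hi]) * hi.sum() + np.var(vals[lo]) * lo.sum()) / vals.size
    )
    if pooled_sd > 0 and (vals[hi].mean() - vals[lo].mean()) < min_separation * pooled_sd:
        warnings.warn("intra-nuclear histogram near-unimodal; no nucleoli detected")
        return np.zeros_like(nucleus_mask)

    mask = np.zeros_like(nucleus_mask)
    mask[nucleus_mask] = tomogram.values[nucleus_mask] > thr
    comps, n_comp = ndimage.label(mask)
    voxvol = _voxel_volume(tomogram.voxel_size_um)
    for comp in range(1, n_comp + 1):
        cm = comps == comp
        if cm.sum() * voxvol < min_volume_um3:
            mask[cm] = False
    return mask


def classify_cell_cycle(
    mko2_mean: float,
    mag1_mean: float,
    gates: tuple[float, float],
) -> CellCyclePhase:
    """Two-threshold FUCCI gate.

    mKO2-only above gate → G1; both above → early S; mAG1-only → S/G2;
    neither → unclassified (excluded from downstream statistics).
    """
    if mko2_mean < 0 or mag1_mean < 0:
        raise ValueError("intensities must be non-negative")
    gk, ga = gates
    k = mko2_mean > gk
    a = mag1_mean > ga
    if k and a:
        label = "earlyS"
    elif k:
        label = "G1"
    elif a:
        label = "SG2"
    else:
        label = "unclassified"
    return CellCyclePhase(label, float(mko2_mean), float(mag1_mean))


def otsu_gates(
    mko2_means: np.ndarray, mag1_means: np.ndarray
) -> tuple[float, float]:
    """Per-channel Otsu thresholds on a population of per-cell reporter means.

    Parameter-free FUCCI gates: any monotone gate separates the phantom's
    reporter levels, and Otsu on the population of cell means is the
    documented default.  Falls back to half the maximum for degenerate
    (single-phase) populations.
    """

    def gate(v):
        v = np.asarray(v, dtype=np.float64)
        if np.ptp(v) < 1e-12 or v.size < 2:
            return float(v.max()) / 2.0
        return float(threshold_otsu(v))

    return gate(mko2_means), gate(mag1_means)


def validate_masks(predicted: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(sensitivity, Dice) of a predicted mask against ground truth.

    TPR = |pred ∩ truth| / |truth|;  Dice = 2|pred ∩ truth| / (|pred| + |truth|).
    """
    predicted = np.asarray(predicted, bool)
    truth = np.asarray(truth, bool)
    if predicted.shape != truth.shape:
        raise ValueError("masks must share one grid")
    n_truth = truth.sum()
    if n_truth == 0:
        raise ValueError("empty truth mask: sensitivity undefined")
    inter = (predicted & truth).sum()
    tpr = inter / n_truth
    dice = 2.0 * inter / (predicted.sum() + n_truth)
    return float(tpr), float(dice)


def segment_cell_compartments(
    tomogram: RITomogram,
    fluorescence: FluorescenceStack,
    cell_label: int = 1,
    cell_labels: np.ndarray | None = None,
    shell_thickness_um: float = 2.0,
    nucleus_mode: str = "3d",
) -> CompartmentMasks:
    """Run the full cascade for one cell and return consistent masks."""
    if cell_labels is None:
        cell_labels = segment_cells(tomogram)
    cell = cell_labels == cell_label
    if not cell.any():
        raise ValueError(f"cell label {cell_label} not found")
    nuclei = assign_nuclei(cell_labels, fluorescence, mode=nucleus_mode)
    nucleus = nuclei.get(cell_label, np.zeros_like(cell))
    if nucleus.any():
        nucleoli = segment_nucleoli(tomogram, nucleus)
        shell = perinuclear_shell(
            nucleus, tomogram.voxel_size_um, shell_thickness_um, cell
        )
    else:
        logger.warning("cell %d has no detected nucleus", cell_label)
        nucleoli = np.zeros_like(cell)
        shell = np.zeros_like(cell)
    masks = CompartmentMasks.from_primary(cell, nucleus, nucleoli, shell)
    masks.validate()
    return masks
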