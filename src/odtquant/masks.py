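"""Compartment mask container shared by the phantom generator and the
segmentation cascade."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CompartmentMasks", "COMPARTMENTS"]

#: Canonical compartment order used in tables.
COMPARTMENTS = ("cell", "cytoplasm", "perinuclear", "nucleus", "nucleoplasm", "nucleoli")


@dataclass
class CompartmentMasks:
    """Mutually consistent 3D binary masks for one cell.

    Invariants (enforced by :meth:`validate`):
      nucleus ⊆ cell, nucleoli ⊆ nucleus,
      nucleoplasm = nucleus \\ nucleoli, cytoplasm = cell \\ nucleus,
      perinuclear ⊆ cytoplasm, perinuclear ∩ nucleus = ∅.
    """

    cell: np.ndarray
    cytoplasm: np.ndarray
    perinuclear: np.ndarray
    nucleus: np.ndarray
    nucleoplasm: np.ndarray
    nucleoli: np.ndarray

    def __post_init__(self) -> None:
        shape = None
        for name in COMPARTMENTS:
            m = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, m)
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError("all masks must share one grid")

    @classmethod
    def from_primary(
        cls,
        cell: np.ndarray,
        nucleus: np.ndarray,
        nucleoli: np.ndarray,
        perinuclear: np.ndarray,
    ) -> "CompartmentMasks":
        """Derive the dependent masks from the four primary ones."""
        cell = np.asarray(cell, bool)
        nucleus = np.asarray(nucleus, bool) & cell
        nucleoli = np.asarray(nucleoli, bool) & nucleus
        cytoplasm = cell & ~nucleus
        perinuclear = np.asarray(perinuclear, bool) & cytoplasm
        return cls(
            cell=cell,
            cytoplasm=cytoplasm,
            perinuclear=perinuclear,
            nucleus=nucleus,
            nucleoplasm=nucleus & ~nucleoli,
            nucleoli=nucleoli,
        )

    def validate(self) -> None:
        """Raise ValueError if any mask-algebra invariant is violated."""
        if np.any(self.nucleus & ~self.cell):
            raise ValueError("nucleus must lie inside the cell")
        if np.any(self.nucleoli & ~self.nucleus):
            raise ValueError("nucleoli must lie inside the nucleus")
        if np.any(self.nucleoplasm != (self.nucleus & ~self.nucleoli)):
            raise ValueError("nucleoplasm must equal nucleus minus nucleoli")
        if np.any(self.cytoplasm != (self.cell & ~self.nucleus)):
            raise ValueError("cytoplasm must equal cell minus nucleus")
        if np.any(self.perinuclear & ~self.cytoplasm):
            raise ValueError("perinuclear shell must lie inside the cytoplasm")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in COMPARTMENTS}
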