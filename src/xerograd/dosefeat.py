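"""Dosimetric features of a structure on a planned dose grid.

Two per-gland features drive the toxicity models:

* **MD** — mean planned dose over the structure's voxels (Gy).
* **GRADX** — average dose gradient along the lateral axis within the
  structure (Gy/mm), signed so that positive means dose increasing toward
  the patient midline.  With sharp IMRT falloffs a large medial-positive
  GRADX flags glands whose delivered dose is sensitive to medial drift.

The delivered-dose accumulator averages MD over a sequence of per-fraction
masks and underpins the first-order relation

    delivered MD - planned MD  ≈  GRADX * (mean medial shift),

which for linear migration totalling PGM mm equals GRADX * PGM / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import DoseGrid, GridValidationError, StructureMask, validate_lattice_match


@dataclass(frozen=True)
class DoseFeatures:
    md_gy: float
    gradx_gy_per_mm: float
    n_voxels: int


def compute_md(grid: DoseGrid, mask: StructureMask) -> float:
    """Mean planned dose over in-mask voxels (uniform voxel volume), in Gy."""
    validate_lattice_match(grid, mask)
    if mask.n_voxels == 0:
        raise GridValidationError("cannot compute mean dose of an empty mask")
    return float(grid.values[mask.values].mean())


def compute_gradx(grid: DoseGrid, mask: StructureMask, *, absolute: bool = False) -> float:
    """Average lateral dose gradient within the mask, in Gy/mm.

    The per-voxel derivative uses central differences in the interior and
    one-sided differences at the grid boundary (exact for affine dose
    fields).  The raw derivative is multiplied by the gland's
    ``medial_direction`` so that positive GRADX always means "dose increases
    toward medial".  With ``absolute=True`` the magnitude of the derivative
    is averaged instead (the sign convention then plays no role).
    """
    validate_lattice_match(grid, mask)
    if mask.n_voxels == 0:
        raise GridValidationError("cannot compute GRADX of an empty mask")
    axis = grid.lateral_axis
    if grid.shape[axis] < 3:
        raise GridValidationError("need >= 3 voxels along the lateral axis")
    deriv = np.gradient(grid.values, grid.spacing_mm[axis], axis=axis)
    if absolute:
        return float(np.abs(deriv)[mask.values].mean())
    deriv = deriv * mask.medial_direction
    return float(deriv[mask.values].mean())


def compute_features(grid: DoseGrid, mask: StructureMask, *, absolute_gradient: bool = False) -> DoseFeatures:
    return DoseFeatures(
        md_gy=compute_md(grid, mask),
        gradx_gy_per_mm=compute_gradx(grid, mask, absolute=absolute_gradient),
        n_voxels=mask.n_voxels,
    )


def accumulate_delivered_md(grid: DoseGrid, masks: Sequence[StructureMask]) -> float:
    """Delivered mean dose: unweighted average of per-fraction mean doses."""
    if len(masks) == 0:
        raise GridValidationError("need at least one per-fraction mask")
    return float(np.mean([compute_md(grid, m) for m in masks]))
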