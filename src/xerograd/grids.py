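"""Volumetric containers for planned dose distributions and structure masks.

A :class:`DoseGrid` is a 3D scalar field of absorbed dose (Gy) on a regular
lattice; a :class:`StructureMask` is a binary region of interest on the same
lattice.  World coordinates follow the convention

    world = origin_mm + index * spacing_mm        (voxel centers, 0-based)

Exactly one grid axis is labelled ``lateral`` (patient left-right); per-gland
medial direction (+1 or -1 along that axis) orients gradient features so that
positive means "toward the patient midline".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PATIENT_AXES = ("lateral", "ap", "si")


class GridValidationError(ValueError):
    """Raised when a grid/mask violates its structural invariants."""


def _as_tuple3(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(x))
    if len(t) != 3:
        raise GridValidationError(f"{name} must have 3 entries, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class DoseGrid:
    """Planned 3D dose distribution with lattice metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Dose per voxel in Gy; finite and non-negative.
    spacing_mm, origin_mm : length-3 sequences
        Voxel size and world position of voxel (0, 0, 0), in mm.
    axis_labels : tuple of str
        Patient-axis label per grid axis; exactly one must be ``"lateral"``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = PATIENT_AXES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise GridValidationError("dose array must be 3D")
        if not np.all(np.isfinite(values)):
            raise GridValidationError("dose values must be finite")
        if np.any(values < 0):
            raise GridValidationError("dose values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", _as_tuple3(self.spacing_mm, "spacing_mm"))
        object.__setattr__(self, "origin_mm", _as_tuple3(self.origin_mm, "origin_mm"))
        if any(s <= 0 for s in self.spacing_mm):
            raise GridValidationError("spacing must be positive")
        labels = tuple(self.axis_labels)
        if labels.count("lateral") != 1:
            raise GridValidationError("exactly one axis must be labelled 'lateral'")
        object.__setattr__(self, "axis_labels", labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def lateral_axis(self) -> int:
        return self.axis_labels.index("lateral")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates along one grid axis, in mm."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.spacing_mm[axis]


@dataclass(frozen=True)
class StructureMask:
    """Binary structure on the lattice of its paired :class:`DoseGrid`.

    ``medial_direction`` is +1 if increasing index along the lateral axis
    points toward the patient midline for this gland, else -1.
    """

    values: np.ndarray
    laterality: str = "contralateral"
    medial_direction: int = 1

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise GridValidationError("mask array must be 3D")
        values = values.astype(bool)
        object.__setattr__(self, "values", values)
        if self.laterality not in ("contralateral", "ipsilateral"):
            raise GridValidationError(
                "laterality must be 'contralateral' or 'ipsilateral'"
            )
        if self.medial_direction not in (-1, 1):
            raise GridValidationError("medial_direction must be +1 or -1")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def validate_lattice_match(grid: DoseGrid, mask: StructureMask) -> None:
    """Dose features never resample: mask and grid must share one lattice."""
    if grid.shape != mask.shape:
        raise GridValidationError(
            f"mask shape {mask.shape} does not match dose grid {grid.shape}"
        )


# --- NIfTI I/O -------------------------------------------------------------

def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_nifti(path, values: np.ndarray, spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(spacing_mm, origin_mm))
    nib.save(img, str(path))


def read_dose_nifti(path, axis_labels: tuple[str, str, str] = PATIENT_AXES) -> DoseGrid:
    """Load a dose volume; spacing/origin come from the NIfTI header."""
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return DoseGrid(np.asanyarray(img.dataobj), spacing, origin, axis_labels)


def read_mask_nifti(path, laterality: str = "contralateral", medial_direction: int = 1) -> StructureMask:
    import nibabel as nib

    img = nib.load(str(path))
    return StructureMask(np.asanyarray(img.dataobj) > 0.5, laterality, medial_direction)
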