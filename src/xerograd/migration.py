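"""Parotid gland migration estimated from external-contour volume change.

Daily setup CT rarely covers the whole gland, so medial gland drift is
proxied by shrinkage of the external body contour in a slab at the level of
the C2 vertebral body.  The chain is:

1. ``delta_vc2`` — relative slab-volume change between fraction 1 and a
   control day, in percent: 100 * (VC2_c - VC2_1) / VC2_1.
2. ``pgm_at_control`` — linear map to medial gland migration at the control
   day: PGM_c = -0.413 mm per percent of volume change (an empirical
   coefficient from serial-imaging studies; override via
   :class:`MigrationModelParams` to recalibrate).
3. ``extrapolate_pgm`` — gland motion is approximately linear in time, so
   PGM at the end of treatment is PGM_c scaled by end_day / control_day
   (a line through the origin at day 0 = fraction 1).

ΔVC2 enters the linear map on the PERCENT scale.  Contour shrinkage
(ΔVC2 < 0) therefore yields positive (medial) PGM under the default
negative slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridValidationError, StructureMask

#: mm of medial gland migration per percent of C2-slab volume change
DEFAULT_SLOPE_MM_PER_PCT = -0.413


class MigrationInputError(ValueError):
    """Raised on invalid volumes or acquisition days."""


@dataclass(frozen=True)
class MigrationModelParams:
    slope_mm_per_pct: float = DEFAULT_SLOPE_MM_PER_PCT

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope_mm_per_pct) or self.slope_mm_per_pct == 0:
            raise MigrationInputError("slope must be finite and nonzero")


@dataclass(frozen=True)
class MigrationRecord:
    """Per-patient migration summary derived from two slab volumes."""

    patient_id: str
    vc2_first_ml: float
    vc2_control_ml: float
    control_day: float
    end_day: float
    delta_vc2_pct: float
    pgm_control_mm: float
    pgm_mm: float


def slab_volume(mask: StructureMask, spacing_mm) -> float:
    """Volume of a binary slab mask in mL (voxel count x voxel volume)."""
    if mask.n_voxels == 0:
        raise GridValidationError("cannot compute volume of an empty mask")
    voxel_mm3 = float(np.prod(np.asarray(spacing_mm, dtype=float)))
    if voxel_mm3 <= 0:
        raise MigrationInputError("spacing must be positive")
    return mask.n_voxels * voxel_mm3 / 1000.0


def delta_vc2(vc2_first_ml: float, vc2_control_ml: float) -> float:
    """Relative volume change between fraction 1 and control day, percent."""
    if not vc2_first_ml > 0:
        raise MigrationInputError("baseline slab volume must be positive")
    return 100.0 * (vc2_control_ml - vc2_first_ml) / vc2_first_ml


def pgm_at_control(delta_vc2_pct: float, params: MigrationModelParams | None = None) -> float:
    """Medial migration at the control day (mm) from ΔVC2 in percent."""
    if not math.isfinite(delta_vc2_pct):
        raise MigrationInputError("delta_vc2_pct must be finite")
    params = params or MigrationModelParams()
    return params.slope_mm_per_pct * delta_vc2_pct


def extrapolate_pgm(pgm_control_mm: float, control_day: float, end_day: float) -> float:
    """Linear-in-time extrapolation of migration to the end of treatment."""
    if not 0 < control_day <= end_day:
        raise MigrationInputError("need 0 < control_day <= end_day")
    return pgm_control_mm * end_day / control_day


def migration_record(
    patient_id: str,
    vc2_first_ml: float,
    vc2_control_ml: float,
    control_day: float,
    end_day: float,
    params: MigrationModelParams | None = None,
) -> MigrationRecord:
    dv = delta_vc2(vc2_first_ml, vc2_control_ml)
    pgm_c = pgm_at_control(dv, params)
    return MigrationRecord(
        patient_id=str(patient_id),
        vc2_first_ml=float(vc2_first_ml),
        vc2_control_ml=float(vc2_control_ml),
        control_day=float(control_day),
        end_day=float(end_day),
        delta_vc2_pct=dv,
        pgm_control_mm=pgm_c,
        pgm_mm=extrapolate_pgm(pgm_c, control_day, end_day),
    )


def migration_table(
    volumes: pd.DataFrame,
    end_day: float,
    params: MigrationModelParams | None = None,
) -> pd.DataFrame:
    """Per-patient migration records from a long volume table.

    ``volumes`` needs columns ``patient_id, day, vc2_ml``; each patient must
    have a row at day 0 (fraction 1).  The control day is the latest
    available day > 0.
    """
    required = {"patient_id", "day", "vc2_ml"}
    missing = required - set(volumes.columns)
    if missing:
        raise MigrationInputError(f"volumes table missing columns: {sorted(missing)}")
    records = []
    for pid, sub in volumes.groupby("patient_id", sort=True):
        sub = sub.sort_values("day")
        baseline = sub[sub["day"] == 0]
        if baseline.empty:
            raise MigrationInputError(f"patient {pid}: no day-0 baseline volume")
        later = sub[sub["day"] > 0]
        if later.empty:
            raise MigrationInputError(f"patient {pid}: no control-day volume")
        control = later.iloc[-1]
        records.append(
            migration_record(
                pid,
                float(baseline["vc2_ml"].iloc[0]),
                float(control["vc2_ml"]),
                float(control["day"]),
                end_day,
                params,
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])
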