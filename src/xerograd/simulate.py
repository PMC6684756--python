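"""Synthetic phantoms and cohorts for dose-gradient toxicity modelling.

The clinical data behind gradient/migration xerostomia studies are not
public, so this module provides two generators that every downstream stage
can be tested against:

* **Phantoms** — a sigmoid lateral dose falloff (a caricature of a sharp
  IMRT gradient next to a spared gland) plus an ellipsoidal gland mask, and
  a per-fraction mask sequence under linear medial drift.  Gradient and
  migration are known in closed form, so delivered-dose properties can be
  checked exactly.
* **Cohorts** — per-patient feature tables, C2-slab volume series and
  follow-up reports whose marginals match the published cohort: mean dose
  18.6 ± 5.9 Gy (contralateral) / 25.6 ± 8.9 Gy (ipsilateral), ipsi-contra
  concordance via a Gaussian copula (Kendall τ default 0.5), log-normal
  lateral gradient with median 1.27 Gy/mm, C2 volume change −2.0 ± 4.2 %
  with control day 28–36 of a 40-day course, and ~11.4 % prevalence of the
  positive endpoint.

The outcome mechanism is a logistic model on standardized terms.  Its
default places most weight on the first-order delivered-dose increment
GRADX · PGM / 2 and a gradient main effect, with only a weak mean-dose
term — the coefficient calibration is documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import migration as mig
from .grids import DoseGrid, GridValidationError, StructureMask, write_nifti


class SimulationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a sigmoid-falloff dose phantom with an ellipsoidal gland.

    The dose along the lateral axis is
    ``plateau_dose_gy * sigmoid((x - falloff_center_mm) * medial_direction
    / falloff_scale_mm)`` and constant along the other axes, i.e. dose rises
    toward the midline as it does medially of a spared parotid gland.
    """

    grid_shape: tuple[int, int, int] = (101, 21, 21)
    spacing_mm: tuple[float, float, float] = (1.0, 2.0, 2.0)
    plateau_dose_gy: float = 40.0
    falloff_center_mm: float = 50.0
    falloff_scale_mm: float = 5.0
    gland_center_mm: tuple[float, float, float] = (30.0, 20.0, 20.0)
    gland_radii_mm: tuple[float, float, float] = (10.0, 12.0, 14.0)
    medial_axis: int = 0
    medial_direction: int = 1

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 3 for n in self.grid_shape):
            raise GridValidationError("grid_shape must be 3 axes of >= 3 voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise GridValidationError("spacing must be positive")
        if self.falloff_scale_mm <= 0:
            raise GridValidationError("falloff_scale_mm must be positive")
        if self.medial_axis not in (0, 1, 2):
            raise GridValidationError("medial_axis must be 0, 1 or 2")
        if self.medial_direction not in (-1, 1):
            raise GridValidationError("medial_direction must be +1 or -1")
        for ax in range(3):
            lo = self.gland_center_mm[ax] - self.gland_radii_mm[ax]
            hi = self.gland_center_mm[ax] + self.gland_radii_mm[ax]
            extent = (self.grid_shape[ax] - 1) * self.spacing_mm[ax]
            if lo < 0 or hi > extent:
                raise GridValidationError(
                    f"gland ellipsoid leaves the grid along axis {ax}"
                )

    @property
    def axis_labels(self) -> tuple[str, str, str]:
        others = iter(("ap", "si"))
        return tuple(
            "lateral" if ax == self.medial_axis else next(others) for ax in range(3)
        )  # type: ignore[return-value]


def make_phantom_dose(spec: PhantomSpec) -> DoseGrid:
    """Sigmoid lateral dose falloff, constant along non-lateral axes."""
    x = np.arange(spec.grid_shape[spec.medial_axis]) * spec.spacing_mm[spec.medial_axis]
    profile = spec.plateau_dose_gy * expit(
        (x - spec.falloff_center_mm) * spec.medial_direction / spec.falloff_scale_mm
    )
    shape = [1, 1, 1]
    shape[spec.medial_axis] = len(x)
    values = np.broadcast_to(profile.reshape(shape), spec.grid_shape).copy()
    return DoseGrid(values, spec.spacing_mm, axis_labels=spec.axis_labels)


def make_gland_mask(spec: PhantomSpec, laterality: str = "contralateral") -> StructureMask:
    """Voxels whose centers lie inside the gland ellipsoid."""
    coords = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]
    xs = np.meshgrid(*coords, indexing="ij")
    q = sum(
        ((xi - c) / r) ** 2
        for xi, c, r in zip(xs, spec.gland_center_mm, spec.gland_radii_mm)
    )
    values = q <= 1.0
    if not values.any():
        raise GridValidationError("gland ellipsoid contains no voxel center")
    return StructureMask(values, laterality, spec.medial_direction)


@dataclass(frozen=True)
class CourseTrajectory:
    """Linear medial drift sampled at the imaging days of a course."""

    fraction_days: tuple[float, ...]
    shift_mm_per_day: float

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.fraction_days)
        if len(days) < 1 or days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise SimulationError("fraction_days must start at 0 and strictly increase")
        object.__setattr__(self, "fraction_days", days)

    @property
    def total_shift_mm(self) -> float:
        return self.shift_mm_per_day * self.fraction_days[-1]


def _translate_mask(values: np.ndarray, axis: int, shift_vox: int) -> np.ndarray:
    if shift_vox == 0:
        return values.copy()
    out = np.zeros_like(values)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift_vox > 0:
        if values.take(range(values.shape[axis] - shift_vox, values.shape[axis]), axis=axis).any():
            raise SimulationError("mask leaves the grid under the requested shift")
        src[axis] = slice(0, values.shape[axis] - shift_vox)
        dst[axis] = slice(shift_vox, None)
    else:
        if values.take(range(0, -shift_vox), axis=axis).any():
            raise SimulationError("mask leaves the grid under the requested shift")
        src[axis] = slice(-shift_vox, None)
        dst[axis] = slice(0, values.shape[axis] + shift_vox)
    out[tuple(dst)] = values[tuple(src)]
    return out


def simulate_course(
    mask: StructureMask,
    trajectory: CourseTrajectory,
    spacing_mm,
    lateral_axis: int,
) -> list[StructureMask]:
    """Per-fraction masks under linear medial translation.

    The shift at day t is ``shift_mm_per_day * t`` toward medial, applied as
    a nearest-voxel translation; voxel count is conserved at every fraction
    (an error is raised if the mask would leave the grid).
    """
    step = float(np.asarray(spacing_mm, dtype=float)[lateral_axis])
    out = []
    for day in trajectory.fraction_days:
        shift_mm = trajectory.shift_mm_per_day * day * mask.medial_direction
        shift_vox = int(round(shift_mm / step))
        out.append(
            StructureMask(
                _translate_mask(mask.values, lateral_axis, shift_vox),
                mask.laterality,
                mask.medial_direction,
            )
        )
    return out


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

DEFAULT_COEFFICIENTS: Mapping[str, float] = {
    "md": 0.25,
    "gradx": 0.59,
    "dose_increment": 0.91,
}

#: terms accepted in CohortSimConfig.coefficients
SIM_TERMS = ("md", "gradx", "pgm", "md_x_gradx", "dose_increment", "delivered_md")


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for a simulated cohort.

    Marginal locations/scales default to the published cohort summaries;
    ``coefficients`` are per-term log-odds on standardized columns.  With
    ``intercept=None`` the intercept is solved on the drawn cohort so the
    expected prevalence equals ``target_prevalence``.
    """

    n_patients: int = 88
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    intercept: float | None = None
    target_prevalence: float = 0.114
    md_contra_mean_sd: tuple[float, float] = (18.6, 5.9)
    md_ipsi_mean_sd: tuple[float, float] = (25.6, 8.9)
    gradx_median: float = 1.27
    gradx_sigma_log: float = 0.5
    ipsi_contra_tau: float = 0.5
    delta_vc2_mean_sd_pct: tuple[float, float] = (-2.0, 4.2)
    control_day_range: tuple[int, int] = (28, 36)
    course_length_days: float = 40.0
    vc2_first_mean_sd_ml: tuple[float, float] = (200.0, 25.0)
    reports_per_patient_mean: float = 4.5
    report_window_months: tuple[float, float] = (6.0, 24.0)
    grade_flip_prob: float = 0.1
    max_retries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise SimulationError("need n_patients >= 4")
        if not -1 < self.ipsi_contra_tau < 1:
            raise SimulationError("ipsi_contra_tau must lie in (-1, 1)")
        for name in ("md_contra_mean_sd", "md_ipsi_mean_sd", "delta_vc2_mean_sd_pct",
                     "vc2_first_mean_sd_ml"):
            if getattr(self, name)[1] <= 0:
                raise SimulationError(f"{name}: scale must be positive")
        if self.gradx_median <= 0 or self.gradx_sigma_log <= 0:
            raise SimulationError("gradx parameters must be positive")
        if not 0 < self.target_prevalence < 1:
            raise SimulationError("target_prevalence must lie in (0, 1)")
        unknown = set(self.coefficients) - set(SIM_TERMS)
        if unknown:
            raise SimulationError(f"unknown coefficient terms: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "CohortSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


@dataclass(frozen=True)
class SimulatedCohort:
    """Cohort feature table + follow-up reports + C2 volume series."""

    cohort: pd.DataFrame
    reports: pd.DataFrame
    volumes: pd.DataFrame
    config: CohortSimConfig

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("cohort", self.cohort), ("reports", self.reports),
                         ("volumes", self.volumes)):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _gaussian_copula_rho(tau: float) -> float:
    """Pearson ρ of the latent normal giving Kendall τ: ρ = sin(πτ/2)."""
    return math.sin(math.pi * tau / 2.0)


def simulate_cohort(config: CohortSimConfig | None = None) -> SimulatedCohort:
    """Draw one fully reproducible synthetic cohort.

    Ipsi/contra feature pairs share a Gaussian copula calibrated to the
    configured Kendall τ.  PGM is produced through the migration chain
    (ΔVC2 → linear map → temporal extrapolation), not drawn directly, so the
    feature table and volume series are mutually consistent.  The binary
    outcome is Bernoulli with a logit linear in the configured standardized
    terms; the label draw is retried (bounded) until both classes appear.
    """
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    rho = _gaussian_copula_rho(config.ipsi_contra_tau)
    cov = [[1.0, rho], [rho, 1.0]]

    z_md = rng.multivariate_normal([0, 0], cov, size=n)
    md_contra = np.clip(
        config.md_contra_mean_sd[0] + config.md_contra_mean_sd[1] * z_md[:, 0], 0.0, None
    )
    md_ipsi = np.clip(
        config.md_ipsi_mean_sd[0] + config.md_ipsi_mean_sd[1] * z_md[:, 1], 0.0, None
    )

    z_g = rng.multivariate_normal([0, 0], cov, size=n)
    mu_log = math.log(config.gradx_median)
    gradx_contra = np.exp(mu_log + config.gradx_sigma_log * z_g[:, 0])
    gradx_ipsi = np.exp(mu_log + config.gradx_sigma_log * z_g[:, 1])

    dv = rng.normal(*config.delta_vc2_mean_sd_pct, size=n)
    control_day = rng.integers(
        config.control_day_range[0], config.control_day_range[1] + 1, size=n
    )
    vc2_first = np.clip(rng.normal(*config.vc2_first_mean_sd_ml, size=n), 50.0, None)
    vc2_control = vc2_first * (1.0 + dv / 100.0)
    pgm = np.array(
        [
            mig.extrapolate_pgm(mig.pgm_at_control(d), c, config.course_length_days)
            for d, c in zip(dv, control_day)
        ]
    )

    increment = gradx_contra * pgm / 2.0  # first-order delivered-dose increment
    columns = {
        "md": md_contra,
        "gradx": gradx_contra,
        "pgm": pgm,
        "md_x_gradx": _zscore(md_contra) * _zscore(gradx_contra),
        "dose_increment": increment,
        "delivered_md": md_contra + increment,
    }
    eta = np.zeros(n)
    for term, coef in config.coefficients.items():
        eta += coef * _zscore(columns[term])

    if config.intercept is not None:
        beta0 = float(config.intercept)
    elif all(c == 0 for c in config.coefficients.values()):
        beta0 = float(logit(config.target_prevalence))
    else:
        def gap(b0):
            return expit(b0 + eta).mean() - config.target_prevalence
        beta0 = brentq(gap, -30.0, 30.0)

    p = expit(beta0 + eta)
    label = None
    for _ in range(config.max_retries):
        cand = (rng.random(n) < p).astype(int)
        if 0 < cand.sum() < n:
            label = cand
            break
    if label is None:
        raise SimulationError(
            "could not draw a cohort with both outcome classes; "
            "check prevalence and n_patients"
        )

    ids = [f"P{i + 1:04d}" for i in range(n)]
    cohort = pd.DataFrame(
        {
            "patient_id": ids,
            "md_contra_gy": md_contra,
            "md_ipsi_gy": md_ipsi,
            "gradx_contra_gypermm": gradx_contra,
            "gradx_ipsi_gypermm": gradx_ipsi,
            "pgm_mm": pgm,
            "label": label,
        }
    )

    volumes = pd.DataFrame(
        {
            "patient_id": np.repeat(ids, 2),
            "day": np.column_stack([np.zeros(n, dtype=int), control_day]).ravel(),
            "vc2_ml": np.column_stack([vc2_first, vc2_control]).ravel(),
        }
    )

    lo, hi = config.report_window_months
    report_rows = []
    for i, pid in enumerate(ids):
        k = max(1, int(rng.poisson(config.reports_per_patient_mean)))
        months = np.sort(rng.uniform(lo, hi, size=k))
        base = 2 if label[i] == 1 else int(rng.integers(0, 2))
        flips = rng.random(k)
        for m, f in zip(months, flips):
            g = base
            if f < config.grade_flip_prob:
                g += 1
            elif f > 1 - config.grade_flip_prob:
                g -= 1
            report_rows.append((pid, float(m), int(np.clip(g, 0, 4))))
    reports = pd.DataFrame(report_rows, columns=["patient_id", "months_after_rt", "grade"])

    return SimulatedCohort(cohort=cohort, reports=reports, volumes=volumes, config=config)


def to_model_table(cohort: pd.DataFrame, labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Contralateral-gland modelling view of a simulated cohort table.

    Optionally replaces the generating labels by pooled endpoint labels
    (joined on ``patient_id``); patients without a label are dropped.
    """
    table = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "md_gy": cohort["md_contra_gy"],
            "gradx_gy_per_mm": cohort["gradx_contra_gypermm"],
            "pgm_mm": cohort["pgm_mm"],
            "label": cohort["label"],
        }
    )
    if labels is not None:
        table = table.drop(columns="label").merge(
            labels[["patient_id", "label"]], on="patient_id", how="inner"
        )
    return table


def write_phantom(spec: PhantomSpec, outdir) -> dict[str, Path]:
    """Write phantom dose and gland mask volumes as NIfTI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dose = make_phantom_dose(spec)
    mask = make_gland_mask(spec)
    paths = {
        "dose": outdir / "phantom_dose.nii.gz",
        "mask": outdir / "phantom_gland.nii.gz",
    }
    write_nifti(paths["dose"], dose.values, spec.spacing_mm)
    write_nifti(paths["mask"], mask.values.astype(np.uint8), spec.spacing_mm)
    return paths
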