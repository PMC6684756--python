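"""Logistic NTCP models of xerostomia risk, statsmodels-style.

:class:`XerostomiaModel` wraps a per-patient cohort table (mean dose
``md_gy``, lateral dose gradient ``gradx_gy_per_mm``, medial gland
migration ``pgm_mm``, binary ``label``) together with a :class:`ModelSpec`;
``fit()`` returns a :class:`XerostomiaResults` carrying coefficients, their
standard errors, partial dependence and a ``summary()`` table.

The three canonical nested specifications are::

    MODEL_MD            P(tox) = sigma(b0 + b1 MD)
    MODEL_MD_GRADX      ... + GRADX + MD*GRADX
    MODEL_MD_GRADX_PGM  ... + PGM

Features are z-scored before fitting (recomputed from whatever rows the
model is fitted on) and the interaction column is the product of the
standardized MD and GRADX columns.  An unpenalized fit raises
:class:`~xerograd._irls.SeparationError` on separated data; set
``ridge_lambda > 0`` for the small-sample / few-events regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._irls import SeparationError, covariance, fit_logistic

#: model term -> cohort-table column
FEATURE_COLUMNS: Mapping[str, str] = {
    "md": "md_gy",
    "gradx": "gradx_gy_per_mm",
    "pgm": "pgm_mm",
}
VALID_TERMS = ("md", "gradx", "pgm", "md_x_gradx")
LABEL_COLUMN = "label"


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Ordered model terms plus fitting options."""

    terms: tuple[str, ...]
    standardize: bool = True
    ridge_lambda: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        unknown = set(terms) - set(VALID_TERMS)
        if unknown:
            raise CohortValidationError(f"unknown model terms: {sorted(unknown)}")
        if len(set(terms)) != len(terms):
            raise CohortValidationError("duplicate model terms")
        if "md_x_gradx" in terms and not {"md", "gradx"} <= set(terms):
            raise CohortValidationError(
                "interaction md_x_gradx requires both md and gradx main effects"
            )
        if self.ridge_lambda < 0:
            raise CohortValidationError("ridge_lambda must be >= 0")
        object.__setattr__(self, "terms", terms)
        if not self.name:
            object.__setattr__(self, "name", "+".join(terms))

    @property
    def base_features(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if t != "md_x_gradx")


MODEL_MD = ModelSpec(("md",), name="md")
MODEL_MD_GRADX = ModelSpec(("md", "gradx", "md_x_gradx"), name="md_gradx")
MODEL_MD_GRADX_PGM = ModelSpec(("md", "gradx", "md_x_gradx", "pgm"), name="md_gradx_pgm")
CANONICAL_MODELS: Mapping[str, ModelSpec] = {
    m.name: m for m in (MODEL_MD, MODEL_MD_GRADX, MODEL_MD_GRADX_PGM)
}


def validate_cohort(table: pd.DataFrame, spec: ModelSpec) -> None:
    needed = [FEATURE_COLUMNS[f] for f in spec.base_features] + [LABEL_COLUMN]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise CohortValidationError(f"cohort table missing columns: {missing}")
    sub = table[needed]
    if sub.isna().any().any():
        raise CohortValidationError("cohort table has missing values in modeled columns")
    labels = set(int(v) for v in table[LABEL_COLUMN].unique())
    if not labels <= {0, 1}:
        raise CohortValidationError("label must be binary 0/1")
    if labels != {0, 1}:
        raise CohortValidationError("need at least one positive and one negative case")


def standardization_params(
    table: pd.DataFrame, features: Iterable[str]
) -> dict[str, tuple[float, float]]:
    """Per-feature (mean, sd) with population (ddof=0) scaling."""
    out = {}
    for f in features:
        col = table[FEATURE_COLUMNS[f]].to_numpy(dtype=float)
        sd = float(col.std())
        if sd == 0:
            raise CohortValidationError(f"feature {f} is constant; cannot standardize")
        out[f] = (float(col.mean()), sd)
    return out


def build_design(
    table: pd.DataFrame,
    spec: ModelSpec,
    std: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, tuple[float, float]]]:
    """Design matrix with intercept; interaction from standardized columns.

    ``std`` supplies frozen (mean, sd) per feature — pass the training-fold
    parameters when scoring held-out rows.
    """
    if spec.standardize and std is None:
        std = standardization_params(table, spec.base_features)
    cols, names = [np.ones(len(table))], ["const"]
    z = {}
    for f in spec.base_features:
        x = table[FEATURE_COLUMNS[f]].to_numpy(dtype=float)
        if spec.standardize:
            m, s = std[f]  # type: ignore[index]
            x = (x - m) / s
        z[f] = x
        cols.append(x)
        names.append(f)
    if "md_x_gradx" in spec.terms:
        cols.append(z["md"] * z["gradx"])
        names.append("md_x_gradx")
    return np.column_stack(cols), names, dict(std or {})


class XerostomiaModel:
    """Logistic toxicity model bound to a cohort table and a spec."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec = MODEL_MD_GRADX_PGM):
        validate_cohort(table, spec)
        self.table = table.reset_index(drop=True)
        self.spec = spec
        self.endog = self.table[LABEL_COLUMN].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, spec: ModelSpec = MODEL_MD_GRADX_PGM):
        return cls(table, spec)

    def fit(self, ridge_lambda: float | None = None) -> "XerostomiaResults":
        """Maximum-likelihood (ridge-penalized when lambda > 0) fit.

        The unpenalized path is delegated to statsmodels' Logit; the
        penalized path uses the package's Newton solver.  Both raise
        :class:`SeparationError` on separated data at lambda = 0.
        """
        lam = self.spec.ridge_lambda if ridge_lambda is None else float(ridge_lambda)
        X, names, std = build_design(self.table, self.spec)
        if lam == 0.0:
            params, bse, converged = _fit_statsmodels(X, self.endog)
        else:
            beta, converged, _ = fit_logistic(X, self.endog, ridge_lambda=lam)
            params = beta
            bse = np.sqrt(np.diag(covariance(X, beta, lam)))
        return XerostomiaResults(
            model=self,
            params=pd.Series(params, index=names),
            bse=pd.Series(bse, index=names),
            converged=converged,
            standardization=std,
            ridge_lambda=lam,
        )


def _fit_statsmodels(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.filterwarnings("error", message=".*[Ss]eparation.*")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, Warning, np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"unpenalized logistic fit failed ({exc}); set ridge_lambda > 0"
            ) from exc
    if not res.mle_retvals.get("converged", False) or np.max(np.abs(res.params)) > 40:
        raise SeparationError(
            "unpenalized logistic fit did not converge (possible separation); "
            "set ridge_lambda > 0"
        )
    return np.asarray(res.params), np.asarray(res.bse), True


@dataclass(frozen=True)
class PDGrid:
    """Partial-dependence values with data-percentile rug marks."""

    features: tuple[str, ...]
    grid: tuple[np.ndarray, ...]
    pd_values: np.ndarray
    rug_percentiles: Mapping[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        if len(self.features) == 1:
            return pd.DataFrame({self.features[0]: self.grid[0], "pd": self.pd_values})
        g0, g1 = np.meshgrid(self.grid[0], self.grid[1], indexing="ij")
        return pd.DataFrame(
            {
                self.features[0]: g0.ravel(),
                self.features[1]: g1.ravel(),
                "pd": self.pd_values.ravel(),
            }
        )


@dataclass(frozen=True)
class XerostomiaResults:
    """Fitted-model container: estimates, uncertainty, diagnostics, PD."""

    model: XerostomiaModel
    params: pd.Series
    bse: pd.Series
    converged: bool
    standardization: Mapping[str, tuple[float, float]]
    ridge_lambda: float

    def predict(self, table: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted toxicity probabilities, using the training scaling."""
        table = self.model.table if table is None else table
        X, _, _ = build_design(table, self.model.spec, std=self.standardization)
        return expit(X @ self.params.to_numpy())

    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues().to_numpy())), index=self.params.index
        )

    def partial_dependence(
        self,
        features: Sequence[str] | str,
        grid_size: int = 50,
        percentile_range: tuple[float, float] = (1.0, 99.0),
    ) -> PDGrid:
        """Average predicted probability as 1 or 2 features are swept.

        Each grid value v (``grid_size`` points spanning the observed
        percentile range) is imposed on the feature in *every* cohort row —
        interaction columns are recomputed — and predictions are averaged.
        Rug marks are the 1..99 percentiles of the observed values.
        """
        if isinstance(features, str):
            features = (features,)
        features = tuple(features)
        if not 1 <= len(features) <= 2:
            raise CohortValidationError("partial dependence takes 1 or 2 features")
        for f in features:
            if f not in self.model.spec.base_features:
                raise CohortValidationError(f"feature {f!r} not in the model")
        table = self.model.table
        grids = []
        rug = {}
        for f in features:
            obs = table[FEATURE_COLUMNS[f]].to_numpy(dtype=float)
            lo, hi = np.percentile(obs, percentile_range)
            grids.append(np.linspace(lo, hi, grid_size))
            rug[f] = np.percentile(obs, np.arange(1, 100))
        if len(features) == 1:
            values = np.array([self._pd_point({features[0]: v}) for v in grids[0]])
        else:
            values = np.array(
                [
                    [self._pd_point({features[0]: v0, features[1]: v1}) for v1 in grids[1]]
                    for v0 in grids[0]
                ]
            )
        return PDGrid(features, tuple(grids), values, rug)

    def _pd_point(self, assignment: Mapping[str, float]) -> float:
        modified = self.model.table.copy()
        for f, v in assignment.items():
            modified[FEATURE_COLUMNS[f]] = v
        return float(self.predict(modified).mean())

    def summary(self) -> str:
        n = len(self.model.table)
        events = int(self.model.endog.sum())
        lines = [
            "Xerostomia logistic NTCP model",
            "=" * 62,
            f"terms: {' + '.join(self.model.spec.terms)}",
            f"n = {n}   events = {events}   ridge_lambda = {self.ridge_lambda:g}   "
            f"converged = {self.converged}",
            "-" * 62,
            f"{'term':<12}{'coef':>10}{'std err':>10}{'z':>8}{'P>|z|':>9}",
        ]
        z, p = self.zvalues(), self.pvalues()
        for name in self.params.index:
            lines.append(
                f"{name:<12}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{z[name]:>8.2f}{p[name]:>9.3f}"
            )
        lines.append("=" * 62)
        lines.append("features z-scored on the fitted rows; interaction on z-scores")
        return "\n".join(lines)
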