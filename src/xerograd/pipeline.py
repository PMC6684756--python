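"""End-to-end reproducible run: simulate -> migration -> endpoint -> models.

``run_pipeline`` writes a report bundle (CSVs, evaluation JSONs, partial
dependence grids, stratification report) plus a manifest with the config,
the seed and a checksum per output file.  One global seed is fanned out to
per-stage child seeds through ``numpy.random.SeedSequence.spawn``, so one
knob reproduces every number in the bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import endpoint as ep
from . import migration as mig
from .evaluate import evaluate_model, kendall_concordance, stratify_by_median
from .model import CANONICAL_MODELS, ModelSpec, XerostomiaModel
from .simulate import CohortSimConfig, simulate_cohort, to_model_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_patients: int = 88
    models: tuple[str, ...] = ("md", "md_gradx", "md_gradx_pgm")
    ridge_lambda: float = 1.0
    n_bootstrap: int = 200
    alpha: float = 0.05
    end_day: float = 40.0
    pd_features: tuple[str, ...] = ("md", "gradx", "pgm")
    use_pooled_labels: bool = True
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise PipelineError("model list must be non-empty")
        unknown = set(self.models) - set(CANONICAL_MODELS)
        if unknown:
            raise PipelineError(f"unknown models: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("models", "pd_features"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sim_seed, *boot_seeds = ss.spawn(1 + len(config.models))

    try:
        sim_cfg = CohortSimConfig(
            n_patients=config.n_patients,
            course_length_days=config.end_day,
            seed=int(sim_seed.generate_state(1)[0] % (2**31)),
            **config.sim_overrides,
        )
        sim = simulate_cohort(sim_cfg)
        paths = sim.write(outdir)
    except Exception as exc:
        raise PipelineError(f"[simulate] {exc}") from exc

    try:
        migration = mig.migration_table(sim.volumes, end_day=config.end_day)
        paths["migration"] = outdir / "migration.csv"
        migration.to_csv(paths["migration"], index=False)
    except Exception as exc:
        raise PipelineError(f"[migration] {exc}") from exc

    try:
        labels = ep.pool_reports(sim.reports)
        paths["labels"] = outdir / "labels.csv"
        labels.to_csv(paths["labels"], index=False)
    except Exception as exc:
        raise PipelineError(f"[endpoint] {exc}") from exc

    try:
        table = to_model_table(sim.cohort, labels if config.use_pooled_labels else None)
        # the migration stage recomputes PGM from the volume series; use it
        table = table.drop(columns="pgm_mm").merge(
            migration[["patient_id", "pgm_mm"]], on="patient_id", how="inner"
        )
        if table["label"].nunique() < 2:
            raise PipelineError("pooled labels left a single outcome class")
        paths["model_table"] = outdir / "model_table.csv"
        table.to_csv(paths["model_table"], index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[join] {exc}") from exc

    results = {}
    try:
        for name, child in zip(config.models, boot_seeds):
            spec = CANONICAL_MODELS[name]
            res = evaluate_model(
                table,
                spec,
                ridge_lambda=config.ridge_lambda,
                n_bootstrap=config.n_bootstrap,
                alpha=config.alpha,
                seed=child,
            )
            results[name] = res
            p = outdir / f"evaluation_{name}.json"
            p.write_text(json.dumps(res.to_dict(), indent=2, sort_keys=True))
            paths[f"evaluation_{name}"] = p
    except Exception as exc:
        raise PipelineError(f"[evaluate] {exc}") from exc

    try:
        full_name = config.models[-1]
        fit = XerostomiaModel(table, CANONICAL_MODELS[full_name]).fit(
            ridge_lambda=config.ridge_lambda
        )
        for feat in config.pd_features:
            if feat not in CANONICAL_MODELS[full_name].base_features:
                continue
            pd_grid = fit.partial_dependence(feat)
            p = outdir / f"pd_{full_name}_{feat}.csv"
            pd_grid.to_frame().to_csv(p, index=False)
            paths[f"pd_{full_name}_{feat}"] = p
    except Exception as exc:
        raise PipelineError(f"[partial_dependence] {exc}") from exc

    try:
        strat = stratify_by_median(table).to_dict()
        tau_md = kendall_concordance(
            sim.cohort["md_contra_gy"], sim.cohort["md_ipsi_gy"]
        )
        tau_gx = kendall_concordance(
            sim.cohort["gradx_contra_gypermm"], sim.cohort["gradx_ipsi_gypermm"]
        )
        report = {
            "stratification": strat,
            "concordance_screen": {
                "md_tau": tau_md.tau,
                "md_concordance_prob": tau_md.concordance_prob,
                "gradx_tau": tau_gx.tau,
                "gradx_concordance_prob": tau_gx.concordance_prob,
            },
        }
        p = outdir / "stratification.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True))
        paths["stratification"] = p
    except Exception as exc:
        raise PipelineError(f"[stratify] {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "files": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in paths.items()},
        "evaluations": {name: res.to_dict() for name, res in results.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
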