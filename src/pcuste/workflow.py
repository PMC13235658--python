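"""Experiment orchestration: run a resampler x model comparison grid on one
cohort, with per-cell isolation, provenance, and a metric-by-split summary
table (the layout used to compare generalization against memorization)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cohort import CohortTable
from .evaluation import BootstrapConfig, MetricReport, null_model_report, overfit_report
from .modeling import (
    IncrementalTrainerConfig,
    PriorCorrectionParams,
    correct_prior,
    incidence_threshold,
    train_incremental_pcuste,
)
from .preprocess import apply_standardization, fit_standardization, split_cohort
from .resampling import MatchingSpec, ResamplerParams, _input_hash, pcuste_sample
from . import resampling as rs

__all__ = ["ExperimentSpec", "RunManifest", "run_grid", "render_summary"]


@dataclass
class ExperimentSpec:
    """A grid of (resampler, model) cells plus shared evaluation settings.

    ``resamplers`` maps a name to None (no resampling), a MatchingSpec, a
    ResamplerParams, or an IncrementalTrainerConfig (incremental training on
    re-drawn undersampled sets).  ``models`` maps a name to a RiskModel
    factory (ignored for incremental cells, which carry their own learner).
    """

    resamplers: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    train_fraction: float = 0.7
    bootstrap: BootstrapConfig = field(default_factory=lambda: BootstrapConfig(n_reps=200))
    seed: int = 0
    correct_priors: bool = True

    def cells(self) -> list[tuple[str, str]]:
        return [(r, m) for r in self.resamplers for m in self.models]


@dataclass
class RunManifest:
    spec_hash: str
    cohort_hash: str
    seed: int
    cells: list[dict] = field(default_factory=list)


def _spec_hash(spec: ExperimentSpec) -> str:
    payload = json.dumps(
        {
            "resamplers": {k: repr(v) for k, v in spec.resamplers.items()},
            "models": sorted(spec.models),
            "train_fraction": spec.train_fraction,
            "seed": spec.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_cell(resampler, model_factory, train, test, policy, spec):
    """One grid cell: resample, train, prior-correct, evaluate three ways."""
    target_prior = train.prior
    if isinstance(resampler, IncrementalTrainerConfig):
        model, log = train_incremental_pcuste(train, resampler)
        resampled = pcuste_sample(
            train,
            MatchingSpec(
                resampler.matching.matching_covariates,
                resampler.matching.control_ratio,
                resampler.base_seed,
            ),
        )
        extra = {"control_coverage_fraction": log.coverage_fraction}
    else:
        if resampler is None:
            resampled = None
        elif isinstance(resampler, MatchingSpec):
            resampled = pcuste_sample(train, resampler)
        elif isinstance(resampler, ResamplerParams):
            fn = {
                "SMOTE": rs.smote_oversample,
                "ADASYN": rs.adasyn_oversample,
                "SMOTE_ENN": rs.smote_enn,
            }[resampler.method]
            resampled = fn(train, resampler)
        else:
            raise TypeError(f"unsupported resampler {resampler!r}")
        model = model_factory()
        model.fit(resampled.data if resampled is not None else train)
        extra = {}

    correction = None
    if spec.correct_priors and resampled is not None:
        src = resampled.resampled_prior if hasattr(resampled, "resampled_prior") else resampled.prior
        if 0 < src < 1 and src != target_prior:
            params = PriorCorrectionParams(source_prior=src, target_prior=target_prior)
            correction = lambda p: correct_prior(p, params)  # noqa: E731

    splits = {
        "test": test,
        "train_original": train,
        "train_resampled": resampled.data if resampled is not None else None,
    }
    reports = overfit_report(model, splits, policy, spec.bootstrap, correction=correction)
    return reports, extra


def run_grid(spec: ExperimentSpec, cohort: CohortTable) -> dict:
    """Preprocess, split, and run every (resampler, model) cell.

    Cell failures are recorded in the manifest and do not stop the grid.
    The test split is touched only at evaluation time.
    """
    split = split_cohort(cohort, spec.train_fraction, seed=spec.seed, stratified=True)
    std = fit_standardization(split.train)
    train = apply_standardization(split.train, std)
    test = apply_standardization(split.test, std)
    policy = incidence_threshold(train)

    manifest = RunManifest(_spec_hash(spec), _input_hash(cohort), spec.seed)
    results: dict[tuple[str, str], dict[str, MetricReport | None]] = {}
    for rname, mname in spec.cells():
        resampler = spec.resamplers[rname]
        cell = {"resampler": rname, "model": mname, "status": "ok"}
        try:
            reports, extra = _run_cell(resampler, spec.models.get(mname), train, test, policy, spec)
            results[(rname, mname)] = reports
            cell.update(extra)
        except Exception as exc:  # noqa: BLE001 — cell isolation is the contract
            cell["status"] = f"failed: {exc}"
        manifest.cells.append(cell)

    null = null_model_report(test.y)
    return {
        "results": results,
        "null": null,
        "threshold": policy,
        "manifest": manifest,
        "train": train,
        "test": test,
    }


def render_summary(
    results: dict, null: MetricReport | None = None, metrics: Sequence[str] = ("sensitivity", "specificity", "auc", "mcc")
) -> pd.DataFrame:
    """Render grid results as a metric x split table with CIs."""
    rows = []

    def fmt(report: MetricReport, split_label: str, config: str) -> dict:
        row = {"configuration": config, "split": split_label}
        for m in metrics:
            lo, hi = report.ci(m)
            row[m] = f"{report.point(m):.2f} ({lo:.2f}-{hi:.2f})"
        return row

    if null is not None:
        row = {"configuration": "null (incidence-only)", "split": "test"}
        for m in metrics:
            row[m] = f"{null.point(m):.2f}"
        rows.append(row)
    for (rname, mname), reports in results.items():
        for split_label, report in reports.items():
            if report is not None:
                rows.append(fmt(report, split_label, f"{mname} + {rname}"))
    return pd.DataFrame(rows)
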