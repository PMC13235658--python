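"""Cohort preprocessing: exclusion filters, energy adjustment, derived
variables, control-referenced standardization, splitting, and events-per-
variable accounting.

The preprocessing conventions follow epidemiological practice for
diet-and-disease cohorts: implausible total energy intakes are excluded,
nutrient intakes are energy-adjusted by the Willett residual method, LDL is
derived with the Friedewald equation, and continuous predictors are z-scored
against the *training controls only* so that case values are expressed as
deviations from the healthy population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "ExclusionRules",
    "StandardizationParams",
    "SplitResult",
    "ComplexitySummary",
    "apply_exclusion_filters",
    "energy_adjust_residuals",
    "friedewald_ldl",
    "fit_standardization",
    "apply_standardization",
    "split_cohort",
    "compute_epv",
]


@dataclass(frozen=True)
class ExclusionRules:
    """Row-exclusion bounds applied before analysis.

    Defaults: drop implausible energy intake (<500 or >4000 kcal/d), cap
    triglyceride / AST / GGT at 1000 (values *exceeding* 1000 are dropped),
    and require fasting glucose in (55, 200) mg/dL.  All comparisons are
    strict, so boundary values survive.  ``drop_missing`` enforces
    complete-case analysis.
    """

    energy_min: float = 500.0
    energy_max: float = 4000.0
    biomarker_cap: float = 1000.0
    glucose_min: float = 55.0
    glucose_max: float = 200.0
    drop_missing: bool = True
    energy_column: str = "energy"
    cap_columns: tuple[str, ...] = ("triglyceride", "ast", "ggt")
    glucose_column: str = "glucose"

    def __post_init__(self) -> None:
        if not (0 < self.energy_min < self.energy_max):
            raise ValueError("require 0 < energy_min < energy_max")
        if not (0 < self.glucose_min < self.glucose_max):
            raise ValueError("require 0 < glucose_min < glucose_max")
        if self.biomarker_cap <= 0:
            raise ValueError("biomarker_cap must be positive")


def apply_exclusion_filters(
    table: CohortTable, rules: ExclusionRules | None = None
) -> tuple[CohortTable, list[dict]]:
    """Apply exclusion rules in order; return survivors and a removal log.

    The log is a list of ``{"rule": name, "removed": count}`` entries in
    application order (missingness, energy bounds, per-biomarker caps,
    glucose bounds).  Idempotent: re-applying the same rules removes nothing.
    """
    rules = rules or ExclusionRules()
    df = table.data
    log: list[dict] = []

    def _require(col: str) -> None:
        if col not in df.columns:
            raise KeyError(f"exclusion rule requires missing column {col!r}")

    if rules.drop_missing:
        analysis_cols = [c for c in table.schema.all_columns() if c in df.columns]
        keep = ~df[analysis_cols].isna().any(axis=1)
        log.append({"rule": "missing", "removed": int((~keep).sum())})
        df = df.loc[keep]

    _require(rules.energy_column)
    e = df[rules.energy_column]
    keep = (e >= rules.energy_min) & (e <= rules.energy_max)
    log.append({"rule": "energy", "removed": int((~keep).sum())})
    df = df.loc[keep]

    for col in rules.cap_columns:
        _require(col)
        keep = df[col] <= rules.biomarker_cap
        log.append({"rule": f"{col}_cap", "removed": int((~keep).sum())})
        df = df.loc[keep]

    _require(rules.glucose_column)
    g = df[rules.glucose_column]
    keep = (g >= rules.glucose_min) & (g <= rules.glucose_max)
    log.append({"rule": "glucose", "removed": int((~keep).sum())})
    df = df.loc[keep]

    return table.with_data(df), log


def energy_adjust_residuals(
    table: CohortTable,
    nutrient_columns: list[str] | tuple[str, ...],
    energy_column: str = "energy",
) -> CohortTable:
    """Willett residual-method energy adjustment.

    Each nutrient is replaced by its residual from a simple linear regression
    on total energy intake, plus the fitted value at the sample-mean energy,
    so adjusted intakes keep the nutrient's original scale and mean.  The
    energy column itself is unchanged.
    """
    df = table.data.copy()
    e = df[energy_column].to_numpy(dtype=float)
    if len(e) < 3:
        raise ValueError("need at least 3 rows to fit the energy regression")
    e_centered = e - e.mean()
    sxx = float(e_centered @ e_centered)
    if sxx == 0.0:
        raise ValueError("zero variance in energy; residual regression undefined")
    for col in nutrient_columns:
        if col == energy_column:
            continue
        y = df[col].to_numpy(dtype=float)
        slope = float(e_centered @ (y - y.mean())) / sxx
        # residual + prediction at mean energy == y - slope * (e - mean(e))
        df[col] = y - slope * e_centered
    return table.with_data(df)


def friedewald_ldl(total_cholesterol, hdl, triglyceride, tg_validity_bound: float = 400.0):
    """Friedewald LDL estimate: TC − HDL − TG/5 (all mg/dL).

    Returns ``(ldl, valid)``; ``valid`` is False where triglyceride exceeds
    the equation's 400 mg/dL validity bound (advisory only — the value is
    still returned).
    """
    tc = np.asarray(total_cholesterol, dtype=float)
    hd = np.asarray(hdl, dtype=float)
    tg = np.asarray(triglyceride, dtype=float)
    if (tc < 0).any() or (hd < 0).any() or (tg < 0).any():
        raise ValueError("lipid concentrations must be non-negative")
    ldl = tc - hd - tg / 5.0
    valid = tg <= tg_validity_bound
    if ldl.ndim == 0:
        return float(ldl), bool(valid)
    return ldl, valid


@dataclass(frozen=True)
class StandardizationParams:
    """Per-predictor location/scale fitted on training controls only."""

    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        bad = [c for c, s in self.sds.items() if not s > 0]
        if bad:
            raise ValueError(f"non-positive control SD for predictors: {bad}")


def fit_standardization(train: CohortTable) -> StandardizationParams:
    """Fit control-referenced z-score parameters on the training controls.

    Cases do not enter the fit; after transformation the training controls
    have mean 0 / SD 1 per predictor while cases are expressed in control-SD
    units of deviation.
    """
    ctrl = train.controls().data
    if len(ctrl) < 2:
        raise ValueError("need at least 2 training controls")
    means, sds = {}, {}
    for col in train.schema.predictors:
        x = ctrl[col].to_numpy(dtype=float)
        sd = float(x.std(ddof=1))
        if not sd > 0:
            raise ValueError(f"predictor {col!r} has zero SD among training controls")
        means[col] = float(x.mean())
        sds[col] = sd
    return StandardizationParams(means, sds)


def apply_standardization(table: CohortTable, params: StandardizationParams) -> CohortTable:
    """Apply fitted control-referenced z-scoring to every row of ``table``."""
    df = table.data.copy()
    for col in table.schema.predictors:
        df[col] = (df[col].astype(float) - params.means[col]) / params.sds[col]
    return table.with_data(df)


@dataclass
class SplitResult:
    train: CohortTable
    test: CohortTable
    train_fraction: float
    seed: int
    stratified: bool


def _largest_remainder_counts(class_sizes: list[int], fraction: float, total_target: int) -> list[int]:
    floors = [math.floor(fraction * m) for m in class_sizes]
    remainder = total_target - sum(floors)
    fracs = [fraction * m - f for m, f in zip(class_sizes, floors)]
    order = np.argsort(fracs)[::-1]
    for j in range(remainder):
        floors[order[j % len(floors)]] += 1
    return floors


def split_cohort(
    table: CohortTable,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> SplitResult:
    """Reproducible train/test partition, stratified by outcome by default.

    Stratified allocation uses per-class floors with largest-remainder
    top-up so that |train| = floor(train_fraction * n) exactly (70% of a
    7,652-row cohort with 156 cases gives a 5,356-row training split with
    109 cases).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = table.n
    target = math.floor(train_fraction * n)
    if stratified:
        y = table.y
        classes = [0, 1]
        if any((y == c).sum() == 0 for c in classes):
            raise ValueError("both outcome classes required for a stratified split")
        sizes = [int((y == c).sum()) for c in classes]
        takes = _largest_remainder_counts(sizes, train_fraction, target)
        train_idx: list[np.ndarray] = []
        for c, take in zip(classes, takes):
            idx = np.flatnonzero(y == c)
            perm = rng.permutation(len(idx))
            train_idx.append(idx[perm[:take]])
        tr = np.sort(np.concatenate(train_idx))
    else:
        perm = rng.permutation(n)
        tr = np.sort(perm[:target])
    mask = np.zeros(n, dtype=bool)
    mask[tr] = True
    return SplitResult(
        train=table.subset(mask),
        test=table.subset(~mask),
        train_fraction=train_fraction,
        seed=seed,
        stratified=stratified,
    )


@dataclass(frozen=True)
class ComplexitySummary:
    """Events-per-variable summary for sample-size adequacy accounting."""

    n_events: int
    n_predictors: int
    epv: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_predictors < 1:
            raise ValueError("n_predictors must be >= 1")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        object.__setattr__(self, "epv", self.n_events / self.n_predictors)

    @property
    def epv_1dp(self) -> float:
        return round(self.epv, 1)


def compute_epv(n_events: int, n_predictors: int) -> ComplexitySummary:
    """Events per variable: outcome events divided by candidate predictors."""
    return ComplexitySummary(n_events=n_events, n_predictors=n_predictors)
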