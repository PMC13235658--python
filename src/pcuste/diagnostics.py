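"""Resampling diagnostics: how a resampled set differs from the original.

Three views, all in the standardized continuous-predictor space:

* a 2-D PCA projection *fitted on the original training data only* and
  applied unchanged to every resampled set, so projections are comparable;
* mean pairwise Euclidean distances — between classes, within each class,
  and between a resampled set and the original — as scalar summaries of
  separation and of how far resampling moved the data;
* per-predictor point-biserial correlations with the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import PCA

from .cohort import CohortTable
from .resampling import (
    MatchingSpec,
    ResamplerParams,
    adasyn_oversample,
    fraction_to_k,
    pcuste_sample,
    smote_enn,
    smote_oversample,
)

__all__ = [
    "ProjectionModel",
    "fit_projection",
    "project",
    "DistanceSummary",
    "mean_cross_distance",
    "mean_within_distance",
    "distance_summary",
    "predictor_outcome_correlation",
    "k_sensitivity_curves",
]


@dataclass
class ProjectionModel:
    """A 2-component PCA anchored to the original training data."""

    pca: PCA

    @property
    def components(self) -> np.ndarray:
        return self.pca.components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_


def fit_projection(original_train: CohortTable, n_components: int = 2) -> ProjectionModel:
    X = original_train.X
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows to fit a projection")
    if X.shape[1] < n_components:
        raise ValueError("fewer predictors than components")
    # inputs are control-standardized upstream; center only, no re-scaling
    return ProjectionModel(PCA(n_components=n_components).fit(X))


def project(table: CohortTable, model: ProjectionModel) -> np.ndarray:
    return model.pca.transform(table.X)


def mean_cross_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Mean Euclidean distance over all cross pairs (exact, no sampling)."""
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    if A.size == 0 or B.size == 0:
        raise ValueError("empty set in distance summary")
    return float(cdist(A, B).mean())


def mean_within_distance(A: np.ndarray) -> float:
    """Mean distance over distinct unordered within-set pairs."""
    A = np.atleast_2d(A)
    if len(A) < 2:
        raise ValueError("need at least 2 points for a within-set distance")
    return float(pdist(A).mean())


@dataclass
class DistanceSummary:
    case_vs_control: float
    case_vs_case: float
    control_vs_control: float
    resampled_vs_original: float | None = None

    def as_dict(self) -> dict:
        return {
            "case_vs_control": self.case_vs_control,
            "case_vs_case": self.case_vs_case,
            "control_vs_control": self.control_vs_control,
            "resampled_vs_original": self.resampled_vs_original,
        }


def distance_summary(
    table: CohortTable,
    original: CohortTable | None = None,
    cross_mode: str = "all_pairs",
) -> DistanceSummary:
    """Distance summaries for one (possibly resampled) cohort.

    ``resampled_vs_original`` is the mean over all cross-set pairs by
    default; ``cross_mode="nearest"`` instead averages each resampled row's
    distance to its nearest original row.
    """
    Xc, Xk = table.cases().X, table.controls().X
    rvo = None
    if original is not None:
        if cross_mode == "all_pairs":
            rvo = mean_cross_distance(table.X, original.X)
        elif cross_mode == "nearest":
            rvo = float(cdist(table.X, original.X).min(axis=1).mean())
        else:
            raise ValueError(f"unknown cross_mode {cross_mode!r}")
    return DistanceSummary(
        case_vs_control=mean_cross_distance(Xc, Xk),
        case_vs_case=mean_within_distance(Xc),
        control_vs_control=mean_within_distance(Xk),
        resampled_vs_original=rvo,
    )


def predictor_outcome_correlation(table: CohortTable) -> pd.Series:
    """Point-biserial (Pearson) correlation of each predictor with the outcome.

    Zero-variance predictors yield NaN (flagged undefined) rather than an
    error.
    """
    y = table.y.astype(float)
    if y.std() == 0:
        raise ValueError("both classes required for outcome correlations")
    yc = y - y.mean()
    out = {}
    for col in table.schema.predictors:
        x = table.data[col].to_numpy(dtype=float)
        sx = x.std()
        out[col] = float((yc * (x - x.mean())).mean() / (sx * y.std())) if sx > 0 else float("nan")
    return pd.Series(out, name="correlation")


_METHOD_FNS = {
    "SMOTE": smote_oversample,
    "ADASYN": adasyn_oversample,
    "SMOTE_ENN": smote_enn,
}


def k_sensitivity_curves(
    train: CohortTable,
    methods: tuple[str, ...] = ("SMOTE", "ADASYN", "SMOTE_ENN"),
    fractions: tuple[float, ...] = (0.02, 0.05, 0.10, 0.30, 0.50, 0.80),
    matching: MatchingSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance summaries per (oversampler, k-fraction).

    Undersampling is k-independent, so the PCUSTe row repeats its single
    summary at every fraction as a horizontal reference line.
    """
    rows = []
    n_min = train.n_cases
    for frac in fractions:
        k = fraction_to_k(frac, n_min)
        for method in methods:
            rs = _METHOD_FNS[method](train, ResamplerParams(method, k_fraction=frac, seed=seed))
            d = distance_summary(rs.data, original=train)
            rows.append({"method": method, "k_fraction": frac, "k": k, **d.as_dict()})
    if matching is not None:
        ref = pcuste_sample(train, matching)
        d = distance_summary(ref.data, original=train)
        for frac in fractions:
            rows.append(
                {
                    "method": "PCUSTE",
                    "k_fraction": frac,
                    "k": fraction_to_k(frac, n_min),
                    **d.as_dict(),
                }
            )
    return pd.DataFrame(rows)
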