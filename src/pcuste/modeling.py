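"""Risk-model contracts, incremental training on re-drawn control subsets,
prior-shift probability correction, incidence-based thresholds, and
leakage-safe cross-validation.

The incremental loop is the counterpart of patient-centered undersampling:
a single undersampled draw discards most controls, so the model is instead
updated over many draws — cases fixed, controls re-drawn per iteration with
``seed = base_seed + i`` — until nearly the whole control pool has been seen.

Because resampling changes the class prior, raw predicted probabilities are
mis-calibrated for the source population; :func:`correct_prior` applies the
standard odds reweighting that maps probabilities from the resampled prior
back to the target prior.  Decisions then use a threshold equal to the
training cohort's cumulative incidence: anyone whose corrected risk exceeds
the base rate is flagged high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable
from .resampling import MatchingSpec, ResampledSet, pcuste_sample

__all__ = [
    "RiskModel",
    "SklearnRiskModel",
    "IncrementalSGDModel",
    "IncrementalTrainerConfig",
    "TrainingLog",
    "train_incremental_pcuste",
    "PriorCorrectionParams",
    "correct_prior",
    "ThresholdPolicy",
    "incidence_threshold",
    "classify",
    "cross_validated_fit",
]


@runtime_checkable
class RiskModel(Protocol):
    """A pluggable binary scorer."""

    def fit(self, table: CohortTable) -> "RiskModel": ...

    def predict_proba(self, table: CohortTable) -> np.ndarray: ...


class SklearnRiskModel:
    """Adapter wrapping any scikit-learn binary classifier as a RiskModel.

    Fits on the cohort's continuous predictor matrix; ``predict_proba``
    returns the positive-class probability per row.
    """

    def __init__(self, estimator=None):
        self.estimator = estimator if estimator is not None else LogisticRegression(max_iter=1000)

    def clone(self) -> "SklearnRiskModel":
        return SklearnRiskModel(clone(self.estimator))

    def fit(self, table: CohortTable) -> "SklearnRiskModel":
        self.estimator.fit(table.X, table.y)
        return self

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        return self.estimator.predict_proba(table.X)[:, 1]


class IncrementalSGDModel:
    """Logistic model trained by stochastic gradient descent, one pass per
    update call.

    Configuration mirrors the constraints an incremental setting imposes:
    L2 penalty with strength ``alpha``, constant learning rate ``eta0``, a
    single epoch per partial update, and no stopping tolerance.  The final
    iterate (not an average) is the model state.
    """

    def __init__(self, eta0: float = 0.01, alpha: float = 1e-4, seed: int = 0):
        self.eta0 = eta0
        self.alpha = alpha
        self.seed = seed
        self.estimator = SGDClassifier(
            loss="log_loss",
            penalty="l2",
            alpha=alpha,
            learning_rate="constant",
            eta0=eta0,
            max_iter=1,
            tol=None,
            random_state=seed,
        )

    def clone(self) -> "IncrementalSGDModel":
        return IncrementalSGDModel(self.eta0, self.alpha, self.seed)

    def fit(self, table: CohortTable) -> "IncrementalSGDModel":
        self.estimator.fit(table.X, table.y)
        return self

    def partial_update(self, table: CohortTable) -> "IncrementalSGDModel":
        self.estimator.partial_fit(table.X, table.y, classes=np.array([0, 1]))
        return self

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        return self.estimator.predict_proba(table.X)[:, 1]

    @property
    def coef_(self) -> np.ndarray:
        return self.estimator.coef_.ravel()


@dataclass(frozen=True)
class IncrementalTrainerConfig:
    """Incremental PCUSTe training configuration.

    ``n_iterations`` re-draws of the control subset (default 1000), each
    with seed ``base_seed + iteration``; one SGD pass per draw.
    """

    n_iterations: int = 1000
    base_seed: int = 0
    matching: MatchingSpec = field(default_factory=MatchingSpec)
    eta0: float = 0.01
    alpha: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class TrainingLog:
    """Per-iteration control-id coverage of the incremental loop."""

    control_ids_per_iteration: list[set]
    n_control_pool: int

    @property
    def distinct_controls_seen(self) -> int:
        seen: set = set()
        for ids in self.control_ids_per_iteration:
            seen |= ids
        return len(seen)

    @property
    def coverage_fraction(self) -> float:
        """Fraction of the control pool ever used across iterations."""
        return self.distinct_controls_seen / self.n_control_pool


def train_incremental_pcuste(
    train: CohortTable, config: IncrementalTrainerConfig, model: IncrementalSGDModel | None = None
) -> tuple[IncrementalSGDModel, TrainingLog]:
    """Train an SGD logistic model over repeatedly re-drawn PCUSTe sets.

    Cases are identical across iterations; the control subset varies, so
    over many iterations the model is exposed to most of the control pool
    (the log reports the exact distinct-control coverage).  Reproducible:
    the i-th draw uses seed ``base_seed + i``.
    """
    if model is None:
        model = IncrementalSGDModel(eta0=config.eta0, alpha=config.alpha, seed=config.base_seed)
    if not hasattr(model, "partial_update"):
        raise TypeError("incremental training requires a model with partial_update")
    id_col = train.schema.participant_id
    control_ids: list[set] = []
    for i in range(config.n_iterations):
        spec = MatchingSpec(
            matching_covariates=config.matching.matching_covariates,
            control_ratio=config.matching.control_ratio,
            seed=config.base_seed + i,
        )
        drawn: ResampledSet = pcuste_sample(train, spec)
        model.partial_update(drawn.data)
        d = drawn.data.data
        control_ids.append(set(d.loc[d[train.schema.outcome] == 0, id_col]))
    return model, TrainingLog(control_ids, n_control_pool=train.n_controls)


# ---------------------------------------------------------------------------
# prior correction and thresholds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorCorrectionParams:
    """Source (resampled) and target (population) class priors."""

    source_prior: float
    target_prior: float

    def __post_init__(self) -> None:
        for p in (self.source_prior, self.target_prior):
            if not 0 < p < 1:
                raise ValueError("priors must lie strictly inside (0, 1)")

    def inverse(self) -> "PriorCorrectionParams":
        return PriorCorrectionParams(self.target_prior, self.source_prior)


def correct_prior(p, params: PriorCorrectionParams):
    """Map probabilities from the resampled prior back to the target prior.

    ``p' = p r1 / (p r1 + (1-p) r0)`` with ``r1 = pi_t/pi_s`` and
    ``r0 = (1-pi_t)/(1-pi_s)``.  Strictly increasing in p (rank- and hence
    AUC-preserving) with fixed points at 0 and 1; the identity when the two
    priors coincide.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    r1 = params.target_prior / params.source_prior
    r0 = (1 - params.target_prior) / (1 - params.source_prior)
    num = p * r1
    out = num / (num + (1 - p) * r0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ThresholdPolicy:
    """A probability cutoff and where it came from."""

    threshold: float
    origin: str = "fixed"  # training_incidence | fixed | sweep
    sweep_grid: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.sweep_grid and not all(
            a < b for a, b in zip(self.sweep_grid, self.sweep_grid[1:])
        ):
            raise ValueError("sweep_grid must be strictly increasing")

    @property
    def threshold_2dp(self) -> float:
        return round(self.threshold, 2)


def incidence_threshold(train: CohortTable) -> ThresholdPolicy:
    """Decision threshold equal to the training cumulative incidence.

    The exact event proportion is retained (109 cases among 5,356
    participants gives 0.02035..., rendered 0.02 at 2 dp).
    """
    if train.n_cases == 0 or train.n_controls == 0:
        raise ValueError("incidence threshold undefined without both classes")
    return ThresholdPolicy(train.n_cases / train.n, origin="training_incidence")


def classify(scores, policy: ThresholdPolicy) -> np.ndarray:
    """Predict positive iff score >= threshold.

    The >= convention makes the incidence-only null model — everyone scored
    at the base rate — classify every row positive.
    """
    scores = np.asarray(scores, dtype=float)
    return (scores >= policy.threshold).astype(int)


# ---------------------------------------------------------------------------
# leakage-safe cross-validation
# ---------------------------------------------------------------------------


def _resample(train: CohortTable, resampler, fold_seed: int) -> CohortTable:
    from . import resampling as rs

    if resampler is None:
        return train
    if isinstance(resampler, MatchingSpec):
        spec = MatchingSpec(resampler.matching_covariates, resampler.control_ratio, fold_seed)
        return pcuste_sample(train, spec).data
    if isinstance(resampler, rs.ResamplerParams):
        params = rs.ResamplerParams(resampler.method, resampler.k_fraction, resampler.enn_k, fold_seed)
        fn = {
            "SMOTE": rs.smote_oversample,
            "ADASYN": rs.adasyn_oversample,
            "SMOTE_ENN": rs.smote_enn,
        }[params.method]
        return fn(train, params).data
    raise TypeError(f"unsupported resampler {resampler!r}")


def cross_validated_fit(
    train: CohortTable,
    k_folds: int,
    resampler,
    model: RiskModel,
    tuner: Callable | None = None,
    seed: int = 0,
    leak_resample_before_split: bool = False,
) -> dict:
    """Stratified k-fold CV with resampling confined to the training folds.

    Per fold: resample only the k-1 training folds, apply the optional
    ``tuner(model, fold_train) -> model`` hook, fit, and score the untouched
    validation fold by rank AUC.  ``leak_resample_before_split=True``
    deliberately resamples the whole set before folding — the classic
    leakage bug, kept for demonstrating how it inflates null performance.
    """
    from .evaluation import auc_rank

    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    working = train
    if leak_resample_before_split:
        working = _resample(train, resampler, seed)
    y = working.y
    if y.sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("stratified folding requires both classes")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for f, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        mask = np.zeros(len(y), dtype=bool)
        mask[tr_idx] = True
        fold_train, fold_val = working.subset(mask), working.subset(~mask)
        if not leak_resample_before_split:
            fold_train = _resample(fold_train, resampler, seed * 1000 + f)
        m = model.clone() if hasattr(model, "clone") else model
        if tuner is not None:
            m = tuner(m, fold_train)
        m.fit(fold_train)
        fold_aucs.append(auc_rank(fold_val.y, m.predict_proba(fold_val)))
    return {"fold_aucs": fold_aucs, "mean_auc": float(np.mean(fold_aucs)), "k_folds": k_folds}
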