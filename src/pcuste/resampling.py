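"""Class-imbalance resampling.

Two families:

* **PCUSTe** (patient-centered undersampling): controls are drawn per
  covariate stratum in proportion to the empirical distribution of cases
  across those strata, emulating a frequency-matched case-control design.
  All cases are retained; the control subset mirrors the cases' joint
  matching-covariate composition.  Two named presets match on
  sociodemographics (PCUSTe-1) or lifestyle (PCUSTe-2).

* **Synthetic oversampling** (SMOTE, ADASYN, SMOTE+ENN): minority rows are
  synthesized by interpolating between a case and one of its k nearest
  case neighbors in standardized continuous-predictor space.  The neighbor
  count k is parameterized as a *fraction of the minority count*, so the
  same setting transfers across cohort sizes.  ADASYN weights generation
  toward cases whose neighborhoods are majority-dominated; SMOTE+ENN cleans
  the oversampled set with an edited-nearest-neighbors pass that can leave
  cases as the majority class.

Binary covariates never enter the interpolation; synthetic rows copy the
seed case's covariate values.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .cohort import CohortTable

__all__ = [
    "MatchingSpec",
    "ResamplerParams",
    "ResampledSet",
    "PCUSTE_1",
    "PCUSTE_2",
    "pcuste_sample",
    "fraction_to_k",
    "smote_oversample",
    "adasyn_oversample",
    "smote_enn",
]

logger = logging.getLogger(__name__)

#: Sociodemographic matching preset.
PCUSTE_1 = ("higher_education", "unemployed", "lower_income", "married")
#: Lifestyle matching preset.
PCUSTE_2 = ("smoker", "drinker")


@dataclass(frozen=True)
class MatchingSpec:
    """Parameterization of patient-centered undersampling."""

    matching_covariates: tuple[str, ...] = PCUSTE_1
    control_ratio: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.matching_covariates:
            raise ValueError("matching_covariates must be non-empty")
        if not (isinstance(self.control_ratio, (int, np.integer)) and self.control_ratio >= 1):
            raise ValueError("control_ratio must be an integer >= 1")


@dataclass(frozen=True)
class ResamplerParams:
    """Oversampler parameterization; k is resolved from a minority fraction."""

    method: str = "SMOTE"
    k_fraction: float = 0.05
    enn_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.k_fraction <= 1:
            raise ValueError("k_fraction must be in (0, 1]")
        if self.enn_k < 1:
            raise ValueError("enn_k must be >= 1")


@dataclass
class ResampledSet:
    """A resampled cohort plus the provenance needed to regenerate it."""

    data: CohortTable
    provenance: dict = field(default_factory=dict)

    @property
    def resampled_prior(self) -> float:
        return self.data.prior

    @property
    def source_prior(self) -> float:
        return self.provenance["source_prior"]


def _input_hash(table: CohortTable) -> str:
    h = hashlib.sha256(
        pd.util.hash_pandas_object(table.data, index=False).to_numpy().tobytes()
    )
    return h.hexdigest()[:16]


def _provenance(method: str, table: CohortTable, out: CohortTable, seed: int, **params) -> dict:
    return {
        "method": method,
        "params": params,
        "seed": seed,
        "input_hash": _input_hash(table),
        "source_prior": table.prior,
        "counts_before": {"cases": table.n_cases, "controls": table.n_controls},
        "counts_after": {"cases": out.n_cases, "controls": out.n_controls},
    }


# ---------------------------------------------------------------------------
# PCUSTe
# ---------------------------------------------------------------------------

def pcuste_sample(train: CohortTable, spec: MatchingSpec) -> ResampledSet:
    """Frequency-matched undersampling of controls.

    Strata are the joint levels of the matching covariates.  For each
    stratum holding ``c`` cases, ``ratio * c`` controls are drawn uniformly
    without replacement from that stratum.  When a stratum holds fewer
    controls than required, all of them are taken and the deficit is
    backfilled by a uniform draw from the remaining unsampled controls
    cohort-wide (a warning reports per-stratum deficits).  All cases are
    retained unchanged, and the combined set is shuffled to prevent
    ordering bias.
    """
    df = train.data
    y = train.y
    if y.sum() == 0:
        raise ValueError("PCUSTe requires at least one case")
    for c in spec.matching_covariates:
        if c not in df.columns:
            raise KeyError(f"matching covariate {c!r} not in table")
        if not df[c].isin([0, 1]).all():
            raise ValueError(f"matching covariate {c!r} must be binary 0/1")

    rng = np.random.default_rng(spec.seed)
    cov = df[list(spec.matching_covariates)].to_numpy(dtype=int)
    strata = [tuple(row) for row in cov]
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)

    # per-stratum control index pools, in stable (sorted-key) order
    ctrl_pools: dict[tuple, np.ndarray] = {}
    for i in ctrl_idx:
        ctrl_pools.setdefault(strata[i], [])
    for i in ctrl_idx:
        ctrl_pools[strata[i]].append(i)
    ctrl_pools = {k: np.asarray(v) for k, v in sorted(ctrl_pools.items())}

    case_counts: dict[tuple, int] = {}
    for i in case_idx:
        case_counts[strata[i]] = case_counts.get(strata[i], 0) + 1

    sampled: list[np.ndarray] = []
    deficits: dict[tuple, int] = {}
    for key in sorted(case_counts):
        need = spec.control_ratio * case_counts[key]
        pool = ctrl_pools.get(key, np.asarray([], dtype=int))
        take = min(need, len(pool))
        if take:
            sampled.append(rng.choice(pool, size=take, replace=False))
        if take < need:
            deficits[key] = need - take
    if deficits:
        taken = set(np.concatenate(sampled).tolist()) if sampled else set()
        remaining = np.asarray([i for i in ctrl_idx if i not in taken])
        backfill = sum(deficits.values())
        backfill = min(backfill, len(remaining))
        if backfill:
            sampled.append(rng.choice(remaining, size=backfill, replace=False))
        warnings.warn(
            f"PCUSTe stratum deficits {deficits}; backfilled {backfill} controls "
            "by uniform cohort-wide draw",
            stacklevel=2,
        )

    chosen_ctrl = np.concatenate(sampled) if sampled else np.asarray([], dtype=int)
    keep = np.concatenate([case_idx, chosen_ctrl])
    out_df = df.iloc[keep]
    shuffled = out_df.iloc[rng.permutation(len(out_df))]
    out = train.with_data(shuffled)
    prov = _provenance(
        "PCUSTE",
        train,
        out,
        spec.seed,
        matching_covariates=list(spec.matching_covariates),
        control_ratio=spec.control_ratio,
        deficits={str(k): v for k, v in deficits.items()},
    )
    return ResampledSet(out, prov)


# ---------------------------------------------------------------------------
# fraction-parameterized k
# ---------------------------------------------------------------------------

def fraction_to_k(k_fraction: float, n_minority: int) -> int:
    """Resolve a neighbor count from a fraction of the minority count.

    ``k = max(1, floor(k_fraction * n_minority))``, clamped below the
    minority count.  Floor is the rounding rule: 2%, 5%, 10%, 30%, 50% and
    80% of 109 cases give k = 2, 5, 10, 32, 54 and 87.
    """
    if not 0 < k_fraction <= 1:
        raise ValueError("k_fraction must be in (0, 1]")
    if n_minority < 1:
        raise ValueError("n_minority must be >= 1")
    k = max(1, math.floor(k_fraction * n_minority + 1e-9))
    if n_minority > 1:
        k = min(k, n_minority - 1)
    return k


# ---------------------------------------------------------------------------
# oversamplers
# ---------------------------------------------------------------------------

def _minority_neighbors(X_min: np.ndarray, k: int) -> np.ndarray:
    """Indices of each minority point's k nearest minority neighbors (no self)."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    idx = nn.kneighbors(X_min, return_distance=False)
    out = np.empty((len(X_min), k), dtype=int)
    for i, row in enumerate(idx):
        out[i] = row[row != i][:k]
    return out


def _interpolate(
    train: CohortTable,
    seeds: np.ndarray,
    nbr_table: np.ndarray,
    rng: np.random.Generator,
    min_rows: pd.DataFrame,
    X_min: np.ndarray,
) -> pd.DataFrame:
    """Build synthetic minority rows x_i + u (x_nn - x_i), u ~ U(0,1)."""
    preds = list(train.schema.predictors)
    nbr_choice = rng.integers(0, nbr_table.shape[1], size=len(seeds))
    u = rng.uniform(0.0, 1.0, size=len(seeds))
    base = X_min[seeds]
    other = X_min[nbr_table[seeds, nbr_choice]]
    X_new = base + u[:, None] * (other - base)
    syn = min_rows.iloc[seeds].copy().reset_index(drop=True)
    syn[preds] = X_new
    syn[train.schema.participant_id] = [f"syn_{i}" for i in range(len(seeds))]
    return syn


def _oversample_common(train: CohortTable, params: ResamplerParams):
    y = train.y
    n_min, n_maj = int(y.sum()), int((y == 0).sum())
    if n_min == 0 or n_maj == 0:
        raise ValueError("both classes required for oversampling")
    k = fraction_to_k(params.k_fraction, n_min)
    if k >= n_min:
        raise ValueError(f"k={k} must be below the minority count {n_min}")
    min_rows = train.cases().data
    X_min = train.cases().X
    return y, n_min, n_maj, k, min_rows, X_min


def smote_oversample(train: CohortTable, params: ResamplerParams | None = None) -> ResampledSet:
    """SMOTE: interpolated synthetic cases up to a 1:1 class prior.

    Synthetic points lie on segments between a case and one of its k nearest
    case neighbors (Euclidean, standardized predictor space), so they stay
    inside the minority convex hull.  Seed points cycle through the cases so
    generation is spread evenly; originals are always retained.
    """
    params = params or ResamplerParams(method="SMOTE")
    y, n_min, n_maj, k, min_rows, X_min = _oversample_common(train, params)
    rng = np.random.default_rng(params.seed)
    n_syn = n_maj - n_min
    nbr = _minority_neighbors(X_min, k)
    seeds = np.tile(np.arange(n_min), n_syn // n_min + 1)[:n_syn]
    syn = _interpolate(train, seeds, nbr, rng, min_rows, X_min)
    out_df = pd.concat([train.data, syn], ignore_index=True)
    out = train.with_data(out_df.iloc[rng.permutation(len(out_df))])
    prov = _provenance("SMOTE", train, out, params.seed, k=k, k_fraction=params.k_fraction)
    return ResampledSet(out, prov)


def adasyn_oversample(train: CohortTable, params: ResamplerParams | None = None) -> ResampledSet:
    """ADASYN: SMOTE-like generation weighted toward hard cases.

    Each case's weight is the fraction of majority points among its k
    nearest neighbors in the full training set; synthetic counts are
    apportioned to cases by normalized weight (largest-remainder rounding).
    If every weight is zero (all-case neighborhoods) the weights fall back
    to uniform, logged.
    """
    params = params or ResamplerParams(method="ADASYN")
    y, n_min, n_maj, k, min_rows, X_min = _oversample_common(train, params)
    rng = np.random.default_rng(params.seed)
    n_syn = n_maj - n_min

    X_all = train.X
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X_all)
    case_pos = np.flatnonzero(y == 1)
    idx = nn_all.kneighbors(X_all[case_pos], return_distance=False)
    weights = np.empty(n_min)
    for i, row in enumerate(idx):
        nbrs = row[row != case_pos[i]][:k]
        weights[i] = np.mean(y[nbrs] == 0)
    if weights.sum() == 0:
        logger.info("ADASYN: all-minority neighborhoods; falling back to uniform weights")
        weights = np.ones(n_min)
    weights = weights / weights.sum()

    raw = weights * n_syn
    counts = np.floor(raw).astype(int)
    short = n_syn - counts.sum()
    order = np.argsort(raw - counts)[::-1]
    counts[order[:short]] += 1

    nbr = _minority_neighbors(X_min, k)
    seeds = np.repeat(np.arange(n_min), counts)
    syn = _interpolate(train, seeds, nbr, rng, min_rows, X_min)
    out_df = pd.concat([train.data, syn], ignore_index=True)
    out = train.with_data(out_df.iloc[rng.permutation(len(out_df))])
    prov = _provenance("ADASYN", train, out, params.seed, k=k, k_fraction=params.k_fraction)
    return ResampledSet(out, prov)


def enn_clean(table: CohortTable, enn_k: int = 3) -> tuple[CohortTable, int]:
    """Edited-nearest-neighbors cleaning.

    Deletes (simultaneously) every row whose label disagrees with the
    majority vote of its ``enn_k`` nearest neighbors; both classes are
    eligible.  Returns the cleaned table and the number of removals.
    """
    X, y = table.X, table.y
    nn = NearestNeighbors(n_neighbors=enn_k + 1).fit(X)
    idx = nn.kneighbors(X, return_distance=False)
    keep = np.ones(len(y), dtype=bool)
    for i, row in enumerate(idx):
        nbrs = row[row != i][:enn_k]
        vote = y[nbrs].mean()
        if (vote > 0.5) != (y[i] == 1) and vote != 0.5:
            keep[i] = False
        elif vote == 0.5:
            pass  # ties keep the row
    cleaned = table.subset(keep)
    if cleaned.n_cases == 0 or cleaned.n_controls == 0:
        raise ValueError(
            f"ENN cleaning emptied a class (kept {cleaned.n_cases} cases, "
            f"{cleaned.n_controls} controls of {len(y)} rows)"
        )
    return cleaned, int((~keep).sum())


def smote_enn(train: CohortTable, params: ResamplerParams | None = None) -> ResampledSet:
    """SMOTE followed by edited-nearest-neighbors cleaning.

    The cleaning pass deletes boundary rows of either class, so the output
    prior can depart from 1:1 — with aggressive cleaning the cases can end
    up the majority class.
    """
    params = params or ResamplerParams(method="SMOTE_ENN")
    smoted = smote_oversample(train, params)
    cleaned, n_removed = enn_clean(smoted.data, params.enn_k)
    prov = _provenance(
        "SMOTE_ENN",
        train,
        cleaned,
        params.seed,
        k=smoted.provenance["params"]["k"],
        k_fraction=params.k_fraction,
        enn_k=params.enn_k,
        enn_removed=n_removed,
    )
    return ResampledSet(cleaned, prov)
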