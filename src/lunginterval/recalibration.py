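"""Recalibration of the image malignancy score to 1-year risk.

The image model scores immediate malignancy of a nodule, not 1-year
screen-detected cancer risk, so its score must be recalibrated.  The default
recalibration is a single-parameter logistic model: the linear predictor is
``alpha + logit(score)`` with the slope fixed at 1, so only the intercept
(a log-odds shift) is estimated.  A free-slope variant and a combined model
that enters both the prescreening risk and the image score as log-odds are
also provided, along with k-fold out-of-fold risk prediction so that no
screen is scored by a model trained on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .data_model import Cohort, ScreenRecord
from .errors import DataError, FitError

__all__ = [
    "RecalibrationModel",
    "CombinedModel",
    "FoldAssignment",
    "fit_recalibration",
    "fit_combined",
    "apply_model",
    "predict",
    "make_folds",
    "crossval_risks",
    "MODEL_KINDS",
]

_GRADIENT_TOL = 1e-8  # score equations satisfied to this tolerance at the MLE


@dataclass(frozen=True)
class RecalibrationModel:
    """Logistic recalibration on the log-odds of the image score.

    ``alpha`` is the fitted log-odds shift; ``beta`` multiplies logit(score)
    and is identically 1 unless the model was fitted with a free slope.
    """

    alpha: float
    beta: float
    n_train: int
    loglik: float
    slope_free: bool = False
    alpha_se: float = float("nan")

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise FitError("non-finite recalibration parameters")
        if not self.slope_free and self.beta != 1.0:
            raise FitError("beta must be fixed at 1 unless slope_free")

    def linear_predictor(self, image_score: np.ndarray) -> np.ndarray:
        return self.alpha + self.beta * logit(image_score)

    def to_dict(self) -> dict:
        return {
            "kind": "recalibration",
            "alpha": self.alpha,
            "beta": self.beta,
            "slope_free": self.slope_free,
            "alpha_se": self.alpha_se,
            "n_train": self.n_train,
            "loglik": self.loglik,
        }


@dataclass(frozen=True)
class CombinedModel:
    """Logistic model combining prescreening risk and image score, both
    entered as log-odds."""

    intercept: float
    coef_prescreen: float
    coef_image: float
    n_train: int
    loglik: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.intercept, self.coef_prescreen, self.coef_image])):
            raise FitError("non-finite combined-model parameters")

    def linear_predictor(self, prescreen_risk: np.ndarray, image_score: np.ndarray) -> np.ndarray:
        return self.intercept + self.coef_prescreen * logit(prescreen_risk) + self.coef_image * logit(image_score)

    def to_dict(self) -> dict:
        return {
            "kind": "combined",
            "intercept": self.intercept,
            "coef_prescreen": self.coef_prescreen,
            "coef_image": self.coef_image,
            "n_train": self.n_train,
            "loglik": self.loglik,
        }


def _check_two_classes(outcomes: np.ndarray) -> None:
    if outcomes.sum() == 0 or outcomes.sum() == outcomes.size:
        raise FitError("training data must contain at least one case and one noncase")


def _fit_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray | None, context: str):
    model = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit(maxiter=200, tol=1e-12)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise FitError(f"complete separation while fitting {context}; try slope_free=False") from exc
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
        raise FitError(f"divergent parameters while fitting {context}; try slope_free=False")
    grad = model.score(res.params)
    if np.max(np.abs(grad)) > _GRADIENT_TOL * max(1.0, y.size):
        raise FitError(f"fit of {context} did not converge (|score| = {np.max(np.abs(grad)):.3g})")
    return res


def fit_recalibration(cohort: Cohort, slope_free: bool = False) -> RecalibrationModel:
    """Fit the logistic recalibration of the image score by maximum likelihood.

    With the slope fixed at 1 (default), only the intercept is free, and at
    the MLE the sum of predicted risks equals the number of observed cases on
    the training data (the intercept's score equation).
    """
    y = cohort.outcomes
    _check_two_classes(y)
    off = logit(cohort.image_scores)
    if slope_free:
        X = np.column_stack([np.ones(len(cohort)), off])
        res = _fit_glm(y, X, None, "free-slope recalibration")
        alpha, beta = res.params
        se = float(res.bse[0])
    else:
        X = np.ones((len(cohort), 1))
        res = _fit_glm(y, X, off, "fixed-slope recalibration")
        alpha, beta = float(res.params[0]), 1.0
        se = float(res.bse[0])
    return RecalibrationModel(
        alpha=float(alpha),
        beta=float(beta),
        n_train=len(cohort),
        loglik=float(res.llf),
        slope_free=slope_free,
        alpha_se=se,
    )


def fit_combined(cohort: Cohort) -> CombinedModel:
    """Fit the combined prescreening-risk + image-score logistic model."""
    y = cohort.outcomes
    _check_two_classes(y)
    X = np.column_stack(
        [np.ones(len(cohort)), logit(cohort.prescreen_risks), logit(cohort.image_scores)]
    )
    res = _fit_glm(y, X, None, "combined model")
    return CombinedModel(
        intercept=float(res.params[0]),
        coef_prescreen=float(res.params[1]),
        coef_image=float(res.params[2]),
        n_train=len(cohort),
        loglik=float(res.llf),
    )


def apply_model(model: RecalibrationModel | CombinedModel, record: ScreenRecord) -> float:
    """Predicted 1-year risk for one screen; strictly inside (0, 1)."""
    if isinstance(model, RecalibrationModel):
        lp = model.linear_predictor(np.array([record.image_score]))
    elif isinstance(model, CombinedModel):
        if record.prescreen_risk is None:
            raise DataError("combined model requires prescreen_risk")
        lp = model.linear_predictor(np.array([record.prescreen_risk]), np.array([record.image_score]))
    else:
        raise TypeError(f"unsupported model type: {type(model).__name__}")
    return float(expit(lp)[0])


def predict(model: RecalibrationModel | CombinedModel, cohort: Cohort) -> np.ndarray:
    """Vectorized predicted risks for every screen in the cohort."""
    if isinstance(model, RecalibrationModel):
        return expit(model.linear_predictor(cohort.image_scores))
    if isinstance(model, CombinedModel):
        return expit(model.linear_predictor(cohort.prescreen_risks, cohort.image_scores))
    raise TypeError(f"unsupported model type: {type(model).__name__}")


@dataclass(frozen=True)
class FoldAssignment:
    """A k-fold partition of a cohort.

    Folds are assigned on a canonical ordering of records — sorted by
    (person_id, round), then permuted by the seeded RNG — so the assignment
    is a function of the records themselves, not of their input order.
    """

    k: int
    unit: str  # "screen" or "person"
    seed: int
    fold_index: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise FitError("k must be >= 2")
        if self.unit not in ("screen", "person"):
            raise FitError(f"unit must be 'screen' or 'person'; got {self.unit!r}")
        counts = np.bincount(self.fold_index, minlength=self.k)
        if counts.min() == 0:
            raise FitError("a fold is empty; reduce k")


def make_folds(cohort: Cohort, k: int = 8, unit: str = "screen", seed: int = 0) -> FoldAssignment:
    """Balanced fold assignment (sizes differ by at most one unit)."""
    if k < 2:
        raise FitError("k must be >= 2")
    if k > len(cohort):
        raise FitError(f"k={k} exceeds cohort size {len(cohort)}")
    rng = np.random.default_rng(seed)
    keys = [(r.person_id, r.round) for r in cohort.records]
    order = sorted(range(len(cohort)), key=keys.__getitem__)
    fold = np.empty(len(cohort), dtype=int)
    if unit == "screen":
        perm = rng.permutation(len(cohort))
        for pos, idx in enumerate(order):
            fold[idx] = perm[pos] % k
    elif unit == "person":
        persons = sorted({r.person_id for r in cohort.records})
        perm = rng.permutation(len(persons))
        person_fold = {p: perm[i] % k for i, p in enumerate(persons)}
        for i, r in enumerate(cohort.records):
            fold[i] = person_fold[r.person_id]
    else:
        raise FitError(f"unit must be 'screen' or 'person'; got {unit!r}")
    return FoldAssignment(k=k, unit=unit, seed=seed, fold_index=fold)


MODEL_KINDS = ("recalibrated", "recalibrated_slope", "combined")


def _fit_kind(cohort: Cohort, model_kind: str):
    if model_kind == "recalibrated":
        return fit_recalibration(cohort, slope_free=False)
    if model_kind == "recalibrated_slope":
        return fit_recalibration(cohort, slope_free=True)
    if model_kind == "combined":
        return fit_combined(cohort)
    raise FitError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")


def crossval_risks(cohort: Cohort, folds: FoldAssignment, model_kind: str = "recalibrated") -> np.ndarray:
    """Out-of-fold predicted risks: each screen is scored by the model fitted
    with its fold held out.  Deterministic given the fold seed, and invariant
    to record order."""
    if folds.fold_index.shape[0] != len(cohort):
        raise FitError("fold assignment does not match cohort size")
    risks = np.full(len(cohort), np.nan)
    for f in range(folds.k):
        hold = folds.fold_index == f
        train = cohort.subset(~hold)
        if train.outcomes.sum() == 0:
            raise FitError(
                f"training split for fold {f} contains no cases; use fewer folds or unit='person'"
            )
        model = _fit_kind(train, model_kind)
        test = cohort.subset(hold)
        risks[hold] = predict(model, test)
    return risks
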