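"""Discrimination and calibration metrics for 1-year risk models.

Discrimination is the probability that a random case outranks a random
noncase (the Mann-Whitney AUC, ties counted half), with Harrell's bootstrap
optimism adjustment for models refit to the data at hand, and DeLong's test
for comparing two correlated AUCs measured on the same screens.  Calibration
is the ratio of expected (sum of predicted risks) to observed cases, with a
lognormal confidence interval treating the observed count as Poisson.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .data_model import Cohort
from .errors import DataError, FitError
from .recalibration import predict

__all__ = [
    "AUCResult",
    "CalibrationResult",
    "auc",
    "optimism_adjusted_auc",
    "compare_auc",
    "expected_observed",
]

logger = logging.getLogger(__name__)


def _as_arrays(risks, outcomes) -> tuple[np.ndarray, np.ndarray]:
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if risks.shape != outcomes.shape:
        raise DataError("risks and outcomes must have the same length")
    return risks, outcomes


def auc(risks, outcomes) -> float:
    """Mann-Whitney AUC: P(case risk > noncase risk) + 0.5 P(tie)."""
    risks, outcomes = _as_arrays(risks, outcomes)
    n1 = int(outcomes.sum())
    if n1 == 0 or n1 == outcomes.size:
        raise DataError("AUC requires at least one case and one noncase")
    return float(roc_auc_score(outcomes, risks))


@dataclass(frozen=True)
class AUCResult:
    """Apparent AUC, bootstrap optimism, and the adjusted AUC."""

    auc: float
    apparent_auc: float
    optimism: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if abs(self.auc - (self.apparent_auc - self.optimism)) > 1e-12:
            raise DataError("auc must equal apparent_auc - optimism")


def optimism_adjusted_auc(
    cohort: Cohort,
    fitter: Callable[[Cohort], object],
    n_boot: int = 200,
    seed: int = 0,
) -> AUCResult:
    """Harrell's bootstrap optimism adjustment of the apparent AUC.

    For each of ``n_boot`` screen-level resamples with replacement: refit with
    ``fitter``, and take the difference between the refit model's AUC on the
    resample and on the original cohort.  The adjusted AUC is the apparent AUC
    minus the mean of those differences.  Resamples with a single outcome
    class are redrawn (logged).  Deterministic given the seed.
    """
    if n_boot < 1:
        raise DataError("n_boot must be >= 1")
    y = cohort.outcomes
    if y.sum() == 0 or y.sum() == y.size:
        raise DataError("optimism adjustment requires both outcome classes")
    rng = np.random.default_rng(seed)
    model = fitter(cohort)
    apparent = auc(predict(model, cohort), y)

    n = len(cohort)
    optimisms = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
        else:
            raise FitError("could not draw a bootstrap resample with both classes")
        if attempt:
            logger.info("bootstrap replicate %d: redrew %d one-class resample(s)", b, attempt)
        # duplicated screens get fresh ids so the resample is a valid cohort
        records = [
            dataclasses.replace(cohort.records[i], person_id=f"B{b}:{j}") for j, i in enumerate(idx)
        ]
        boot = Cohort(records, provenance=f"bootstrap[{b}]")
        model_b = fitter(boot)
        auc_boot = auc(predict(model_b, boot), boot.outcomes)
        auc_orig = auc(predict(model_b, cohort), y)
        optimisms[b] = auc_boot - auc_orig
    optimism = float(optimisms.mean())
    return AUCResult(
        auc=apparent - optimism, apparent_auc=apparent, optimism=optimism, n_boot=n_boot, seed=seed
    )


def _delong_components(risks: np.ndarray, outcomes: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus its per-case and per-noncase structural components."""
    cases = risks[outcomes == 1]
    controls = risks[outcomes == 0]
    m, n = cases.size, controls.size
    tx = rankdata(cases)
    ty = rankdata(controls)
    tz = rankdata(np.concatenate([cases, controls]))
    v_case = (tz[:m] - tx) / n
    v_control = 1.0 - (tz[m:] - ty) / m
    a = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    return float(a), v_case, v_control


def compare_auc(risks_a, risks_b, outcomes) -> float:
    """Two-sided DeLong p-value for the difference of two correlated AUCs
    measured on the same records."""
    risks_a, outcomes = _as_arrays(risks_a, outcomes)
    risks_b, _ = _as_arrays(risks_b, outcomes)
    if outcomes.sum() == 0 or outcomes.sum() == outcomes.size:
        raise DataError("AUC comparison requires both outcome classes")
    auc_a, ca, ka = _delong_components(risks_a, outcomes)
    auc_b, cb, kb = _delong_components(risks_b, outcomes)
    m, n = ca.size, ka.size
    s_case = np.cov(np.vstack([ca, cb])) if m > 1 else np.zeros((2, 2))
    s_control = np.cov(np.vstack([ka, kb])) if n > 1 else np.zeros((2, 2))
    s = s_case / m + s_control / n
    var = s[0, 0] + s[1, 1] - 2.0 * s[0, 1]
    diff = auc_a - auc_b
    if var <= 1e-15:
        # identical rankings (e.g. a monotone transform): no evidence of a difference
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * ndtr(-abs(z)))


@dataclass(frozen=True)
class CalibrationResult:
    """Expected/observed case ratio with a lognormal 95% CI.

    The CI is ``ratio * exp(+-1.96 / sqrt(O))``, i.e. Poisson variance on the
    observed count on the log scale.  ``flagged`` marks an undefined ratio
    (no observed cases).
    """

    expected: float
    observed: int
    ratio: float
    ci_low: float
    ci_high: float
    z: float
    flagged: bool = False


def expected_observed(risks, outcomes) -> CalibrationResult:
    """Mean calibration: sum of predicted risks over observed case count."""
    risks, outcomes = _as_arrays(risks, outcomes)
    expected = float(risks.sum())
    observed = int(outcomes.sum())
    if observed == 0:
        return CalibrationResult(
            expected=expected,
            observed=0,
            ratio=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            z=float("nan"),
            flagged=True,
        )
    ratio = expected / observed
    half_width = 1.96 / np.sqrt(observed)
    z = float(np.log(ratio) * np.sqrt(observed))
    return CalibrationResult(
        expected=expected,
        observed=observed,
        ratio=ratio,
        ci_low=float(ratio * np.exp(-half_width)),
        ci_high=float(ratio * np.exp(half_width)),
        z=z,
    )
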