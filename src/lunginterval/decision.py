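"""Biennial screening-interval assignment and its harms.

Given per-screen 1-year risks, the policy assigns the lowest-risk screens a
2-year instead of 1-year interval.  A cancer is "delayed" if its screen was
assigned biennial and the cancer was detected at the following year's screen:
its diagnosis would have come one year later under the policy.  The module
computes assignments at a target fraction of screens, at a tolerated fraction
of delayed cancers, under nested Lung-RADS thresholds (the guideline
comparator), the full tradeoff curve, nodule-size-stratified results at the
overall threshold, and the sensitivity restrictions (one screen per person,
Lung-RADS 2 only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import Cohort, LungRadsCategory, SizeClass
from .errors import DataError

__all__ = [
    "AssignmentResult",
    "TradeoffCurve",
    "assign_by_fraction",
    "assign_by_lungrads",
    "fraction_assigned_at_delay",
    "one_screen_per_person",
    "restrict_lungrads2",
    "stratify",
    "tradeoff_curve",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class AssignmentResult:
    """Summary of one biennial assignment.

    ``absolute_risk`` is the percent risk of a delayed diagnosis among the
    screens assigned biennial (NaN when nothing is assigned, ``flagged``).
    ``pct_cancers_delayed`` is relative to all cancers, and
    ``pct_noncases_assigned`` relative to all noncases, in the population the
    assignment was computed over.
    """

    target_fraction: float
    n_assigned: int
    n_delayed: int
    absolute_risk: float
    pct_cancers_delayed: float
    pct_noncases_assigned: float
    risk_threshold: float
    label: str = ""
    flagged: bool = False


def _as_arrays(risks, outcomes) -> tuple[np.ndarray, np.ndarray]:
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if risks.shape != outcomes.shape or risks.ndim != 1:
        raise DataError("risks and outcomes must be 1-d and the same length")
    return risks, outcomes


def _summarize(
    assigned: np.ndarray,
    outcomes: np.ndarray,
    target_fraction: float,
    risk_threshold: float,
    label: str = "",
) -> AssignmentResult:
    n_assigned = int(assigned.sum())
    n_delayed = int(outcomes[assigned].sum())
    total_cases = int(outcomes.sum())
    total_noncases = int(outcomes.size - total_cases)
    return AssignmentResult(
        target_fraction=target_fraction,
        n_assigned=n_assigned,
        n_delayed=n_delayed,
        absolute_risk=100.0 * n_delayed / n_assigned if n_assigned else float("nan"),
        pct_cancers_delayed=100.0 * n_delayed / total_cases if total_cases else float("nan"),
        pct_noncases_assigned=(
            100.0 * (n_assigned - n_delayed) / total_noncases if total_noncases else float("nan")
        ),
        risk_threshold=risk_threshold,
        label=label,
        flagged=n_assigned == 0,
    )


def assign_by_fraction(risks, outcomes, fraction: float) -> AssignmentResult:
    """Assign the lowest-risk ``round(fraction * n)`` screens to biennial.

    Ties in risk are broken by stable input order; the rounding is
    half-up on the real count.  ``risk_threshold`` is the largest risk among
    the assigned screens.
    """
    risks, outcomes = _as_arrays(risks, outcomes)
    if not 0.0 <= fraction <= 1.0:
        raise DataError(f"fraction must lie in [0, 1]; got {fraction}")
    n = risks.size
    n_assign = _round_half_up(fraction * n)
    order = np.argsort(risks, kind="stable")
    assigned = np.zeros(n, dtype=bool)
    assigned[order[:n_assign]] = True
    threshold = float(risks[order[n_assign - 1]]) if n_assign else float("nan")
    return _summarize(assigned, outcomes, fraction, threshold)


def assign_by_lungrads(cohort: Cohort, max_category: LungRadsCategory) -> AssignmentResult:
    """Guideline comparator: assign every screen whose Lung-RADS category is
    nested at or below ``max_category``."""
    ranks = cohort.lungrads_ranks
    outcomes = cohort.outcomes
    assigned = ranks <= max_category.nested_rank
    n = len(cohort)
    return _summarize(
        assigned,
        outcomes,
        target_fraction=float(assigned.sum()) / n,
        risk_threshold=float("nan"),
        label=f"<={max_category.label}",
    )


@dataclass(frozen=True)
class TradeoffCurve:
    """Delayed-cancer vs assigned-noncase tradeoff over all rank thresholds.

    One point per achievable threshold (n+1 points for n screens), from
    assigning nobody (0, 0) to everybody (100, 100); both coordinates are
    nondecreasing.  ``n_assigned`` gives the screen count at each point.
    """

    pct_noncases_assigned: np.ndarray = field(repr=False)
    pct_cancers_delayed: np.ndarray = field(repr=False)
    n_assigned: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        x, y = self.pct_noncases_assigned, self.pct_cancers_delayed
        if np.any(np.diff(x) < 0) or np.any(np.diff(y) < 0):
            raise DataError("tradeoff curve coordinates must be nondecreasing")
        if not (x[0] == 0 and y[0] == 0 and x[-1] == 100 and y[-1] == 100):
            raise DataError("tradeoff curve must run from (0, 0) to (100, 100)")


def tradeoff_curve(risks, outcomes) -> TradeoffCurve:
    """Sweep every rank threshold of the risk ordering."""
    risks, outcomes = _as_arrays(risks, outcomes)
    total_cases = int(outcomes.sum())
    total_noncases = int(outcomes.size - total_cases)
    if total_cases == 0 or total_noncases == 0:
        raise DataError("tradeoff curve requires at least one case and one noncase")
    order = np.argsort(risks, kind="stable")
    cum_cases = np.concatenate([[0], np.cumsum(outcomes[order])])
    n_assigned = np.arange(outcomes.size + 1)
    cum_noncases = n_assigned - cum_cases
    return TradeoffCurve(
        pct_noncases_assigned=100.0 * cum_noncases / total_noncases,
        pct_cancers_delayed=100.0 * cum_cases / total_cases,
        n_assigned=n_assigned,
    )


def fraction_assigned_at_delay(risks, outcomes, delay_fraction: float) -> AssignmentResult:
    """Largest rank threshold delaying at most ``delay_fraction`` of cancers.

    Returns the realized assignment at that threshold; with ``delay_fraction``
    of 0 the threshold sits just below the lowest-ranked cancer.
    """
    risks, outcomes = _as_arrays(risks, outcomes)
    if not 0.0 <= delay_fraction <= 1.0:
        raise DataError(f"delay_fraction must lie in [0, 1]; got {delay_fraction}")
    total_cases = int(outcomes.sum())
    if total_cases == 0:
        raise DataError("delay-targeted assignment requires at least one case")
    order = np.argsort(risks, kind="stable")
    cum_cases = np.concatenate([[0], np.cumsum(outcomes[order])])
    allowed = delay_fraction * total_cases
    n_assign = int(np.max(np.flatnonzero(cum_cases <= allowed + 1e-12)))
    assigned = np.zeros(outcomes.size, dtype=bool)
    assigned[order[:n_assign]] = True
    threshold = float(risks[order[n_assign - 1]]) if n_assign else float("nan")
    return _summarize(assigned, outcomes, delay_fraction, threshold)


def stratify(
    cohort: Cohort,
    risks,
    overall_fraction: float,
    by: str = "size_class",
) -> list[tuple[str, AssignmentResult]]:
    """Per-stratum assignment counts at the *overall* risk threshold.

    The threshold is chosen on the whole cohort (via
    :func:`assign_by_fraction`); each stratum then reports how many of its
    screens fall below it, so stratum counts sum to the overall counts.
    Empty strata yield zero-count rows.
    """
    risks, outcomes = _as_arrays(risks, cohort.outcomes)
    n = len(cohort)
    n_assign = _round_half_up(overall_fraction * n)
    order = np.argsort(risks, kind="stable")
    assigned = np.zeros(n, dtype=bool)
    assigned[order[:n_assign]] = True
    threshold = float(risks[order[n_assign - 1]]) if n_assign else float("nan")

    if by == "size_class":
        strata = [(s.value, np.array([r.size_class is s for r in cohort.records])) for s in SizeClass]
    elif by == "lung_rads":
        strata = [
            (c.label, np.array([r.lung_rads is c for r in cohort.records])) for c in LungRadsCategory
        ]
    else:
        raise DataError(f"unknown stratifier {by!r}; expected 'size_class' or 'lung_rads'")

    out: list[tuple[str, AssignmentResult]] = []
    for label, mask in strata:
        n_s = int(mask.sum())
        if n_s == 0:
            out.append(
                (
                    label,
                    AssignmentResult(
                        target_fraction=overall_fraction,
                        n_assigned=0,
                        n_delayed=0,
                        absolute_risk=float("nan"),
                        pct_cancers_delayed=float("nan"),
                        pct_noncases_assigned=float("nan"),
                        risk_threshold=threshold,
                        label=label,
                        flagged=True,
                    ),
                )
            )
            continue
        stratum_cases = int(outcomes[mask].sum())
        stratum_noncases = n_s - stratum_cases
        n_assigned = int((assigned & mask).sum())
        n_delayed = int(outcomes[assigned & mask].sum())
        out.append(
            (
                label,
                AssignmentResult(
                    target_fraction=overall_fraction,
                    n_assigned=n_assigned,
                    n_delayed=n_delayed,
                    absolute_risk=100.0 * n_delayed / n_assigned if n_assigned else float("nan"),
                    pct_cancers_delayed=(
                        100.0 * n_delayed / stratum_cases if stratum_cases else float("nan")
                    ),
                    pct_noncases_assigned=(
                        100.0 * (n_assigned - n_delayed) / stratum_noncases
                        if stratum_noncases
                        else float("nan")
                    ),
                    risk_threshold=threshold,
                    label=label,
                    flagged=n_assigned == 0,
                ),
            )
        )
    return out


def one_screen_per_person(cohort: Cohort, seed: int) -> Cohort:
    """Sensitivity restriction: keep one screen per person, chosen uniformly
    at random; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    by_person: dict[str, list[int]] = {}
    for i, rec in enumerate(cohort.records):
        by_person.setdefault(rec.person_id, []).append(i)
    keep = np.zeros(len(cohort), dtype=bool)
    for person in sorted(by_person):
        idxs = by_person[person]
        keep[idxs[rng.integers(0, len(idxs))]] = True
    return cohort.subset(keep, provenance=f"{cohort.provenance} | one-screen-per-person(seed={seed})")


def restrict_lungrads2(cohort: Cohort) -> Cohort:
    """Sensitivity restriction: screens with Lung-RADS category exactly 2 —
    those a guideline policy would already keep on an annual interval."""
    mask = cohort.lungrads_ranks == LungRadsCategory.CAT_2.nested_rank
    if not mask.any():
        warnings.warn("no Lung-RADS 2 screens in cohort; returning an empty cohort", stacklevel=2)
    return cohort.subset(mask, provenance=f"{cohort.provenance} | lungrads2-only")
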