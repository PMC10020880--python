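"""Synthetic screen-level cohorts with controlled discrimination.

Two generators are provided:

* :func:`generate_cohort` draws cohorts from a binormal latent model: given the
  outcome, the log-odds of each score are normal with common variance, and the
  case/noncase mean separation is chosen in closed form to hit a target AUC
  (``AUC = Phi(delta / (sigma * sqrt(2)))``).  Nodule-size class and Lung-RADS
  category are drawn from outcome-conditional categorical distributions whose
  defaults are the observed NLST marginals for abnormal presumed nonmalignant
  screens.

* :func:`table1_fixture` is an exact, deterministic expansion of the published
  Lung-RADS x outcome counts into 10,831 records, for the comparator analysis
  that depends only on categories and outcomes.
"""

from __future__ import annotations

import warnings

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit, logit, ndtri

from .data_model import Cohort, LungRadsCategory, ScreenRecord, SizeClass

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "generate_shifted_score_cohort",
    "table1_fixture",
    "binormal_auc",
    "binormal_separation",
    "TABLE1_LUNGRADS_COUNTS",
    "TABLE1_SIZE_COUNTS",
]

# Observed NLST marginals (cancer, benign) for abnormal presumed nonmalignant
# screens: 195 cancers / 10,636 benign / 10,831 total.
TABLE1_LUNGRADS_COUNTS: dict[str, tuple[int, int]] = {
    "2": (69, 7026),
    "3": (19, 1613),
    "3|4A": (2, 83),
    "3|4A|4B": (11, 141),
    "4A": (48, 1194),
    "4A|4B": (11, 105),
    "4B": (35, 474),
}

TABLE1_SIZE_COUNTS: dict[str, tuple[int, int]] = {
    "NA": (1, 32),
    "4-5": (22, 3808),
    "6-7": (39, 3290),
    "8-10": (47, 1976),
    "11-13": (41, 664),
    ">=14": (45, 866),
}


def _proportions(counts: dict[str, tuple[int, int]], idx: int) -> dict[str, float]:
    total = sum(v[idx] for v in counts.values())
    return {k: v[idx] / total for k, v in counts.items()}


def binormal_separation(auc: float, sigma: float = 1.0) -> float:
    """Case/noncase latent mean separation giving a target AUC under the
    equal-variance binormal model."""
    return float(sigma * np.sqrt(2.0) * ndtri(auc))


def binormal_auc(delta: float, sigma: float = 1.0) -> float:
    """Closed-form AUC of the equal-variance binormal model (the oracle the
    generator is checked against)."""
    from scipy.special import ndtr

    return float(ndtr(delta / (sigma * np.sqrt(2.0))))


class SyntheticConfig(BaseModel):
    """Parameters of the cohort generator.

    Defaults reproduce the study conditions: ~1.8% of screens lead to a
    cancer detected at the next annual screen; the image score discriminates
    at AUC ~0.87 and the precomputed comparator risk at ~0.79; the
    prescreening risk alone is weaker (0.70); 10,831 screens came from 7,495
    people, i.e. ~44.5% of people contribute both a T0 and a T1 screen.
    """

    n_screens: int = Field(gt=0)
    prevalence: float = Field(default=0.018, gt=0.0, lt=1.0)
    auc_image: float = Field(default=0.87, gt=0.0, lt=1.0)
    auc_prescreen: float = Field(default=0.70, gt=0.0, lt=1.0)
    auc_comparator: float | None = Field(default=0.79)
    rho: float = Field(default=0.3, gt=-1.0, lt=1.0)
    two_screen_fraction: float = Field(default=0.445, ge=0.0, le=1.0)
    size_dist: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "benign": _proportions(TABLE1_SIZE_COUNTS, 1),
            "cancer": _proportions(TABLE1_SIZE_COUNTS, 0),
        }
    )
    lungrads_dist: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "benign": _proportions(TABLE1_LUNGRADS_COUNTS, 1),
            "cancer": _proportions(TABLE1_LUNGRADS_COUNTS, 0),
        }
    )
    couple_lungrads: bool = False
    seed: int = 0

    @field_validator("auc_comparator")
    @classmethod
    def _check_auc_comparator(cls, v: float | None) -> float | None:
        if v is not None and not (0.0 < v < 1.0):
            raise ValueError("auc_comparator must lie in (0, 1) or be None")
        return v

    @model_validator(mode="after")
    def _check_dists(self) -> "SyntheticConfig":
        for name, dist in (("size_dist", self.size_dist), ("lungrads_dist", self.lungrads_dist)):
            for arm in ("benign", "cancer"):
                if arm not in dist:
                    raise ValueError(f"{name} must have 'benign' and 'cancer' arms")
                total = sum(dist[arm].values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{name}[{arm!r}] sums to {total!r}, not 1")
        return self


# Baseline (noncase) latent means on the log-odds scale.  The image score is a
# malignancy probability (typical benign nodules score low but not vanishingly
# so); the prescreening risk is deliberately NOT calibrated to the outcome
# (1-year risk after an abnormal screen runs several-fold above prescreening
# risk); the comparator's baseline is solved at generation time so its mean
# risk matches the prevalence (it emulates an externally calibrated model).
_MU0 = {"image": float(logit(0.10)), "prescreen": float(logit(0.005))}
_SIGMA = 1.0

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(61)


def _mean_risk(mu: float, delta: float, prevalence: float, sigma: float) -> float:
    """Population mean of expit(latent) under the two-class binormal mixture
    (Gauss-Hermite quadrature)."""
    z = np.sqrt(2.0) * sigma * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    m0 = float(w @ expit(mu + z))
    m1 = float(w @ expit(mu + delta + z))
    return (1.0 - prevalence) * m0 + prevalence * m1


def _calibrated_base(delta: float, prevalence: float, sigma: float = _SIGMA) -> float:
    """Baseline latent mean making the score mean-calibrated: mean generated
    risk equals the outcome prevalence."""
    from scipy.optimize import brentq

    return float(brentq(lambda mu: _mean_risk(mu, delta, prevalence, sigma) - prevalence, -20.0, 5.0))


def _draw_categories(rng: np.random.Generator, outcomes: np.ndarray, dist: dict[str, dict[str, float]], labels: list[str]) -> np.ndarray:
    out = np.empty(outcomes.shape[0], dtype=object)
    for arm, y in (("benign", 0), ("cancer", 1)):
        mask = outcomes == y
        p = np.array([dist[arm].get(lbl, 0.0) for lbl in labels])
        p = p / p.sum()
        out[mask] = rng.choice(labels, size=int(mask.sum()), p=p)
    return out


def _couple_to_score(values: np.ndarray, outcomes: np.ndarray, latent: np.ndarray, rank_of: dict[str, int]) -> np.ndarray:
    """Within each outcome arm, reassign the drawn categories so that higher
    latent scores receive higher-ranked categories (counts preserved)."""
    out = values.copy()
    for y in (0, 1):
        idx = np.flatnonzero(outcomes == y)
        if idx.size == 0:
            continue
        drawn = sorted(values[idx], key=lambda lbl: rank_of[lbl])
        order = idx[np.argsort(latent[idx], kind="stable")]
        out[order] = drawn
    return out


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a synthetic cohort; deterministic given ``config.seed``.

    Outcomes are Bernoulli(prevalence) per screen.  Score log-odds follow the
    equal-variance binormal model with pairwise latent correlation ``rho``
    between image, prescreening, and comparator scores.  Size class and
    Lung-RADS category are drawn conditionally on the outcome only, unless
    ``couple_lungrads`` sorts categories by the latent image score within each
    outcome arm.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_screens
    if config.prevalence * n < 1:
        warnings.warn(
            f"expected case count {config.prevalence * n:.2f} < 1; cohort may contain no cases",
            stacklevel=2,
        )

    # Person structure: each person contributes T0+T1 with probability
    # two_screen_fraction, else a single screen (round chosen at random).
    two = rng.random(n) < config.two_screen_fraction
    screens_per_person = np.where(two, 2, 1)
    cum = np.cumsum(screens_per_person)
    m = int(np.searchsorted(cum, n)) + 1
    person_idx: list[int] = []
    rounds: list[str] = []
    for p in range(m):
        if two[p]:
            person_idx += [p, p]
            rounds += ["T0", "T1"]
        else:
            person_idx.append(p)
            rounds.append("T0" if rng.random() < 0.5 else "T1")
    person_idx = person_idx[:n]
    rounds = rounds[:n]

    outcomes = (rng.random(n) < config.prevalence).astype(int)

    names = ["image", "prescreen"] + (["comparator"] if config.auc_comparator is not None else [])
    k = len(names)
    aucs = {"image": config.auc_image, "prescreen": config.auc_prescreen, "comparator": config.auc_comparator}
    cov = np.full((k, k), config.rho * _SIGMA**2)
    np.fill_diagonal(cov, _SIGMA**2)
    chol = np.linalg.cholesky(cov)
    eps = rng.standard_normal((n, k)) @ chol.T
    latent = np.empty((n, k))
    for j, name in enumerate(names):
        delta = binormal_separation(aucs[name], _SIGMA)
        mu0 = _MU0[name] if name in _MU0 else _calibrated_base(delta, config.prevalence)
        latent[:, j] = mu0 + delta * outcomes + eps[:, j]
    scores = expit(latent)

    size_labels = [s.value for s in SizeClass]
    lr_labels = [c.label for c in LungRadsCategory]
    sizes = _draw_categories(rng, outcomes, config.size_dist, size_labels)
    lungrads = _draw_categories(rng, outcomes, config.lungrads_dist, lr_labels)
    if config.couple_lungrads:
        rank_of = {c.label: c.nested_rank for c in LungRadsCategory}
        lungrads = _couple_to_score(lungrads, outcomes, latent[:, 0], rank_of)

    size_of = {s.value: s for s in SizeClass}
    lr_of = {c.label: c for c in LungRadsCategory}
    has_comp = config.auc_comparator is not None
    records = [
        ScreenRecord(
            person_id=f"S{person_idx[i]:07d}",
            round=rounds[i],
            image_score=scores[i, 0],
            prescreen_risk=scores[i, 1],
            comparator_risk=scores[i, 2] if has_comp else None,
            lung_rads=lr_of[lungrads[i]],
            size_class=size_of[sizes[i]],
            outcome=int(outcomes[i]),
        )
        for i in range(n)
    ]
    return Cohort(records, provenance=f"synthetic(seed={config.seed}, n={n})")


def generate_shifted_score_cohort(
    n_screens: int,
    shift: float,
    seed: int,
    score_mu: float = -2.0,
    score_sigma: float = 1.5,
) -> Cohort:
    """Cohort whose outcomes truly follow an intercept-shifted score.

    The image score's log-odds are Normal(score_mu, score_sigma^2) and the
    outcome is Bernoulli(expit(shift + logit(score))).  Used for parameter
    recovery: the fixed-slope recalibration's intercept estimates ``shift``.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(score_mu, score_sigma, n_screens)
    score = expit(z)
    p = expit(shift + z)
    y = (rng.random(n_screens) < p).astype(int)
    records = [
        ScreenRecord(
            person_id=f"R{i:07d}",
            round="T0",
            image_score=float(score[i]),
            prescreen_risk=0.01,
            lung_rads=LungRadsCategory.CAT_2,
            size_class=SizeClass.NA,
            outcome=int(y[i]),
        )
        for i in range(n_screens)
    ]
    return Cohort(records, provenance=f"shifted-score(shift={shift}, seed={seed})")


def table1_fixture() -> Cohort:
    """Exact expansion of the published Lung-RADS x outcome counts.

    Returns 10,831 records: per category, the published cancer and benign
    counts, with mid-range placeholder scores (the comparator analyses this
    fixture supports use only categories and outcomes).  Deterministic.
    """
    records: list[ScreenRecord] = []
    i = 0
    for cat in LungRadsCategory:
        n_cancer, n_benign = TABLE1_LUNGRADS_COUNTS[cat.label]
        for outcome, count in ((0, n_benign), (1, n_cancer)):
            for _ in range(count):
                records.append(
                    ScreenRecord(
                        person_id=f"F{i:05d}",
                        round="T0",
                        image_score=0.5,
                        prescreen_risk=0.5,
                        lung_rads=cat,
                        size_class=SizeClass.NA,
                        outcome=outcome,
                    )
                )
                i += 1
    return Cohort(records, provenance="table1-lungrads-fixture")
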