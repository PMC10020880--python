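"""Domain types and CSV I/O for screen-level lung-screening cohorts.

The unit of analysis is a single LDCT screen with at least one presumed
nonmalignant nodule.  Each screen carries the screen-level image malignancy
score (the maximum over nodules), a prescreening 1-year risk, an optional
precomputed comparator risk, the Lung-RADS category (grouped categories such
as "3 or 4A" are first-class, atomic labels), a nodule-size class, and the
binary outcome "lung cancer detected as a result of the next annual screen".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "LungRadsCategory",
    "SizeClass",
    "Stage",
    "ScreenRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "COLUMNS",
]


class LungRadsCategory(enum.Enum):
    """Lung-RADS v1.1 category of a screen, including grouped labels.

    Grouped labels arise when the available metadata cannot pin a nodule to a
    single category; they are atomic (never split).  ``nested_rank`` orders the
    seven labels so that thresholding at rank *r* assigns every category that a
    nested "category <= X" policy would include, from 2 (rank 1) up to 4B
    (rank 7).
    """

    CAT_2 = ("2", 1)
    CAT_3 = ("3", 2)
    CAT_3_4A = ("3|4A", 3)
    CAT_3_4A_4B = ("3|4A|4B", 4)
    CAT_4A = ("4A", 5)
    CAT_4A_4B = ("4A|4B", 6)
    CAT_4B = ("4B", 7)

    def __init__(self, label: str, nested_rank: int) -> None:
        self.label = label
        self.nested_rank = nested_rank

    def __lt__(self, other: "LungRadsCategory") -> bool:
        if not isinstance(other, LungRadsCategory):
            return NotImplemented
        return self.nested_rank < other.nested_rank

    def __le__(self, other: "LungRadsCategory") -> bool:
        if not isinstance(other, LungRadsCategory):
            return NotImplemented
        return self.nested_rank <= other.nested_rank

    def __gt__(self, other: "LungRadsCategory") -> bool:
        if not isinstance(other, LungRadsCategory):
            return NotImplemented
        return self.nested_rank > other.nested_rank

    def __ge__(self, other: "LungRadsCategory") -> bool:
        if not isinstance(other, LungRadsCategory):
            return NotImplemented
        return self.nested_rank >= other.nested_rank

    @classmethod
    def parse(cls, value: str) -> "LungRadsCategory":
        """Parse a serialized label; also accepts prose forms like "3 or 4A"."""
        key = str(value).strip()
        normalized = (
            key.replace(", or ", "|").replace(" or ", "|").replace(", ", "|").replace(",", "|")
        )
        for member in cls:
            if member.label == normalized:
                return member
        raise DataError(f"unknown Lung-RADS category: {value!r}")


class SizeClass(enum.Enum):
    """Largest-nodule diameter bin (mm); NA marks screens positive for a
    non-nodule abnormality."""

    NA = "NA"
    MM_4_5 = "4-5"
    MM_6_7 = "6-7"
    MM_8_10 = "8-10"
    MM_11_13 = "11-13"
    MM_GE_14 = ">=14"

    @classmethod
    def parse(cls, value: str) -> "SizeClass":
        key = str(value).strip().replace("≥", ">=")  # accept the unicode >= sign
        for member in cls:
            if member.value == key:
                return member
        raise DataError(f"unknown nodule size class: {value!r}")


class Stage(enum.Enum):
    """Stage at diagnosis for screens whose outcome is a detected cancer."""

    S1A = "1A"
    S1B = "1B"
    S2 = "2"
    S3 = "3"
    S4 = "4"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: str) -> "Stage":
        key = str(value).strip()
        for member in cls:
            if member.value == key:
                return member
        raise DataError(f"unknown stage: {value!r}")


def _check_probability(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not (0.0 < value < 1.0):
        raise DataError(f"{name} must lie strictly in (0, 1); got {value!r}")
    return value


@dataclass(slots=True)
class ScreenRecord:
    """One LDCT screen.

    Probabilities are required to be strictly inside (0, 1) so their log-odds
    are finite; recalibration operates on the log-odds scale.
    """

    person_id: str
    round: str  # "T0" (baseline) or "T1" (year-1 screen)
    image_score: float
    prescreen_risk: float
    lung_rads: LungRadsCategory
    size_class: SizeClass
    outcome: int
    comparator_risk: float | None = None
    stage: Stage | None = None

    def __post_init__(self) -> None:
        if self.round not in ("T0", "T1"):
            raise DataError(f"round must be 'T0' or 'T1'; got {self.round!r}")
        self.image_score = _check_probability("image_score", self.image_score)
        self.prescreen_risk = _check_probability("prescreen_risk", self.prescreen_risk)
        if self.comparator_risk is not None:
            self.comparator_risk = _check_probability("comparator_risk", self.comparator_risk)
        if self.outcome not in (0, 1):
            raise DataError(f"outcome must be 0 or 1; got {self.outcome!r}")


class Cohort:
    """An ordered collection of :class:`ScreenRecord` with array views.

    Enforces uniqueness of (person_id, round) pairs, which bounds each person
    at two screens (one per round).  Array properties are cached on first use.
    """

    def __init__(
        self,
        records: Iterable[ScreenRecord],
        provenance: str = "",
        allow_empty: bool = False,
    ) -> None:
        self.records: tuple[ScreenRecord, ...] = tuple(records)
        self.provenance = provenance
        if not self.records and not allow_empty:
            raise DataError("cohort is empty")
        keys = set()
        for rec in self.records:
            key = (rec.person_id, rec.round)
            if key in keys:
                raise DataError(f"duplicate (person_id, round) pair: {key}")
            keys.add(key)
        self._cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ScreenRecord]:
        return iter(self.records)

    def _array(self, name: str, build) -> np.ndarray:
        if name not in self._cache:
            self._cache[name] = build()
        return self._cache[name]

    @property
    def outcomes(self) -> np.ndarray:
        return self._array("outcomes", lambda: np.array([r.outcome for r in self.records], dtype=int))

    @property
    def image_scores(self) -> np.ndarray:
        return self._array("image_scores", lambda: np.array([r.image_score for r in self.records]))

    @property
    def prescreen_risks(self) -> np.ndarray:
        return self._array("prescreen_risks", lambda: np.array([r.prescreen_risk for r in self.records]))

    @property
    def comparator_risks(self) -> np.ndarray:
        """Comparator risks with NaN where absent."""
        return self._array(
            "comparator_risks",
            lambda: np.array(
                [np.nan if r.comparator_risk is None else r.comparator_risk for r in self.records]
            ),
        )

    @property
    def lungrads_ranks(self) -> np.ndarray:
        return self._array(
            "lungrads_ranks", lambda: np.array([r.lung_rads.nested_rank for r in self.records], dtype=int)
        )

    @property
    def person_ids(self) -> np.ndarray:
        return self._array("person_ids", lambda: np.array([r.person_id for r in self.records], dtype=object))

    @property
    def size_classes(self) -> np.ndarray:
        return self._array("size_classes", lambda: np.array([r.size_class for r in self.records], dtype=object))

    @property
    def n_cases(self) -> int:
        return int(self.outcomes.sum())

    def subset(self, mask: Sequence[bool] | np.ndarray, provenance: str = "") -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        records = [rec for rec, keep in zip(self.records, mask) if keep]
        return Cohort(records, provenance=provenance or self.provenance, allow_empty=True)

    def to_frame(self) -> pd.DataFrame:
        """Serialize to a DataFrame in the canonical column order."""
        return pd.DataFrame(
            {
                "person_id": [r.person_id for r in self.records],
                "round": [r.round for r in self.records],
                "image_score": [r.image_score for r in self.records],
                "prescreen_risk": [r.prescreen_risk for r in self.records],
                "comparator_risk": [r.comparator_risk for r in self.records],
                "lung_rads": [r.lung_rads.label for r in self.records],
                "size_class": [r.size_class.value for r in self.records],
                "outcome": [r.outcome for r in self.records],
                "stage": [None if r.stage is None else r.stage.value for r in self.records],
            }
        )


COLUMNS = (
    "person_id",
    "round",
    "image_score",
    "prescreen_risk",
    "comparator_risk",
    "lung_rads",
    "size_class",
    "outcome",
    "stage",
)

_REQUIRED = (
    "person_id",
    "round",
    "image_score",
    "prescreen_risk",
    "lung_rads",
    "size_class",
    "outcome",
)


def _parse_row(row: Mapping[str, object]) -> ScreenRecord:
    comparator = row.get("comparator_risk")
    if comparator is None or (isinstance(comparator, float) and math.isnan(comparator)) or comparator == "":
        comparator = None
    else:
        comparator = float(comparator)
    stage = row.get("stage")
    if stage is None or (isinstance(stage, float) and math.isnan(stage)) or stage == "":
        stage = None
    else:
        stage = Stage.parse(str(stage))
    return ScreenRecord(
        person_id=str(row["person_id"]),
        round=str(row["round"]).strip(),
        image_score=float(row["image_score"]),
        prescreen_risk=float(row["prescreen_risk"]),
        comparator_risk=comparator,
        lung_rads=LungRadsCategory.parse(str(row["lung_rads"])),
        size_class=SizeClass.parse(str(row["size_class"])),
        outcome=int(row["outcome"]),
        stage=stage,
    )


def read_cohort(path: str | Path, dialect: Mapping[str, str] | None = None) -> Cohort:
    """Read a screen-level cohort from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional map from canonical column names (see :data:`COLUMNS`) to the
        names used in the file, for ingesting external exports.

    Raises
    ------
    ConfigurationError
        If a required column is missing.
    DataError
        If any row violates the record invariants; the message lists the
        offending 1-based data-row numbers and values.
    """
    path = Path(path)
    # keep_default_na so the literal size-class label "NA" survives
    frame = pd.read_csv(
        path,
        dtype={"person_id": str, "round": str, "lung_rads": str, "size_class": str, "stage": str},
        keep_default_na=False,
        na_values=[""],
    )
    if dialect:
        frame = frame.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "comparator_risk" not in frame.columns:
        frame["comparator_risk"] = None
    if "stage" not in frame.columns:
        frame["stage"] = None

    records: list[ScreenRecord] = []
    problems: list[str] = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            records.append(_parse_row(row))
        except (DataError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        shown = "; ".join(problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        raise DataError(f"{path}: {shown}{more}")
    if not records:
        raise DataError(f"{path}: no data rows")
    return Cohort(records, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical column order.

    Optional fields (comparator_risk, stage) serialize as empty strings.
    Floats round-trip exactly (shortest repr).
    """
    path = Path(path)
    frame = cohort.to_frame()
    frame.to_csv(path, index=False, na_rep="")
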