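"""Registry score records: parsing, encoding, data edits and transformations.

The public dysplasia registry releases one row per scored joint:
dog id, breed, sex, birth date, sire id, dam id, trait, score, test date.
Hip conformation is graded on a 7-point ordinal scale (1 = excellent ...
7 = severe dysplasia); elbow conformation on a 4-point scale (1 = normal,
2-4 = degenerative joint disease grades I-III). Lower is better for both.

This module turns such files into clean per-trait datasets: it encodes the
textual grades, applies the standard editing rules (age window, birth/test
year windows, breed thresholds, last-record-per-dog) and records an audit
trail of how many rows each rule removed.
"""

from __future__ import annotations

import json
import logging

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIP, ELBOW = "hip", "elbow"
TRAITS = (HIP, ELBOW)

#: textual hip grades -> ordinal codes (1 best .. 7 worst)
HIP_GRADE_CODES = {
    "excellent": 1,
    "good": 2,
    "fair": 3,
    "borderline": 4,
    "mild": 5,
    "moderate": 6,
    "severe": 7,
}

#: textual elbow grades -> ordinal codes (1 normal, 2-4 = DJD grade I-III)
ELBOW_GRADE_CODES = {
    "normal": 1,
    "djd i": 2,
    "djd ii": 3,
    "djd iii": 4,
    "grade i": 2,
    "grade ii": 3,
    "grade iii": 4,
    "dysplastic grade i": 2,
    "dysplastic grade ii": 3,
    "dysplastic grade iii": 4,
}

HIP_SCORE_RANGE = (1, 7)
ELBOW_SCORE_RANGE = (1, 4)

#: hip codes counted as dysplastic when dichotomizing (mild/moderate/severe);
#: borderline (4) belongs to neither class.
HIP_DYSPLASTIC_CODES = frozenset({5, 6, 7})
#: elbow codes counted as dysplastic (DJD I-III)
ELBOW_DYSPLASTIC_CODES = frozenset({2, 3, 4})

#: age-group labels used as a fixed effect (months at scoring)
AGE_GROUP_LABELS = ("24", "25-29", "30-36", "37-60")

#: chondrodysplastic breeds excluded from analysis
CHONDRODYSPLASTIC_BREEDS = (
    "Havanese",
    "Cardigan Welsh Corgi",
    "Miniature Australian Shepherd",
    "Pembroke Welsh Corgi",
    "Cavalier King Charles Spaniel",
    "Bichon Frise",
    "Cocker Spaniel",
    "Soft Coated Wheaten Terrier",
    "English Cocker Spaniel",
)

REQUIRED_COLUMNS = (
    "dog_id",
    "breed",
    "sex",
    "birth_date",
    "sire_id",
    "dam_id",
    "trait",
    "score",
    "test_date",
)

ELBOW_TRANSFORMS = ("identity", "log", "sqrt", "reciprocal")


@dataclass(frozen=True)
class ScoreRecord:
    """A single scored joint for one dog.

    Dates carry calendar-month precision as ``(year, month)`` tuples.
    ``score`` is the ordinal code (hip 1-7, elbow 1-4); the float type
    also accommodates transformed or simulated continuous liabilities.
    """

    dog_id: str
    breed: str
    sex: str
    birth_date: tuple[int, int]
    test_date: tuple[int, int]
    trait: str
    score: float
    sire_id: str = ""
    dam_id: str = ""

    @property
    def age_months(self) -> int:
        """Whole calendar months elapsed between birth and test dates."""
        by, bm = self.birth_date
        ty, tm = self.test_date
        return (ty - by) * 12 + (tm - bm)


@dataclass
class EditConfig:
    """Thresholds for the registry editing rules."""

    min_age_months: int = 24
    max_age_months: int = 60
    min_birth_year: int = 1970
    max_birth_year: int = 2007
    min_test_year: int = 1974
    max_test_year: int = 2009
    min_breed_records: int = 1000
    min_ed_dogs: int = 10
    elbow_birth_year_floor: int = 1988
    excluded_breeds: tuple[str, ...] = CHONDRODYSPLASTIC_BREEDS
    #: first test years of the 2nd.. scoring-strategy eras; the prior-study
    #: era definition is not public, so these are configurable stand-ins.
    period_breaks: tuple[int, ...] = (1986, 2000)

    def __post_init__(self) -> None:
        if self.min_age_months >= self.max_age_months:
            raise ValueError("min_age_months must be below max_age_months")
        for name in ("min_age_months", "max_age_months", "min_breed_records",
                     "min_ed_dogs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def test_year_period(self, test_year: int) -> int:
        """Index (0-based) of the scoring-strategy era containing a test year."""
        return int(np.searchsorted(np.asarray(self.period_breaks), test_year,
                                   side="right"))


@dataclass
class TraitDataset:
    """Edited records for one trait, ready for model building.

    ``data`` holds one row per dog with columns: dog_id, breed, sex,
    birth_year, birth_month, test_year, test_month, age_months, age_group,
    score (original ordinal code or simulated liability) and value (the
    response actually analysed, i.e. the transformed score).
    """

    trait: str
    data: pd.DataFrame
    transformation: str = "identity"
    audit: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.data["dog_id"].duplicated().any():
            raise ValueError("TraitDataset must hold at most one record per dog")

    @property
    def n_records(self) -> int:
        return len(self.data)

    def with_transformation(self, kind: str) -> "TraitDataset":
        """Return a copy whose ``value`` column is the transformed score."""
        out = self.data.copy()
        out["value"] = transform_elbow(out["score"].to_numpy(float), kind)
        return replace(self, data=out, transformation=kind)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def write_audit(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.audit, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# parsing


def _parse_month(token: str) -> tuple[int, int] | None:
    """Parse ISO-8601 YYYY-MM or YYYY-MM-DD into (year, month)."""
    parts = str(token).strip().split("-")
    if len(parts) not in (2, 3):
        return None
    try:
        year, month = int(parts[0]), int(parts[1])
    except ValueError:
        return None
    if not (1 <= month <= 12) or year < 1800:
        return None
    return year, month


def _parse_score(token, trait: str) -> int | None:
    text = str(token).strip().lower()
    table = HIP_GRADE_CODES if trait == HIP else ELBOW_GRADE_CODES
    lo, hi = HIP_SCORE_RANGE if trait == HIP else ELBOW_SCORE_RANGE
    if text in table:
        return table[text]
    try:
        value = float(text)
    except ValueError:
        return None
    if not value.is_integer() or not (lo <= value <= hi):
        return None
    return int(value)


_SEX_TOKENS = {"male": "male", "m": "male", "female": "female", "f": "female"}


def parse_registry(path) -> list[ScoreRecord]:
    """Read a delimited registry file into :class:`ScoreRecord` objects.

    Scores may be ordinal codes, textual grades, or -- for simulated
    liability-scale files -- arbitrary floats (detected when the column is
    numeric with non-integer values; grade validation is then skipped).
    Malformed rows (bad dates, unknown score tokens, test before birth) are
    skipped with a logged warning; a missing mandatory column is an error.
    """
    frame = pd.read_csv(path, dtype=str, sep=None, engine="python",
                        keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"registry file is missing mandatory columns: {missing}")
    if frame.empty:
        logger.warning("registry file %s contains no records", path)
        return []

    as_float = pd.to_numeric(frame["score"], errors="coerce")
    continuous = bool(as_float.notna().all()
                      and np.any(as_float != np.round(as_float)))
    if continuous:
        logger.info("registry scores are continuous (liability scale); "
                    "grade validation skipped")

    records: list[ScoreRecord] = []
    n_bad = 0
    for row in frame.itertuples(index=False):
        trait = str(row.trait).strip().lower()
        sex = _SEX_TOKENS.get(str(row.sex).strip().lower())
        birth = _parse_month(row.birth_date)
        test = _parse_month(row.test_date)
        if trait not in TRAITS:
            score = None
        elif continuous:
            score = float(row.score)
        else:
            score = _parse_score(row.score, trait)
        ok = (trait in TRAITS and sex is not None and birth is not None
              and test is not None and score is not None and test >= birth)
        if not ok:
            n_bad += 1
            continue
        records.append(ScoreRecord(
            dog_id=str(row.dog_id).strip(), breed=str(row.breed).strip(),
            sex=sex, birth_date=birth, test_date=test, trait=trait,
            score=float(score), sire_id=str(row.sire_id).strip(),
            dam_id=str(row.dam_id).strip()))
    if n_bad:
        logger.warning("skipped %d malformed registry rows", n_bad)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate ScoreRecords (or an already-tabular frame) for editing."""
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = [(r.dog_id, r.breed, r.sex, r.birth_date[0], r.birth_date[1],
             r.test_date[0], r.test_date[1], r.trait, r.score)
            for r in records]
    return pd.DataFrame(rows, columns=[
        "dog_id", "breed", "sex", "birth_year", "birth_month",
        "test_year", "test_month", "trait", "score"])


# ---------------------------------------------------------------------------
# editing


def assign_age_group(age_months: np.ndarray) -> np.ndarray:
    """Map months-at-scoring onto the four age-group labels."""
    age = np.asarray(age_months)
    bins = np.select(
        [age <= 24, age <= 29, age <= 36],
        [AGE_GROUP_LABELS[0], AGE_GROUP_LABELS[1], AGE_GROUP_LABELS[2]],
        default=AGE_GROUP_LABELS[3])
    return bins


def _breed_record_counts(frame: pd.DataFrame) -> pd.Series:
    """Hip+elbow record counts per breed, evaluated before other filters."""
    return frame.groupby("breed").size()


def _scores_are_ordinal(scores: np.ndarray) -> bool:
    return bool(np.allclose(scores, np.round(scores)))


def apply_hip_edits(records, config: EditConfig | None = None,
                    trait: str = HIP) -> TraitDataset:
    """Apply the standard registry edits and return the hip dataset.

    ``records`` may contain both traits; breed record counts are evaluated
    on the combined (hip + elbow) rows before any other filter, then the
    remaining rules run on this trait's rows in order: excluded/low-count
    breeds, age window, birth-year window, test-year window, last record
    per dog.  Each rule's removal count is logged and recorded.
    """
    config = config or EditConfig()
    frame = records_to_frame(records)
    audit: dict[str, int] = {}

    dup = frame.duplicated()
    audit["duplicate_rows"] = int(dup.sum())
    frame = frame[~dup]

    counts = _breed_record_counts(frame)
    low_breeds = set(counts.index[counts < config.min_breed_records])

    n_all = len(frame)
    frame = frame[frame["trait"] == trait]
    audit["other_trait_records"] = int(n_all - len(frame))
    n = len(frame)

    keep = ~frame["breed"].isin(set(config.excluded_breeds) | low_breeds)
    audit["breed_excluded_or_low_count"] = int(n - keep.sum())
    frame = frame[keep]

    age = ((frame["test_year"] - frame["birth_year"]) * 12
           + (frame["test_month"] - frame["birth_month"]))
    keep = (age >= config.min_age_months) & (age <= config.max_age_months)
    audit["age_outside_window"] = int(len(frame) - keep.sum())
    frame = frame.assign(age_months=age)[keep]

    keep = ((frame["birth_year"] >= config.min_birth_year)
            & (frame["birth_year"] <= config.max_birth_year))
    audit["birth_year_outside_window"] = int(len(frame) - keep.sum())
    frame = frame[keep]

    keep = ((frame["test_year"] >= config.min_test_year)
            & (frame["test_year"] <= config.max_test_year))
    audit["test_year_outside_window"] = int(len(frame) - keep.sum())
    frame = frame[keep]

    # last record per dog by test date; ties broken by file order (last wins)
    order = frame["test_year"] * 12 + frame["test_month"]
    frame = frame.assign(_order=order)
    ties = frame.duplicated(subset=["dog_id", "_order"], keep=False)
    if ties.any():
        logger.info("%d records tie on test date; keeping last in file order",
                    int(ties.sum()))
    frame = frame.sort_values("_order", kind="stable")
    first = frame.duplicated(subset="dog_id", keep="last")
    audit["earlier_record_superseded"] = int(first.sum())
    frame = frame[~first].drop(columns="_order")

    frame = frame.assign(age_group=assign_age_group(frame["age_months"]))
    frame = frame.sort_index().reset_index(drop=True)
    frame["value"] = frame["score"].astype(float)

    for rule, removed in audit.items():
        if removed:
            logger.info("%s edit %s removed %d records", trait, rule, removed)
    return TraitDataset(trait=trait, data=frame, audit=audit)


def apply_elbow_edits(records, config: EditConfig | None = None) -> TraitDataset:
    """Elbow edits: hip rules plus breed variation / dysplastic-count
    thresholds and the birth-year floor (pre-1988 grouped into 1988)."""
    config = config or EditConfig()
    dataset = apply_hip_edits(records, config, trait=ELBOW)
    frame, audit = dataset.data, dataset.audit

    scores = frame["score"].to_numpy(float)
    if _scores_are_ordinal(scores) and len(frame):
        by_breed = frame.groupby("breed")["score"]
        variation = by_breed.nunique()
        n_ed = by_breed.apply(
            lambda s: int(s.isin(ELBOW_DYSPLASTIC_CODES).sum()))
        bad = set(variation.index[variation < 2]) | set(
            n_ed.index[n_ed < config.min_ed_dogs])
        keep = ~frame["breed"].isin(bad)
        audit["breed_no_variation_or_few_ed_dogs"] = int(len(frame) - keep.sum())
        frame = frame[keep].reset_index(drop=True)
    else:
        # continuous (liability-scale) responses carry no ordinal categories
        audit["breed_no_variation_or_few_ed_dogs"] = 0
        if len(frame):
            logger.info("elbow scores are continuous; breed variation/ED-count "
                        "rules skipped")

    floored = int((frame["birth_year"] < config.elbow_birth_year_floor).sum())
    if floored:
        logger.info("floored %d elbow birth years to %d", floored,
                    config.elbow_birth_year_floor)
    frame = frame.assign(birth_year=frame["birth_year"].clip(
        lower=config.elbow_birth_year_floor))
    return TraitDataset(trait=ELBOW, data=frame, audit=audit)


# ---------------------------------------------------------------------------
# transformations and dichotomization


def transform_elbow(scores, kind: str):
    """Elementwise transformation of (elbow) scores.

    ``kind`` is one of identity / log / sqrt / reciprocal.  The reciprocal
    reverses score ordering (4 -> 0.25 < 1 -> 1.0), which flips the sign of
    any covariance with the untransformed hip score.
    """
    arr = np.asarray(scores, dtype=float)
    if kind not in ELBOW_TRANSFORMS:
        raise ValueError(f"unknown transformation {kind!r}")
    if kind == "identity":
        return arr.copy()
    if np.any(arr <= 0):
        raise ValueError("scores must be positive for transformation")
    if kind == "log":
        return np.log(arr)
    if kind == "sqrt":
        return np.sqrt(arr)
    return 1.0 / arr


@dataclass(frozen=True)
class Incidence:
    n_total: int
    n_dysplastic: int

    @property
    def proportion(self) -> float:
        return self.n_dysplastic / self.n_total


def dichotomize(dataset: TraitDataset) -> Incidence:
    """Dysplastic count and proportion for an edited dataset.

    Hip scores 5-7 (mild/moderate/severe) are dysplastic; borderline (4)
    counts in neither class.  Elbow scores 2-4 are dysplastic.
    """
    if dataset.n_records == 0:
        raise ValueError("incidence is undefined for an empty dataset")
    scores = dataset.data["score"].to_numpy(float)
    if not _scores_are_ordinal(scores):
        raise ValueError("dichotomization requires ordinal score codes")
    codes = (HIP_DYSPLASTIC_CODES if dataset.trait == HIP
             else ELBOW_DYSPLASTIC_CODES)
    n_dys = int(np.isin(scores.astype(int), sorted(codes)).sum())
    return Incidence(n_total=len(scores), n_dysplastic=n_dys)
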