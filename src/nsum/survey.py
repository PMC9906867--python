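"""Respondent- and alter-level survey records: domain types, validation, CSV I/O.

The network scale-up method (NSUM) works from *aggregated relational data*:
each respondent reports how many members of a hidden population (here,
female sex workers, FSWs) they know within their personal network.  This
module defines the two record types such a survey produces — one row per
respondent (with the alter count ``m``) and, optionally, one row per
reported alter (with the alter's demographics) — together with strict,
row-addressed CSV parsing and the frequency/percentage tabulation used for
descriptive tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Gender",
    "AgeGroup",
    "Education",
    "MaritalStatus",
    "AlterMaritalStatus",
    "NChildren",
    "SurveyRespondent",
    "AlterRecord",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "read_alters",
    "write_alters",
    "summarize_demographics",
]


class SurveyValidationError(ValueError):
    """Raised when a survey table violates the schema or a record contract.

    The message lists every offending row (1-based, excluding the header) so
    a data manager can fix the file in one pass.
    """


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class AgeGroup(str, enum.Enum):
    A18_29 = "18-29"
    A30_44 = "30-44"
    A45_65 = "45-65"


class Education(str, enum.Enum):
    ILLITERATE = "illiterate"
    ELEMENTARY = "elementary"
    GUIDANCE = "guidance"
    DIPLOMA_PLUS = "diploma_plus"


class MaritalStatus(str, enum.Enum):
    """Respondent marital status (divorced and widowed pooled at collection)."""

    SINGLE = "single"
    MARRIED = "married"
    DIVORCED_WIDOW = "divorced_widow"


class AlterMaritalStatus(str, enum.Enum):
    """Alter marital status; divorced and widowed reported separately."""

    SINGLE = "single"
    MARRIED = "married"
    DIVORCED = "divorced"
    WIDOW = "widow"


class NChildren(str, enum.Enum):
    NONE = "0"
    ONE = "1"
    TWO = "2"
    THREE_PLUS = "3_plus"


#: normalisation aliases accepted on input (case-insensitive, en-dash tolerant)
_ALIASES: dict[type[enum.Enum], dict[str, str]] = {
    Gender: {"m": "male", "f": "female", "man": "male", "woman": "female"},
    AgeGroup: {"18–29": "18-29", "30–44": "30-44", "45–65": "45-65"},
    Education: {
        "diploma": "diploma_plus",
        "diploma+": "diploma_plus",
        "diploma & higher": "diploma_plus",
        "diploma_and_higher": "diploma_plus",
    },
    MaritalStatus: {
        "divorced/widow": "divorced_widow",
        "divorced": "divorced_widow",
        "widow": "divorced_widow",
    },
    AlterMaritalStatus: {},
    NChildren: {"no_child": "0", "none": "0", "one": "1", "two": "2",
                ">=3": "3_plus", "3+": "3_plus", "three_plus": "3_plus"},
}


def _parse_enum(cls: type[enum.Enum], raw: object) -> enum.Enum | None:
    """Normalise a raw CSV cell into an enum member, or None if blank."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip().lower().replace("–", "-")
    if text in ("", "na", "nan"):
        return None
    text = _ALIASES.get(cls, {}).get(text, text)
    for member in cls:
        if member.value == text:
            return member
    raise ValueError(f"{text!r} is not a valid {cls.__name__}")


def _parse_bool(raw: object) -> bool | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip().lower()
    if text in ("", "na", "nan"):
        return None
    if text in ("1", "true", "yes", "y"):
        return True
    if text in ("0", "false", "no", "n"):
        return False
    raise ValueError(f"{text!r} is not a boolean")


@dataclass(frozen=True)
class SurveyRespondent:
    """One interviewee and the count of hidden-population alters they report.

    Parameters
    ----------
    id : str
        Opaque respondent identifier, unique within a survey.
    gender : Gender
        Determines which personal network size (degree) applies in the
        scale-up ratio.
    m : int
        Number of FSW alters the respondent reports knowing (``m_i`` in the
        scale-up formula).  Must be a non-negative integer.
    age_group, education, marital_status : optional
        Demographics used only for descriptive tabulation.
    """

    id: str
    gender: Gender
    m: int
    age_group: AgeGroup | None = None
    education: Education | None = None
    marital_status: MaritalStatus | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.m, int) or isinstance(self.m, bool):
            raise SurveyValidationError(f"respondent {self.id!r}: m must be an integer")
        if self.m < 0:
            raise SurveyValidationError(f"respondent {self.id!r}: m must be >= 0, got {self.m}")
        if not isinstance(self.gender, Gender):
            raise SurveyValidationError(f"respondent {self.id!r}: invalid gender")


@dataclass(frozen=True)
class AlterRecord:
    """Demographics of one reported FSW alter, linked to its respondent."""

    respondent_id: str
    age_group: AgeGroup | None = None
    education: Education | None = None
    marital_status: AlterMaritalStatus | None = None
    n_children: NChildren | None = None
    ever_alcohol: bool | None = None
    ever_prison: bool | None = None
    ever_drug: bool | None = None


#: canonical column order written by :func:`write_survey`
RESPONDENT_COLUMNS = ("id", "gender", "age_group", "education", "marital_status", "m")
#: canonical column order written by :func:`write_alters`
ALTER_COLUMNS = (
    "respondent_id", "age_group", "education", "marital_status",
    "n_children", "ever_alcohol", "ever_prison", "ever_drug",
)


def read_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[SurveyRespondent]:
    """Read a respondent-level CSV into validated :class:`SurveyRespondent` records.

    Parameters
    ----------
    path : path-like
        UTF-8 comma-separated file with a header row.
    schema : mapping, optional
        Maps canonical column names (``id``, ``gender``, ``m``, ...) to the
        names actually used in the file, for surveys exported under
        different headers.

    Raises
    ------
    SurveyValidationError
        If a required column is missing, or any row fails validation.  All
        bad rows are reported together.
    """
    df = pd.read_csv(path, dtype=str)
    return respondents_from_dataframe(df, schema=schema)


def respondents_from_dataframe(
    df: pd.DataFrame, schema: Mapping[str, str] | None = None
) -> list[SurveyRespondent]:
    """Validate a DataFrame of respondents (see :func:`read_survey`)."""
    colmap = {name: (schema or {}).get(name, name) for name in RESPONDENT_COLUMNS}
    missing = [colmap[c] for c in ("id", "gender", "m") if colmap[c] not in df.columns]
    if missing:
        raise SurveyValidationError(f"missing required column(s): {', '.join(missing)}")

    records: list[SurveyRespondent] = []
    errors: list[str] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            raw_m = row[colmap["m"]]
            m_float = float(raw_m)
            if not m_float.is_integer():
                raise ValueError(f"m={raw_m!r} is not an integer")
            records.append(
                SurveyRespondent(
                    id=str(row[colmap["id"]]),
                    gender=_parse_enum(Gender, row[colmap["gender"]]),
                    m=int(m_float),
                    age_group=_parse_enum(AgeGroup, row.get(colmap["age_group"])),
                    education=_parse_enum(Education, row.get(colmap["education"])),
                    marital_status=_parse_enum(MaritalStatus, row.get(colmap["marital_status"])),
                )
            )
        except (ValueError, SurveyValidationError) as exc:
            errors.append(f"row {pos}: {exc}")
    if errors:
        raise SurveyValidationError("invalid survey rows:\n" + "\n".join(errors))
    return records


def write_survey(respondents: Sequence[SurveyRespondent], path: str | Path) -> None:
    """Write respondents to CSV in the canonical column order.

    ``read_survey(write_survey(x))`` is the identity for valid records.
    """
    if not respondents:
        raise ValueError("cannot write an empty respondent list")
    rows = [
        {
            "id": r.id,
            "gender": r.gender.value,
            "age_group": r.age_group.value if r.age_group else "",
            "education": r.education.value if r.education else "",
            "marital_status": r.marital_status.value if r.marital_status else "",
            "m": r.m,
        }
        for r in respondents
    ]
    pd.DataFrame(rows, columns=list(RESPONDENT_COLUMNS)).to_csv(path, index=False)


def read_alters(
    path: str | Path,
    respondents: Sequence[SurveyRespondent] | None = None,
) -> list[AlterRecord]:
    """Read an alter-level CSV; cross-check against respondents when given.

    When ``respondents`` is supplied, every ``respondent_id`` must exist in
    the respondent table and no respondent may have more alter rows than
    their reported count ``m``.
    """
    df = pd.read_csv(path, dtype=str)
    if "respondent_id" not in df.columns:
        raise SurveyValidationError("missing required column(s): respondent_id")
    records: list[AlterRecord] = []
    errors: list[str] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(
                AlterRecord(
                    respondent_id=str(row["respondent_id"]),
                    age_group=_parse_enum(AgeGroup, row.get("age_group")),
                    education=_parse_enum(Education, row.get("education")),
                    marital_status=_parse_enum(AlterMaritalStatus, row.get("marital_status")),
                    n_children=_parse_enum(NChildren, row.get("n_children")),
                    ever_alcohol=_parse_bool(row.get("ever_alcohol")),
                    ever_prison=_parse_bool(row.get("ever_prison")),
                    ever_drug=_parse_bool(row.get("ever_drug")),
                )
            )
        except ValueError as exc:
            errors.append(f"row {pos}: {exc}")
    if errors:
        raise SurveyValidationError("invalid alter rows:\n" + "\n".join(errors))
    if respondents is not None:
        by_id = {r.id: r.m for r in respondents}
        counts: dict[str, int] = {}
        for rec in records:
            if rec.respondent_id not in by_id:
                errors.append(f"unknown respondent_id {rec.respondent_id!r}")
            counts[rec.respondent_id] = counts.get(rec.respondent_id, 0) + 1
        for rid, k in counts.items():
            if rid in by_id and k > by_id[rid]:
                errors.append(f"respondent {rid!r} has {k} alter rows but reported m={by_id[rid]}")
        if errors:
            raise SurveyValidationError("alter/respondent mismatch:\n" + "\n".join(errors))
    return records


def write_alters(alters: Sequence[AlterRecord], path: str | Path) -> None:
    """Write alter records to CSV in the canonical column order."""
    if not alters:
        raise ValueError("cannot write an empty alter list")

    def cell(v: object) -> object:
        if v is None:
            return ""
        if isinstance(v, enum.Enum):
            return v.value
        if isinstance(v, bool):
            return str(v).lower()
        return v

    rows = [{c: cell(getattr(a, c)) for c in ALTER_COLUMNS} for a in alters]
    pd.DataFrame(rows, columns=list(ALTER_COLUMNS)).to_csv(path, index=False)


def summarize_demographics(
    records: Sequence[SurveyRespondent] | Sequence[AlterRecord],
    variables: Iterable[str],
    percent_denominator: str = "all",
) -> pd.DataFrame:
    """Frequency/percentage table over categorical variables.

    Parameters
    ----------
    records : sequence of SurveyRespondent or AlterRecord
    variables : iterable of str
        Field names to tabulate (e.g. ``["gender", "age_group"]``).
    percent_denominator : {"all", "nonmissing"}
        Whether percentages are taken against the full record count
        (default; matches how the source tables are computed) or only the
        records with a non-missing value for the variable.

    Returns
    -------
    DataFrame indexed by (variable, category) with columns ``count`` and
    ``percent``.  Percentages are kept at full precision; round at display.
    """
    if percent_denominator not in ("all", "nonmissing"):
        raise ValueError("percent_denominator must be 'all' or 'nonmissing'")
    if not records:
        raise ValueError("no records to summarize")
    valid_fields = {f.name for f in fields(type(records[0]))}
    rows = []
    n_all = len(records)
    for var in variables:
        if var not in valid_fields:
            raise ValueError(f"unknown variable {var!r} for {type(records[0]).__name__}")
        values = [getattr(r, var) for r in records]
        nonmissing = [v for v in values if v is not None]
        denom = n_all if percent_denominator == "all" else max(len(nonmissing), 1)
        # preserve enum declaration order; booleans tabulated as yes/no
        sample = next((v for v in nonmissing), None)
        if isinstance(sample, enum.Enum):
            categories = [member for member in type(sample)]
            labels = [member.value for member in categories]
        elif isinstance(sample, bool) or sample is None:
            categories = [True, False]
            labels = ["yes", "no"]
        else:  # pragma: no cover - record types only hold enums/bools
            categories = sorted(set(nonmissing))
            labels = [str(c) for c in categories]
        for cat, label in zip(categories, labels):
            count = sum(1 for v in nonmissing if v == cat)
            rows.append(
                {"variable": var, "category": label, "count": count,
                 "percent": 100.0 * count / denom}
            )
    return pd.DataFrame(rows).set_index(["variable", "category"])
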