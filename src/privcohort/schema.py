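"""Cohort schema: typed attribute declarations and the tabular container.

A cohort is a flat table with one row per individual.  Every attribute
carries a semantic type (how values are represented and transformed) and a
role (which analysis stage consumes it).  The default schema emulates a
small, high-dimensional health-claims extract: demographics, a block of
binary comorbidity flags, study bookkeeping (treatment arm, anchor dates,
exposure durations) and rare time-to-event outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
import yaml

# Semantic types ------------------------------------------------------------

AGE = "integer-age-years"
CATEGORICAL = "categorical"
BINARY = "binary-flag"
DATE = "date"
DAY_OFFSET = "day-offset"
EVENT_TIME = "event-time-days"

SEMANTIC_TYPES = {AGE, CATEGORICAL, BINARY, DATE, DAY_OFFSET, EVENT_TIME}

# Roles ---------------------------------------------------------------------

DEMOGRAPHIC = "demographic"
COMORBIDITY = "comorbidity"
STUDY_INFO = "study-info"
OUTCOME = "outcome"

ROLES = {DEMOGRAPHIC, COMORBIDITY, STUDY_INFO, OUTCOME}


@dataclass(frozen=True)
class Attribute:
    """One column of a cohort.

    ``standin`` marks attribute names invented for the stand-in schema (the
    real attribute inventory is not public); paper-named attributes carry
    ``standin=False``.
    """

    name: str
    semantic_type: str
    role: str
    standin: bool = True

    def __post_init__(self) -> None:
        if self.semantic_type not in SEMANTIC_TYPES:
            raise ValueError(f"unknown semantic type {self.semantic_type!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class CohortSchema:
    """Ordered attribute list plus treatment-arm metadata.

    ``event_pairs`` maps each outcome event flag to its paired
    time-to-event attribute (observed follow-up time in days).
    """

    attributes: list[Attribute]
    treatment_column: str
    group_labels: tuple[str, str]  # (exposed, comparator)
    event_pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate attribute names: {dupes}")
        if self.treatment_column not in names:
            raise ValueError(f"treatment column {self.treatment_column!r} not in schema")
        for flag, time_attr in self.event_pairs.items():
            if flag not in names or time_attr not in names:
                raise ValueError(f"event pair ({flag}, {time_attr}) not in schema")

    # -- convenience views ---------------------------------------------

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def by_role(self, role: str) -> list[Attribute]:
        return [a for a in self.attributes if a.role == role]

    def by_type(self, semantic_type: str) -> list[Attribute]:
        return [a for a in self.attributes if a.semantic_type == semantic_type]

    def to_yaml(self, path: str) -> None:
        payload = {
            "attributes": [
                {
                    "name": a.name,
                    "semantic_type": a.semantic_type,
                    "role": a.role,
                    "standin": a.standin,
                }
                for a in self.attributes
            ],
            "treatment_column": self.treatment_column,
            "group_labels": list(self.group_labels),
            "event_pairs": dict(self.event_pairs),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            attributes=[Attribute(**a) for a in payload["attributes"]],
            treatment_column=payload["treatment_column"],
            group_labels=tuple(payload["group_labels"]),
            event_pairs=dict(payload.get("event_pairs", {})),
        )


@dataclass
class CohortTable:
    """A schema-conforming cohort: one row per individual."""

    schema: CohortSchema
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [n for n in self.schema.names if n not in self.df.columns]
        if missing:
            raise ValueError(f"table missing schema attributes: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str) -> None:
        # empty field == missing marker
        self.df.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path: str, schema: CohortSchema) -> "CohortTable":
        df = read_cohort_csv(path, schema)
        return cls(schema=schema, df=df)


def read_cohort_csv(path: str, schema: CohortSchema | None = None) -> pd.DataFrame:
    """Read a cohort CSV, casting columns per the schema's semantic types."""
    df = pd.read_csv(path, keep_default_na=True)
    if schema is None:
        return df
    for a in schema.attributes:
        if a.name not in df.columns:
            continue  # suppressed attribute
        col = df[a.name]
        if a.semantic_type in (AGE, DAY_OFFSET, EVENT_TIME, BINARY):
            df[a.name] = pd.to_numeric(col, errors="coerce")
        elif a.semantic_type == DATE:
            df[a.name] = col.astype("string")
    return df


def iter_event_pairs(schema: CohortSchema) -> Iterable[tuple[str, str]]:
    return schema.event_pairs.items()
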