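"""Attribute-level threat modeling.

Every non-directly-identifying attribute is rated 1-3 (low/medium/high) on
three re-identification dimensions:

* replicability  — how stable the value is for an individual over time,
* availability   — how plausibly an adversary can obtain it elsewhere,
* distinguishability — how strongly it can single out individuals.

The three ratings are summed; attributes at or above a threshold become
indirect identifiers (quasi-identifiers).  Remaining attributes whose
disclosure could cause harm are sensitive; the rest are insensitive.
Ratings and the threshold are expert inputs; the bundled defaults cover the
stand-in schema and reproduce a 1 direct / 10 indirect / 5 sensitive split.
"""

from __future__ import annotations


from dataclasses import dataclass

import yaml

from .schema import CohortSchema

DIRECT = "direct"
INDIRECT = "indirect"
SENSITIVE = "sensitive"
INSENSITIVE = "insensitive"

DEFAULT_THRESHOLD = 7

_RATING_VALUES = {1, 2, 3}


@dataclass(frozen=True)
class AttributeProfile:
    name: str
    is_direct_identifier: bool = False
    replicability: int | None = None
    availability: int | None = None
    distinguishability: int | None = None
    is_sensitive: bool = False

    def __post_init__(self) -> None:
        ratings = (self.replicability, self.availability, self.distinguishability)
        if self.is_direct_identifier:
            if any(r is not None for r in ratings):
                raise ValueError(
                    f"{self.name}: direct identifiers bypass scoring, drop ratings"
                )
        else:
            if any(r not in _RATING_VALUES for r in ratings):
                raise ValueError(f"{self.name}: ratings must all be in {{1,2,3}}")


@dataclass
class Classification:
    classes: dict[str, str]  # attribute name -> class
    threshold: int

    def of(self, kind: str) -> list[str]:
        return [n for n, c in self.classes.items() if c == kind]

    def counts(self) -> dict[str, int]:
        return {k: len(self.of(k)) for k in (DIRECT, INDIRECT, SENSITIVE, INSENSITIVE)}


def score_attribute(profile: AttributeProfile) -> int:
    """Sum of the three ratings, in [3, 9]."""
    if profile.is_direct_identifier:
        raise ValueError(f"{profile.name} is a direct identifier and bypasses scoring")
    return profile.replicability + profile.availability + profile.distinguishability


def classify(
    profiles: list[AttributeProfile],
    threshold: int = DEFAULT_THRESHOLD,
    schema: CohortSchema | None = None,
) -> Classification:
    """Assign each profiled attribute to exactly one of the four classes.

    Precedence: direct flag, then score >= threshold (indirect), then the
    sensitivity flag, else insensitive.  When a schema is given, every
    schema attribute must be profiled.
    """
    if schema is not None:
        profiled = {p.name for p in profiles}
        missing = [n for n in schema.names if n not in profiled]
        if missing:
            raise ValueError(f"no threat profile for schema attributes: {missing}")
    classes: dict[str, str] = {}
    for p in profiles:
        if p.is_direct_identifier:
            classes[p.name] = DIRECT
        elif score_attribute(p) >= threshold:
            classes[p.name] = INDIRECT
        elif p.is_sensitive:
            classes[p.name] = SENSITIVE
        else:
            classes[p.name] = INSENSITIVE
    return Classification(classes=classes, threshold=threshold)


def default_profiles() -> list[AttributeProfile]:
    """Bundled expert ratings for the stand-in schema.

    Demographics and all date/offset/duration bookkeeping rate high on
    availability or distinguishability (indirect identifiers); chronic
    comorbidity flags are replicable but poorly distinguishing; mortality,
    bleeding and two medication flags proxying sensitive conditions carry
    the sensitivity mark.
    """
    P = AttributeProfile
    profiles = [
        P("patient_pseudonym", is_direct_identifier=True),
        # indirect identifiers (score >= 7)
        P("age", replicability=3, availability=3, distinguishability=2),
        P("gender", replicability=3, availability=3, distinguishability=1),
        P("birth_quarter", replicability=3, availability=3, distinguishability=2),
        P("first_vte_date", replicability=3, availability=2, distinguishability=3),
        P("index_date", replicability=3, availability=2, distinguishability=3),
        P("followup_end_date", replicability=2, availability=2, distinguishability=3),
        P("index_offset_days", replicability=2, availability=2, distinguishability=3),
        P("followup_end_offset_days", replicability=2, availability=2, distinguishability=3),
        P("anticoagulant_exposure_days", replicability=2, availability=2, distinguishability=3),
        P("antiplatelet_exposure_days", replicability=2, availability=2, distinguishability=3),
        # sensitive attributes
        P("liver_disease_mod_severe", replicability=3, availability=2,
          distinguishability=1, is_sensitive=True),
        P("oral_contraception", replicability=2, availability=2,
          distinguishability=1, is_sensitive=True),
        P("tamoxifen", replicability=2, availability=2,
          distinguishability=1, is_sensitive=True),
        P("death_flag", replicability=2, availability=2,
          distinguishability=1, is_sensitive=True),
        P("major_bleeding_flag", replicability=2, availability=2,
          distinguishability=1, is_sensitive=True),
        # insensitive study bookkeeping
        P("treatment_group", replicability=2, availability=2, distinguishability=1),
        P("censoring_flag", replicability=1, availability=1, distinguishability=1),
        P("death_time_days", replicability=1, availability=1, distinguishability=3),
        P("major_bleeding_time_days", replicability=1, availability=1, distinguishability=3),
        P("rehospitalization_flag", replicability=2, availability=1, distinguishability=1),
        P("rehospitalization_time_days", replicability=1, availability=1, distinguishability=3),
    ]
    done = {p.name for p in profiles}
    from .cohort import COMORBIDITY_FLAGS

    for name in COMORBIDITY_FLAGS:
        if name not in done:
            profiles.append(
                P(name, replicability=3, availability=2, distinguishability=1)
            )
    return profiles


def load_profiles(path: str) -> tuple[list[AttributeProfile], int | None]:
    """Read a YAML profile file: a list of rating entries plus an optional
    top-level threshold."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if isinstance(payload, dict):
        entries = payload["profiles"]
        threshold = payload.get("threshold")
    else:
        entries, threshold = payload, None
    profiles = [
        AttributeProfile(
            name=e["name"],
            is_direct_identifier=bool(e.get("direct", False)),
            replicability=e.get("replicability"),
            availability=e.get("availability"),
            distinguishability=e.get("distinguishability"),
            is_sensitive=bool(e.get("sensitive", False)),
        )
        for e in entries
    ]
    return profiles, threshold


def save_profiles(
    profiles: list[AttributeProfile], path: str, threshold: int | None = None
) -> None:
    entries = []
    for p in profiles:
        e: dict = {"name": p.name}
        if p.is_direct_identifier:
            e["direct"] = True
        else:
            e.update(
                replicability=p.replicability,
                availability=p.availability,
                distinguishability=p.distinguishability,
            )
            if p.is_sensitive:
                e["sensitive"] = True
        entries.append(e)
    payload: dict = {"profiles": entries}
    if threshold is not None:
        payload["threshold"] = threshold
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
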