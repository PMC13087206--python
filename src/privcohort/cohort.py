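"""Seeded generation of synthetic health-claims cohorts.

The generator emulates a small anticoagulation-safety cohort: adults with a
first venous thromboembolism (VTE) who start either a direct oral
anticoagulant (DOAC, exposed arm) or a vitamin K antagonist (VKA,
comparator arm).  Records carry demographics, correlated rare binary
comorbidity flags (latent Gaussian-threshold model), calendar dates anchored
on the first-VTE diagnosis, and right-censored exponential time-to-event
outcomes (all-cause death, major bleeding, rehospitalization).

Defaults are calibrated to the magnitudes of the emulated study population:
1727 records, a ~71.5/28.5 DOAC/VKA split, mean age ~74.7 (SD ~11.7),
~43% female, and tens of death/bleeding events per arm with a per-arm
hazard ratio of ~1.25.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .schema import (
    AGE,
    BINARY,
    CATEGORICAL,
    COMORBIDITY,
    DATE,
    DAY_OFFSET,
    DEMOGRAPHIC,
    EVENT_TIME,
    OUTCOME,
    STUDY_INFO,
    Attribute,
    CohortSchema,
    CohortTable,
)

EXPOSED = "DOAC"
COMPARATOR = "VKA"

# Comorbidity flags whose names come from the emulated study's figures; the
# remainder are documented stand-ins completing the 20-flag block.
_NAMED_FLAGS = [
    "arterial_hypertension",
    "varicose_veins_pts",
    "stroke",
    "liver_disease_mod_severe",
    "obesity",
    "myocardial_infarction",
    "oral_contraception",
    "tamoxifen",
]
_STANDIN_FLAGS = [
    "diabetes_mellitus",
    "chronic_heart_failure",
    "chronic_kidney_disease",
    "copd",
    "active_cancer",
    "atrial_fibrillation",
    "peptic_ulcer_disease",
    "anemia",
    "dementia",
    "rheumatic_disease",
    "prior_major_bleeding",
    "thrombophilia",
]
COMORBIDITY_FLAGS = _NAMED_FLAGS + _STANDIN_FLAGS


def default_schema() -> CohortSchema:
    """The fixed 39-attribute stand-in schema.

    3 demographic + 20 comorbidity + 9 study-info + 7 outcome attributes.
    ``patient_pseudonym`` stands in for the hash-based insured-person
    pseudonym that a claims extract carries (the schema's only direct
    identifier).
    """
    attrs: list[Attribute] = [
        Attribute("age", AGE, DEMOGRAPHIC, standin=False),
        Attribute("gender", CATEGORICAL, DEMOGRAPHIC, standin=False),
        Attribute("birth_quarter", DATE, DEMOGRAPHIC, standin=False),
    ]
    for name in _NAMED_FLAGS:
        attrs.append(Attribute(name, BINARY, COMORBIDITY, standin=False))
    for name in _STANDIN_FLAGS:
        attrs.append(Attribute(name, BINARY, COMORBIDITY, standin=True))
    attrs += [
        Attribute("patient_pseudonym", CATEGORICAL, STUDY_INFO),
        Attribute("treatment_group", CATEGORICAL, STUDY_INFO, standin=False),
        Attribute("first_vte_date", DATE, STUDY_INFO, standin=False),
        Attribute("index_date", DATE, STUDY_INFO, standin=False),
        Attribute("followup_end_date", DATE, STUDY_INFO, standin=False),
        Attribute("index_offset_days", DAY_OFFSET, STUDY_INFO),
        Attribute("followup_end_offset_days", DAY_OFFSET, STUDY_INFO),
        Attribute("anticoagulant_exposure_days", DAY_OFFSET, STUDY_INFO),
        Attribute("antiplatelet_exposure_days", DAY_OFFSET, STUDY_INFO),
        Attribute("death_flag", BINARY, OUTCOME, standin=False),
        Attribute("death_time_days", EVENT_TIME, OUTCOME, standin=False),
        Attribute("major_bleeding_flag", BINARY, OUTCOME, standin=False),
        Attribute("major_bleeding_time_days", EVENT_TIME, OUTCOME, standin=False),
        Attribute("rehospitalization_flag", BINARY, OUTCOME),
        Attribute("rehospitalization_time_days", EVENT_TIME, OUTCOME),
        Attribute("censoring_flag", BINARY, OUTCOME),
    ]
    return CohortSchema(
        attributes=attrs,
        treatment_column="treatment_group",
        group_labels=(EXPOSED, COMPARATOR),
        event_pairs={
            "death_flag": "death_time_days",
            "major_bleeding_flag": "major_bleeding_time_days",
            "rehospitalization_flag": "rehospitalization_time_days",
        },
    )


def _default_prevalences() -> dict[str, tuple[float, float]]:
    """Per-flag (exposed, comparator) prevalences.

    Chronic cardiometabolic flags are common; obesity and tamoxifen are
    deliberately rare (a handful of cases in ~1700 records) so that
    protection methods visibly erase them, as happens with real rare flags.
    """
    return {
        "arterial_hypertension": (0.72, 0.78),
        "varicose_veins_pts": (0.10, 0.08),
        "stroke": (0.09, 0.12),
        "liver_disease_mod_severe": (0.015, 0.02),
        "obesity": (0.002, 0.002),
        "myocardial_infarction": (0.08, 0.10),
        "oral_contraception": (0.02, 0.01),
        "tamoxifen": (0.006, 0.006),
        "diabetes_mellitus": (0.30, 0.36),
        "chronic_heart_failure": (0.22, 0.30),
        "chronic_kidney_disease": (0.25, 0.32),
        "copd": (0.15, 0.18),
        "active_cancer": (0.12, 0.15),
        "atrial_fibrillation": (0.18, 0.35),
        "peptic_ulcer_disease": (0.04, 0.05),
        "anemia": (0.12, 0.15),
        "dementia": (0.08, 0.10),
        "rheumatic_disease": (0.05, 0.05),
        "prior_major_bleeding": (0.06, 0.07),
        "thrombophilia": (0.05, 0.04),
    }


def default_flag_correlation() -> np.ndarray:
    """Latent correlation: exchangeable 0.15 within the cardiometabolic
    cluster, independence elsewhere (positive semi-definite by block
    construction)."""
    n = len(COMORBIDITY_FLAGS)
    corr = np.eye(n)
    cluster = [
        "arterial_hypertension",
        "stroke",
        "myocardial_infarction",
        "diabetes_mellitus",
        "chronic_heart_failure",
        "chronic_kidney_disease",
        "atrial_fibrillation",
        "anemia",
    ]
    idx = [COMORBIDITY_FLAGS.index(c) for c in cluster]
    for i in idx:
        for j in idx:
            if i != j:
                corr[i, j] = 0.15
    return corr


@dataclass
class CohortGenConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_records: int = 1727
    group_probability: float = 0.715  # P(exposed arm)
    age_mean: float = 74.7
    age_sd: float = 11.67
    age_bounds: tuple[int, int] = (18, 108)
    female_probability: dict[str, float] = field(
        default_factory=lambda: {EXPOSED: 0.445, COMPARATOR: 0.405}
    )
    comorbidity_prevalences: dict[str, tuple[float, float]] = field(
        default_factory=_default_prevalences
    )
    flag_correlation: np.ndarray = field(default_factory=default_flag_correlation)
    # events/day, (exposed, comparator); exposed/comparator ratio ~1.25
    outcome_hazards: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "death": (1.25e-4, 1.0e-4),
            "major_bleeding": (9.5e-5, 7.6e-5),
            "rehospitalization": (6.25e-4, 5.0e-4),
        }
    )
    censoring_rate: float = 1.0e-3  # events/day
    admin_followup_days: int = 365
    date_anchor_window: tuple[str, str] = ("2016-01-01", "2018-12-31")
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 2:
            raise ValueError("n_records must be >= 2")
        probs = [self.group_probability, *self.female_probability.values()]
        for p_pair in self.comorbidity_prevalences.values():
            probs.extend(p_pair)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        corr = np.asarray(self.flag_correlation, dtype=float)
        k = len(self.comorbidity_prevalences)
        if corr.shape != (k, k):
            raise ValueError(f"flag_correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T):
            raise ValueError("flag_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("flag_correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("flag_correlation must be positive semi-definite")
        for rates in self.outcome_hazards.values():
            if any(r <= 0 for r in rates):
                raise ValueError("outcome hazards must be > 0")
        if self.censoring_rate <= 0:
            raise ValueError("censoring rate must be > 0")

    def to_yaml(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        payload["flag_correlation"] = np.asarray(self.flag_correlation).tolist()
        payload["comorbidity_prevalences"] = {
            k: list(v) for k, v in self.comorbidity_prevalences.items()
        }
        payload["outcome_hazards"] = {k: list(v) for k, v in self.outcome_hazards.items()}
        payload["age_bounds"] = list(self.age_bounds)
        payload["date_anchor_window"] = list(self.date_anchor_window)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortGenConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["flag_correlation"] = np.asarray(payload["flag_correlation"], dtype=float)
        payload["comorbidity_prevalences"] = {
            k: tuple(v) for k, v in payload["comorbidity_prevalences"].items()
        }
        payload["outcome_hazards"] = {
            k: tuple(v) for k, v in payload["outcome_hazards"].items()
        }
        payload["age_bounds"] = tuple(payload["age_bounds"])
        payload["date_anchor_window"] = tuple(payload["date_anchor_window"])
        payload["female_probability"] = dict(payload["female_probability"])
        return cls(**payload)


def generate_cohort(config: CohortGenConfig) -> CohortTable:
    """Draw a cohort; deterministic given ``config.seed``."""
    config.validate()
    schema = default_schema()
    rng = np.random.default_rng(config.seed)
    n = config.n_records

    exposed = rng.random(n) < config.group_probability
    group = np.where(exposed, EXPOSED, COMPARATOR)

    age = np.rint(rng.normal(config.age_mean, config.age_sd, n))
    age = np.clip(age, *config.age_bounds).astype(int)

    p_female = np.where(
        exposed,
        config.female_probability[EXPOSED],
        config.female_probability[COMPARATOR],
    )
    gender = np.where(rng.random(n) < p_female, "F", "M")

    # correlated binary flags: latent Gaussian threshold per group-specific
    # prevalence; shared latent draw carries the correlation
    flags = list(config.comorbidity_prevalences)
    corr = np.asarray(config.flag_correlation, dtype=float)
    # eigendecomposition handles PSD (possibly singular) targets
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, len(flags))) @ root.T
    flag_values = {}
    for j, name in enumerate(flags):
        p_exp, p_cmp = config.comorbidity_prevalences[name]
        thresh = np.where(exposed, stats.norm.ppf(p_exp), stats.norm.ppf(p_cmp))
        flag_values[name] = (z[:, j] < thresh).astype(int)

    # dates anchored on the first-VTE diagnosis
    lo = np.datetime64(config.date_anchor_window[0])
    hi = np.datetime64(config.date_anchor_window[1])
    window = int((hi - lo) / np.timedelta64(1, "D"))
    first_vte = lo + rng.integers(0, window + 1, n).astype("timedelta64[D]")
    index_offset = rng.integers(0, 31, n)  # treatment start within a month
    index_date = first_vte + index_offset.astype("timedelta64[D]")

    # follow-up: exponential censoring truncated by administrative end
    censor = np.minimum(
        rng.exponential(1.0 / config.censoring_rate, n), config.admin_followup_days
    )

    def draw_times(key: str) -> np.ndarray:
        lam_exp, lam_cmp = config.outcome_hazards[key]
        lam = np.where(exposed, lam_exp, lam_cmp)
        return rng.exponential(1.0 / lam)

    t_death = draw_times("death")
    death_flag = (t_death <= censor).astype(int)
    followup = np.minimum(t_death, censor)  # death ends follow-up

    outcome_cols = {}
    for key, flag_name, time_name in [
        ("major_bleeding", "major_bleeding_flag", "major_bleeding_time_days"),
        ("rehospitalization", "rehospitalization_flag", "rehospitalization_time_days"),
    ]:
        t = draw_times(key)
        outcome_cols[flag_name] = (t <= followup).astype(int)
        outcome_cols[time_name] = np.ceil(np.minimum(t, followup)).astype(int)

    followup_days = np.maximum(np.ceil(followup).astype(int), 1)
    followup_end = index_date + followup_days.astype("timedelta64[D]")

    birth_year = first_vte.astype("datetime64[Y]").astype(int) + 1970 - age
    birth_quarter_month = rng.integers(0, 4, n) * 3  # 0, 3, 6, 9 -> Q1..Q4
    birth_quarter = (
        np.array([f"{y}-{m + 1:02d}-01" for y, m in zip(birth_year, birth_quarter_month)])
    ).astype("datetime64[D]")

    df = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "birth_quarter": np.datetime_as_string(birth_quarter, unit="D"),
            **flag_values,
            "patient_pseudonym": [f"P{i:06d}" for i in range(n)],
            "treatment_group": group,
            "first_vte_date": np.datetime_as_string(first_vte, unit="D"),
            "index_date": np.datetime_as_string(index_date, unit="D"),
            "followup_end_date": np.datetime_as_string(followup_end, unit="D"),
            "index_offset_days": index_offset.astype(int),
            "followup_end_offset_days": (index_offset + followup_days).astype(int),
            "anticoagulant_exposure_days": np.minimum(
                rng.integers(30, 366, n), followup_days
            ),
            "antiplatelet_exposure_days": np.minimum(
                rng.integers(14, 366, n), followup_days
            ),
            "death_flag": death_flag,
            "death_time_days": np.maximum(np.ceil(followup).astype(int), 1),
            "major_bleeding_flag": outcome_cols["major_bleeding_flag"],
            "major_bleeding_time_days": np.maximum(
                outcome_cols["major_bleeding_time_days"], 1
            ),
            "rehospitalization_flag": outcome_cols["rehospitalization_flag"],
            "rehospitalization_time_days": np.maximum(
                outcome_cols["rehospitalization_time_days"], 1
            ),
            "censoring_flag": 1 - death_flag,
        }
    )
    df = df[default_schema().names]
    return CohortTable(schema=schema, df=df)


def split_cohort(
    cohort: CohortTable,
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[CohortTable, CohortTable, CohortTable]:
    """Disjoint (train, control, attacker-pool) row partition.

    The train split feeds protected-data generation, control feeds the
    control attacks, and the attacker pool feeds shadow modeling.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if sum(fractions) > 1.0 + 1e-9:
        raise ValueError("fractions must sum to at most 1")
    n = len(cohort)
    sizes = [int(n * f) for f in fractions]
    if any(s == 0 for s in sizes):
        raise ValueError("every split must be non-empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out = []
    start = 0
    for s in sizes:
        idx = perm[start : start + s]
        out.append(CohortTable(schema=cohort.schema, df=cohort.df.iloc[np.sort(idx)]))
        start += s
    return tuple(out)
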