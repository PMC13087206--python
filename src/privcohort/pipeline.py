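"""End-to-end orchestration of the three-way protection comparison.

One run: simulate a cohort, split it into train / control / attacker-pool,
protect the training split three ways (context-independent anonymization:
all attributes; context-dependent anonymization: attributes picked by
threat modeling; synthetization: autoregressive generator), then score
every protected dataset on fidelity, study utility (IPTW Cox hazard
ratios) and empirical privacy risk under both adversary scenarios, with
the unprotected training data as the baseline release.

Dates are carried through protection in a single representation (the
first-VTE anchor plus day offsets); the redundant calendar-date columns
are recomputed afterwards so every dataset leaves the pipeline with the
same harmonized schema.  Shadow-model membership inference runs only in
the context-independent scenario (the strongest attacker assumption) and
is optional because of its cost.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attacks, fidelity, synthesize, threat, utility
from .anonymize import AnonConfig, AnonResult
from .anonymize import anonymize as anonymize_table
from .cohort import CohortGenConfig, default_schema, generate_cohort, split_cohort
from .hierarchy import default_hierarchies
from .schema import DATE, CohortSchema, CohortTable

REDUNDANT_DATE_COLUMNS = {
    "index_date": "index_offset_days",
    "followup_end_date": "followup_end_offset_days",
}
ANCHOR = "first_vte_date"


# ---------------------------------------------------------------------------
# reporting arithmetic (printed-precision conventions)


def retained_percent(n_original: int, n_protected: int) -> float:
    """Retained records as a percentage of the original, 1 decimal."""
    return round(100.0 * n_protected / n_original, 1)


def group_share_percent(n_group: int, n_total: int) -> float:
    return round(100.0 * n_group / n_total, 1)


def share_shift_points(
    n_group_orig: int, n_total_orig: int, n_group_prot: int, n_total_prot: int
) -> float:
    """Proportional shift of a group's share, in percentage points."""
    return round(
        group_share_percent(n_group_prot, n_total_prot)
        - group_share_percent(n_group_orig, n_total_orig),
        1,
    )


def relative_mean_change(mean_original: float, mean_protected: float) -> float:
    """Relative change of a mean in percent, 2 decimals."""
    return round(100.0 * (mean_protected - mean_original) / mean_original, 2)


def summarize_table1(
    original: pd.DataFrame, protected: pd.DataFrame, schema: CohortSchema
) -> dict:
    """Population summary: record retention, arm shares, female share, age."""
    exposed, comparator = schema.group_labels
    tcol = schema.treatment_column

    def arm_counts(df: pd.DataFrame) -> tuple[int, int]:
        if tcol not in df.columns:
            return 0, 0
        return int((df[tcol] == exposed).sum()), int((df[tcol] == comparator).sum())

    n_o, n_p = len(original), len(protected)
    e_o, c_o = arm_counts(original)
    e_p, c_p = arm_counts(protected)
    out = {
        "records": n_p,
        "records_pct_of_original": retained_percent(n_o, n_p),
        "exposed_n": e_p,
        "exposed_pct": group_share_percent(e_p, n_p) if n_p else np.nan,
        "comparator_n": c_p,
        "comparator_pct": group_share_percent(c_p, n_p) if n_p else np.nan,
        "exposed_shift_points": share_shift_points(e_o, n_o, e_p, n_p)
        if n_p and e_p
        else np.nan,
    }
    if "gender" in protected.columns:
        female = int((protected["gender"].astype(str) == "F").sum())
        out["female_n"] = female
        out["female_pct"] = group_share_percent(female, n_p)
    if "age" in protected.columns and "age" in original.columns:
        age_p = pd.to_numeric(protected["age"], errors="coerce")
        age_o = pd.to_numeric(original["age"], errors="coerce")
        out["age_mean"] = round(float(age_p.mean()), 2)
        out["age_sd"] = round(float(age_p.std()), 2)
        out["age_mean_rel_change_pct"] = relative_mean_change(
            float(age_o.mean()), float(age_p.mean())
        )
    return out


# ---------------------------------------------------------------------------
# protection stages


def rebuild_dates(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute redundant calendar dates from the (possibly
    microaggregated) anchor and the (possibly generalized) offsets."""
    out = df.copy()
    if ANCHOR not in out.columns:
        return out
    anchor = pd.to_datetime(out[ANCHOR], errors="coerce")
    for date_col, offset_col in REDUNDANT_DATE_COLUMNS.items():
        if offset_col in out.columns:
            off = pd.to_numeric(out[offset_col], errors="coerce")
            days = np.floor(off + 0.5)
            out[date_col] = (anchor + pd.to_timedelta(days, unit="D")).dt.strftime(
                "%Y-%m-%d"
            )
    return out


def anonymization_config(
    classification: threat.Classification,
    schema: CohortSchema,
    columns: list[str],
    context: str,
    k: int = 2,
    t: float = 0.5,
    max_search_nodes: int = 4000,
) -> AnonConfig:
    """Build the anonymizer configuration for a sharing context.

    Context-independent protects every attribute; context-dependent
    protects the direct, indirect and sensitive attributes flagged by the
    threat modeling.  Both share k and t and treat sensitive attributes as
    t-closeness targets; direct identifiers are removed outright; date
    attributes are microaggregated.
    """
    direct = set(classification.of(threat.DIRECT))
    sensitive = set(classification.of(threat.SENSITIVE))
    if context == attacks.CONTEXT_INDEPENDENT:
        protected = set(columns)
    elif context == attacks.CONTEXT_DEPENDENT:
        protected = (
            direct | set(classification.of(threat.INDIRECT)) | sensitive
        ) & set(columns)
    else:
        raise ValueError(f"unknown context {context!r}")
    micro = {
        c for c in protected if c in schema and schema[c].semantic_type == DATE
    }
    return AnonConfig(
        k=k,
        t=t,
        protected_attributes=protected,
        sensitive_attributes=sensitive & protected,
        microaggregate_attributes=micro,
        drop_attributes=direct & set(columns),
        max_search_nodes=max_search_nodes,
    )


def protect_by_anonymization(
    train: pd.DataFrame,
    schema: CohortSchema,
    classification: threat.Classification,
    context: str,
    k: int = 2,
    t: float = 0.5,
    max_search_nodes: int = 4000,
) -> AnonResult:
    """Anonymize the training split for one sharing context and rebuild the
    redundant date columns."""
    work = train.drop(columns=[c for c in REDUNDANT_DATE_COLUMNS if c in train.columns])
    hiers = default_hierarchies(schema, work)
    cfg = anonymization_config(
        classification, schema, list(work.columns), context, k=k, t=t,
        max_search_nodes=max_search_nodes,
    )
    result = anonymize_table(work, cfg, hiers, schema=schema)
    result.df = rebuild_dates(result.df)
    return result


def protect_by_synthetization(
    train: pd.DataFrame,
    schema: CohortSchema,
    config: synthesize.SynthConfig,
    n: int | None = None,
) -> tuple[pd.DataFrame, synthesize.GeneratorModel]:
    """Fit the generator on the training split (without the direct
    identifier and redundant dates) and sample a same-size release."""
    drop = [c for c in REDUNDANT_DATE_COLUMNS if c in train.columns]
    drop += [c for c in ("patient_pseudonym",) if c in train.columns]
    work = train.drop(columns=drop)
    model = synthesize.fit(CohortTable(schema=_subschema(schema, work.columns), df=work), config)
    out = synthesize.sample(model, n or len(train), seed=config.seed + 1)
    if isinstance(out, CohortTable):
        out = out.df
    return rebuild_dates(out), model


def _subschema(schema: CohortSchema, columns) -> CohortSchema:
    attrs = [a for a in schema.attributes if a.name in set(columns)]
    pairs = {
        f: t for f, t in schema.event_pairs.items()
        if f in set(columns) and t in set(columns)
    }
    return CohortSchema(
        attributes=attrs,
        treatment_column=schema.treatment_column,
        group_labels=schema.group_labels,
        event_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    cohort: CohortGenConfig = field(default_factory=CohortGenConfig)
    # equal train/control keeps the singling-out normalization unbiased;
    # the pool must still cover the shadow-model sample size
    fractions: tuple[float, float, float] = (0.35, 0.35, 0.3)
    threshold: int = threat.DEFAULT_THRESHOLD
    k: int = 2
    t: float = 0.5
    synth: synthesize.SynthConfig = field(default_factory=synthesize.SynthConfig)
    attack_repetitions: int = 10
    n_attack_targets: int | None = None
    n_multivariate_queries: int = 100
    secrets: list[str] | None = None  # attribute-inference secrets
    mia: attacks.MIAConfig | None = None  # None: skip membership inference
    max_search_nodes: int = 4000
    seed: int = 0
    out_dir: str | None = None


DATASET_KEYS = [
    "original",
    "independent_anonymization",
    "dependent_anonymization",
    "synthetization",
]


def _attack_aux(
    classification: threat.Classification, columns: list[str], scenario: str
) -> list[str]:
    direct = set(classification.of(threat.DIRECT))
    if scenario == attacks.CONTEXT_INDEPENDENT:
        return [c for c in columns if c not in direct]
    indirect = set(classification.of(threat.INDIRECT))
    return [c for c in columns if c in indirect]


def run_all(config: RunConfig) -> dict:
    """Execute the full comparison; returns (and optionally writes) the
    consolidated report bundle."""
    schema = default_schema()
    cohort = generate_cohort(config.cohort)
    train_t, control_t, pool_t = split_cohort(
        cohort, config.fractions, seed=config.seed + 1
    )
    train, control, pool = train_t.df, control_t.df, pool_t.df

    classification = threat.classify(
        threat.default_profiles(), config.threshold, schema=schema
    )

    stage = "anonymization (context-independent)"
    bundle: dict = {"seed": config.seed, "stages": {}}
    try:
        anon_ci = protect_by_anonymization(
            train, schema, classification, attacks.CONTEXT_INDEPENDENT,
            k=config.k, t=config.t, max_search_nodes=config.max_search_nodes,
        )
        stage = "anonymization (context-dependent)"
        anon_cd = protect_by_anonymization(
            train, schema, classification, attacks.CONTEXT_DEPENDENT,
            k=config.k, t=config.t, max_search_nodes=config.max_search_nodes,
        )
        stage = "synthetization"
        synth_cfg = dataclasses.replace(config.synth, seed=config.seed + 2)
        synth_df, model = protect_by_synthetization(train, schema, synth_cfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc

    baseline = train.drop(
        columns=[c for c in ("patient_pseudonym",) if c in train.columns]
    )
    datasets = {
        "original": baseline,
        "independent_anonymization": anon_ci.df,
        "dependent_anonymization": anon_cd.df,
        "synthetization": synth_df,
    }
    bundle["protection_metadata"] = {
        "independent_anonymization": {
            "suppressed_records": anon_ci.suppressed_records,
            "suppressed_attributes": sorted(anon_ci.suppressed_attributes),
            "loss": anon_ci.loss,
            "chosen_levels": anon_ci.chosen_levels,
        },
        "dependent_anonymization": {
            "suppressed_records": anon_cd.suppressed_records,
            "suppressed_attributes": sorted(anon_cd.suppressed_attributes),
            "loss": anon_cd.loss,
            "chosen_levels": anon_cd.chosen_levels,
        },
        "synthetization": {"diagnostics_keys": sorted(model.diagnostics)},
    }

    # Table-1-style summaries --------------------------------------------
    bundle["table1"] = {
        key: summarize_table1(train, df, schema) for key, df in datasets.items()
    }

    # fidelity ------------------------------------------------------------
    bundle["fidelity"] = {}
    for key in DATASET_KEYS[1:]:
        rep = fidelity.fidelity_report(
            baseline, datasets[key], schema.treatment_column, schema=schema
        )
        bundle["fidelity"][key] = rep.to_dict()

    # utility -------------------------------------------------------------
    bundle["utility"] = {}
    for key, df in datasets.items():
        try:
            rep = utility.run_utility(df, schema)
            bundle["utility"][key] = rep.to_dict()
        except (ValueError, utility.SeparationError) as exc:
            bundle["utility"][key] = {"error": str(exc)}

    # privacy: Anonymeter-style attacks ----------------------------------
    control_release = control.drop(
        columns=[c for c in ("patient_pseudonym",) if c in control.columns]
    )
    secrets = config.secrets
    if secrets is None:
        secrets = sorted(set(classification.of(threat.SENSITIVE)))
    bundle["risks"] = {}
    for scenario in (attacks.CONTEXT_DEPENDENT, attacks.CONTEXT_INDEPENDENT):
        scen: dict = {}
        for key, released in datasets.items():
            aux = _attack_aux(classification, list(released.columns), scenario)
            acfg = attacks.AttackConfig(
                scenario=scenario,
                aux_attributes=aux,
                n_targets=config.n_attack_targets,
                n_multivariate_queries=config.n_multivariate_queries,
                repetitions=config.attack_repetitions,
                seed=config.seed + 3,
            )
            entry: dict = {}
            if len(aux) >= 2:
                entry["linkage"] = attacks.linkage(
                    released, baseline, control_release, None, acfg
                ).to_dict()
            entry["singling_out_univariate"] = attacks.singling_out(
                released, baseline, control_release, "univariate", acfg
            ).to_dict()
            entry["singling_out_multivariate"] = attacks.singling_out(
                released, baseline, control_release, "multivariate", acfg
            ).to_dict()
            inference = {}
            for secret in secrets:
                try:
                    sec_cfg = dataclasses.replace(
                        acfg, aux_attributes=[a for a in aux if a != secret]
                    )
                    inference[secret] = attacks.attribute_inference(
                        released, baseline, control_release, secret, sec_cfg
                    ).to_dict()
                except (KeyError, ValueError) as exc:
                    inference[secret] = {"error": str(exc)}
            entry["attribute_inference"] = inference
            scen[key] = entry
        bundle["risks"][scenario] = scen

    # privacy: membership inference (context-independent only) -----------
    if config.mia is not None:
        bundle["mia"] = _run_mia(
            config, schema, classification, pool, train, model
        )

    if config.out_dir:
        _write_bundle(bundle, datasets, config.out_dir)
    return bundle


def _run_mia(
    config: RunConfig,
    schema: CohortSchema,
    classification: threat.Classification,
    pool: pd.DataFrame,
    train: pd.DataFrame,
    model: synthesize.GeneratorModel,
) -> dict:
    mia_cfg = config.mia
    drop = [c for c in ("patient_pseudonym", *REDUNDANT_DATE_COLUMNS) if c in pool.columns]
    pool_r = pool.drop(columns=drop).reset_index(drop=True)
    avg_idx, out_idx = attacks.select_targets(
        pool_r, mia_cfg.n_average_targets, mia_cfg.n_outlier_targets
    )

    # hierarchies and configuration are the data holder's fixed
    # parametrization: fit once, reuse across every shadow sample
    anon_hiers = default_hierarchies(schema, pool_r)

    def _make_anon_protector(context: str) -> attacks.Protector:
        cfg = anonymization_config(
            classification, schema, list(pool_r.columns), context,
            k=config.k, t=config.t, max_search_nodes=100,
        )

        def _protect(df: pd.DataFrame, seed: int) -> pd.DataFrame:
            return anonymize_table(df, cfg, anon_hiers, schema=schema).df

        return _protect

    def synth_protector(df: pd.DataFrame, seed: int) -> pd.DataFrame:
        cfg = dataclasses.replace(config.synth, seed=seed)
        m = synthesize.fit(
            CohortTable(schema=_subschema(schema, df.columns), df=df), cfg
        )
        out = synthesize.sample(m, len(df), seed=seed + 1)
        return out.df if isinstance(out, CohortTable) else out

    report: dict = {}
    for name, protector in (
        ("independent_anonymization", _make_anon_protector(attacks.CONTEXT_INDEPENDENT)),
        ("dependent_anonymization", _make_anon_protector(attacks.CONTEXT_DEPENDENT)),
        ("synthetization", synth_protector),
    ):
        results = []
        for kind, idx in (("average", avg_idx), ("outlier", out_idx)):
            for i in idx:
                res = attacks.membership_inference(
                    pool_r.loc[i],
                    protector,
                    pool_r.drop(index=i),
                    mia_cfg,
                    target_id=int(i),
                    target_kind=kind,
                )
                results.append(res.to_dict())
        report[name] = {
            "targets": results,
            "mean_risk_average": float(
                np.mean([r["risk"] for r in results if r["target_kind"] == "average"])
            ),
            "mean_risk_outlier": float(
                np.mean([r["risk"] for r in results if r["target_kind"] == "outlier"])
            ),
        }
    return report


def _write_bundle(bundle: dict, datasets: dict[str, pd.DataFrame], out_dir: str) -> None:
    path = Path(out_dir)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_jsonable)
    for key, df in datasets.items():
        df.to_csv(path / f"{key}.csv", index=False, na_rep="")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    if isinstance(obj, set):
        return sorted(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return str(obj)
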