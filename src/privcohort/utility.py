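"""Study-level utility: IPTW-weighted Cox hazard ratios and balance checks.

Reproduces the emulated medication-safety analysis on any (possibly
protected) cohort: a propensity score for treatment (logistic regression
of the exposed arm on demographics and comorbidity flags) yields
stabilized inverse-probability-of-treatment weights; covariate balance is
assessed with standardized mean differences before/after weighting; each
outcome (all-cause mortality, major bleeding) gets a weighted Cox
proportional-hazards fit with treatment as the sole covariate and a robust
(sandwich) variance for the 95% confidence interval.  An outcome with zero
events in either arm is reported as not estimable (NA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.linear_model import LogisticRegression

from .schema import BINARY, COMORBIDITY, DEMOGRAPHIC, CohortSchema


class SeparationError(RuntimeError):
    pass


@dataclass
class OutcomeResult:
    outcome: str
    events_exposed: int
    events_comparator: int
    hr: float
    ci_low: float
    ci_high: float
    estimable: bool

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "events_exposed": self.events_exposed,
            "events_comparator": self.events_comparator,
            "hr": None if not self.estimable else self.hr,
            "ci_low": None if not self.estimable else self.ci_low,
            "ci_high": None if not self.estimable else self.ci_high,
            "estimable": self.estimable,
        }


@dataclass
class UtilityReport:
    outcomes: dict[str, OutcomeResult]
    smd: pd.DataFrame  # columns: covariate, smd_before, smd_after
    weights: pd.Series = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "outcomes": {k: v.to_dict() for k, v in self.outcomes.items()},
            "smd": self.smd.to_dict("records"),
        }


# ---------------------------------------------------------------------------


def propensity_weights(
    df: pd.DataFrame,
    treatment: pd.Series,
    covariates: list[str],
    truncation_quantile: float | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Stabilized ATE weights from a logistic propensity model.

    Exposed records get ``P(T=1)/e``, comparators ``P(T=0)/(1-e)``.  An
    optional symmetric quantile truncation caps extreme weights; the
    default is no truncation.
    """
    x = df[covariates].apply(pd.to_numeric, errors="coerce")
    if x.isna().any().any():
        x = x.fillna(x.median())
    t = treatment.to_numpy(dtype=int)
    if t.min() == t.max():
        raise ValueError("both treatment arms must be present")
    model = LogisticRegression(C=np.inf, max_iter=2000)  # unpenalized fit
    model.fit(x.to_numpy(dtype=float), t)
    coefs = np.abs(model.coef_[0])
    # a log-odds slope this large only arises under (quasi-)separation
    if coefs.max() > 15.0:
        culprit = covariates[int(np.argmax(coefs))]
        raise SeparationError(
            f"perfect or quasi-perfect separation on covariate {culprit!r}"
        )
    e = model.predict_proba(x.to_numpy(dtype=float))[:, 1]
    e = np.clip(e, 1e-10, 1 - 1e-10)
    p1 = t.mean()
    w = np.where(t == 1, p1 / e, (1 - p1) / (1 - e))
    if truncation_quantile is not None:
        hi = np.quantile(w, truncation_quantile)
        lo = np.quantile(w, 1 - truncation_quantile)
        w = np.clip(w, lo, hi)
    return pd.Series(w, index=df.index), pd.Series(e, index=df.index)


def smd_balance(
    df: pd.DataFrame,
    treatment: pd.Series,
    weights: pd.Series,
    covariates: list[str],
) -> pd.DataFrame:
    """Standardized mean differences, unweighted (before) and weighted
    (after): (mean_exposed - mean_comparator) / pooled SD.  The pooled SD
    is always the unweighted one, so before/after are on the same scale;
    zero pooled SD flags the covariate as undefined."""
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    t = treatment.to_numpy(dtype=bool)
    rows = []
    for c in covariates:
        x = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        w = weights.to_numpy(dtype=float)
        ok = ~np.isnan(x)
        x, tt, w = x[ok], t[ok], w[ok]
        sd = np.sqrt(0.5 * (x[tt].var(ddof=1) + x[~tt].var(ddof=1)))
        if not np.isfinite(sd) or sd == 0:
            rows.append({"covariate": c, "smd_before": np.nan, "smd_after": np.nan,
                         "defined": False})
            continue

        def wmean(vals, wts):
            return float(np.average(vals, weights=wts))

        before = (x[tt].mean() - x[~tt].mean()) / sd
        after = (wmean(x[tt], w[tt]) - wmean(x[~tt], w[~tt])) / sd
        rows.append(
            {"covariate": c, "smd_before": float(before), "smd_after": float(after),
             "defined": True}
        )
    return pd.DataFrame(rows)


def weighted_cox_hr(
    df: pd.DataFrame,
    treatment: pd.Series,
    weights: pd.Series,
    outcome_flag: str,
    outcome_time: str,
) -> OutcomeResult:
    """Weighted Cox fit with treatment as the sole covariate and robust
    variance.  Not estimable (NA) when either arm has zero events."""
    t = treatment.to_numpy(dtype=int)
    ev = pd.to_numeric(df[outcome_flag], errors="coerce").fillna(0).to_numpy()
    ev = (ev > 0.5).astype(int)
    times = pd.to_numeric(df[outcome_time], errors="coerce").to_numpy(dtype=float)
    times = np.where(np.isnan(times) | (times <= 0), 0.5, times)
    events_exposed = int(ev[t == 1].sum())
    events_comparator = int(ev[t == 0].sum())
    if events_exposed == 0 or events_comparator == 0 or ev.sum() == 0:
        return OutcomeResult(outcome_flag, events_exposed, events_comparator,
                             np.nan, np.nan, np.nan, estimable=False)
    frame = pd.DataFrame(
        {"time": times, "event": ev, "treatment": t, "w": weights.to_numpy(dtype=float)}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                frame,
                duration_col="time",
                event_col="event",
                weights_col="w",
                robust=True,
            )
    except ConvergenceError:
        return OutcomeResult(outcome_flag, events_exposed, events_comparator,
                             np.nan, np.nan, np.nan, estimable=False)
    hr = float(np.exp(cph.params_["treatment"]))
    ci = cph.confidence_intervals_
    ci_low = float(np.exp(ci.iloc[0, 0]))
    ci_high = float(np.exp(ci.iloc[0, 1]))
    return OutcomeResult(
        outcome_flag, events_exposed, events_comparator, hr, ci_low, ci_high, True
    )


DEFAULT_OUTCOMES = {
    "all_cause_mortality": ("death_flag", "death_time_days"),
    "major_bleeding": ("major_bleeding_flag", "major_bleeding_time_days"),
}


def run_utility(
    df: pd.DataFrame,
    schema: CohortSchema,
    outcomes: dict[str, tuple[str, str]] | None = None,
) -> UtilityReport:
    """Full utility analysis on a (possibly protected) cohort.

    Covariates are age, gender and every comorbidity flag still present in
    the table.  Outcomes missing their flag or time column are reported as
    not estimable.
    """
    outcomes = outcomes or DEFAULT_OUTCOMES
    if schema.treatment_column not in df.columns:
        raise ValueError("treatment column missing; utility analysis impossible")
    exposed_label = schema.group_labels[0]
    treatment = (df[schema.treatment_column] == exposed_label).astype(int)
    if treatment.min() == treatment.max():
        raise ValueError("both treatment arms must be present")

    covariates = []
    for a in schema.attributes:
        if a.name not in df.columns:
            continue
        if a.role == COMORBIDITY and a.semantic_type == BINARY:
            covariates.append(a.name)
        elif a.role == DEMOGRAPHIC and a.name in ("age",):
            covariates.append(a.name)
    work = df.copy()
    if "gender" in work.columns:
        work["_female"] = (work["gender"].astype(str) == "F").astype(int)
        covariates.append("_female")
    # drop constant covariates (e.g. a flag anonymization zeroed out)
    covariates = [
        c for c in covariates
        if pd.to_numeric(work[c], errors="coerce").nunique(dropna=True) > 1
    ]

    weights, _ = propensity_weights(work, treatment, covariates)
    smd = smd_balance(work, treatment, weights, covariates)

    results = {}
    for name, (flag, time_col) in outcomes.items():
        if flag not in df.columns or time_col not in df.columns:
            results[name] = OutcomeResult(flag, 0, 0, np.nan, np.nan, np.nan, False)
            continue
        res = weighted_cox_hr(work, treatment, weights, flag, time_col)
        results[name] = OutcomeResult(
            name, res.events_exposed, res.events_comparator,
            res.hr, res.ci_low, res.ci_high, res.estimable,
        )
    return UtilityReport(outcomes=results, smd=smd, weights=weights)
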