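"""Empirical privacy-risk estimation for a released (protected) dataset.

Attack families:

* singling-out (univariate / multivariate) — predicates derived from the
  released data that isolate exactly one record in an attacked dataset;
* linkage — k-nearest-neighbor matching across two disjoint auxiliary
  attribute sets, counting overlapping neighbor sets as a link;
* attribute inference — predicting a secret attribute from the nearest
  released neighbor on auxiliary attributes;
* membership inference — shadow-model attack: many protector instances
  trained on reference samples with/without a target teach a random-forest
  classifier to spot the target's footprint in marginal-distribution
  features.

Each of the first three runs as a main attack (evaluated on the training
records behind the release), a naive random-guessing baseline, and a
control attack on an independent holdout.  The normalized risk
``R = (r_main - r_control) / (1 - r_control)`` measures training-specific
leakage: the main attack's excess success over control, relative to the
remaining headroom.  Risks are computed per repetition and averaged; an
attack is valid only if the main attack beats the baseline.  Membership
risk is reported as ``R = TPR - FPR`` (negative values mean no effective
advantage).

Record distances use a Gower-style mixed-type metric: range-normalized
absolute difference for numerics, 0/1 mismatch for categoricals, averaged
over attributes.  Distance ties resolve deterministically by record order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

CONTEXT_DEPENDENT = "context-dependent"
CONTEXT_INDEPENDENT = "context-independent"


# ---------------------------------------------------------------------------
# risk normalization


def risk_score(r_main: float, r_control: float) -> float:
    """Normalized excess success of the main attack over control."""
    if not (0.0 <= r_main <= 1.0 and 0.0 <= r_control <= 1.0):
        raise ValueError("success rates must lie in [0, 1]")
    if r_control >= 1.0:
        raise ValueError("risk undefined when the control attack is perfect")
    return (r_main - r_control) / (1.0 - r_control)


@dataclass
class RiskScore:
    r_main: float
    r_baseline: float
    r_control: float
    risk: float  # mean of per-repetition risks
    risk_sd: float
    valid: bool  # main attack beats baseline on average
    n_valid_reps: int
    repetitions: int
    rep_risks: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r_main": self.r_main,
            "r_baseline": self.r_baseline,
            "r_control": self.r_control,
            "risk": self.risk,
            "risk_sd": self.risk_sd,
            "valid": self.valid,
            "n_valid_reps": self.n_valid_reps,
            "repetitions": self.repetitions,
        }


def _rep_risk(r_main: float, r_control: float) -> float:
    """Per-repetition normalized risk, guarded against a saturated control
    attack: with no remaining headroom the excess is zero, and estimates
    are clamped to [-1, 1] (risks below 0 already mean no advantage)."""
    if r_control >= 1.0 - 1e-12:
        return 0.0 if r_main >= 1.0 - 1e-12 else -1.0
    return float(np.clip(risk_score(r_main, r_control), -1.0, 1.0))


def _aggregate(
    rep_rates: list[tuple[float, float, float]], repetitions: int
) -> RiskScore:
    """Per-repetition (main, baseline, control) rates -> averaged report."""
    risks = [_rep_risk(m, c) for m, _, c in rep_rates]
    mains = [m for m, _, _ in rep_rates]
    bases = [b for _, b, _ in rep_rates]
    ctrls = [c for _, _, c in rep_rates]
    n_valid = sum(m > b for m, b, _ in rep_rates)
    return RiskScore(
        r_main=float(np.mean(mains)),
        r_baseline=float(np.mean(bases)),
        r_control=float(np.mean(ctrls)),
        risk=float(np.mean(risks)),
        risk_sd=float(np.std(risks, ddof=1)) if len(risks) > 1 else 0.0,
        valid=float(np.mean(mains)) > float(np.mean(bases)),
        n_valid_reps=int(n_valid),
        repetitions=repetitions,
        rep_risks=[float(r) for r in risks],
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AttackConfig:
    scenario: str = CONTEXT_INDEPENDENT
    aux_attributes: list[str] = field(default_factory=list)
    n_targets: int | None = None  # default: ~20% of attacked records
    n_multivariate_queries: int = 100
    repetitions: int = 10
    knn_k: int = 1
    numeric_tolerance: float = 0.05
    seed: int = 0

    def resolve_targets(self, n_available: int) -> int:
        n = self.n_targets if self.n_targets is not None else max(1, round(0.2 * n_available))
        return min(n, n_available)


# ---------------------------------------------------------------------------
# mixed-type distances


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def gower_matrix(
    a: pd.DataFrame, b: pd.DataFrame, columns: list[str], ranges: dict[str, float]
) -> np.ndarray:
    """Pairwise Gower distance (len(a) x len(b)) over ``columns``."""
    out = np.zeros((len(a), len(b)))
    for c in columns:
        if _is_numeric(b[c]) and _is_numeric(a[c]):
            av = a[c].to_numpy(dtype=float)[:, None]
            bv = b[c].to_numpy(dtype=float)[None, :]
            rng = ranges.get(c, 0.0)
            if rng > 0:
                d = np.abs(av - bv) / rng
                d = np.minimum(np.nan_to_num(d, nan=1.0), 1.0)
            else:
                d = (av != bv).astype(float)
        else:
            av = a[c].astype(str).to_numpy()[:, None]
            bv = b[c].astype(str).to_numpy()[None, :]
            d = (av != bv).astype(float)
        out += d
    return out / max(len(columns), 1)


def _column_ranges(df: pd.DataFrame, columns: list[str]) -> dict[str, float]:
    ranges = {}
    for c in columns:
        if _is_numeric(df[c]):
            col = df[c].astype(float)
            ranges[c] = float(col.max() - col.min()) if col.notna().any() else 0.0
    return ranges


def _knn_indices(dist_row: np.ndarray, k: int) -> np.ndarray:
    # stable sort: ties resolve by record order
    return np.argsort(dist_row, kind="stable")[:k]


# ---------------------------------------------------------------------------
# singling-out


def _matches(df: pd.DataFrame, predicate: list[tuple[str, str, object]]) -> int:
    mask = np.ones(len(df), dtype=bool)
    for col, op, val in predicate:
        if col not in df.columns:
            return 0
        s = df[col]
        if op == "eq":
            if _is_numeric(s) and isinstance(val, (int, float, np.floating, np.integer)):
                mask &= np.isclose(s.to_numpy(dtype=float), float(val), atol=1e-9)
            else:
                mask &= (s.astype(str) == str(val)).to_numpy()
        elif op == "le":
            mask &= (pd.to_numeric(s, errors="coerce") <= val).to_numpy()
        elif op == "ge":
            mask &= (pd.to_numeric(s, errors="coerce") >= val).to_numpy()
        if not mask.any():
            return 0
    return int(mask.sum())


def _univariate_predicates(protected: pd.DataFrame, columns: list[str]) -> list:
    preds = []
    for c in columns:
        s = protected[c]
        counts = s.value_counts(dropna=True)
        for v in counts[counts == 1].index:
            preds.append([(c, "eq", v)])
        if _is_numeric(s) and s.notna().any():
            preds.append([(c, "le", float(s.min()))])
            preds.append([(c, "ge", float(s.max()))])
    return preds


def _random_predicate(
    protected: pd.DataFrame, columns: list[str], rng: np.random.Generator, width: int = 1
) -> list:
    pred = []
    cols = rng.choice(len(columns), size=min(width, len(columns)), replace=False)
    for ci in cols:
        c = columns[int(ci)]
        s = protected[c]
        if _is_numeric(s) and s.notna().any():
            op = ["eq", "le", "ge"][int(rng.integers(3))]
            if op == "eq":
                val = float(rng.choice(s.dropna().unique()))
            else:
                lo, hi = float(s.min()), float(s.max())
                val = float(lo + rng.random() * (hi - lo))
            pred.append((c, op, val))
        else:
            vals = s.dropna().unique()
            pred.append((c, "eq", vals[int(rng.integers(len(vals)))]))
    return pred


def singling_out(
    protected: pd.DataFrame,
    attacked_original: pd.DataFrame,
    attacked_control: pd.DataFrame,
    mode: str,
    config: AttackConfig,
) -> RiskScore:
    """Singling-out risk: predicates from the released data that isolate
    exactly one record in the attacked dataset."""
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be univariate or multivariate")
    if abs(len(attacked_original) - len(attacked_control)) > 0.1 * len(attacked_original):
        warnings.warn(
            "train and control sets differ in size by more than 10%; "
            "isolating exactly one record is size-dependent, so the "
            "normalized risk may be biased"
        )
    columns = [c for c in (config.aux_attributes or protected.columns) if c in protected.columns]
    rep_rates = []
    for rep in range(config.repetitions):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, rep, 11)))
        if mode == "univariate":
            n_queries = config.resolve_targets(len(attacked_original))
            candidates = _univariate_predicates(protected, columns)
            if not candidates:
                warnings.warn("no univariate singling-out candidates")
                preds = []
            elif len(candidates) <= n_queries:
                if len(candidates) < n_queries:
                    warnings.warn(
                        f"only {len(candidates)} candidate predicates for "
                        f"{n_queries} requested queries; using all"
                    )
                preds = candidates
            else:
                idx = rng.choice(len(candidates), size=n_queries, replace=False)
                preds = [candidates[i] for i in idx]
            baseline_preds = [
                _random_predicate(protected, columns, rng) for _ in range(len(preds))
            ]
        else:
            n_queries = config.n_multivariate_queries
            preds = []
            tries = 0
            while len(preds) < n_queries and tries < 50 * n_queries:
                tries += 1
                row = protected.iloc[int(rng.integers(len(protected)))]
                width = int(rng.integers(2, 5))
                cols = rng.choice(len(columns), size=min(width, len(columns)), replace=False)
                pred = [(columns[int(ci)], "eq", row[columns[int(ci)]]) for ci in cols]
                if any(pd.isna(v) for _, _, v in pred):
                    continue
                if _matches(protected, pred) == 1:
                    preds.append(pred)
            if len(preds) < n_queries:
                warnings.warn(
                    f"found only {len(preds)} isolating multivariate predicates"
                )
            baseline_preds = [
                _random_predicate(protected, columns, rng, width=int(rng.integers(2, 5)))
                for _ in range(len(preds))
            ]
        if not preds:
            rep_rates.append((0.0, 0.0, 0.0))
            continue
        main = np.mean([_matches(attacked_original, p) == 1 for p in preds])
        ctrl = np.mean([_matches(attacked_control, p) == 1 for p in preds])
        base = np.mean([_matches(attacked_original, p) == 1 for p in baseline_preds])
        rep_rates.append((float(main), float(base), float(ctrl)))
    return _aggregate(rep_rates, config.repetitions)


# ---------------------------------------------------------------------------
# linkage


def split_aux(aux_attributes: list[str]) -> tuple[list[str], list[str]]:
    """Deterministic disjoint halves (alternating) of the auxiliary set."""
    return list(aux_attributes[0::2]), list(aux_attributes[1::2])


def linkage(
    protected: pd.DataFrame,
    attacked_original: pd.DataFrame,
    attacked_control: pd.DataFrame,
    aux_split: tuple[list[str], list[str]] | None,
    config: AttackConfig,
) -> RiskScore:
    """Linkage risk: k-NN matches on two disjoint attribute sets overlap."""
    aux = [c for c in config.aux_attributes if c in protected.columns]
    if aux_split is None:
        aux_split = split_aux(aux)
    set_a = [c for c in aux_split[0] if c in protected.columns]
    set_b = [c for c in aux_split[1] if c in protected.columns]
    if not set_a or not set_b:
        raise ValueError("both linkage attribute sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValueError("linkage attribute sets must be disjoint")
    ranges = _column_ranges(protected, set_a + set_b)

    def success_rate(attacked: pd.DataFrame, rng: np.random.Generator) -> float:
        n_t = config.resolve_targets(len(attacked))
        targets = attacked.iloc[rng.choice(len(attacked), size=n_t, replace=False)]
        usable_a = [c for c in set_a if c in attacked.columns]
        usable_b = [c for c in set_b if c in attacked.columns]
        if not usable_a or not usable_b:
            return 0.0
        d_a = gower_matrix(targets, protected, usable_a, ranges)
        d_b = gower_matrix(targets, protected, usable_b, ranges)
        hits = 0
        for i in range(n_t):
            nn_a = set(_knn_indices(d_a[i], config.knn_k))
            nn_b = set(_knn_indices(d_b[i], config.knn_k))
            hits += bool(nn_a & nn_b)
        return hits / n_t

    rep_rates = []
    for rep in range(config.repetitions):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, rep, 23)))
        main = success_rate(attacked_original, rng)
        ctrl = success_rate(attacked_control, rng)
        # naive baseline: random neighbor sets on both sides
        n_t = config.resolve_targets(len(attacked_original))
        base_hits = 0
        for _ in range(n_t):
            nn_a = set(rng.choice(len(protected), size=config.knn_k, replace=False))
            nn_b = set(rng.choice(len(protected), size=config.knn_k, replace=False))
            base_hits += bool(nn_a & nn_b)
        rep_rates.append((main, base_hits / n_t, ctrl))
    return _aggregate(rep_rates, config.repetitions)


# ---------------------------------------------------------------------------
# attribute inference


def attribute_inference(
    protected: pd.DataFrame,
    attacked_original: pd.DataFrame,
    attacked_control: pd.DataFrame,
    secret_attribute: str,
    config: AttackConfig,
) -> RiskScore:
    """Attribute-inference risk: the nearest released neighbor's secret
    value is the prediction; exact match for categorical secrets, a
    range-fraction tolerance for numeric ones."""
    if secret_attribute in config.aux_attributes:
        raise ValueError("the secret must not be an auxiliary attribute")
    if secret_attribute not in protected.columns:
        raise KeyError(f"secret attribute {secret_attribute!r} absent from release")
    aux = [
        c
        for c in config.aux_attributes
        if c in protected.columns and c != secret_attribute
    ]
    if not aux:
        raise ValueError("no auxiliary attributes available")
    ranges = _column_ranges(protected, aux)
    secret = protected[secret_attribute]
    numeric_secret = _is_numeric(secret)
    if numeric_secret:
        rng_secret = float(secret.max() - secret.min())
        tol = config.numeric_tolerance * rng_secret

    def correct(predicted, actual) -> bool:
        if pd.isna(predicted) or pd.isna(actual):
            return bool(pd.isna(predicted) and pd.isna(actual))
        if numeric_secret:
            return abs(float(predicted) - float(actual)) <= tol + 1e-12
        return str(predicted) == str(actual)

    def success_rate(attacked: pd.DataFrame, rng: np.random.Generator) -> float:
        usable = [c for c in aux if c in attacked.columns]
        if not usable or secret_attribute not in attacked.columns:
            return 0.0
        n_t = config.resolve_targets(len(attacked))
        targets = attacked.iloc[rng.choice(len(attacked), size=n_t, replace=False)]
        d = gower_matrix(targets, protected, usable, ranges)
        hits = 0
        for i in range(n_t):
            nn = _knn_indices(d[i], 1)[0]
            hits += correct(secret.iloc[nn], targets[secret_attribute].iloc[i])
        return hits / n_t

    marginal = secret.dropna()
    rep_rates = []
    for rep in range(config.repetitions):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, rep, 37)))
        main = success_rate(attacked_original, rng)
        ctrl = success_rate(attacked_control, rng)
        # baseline: marginal-frequency-weighted random guess
        n_t = config.resolve_targets(len(attacked_original))
        targets = attacked_original.iloc[
            rng.choice(len(attacked_original), size=n_t, replace=False)
        ]
        guesses = marginal.iloc[rng.integers(len(marginal), size=n_t)]
        base = float(
            np.mean(
                [
                    correct(g, a)
                    for g, a in zip(guesses, targets[secret_attribute])
                ]
            )
        )
        rep_rates.append((main, base, ctrl))
    return _aggregate(rep_rates, config.repetitions)


# ---------------------------------------------------------------------------
# shadow-model membership inference


@dataclass
class MIAConfig:
    n_average_targets: int = 10
    n_outlier_targets: int = 10
    sample_size: int = 500
    train_replicates: int = 10
    test_replicates: int = 10
    n_runs: int = 30
    n_bins: int = 10
    coverage_probability: float = 0.95
    seed: int = 0


@dataclass
class MIAResult:
    target_id: object
    target_kind: str
    tpr: float
    fpr: float
    risk: float
    n_runs_used: int
    coverage_ok: bool

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "target_kind": self.target_kind,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "risk": self.risk,
            "n_runs_used": self.n_runs_used,
            "coverage_ok": self.coverage_ok,
        }


def select_targets(
    df: pd.DataFrame, n_average: int, n_outlier: int
) -> tuple[pd.Index, pd.Index]:
    """Average and outlier target records by mean distance to the 5 nearest
    neighbors (Gower space): outliers are the most isolated records,
    average targets sit closest to the median isolation."""
    if len(df) < n_average + n_outlier:
        raise ValueError("cohort smaller than requested target counts")
    cols = list(df.columns)
    ranges = _column_ranges(df, cols)
    d = gower_matrix(df, df, cols, ranges)
    np.fill_diagonal(d, np.inf)
    k = min(5, len(df) - 1)
    nn_mean = np.sort(d, axis=1)[:, :k].mean(axis=1)
    order = np.lexsort((np.arange(len(df)), -nn_mean))  # stable, by isolation desc
    outlier_pos = order[:n_outlier]
    rest = order[n_outlier:]
    med = np.median(nn_mean)
    rest_sorted = rest[np.lexsort((rest, np.abs(nn_mean[rest] - med)))]
    average_pos = rest_sorted[:n_average]
    return df.index[average_pos], df.index[outlier_pos]


def fit_feature_spec(pool: pd.DataFrame, n_bins: int = 10) -> dict:
    """Per-attribute histogram/frequency layout, fitted once on the
    attacker pool and reused for every shadow dataset."""
    spec = {}
    for c in pool.columns:
        s = pool[c]
        if _is_numeric(s):
            lo, hi = float(s.min()), float(s.max())
            if hi <= lo:
                hi = lo + 1.0
            spec[c] = ("num", np.linspace(lo, hi, n_bins + 1).tolist())
        else:
            spec[c] = ("cat", sorted(s.dropna().astype(str).unique().tolist()))
    return spec


def marginal_features(df: pd.DataFrame, spec: dict) -> np.ndarray:
    """Concatenated per-attribute binned counts / category frequencies;
    fixed length regardless of table size.  Out-of-range numerics clip to
    the end bins."""
    parts = []
    for c, (kind, layout) in spec.items():
        if c not in df.columns:
            parts.append(np.zeros(len(layout) - 1 if kind == "num" else len(layout)))
            continue
        s = df[c]
        if kind == "num":
            edges = np.asarray(layout)
            vals = pd.to_numeric(s, errors="coerce").dropna().to_numpy(dtype=float)
            vals = np.clip(vals, edges[0], edges[-1])
            counts, _ = np.histogram(vals, bins=edges)
            parts.append(counts.astype(float))
        else:
            vc = s.dropna().astype(str).value_counts()
            parts.append(np.array([float(vc.get(cat, 0)) for cat in layout]))
    return np.concatenate(parts)


def coverage_probability(pool_size: int, sample_size: int, n_draws: int) -> float:
    """P(a given pool record appears in at least one reference draw)."""
    return 1.0 - (1.0 - sample_size / pool_size) ** n_draws


Protector = Callable[[pd.DataFrame, int], pd.DataFrame]


def membership_inference(
    target: pd.Series,
    protector: Protector,
    attacker_pool: pd.DataFrame,
    config: MIAConfig,
    target_id: object = None,
    target_kind: str = "average",
) -> MIAResult:
    """Shadow-model membership inference against a protection procedure.

    Per run: draw reference samples from the attacker pool, produce
    labeled protected datasets with the target alternately included and
    excluded, fit a random-forest on marginal features, and score fresh
    labeled datasets.  Risk = TPR - FPR aggregated over runs."""
    if config.sample_size > len(attacker_pool):
        raise ValueError("sample_size exceeds the attacker pool")
    pool = attacker_pool
    spec = fit_feature_spec(pool, config.n_bins)
    n_draws = config.n_runs * (config.train_replicates + config.test_replicates)
    cov = coverage_probability(len(pool), config.sample_size, n_draws)
    coverage_ok = cov >= config.coverage_probability
    if not coverage_ok:
        warnings.warn(
            f"reference-draw coverage {cov:.3f} below "
            f"{config.coverage_probability:.2f}; increase replicates or sample size"
        )

    def shadow_features(include: bool, rng: np.random.Generator, seed: int):
        idx = rng.choice(len(pool), size=config.sample_size, replace=False)
        ref = pool.iloc[idx].reset_index(drop=True)
        if include:
            ref.iloc[int(rng.integers(len(ref)))] = target
        protected = protector(ref, seed)
        return marginal_features(protected, spec)

    tprs, fprs = [], []
    n_used = 0
    for run in range(config.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, run, 53)))
        try:
            x_train, y_train = [], []
            for i in range(config.train_replicates):
                for label in (1, 0):
                    seed = int(rng.integers(2**31 - 1))
                    x_train.append(shadow_features(bool(label), rng, seed))
                    y_train.append(label)
            clf = RandomForestClassifier(
                n_estimators=100, random_state=int(rng.integers(2**31 - 1))
            )
            clf.fit(np.array(x_train), np.array(y_train))
            preds_in, preds_out = [], []
            for i in range(config.test_replicates):
                for label in (1, 0):
                    seed = int(rng.integers(2**31 - 1))
                    f = shadow_features(bool(label), rng, seed)
                    p = int(clf.predict(f[None, :])[0])
                    (preds_in if label else preds_out).append(p)
        except Exception as exc:  # protection failure: discard the run
            warnings.warn(f"shadow run {run} discarded: {exc}")
            continue
        tprs.append(float(np.mean(preds_in)))
        fprs.append(float(np.mean(preds_out)))
        n_used += 1
    if n_used == 0:
        raise RuntimeError("all shadow runs failed")
    tpr, fpr = float(np.mean(tprs)), float(np.mean(fprs))
    return MIAResult(
        target_id=target_id,
        target_kind=target_kind,
        tpr=tpr,
        fpr=fpr,
        risk=tpr - fpr,
        n_runs_used=n_used,
        coverage_ok=coverage_ok,
    )


# convenience protectors ----------------------------------------------------


def identity_protector(df: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Releases the training data unchanged (no protection)."""
    return df


def constant_protector(fixed: pd.DataFrame) -> Protector:
    """Releases a fixed dataset regardless of input (maximal protection,
    zero utility)."""

    def _protect(df: pd.DataFrame, seed: int) -> pd.DataFrame:
        return fixed

    return _protect
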