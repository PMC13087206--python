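"""Fully synthetic cohort generation via an autoregressive chain model.

The generator factorizes the joint distribution attribute-by-attribute —
treatment arm first (and forced as a parent of every later attribute, so
arm-stratified distributions survive), then schema order (demographics ->
comorbidities -> study info -> outcomes): each attribute gets a smoothed
conditional frequency table given a small, holdout-selected set of
earlier attributes.  Sampling is ancestral, so the
one-to-one mapping between input and output records is broken by
construction — the model stores only fitted statistics, never rows.

Three safeguards shape the fit:

* rare categories (training count below ``rare_category_min_count``) are
  pooled into a protected label that decodes to the attribute's modal
  value, so rare levels cannot leak through verbatim;
* numeric values are clipped to configurable quantiles before
  discretization, bounding the influence of extreme values;
* parent sets grow greedily and stop as soon as held-out log-likelihood
  stops improving — early stopping against overfitting, with Laplace-style
  smoothing as the regularizer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    AGE,
    BINARY,
    CATEGORICAL,
    DATE,
    DAY_OFFSET,
    EVENT_TIME,
    CohortSchema,
    CohortTable,
)

POOLED = "__rare__"
_UNSEEN = -1


@dataclass
class SynthConfig:
    rare_category_min_count: int = 5
    clip_quantiles: tuple[float, float] = (0.01, 0.99)
    holdout_fraction: float = 0.2
    smoothing: float = 0.5
    max_parents: int = 3
    n_bins: int = 10
    # minimum total holdout log-likelihood gain (nats) to accept a parent
    min_holdout_gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 0.5):
            raise ValueError("holdout_fraction must lie in (0, 0.5)")
        lo, hi = self.clip_quantiles
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("clip_quantiles must satisfy 0 <= low < high <= 1")
        if self.smoothing <= 0:
            raise ValueError("smoothing must be > 0")


@dataclass
class _AttributeModel:
    name: str
    kind: str  # "categorical" | "numeric" | "date"
    integer: bool = False
    categories: list = field(default_factory=list)  # decode labels per code
    decode_map: dict = field(default_factory=dict)  # pooled label -> decoded value
    bin_edges: list = field(default_factory=list)
    clip_bounds: tuple[float, float] | None = None
    parents: list[str] = field(default_factory=list)
    marginal: list = field(default_factory=list)
    # conditional table: "c1,c2" parent-code key -> probability vector
    cpt: dict = field(default_factory=dict)

    @property
    def n_values(self) -> int:
        return len(self.marginal)


@dataclass
class GeneratorModel:
    schema_names: list[str]  # chain (sampling) order
    attributes: dict[str, _AttributeModel]
    diagnostics: dict
    column_order: list[str] | None = None  # presentation order of the output

    def to_json(self, path: str) -> None:
        def _native(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        payload = {
            "schema_names": self.schema_names,
            "column_order": self.column_order,
            "diagnostics": self.diagnostics,
            "attributes": {
                n: {
                    "name": a.name,
                    "kind": a.kind,
                    "integer": a.integer,
                    "categories": a.categories,
                    "decode_map": a.decode_map,
                    "bin_edges": a.bin_edges,
                    "clip_bounds": list(a.clip_bounds) if a.clip_bounds else None,
                    "parents": a.parents,
                    "marginal": a.marginal,
                    "cpt": a.cpt,
                }
                for n, a in self.attributes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=_native)

    @classmethod
    def from_json(cls, path: str) -> "GeneratorModel":
        with open(path) as fh:
            payload = json.load(fh)
        attrs = {}
        for n, a in payload["attributes"].items():
            a = dict(a)
            a["clip_bounds"] = tuple(a["clip_bounds"]) if a["clip_bounds"] else None
            attrs[n] = _AttributeModel(**a)
        return cls(
            schema_names=payload["schema_names"],
            attributes=attrs,
            diagnostics=payload["diagnostics"],
            column_order=payload.get("column_order"),
        )


# ---------------------------------------------------------------------------
# encoding


def _encode_column(
    s: pd.Series, semantic_type: str, config: SynthConfig
) -> tuple[np.ndarray, _AttributeModel]:
    """Map a raw column to integer codes plus the decoding metadata."""
    name = str(s.name)
    if semantic_type in (CATEGORICAL, BINARY):
        counts = s.value_counts(dropna=False)
        keep = counts[counts >= config.rare_category_min_count]
        rare = counts[counts < config.rare_category_min_count]
        labels = list(keep.index)
        decode_map: dict = {}
        if len(rare) > 0:
            mode = counts.idxmax()
            labels.append(POOLED)
            decode_map[POOLED] = mode
        model = _AttributeModel(
            name=name,
            kind="categorical",
            categories=[None if pd.isna(l) else l for l in labels],
            decode_map={k: (None if pd.isna(v) else v) for k, v in decode_map.items()},
        )
        lookup = {l: i for i, l in enumerate(labels)}
        pooled_code = lookup.get(POOLED)
        codes = np.array(
            [lookup.get(v, pooled_code if pooled_code is not None else 0) for v in s]
        )
        return codes, model

    if semantic_type == DATE:
        days = (pd.to_datetime(s, errors="coerce") - pd.Timestamp("1970-01-01")).dt.days
        codes, model = _encode_numeric(days.astype(float), name, config, integer=True)
        model.kind = "date"
        return codes, model

    integer = semantic_type in (AGE, DAY_OFFSET, EVENT_TIME)
    codes, model = _encode_numeric(
        pd.to_numeric(s, errors="coerce").astype(float), name, config, integer=integer
    )
    return codes, model


def _encode_numeric(
    vals: pd.Series, name: str, config: SynthConfig, integer: bool
) -> tuple[np.ndarray, _AttributeModel]:
    lo_q, hi_q = config.clip_quantiles
    finite = vals.dropna()
    if finite.empty:
        raise ValueError(f"attribute {name!r} has no observed values")
    lo, hi = float(finite.quantile(lo_q)), float(finite.quantile(hi_q))
    if hi <= lo:
        warnings.warn(f"attribute {name!r} is (near-)constant; modeled as constant")
        hi = lo
        edges = np.array([lo, lo])
    else:
        edges = np.unique(np.quantile(finite.clip(lo, hi), np.linspace(0, 1, config.n_bins + 1)))
        if len(edges) < 2:
            edges = np.array([lo, hi])
    clipped = vals.clip(lo, hi)
    codes = np.searchsorted(edges[1:-1], clipped.to_numpy(), side="right")
    codes = np.where(vals.isna(), 0, codes).astype(int)
    model = _AttributeModel(
        name=name,
        kind="numeric",
        integer=integer,
        bin_edges=edges.tolist(),
        clip_bounds=(lo, hi),
    )
    return codes, model


# ---------------------------------------------------------------------------
# fitting


def _cpt_from_counts(
    parent_codes: np.ndarray, child_codes: np.ndarray, n_child: int, smoothing: float
) -> dict[str, list[float]]:
    df = pd.DataFrame({"p": [",".join(map(str, r)) for r in parent_codes], "c": child_codes})
    table: dict[str, list[float]] = {}
    for key, grp in df.groupby("p", sort=True):
        counts = np.bincount(grp["c"], minlength=n_child).astype(float)
        probs = (counts + smoothing) / (counts.sum() + smoothing * n_child)
        table[key] = probs.tolist()
    return table


def _loglik(
    cpt: dict, marginal: np.ndarray, parent_codes: np.ndarray, child_codes: np.ndarray
) -> float:
    total = 0.0
    for row, c in zip(parent_codes, child_codes):
        probs = cpt.get(",".join(map(str, row)))
        p = probs[c] if probs is not None else marginal[c]
        total += np.log(max(p, 1e-300))
    return total


def fit(table: CohortTable, config: SynthConfig | None = None) -> GeneratorModel:
    """Fit the autoregressive chain on a cohort (>= 50 records)."""
    config = config or SynthConfig()
    schema = table.schema
    df = table.df
    if len(df) < 50:
        raise ValueError("need at least 50 records to fit the generator")

    rng = np.random.default_rng(config.seed)
    n = len(df)
    holdout_mask = np.zeros(n, dtype=bool)
    holdout_mask[rng.choice(n, size=max(1, int(n * config.holdout_fraction)), replace=False)] = True

    # chain order: treatment arm first (so every attribute can condition on
    # it directly, preserving group-stratified marginals), then schema order
    names = [a.name for a in schema.attributes if a.name in df.columns]
    if schema.treatment_column in names:
        names.remove(schema.treatment_column)
        names.insert(0, schema.treatment_column)
    codes: dict[str, np.ndarray] = {}
    models: dict[str, _AttributeModel] = {}
    for name in names:
        attr = schema[name]
        c, m = _encode_column(df[name], attr.semantic_type, config)
        codes[name] = c
        models[name] = m

    diagnostics: dict = {"parent_trace": {}, "holdout_loglik": {}}
    for j, name in enumerate(names):
        child = codes[name]
        n_child = (
            len(models[name].categories)
            if models[name].kind == "categorical"
            else max(len(models[name].bin_edges) - 1, 1)
        )
        counts = np.bincount(child[~holdout_mask], minlength=n_child).astype(float)
        marginal = (counts + config.smoothing) / (
            counts.sum() + config.smoothing * n_child
        )
        models[name].marginal = marginal.tolist()

        # the treatment arm is a forced parent: arm-stratified
        # distributions drive every downstream analysis and must not be
        # lost to greedy selection noise
        tcol = schema.treatment_column
        forced = (
            [tcol]
            if tcol in names[:j] and models[tcol].n_values > 1
            else []
        )
        parents: list[str] = list(forced)
        trace = []
        if parents:
            pc0 = np.column_stack([codes[p] for p in parents])
            cpt0 = _cpt_from_counts(
                pc0[~holdout_mask], child[~holdout_mask], n_child, config.smoothing
            )
            current_ll = _loglik(cpt0, marginal, pc0[holdout_mask], child[holdout_mask])
        else:
            empty = np.empty((n, 0), dtype=int)
            current_ll = _loglik({}, marginal, empty[holdout_mask], child[holdout_mask])
        candidates = [c for c in names[:j] if c not in parents]
        while len(parents) < config.max_parents and candidates:
            best_gain, best_cand, best_cpt = -np.inf, None, None
            for cand in candidates:
                pc = np.column_stack([codes[p] for p in parents + [cand]])
                cpt = _cpt_from_counts(
                    pc[~holdout_mask], child[~holdout_mask], n_child, config.smoothing
                )
                ll = _loglik(cpt, marginal, pc[holdout_mask], child[holdout_mask])
                if ll - current_ll > best_gain:
                    best_gain, best_cand, best_cpt = ll - current_ll, cand, cpt
            trace.append({"candidate": best_cand, "gain": float(best_gain)})
            if best_gain <= config.min_holdout_gain:
                break  # early stopping: held-out likelihood stopped improving
            parents.append(best_cand)
            candidates = [c for c in candidates if c != best_cand]
            current_ll += best_gain
            models[name].cpt = best_cpt
        models[name].parents = parents
        if not parents:
            models[name].cpt = {}
        else:
            # refit the final table on all rows for sampling
            pc = np.column_stack([codes[p] for p in parents])
            models[name].cpt = _cpt_from_counts(pc, child, n_child, config.smoothing)
        diagnostics["parent_trace"][name] = trace
        diagnostics["holdout_loglik"][name] = float(current_ll)

    return GeneratorModel(
        schema_names=names,
        attributes=models,
        diagnostics=diagnostics,
        column_order=[c for c in df.columns if c in models],
    )


# ---------------------------------------------------------------------------
# sampling


def _decode(
    model: _AttributeModel, sampled: np.ndarray, rng: np.random.Generator
) -> pd.Series:
    if model.kind == "categorical":
        labels = [
            model.decode_map.get(c, c) if isinstance(c, str) else c
            for c in model.categories
        ]
        return pd.Series([labels[c] for c in sampled])
    edges = np.asarray(model.bin_edges, dtype=float)
    if len(edges) < 2 or edges[-1] <= edges[0]:
        vals = np.full(len(sampled), edges[0] if len(edges) else 0.0)
    else:
        lo = edges[sampled]
        hi = edges[sampled + 1]
        vals = lo + rng.random(len(sampled)) * (hi - lo)
    lo_b, hi_b = model.clip_bounds
    vals = np.clip(vals, lo_b, hi_b)
    if model.kind == "date":
        days = np.floor(vals + 0.5).astype(int)
        return pd.Series(
            [(pd.Timestamp("1970-01-01") + pd.Timedelta(days=int(d))).strftime("%Y-%m-%d") for d in days]
        )
    if model.integer:
        return pd.Series(np.floor(vals + 0.5).astype(int))
    return pd.Series(vals)


def sample(
    model: GeneratorModel, n: int, seed: int, schema: CohortSchema | None = None
) -> pd.DataFrame | CohortTable:
    """Draw ``n`` rows ancestrally in attribute order; deterministic given
    the seed."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    sampled_codes: dict[str, np.ndarray] = {}
    out: dict[str, pd.Series] = {}
    for name in model.schema_names:
        am = model.attributes[name]
        marginal = np.asarray(am.marginal)
        marginal = marginal / marginal.sum()
        if not am.parents:
            draws = rng.choice(len(marginal), size=n, p=marginal)
        else:
            pc = np.column_stack([sampled_codes[p] for p in am.parents])
            keys = np.array([",".join(map(str, r)) for r in pc])
            draws = np.zeros(n, dtype=int)
            for key in np.unique(keys):
                mask = keys == key
                probs = np.asarray(am.cpt.get(key, marginal))
                probs = probs / probs.sum()
                draws[mask] = rng.choice(len(probs), size=int(mask.sum()), p=probs)
        sampled_codes[name] = draws
        out[name] = _decode(am, draws, rng)
    df = pd.DataFrame(out)
    if model.column_order and all(c in df.columns for c in model.column_order):
        df = df[model.column_order]
    if schema is not None and all(c in df.columns for c in schema.names):
        return CohortTable(schema=schema, df=df)
    return df
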