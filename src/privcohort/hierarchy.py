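"""Generalization hierarchies for anonymization.

A hierarchy is an ordered list of transformation levels for one attribute:
level 0 is the identity, the last level is full suppression, and each level
strictly coarsens the previous one.  Numeric levels replace a value with
the midpoint of its interval (intervals anchored at 0, i.e. value v with
width w falls in [w*floor(v/w), w*(floor(v/w)+1))); categorical levels map
values to group labels.

Per-cell granularity loss follows the interval-width / domain-range form
for numerics and (covered values - 1) / (domain size - 1) for categoricals;
a suppressed cell has loss 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .schema import (
    AGE,
    BINARY,
    CATEGORICAL,
    DAY_OFFSET,
    EVENT_TIME,
    CohortSchema,
)

SUPPRESSED = "*"


class Hierarchy:
    """Base interface: n_levels, per-level transform / codes / loss."""

    attribute: str

    @property
    def n_levels(self) -> int:
        raise NotImplementedError

    def transform(self, values: pd.Series, level: int) -> pd.Series:
        raise NotImplementedError

    def codes(self, values: pd.Series, level: int) -> np.ndarray:
        """Integer group codes at a level (for equivalence-class grouping)."""
        raise NotImplementedError

    def level_loss(self, level: int) -> float:
        """Per-cell granularity loss at a level (value-independent)."""
        raise NotImplementedError

    def is_suppression(self, level: int) -> bool:
        return level == self.n_levels - 1


@dataclass
class IntervalHierarchy(Hierarchy):
    """Numeric hierarchy: identity, one level per interval width, suppression."""

    attribute: str
    widths: list[int]  # strictly increasing
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if sorted(self.widths) != list(self.widths):
            raise ValueError("widths must be increasing")
        if self.domain[1] <= self.domain[0]:
            raise ValueError("degenerate numeric domain")

    @property
    def n_levels(self) -> int:
        return len(self.widths) + 2

    def _midpoints(self, values: pd.Series, width: int) -> pd.Series:
        # midpoint of the interval clipped to the domain, so generalized
        # values never leave the attribute's observed range
        bucket = np.floor(values.astype(float) / width)
        lo = np.maximum(bucket * width, self.domain[0])
        hi = np.minimum((bucket + 1.0) * width, self.domain[1])
        mid = np.where(hi >= lo, 0.5 * (lo + hi), (bucket + 0.5) * width)
        return pd.Series(mid, index=values.index)

    def transform(self, values: pd.Series, level: int) -> pd.Series:
        if level == 0:
            return values.copy()
        if self.is_suppression(level):
            return pd.Series(SUPPRESSED, index=values.index)
        return self._midpoints(values, self.widths[level - 1])

    def codes(self, values: pd.Series, level: int) -> np.ndarray:
        if self.is_suppression(level):
            return np.zeros(len(values), dtype=np.int64)
        if level == 0:
            return pd.factorize(values)[0]
        width = self.widths[level - 1]
        return np.floor(values.to_numpy(dtype=float) / width).astype(np.int64)

    def level_loss(self, level: int) -> float:
        if level == 0:
            return 0.0
        if self.is_suppression(level):
            return 1.0
        span = self.domain[1] - self.domain[0]
        return min(self.widths[level - 1] / span, 1.0)


@dataclass
class CategoricalHierarchy(Hierarchy):
    """Categorical hierarchy: identity, optional grouping levels, suppression.

    ``groupings`` maps, per intermediate level, each raw value to a group
    label; omitted values stay as-is.
    """

    attribute: str
    domain: list
    groupings: list[dict] | None = None

    @property
    def n_levels(self) -> int:
        return 2 + (len(self.groupings) if self.groupings else 0)

    def _mapping(self, level: int) -> dict:
        return self.groupings[level - 1]

    def transform(self, values: pd.Series, level: int) -> pd.Series:
        if level == 0:
            return values.copy()
        if self.is_suppression(level):
            return pd.Series(SUPPRESSED, index=values.index)
        mapping = self._mapping(level)
        return values.map(lambda v: mapping.get(v, v))

    def codes(self, values: pd.Series, level: int) -> np.ndarray:
        if self.is_suppression(level):
            return np.zeros(len(values), dtype=np.int64)
        return pd.factorize(self.transform(values, level))[0]

    def level_loss(self, level: int) -> float:
        if level == 0:
            return 0.0
        if self.is_suppression(level):
            return 1.0
        d = len(self.domain)
        if d <= 1:
            return 0.0
        mapping = self._mapping(level)
        # mean loss over domain values of (group size - 1) / (domain - 1)
        sizes = {}
        for v in self.domain:
            g = mapping.get(v, v)
            sizes[g] = sizes.get(g, 0) + 1
        losses = [(sizes[mapping.get(v, v)] - 1) / (d - 1) for v in self.domain]
        return float(np.mean(losses))


def binary_hierarchy(attribute: str) -> CategoricalHierarchy:
    """Binary flags generalize only by suppression (two levels)."""
    return CategoricalHierarchy(attribute=attribute, domain=[0, 1])


AGE_WIDTHS = [5, 10]
OFFSET_WIDTHS = [30, 90, 360]


def default_hierarchies(
    schema: CohortSchema, df: pd.DataFrame
) -> dict[str, Hierarchy]:
    """Hierarchies for every generalizable attribute of a schema.

    Ages use 5/10-year intervals over the clinical age domain; day offsets,
    durations and event times use 30/90/360-day intervals over their
    observed range; categoricals and flags have identity + suppression.
    Date attributes are excluded: they are protected by within-class
    microaggregation, not lattice generalization.
    """
    out: dict[str, Hierarchy] = {}
    for attr in schema.attributes:
        name = attr.name
        if name not in df.columns:
            continue
        if attr.semantic_type == AGE:
            out[name] = IntervalHierarchy(name, AGE_WIDTHS, (18, 108))
        elif attr.semantic_type in (DAY_OFFSET, EVENT_TIME):
            col = pd.to_numeric(df[name], errors="coerce")
            lo, hi = float(col.min()), float(col.max())
            if not math.isfinite(lo) or hi <= lo:
                lo, hi = 0.0, max(hi if math.isfinite(hi) else 1.0, 1.0)
            out[name] = IntervalHierarchy(name, OFFSET_WIDTHS, (lo, hi))
        elif attr.semantic_type == BINARY:
            out[name] = binary_hierarchy(name)
        elif attr.semantic_type == CATEGORICAL:
            domain = sorted(df[name].dropna().unique().tolist())
            out[name] = CategoricalHierarchy(name, domain=domain)
    return out


def load_hierarchies(path: str, df: pd.DataFrame) -> dict[str, Hierarchy]:
    """Hierarchy spec from YAML: per attribute a type plus widths/domain or
    category groupings."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out: dict[str, Hierarchy] = {}
    for name, spec in payload.items():
        kind = spec["type"]
        if kind == "interval":
            domain = spec.get("domain")
            if domain is None:
                col = pd.to_numeric(df[name], errors="coerce")
                domain = [float(col.min()), float(col.max())]
            out[name] = IntervalHierarchy(name, list(spec["widths"]), tuple(domain))
        elif kind == "categorical":
            domain = spec.get("domain") or sorted(df[name].dropna().unique().tolist())
            out[name] = CategoricalHierarchy(
                name, domain=list(domain), groupings=spec.get("groupings")
            )
        else:
            raise ValueError(f"unknown hierarchy type {kind!r} for {name}")
    return out
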