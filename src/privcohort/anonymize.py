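"""k-anonymity / t-closeness anonymization with generalization-lattice search.

The anonymizer transforms a cohort until every equivalence class (records
sharing identical generalized quasi-identifier values) has at least ``k``
members and, for each sensitive attribute, the class-level value
distribution stays within total-variation distance ``t`` of the table-level
distribution (equal-distance t-closeness: with uniform ground distances the
earth-mover distance reduces to total variation).

Transformations combine per-attribute generalization (interval midpoints /
category groups), whole-attribute suppression (the hierarchy's top level),
record suppression of residual small or t-violating classes, and
within-class mean microaggregation for calendar dates.  Among the lattice
nodes examined, the returned node minimizes the granularity loss (mean
per-cell fraction of the domain covered by the generalized value; a
suppressed cell counts 1).

Search strategy: best-first expansion from the identity node ordered by a
generalization-only loss lower bound (exact once the frontier is
exhausted), combined with a greedy descent from the fully suppressed node
for lattices too large to enumerate.  A node cap keeps the search
desk-scale; ``search_complete`` records whether the bound-guided search
finished, in which case the result is the lattice optimum.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import SUPPRESSED, Hierarchy
from .schema import CohortSchema

_EPS = 1e-12


class InfeasibleAnonymizationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# privacy checkers


def _included_rows(df: pd.DataFrame, quasi_identifiers: list[str]) -> pd.Series:
    """Rows that are not fully suppressed over the quasi-identifiers."""
    sub = df[quasi_identifiers]
    suppressed = sub.isna() | (sub.astype(object) == SUPPRESSED)
    return ~suppressed.all(axis=1)


def check_k_anonymity(
    df: pd.DataFrame, quasi_identifiers: list[str], k: int
) -> tuple[bool, list[int]]:
    """True iff every equivalence class over the quasi-identifiers holds at
    least ``k`` records.  Fully suppressed records are excluded."""
    quasi_identifiers = [q for q in quasi_identifiers if q in df.columns]
    if not quasi_identifiers:
        warnings.warn("empty quasi-identifier set: k-anonymity is vacuous")
        return True, [len(df)] if len(df) else []
    mask = _included_rows(df, quasi_identifiers)
    sub = df.loc[mask, quasi_identifiers]
    if sub.empty:
        return True, []
    sizes = sub.groupby(quasi_identifiers, dropna=False, sort=True).size()
    return bool((sizes >= k).all()), sizes.tolist()


def check_t_closeness(
    df: pd.DataFrame,
    quasi_identifiers: list[str],
    sensitive_attribute: str,
    t: float,
) -> tuple[bool, dict]:
    """Equal-distance t-closeness: per equivalence class, the total-variation
    distance between the class's sensitive-value distribution and the whole
    table's must not exceed ``t``."""
    if sensitive_attribute not in df.columns:
        raise KeyError(f"sensitive attribute {sensitive_attribute!r} absent")
    quasi_identifiers = [q for q in quasi_identifiers if q in df.columns]
    mask = _included_rows(df, quasi_identifiers) if quasi_identifiers else pd.Series(
        True, index=df.index
    )
    sub = df.loc[mask]
    table_dist = sub[sensitive_attribute].value_counts(normalize=True, dropna=False)
    distances: dict = {}
    if not quasi_identifiers:
        warnings.warn("empty quasi-identifier set: single class equals table")
        groups = [("<all>", sub)]
    else:
        groups = sub.groupby(quasi_identifiers, dropna=False, sort=True)
    for key, g in groups:
        class_dist = g[sensitive_attribute].value_counts(normalize=True, dropna=False)
        aligned = pd.concat([class_dist, table_dist], axis=1).fillna(0.0)
        distances[key] = 0.5 * float((aligned.iloc[:, 0] - aligned.iloc[:, 1]).abs().sum())
    ok = all(d <= t + _EPS for d in distances.values())
    return ok, distances


# ---------------------------------------------------------------------------
# granularity loss


def _cell_matches(orig_t: pd.Series, transformed: pd.Series) -> np.ndarray:
    """Element-wise equality tolerant of numeric/string representation."""
    a = orig_t.to_numpy(dtype=object)
    b = transformed.to_numpy(dtype=object)
    out = np.zeros(len(a), dtype=bool)
    for i in range(len(a)):
        x, y = a[i], b[i]
        if x is None or y is None:
            out[i] = x is y
            continue
        try:
            out[i] = bool(np.isclose(float(x), float(y), atol=1e-9))
        except (TypeError, ValueError):
            out[i] = str(x) == str(y)
    return out


def granularity_loss(
    original: pd.DataFrame,
    transformed: pd.DataFrame,
    hierarchies: dict[str, Hierarchy],
) -> float:
    """Mean per-cell loss over the protected cells (hierarchy attributes).

    Per cell, loss is the loss of the lowest hierarchy level that reproduces
    the transformed value; a suppressed cell, record or attribute counts 1.
    """
    total = 0.0
    n_cells = 0
    present = transformed.index.intersection(original.index)
    n_removed = len(original.index) - len(present)
    for name, h in hierarchies.items():
        if name not in original.columns:
            continue
        n_cells += len(original)
        total += float(n_removed)  # suppressed records
        if name not in transformed.columns:
            total += float(len(present))  # whole attribute suppressed
            continue
        orig_col = original.loc[present, name]
        trans_col = transformed.loc[present, name]
        loss = np.full(len(present), np.nan)
        for level in range(h.n_levels):
            unresolved = np.isnan(loss)
            if not unresolved.any():
                break
            match = _cell_matches(h.transform(orig_col, level), trans_col)
            loss[unresolved & match] = h.level_loss(level)
        loss[np.isnan(loss)] = 1.0  # unexplained (e.g. cell-suppressed)
        total += float(loss.sum())
    if n_cells == 0:
        return 0.0
    return total / n_cells


# ---------------------------------------------------------------------------
# date handling


def microaggregate_dates(
    df: pd.DataFrame,
    date_attribute: str,
    equivalence_classes,
) -> pd.DataFrame:
    """Replace each class's dates with the class-wise mean date (rounded to
    the nearest day).  Missing dates are excluded from the mean; an
    all-missing class stays missing."""
    out = df.copy()
    dates = pd.to_datetime(df[date_attribute], errors="coerce")
    epoch = pd.Timestamp("1970-01-01")
    days = (dates - epoch).dt.days  # float, NaN for missing
    for idx in equivalence_classes:
        vals = days.loc[idx]
        if vals.notna().any():
            mean_day = int(np.floor(vals.mean() + 0.5))
            out.loc[idx, date_attribute] = (epoch + pd.Timedelta(days=mean_day)).strftime(
                "%Y-%m-%d"
            )
    return out


def dates_to_offsets(
    df: pd.DataFrame, anchor_attribute: str, columns: list[str]
) -> pd.DataFrame:
    """Convert date columns to integer day offsets relative to the anchor
    (offset 0 = the anchor date).  Missing anchors yield missing offsets."""
    out = df.copy()
    anchor = pd.to_datetime(df[anchor_attribute], errors="coerce")
    for col in columns:
        d = pd.to_datetime(df[col], errors="coerce")
        out[col] = (d - anchor).dt.days
    return out


def offsets_to_dates(
    df: pd.DataFrame, anchor_attribute: str, columns: list[str]
) -> pd.DataFrame:
    """Reconstruct concrete dates from the anchor plus (possibly
    generalized, midpoint-valued) day offsets, rounding to whole days."""
    out = df.copy()
    anchor = pd.to_datetime(df[anchor_attribute], errors="coerce")
    for col in columns:
        off = pd.to_numeric(df[col], errors="coerce")
        days = np.floor(off + 0.5)
        rebuilt = anchor + pd.to_timedelta(days, unit="D")
        out[col] = rebuilt.dt.strftime("%Y-%m-%d")
    return out


# ---------------------------------------------------------------------------
# configuration and result


@dataclass
class AnonConfig:
    k: int = 2
    t: float = 0.5
    protected_attributes: set[str] = field(default_factory=set)
    sensitive_attributes: set[str] = field(default_factory=set)
    microaggregate_attributes: set[str] = field(default_factory=set)
    drop_attributes: set[str] = field(default_factory=set)  # direct identifiers
    allow_attribute_suppression: bool = True
    allow_cell_suppression: bool = True
    record_suppression_limit: float = 1.0
    max_search_nodes: int = 4000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.t <= 1.0):
            raise ValueError("t must lie in (0, 1]")
        if not (0.0 <= self.record_suppression_limit <= 1.0):
            raise ValueError("record_suppression_limit must lie in [0, 1]")


@dataclass
class AnonResult:
    df: pd.DataFrame
    schema: CohortSchema | None
    chosen_levels: dict[str, int]
    suppressed_records: int
    suppressed_cells: int
    suppressed_attributes: set[str]
    loss: float
    quasi_identifiers: list[str]
    nodes_examined: int
    search_complete: bool


# ---------------------------------------------------------------------------
# lattice search


class _NodeEvaluator:
    """Vectorized evaluation of one lattice node (a level per QI)."""

    def __init__(
        self,
        df: pd.DataFrame,
        qis: list[str],
        hierarchies: dict[str, Hierarchy],
        sensitive: list[str],
        k: int,
        t: float,
        limit: float,
    ):
        self.n = len(df)
        self.qis = qis
        self.k = k
        self.t = t
        self.limit = limit
        self.codes = {
            q: [hierarchies[q].codes(df[q], lvl) for lvl in range(hierarchies[q].n_levels)]
            for q in qis
        }
        self.losses = {
            q: [hierarchies[q].level_loss(lvl) for lvl in range(hierarchies[q].n_levels)]
            for q in qis
        }
        self.sens_codes = {}
        for s in sensitive:
            c, _ = pd.factorize(df[s], use_na_sentinel=False)
            self.sens_codes[s] = (c.astype(np.int64), int(c.max()) + 1)
        self.n_prot = len(qis) + len(sensitive)

    def lower_bound(self, levels: tuple[int, ...]) -> float:
        if self.n_prot == 0:
            return 0.0
        return sum(self.losses[q][l] for q, l in zip(self.qis, levels)) / self.n_prot

    def evaluate(self, levels: tuple[int, ...]):
        """Return (feasible, total_loss, keep_mask, class_inverse)."""
        n = self.n
        if self.qis:
            key = np.column_stack([self.codes[q][l] for q, l in zip(self.qis, levels)])
            _, inv, counts = np.unique(
                key, axis=0, return_inverse=True, return_counts=True
            )
            inv = inv.ravel()
        else:
            inv = np.zeros(n, dtype=np.int64)
            counts = np.array([n])
        keep = counts[inv] >= self.k
        # suppress t-violating classes until stable
        for _ in range(len(counts) + 1):
            changed = False
            kept_total = keep.sum()
            if kept_total == 0:
                break
            for s, (sc, nv) in self.sens_codes.items():
                m = np.zeros((len(counts), nv))
                np.add.at(m, (inv[keep], sc[keep]), 1.0)
                class_tot = m.sum(axis=1)
                table = m.sum(axis=0) / kept_total
                with np.errstate(invalid="ignore", divide="ignore"):
                    dist = 0.5 * np.abs(
                        m / np.where(class_tot[:, None] > 0, class_tot[:, None], 1.0)
                        - table
                    ).sum(axis=1)
                bad = (class_tot > 0) & (dist > self.t + _EPS)
                if bad.any():
                    keep &= ~bad[inv]
                    changed = True
            if not changed:
                break
        suppressed = n - int(keep.sum())
        feasible = suppressed <= self.limit * n + _EPS
        if self.n_prot == 0:
            return feasible, 0.0, keep, inv
        gen_loss = sum(self.losses[q][l] for q, l in zip(self.qis, levels))
        total = (int(keep.sum()) * gen_loss + suppressed * self.n_prot) / (
            n * self.n_prot
        )
        return feasible, total, keep, inv


def _search(
    evaluator: _NodeEvaluator,
    max_levels: tuple[int, ...],
    max_nodes: int,
) -> tuple[tuple[int, ...] | None, float, int, bool]:
    """Best-first (exact when completed) plus greedy descent from the top."""
    n_qi = len(max_levels)
    best_levels: tuple[int, ...] | None = None
    best_loss = np.inf
    examined = 0
    cache: dict[tuple[int, ...], tuple[bool, float]] = {}

    def eval_node(levels: tuple[int, ...]) -> tuple[bool, float]:
        nonlocal examined, best_levels, best_loss
        if levels in cache:
            return cache[levels]
        feasible, total, _, _ = evaluator.evaluate(levels)
        examined += 1
        cache[levels] = (feasible, total)
        if feasible and (total, levels) < (best_loss, best_levels or levels):
            best_loss, best_levels = total, levels
        return feasible, total

    # Phase 1: bound-guided best-first from the identity node.
    start = tuple([0] * n_qi)
    heap = [(evaluator.lower_bound(start), start)]
    seen = {start}
    complete = True
    while heap:
        lb, levels = heapq.heappop(heap)
        if lb >= best_loss - _EPS:
            break  # all remaining nodes are at least this coarse
        if examined >= max_nodes:
            complete = False
            break
        eval_node(levels)
        for i in range(n_qi):
            if levels[i] < max_levels[i]:
                succ = levels[:i] + (levels[i] + 1,) + levels[i + 1 :]
                if succ not in seen:
                    seen.add(succ)
                    heapq.heappush(heap, (evaluator.lower_bound(succ), succ))
    if heap and not complete:
        # Phase 2 (large lattices): steepest descent from full suppression.
        current = tuple(max_levels)
        eval_node(current)
        _, current_loss = cache[current]
        budget = max_nodes + 2 * max_nodes  # descent gets its own allowance
        while examined < budget:
            candidates = []
            for i in range(n_qi):
                if current[i] > 0:
                    cand = current[:i] + (current[i] - 1,) + current[i + 1 :]
                    feasible, total = eval_node(cand)
                    if feasible:
                        candidates.append((total, cand))
            if not candidates:
                break
            candidates.sort()
            if candidates[0][0] < current_loss - _EPS:
                current_loss, current = candidates[0]
            else:
                break
    return best_levels, best_loss, examined, complete


def anonymize(
    table,
    config: AnonConfig,
    hierarchies: dict[str, Hierarchy],
    schema: CohortSchema | None = None,
) -> AnonResult:
    """Anonymize a cohort under ``config``; see the module docstring.

    ``table`` may be a CohortTable or a plain DataFrame.  Every protected
    attribute must either carry a hierarchy, be listed for
    microaggregation, or be listed for outright dropping (direct
    identifiers).
    """
    if hasattr(table, "df"):
        schema = schema or table.schema
        df = table.df.copy()
    else:
        df = table.copy()

    protected = set(config.protected_attributes) & set(df.columns)
    sensitive = sorted(set(config.sensitive_attributes) & protected & set(df.columns))
    micro = sorted(set(config.microaggregate_attributes) & protected)
    drop = sorted(set(config.drop_attributes) & set(df.columns))
    qis = [
        c
        for c in df.columns
        if c in protected and c not in sensitive and c not in micro and c not in drop
    ]
    missing = [q for q in qis if q not in hierarchies]
    if missing:
        raise ValueError(f"no hierarchy for protected attributes: {missing}")

    work = df.drop(columns=drop)
    evaluator = _NodeEvaluator(
        work, qis, hierarchies, sensitive, config.k, config.t,
        config.record_suppression_limit,
    )
    top = tuple(
        hierarchies[q].n_levels - (1 if config.allow_attribute_suppression else 2)
        for q in qis
    )
    top = tuple(max(l, 0) for l in top)
    best, best_loss, examined, complete = _search(
        evaluator, top, config.max_search_nodes
    )
    if best is None:
        raise InfeasibleAnonymizationError(
            f"no transformation satisfies k={config.k}, t={config.t} within the "
            f"record-suppression limit of {config.record_suppression_limit:.0%}"
        )

    _, total, keep, inv = evaluator.evaluate(best)
    out = work.loc[keep].copy()
    suppressed_attrs: set[str] = set(drop)
    for q, lvl in zip(qis, best):
        h = hierarchies[q]
        if h.is_suppression(lvl):
            out = out.drop(columns=[q])
            suppressed_attrs.add(q)
        elif lvl > 0:
            out[q] = h.transform(work[q], lvl).loc[keep]

    # microaggregate dates within the final equivalence classes
    kept_inv = inv[keep]
    classes = [out.index[kept_inv == c] for c in np.unique(kept_inv)]
    for m in micro:
        out = microaggregate_dates(out, m, classes)

    return AnonResult(
        df=out,
        schema=schema,
        chosen_levels={q: int(l) for q, l in zip(qis, best)},
        suppressed_records=int(len(work) - keep.sum()),
        suppressed_cells=0,
        suppressed_attributes=suppressed_attrs,
        loss=float(total),
        quasi_identifiers=[q for q in qis if q not in suppressed_attrs],
        nodes_examined=examined,
        search_complete=complete,
    )
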