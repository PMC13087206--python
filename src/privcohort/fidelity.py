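"""Fidelity: structural similarity between a protected cohort and its source.

Three layers of comparison:

* univariate — per-treatment-group prevalences of the binary flags,
  expressed as a percentage of the original value (baseline 100), with a
  group-level mean absolute deviation;
* bivariate — pairwise Pearson correlations over the numeric attributes
  (binary flags enter as 0/1, i.e. point-biserial), summarized as the mean
  absolute difference to the original correlation matrix;
* multivariate — integrated alpha-precision (IP-alpha: protected records
  inside the original's support), integrated beta-recall (IR-beta: original
  records covered by the protected support) and authenticity (protected
  records that are not near-copies of originals), computed on min-max
  normalized numerics with original-data median imputation.

The alpha-support is estimated by distance-from-center quantile balls in
the normalized space: the alpha-ball of a dataset is the sphere around its
centroid holding the alpha-quantile of its own records.  The precision and
recall curves are integrated against the ideal diagonal over a 20-point
level grid (trapezoid rule), so a dataset compared with itself scores ~1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .schema import CohortSchema, BINARY, COMORBIDITY

DEFAULT_GRID = 20


@dataclass
class FidelityReport:
    normalized_prevalence: pd.DataFrame
    mean_abs_deviation: dict[str, float]
    correlation_distance: float
    correlation_diff: pd.DataFrame
    undefined_pairs: list[tuple[str, str]]
    ip_alpha: float
    ir_beta: float
    authenticity: float

    def to_dict(self) -> dict:
        return {
            "mean_abs_deviation": self.mean_abs_deviation,
            "correlation_distance": self.correlation_distance,
            "undefined_pairs": [list(p) for p in self.undefined_pairs],
            "ip_alpha": self.ip_alpha,
            "ir_beta": self.ir_beta,
            "authenticity": self.authenticity,
            "normalized_prevalence": self.normalized_prevalence.to_dict("records"),
        }


# ---------------------------------------------------------------------------
# univariate


def normalized_prevalence(
    original: pd.DataFrame,
    protected: pd.DataFrame,
    group_column: str,
    flags: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Within-group flag prevalences of the protected data as a percentage
    of the original (100 = perfectly preserved).

    Suppressed attributes and flags with zero original prevalence are
    flagged and excluded from the group-level mean absolute deviation,
    which is reported as a fraction (``|normalized - 100| / 100``).
    """
    if flags is None:
        flags = [
            c
            for c in original.columns
            if c != group_column and set(pd.unique(original[c].dropna())) <= {0, 1}
        ]
    groups = sorted(original[group_column].dropna().unique())
    rows = []
    for flag in flags:
        for g in groups:
            p_orig = float(original.loc[original[group_column] == g, flag].mean())
            status = "ok"
            p_prot = np.nan
            norm = np.nan
            if flag not in protected.columns:
                status = "suppressed"
            elif group_column not in protected.columns:
                status = "group-suppressed"
            else:
                sel = protected.loc[protected[group_column] == g, flag]
                p_prot = float(sel.mean()) if len(sel) else np.nan
                if p_orig == 0:
                    status = "undefined"
                elif np.isnan(p_prot):
                    status = "empty-group"
                elif p_prot == p_orig:
                    norm = 100.0  # identity is exact, not a float ratio
                else:
                    norm = 100.0 * p_prot / p_orig
            rows.append(
                {
                    "attribute": flag,
                    "group": g,
                    "original": p_orig,
                    "protected": p_prot,
                    "normalized": norm,
                    "status": status,
                }
            )
    table = pd.DataFrame(rows)
    deviation = {}
    for g in groups:
        ok = table[(table["group"] == g) & (table["status"] == "ok")]
        deviation[g] = (
            float((ok["normalized"] - 100.0).abs().mean() / 100.0) if len(ok) else np.nan
        )
    return table, deviation


# ---------------------------------------------------------------------------
# bivariate


def _numeric_frame(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = {}
    for c in columns:
        if c in df.columns:
            out[c] = pd.to_numeric(df[c], errors="coerce")
    return pd.DataFrame(out)


def correlation_distance(
    original: pd.DataFrame,
    protected: pd.DataFrame,
    columns: list[str] | None = None,
) -> tuple[float, pd.DataFrame, list[tuple[str, str]]]:
    """Mean absolute difference of pairwise Pearson correlations.

    Pairs undefined in either dataset (zero variance or suppressed column)
    are excluded and reported.
    """
    if columns is None:
        columns = [
            c
            for c in original.columns
            if pd.to_numeric(original[c], errors="coerce").notna().any()
        ]
    a = _numeric_frame(original, columns)
    b = _numeric_frame(protected, columns)
    usable = [c for c in a.columns if a[c].notna().any()]
    if len(usable) < 2:
        raise ValueError("need at least two usable numeric attributes")
    corr_a = a[usable].corr()
    corr_b = b.reindex(columns=usable).corr().reindex(index=usable, columns=usable)
    diff = (corr_a - corr_b).abs()
    undefined = []
    vals = []
    for i, ci in enumerate(usable):
        for cj in usable[i + 1 :]:
            d = diff.loc[ci, cj]
            if np.isnan(d):
                undefined.append((ci, cj))
            else:
                vals.append(float(d))
    scalar = float(np.mean(vals)) if vals else np.nan
    return scalar, diff, undefined


# ---------------------------------------------------------------------------
# multivariate


def impute_and_normalize(df: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Min-max normalize against the reference; missing values (including
    entire suppressed columns) are imputed with the reference column
    median before scaling.  Constant reference columns map to 0.5."""
    cols = [
        c
        for c in reference.columns
        if pd.to_numeric(reference[c], errors="coerce").notna().any()
    ]
    extra = [
        c
        for c in df.columns
        if c not in reference.columns
        and pd.to_numeric(df[c], errors="coerce").notna().any()
    ]
    if extra:
        raise ValueError(f"columns absent from the reference: {extra}")
    ref = _numeric_frame(reference, cols)
    out = np.empty((len(df), len(cols)))
    for j, c in enumerate(cols):
        lo, hi, med = ref[c].min(), ref[c].max(), ref[c].median()
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        else:
            vals = np.full(len(df), np.nan)
        vals = np.where(np.isnan(vals), med, vals)
        if hi > lo:
            out[:, j] = (vals - lo) / (hi - lo)
        else:
            out[:, j] = 0.5
    return out


def _support_curve(
    reference: np.ndarray, query: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Fraction of query points inside the reference's alpha-quantile ball,
    per grid level."""
    center = reference.mean(axis=0)
    ref_d = np.linalg.norm(reference - center, axis=1)
    q_d = np.linalg.norm(query - center, axis=1)
    radii = np.quantile(ref_d, grid)
    return np.array([(q_d <= r + 1e-12).mean() for r in radii])


def _integrate_against_diagonal(curve: np.ndarray, grid: np.ndarray) -> float:
    deviation = np.trapezoid(np.abs(curve - grid), grid)
    return float(np.clip(1.0 - 2.0 * deviation, 0.0, 1.0))


def precision_recall_authenticity(
    original: pd.DataFrame,
    protected: pd.DataFrame,
    n_grid: int = DEFAULT_GRID,
) -> tuple[float, float, float]:
    """(IP-alpha, IR-beta, authenticity) on min-max normalized numerics.

    Authenticity: fraction of protected records whose nearest original
    neighbor is farther away than that original record's own nearest
    neighbor within the original data (exact nearest-neighbor computation).
    """
    if len(original) < 10 or len(protected) < 10:
        raise ValueError("need at least 10 records per dataset")
    x = impute_and_normalize(original, original)
    y = impute_and_normalize(protected, original)
    if np.allclose(x.std(axis=0), 0.0):
        raise ValueError("all-constant data: multivariate metrics undefined")
    grid = np.linspace(1.0 / n_grid, 1.0, n_grid)
    ip_alpha = _integrate_against_diagonal(_support_curve(x, y, grid), grid)
    ir_beta = _integrate_against_diagonal(_support_curve(y, x, grid), grid)

    nn_orig = NearestNeighbors(n_neighbors=2).fit(x)
    d_self, _ = nn_orig.kneighbors(x)
    own_nn = d_self[:, 1]  # distance to nearest *other* original record
    d_prot, idx = nn_orig.kneighbors(y, n_neighbors=1)
    authenticity = float((d_prot[:, 0] > own_nn[idx[:, 0]] + 1e-12).mean())
    return ip_alpha, ir_beta, authenticity


# ---------------------------------------------------------------------------
# report


def fidelity_report(
    original: pd.DataFrame,
    protected: pd.DataFrame,
    group_column: str,
    schema: CohortSchema | None = None,
) -> FidelityReport:
    flags = None
    numeric_cols = None
    if schema is not None:
        flags = [
            a.name
            for a in schema.attributes
            if a.role == COMORBIDITY and a.semantic_type == BINARY
            and a.name in original.columns
        ]
        numeric_cols = [
            c
            for c in original.columns
            if pd.to_numeric(original[c], errors="coerce").notna().any()
        ]
    prev, dev = normalized_prevalence(original, protected, group_column, flags)
    dist, diff, undef = correlation_distance(original, protected, numeric_cols)
    ip_a, ir_b, auth = precision_recall_authenticity(original, protected)
    return FidelityReport(
        normalized_prevalence=prev,
        mean_abs_deviation=dev,
        correlation_distance=dist,
        correlation_diff=diff,
        undefined_pairs=undef,
        ip_alpha=ip_a,
        ir_beta=ir_b,
        authenticity=auth,
    )
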