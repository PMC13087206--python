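"""Anonymizer: privacy checkers, granularity loss, date handling, and
lattice-search optimality against an exhaustive-enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from privcohort.anonymize import (
    AnonConfig,
    anonymize,
    check_k_anonymity,
    check_t_closeness,
    dates_to_offsets,
    granularity_loss,
    microaggregate_dates,
    offsets_to_dates,
)
from privcohort.hierarchy import (
    SUPPRESSED,
    CategoricalHierarchy,
    IntervalHierarchy,
    binary_hierarchy,
)


# ---------------------------------------------------------------------------
# checkers


class TestKAnonymity:
    def test_pairs_satisfy_k2(self):
        df = pd.DataFrame({"qi": ["A", "A", "B", "B"]})
        ok, sizes = check_k_anonymity(df, ["qi"], 2)
        assert ok and sorted(sizes) == [2, 2]

    def test_pairs_fail_k3(self):
        df = pd.DataFrame({"qi": ["A", "A", "B", "B"]})
        ok, _ = check_k_anonymity(df, ["qi"], 3)
        assert not ok

    def test_offending_singleton_class(self):
        # classes of sizes 3, 2, 1 enumerated by hand
        df = pd.DataFrame({"qi": ["A", "A", "A", "B", "B", "C"]})
        ok, sizes = check_k_anonymity(df, ["qi"], 2)
        assert not ok
        assert sorted(sizes) == [1, 2, 3]

    def test_empty_qi_set_vacuous_with_warning(self):
        df = pd.DataFrame({"x": [1, 2]})
        with pytest.warns(UserWarning, match="vacuous"):
            ok, _ = check_k_anonymity(df, [], 5)
        assert ok

    def test_fully_suppressed_rows_excluded(self):
        df = pd.DataFrame({"qi": ["A", "A", SUPPRESSED]})
        ok, sizes = check_k_anonymity(df, ["qi"], 2)
        assert ok and sizes == [2]


class TestTCloseness:
    def test_class_equal_to_table_passes_any_t(self):
        df = pd.DataFrame({"qi": ["A", "A", "B", "B"], "s": [0, 1, 0, 1]})
        ok, dist = check_t_closeness(df, ["qi"], "s", 0.01)
        assert ok and all(d == 0 for d in dist.values())

    def test_homogeneous_class_against_balanced_table(self):
        # table is 50/50; one class entirely value 1 -> TV distance 0.5
        df = pd.DataFrame({"qi": ["A", "A", "B", "B"], "s": [1, 1, 0, 0]})
        ok_05, dist = check_t_closeness(df, ["qi"], "s", 0.5)
        assert ok_05 and max(dist.values()) == pytest.approx(0.5)
        ok_04, _ = check_t_closeness(df, ["qi"], "s", 0.4)
        assert not ok_04

    def test_single_class_always_passes(self):
        df = pd.DataFrame({"qi": ["A"] * 6, "s": [0, 0, 0, 1, 1, 1]})
        ok, _ = check_t_closeness(df, ["qi"], "s", 0.01)
        assert ok

    def test_missing_sensitive_attribute_rejected(self):
        with pytest.raises(KeyError):
            check_t_closeness(pd.DataFrame({"qi": [1]}), ["qi"], "nope", 0.5)


# ---------------------------------------------------------------------------
# granularity


class TestGranularityLoss:
    def test_identity_is_zero(self):
        df = pd.DataFrame({"age": [30, 40, 50]})
        h = {"age": IntervalHierarchy("age", [10], (18, 108))}
        assert granularity_loss(df, df.copy(), h) == 0.0

    def test_full_suppression_is_one(self):
        df = pd.DataFrame({"age": [30, 40, 50]})
        h = {"age": IntervalHierarchy("age", [10], (18, 108))}
        sup = pd.DataFrame({"age": [SUPPRESSED] * 3})
        assert granularity_loss(df, sup, h) == 1.0

    def test_ten_year_bucket_over_ninety_year_domain(self):
        # width 10 over domain 18..108 (range 90) -> per-cell loss 10/90
        # (values distinct from the interval midpoint: a cell whose raw
        # value equals the midpoint is indistinguishable from identity)
        df = pd.DataFrame({"age": [31, 36, 39]})
        h = IntervalHierarchy("age", [10], (18, 108))
        transformed = pd.DataFrame({"age": h.transform(df["age"], 1)})
        assert granularity_loss(df, transformed, {"age": h}) == pytest.approx(10 / 90)

    def test_removed_records_count_as_suppressed(self):
        df = pd.DataFrame({"age": [30, 40]}, index=[0, 1])
        h = {"age": IntervalHierarchy("age", [10], (18, 108))}
        assert granularity_loss(df, df.iloc[:1], h) == pytest.approx(0.5)

    def test_single_value_categorical_domain_costs_nothing(self):
        h = CategoricalHierarchy("c", domain=["only"], groupings=[{"only": "g"}])
        assert h.level_loss(1) == 0.0


# ---------------------------------------------------------------------------
# dates


class TestDateOperations:
    def test_mean_of_two_dates(self):
        df = pd.DataFrame({"d": ["2020-01-01", "2020-01-03"]})
        out = microaggregate_dates(df, "d", [df.index])
        assert list(out["d"]) == ["2020-01-02", "2020-01-02"]

    def test_singleton_class_unchanged(self):
        df = pd.DataFrame({"d": ["2021-06-15"]})
        out = microaggregate_dates(df, "d", [df.index])
        assert out["d"].iloc[0] == "2021-06-15"

    def test_mean_rounding_to_day_seven(self):
        # days 0, 10, 11 since epoch -> mean 7.0 -> day 7
        df = pd.DataFrame({"d": ["1970-01-01", "1970-01-11", "1970-01-12"]})
        out = microaggregate_dates(df, "d", [df.index])
        assert set(out["d"]) == {"1970-01-08"}  # day 7 relative to epoch day 0

    def test_all_missing_class_left_missing(self):
        df = pd.DataFrame({"d": [None, None]})
        out = microaggregate_dates(df, "d", [df.index])
        assert out["d"].isna().all()

    def test_offset_day_arithmetic(self):
        df = pd.DataFrame({"anchor": ["2020-03-01"], "ev": ["2020-03-31"]})
        out = dates_to_offsets(df, "anchor", ["ev"])
        assert out["ev"].iloc[0] == 30

    def test_midpoint_reconstruction(self):
        # offset generalized to [0, 30) -> midpoint 15 -> anchor + 15 days
        df = pd.DataFrame({"anchor": ["2020-03-01"], "ev": [15.0]})
        out = offsets_to_dates(df, "anchor", ["ev"])
        assert out["ev"].iloc[0] == "2020-03-16"

    def test_round_trip_identity_at_level_zero(self):
        df = pd.DataFrame(
            {"anchor": ["2020-03-01", "2021-01-10"], "ev": ["2020-04-15", "2021-01-05"]}
        )
        off = dates_to_offsets(df, "anchor", ["ev"])
        back = offsets_to_dates(off, "anchor", ["ev"])
        assert list(back["ev"]) == list(df["ev"])

    def test_missing_anchor_gives_missing_offsets(self):
        df = pd.DataFrame({"anchor": [None], "ev": ["2020-04-15"]})
        out = dates_to_offsets(df, "anchor", ["ev"])
        assert out["ev"].isna().all()


# ---------------------------------------------------------------------------
# exhaustive oracle for the lattice search


def _oracle_optimum(df, qis, hierarchies, k, sensitive=(), t=1.0, limit=1.0):
    """Brute-force enumeration of every lattice node, applying the same
    class-suppression semantics, independent of the search code."""
    n = len(df)
    n_prot = len(qis) + len(sensitive)
    best = np.inf
    for levels in itertools.product(*[range(hierarchies[q].n_levels) for q in qis]):
        tdf = pd.DataFrame(
            {q: hierarchies[q].transform(df[q], lv).astype(str) for q, lv in zip(qis, levels)}
        )
        key = tdf.apply(lambda r: tuple(r), axis=1)
        sizes = key.map(key.value_counts())
        keep = (sizes >= k).to_numpy()
        for _ in range(n + 1):  # t-closeness fixpoint by class suppression
            changed = False
            for s in sensitive:
                sub = df.loc[keep, s]
                if sub.empty:
                    break
                table = sub.value_counts(normalize=True)
                for cls_key in key[keep].unique():
                    cls_vals = df.loc[keep & (key == cls_key).to_numpy(), s]
                    cls_dist = cls_vals.value_counts(normalize=True)
                    aligned = pd.concat([cls_dist, table], axis=1).fillna(0.0)
                    tv = 0.5 * (aligned.iloc[:, 0] - aligned.iloc[:, 1]).abs().sum()
                    if tv > t + 1e-12:
                        keep &= ~(key == cls_key).to_numpy()
                        changed = True
            if not changed:
                break
        suppressed = n - keep.sum()
        if suppressed > limit * n + 1e-12:
            continue
        gen = sum(hierarchies[q].level_loss(lv) for q, lv in zip(qis, levels))
        loss = (keep.sum() * gen + suppressed * n_prot) / (n * n_prot)
        best = min(best, loss)
    return best


def _random_instance(rng):
    n = int(rng.integers(3, 9))
    n_attrs = int(rng.integers(1, 4))
    cols, hiers = {}, {}
    for j in range(n_attrs):
        name = f"a{j}"
        if rng.random() < 0.5:
            vals = rng.integers(0, 10, n)
            cols[name] = vals
            hiers[name] = IntervalHierarchy(name, [2, 4], (0, 10))
        else:
            vals = rng.choice(["x", "y", "z"], n)
            cols[name] = vals
            hiers[name] = CategoricalHierarchy(name, domain=["x", "y", "z"])
    return pd.DataFrame(cols), list(cols), hiers


class TestLatticeSearchOracle:
    @pytest.mark.parametrize("seed", range(25))
    def test_search_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        df, qis, hiers = _random_instance(rng)
        k = int(rng.integers(1, 4))
        cfg = AnonConfig(k=k, t=1.0, protected_attributes=set(qis))
        res = anonymize(df, cfg, hiers)
        oracle = _oracle_optimum(df, qis, hiers, k)
        assert res.search_complete
        assert res.loss == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_search_matches_oracle_with_t_closeness(self, seed):
        rng = np.random.default_rng(100 + seed)
        df, qis, hiers = _random_instance(rng)
        df["s"] = rng.integers(0, 2, len(df))
        cfg = AnonConfig(
            k=2, t=0.4, protected_attributes=set(qis) | {"s"},
            sensitive_attributes={"s"},
        )
        res = anonymize(df, cfg, hiers)
        oracle = _oracle_optimum(df, qis, hiers, 2, sensitive=["s"], t=0.4)
        assert res.loss == pytest.approx(oracle, abs=1e-12)


class TestAnonymize:
    def test_vacuous_constraints_identity(self):
        df = pd.DataFrame({"age": [21, 35, 60], "flag": [0, 1, 0]})
        hiers = {
            "age": IntervalHierarchy("age", [5, 10], (18, 108)),
            "flag": binary_hierarchy("flag"),
        }
        cfg = AnonConfig(k=1, t=1.0, protected_attributes={"age", "flag"})
        res = anonymize(df, cfg, hiers)
        assert res.loss == 0.0
        assert res.suppressed_records == 0
        assert all(lv == 0 for lv in res.chosen_levels.values())

    def test_toy_ages_suppress_the_isolated_record(self):
        # ages 21,22,23,41,42,80 with k=2: the 80-year-old cannot share a
        # 10-year bucket, so the optimum suppresses (or fully generalizes) it
        df = pd.DataFrame({"age": [21, 22, 23, 41, 42, 80], "s": [0, 1, 0, 1, 0, 1]})
        hiers = {"age": IntervalHierarchy("age", [10], (0, 100))}
        cfg = AnonConfig(k=2, t=1.0, protected_attributes={"age"})
        res = anonymize(df, cfg, hiers)
        ok, _ = check_k_anonymity(res.df, ["age"], 2)
        assert ok
        assert res.suppressed_records >= 1 or "age" in res.suppressed_attributes

    def test_loss_monotone_in_k(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(
            {"age": rng.integers(20, 90, 30), "flag": rng.integers(0, 2, 30)}
        )
        hiers = {
            "age": IntervalHierarchy("age", [5, 10], (18, 108)),
            "flag": binary_hierarchy("flag"),
        }
        losses = []
        for k in (1, 2, 3, 5):
            cfg = AnonConfig(k=k, t=1.0, protected_attributes={"age", "flag"})
            losses.append(anonymize(df, cfg, hiers).loss)
        assert losses == sorted(losses)

    def test_result_satisfies_both_checkers(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "age": rng.integers(20, 90, 60),
                "dur": rng.integers(0, 365, 60),
                "s": rng.integers(0, 2, 60),
            }
        )
        hiers = {
            "age": IntervalHierarchy("age", [5, 10], (18, 108)),
            "dur": IntervalHierarchy("dur", [30, 90, 360], (0, 365)),
        }
        cfg = AnonConfig(
            k=2, t=0.5, protected_attributes={"age", "dur", "s"},
            sensitive_attributes={"s"},
        )
        res = anonymize(df, cfg, hiers)
        qis = res.quasi_identifiers
        ok_k, _ = check_k_anonymity(res.df, qis, 2)
        ok_t, _ = check_t_closeness(res.df, qis, "s", 0.5)
        assert ok_k and ok_t

    def test_infeasible_with_zero_suppression_budget(self):
        df = pd.DataFrame({"age": [20, 30, 40, 99]})
        hiers = {"age": IntervalHierarchy("age", [5], (18, 108))}
        cfg = AnonConfig(
            k=4, t=1.0, protected_attributes={"age"},
            allow_attribute_suppression=False, record_suppression_limit=0.0,
        )
        from privcohort.anonymize import InfeasibleAnonymizationError

        with pytest.raises(InfeasibleAnonymizationError):
            anonymize(df, cfg, hiers)

    def test_missing_hierarchy_rejected(self):
        df = pd.DataFrame({"x": [1, 2]})
        with pytest.raises(ValueError, match="hierarchy"):
            anonymize(df, AnonConfig(protected_attributes={"x"}), {})
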