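"""Privacy attacks: risk normalization, leak detection, null calibration,
target selection, marginal features and membership inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from privcohort import attacks
from privcohort.attacks import (
    AttackConfig,
    MIAConfig,
    attribute_inference,
    constant_protector,
    coverage_probability,
    fit_feature_spec,
    identity_protector,
    linkage,
    marginal_features,
    membership_inference,
    risk_score,
    select_targets,
    singling_out,
)


class TestRiskScore:
    @pytest.mark.parametrize(
        "r_main,r_control,expected",
        [
            # the four printed attack-rate pairs and their published risks
            (0.960, 0.926, 0.46),
            (0.968, 0.957, 0.26),
            (0.916, 0.894, 0.21),
            (0.235, 0.037, 0.21),
        ],
    )
    def test_published_rate_pairs(self, r_main, r_control, expected):
        assert round(risk_score(r_main, r_control), 2) == expected

    def test_equal_rates_give_zero(self):
        assert risk_score(0.4, 0.4) == 0.0

    def test_perfect_main_attack_gives_one(self):
        assert risk_score(1.0, 0.4) == pytest.approx(1.0)

    def test_perfect_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            risk_score(0.9, 1.0)

    @given(
        m=st.floats(0, 1, allow_nan=False),
        c=st.floats(0, 0.999, allow_nan=False),
    )
    def test_bounded_above_by_one_and_sign_matches_excess(self, m, c):
        r = risk_score(m, c)
        assert r <= 1.0 + 1e-12
        assert (r > 0) == (m > c)


def _aux(df):
    return [c for c in df.columns]


class TestSinglingOut:
    def test_identity_release_has_high_risk(self, split_400):
        train = split_400[0].df.drop(columns=["patient_pseudonym"])
        control = split_400[1].df.drop(columns=["patient_pseudonym"])
        cfg = AttackConfig(aux_attributes=_aux(train), repetitions=3, seed=1)
        uni = singling_out(train, train, control, "univariate", cfg)
        multi = singling_out(train, train, control, "multivariate", cfg)
        assert uni.risk > 0.8
        assert multi.risk > 0.8

    def test_independent_release_has_null_risk(self, split_400):
        train = split_400[0].df.drop(columns=["patient_pseudonym"])
        control = split_400[1].df.drop(columns=["patient_pseudonym"])
        released = split_400[2].df.drop(columns=["patient_pseudonym"])
        cfg = AttackConfig(aux_attributes=_aux(train), repetitions=5, seed=2)
        for mode in ("univariate", "multivariate"):
            r = singling_out(released, train, control, mode, cfg)
            assert abs(r.risk) <= 3 * max(r.risk_sd, 0.02), mode

    def test_reports_repetition_statistics(self, split_400):
        train = split_400[0].df.drop(columns=["patient_pseudonym"])
        control = split_400[1].df.drop(columns=["patient_pseudonym"])
        cfg = AttackConfig(aux_attributes=_aux(train), repetitions=4, seed=3)
        r = singling_out(train, train, control, "multivariate", cfg)
        assert len(r.rep_risks) == 4
        assert r.repetitions == 4
        assert r.risk == pytest.approx(float(np.mean(r.rep_risks)))


class TestLinkage:
    def test_identity_release_self_match(self, split_400):
        train = split_400[0].df.drop(columns=["patient_pseudonym"])
        control = split_400[1].df.drop(columns=["patient_pseudonym"])
        cfg = AttackConfig(aux_attributes=_aux(train), repetitions=3, seed=4)
        r = linkage(train, train, control, None, cfg)
        assert r.r_main == pytest.approx(1.0)
        assert r.risk > 0.8

    def test_shuffled_columns_break_linkage(self):
        rng = np.random.default_rng(5)
        n = 300
        df = pd.DataFrame(
            {f"x{j}": rng.integers(0, 50, n) for j in range(6)}
        )
        shuffled = df.copy()
        for c in shuffled.columns:  # independent permutation per column
            shuffled[c] = rng.permutation(shuffled[c].to_numpy())
        control = pd.DataFrame({f"x{j}": rng.integers(0, 50, n) for j in range(6)})
        cfg = AttackConfig(aux_attributes=list(df.columns), repetitions=5, seed=6)
        r = linkage(shuffled, df, control, None, cfg)
        assert abs(r.risk) <= 3 * max(r.risk_sd, 0.02)

    def test_distance_ties_resolve_by_record_order(self):
        assert list(attacks._knn_indices(np.array([0.5, 0.2, 0.2]), 1)) == [1]
        assert list(attacks._knn_indices(np.array([0.0, 0.0, 0.0]), 2)) == [0, 1]

    def test_empty_side_rejected(self, split_400):
        train = split_400[0].df
        cfg = AttackConfig(aux_attributes=["age"], repetitions=1, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            linkage(train, train, train, (["age"], []), cfg)


class TestAttributeInference:
    def test_identity_release_reveals_secret(self, split_400):
        train = split_400[0].df.drop(columns=["patient_pseudonym"])
        control = split_400[1].df.drop(columns=["patient_pseudonym"])
        aux = [c for c in train.columns if c != "death_flag"]
        cfg = AttackConfig(aux_attributes=aux, repetitions=3, seed=7)
        r = attribute_inference(train, train, control, "death_flag", cfg)
        assert r.r_main == pytest.approx(1.0)
        assert r.valid

    def test_baseline_beats_main_marks_invalid(self):
        # nearest neighbors always land on the one wrong-secret record,
        # while the marginal baseline guesses mostly right
        n = 60
        protected = pd.DataFrame(
            {"x": [0.0] + [100.0 + i for i in range(n - 1)],
             "secret": ["b"] + ["a"] * (n - 1)}
        )
        train = pd.DataFrame({"x": [0.0] * n, "secret": ["a"] * n})
        control = pd.DataFrame({"x": [0.0] * n, "secret": ["a"] * n})
        cfg = AttackConfig(aux_attributes=["x"], repetitions=3, seed=8)
        r = attribute_inference(protected, train, control, "secret", cfg)
        assert r.r_main == pytest.approx(0.0)
        assert not r.valid
        assert r.n_valid_reps == 0

    def test_secret_may_not_be_auxiliary(self, split_400):
        train = split_400[0].df
        cfg = AttackConfig(aux_attributes=["age", "death_flag"], repetitions=1, seed=0)
        with pytest.raises(ValueError, match="secret"):
            attribute_inference(train, train, train, "death_flag", cfg)


class TestSelectTargets:
    def test_distinct_record_is_top_outlier(self):
        df = pd.DataFrame({"x": [1.0] * 20 + [50.0], "y": [0.0] * 20 + [9.0]})
        avg, out = select_targets(df, n_average=3, n_outlier=1)
        assert list(out) == [20]
        assert 20 not in set(avg)

    def test_partition_covers_cohort_at_boundary(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": rng.random(12), "y": rng.random(12)})
        avg, out = select_targets(df, n_average=6, n_outlier=6)
        assert sorted(list(avg) + list(out)) == list(range(12))

    def test_deterministic_under_reordering(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"x": rng.random(30), "y": rng.random(30)})
        a1, o1 = select_targets(df, 5, 5)
        a2, o2 = select_targets(df, 5, 5)
        assert list(a1) == list(a2) and list(o1) == list(o2)


class TestMarginalFeatures:
    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.random(50), "c": rng.choice(list("ab"), 50)})
        spec = fit_feature_spec(df, n_bins=5)
        f1 = marginal_features(df, spec)
        f2 = marginal_features(df.sample(frac=1, random_state=0), spec)
        assert np.array_equal(f1, f2)

    def test_duplicating_rows_doubles_counts(self):
        df = pd.DataFrame({"x": [0.1, 0.9], "c": ["a", "b"]})
        spec = fit_feature_spec(df, n_bins=4)
        assert np.array_equal(
            marginal_features(pd.concat([df, df]), spec),
            2 * marginal_features(df, spec),
        )

    def test_feature_length_is_sum_of_bins_and_categories(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 20), "c": list("ab") * 10})
        spec = fit_feature_spec(df, n_bins=7)
        assert len(marginal_features(df, spec)) == 7 + 2

    def test_out_of_range_values_clip_to_end_bins(self):
        df = pd.DataFrame({"x": [0.0, 1.0]})
        spec = fit_feature_spec(df, n_bins=4)
        f = marginal_features(pd.DataFrame({"x": [-5.0, 99.0]}), spec)
        assert f[0] == 1 and f[-1] == 1 and f.sum() == 2


def _mia_pool(n=300, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "x": rng.normal(0, 1, n),
            "y": rng.normal(0, 1, n),
            "c": rng.choice(["a", "b"], n),
        }
    )


def _isolated_target_pool(n=300, seed=0):
    """Pool clustered at low x with a few range-stretching records, plus a
    target whose x falls in a histogram cell no pool record occupies: its
    membership is directly observable in the marginal features."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 0.3, n)
    x[:5] = 1.0
    pool = pd.DataFrame(
        {"x": x, "y": rng.normal(0, 1, n), "c": rng.choice(["a", "b"], n)}
    )
    target = pd.Series({"x": 0.55, "y": 0.0, "c": "a"})
    return pool, target


class TestMembershipInference:
    def test_identity_protector_leaks_membership(self):
        pool, target = _isolated_target_pool()
        cfg = MIAConfig(sample_size=50, train_replicates=6, test_replicates=6,
                        n_runs=4, seed=1)
        res = membership_inference(target, identity_protector, pool, cfg)
        assert res.coverage_ok
        assert res.risk > 0.7

    def test_input_ignoring_protector_gives_null_risk(self):
        pool = _mia_pool(seed=2)
        target = pd.Series({"x": 7.0, "y": -7.0, "c": "a"})
        fixed = pool.iloc[:50].reset_index(drop=True)
        cfg = MIAConfig(sample_size=50, train_replicates=5, test_replicates=5,
                        n_runs=4, seed=3)
        res = membership_inference(target, constant_protector(fixed), pool, cfg)
        assert abs(res.risk) <= 0.15

    def test_coverage_criterion_arithmetic(self):
        # each of the N pool records appears in one draw of size s with
        # probability s/N; over D draws: 1 - (1 - s/N)^D
        assert coverage_probability(1000, 500, 10) == pytest.approx(
            1 - 0.5**10
        )
        assert coverage_probability(400, 100, 1) == pytest.approx(0.25)

    def test_oversized_sample_rejected(self):
        pool = _mia_pool(n=40)
        cfg = MIAConfig(sample_size=100, n_runs=1)
        with pytest.raises(ValueError, match="pool"):
            membership_inference(pd.Series({"x": 0, "y": 0, "c": "a"}),
                                 identity_protector, pool, cfg)
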