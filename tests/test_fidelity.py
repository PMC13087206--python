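"""Fidelity metrics: identities, arithmetic, support-overlap behavior."""

import numpy as np
import pandas as pd
import pytest

from privcohort.fidelity import (
    correlation_distance,
    impute_and_normalize,
    normalized_prevalence,
    precision_recall_authenticity,
)


def _two_group_flags(rng, n=400, p=(0.1, 0.2)):
    g = np.where(rng.random(n) < 0.5, "DOAC", "VKA")
    return pd.DataFrame(
        {
            "treatment_group": g,
            "f1": (rng.random(n) < p[0]).astype(int),
            "f2": (rng.random(n) < p[1]).astype(int),
        }
    )


class TestNormalizedPrevalence:
    def test_identity_is_all_hundred(self):
        df = _two_group_flags(np.random.default_rng(0))
        table, dev = normalized_prevalence(df, df, "treatment_group")
        assert (table["normalized"].dropna() == 100.0).all()
        assert all(v == 0.0 for v in dev.values())

    def test_ratio_arithmetic(self):
        orig = pd.DataFrame({"treatment_group": ["A"] * 100,
                             "f": [1] * 10 + [0] * 90})
        prot = pd.DataFrame({"treatment_group": ["A"] * 100,
                             "f": [1] * 12 + [0] * 88})
        table, _ = normalized_prevalence(orig, prot, "treatment_group", ["f"])
        assert table["normalized"].iloc[0] == pytest.approx(120.0)

    def test_mean_deviation_over_three_flags(self):
        # ratios 1.0, 0.5, 1.5 -> mean |dev| = (0 + 0.5 + 0.5) / 3
        orig = pd.DataFrame(
            {
                "treatment_group": ["A"] * 200,
                "a": [1] * 40 + [0] * 160,
                "b": [1] * 40 + [0] * 160,
                "c": [1] * 40 + [0] * 160,
            }
        )
        prot = pd.DataFrame(
            {
                "treatment_group": ["A"] * 200,
                "a": [1] * 40 + [0] * 160,
                "b": [1] * 20 + [0] * 180,
                "c": [1] * 60 + [0] * 140,
            }
        )
        _, dev = normalized_prevalence(orig, prot, "treatment_group", ["a", "b", "c"])
        assert dev["A"] == pytest.approx((0 + 0.5 + 0.5) / 3)

    def test_zero_original_prevalence_flagged_undefined(self):
        orig = pd.DataFrame({"treatment_group": ["A"] * 10, "f": [0] * 10})
        prot = pd.DataFrame({"treatment_group": ["A"] * 10, "f": [1] * 10})
        table, dev = normalized_prevalence(orig, prot, "treatment_group", ["f"])
        assert table["status"].iloc[0] == "undefined"
        assert np.isnan(dev["A"])

    def test_suppressed_attribute_flagged(self):
        orig = _two_group_flags(np.random.default_rng(1))
        prot = orig.drop(columns=["f2"])
        table, _ = normalized_prevalence(orig, prot, "treatment_group", ["f1", "f2"])
        assert (table.loc[table["attribute"] == "f2", "status"] == "suppressed").all()


class TestCorrelationDistance:
    def test_identical_datasets_distance_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((100, 4)), columns=list("abcd"))
        scalar, _, undef = correlation_distance(df, df)
        assert scalar == pytest.approx(0.0)
        assert undef == []

    def test_single_pair_arithmetic(self):
        # two synthetic two-column datasets with known correlations
        rng = np.random.default_rng(3)
        n = 20_000
        x = rng.standard_normal(n)
        orig = pd.DataFrame({"x": x, "y": 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)})
        prot = pd.DataFrame({"x": x, "y": 0.3 * x + np.sqrt(1 - 0.09) * rng.standard_normal(n)})
        scalar, _, _ = correlation_distance(orig, prot)
        assert scalar == pytest.approx(0.2, abs=0.03)

    def test_zero_variance_column_reported_undefined(self):
        rng = np.random.default_rng(4)
        orig = pd.DataFrame(
            {"x": rng.random(50), "y": rng.random(50), "obesity": rng.integers(0, 2, 50)}
        )
        prot = orig.copy()
        prot["obesity"] = 0  # protection removed every case
        scalar, _, undef = correlation_distance(orig, prot)
        assert ("x", "obesity") in undef and ("y", "obesity") in undef
        assert np.isfinite(scalar)

    def test_too_few_usable_attributes_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            correlation_distance(df, df)


class TestImputeAndNormalize:
    def test_minmax_scaling(self):
        ref = pd.DataFrame({"x": [0.0, 10.0]})
        out = impute_and_normalize(pd.DataFrame({"x": [5.0]}), ref)
        assert out[0, 0] == pytest.approx(0.5)

    def test_missing_imputed_with_reference_median_then_scaled(self):
        ref = pd.DataFrame({"x": [0.0, 3.0, 10.0]})
        out = impute_and_normalize(pd.DataFrame({"x": [np.nan]}), ref)
        assert out[0, 0] == pytest.approx(0.3)

    def test_suppressed_column_becomes_scaled_median_constant(self):
        ref = pd.DataFrame({"x": [0.0, 2.0, 10.0], "y": [1.0, 2.0, 3.0]})
        out = impute_and_normalize(pd.DataFrame({"y": [1.0, 3.0]}), ref)
        assert np.allclose(out[:, 0], 0.2)  # median 2 over range 0..10

    def test_constant_reference_column_maps_to_half(self):
        ref = pd.DataFrame({"x": [4.0, 4.0], "y": [0.0, 1.0]})
        out = impute_and_normalize(ref, ref)
        assert np.allclose(out[:, 0], 0.5)

    def test_unknown_column_rejected(self):
        ref = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="absent"):
            impute_and_normalize(pd.DataFrame({"x": [0.5], "z": [1.0]}), ref)


class TestPrecisionRecallAuthenticity:
    def test_exact_copy_is_inauthentic_with_full_precision(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.random((300, 5)), columns=list("abcde"))
        ip_a, ir_b, auth = precision_recall_authenticity(df, df.copy())
        assert auth == 0.0
        assert ip_a > 0.95 and ir_b > 0.95

    def test_same_distribution_scores_high(self):
        rng = np.random.default_rng(6)
        a = pd.DataFrame(rng.standard_normal((800, 4)), columns=list("abcd"))
        b = pd.DataFrame(rng.standard_normal((800, 4)), columns=list("abcd"))
        ip_a, ir_b, auth = precision_recall_authenticity(a, b)
        assert ip_a >= 0.9 and ir_b >= 0.9
        assert 0.2 < auth < 0.8  # independent draws are mostly novel

    def test_far_shifted_data_has_no_support_overlap(self):
        rng = np.random.default_rng(7)
        a = pd.DataFrame(rng.random((200, 3)), columns=list("abc"))
        b = a + 100.0
        ip_a, _, auth = precision_recall_authenticity(a, b)
        assert ip_a == pytest.approx(0.0, abs=0.02)
        assert auth == 1.0

    def test_swapping_roles_swaps_precision_and_recall(self):
        rng = np.random.default_rng(8)
        a = pd.DataFrame(rng.standard_normal((400, 3)), columns=list("abc"))
        b = pd.DataFrame(0.5 * rng.standard_normal((400, 3)), columns=list("abc"))
        ip_ab, ir_ab, _ = precision_recall_authenticity(a, b)
        # compare on a fixed normalization frame so the roles are symmetric
        ip_ba, ir_ba, _ = precision_recall_authenticity(b, a)
        assert (ip_ab > ir_ab) == (ir_ba > ip_ba)

    def test_all_constant_data_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 20})
        with pytest.raises(ValueError, match="constant"):
            precision_recall_authenticity(df, df)

    def test_too_small_datasets_rejected(self):
        df = pd.DataFrame({"x": np.arange(5.0)})
        with pytest.raises(ValueError, match="10"):
            precision_recall_authenticity(df, df)
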