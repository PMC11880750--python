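"""Signature scoring, thresholds, quadrant classification, proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvdsig.scoring import (
    classify_quadrants,
    compare_signatures,
    high_by_top_quartile,
    signature_score,
    subgroup_proportions,
    threshold_median,
    threshold_top_quartile,
)
from mvdsig.signature import SignatureDefinition


def _expr(values: dict[str, list[float]], samples=None) -> pd.DataFrame:
    genes = list(values)
    n = len(next(iter(values.values())))
    cols = samples or [f"S{i}" for i in range(n)]
    return pd.DataFrame(
        np.array([values[g] for g in genes], dtype=float),
        index=pd.Index(genes, name="gene"),
        columns=cols,
    )


class TestSignatureScore:
    def test_constant_tpm_gives_log2_of_four(self):
        sig = SignatureDefinition("MVD", tuple("ABCDEF"))
        expr = _expr({g: [3.0] for g in "ABCDEF"})
        assert signature_score(expr, sig)["S0"] == pytest.approx(2.0)

    def test_two_gene_mean(self):
        sig = SignatureDefinition("s", ("A", "B"))
        expr = _expr({"A": [1.0], "B": [3.0]})
        assert signature_score(expr, sig)["S0"] == pytest.approx(1.5)

    def test_gene_order_irrelevant(self):
        expr = _expr({"A": [1.0, 7.0], "B": [3.0, 2.0], "C": [9.0, 0.0]})
        s1 = signature_score(expr, SignatureDefinition("s", ("A", "B", "C")))
        s2 = signature_score(expr, SignatureDefinition("s", ("C", "A", "B")))
        assert np.allclose(s1, s2)

    def test_monotone_in_any_gene(self):
        sig = SignatureDefinition("s", ("A", "B"))
        lo = _expr({"A": [1.0], "B": [3.0]})
        hi = _expr({"A": [2.0], "B": [3.0]})
        assert signature_score(hi, sig)["S0"] > signature_score(lo, sig)["S0"]

    def test_missing_gene_budget(self, caplog):
        expr = _expr({"A": [1.0], "B": [3.0]})
        ok = SignatureDefinition("s", ("A", "B", "MISSING"))
        scores = signature_score(expr, ok)  # 1/3 missing: allowed
        assert scores.attrs["n_genes_used"] == 2
        too_many = SignatureDefinition("s", ("A", "M1", "M2"))
        with pytest.raises(ValueError, match="missing"):
            signature_score(expr, too_many)
        none = SignatureDefinition("s", ("M1", "M2"))
        with pytest.raises(ValueError, match="present"):
            signature_score(expr, none)

    def test_weighted_mean(self):
        sig = SignatureDefinition("s", ("A", "B"))
        expr = _expr({"A": [1.0], "B": [3.0]})
        scores = signature_score(expr, sig, weights={"A": 3.0, "B": 1.0})
        assert scores["S0"] == pytest.approx((3 * 1.0 + 1 * 2.0) / 4)


class TestThresholds:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 2, 3], 2.0), ([1, 2, 3, 4], 2.5), ([5], 5.0)],
    )
    def test_median_conventions(self, values, expected):
        assert threshold_median(values) == expected

    def test_median_empty_rejected(self):
        with pytest.raises(ValueError):
            threshold_median([])

    def test_twelve_models_give_three_high(self):
        means = pd.Series(np.arange(1.0, 13.0), index=[f"M{i}" for i in range(12)])
        high = high_by_top_quartile(means)
        assert int(high.sum()) == 3
        assert set(means[high]) == {10.0, 11.0, 12.0}

    def test_eight_models_give_two_high(self):
        means = pd.Series(np.arange(1.0, 9.0))
        assert int(high_by_top_quartile(means).sum()) == 2

    def test_all_equal_all_high(self, caplog):
        means = pd.Series([4.0] * 6)
        assert high_by_top_quartile(means).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            threshold_top_quartile([1.0, 2.0, 3.0])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        assert threshold_top_quartile(v) == threshold_top_quartile(v[::-1])
        assert threshold_median(v) == threshold_median(rng.permutation(v))


class TestClassifyQuadrants:
    def test_partition_and_labels(self):
        mvd = pd.Series({"a": 2.0, "b": 2.0, "c": 0.0, "d": 0.0})
        gep = pd.Series({"a": 2.0, "b": 0.0, "c": 2.0, "d": 0.0})
        labels = classify_quadrants(mvd, gep, 1.0, 1.0)
        assert labels["a"] == "MVD-high/Tcell_inf_GEP-high"
        assert labels["b"] == "MVD-high/Tcell_inf_GEP-low"
        assert labels["c"] == "MVD-low/Tcell_inf_GEP-high"
        assert labels["d"] == "MVD-low/Tcell_inf_GEP-low"
        assert labels.value_counts().sum() == 4

    def test_at_threshold_is_low(self):
        mvd = pd.Series({"a": 1.0})
        gep = pd.Series({"a": 5.0})
        labels = classify_quadrants(mvd, gep, 1.0, 1.0)
        assert labels["a"] == "MVD-low/Tcell_inf_GEP-high"

    def test_thresholds_recorded(self):
        mvd = pd.Series({"a": 2.0})
        gep = pd.Series({"a": 2.0})
        labels = classify_quadrants(mvd, gep, 1.5, 0.5)
        assert labels.attrs["mvd_threshold"] == 1.5
        assert labels.attrs["tgep_threshold"] == 0.5

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError, match="same samples"):
            classify_quadrants(
                pd.Series({"a": 1.0}), pd.Series({"b": 1.0}), 0.0, 0.0
            )

    def test_relabeling_idempotent(self):
        rng = np.random.default_rng(4)
        mvd = pd.Series(rng.normal(size=30))
        gep = pd.Series(rng.normal(size=30))
        l1 = classify_quadrants(mvd, gep, 0.0, 0.0)
        l2 = classify_quadrants(mvd, gep, 0.0, 0.0)
        assert (l1 == l2).all()
        assert len(l1) == 30


class TestSubgroupProportions:
    def test_uniform_group(self):
        labels = pd.Series(
            ["MVD-high/Tcell_inf_GEP-high", "MVD-high/Tcell_inf_GEP-low",
             "MVD-low/Tcell_inf_GEP-high", "MVD-low/Tcell_inf_GEP-low"],
            index=list("abcd"),
        )
        groups = pd.Series(["T1"] * 4, index=labels.index)
        props = subgroup_proportions(labels, groups)
        assert np.allclose(props.loc["T1"], 0.25)

    def test_single_quadrant_group_and_row_sums(self):
        labels = pd.Series(
            ["MVD-high/Tcell_inf_GEP-high"] * 3 + ["MVD-low/Tcell_inf_GEP-low"] * 2,
            index=list("abcde"),
        )
        groups = pd.Series(["T1"] * 3 + ["T2"] * 2, index=labels.index)
        props = subgroup_proportions(labels, groups)
        assert props.loc["T1", "MVD-high/Tcell_inf_GEP-high"] == 1.0
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_counts_recoverable(self):
        rng = np.random.default_rng(8)
        quadrants = np.array([
            "MVD-high/Tcell_inf_GEP-high", "MVD-high/Tcell_inf_GEP-low",
            "MVD-low/Tcell_inf_GEP-high", "MVD-low/Tcell_inf_GEP-low"])
        labels = pd.Series(rng.choice(quadrants, size=40))
        groups = pd.Series(rng.choice(["T1", "T2"], size=40))
        props = subgroup_proportions(labels, groups)
        sizes = groups.value_counts()
        counts = props.mul(sizes, axis=0)
        assert np.allclose(counts, np.round(counts))
        assert counts.to_numpy().sum() == 40


class TestCompareSignatures:
    def test_self_reference_ranks_first(self):
        rng = np.random.default_rng(9)
        expr = _expr({g: list(rng.uniform(1, 50, 10)) for g in "ABCD"})
        sig_a = SignatureDefinition("a", ("A", "B"))
        sig_b = SignatureDefinition("b", ("C", "D"))
        ref = np.log2(expr.loc[["A", "B"]] + 1).mean(axis=0)
        table = compare_signatures(expr, [sig_a, sig_b], ref)
        assert table.iloc[0]["signature"] == "a"
        assert table.iloc[0]["pearson_r"] == pytest.approx(1.0)

    def test_independent_reference_gives_small_r(self):
        rng = np.random.default_rng(10)
        expr = _expr({g: list(rng.uniform(1, 50, 500)) for g in "AB"})
        sig = SignatureDefinition("a", ("A", "B"))
        ref = pd.Series(rng.normal(size=500), index=expr.columns)
        table = compare_signatures(expr, [sig], ref)
        assert abs(table.iloc[0]["pearson_r"]) < 0.15

    def test_tracking_signature_outranks_nontracking(self):
        rng = np.random.default_rng(11)
        ref = pd.Series(rng.uniform(10, 100, 12), index=[f"S{i}" for i in range(12)])
        expr = _expr(
            {"A": list(ref * 2), "B": list(ref * 3),
             "C": list(rng.uniform(1, 50, 12)), "D": list(rng.uniform(1, 50, 12))},
            samples=list(ref.index),
        )
        table = compare_signatures(
            expr,
            [SignatureDefinition("tracks", ("A", "B")),
             SignatureDefinition("noise", ("C", "D"))],
            ref,
        ).set_index("signature")
        assert table.loc["tracks", "pearson_r"] > table.loc["noise", "pearson_r"]
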