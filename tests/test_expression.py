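"""Differential-expression machinery: oracles, hand cases, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dioica import expression
from dioica.design import SampleDesign
from dioica.errors import InputError
from dioica.simulate import gene_lengths


def _design_2v2():
    return SampleDesign.from_lists(["m1", "m2"], ["f1", "f2"])


def _design_3v3():
    return SampleDesign.from_lists(["m1", "m2", "m3"], ["f1", "f2", "f3"])


class TestSizeFactors:
    def test_identical_columns_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        sf = expression.compute_size_factors(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_hand_computed_median_of_ratios(self):
        # geometric means: sqrt(100*200), sqrt(300*600); both ratios 1/sqrt2, sqrt2
        counts = pd.DataFrame({"a": [100, 300], "b": [200, 600]})
        sf = expression.compute_size_factors(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_scaling_one_sample_scales_relative_factors(self):
        """Scaling one library by c scales its factor by c relative to the
        others (the absolute scale shifts by c**(1/S) through the
        geometric-mean reference, which cancels in all downstream ratios)."""
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(50, 4)), columns=list("abcd")
        )
        sf = expression.compute_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] *= 7
        sf2 = expression.compute_size_factors(scaled)
        assert np.allclose(sf2["c"] / sf2["a"], 7 * sf["c"] / sf["a"])
        assert np.allclose(sf2["b"] / sf2["a"], sf["b"] / sf["a"])
        assert np.allclose(sf2 / sf, [7 ** -0.25] * 2 + [7 ** 0.75, 7 ** -0.25])

    def test_no_reference_gene_raises_with_fallback_hint(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 9]})
        with pytest.raises(InputError, match="pseudo_reference"):
            expression.compute_size_factors(counts)
        sf = expression.compute_size_factors(counts, allow_pseudo_reference=True)
        assert (sf > 0).all()


class TestFpkm:
    def test_formula_forced_case(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 2000, "g2": 500})
        fpkm = expression.compute_fpkm(counts, lengths, pd.Series({"s": 1_000_000}))
        assert fpkm.loc["g1", "s"] == pytest.approx(5.0)
        assert fpkm.loc["g2", "s"] == 0.0

    def test_doubling_length_halves_fpkm(self):
        counts = pd.DataFrame({"s": [8, 8]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2000})
        fpkm = expression.compute_fpkm(counts, lengths, pd.Series({"s": 1e6}))
        assert fpkm.loc["g1", "s"] == pytest.approx(2 * fpkm.loc["g2", "s"])

    def test_zero_iff_zero_count(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 5, size=(30, 3)), columns=list("abc"))
        lengths = pd.Series(rng.integers(200, 2000, size=30), index=counts.index)
        fpkm = expression.compute_fpkm(counts, lengths)
        assert ((fpkm == 0) == (counts == 0)).all().all()

    def test_nonpositive_length_names_gene(self):
        counts = pd.DataFrame({"s": [1]}, index=["bad_gene"])
        with pytest.raises(InputError, match="bad_gene"):
            expression.compute_fpkm(counts, pd.Series({"bad_gene": 0}))


def _bh_oracle(p):
    """Brute-force BH step-up: adj_i = min over ranks j >= rank(i) of m*p_(j)/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBenjaminiHochberg:
    def test_hand_stepped_quadruple(self):
        out = expression.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_inputs(self):
        assert expression.adjust_bh([0.3]) == pytest.approx([0.3])
        assert np.allclose(expression.adjust_bh([1.0, 1.0, 1.0]), 1.0)
        assert expression.adjust_bh([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            expression.adjust_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(expression.adjust_bh(p), _bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_adjusted_never_below_raw(self, p):
        assert (expression.adjust_bh(p) >= np.asarray(p) - 1e-15).all()


class TestDifferentialTest:
    def test_all_zero_gene_is_null(self):
        counts = pd.DataFrame(
            {s: [0, 5] for s in ["m1", "m2", "f1", "f2"]}, index=["z", "ok"]
        )
        res = expression.test_differential(counts, _design_2v2())
        assert res.loc["z", "log2fc"] == 0.0
        assert res.loc["z", "p"] == 1.0

    def test_requires_two_replicates_per_sex(self):
        counts = pd.DataFrame({"m1": [1], "f1": [2], "f2": [3]})
        design = SampleDesign.from_lists(["m1"], ["f1", "f2"])
        with pytest.raises(InputError):
            expression.test_differential(counts, design)

    def test_label_swap_negates_log2fc_and_keeps_p(self, default_ds):
        counts = default_ds.counts.iloc[:100]
        design = default_ds.design
        res = expression.test_differential(counts, design)
        res_sw = expression.test_differential(counts, design.swapped())
        assert np.allclose(res_sw["log2fc"], -res["log2fc"])
        assert np.allclose(res_sw["p"], res["p"])

    def test_scaling_a_sample_leaves_log2fc_unchanged(self, default_ds):
        """Size factors absorb a library-wide rescaling: log2FC is invariant
        for every gene expressed in both sexes.  (Structural zeros go through
        the pseudo-count, which is not scale-free, so they are exempt.)"""
        counts = default_ds.counts.iloc[:200].copy()
        res = expression.test_differential(counts, default_ds.design)
        scaled = counts.copy()
        scaled[scaled.columns[0]] *= 13
        res2 = expression.test_differential(scaled, default_ds.design)
        both = (res["baseMeanM"] > 0) & (res["baseMeanF"] > 0)
        assert both.sum() > 150
        assert np.allclose(res.loc[both, "log2fc"], res2.loc[both, "log2fc"])


class TestClassification:
    def _frame(self, p_adj, log2fc):
        return pd.DataFrame({"p_adj": [p_adj], "log2fc": [log2fc]}, index=["g"])

    @pytest.mark.parametrize(
        "p_adj,log2fc,expected",
        [
            (0.01, 6.0, expression.MALE_BIASED),
            (0.01, -6.0, expression.FEMALE_BIASED),
            (0.04, 0.5, expression.UNBIASED),   # below fold-change threshold
            (0.05, 3.0, expression.UNBIASED),   # alpha comparison is strict
            (0.04, 1.0, expression.MALE_BIASED),  # lfc threshold is inclusive
            (0.04, -1.0, expression.FEMALE_BIASED),
        ],
    )
    def test_bias_rules(self, p_adj, log2fc, expected):
        cls = expression.classify_deg(self._frame(p_adj, log2fc))
        assert cls["g"] == expected

    def test_sex_specific_rules(self):
        design = _design_3v3()
        counts = pd.DataFrame(
            {
                "m1": [10, 10, 10], "m2": [12, 12, 12], "m3": [8, 8, 8],
                "f1": [0, 0, 0], "f2": [0, 0, 0], "f3": [0, 0, 1],
            },
            index=["spec", "weak", "leaky"],
        )
        fpkm = pd.DataFrame(
            {
                "m1": [1.2, 0.02, 1.2], "m2": [1.2, 0.02, 1.2],
                "m3": [1.2, 0.02, 1.2],
                "f1": [0, 0, 0], "f2": [0, 0, 0], "f3": [0, 0, 0.1],
            },
            index=counts.index,
        )
        deg = pd.Series(True, index=counts.index)
        out = expression.classify_sex_specific(counts, fpkm, design, deg)
        assert out["spec"] == expression.MALE_SPECIFIC
        assert out["weak"] == expression.NOT_SPECIFIC  # FPKM floor (> 0.03)
        assert out["leaky"] == expression.NOT_SPECIFIC  # non-zero female count

    def test_specificity_confined_to_degs(self):
        design = _design_3v3()
        counts = pd.DataFrame(
            {s: ([7] if s.startswith("m") else [0]) for s in design.samples},
            index=["g"],
        )
        fpkm = counts.astype(float)
        out = expression.classify_sex_specific(
            counts, fpkm, design, pd.Series({"g": False})
        )
        assert out["g"] == expression.NOT_SPECIFIC


class TestSampleClustering:
    def test_identical_samples_merge_at_zero_distance(self):
        rng = np.random.default_rng(2)
        base = rng.random(20)
        fpkm = pd.DataFrame(
            {
                "m1": base, "m2": base,  # identical profiles
                "m3": base + rng.random(20),
                "f1": rng.random(20), "f2": rng.random(20), "f3": rng.random(20),
            }
        )
        cl = expression.cluster_samples(fpkm, _design_3v3())
        assert cl.linkage[:, 2].min() == pytest.approx(0.0, abs=1e-12)
        assert cl.partition["m1"] == cl.partition["m2"]

    def test_column_order_invariance(self, default_ds, default_lengths):
        fpkm = expression.compute_fpkm(default_ds.counts, default_lengths)
        degs = default_ds.manifest.deg_genes
        design = default_ds.design
        cl1 = expression.cluster_samples(fpkm.loc[degs], design)
        shuffled = fpkm.loc[degs, list(reversed(design.samples))]
        cl2 = expression.cluster_samples(shuffled, design)
        part1 = {frozenset(s for s, g in cl1.partition.items() if g == v) for v in (0, 1)}
        part2 = {frozenset(s for s, g in cl2.partition.items() if g == v) for v in (0, 1)}
        assert part1 == part2

    def test_requires_two_genes(self):
        fpkm = pd.DataFrame({s: [1.0] for s in _design_3v3().samples})
        with pytest.raises(InputError):
            expression.cluster_samples(fpkm, _design_3v3())

    def test_newick_contains_all_samples(self, default_ds, default_lengths):
        fpkm = expression.compute_fpkm(default_ds.counts, default_lengths)
        cl = expression.cluster_samples(
            fpkm.loc[default_ds.manifest.deg_genes], default_ds.design
        )
        for s in default_ds.design.samples:
            assert s in cl.newick


class TestEndToEndRecovery:
    def test_specificity_calls_match_truth_exactly(self, default_ds, default_lengths):
        res = expression.run_differential_expression(
            default_ds.counts, default_ds.design, default_lengths
        )
        truth = default_ds.manifest.gene_class
        for cls in (expression.MALE_SPECIFIC, expression.FEMALE_SPECIFIC):
            called = set(res.index[res["specificity"] == cls])
            planted = set(truth.index[truth == cls])
            assert called == planted

    def test_padj_dominates_p(self, default_ds, default_lengths):
        res = expression.run_differential_expression(
            default_ds.counts, default_ds.design, default_lengths
        )
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        deg = res["bias_class"] != expression.UNBIASED
        assert (res.loc[deg, "p_adj"] < 0.05).all()
        assert (res.loc[deg, "log2fc"].abs() >= 1.0).all()
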