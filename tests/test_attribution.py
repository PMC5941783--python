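"""Swap-end classification, proportional allocation, population contrast."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from indexswap.attribution import (
    AllocationError,
    SwapEndClass,
    UnsupportedDesignError,
    classify_swap_end,
    compare_populations,
    count_swap_ends,
    estimate_attribution,
)
from indexswap.demux import ReadAssignment, ReadClass

counts = st.integers(min_value=0, max_value=100)

# Frozen worked example: the human / E. coli mixture-experiment counts.
MIXTURE_COUNTS = dict(
    non_swapped=807_029_454,
    undetermined=17_136_498,
    known_i7=5_300_327,
    known_i5=12_697_618,
    double=689_363,
)
MIXTURE_TOTAL_PF = 842_853_260
MIXTURE_TOTAL_SWAPPED = 34_219_842


class TestClassifySwapEnd:
    def test_own_pair_is_non_swap(self):
        assert (
            classify_swap_end(ReadClass.MATCHED, "human", "human", "human")
            is SwapEndClass.NON_SWAP
        )

    def test_cross_organism_i7_swap(self):
        """Human-mapped read with an E. coli i7 and a human i5."""
        assert (
            classify_swap_end(ReadClass.SWAPPED, "human", "ecoli", "human")
            is SwapEndClass.I7_SWAP
        )

    def test_cross_organism_i5_swap(self):
        assert (
            classify_swap_end(ReadClass.SWAPPED, "ecoli", "ecoli", "human")
            is SwapEndClass.I5_SWAP
        )

    def test_within_organism_swap_end_unknowable(self):
        assert (
            classify_swap_end(ReadClass.SWAPPED, "human", "human", "human")
            is SwapEndClass.UNDETERMINED_END
        )

    def test_other_organisms_valid_pair_is_double_swap(self):
        """Human-mapped read carrying a complete E. coli sample pair."""
        assert (
            classify_swap_end(ReadClass.MATCHED, "human", "ecoli", "ecoli")
            is SwapEndClass.DOUBLE_SWAP
        )

    def test_swapped_pair_both_foreign_is_double_swap(self):
        assert (
            classify_swap_end(ReadClass.SWAPPED, "human", "ecoli", "ecoli")
            is SwapEndClass.DOUBLE_SWAP
        )

    def test_rejects_unresolved_reads(self):
        with pytest.raises(ValueError):
            classify_swap_end(ReadClass.UNDETERMINED, "human", "human", "human")

    def test_three_organism_design_rejected(self):
        organism_of = {"a": "human", "b": "ecoli", "c": "yeast"}
        with pytest.raises(UnsupportedDesignError):
            count_swap_ends([], organism_of)


class TestEstimateAttribution:
    def test_mixture_worked_example(self):
        r = estimate_attribution(
            **MIXTURE_COUNTS, total_pf=MIXTURE_TOTAL_PF, total_swapped=MIXTURE_TOTAL_SWAPPED
        )
        d = r.to_dict()
        assert d["Estimated total i7 swaps"] == 11_036_324
        assert d["Estimated total i5 swaps"] == 25_476_845
        assert d["p(i7 Swap)"] == 0.0131
        assert d["p(i5 Swap)"] == 0.0302
        assert d["p(Total Swap)"] == 0.0406
        assert r.total_pf == MIXTURE_TOTAL_PF

    def test_component_vs_supplied_totals_discrepancy_is_reported(self):
        r = estimate_attribution(
            **MIXTURE_COUNTS, total_pf=MIXTURE_TOTAL_PF, total_swapped=MIXTURE_TOTAL_SWAPPED
        )
        assert r.swapped_component_total == 35_823_806
        assert r.swapped_total_discrepancy == MIXTURE_TOTAL_SWAPPED - 35_823_806

    def test_no_undetermined_no_double_collapses_to_known_counts(self):
        r = estimate_attribution(100, 0, 7, 13, 0)
        assert r.est_total_i7_exact == 7
        assert r.est_total_i5_exact == 13

    def test_allocation_undefined_without_known_swaps(self):
        with pytest.raises(AllocationError):
            estimate_attribution(10, 5, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_attribution(-1, 0, 1, 1, 0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(counts, counts, counts, counts, counts)
    def test_allocation_identity_exact(self, ns, u, k7, k5, d):
        if u > 0 and k7 + k5 == 0:
            return
        r = estimate_attribution(ns, u, k7, k5, d)
        assert (
            r.est_total_i7_exact + r.est_total_i5_exact
            == u + k7 + k5 + 2 * d
        )

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(counts, counts, st.integers(1, 100), st.integers(1, 100), counts)
    def test_probability_sum_identity(self, ns, u, k7, k5, d):
        r = estimate_attribution(ns, u, k7, k5, d)
        lhs = Fraction(r.est_total_i7_exact + r.est_total_i5_exact, r.total_pf)
        assert lhs == Fraction(u + k7 + k5 + 2 * d, r.total_pf)


def test_organism_relabeling_leaves_probabilities_unchanged():
    """Swapping the two organism names everywhere is a symmetry."""

    def assignment(cls, o7, o5):
        return ReadAssignment(cls, None, o7, o5)

    def probs(rename):
        organism_of = {
            "h1": rename("human"),
            "h2": rename("human"),
            "e1": rename("ecoli"),
            "e2": rename("ecoli"),
        }
        reads = [
            (assignment(ReadClass.MATCHED, "h1", "h1"), rename("human")),
            (assignment(ReadClass.SWAPPED, "h1", "h2"), rename("human")),
            (assignment(ReadClass.SWAPPED, "e1", "h1"), rename("human")),
            (assignment(ReadClass.SWAPPED, "h2", "e2"), rename("ecoli")),
            (assignment(ReadClass.MATCHED, "e2", "e2"), rename("human")),
        ] * 10
        c = count_swap_ends(reads, organism_of)
        r = estimate_attribution(
            c.non_swapped, c.undetermined, c.known_i7, c.known_i5, c.double
        )
        return (r.p_i7, r.p_i5, r.p_total)

    flip = {"human": "ecoli", "ecoli": "human"}
    assert probs(lambda o: o) == probs(lambda o: flip[o])


def _population_frame(rng, n, shift=0.0, chim_sw=0.05, chim_ns=0.01):
    swapped = rng.random(n) < 0.3
    insert = rng.lognormal(5.8 + shift * swapped, 0.3, n)
    gc = rng.beta(6, 8.6, n)
    chim = rng.random(n) < np.where(swapped, chim_sw, chim_ns)
    return pd.DataFrame(
        {"swapped": swapped, "insert_len": insert, "gc": gc, "chimeric": chim}
    )


class TestComparePopulations:
    def test_shorter_swapped_inserts_detected(self):
        frame = _population_frame(np.random.default_rng(1), 50_000, shift=-0.2)
        c = compare_populations(frame)
        assert c.insert_mean_swapped < c.insert_mean_non_swapped

    def test_identical_distributions_give_unit_gc_ratio(self):
        frame = _population_frame(np.random.default_rng(2), 100_000)
        c = compare_populations(frame)
        solid = c.gc_hist_non_swapped > 0.02
        assert np.nanmax(np.abs(c.gc_ratio[solid] - 1.0)) < 0.15
        assert np.nansum(c.gc_hist_swapped) == pytest.approx(1.0)
        assert np.nansum(c.gc_hist_non_swapped) == pytest.approx(1.0)

    def test_elevated_chimerism_in_swapped_population(self):
        frame = _population_frame(
            np.random.default_rng(3), 100_000, chim_sw=0.08, chim_ns=0.01
        )
        c = compare_populations(frame)
        assert c.pct_chimeric_swapped > c.pct_chimeric_non_swapped

    def test_empty_population_reports_nan_not_zero(self):
        frame = pd.DataFrame(
            {
                "swapped": [False, False],
                "insert_len": [300.0, 310.0],
                "gc": [0.4, 0.5],
                "chimeric": [False, True],
            }
        )
        c = compare_populations(frame)
        assert c.n_swapped == 0
        assert np.isnan(c.insert_mean_swapped)
        assert np.isnan(c.pct_chimeric_swapped)
        assert np.isnan(c.gc_hist_swapped).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            compare_populations(pd.DataFrame({"swapped": [True]}))
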