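import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lofburden.stats import (
    ContingencyTable,
    EnumerationGuardError,
    ReferencePopulation,
    associate,
    burden_scan,
    fisher_two_sided,
    read_reference_table,
    sample_odds_ratio,
)
from lofburden.cohorts import BurdenCount


def rational_fisher(a: int, b: int, c: int, d: int) -> Fraction:
    """Independent oracle: exact rational enumeration of the hypergeometric
    support under the minimum-likelihood rule with the 1 + 1e-7 guard."""
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(k, n1)
    weights = {x: math.comb(n1, x) * math.comb(n2, k - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    guard = Fraction(10**7 + 1, 10**7)
    kept = sum(w for w in weights.values() if Fraction(w) <= w_obs * guard)
    return Fraction(kept, math.comb(n1 + n2, k))


class TestSampleOddsRatio:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((4, 368, 30, 19924), 7.22),
            ((1, 2087, 1, 282669), 135.44),
            ((3, 2085, 4, 282666), 101.68),
            ((7, 2081, 8, 4482), 1.88),
        ],
    )
    def test_printed_estimates(self, table, expected):
        assert round(sample_odds_ratio(ContingencyTable(*table)), 2) == expected

    def test_infinite_when_comparator_empty(self):
        assert sample_odds_ratio(ContingencyTable(4, 2084, 0, 4490)) == math.inf

    def test_zero_when_case_cell_empty(self):
        assert sample_odds_ratio(ContingencyTable(0, 10, 5, 100)) == 0.0

    def test_not_applicable_when_both_zero(self):
        assert math.isnan(sample_odds_ratio(ContingencyTable(0, 10, 0, 100)))

    @given(
        a=st.integers(0, 50), b=st.integers(0, 50),
        c=st.integers(0, 50), d=st.integers(0, 50),
    )
    def test_swap_inverts(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        orig, swapped = sample_odds_ratio(t), sample_odds_ratio(t.swapped())
        if math.isnan(orig):
            assert math.isnan(swapped)
        elif orig == 0:
            assert swapped == math.inf
        elif math.isinf(orig):
            assert swapped == 0
        else:
            assert swapped == pytest.approx(1 / orig)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table,printed",
        [
            ((4, 368, 30, 19924), 0.0033),
            ((4, 2084, 0, 4490), 0.010),
            ((3, 2085, 0, 4490), 0.032),
            ((1, 2087, 0, 19954), 0.095),
            ((1, 2087, 0, 4490), 0.32),
            ((4, 2084, 0, 2148), 0.059),
            ((1, 2087, 1, 282669), 0.015),
            ((3, 2085, 4, 19950), 0.022),
            ((4, 2084, 4, 19950), 0.0041),
        ],
    )
    def test_printed_p_values(self, table, printed):
        p = fisher_two_sided(ContingencyTable(*table))
        assert round(p, -int(math.floor(math.log10(p))) + 1) == pytest.approx(printed)

    def test_printed_scientific_p_values(self):
        p1 = fisher_two_sided(ContingencyTable(3, 2085, 4, 282666))
        assert p1 == pytest.approx(1.3e-5, rel=0.05)
        p2 = fisher_two_sided(ContingencyTable(4, 2084, 5, 282665))
        assert p2 == pytest.approx(3.5e-7, rel=0.05)

    def test_no_carriers_anywhere_gives_one(self):
        assert fisher_two_sided(ContingencyTable(0, 25, 0, 75)) == 1.0

    def test_degenerate_margins_give_one(self):
        assert fisher_two_sided(ContingencyTable(3, 0, 7, 0)) == 1.0

    def test_matches_scipy_on_large_tables(self):
        from scipy.stats import fisher_exact

        for table in [(4, 2084, 5, 282665), (7, 2081, 427, 282243), (1, 2087, 1, 282669)]:
            ours = fisher_two_sided(ContingencyTable(*table))
            ref = fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_enumeration_guard(self):
        big = 30_000_000
        with pytest.raises(EnumerationGuardError, match="guard"):
            fisher_two_sided(ContingencyTable(big, big, big, big))

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    @settings(max_examples=300, deadline=None)
    def test_oracle_agreement_random(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_two_sided(ContingencyTable(a, b, c, d))
        assert math.isclose(p, float(rational_fisher(a, b, c, d)), rel_tol=1e-12)

    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetries_and_range(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        p = fisher_two_sided(t)
        assert 0.0 < p <= 1.0
        assert fisher_two_sided(t.swapped()) == pytest.approx(p, rel=1e-12)
        assert fisher_two_sided(t.transposed()) == pytest.approx(p, rel=1e-12)

    @given(
        a=st.integers(1, 20), b=st.integers(1, 20),
        c=st.integers(1, 20), d=st.integers(1, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_the_heavy_tail(self, a, b, c, d):
        # with all margins fixed, pushing one carrier from group 2 to group 1
        # while the group-1 odds already dominate never increases p
        if a * d < b * c:
            return
        p_before = fisher_two_sided(ContingencyTable(a, b, c, d))
        p_after = fisher_two_sided(ContingencyTable(a + 1, b - 1, c - 1, d + 1))
        assert p_after <= p_before + 1e-12

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestReferencePopulation:
    def test_bundled_reference_counts(self, references):
        ea, all_pop = references["gnomad_ea"], references["gnomad_all"]
        assert ea.n_alleles == 19954
        assert all_pop.n_alleles == 282670
        assert ea.variant_counts["all_lof"] == 30
        assert all_pop.variant_counts["all_lof"] == 427
        assert all_pop.variant_counts["p.Q672X"] == 1

    def test_count_above_total_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ReferencePopulation("r", 10, {"x": 11})

    def test_missing_variant_set(self, references):
        with pytest.raises(KeyError, match="p.MISSING"):
            references["gnomad_ea"].burden("p.MISSING")

    def test_inconsistent_totals_rejected(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text(
            "population\tn_alleles\tvariant_set\tcount\nr\t10\ta\t1\nr\t12\tb\t1\n"
        )
        with pytest.raises(ValueError, match="inconsistent"):
            read_reference_table(path)


class TestBurdenScan:
    def test_scan_against_references(self, lof_variants, cohort_sets, references):
        from lofburden.cohorts import count_burden, lof_in_domain_set, lof_set

        familial = cohort_sets["familial"]
        burdens = [
            count_burden(lof_variants, lof_in_domain_set("zinc_hook"), familial),
            count_burden(lof_variants, lof_set(), familial),
        ]
        nonfam = count_burden(lof_variants, lof_set(), cohort_sets["nonfamilial"])
        results = burden_scan(
            [burdens[0]], [references["gnomad_ea"], references["gnomad_all"]]
        )
        assert round(results[0].odds_ratio, 2) == 9.57
        assert results[0].p_two_sided == pytest.approx(4.1e-3, rel=0.05)
        assert round(results[1].odds_ratio, 2) == 108.51
        all_vs_nonfam = burden_scan([burdens[1]], [nonfam])[0]
        assert round(all_vs_nonfam.odds_ratio, 2) == 1.88
        assert not all_vs_nonfam.significant

    def test_missing_reference_count_is_error(self, lof_variants, cohort_sets, references):
        from lofburden.cohorts import count_burden, protein_change_set

        burden = count_burden(
            lof_variants, protein_change_set("p.K994fs"), cohort_sets["familial"]
        )
        with pytest.raises(ValueError, match="p.K994fs"):
            burden_scan([burden], [references["gnomad_all"]])

    def test_variant_set_mismatch_rejected(self):
        case = BurdenCount("set_a", "g1", carriers=1, allele_total=10)
        other = BurdenCount("set_b", "g2", carriers=1, allele_total=10)
        with pytest.raises(ValueError, match="mismatch"):
            burden_scan([case], [other])

    def test_significance_flag_threshold(self):
        case = BurdenCount("s", "g1", carriers=4, allele_total=2088)
        comp = BurdenCount("s", "g2", carriers=0, allele_total=4490)
        result = associate(case, comp)
        assert result.p_two_sided < 0.05
        assert result.significant
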