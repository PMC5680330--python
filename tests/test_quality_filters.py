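"""Filter semantics, the exact Hardy-Weinberg test, and the filter battery."""

import itertools
import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from privar.quality_filters import (
    FilterConfig,
    allele_balance_pass,
    apply_site_filters,
    completeness_pass,
    depth_pass,
    hwe_exact_pvalue,
    site_quality_pass,
)
from privar.synthetic_data import (
    CohortSpec,
    PopulationSpec,
    make_mappability,
    plant_filter_failures,
    simulate_cohort,
)

from conftest import make_site


# ---------------------------------------------------------------------------
# Independent HWE oracles
# ---------------------------------------------------------------------------

def hwe_pvalue_fraction_oracle(n_aa, n_ab, n_bb):
    """Exact-arithmetic recomputation of the two-sided conditional test."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return Fraction(1)

    def prob(h):
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        num = (
            Fraction(math.factorial(n), math.factorial(aa) * math.factorial(h) * math.factorial(bb))
            * 2**h
            * math.factorial(n_a)
            * math.factorial(n_b)
        )
        return Fraction(num, math.factorial(2 * n))

    n_minor = min(n_a, n_b)
    support = range(n_minor % 2, n_minor + 1, 2)
    p_obs = prob(n_ab)
    return sum(prob(h) for h in support if prob(h) <= p_obs)


def hwe_distribution_permutation_oracle(n_a, n):
    """P(het count) by brute enumeration of ordered allele arrangements.

    Places n_a 'a' alleles among 2n ordered slots; slots (2i, 2i+1) form
    diploid i. Independent of any closed-form combinatorics.
    """
    counts = {}
    total = 0
    for slots in itertools.combinations(range(2 * n), n_a):
        hets = 0
        chosen = set(slots)
        for i in range(n):
            if (2 * i in chosen) != (2 * i + 1 in chosen):
                hets += 1
        counts[hets] = counts.get(hets, 0) + 1
        total += 1
    return {h: Fraction(c, total) for h, c in counts.items()}


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_pvalue(10, 0, 0) == 1.0
        assert hwe_exact_pvalue(0, 0, 7) == 1.0

    def test_two_hets_two_samples(self):
        """(0,2,0): two possible outcomes {0,2} hets; enumeration oracle."""
        expected = float(hwe_pvalue_fraction_oracle(0, 2, 0))
        assert hwe_exact_pvalue(0, 2, 0) == pytest.approx(expected, abs=1e-12)

    def test_all_counts_zero_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)

    def test_matches_fraction_oracle_small_tables(self):
        """All tables with N <= 8 agree with exact-arithmetic enumeration."""
        for n in range(1, 9):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_exact_pvalue(n_aa, n_ab, n_bb)
                    want = float(hwe_pvalue_fraction_oracle(n_aa, n_ab, n_bb))
                    assert got == pytest.approx(want, abs=1e-12), (n_aa, n_ab, n_bb)

    @pytest.mark.parametrize("n,n_a", [(2, 2), (3, 2), (3, 3), (4, 4), (5, 3)])
    def test_conditional_distribution_matches_permutations(self, n, n_a):
        """The het-count distribution the test sums over equals brute-force
        enumeration of allele arrangements into diploids."""
        from privar.quality_filters import _log_het_prob

        dist = hwe_distribution_permutation_oracle(n_a, n)
        for h, frac in dist.items():
            assert math.exp(_log_het_prob(h, n_a, n)) == pytest.approx(
                float(frac), abs=1e-12
            )


# ---------------------------------------------------------------------------
# Single-site predicates (boundary semantics)
# ---------------------------------------------------------------------------

def _one_sample_site(qual=50.0, gt=(0, 1), dp=30, ad=(15, 15)):
    return make_site([(gt, dp, ad)], qual=qual)


class TestPredicates:
    @pytest.mark.parametrize(
        "qual,expected", [(31.0, True), (30.0, False), (None, False), (30.01, True)]
    )
    def test_qual_strict_threshold(self, qual, expected):
        assert site_quality_pass(_one_sample_site(qual=qual), 30.0) is expected

    def test_depth_checks_only_polymorphic_genotypes(self):
        site = make_site([((0, 1), 6, (3, 3)), ((0, 0), 2, (2, 0))])
        assert depth_pass(site, 5)

    @pytest.mark.parametrize("dp,expected", [(5, False), (6, True), (None, False)])
    def test_depth_strict_threshold(self, dp, expected):
        assert depth_pass(_one_sample_site(dp=dp, ad=None), 5) is expected

    def test_all_hom_ref_passes_depth_vacuously(self):
        site = make_site([((0, 0), 1, (1, 0)), ((0, 0), None, None)])
        assert depth_pass(site, 5)

    def test_completeness(self):
        complete = make_site([((0, 1), 30, (15, 15)), ((0, 0), 30, (30, 0))])
        missing = make_site([((0, 1), 30, (15, 15)), (None, None, None)])
        empty = make_site([])
        assert completeness_pass(complete)
        assert not completeness_pass(missing)
        assert completeness_pass(empty)

    @pytest.mark.parametrize(
        "ad,ok",
        [
            ((5, 5), True),     # AB = 0.5
            ((9, 1), False),    # AB = 0.1 < 0.2
            ((1, 9), False),    # AB = 0.9 > 0.8
            ((8, 2), True),     # AB = 0.2 inclusive boundary
            ((2, 8), True),     # AB = 0.8 inclusive boundary
            ((801, 199), False),  # AB = 0.199
            ((199, 801), False),  # AB = 0.801
        ],
    )
    def test_allele_balance_band(self, ad, ok):
        site = _one_sample_site(ad=ad, dp=sum(ad))
        passed, label = allele_balance_pass(site, 0.2, 0.8)
        assert passed is ok
        if not ok:
            assert label == "ab"

    def test_het_without_ad_fails_with_explicit_label(self):
        site = _one_sample_site(ad=None)
        passed, label = allele_balance_pass(site)
        assert not passed and label == "ab_missing"

    def test_no_heterozygote_passes(self):
        site = make_site([((1, 1), 30, (0, 30)), ((0, 0), 30, (30, 0))])
        assert allele_balance_pass(site)[0]


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def _clean_spec(seed, n_sites=100):
    # Single population and high depth: background passes every filter with
    # overwhelming probability, so planted failures fix the counts exactly.
    # 26 samples: an all-heterozygote table is then far below alpha (tiny
    # cohorts cannot reach p < 1e-4 at all).
    return CohortSpec(
        populations=[PopulationSpec("p", 25, 0.02)],
        case_population="p",
        n_sites=n_sites,
        chrom_lengths={"chr1": 1_000_000},
        seed=seed,
        mean_depth=60.0,
        annotate=False,
    )


PLANT_LABELS = (
    ["q30"] * 3 + ["dp5"] * 3 + ["miss"] * 3 + ["ab"] * 3 + ["ab_missing"] * 2 + ["hwe"] * 3
)


class TestApplySiteFilters:
    def test_planted_failures_are_tallied_exactly(self):
        """100 sites with 20 planted failures -> 80 survivors, per-label
        counts equal to the plant record."""
        sites, truth = simulate_cohort(_clean_spec(0))
        plant_filter_failures(sites, truth, PLANT_LABELS, seed=1)
        planted = {(f["chrom"], f["pos"]) for f in truth.filter_failures}
        exclude = [
            (s.chrom, s.pos) for s in sites if (s.chrom, s.pos) not in planted
        ][:3]
        mask = make_mappability({"chr1": 1_000_000}, exclude=exclude, truth=truth)
        config = FilterConfig(mappability=mask)
        survivors, stats = apply_site_filters(sites, config)
        assert stats.sites_seen == 100
        assert len(survivors) == 100 - len(PLANT_LABELS) - len(exclude) == 80
        expected = {}
        for f in truth.filter_failures:
            expected[f["label"]] = expected.get(f["label"], 0) + 1
        assert stats.removed == expected

    def test_filters_idempotent(self):
        sites, truth = simulate_cohort(_clean_spec(3))
        plant_filter_failures(sites, truth, PLANT_LABELS, seed=4)
        config = FilterConfig()
        survivors, _ = apply_site_filters(sites, config)
        again, stats2 = apply_site_filters(survivors, config)
        assert len(again) == len(survivors)
        assert stats2.removed == {}

    def test_empty_stream(self):
        survivors, stats = apply_site_filters([], FilterConfig())
        assert survivors == [] and stats.sites_seen == 0 and stats.sites_passing == 0

    def test_no_mask_leaves_unmap_untouched(self):
        sites, _ = simulate_cohort(_clean_spec(5, n_sites=30))
        _, stats = apply_site_filters(sites, FilterConfig())
        assert "unmap" not in stats.removed

    @given(st.integers(0, 10_000))
    def test_predicates_order_independent(self, seed):
        """Survivor set is a pure per-site function, invariant to ordering."""
        sites, _ = simulate_cohort(_clean_spec(seed, n_sites=40))
        config = FilterConfig()
        fwd, _ = apply_site_filters(list(sites), config)
        rev, _ = apply_site_filters(list(reversed(sites)), config)
        assert {(s.chrom, s.pos) for s in fwd} == {(s.chrom, s.pos) for s in rev}
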