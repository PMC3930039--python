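"""Heterozygosities, exact HWE tests, F-statistics, AMOVA and B-Y control."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from racecaps.popgen import (
    PopulationSample,
    by_threshold,
    hierarchical_fstats,
    hwe_exact,
    hwe_markov_chain,
    observed_heterozygosity,
    pairwise_fst,
    reconstruct_counts,
    site_summary,
    unbiased_expected_heterozygosity,
)
from racecaps.simulate import PopSpec, simulate_population
from racecaps.table1 import EASTCOAST_SITES, MIDWEST_SITES, TABLE1, table1_samples


class TestHeterozygosity:
    def test_printed_beltsville_h_o(self):
        assert observed_heterozygosity(PopulationSample("7", 18, 13, 0)) == pytest.approx(
            0.419, abs=5e-4
        )

    def test_monomorphic_site_is_zero(self):
        assert observed_heterozygosity(PopulationSample("4", 48, 0, 0)) == 0.0

    def test_all_heterozygote_is_one(self):
        assert observed_heterozygosity(PopulationSample("x", 0, 17, 0)) == 1.0

    @pytest.mark.parametrize(
        "counts,printed",
        [((60, 17, 11), 0.347), ((37, 6, 5), 0.281), ((42, 6, 0), 0.118)],
    )
    def test_printed_unbiased_h_e(self, counts, printed):
        pop = PopulationSample("x", *counts)
        assert round(unbiased_expected_heterozygosity(pop), 3) == printed

    def test_unbiased_correction_identity(self):
        # (2n-1)/2n * H_E equals 2pq exactly
        pop = PopulationSample("x", 30, 12, 8)
        he = unbiased_expected_heterozygosity(pop)
        p = pop.p_e
        assert (2 * pop.n - 1) / (2 * pop.n) * he == pytest.approx(2 * p * (1 - p))

    def test_allele_swap_invariance(self):
        a = PopulationSample("x", 30, 12, 8)
        b = PopulationSample("x", 8, 12, 30)
        assert unbiased_expected_heterozygosity(a) == pytest.approx(
            unbiased_expected_heterozygosity(b)
        )

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            unbiased_expected_heterozygosity(PopulationSample("x", 1, 0, 0))


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,printed_p",
        [((21, 2, 1), 0.126), ((5, 2, 3), 0.082), ((17, 5, 2), 0.152),
         ((16, 1, 0), 1.000)],
    )
    def test_printed_p_values(self, counts, printed_p):
        res = hwe_exact(PopulationSample("x", *counts))
        assert round(res.p_exact, 3) == printed_p

    def test_heterozygote_deficit_sites_significant(self):
        # the two sites printed as "<0.001" (estimated there by Markov chain);
        # full enumeration gives 0.0002 and 0.00104, i.e. <= 0.001 at the
        # table's 3-decimal precision
        for counts in ((60, 17, 11), (37, 6, 5)):
            assert round(hwe_exact(PopulationSample("x", *counts)).p_exact, 3) <= 0.001

    def test_allele_swap_invariance(self):
        for a, b, c in ((21, 2, 1), (10, 5, 3), (4, 4, 4)):
            pa = hwe_exact(PopulationSample("x", a, b, c)).p_exact
            pb = hwe_exact(PopulationSample("x", c, b, a)).p_exact
            assert pa == pytest.approx(pb, abs=1e-12)

    def test_total_probability_mass_is_one_all_n_up_to_100(self):
        """The enumerator's distribution must be proper for every allele count."""
        from racecaps.popgen import _het_support, _log_config_prob

        for n in range(1, 101):
            for n_e in range(0, n + 1):  # n_e beyond n mirrors by symmetry
                total = math.fsum(
                    math.exp(_log_config_prob(n, h, n_e)) for h in _het_support(n, n_e)
                )
                assert abs(total - 1.0) < 1e-9, (n, n_e)

    def test_monomorphic_single_configuration(self):
        assert hwe_exact(PopulationSample("x", 10, 0, 0)).p_exact == 1.0


class TestHweMarkovChain:
    def test_converges_to_enumeration(self):
        for counts in ((21, 2, 1), (60, 17, 11), (5, 2, 3), (10, 20, 10)):
            pop = PopulationSample("x", *counts)
            exact = hwe_exact(pop).p_exact
            mc = hwe_markov_chain(pop, steps=200_000, burnin=2_000, seed=1).p_exact
            assert mc == pytest.approx(exact, abs=0.01)

    def test_agreement_across_sample_sizes(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            n = int(rng.integers(5, 101))
            n_ez = int(rng.integers(0, n + 1))
            rest = n - n_ez
            n_zz = int(rng.integers(0, rest + 1))
            pop = PopulationSample("x", n_zz, n_ez, rest - n_zz)
            exact = hwe_exact(pop).p_exact
            mc = hwe_markov_chain(pop, steps=60_000, burnin=1_000, seed=11).p_exact
            assert mc == pytest.approx(exact, abs=0.03)

    def test_monomorphic_degenerate_state(self):
        res = hwe_markov_chain(PopulationSample("x", 30, 0, 0), steps=5_000, burnin=100, seed=0)
        assert res.p_exact == 1.0

    def test_seed_reproducibility(self):
        pop = PopulationSample("x", 21, 2, 1)
        a = hwe_markov_chain(pop, steps=20_000, burnin=500, seed=42).p_exact
        b = hwe_markov_chain(pop, steps=20_000, burnin=500, seed=42).p_exact
        assert a == b

    def test_steps_must_exceed_burnin(self):
        with pytest.raises(ValueError):
            hwe_markov_chain(PopulationSample("x", 5, 2, 3), steps=100, burnin=100)


def brute_force_reconstruct(n, h_o, h_e, tol=1e-3):
    """Exhaustive search over every genotype triple summing to n."""
    hits = set()
    for n_ez in range(n + 1):
        for n_ee in range(n - n_ez + 1):
            n_zz = n - n_ez - n_ee
            if abs(n_ez / n - h_o) > 5e-3:
                continue
            pop = PopulationSample("x", n_zz, n_ez, n_ee)
            if h_e is None:
                if pop.monomorphic:
                    hits.add((max(n_zz, n_ee), n_ez, min(n_zz, n_ee)))
                continue
            if pop.n >= 2 and abs(unbiased_expected_heterozygosity(pop) - h_e) <= tol:
                hits.add((max(n_zz, n_ee), n_ez, min(n_zz, n_ee)))
    return hits


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "n,h_o,h_e,expected",
        [(24, 0.083, 0.156, (21, 2, 1)), (88, 0.193, 0.347, (60, 17, 11)),
         (10, 0.000, None, (10, 0, 0)), (10, 0.200, 0.506, (5, 2, 3))],
    )
    def test_printed_rows_invert_to_unique_counts(self, n, h_o, h_e, expected):
        assert reconstruct_counts(n, h_o, h_e) == expected

    def test_validated_by_exhaustive_search_on_all_field_rows(self):
        for row in TABLE1:
            if row.site_id == "C":
                continue
            got = reconstruct_counts(row.n, row.h_o, row.h_e)
            brute = brute_force_reconstruct(row.n, row.h_o, row.h_e)
            assert brute == {got}, row.site_id

    def test_inconsistent_input_rejected(self):
        with pytest.raises(ValueError, match="no consistent|no integer"):
            reconstruct_counts(24, 0.083, 0.9)


class TestPairwiseFst:
    def test_identical_frequencies_give_near_zero_theta(self):
        a = PopulationSample("a", 64, 32, 4)
        b = PopulationSample("b", 64, 32, 4)
        theta, _ = pairwise_fst(a, b, n_perm=0)
        assert abs(theta) < 0.02

    def test_fixed_difference_gives_theta_one(self):
        theta, p = pairwise_fst(
            PopulationSample("a", 48, 0, 0), PopulationSample("b", 0, 0, 48),
            n_perm=200, seed=0,
        )
        assert theta == pytest.approx(1.0)
        assert p < 0.01

    def test_same_allele_monomorphic_pair_undefined(self):
        theta, p = pairwise_fst(
            PopulationSample("a", 20, 0, 0), PopulationSample("b", 30, 0, 0)
        )
        assert theta is None and p is None

    def test_reconstructed_midwest_vs_eastcoast_site_significant(self):
        mead = table1_samples(include=["1"])[0]
        newark = table1_samples(include=["8"])[0]
        theta, p = pairwise_fst(mead, newark, n_perm=1000, seed=3)
        assert theta > 0
        assert p < 0.05

    def test_permutation_p_valid_under_null(self):
        """On exchangeable data the permutation p-value must be valid at every
        level: P(p <= a) <= a (up to binomial noise).  The statistic is a
        function of discrete genotype counts, so heavy ties make the p-value
        conservative rather than exactly uniform; validity, not uniformity,
        is the property a permutation test guarantees here."""
        rng = np.random.default_rng(5)
        ps = []
        for rep in range(200):
            genos = rng.choice(3, size=60, p=[0.49, 0.42, 0.09])
            a = PopulationSample("a", *(int((genos[:30] == k).sum()) for k in (0, 1, 2)))
            b = PopulationSample("b", *(int((genos[30:] == k).sum()) for k in (0, 1, 2)))
            if (a.monomorphic and b.monomorphic):
                continue
            _, p = pairwise_fst(a, b, n_perm=99, seed=int(rng.integers(2**31)))
            if p is not None:
                ps.append(p)
        ps = np.array(ps)
        assert len(ps) > 150
        for alpha in (0.05, 0.10, 0.25, 0.50):
            slack = 3 * np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + slack
        # not degenerately conservative either: small p-values do occur
        assert (ps <= 0.25).mean() > 0.02


class TestHierarchicalFstats:
    def test_identical_populations_show_no_group_structure(self):
        pops = [PopulationSample("a", 50, 40, 10, region="g1"),
                PopulationSample("b", 50, 40, 10, region="g2")]
        fs = hierarchical_fstats(pops, {"a": "g1", "b": "g2"}, n_perm=200, seed=0)
        assert abs(fs.F_CT) < 0.02
        assert fs.p_CT > 0.2

    def test_fixed_versus_segregating_group_positive_fct(self):
        # several populations per group: the F_CT permutation test reshuffles
        # whole populations, so its resolution is the number of group labelings
        pops = [PopulationSample(f"f{k}", 50, 0, 0, region="g1") for k in range(4)]
        pops += [PopulationSample(f"s{k}", 13, 24, 13, region="g2") for k in range(4)]
        grouping = {p.site_id: p.region for p in pops}
        fs = hierarchical_fstats(pops, grouping, n_perm=500, seed=1)
        assert fs.F_CT > 0
        assert fs.p_CT < 0.05

    def test_island_model_theta_recovery(self):
        """Balding-Nichols demes at F_ST = 0.10: mean recovered theta in CI."""
        F, p0 = 0.10, 0.5
        shape = p0 * (1 - F) / F
        rng = np.random.default_rng(17)
        thetas = []
        for _ in range(100):
            p1, p2 = rng.beta(shape, shape, size=2)
            pops = []
            for k, p in enumerate((p1, p2)):
                s, _ = simulate_population(
                    PopSpec(n=100, p_e=float(p), site_id=f"d{k}",
                            seed=int(rng.integers(2**31)))
                )
                pops.append(s)
            t = pairwise_fst(pops[0], pops[1], n_perm=0)[0]
            if t is not None:
                thetas.append(t)
        mean = np.mean(thetas)
        se = np.std(thetas, ddof=1) / np.sqrt(len(thetas))
        assert abs(mean - F) < 3 * se + 0.01

    def test_inbreeding_f_recovery(self):
        """F_IS from the AMOVA recovers the generating inbreeding coefficient."""
        F = 0.3
        rng = np.random.default_rng(23)
        fis = []
        for _ in range(60):
            pops = []
            for k in range(2):
                s, _ = simulate_population(
                    PopSpec(n=150, p_e=0.4, inbreeding_F=F, site_id=f"s{k}",
                            region=f"g{k}", seed=int(rng.integers(2**31)))
                )
                pops.append(s)
            fs = hierarchical_fstats(pops, {"s0": "g0", "s1": "g1"}, n_perm=0)
            if fs.F_IS is not None:
                fis.append(fs.F_IS)
        mean = np.mean(fis)
        se = np.std(fis, ddof=1) / np.sqrt(len(fis))
        assert abs(mean - F) < 3 * se + 0.01

    def test_reconstructed_field_data_directionality(self):
        """Region structure and within-region heterozygote deficit, as published."""
        pops = table1_samples(include=MIDWEST_SITES
                              + [s for s in EASTCOAST_SITES if s != "6"])
        grouping = {p.site_id: p.region for p in pops}
        fs = hierarchical_fstats(pops, grouping, n_perm=1000, seed=2)
        assert fs.F_CT > 0 and fs.p_CT < 0.05
        assert fs.F_IS > 0 and fs.p_IS < 0.05

    def test_all_monomorphic_leaves_f_undefined(self):
        pops = [PopulationSample("a", 30, 0, 0, region="g1"),
                PopulationSample("b", 30, 0, 0, region="g2")]
        fs = hierarchical_fstats(pops, {"a": "g1", "b": "g2"}, n_perm=0)
        assert fs.F_CT is None and fs.F_ST is None


class TestByThreshold:
    def test_single_test_unchanged(self):
        assert by_threshold(0.05, 1) == pytest.approx(0.05)

    def test_three_tests_harmonic_sum(self):
        assert by_threshold(0.05, 3) == pytest.approx(0.05 / (1 + 0.5 + 1 / 3))

    def test_fifty_five_pairwise_comparisons(self):
        # H(55) = 4.594: the adjusted threshold is ~0.011
        assert by_threshold(0.05, 55) == pytest.approx(0.0109, abs=5e-4)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            by_threshold(0.05, 0)


class TestSiteSummary:
    def test_printed_eastcoast_mean_and_sd(self):
        pops = table1_samples(include=EASTCOAST_SITES)
        _, summary = site_summary(pops, {"EastCoast": EASTCOAST_SITES})
        row = summary.iloc[0]
        assert round(row["mean_H_O"], 3) == 0.154
        assert round(row["sd_H_O"], 3) == 0.110

    def test_monomorphic_sites_reported_without_test(self):
        pops = table1_samples(include=["4"])  # a fixed pgfar-z site
        per_site, _ = site_summary(pops)
        assert per_site.iloc[0]["monomorphic"]
        assert per_site.iloc[0]["H_O"] == 0.0

    def test_single_site_sd_undefined(self):
        import pandas as pd

        pops = table1_samples(include=["8"])
        _, summary = site_summary(pops, {"one": ["8"]})
        assert pd.isna(summary.iloc[0]["sd_H_O"])

    def test_all_monomorphic_set(self):
        pops = table1_samples(include=MIDWEST_SITES)
        _, summary = site_summary(pops, {"Midwest": MIDWEST_SITES})
        assert summary.iloc[0]["mean_H_O"] == 0.0
        assert summary.iloc[0]["sd_H_O"] == 0.0


class TestWahlund:
    def test_admixture_inflates_hwe_rejection_rate(self):
        """Pooling two demes rejects HWE far above the nominal level."""
        rejections = 0
        n_rep = 150
        for seed in range(n_rep):
            s, _ = simulate_population(
                PopSpec(n=100, admixture=(0.05, 0.5, 0.5), seed=seed)
            )
            if not s.monomorphic and hwe_exact(s).p_exact < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.15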