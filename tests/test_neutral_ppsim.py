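"""Neutral coalescent PPS: analytic expectations, msprime oracle, binning."""

import numpy as np
import pytest
from scipy.stats import hypergeom, ks_2samp

from hybridzone import (
    NeutralSimConfig,
    build_null_distribution,
    compare_binned,
    estimate_false_positive_rate,
    make_pseudo_posterior,
    simulate_neutral_locus,
    wc_fst,
)
from hybridzone.neutral_ppsim import (
    _drop_mutations,
    _simulate_genealogy,
    _simulate_site_counts,
    _tip_bases,
)

POSTERIOR_MEANS = dict(theta_west=0.0592, theta_east=0.217, theta_anc=0.0615, tau=0.00578)


def tree_length(parent, node_time):
    has_parent = parent >= 0
    return float((node_time[parent[has_parent]] - node_time[has_parent]).sum())


class TestGenealogy:
    def test_pairwise_divergence_expectation(self):
        """E[branch length separating one west and one east lineage] = 2*tau + theta_anc.

        At the default posterior-mean parameters this is 0.0731 expected
        substitutions per site.
        """
        rng = np.random.default_rng(1)
        tot = []
        for _ in range(15_000):
            parent, node_time, _ = _simulate_genealogy(
                rng, n_w=1, n_e=1, **POSTERIOR_MEANS
            )
            tot.append(tree_length(parent, node_time))
        tot = np.array(tot)
        expected = 2 * POSTERIOR_MEANS["tau"] + POSTERIOR_MEANS["theta_anc"]
        se = tot.std() / np.sqrt(len(tot))
        assert abs(tot.mean() - expected) < 3 * se
        assert expected == pytest.approx(0.0731, abs=1e-4)

    def test_within_population_diversity_equals_theta(self):
        """E[pairwise coalescent path within a population] = theta_i when
        theta_anc = theta_i (the clean closed-form case)."""
        rng = np.random.default_rng(2)
        for theta in (0.02, 0.08):
            tot = []
            for _ in range(8_000):
                parent, t, _ = _simulate_genealogy(rng, theta, theta, theta, 0.01, 2, 0)
                tot.append(2 * t[-1])
            tot = np.array(tot)
            se = tot.std() / np.sqrt(len(tot))
            assert abs(tot.mean() - theta) < 3 * se

    def test_zero_theta_with_lineages_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="infinite rate"):
            _simulate_genealogy(rng, 0.0, 0.1, 0.1, 0.01, 3, 3)


class TestMsprimeOracle:
    @pytest.mark.parametrize(
        "params",
        [
            (0.05, 0.05, 0.05, 0.02),
            (0.0592, 0.217, 0.0615, 0.00578),
            (0.01, 0.03, 0.02, 0.05),
        ],
    )
    def test_diversity_and_divergence_match_msprime(self, params):
        """Per-site diversity/divergence agree with msprime within 3 MC SE."""
        import msprime

        tw, te, ta, tau = params
        n_w = n_e = 6
        L, reps = 100, 600
        rng = np.random.default_rng(11)

        def my_stats():
            pi_w, dv = [], []
            for _ in range(reps):
                parent, t, n = _simulate_genealogy(rng, tw, te, ta, tau, n_w, n_e)
                sites = _drop_mutations(rng, parent, t, L)
                diff_w = diff_b = 0
                for s, muts in sites.items():
                    b = _tip_bases(rng, parent, t, n, muts)
                    w, e = b[:n_w], b[n_w:]
                    diff_w += sum(w[i] != w[j] for i in range(n_w) for j in range(i + 1, n_w))
                    diff_b += sum(int(w[i] != e[j]) for i in range(n_w) for j in range(n_e))
                pi_w.append(diff_w / (n_w * (n_w - 1) / 2) / L)
                dv.append(diff_b / (n_w * n_e) / L)
            return np.array(pi_w), np.array(dv)

        def msp_stats():
            # haploid msprime: pairwise rate 1/N, so N = theta/2 reproduces rate 2/theta
            dem = msprime.Demography()
            dem.add_population(name="west", initial_size=tw / 2)
            dem.add_population(name="east", initial_size=te / 2)
            dem.add_population(name="anc", initial_size=ta / 2)
            dem.add_population_split(time=tau, derived=["west", "east"], ancestral="anc")
            pi_w, dv = [], []
            mut_rng = np.random.default_rng(12345)
            for ts in msprime.sim_ancestry(
                {"west": n_w, "east": n_e}, demography=dem, ploidy=1,
                sequence_length=L, num_replicates=reps, random_seed=777,
            ):
                mts = msprime.sim_mutations(
                    ts, rate=1.0, model=msprime.JC69(),
                    random_seed=int(mut_rng.integers(1, 2**31)),
                )
                pi_w.append(float(np.asarray(
                    mts.diversity(sample_sets=list(range(n_w)), mode="site"))))
                dv.append(float(np.asarray(mts.divergence(
                    sample_sets=[list(range(n_w)), list(range(n_w, n_w + n_e))],
                    mode="site"))))
            return np.array(pi_w), np.array(dv)

        my_pi, my_dv = my_stats()
        ms_pi, ms_dv = msp_stats()
        for mine, theirs in ((my_pi, ms_pi), (my_dv, ms_dv)):
            se = np.hypot(mine.std() / np.sqrt(reps), theirs.std() / np.sqrt(reps))
            assert abs(mine.mean() - theirs.mean()) < 3.5 * se


class TestSimulateNeutralLocus:
    def test_panmixia_matches_relabeling_oracle(self):
        """tau=0, equal theta: F_ST indistinguishable from random relabeling."""
        rng = np.random.default_rng(21)
        n_w, n_e = 12, 8
        fst_obs, fst_perm = [], []
        for _ in range(2_000):
            counts = _simulate_site_counts(rng, 0.05, 0.05, 0.05, 0.0, n_w, n_e, 100)
            if counts is None:
                continue
            cw, ce = counts
            fst_obs.append(wc_fst(cw, n_w, ce, n_e))
            # permutation oracle: scatter the same alleles over random labels
            k = cw + ce
            cw_p = int(rng.hypergeometric(k, n_w + n_e - k, n_w))
            fst_perm.append(wc_fst(cw_p, n_w, ce + cw - cw_p, n_e))
        assert ks_2samp(fst_obs, fst_perm).pvalue > 0.01

    def test_median_fst_increases_with_tau(self):
        rng = np.random.default_rng(22)
        medians = []
        for tau in (0.005, 0.05, 0.2):
            vals = []
            while len(vals) < 400:
                res = simulate_neutral_locus(0.05, 0.05, 0.05, tau, 10, 10, 100, rng)
                if res is not None:
                    vals.append(res[0])
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_neutral_locus(-0.1, 0.1, 0.1, 0.01, 4, 4)
        with pytest.raises(ValueError):
            simulate_neutral_locus(0.1, 0.1, 0.1, 0.01, 1, 4)


class TestBuildNullDistribution:
    def test_counts_and_determinism(self):
        post = make_pseudo_posterior(n_rows=5, jitter_cv=0.2, seed=1)
        cfg = NeutralSimConfig(loci_per_sample=20, locus_length=100,
                               coverage_west=10, coverage_east=10, seed=9)
        null1 = build_null_distribution(post, cfg)
        null2 = build_null_distribution(post, cfg)
        assert null1.n_total == 100
        assert len(null1.fst) + null1.n_skipped == 100
        np.testing.assert_array_equal(null1.fst, null2.fst)
        np.testing.assert_array_equal(null1.posterior_row, null2.posterior_row)
        assert ((null1.fst >= 0) & (null1.fst <= 1)).all()
        assert ((null1.dxy >= 0) & (null1.dxy <= 1)).all()

    def test_coverage_distribution_mode(self):
        post = make_pseudo_posterior(n_rows=2, jitter_cv=0.0, seed=1)
        cfg = NeutralSimConfig(loci_per_sample=10, locus_length=100,
                               coverage_west=[6, 8, 10], coverage_east=[4, 12], seed=2)
        null = build_null_distribution(post, cfg)
        assert len(null.fst) > 0


@pytest.fixture(scope="module")
def null_vector():
    rng = np.random.default_rng(31)
    vals = []
    while len(vals) < 2_000:
        res = simulate_neutral_locus(0.05, 0.05, 0.05, 0.02, 10, 10, 100, rng)
        if res is not None:
            vals.append(res[0])
    return np.array(vals)


class TestCompareBinned:
    def test_type_i_calibration_under_null(self, null_vector):
        """Bootstrap of the null vs the null: <=10% of bins reject at .05."""
        rng = np.random.default_rng(32)
        n_sig = n_bins = 0
        for _ in range(20):
            emp = rng.choice(null_vector, size=800, replace=True)
            cmp_ = compare_binned(emp, null_vector)
            occupied = (cmp_.empirical_counts + cmp_.simulated_counts) > 0
            n_bins += int(occupied.sum())
            n_sig += int((cmp_.fisher_p[occupied] < 0.05).sum())
        assert n_sig / n_bins <= 0.10

    def test_planted_excess_detected_in_high_bins(self, null_vector):
        rng = np.random.default_rng(33)
        emp = np.concatenate([null_vector[:800], rng.uniform(0.6, 1.0, 200)])
        cmp_ = compare_binned(emp, null_vector)
        high = cmp_.bin_edges[:-1] >= 0.6
        assert (cmp_.fisher_p[high] < 0.01).any()

    def test_default_bin_width(self, null_vector):
        cmp_ = compare_binned(null_vector[:100], null_vector)
        assert len(cmp_.bin_edges) == 11
        np.testing.assert_allclose(np.diff(cmp_.bin_edges), 0.1)
        assert cmp_.empirical_counts.sum() == 100

    def test_empty_bin_in_both_records_p_one(self):
        cmp_ = compare_binned(np.array([0.05, 0.05]), np.array([0.02, 0.08]))
        assert cmp_.fisher_p[-1] == 1.0


class TestFalsePositiveRate:
    def test_identical_distributions_give_one(self):
        v = np.linspace(0, 1, 500)
        assert estimate_false_positive_rate(v, v, 0.6, 1.0) == 1.0

    def test_no_simulated_mass_gives_zero(self):
        emp = np.array([0.7, 0.8, 0.9])
        sim = np.array([0.1, 0.2])
        assert estimate_false_positive_rate(emp, sim, 0.6, 1.0) == 0.0

    def test_fraction_ratio_fixture(self):
        """Simulated mass 0.001 vs empirical 0.005 in (0.6, 1] gives 0.2."""
        emp = np.concatenate([np.full(995, 0.1), np.full(5, 0.7)])
        sim = np.concatenate([np.full(999, 0.1), np.full(1, 0.7)])
        assert estimate_false_positive_rate(emp, sim, 0.6, 1.0) == pytest.approx(0.2)

    def test_no_empirical_mass_is_undefined(self):
        assert np.isnan(estimate_false_positive_rate(
            np.array([0.1]), np.array([0.7]), 0.6, 1.0))
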