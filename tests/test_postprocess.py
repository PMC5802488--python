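import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from haploscan.genmap import Window
from haploscan.mlm import AssociationResult
from haploscan.postprocess import (
    PowerSpec,
    allelic_power,
    clump,
    genomic_inflation,
    ivw_meta,
    ld_r2,
    monte_carlo_power,
    or_ci_to_beta_se,
)


def _res(i, p, chrom="1", start=None):
    start = start if start is not None else 1000 + i * 10
    w = Window(chrom, 0.25, i, i + 9, start, start + 9, 0.0)
    return AssociationResult(
        window=w, allele_string="0" * 10, freq=0.1, beta=0.01, se=0.01,
        z=1.0, p=p, or_=1.1, or_lo=0.9, or_hi=1.3, var_explained_raw=0.0,
    )


class TestLdR2:
    def test_identical_vectors(self):
        d = np.array([0, 1, 2, 1, 0, 2])
        assert ld_r2(d, d) == pytest.approx(1.0)

    def test_orthogonal_balanced_vectors(self):
        a = np.array([1, 1, -1, -1], dtype=float)
        b = np.array([1, -1, 1, -1], dtype=float)
        assert ld_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            ld_r2(np.zeros(5), np.arange(5))

    def test_matches_covariance_oracle(self, rng):
        for _ in range(100):
            a = rng.integers(0, 3, 50).astype(float)
            b = rng.integers(0, 3, 50).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            cov = np.mean(a * b) - a.mean() * b.mean()
            oracle = cov**2 / (a.var() * b.var())
            assert ld_r2(a, b) == pytest.approx(oracle, abs=1e-12)


class TestClump:
    def test_uncorrelated_all_independent(self, rng):
        # orthogonal dosage patterns: every haplotype its own clump
        D = np.eye(6)[:4] * 2
        results = [_res(i, 0.01 * (i + 1)) for i in range(4)]
        rep = clump(results, D)
        assert rep.n_independent == 4
        assert rep.bonferroni_alpha == pytest.approx(0.05 / 4)

    def test_identical_dosages_single_clump(self):
        D = np.tile(np.array([0.0, 1, 2, 1, 0, 2]), (5, 1))
        results = [_res(i, 0.01 * (i + 1)) for i in range(5)]
        rep = clump(results, D)
        assert rep.n_independent == 1
        assert len(rep.clumps[0].members) == 5

    def test_matches_brute_force_oracle(self, rng):
        # greedy oracle written independently: repeatedly take the best-P
        # unassigned item and absorb all correlated unassigned items
        n, m = 40, 60
        D = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        D[1] = D[0]  # force some correlation structure
        D[5] = 2 - D[4]
        results = [_res(i, float(p)) for i, p in enumerate(rng.uniform(0, 1, n))]
        rep = clump(results, D, r2_threshold=0.4, distance_kb=1e6)
        remaining = set(range(n))
        oracle_clumps = []
        while remaining:
            idx = min(remaining, key=lambda i: (results[i].p, i))
            members = {idx}
            for j in list(remaining - {idx}):
                r = np.corrcoef(D[idx], D[j])[0, 1] ** 2
                if r >= 0.4:
                    members.add(j)
            remaining -= members
            oracle_clumps.append(members)
        assert rep.n_independent == len(oracle_clumps)
        got = sorted(frozenset(c.members) for c in rep.clumps)
        assert got == sorted(frozenset(c) for c in oracle_clumps)

    def test_input_order_invariance(self, rng):
        n = 20
        D = rng.binomial(2, 0.3, size=(n, 50)).astype(float)
        ps = rng.uniform(0, 1, n)
        results = [_res(i, float(ps[i])) for i in range(n)]
        rep1 = clump(results, D)
        perm = rng.permutation(n)
        rep2 = clump([results[i] for i in perm], D[perm])
        assert rep1.n_independent == rep2.n_independent

    def test_distance_window_limits_membership(self):
        D = np.tile(np.array([0.0, 1, 2, 1, 0, 2]), (2, 1))
        far = [_res(0, 0.001, start=1000), _res(1, 0.01, start=5_000_000)]
        rep = clump(far, D, distance_kb=1000)
        assert rep.n_independent == 2

    def test_bonferroni_below_genome_wide_line(self):
        # the discovery study's clump count implies a threshold below 5e-8
        assert 0.05 / 1_070_216 < 5e-8

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            clump([], np.zeros((0, 5)))


class TestGenomicInflation:
    def test_uniform_quantiles_give_unity(self):
        p = (np.arange(1, 10001) - 0.5) / 10000
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.01)

    def test_doubled_chi2_doubles_lambda(self):
        p = (np.arange(1, 5001) - 0.5) / 5000
        chi = stats.chi2.isf(p, 1)
        p2 = stats.chi2.sf(2 * chi, 1)
        lam1 = genomic_inflation(p)
        lam2 = genomic_inflation(p2)
        assert lam2 == pytest.approx(2 * lam1, rel=1e-6)

    def test_needs_enough_pvalues(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.full(50, 0.5))


class TestIvwMeta:
    def test_two_identical_cohorts(self):
        m = ivw_meta([(0.2, 0.1), (0.2, 0.1)])
        assert m.beta == pytest.approx(0.2)
        assert m.se == pytest.approx(0.1 / np.sqrt(2))

    def test_k_equal_cohorts_shrink_se_sqrt_k(self):
        for k in (2, 4, 9):
            m = ivw_meta([(0.1, 0.05)] * k)
            assert m.se == pytest.approx(0.05 / np.sqrt(k))

    def test_hand_computed_oracle(self):
        # log-OR/SE pairs reconstructed from printed discovery and
        # replication odds-ratio rows of the chromosome-6 0.25-cM haplotype
        m = ivw_meta([(0.5188, 0.0822), (0.1310, 0.0449)])
        assert m.beta == pytest.approx(0.2200, abs=5e-4)
        assert m.or_ == pytest.approx(1.25, abs=0.01)

    def test_infinite_variance_cohort_contributes_nothing(self):
        base = ivw_meta([(0.3, 0.05), (0.3, 0.05)])
        extra = ivw_meta([(0.3, 0.05), (0.3, 0.05), (99.0, 1e6)])
        assert extra.beta == pytest.approx(base.beta, abs=1e-6)

    def test_combined_se_not_above_best_cohort(self, rng):
        for _ in range(50):
            stats_in = [
                (float(rng.normal()), float(rng.uniform(0.01, 1)))
                for _ in range(3)
            ]
            m = ivw_meta(stats_in)
            assert m.se <= min(s for _, s in stats_in) + 1e-12

    def test_non_positive_se_errors(self):
        with pytest.raises(ValueError):
            ivw_meta([(0.1, 0.0), (0.2, 0.1)])


class TestOrCiConversion:
    def test_closed_form_unit_case(self):
        b, s = or_ci_to_beta_se(1.0, np.exp(-1.959964), np.exp(1.959964))
        assert b == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(1.0, rel=1e-9)

    def test_printed_row_evaluates(self):
        b, s = or_ci_to_beta_se(1.68, 1.42, 1.96)
        assert b == pytest.approx(0.5188, abs=5e-5)
        assert s == pytest.approx(0.0822, abs=5e-5)

    def test_round_trip(self):
        b, s = or_ci_to_beta_se(1.5, 1.2, 1.875)
        assert np.exp(b) == pytest.approx(1.5, abs=1e-10)
        assert np.exp(b - 1.959964 * s) == pytest.approx(1.2, abs=1e-10)
        assert np.exp(b + 1.959964 * s) == pytest.approx(1.875, abs=1e-10)

    def test_bad_ordering_errors(self):
        with pytest.raises(ValueError):
            or_ci_to_beta_se(1.5, 1.6, 1.9)

    @given(
        st.floats(-2.0, 2.0, allow_nan=False),
        st.floats(0.001, 1.0, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_inverse_of_exponentiation(self, beta, se):
        or_ = np.exp(beta)
        lo = np.exp(beta - 1.959964 * se)
        hi = np.exp(beta + 1.959964 * se)
        b, s = or_ci_to_beta_se(or_, lo, hi)
        assert b == pytest.approx(beta, abs=1e-10)
        assert s == pytest.approx(se, rel=1e-10)


class TestAllelicPower:
    def test_null_grr_gives_alpha(self):
        spec = PowerSpec(grr=1.0, freq=0.1, prevalence=0.15,
                         n_case=5000, n_control=5000, alpha=0.05)
        assert allelic_power(spec) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_grr_freq_and_n(self):
        base = dict(freq=0.05, prevalence=0.15, n_case=2000, n_control=4000)
        p1 = allelic_power(PowerSpec(grr=1.2, **base))
        p2 = allelic_power(PowerSpec(grr=1.5, **base))
        assert p1 < p2
        lo = allelic_power(PowerSpec(grr=1.3, freq=0.02, prevalence=0.15,
                                     n_case=2000, n_control=4000))
        hi = allelic_power(PowerSpec(grr=1.3, freq=0.10, prevalence=0.15,
                                     n_case=2000, n_control=4000))
        assert lo < hi
        small = allelic_power(PowerSpec(grr=1.3, freq=0.05, prevalence=0.15,
                                        n_case=500, n_control=1000))
        big = allelic_power(PowerSpec(grr=1.3, freq=0.05, prevalence=0.15,
                                      n_case=5000, n_control=10000))
        assert small < big

    def test_rarest_strongest_candidate_exceeds_99(self):
        # the rarest replication-cohort haplotype, with the largest
        # discovery odds ratio used as its GRR
        spec = PowerSpec(grr=2.33, freq=0.0027, prevalence=0.146,
                         n_case=8508, n_control=16527, alpha=0.05)
        assert allelic_power(spec) > 0.99

    def test_invalid_grr_errors(self):
        with pytest.raises(ValueError):
            PowerSpec(grr=0.0, freq=0.1, prevalence=0.1,
                      n_case=100, n_control=100)

    @pytest.mark.parametrize(
        "grr,freq", [(1.3, 0.1), (1.15, 0.3), (2.0, 0.02)]
    )
    def test_agrees_with_monte_carlo(self, grr, freq):
        spec = PowerSpec(grr=grr, freq=freq, prevalence=0.146,
                         n_case=800, n_control=1500, alpha=0.05)
        mc = monte_carlo_power(spec, n_reps=10_000, seed=99)
        assert allelic_power(spec) == pytest.approx(mc, abs=0.02)
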