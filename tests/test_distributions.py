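from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylkl import (
    BetaDistribution,
    DepthProfile,
    MethylationSite,
    beta_value,
    binomial_pmf,
    mean_methylation,
    observed_distribution,
    random_distribution,
    restrict_to_depth,
    sample_random_methylome,
)

from conftest import TOY_RRAN

F = Fraction


def sites_of(pairs):
    return [
        MethylationSite("c", 2 * i + 2, "+", m, t)
        for i, (t, m) in enumerate(pairs)
    ]


site_lists = st.lists(
    st.integers(min_value=1, max_value=12).flatmap(
        lambda t: st.tuples(st.just(t), st.integers(min_value=0, max_value=t))
    ),
    min_size=1,
    max_size=30,
)


class TestBetaValue:
    @pytest.mark.parametrize(
        "m,t,expected", [(2, 4, F(1, 2)), (0, 7, F(0)), (3, 3, F(1))]
    )
    def test_examples(self, m, t, expected):
        assert beta_value(m, t) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            beta_value(5, 4)
        with pytest.raises(ValueError):
            beta_value(0, 0)


class TestObservedDistribution:
    def test_toy(self, toy_sites):
        dist = observed_distribution(toy_sites)
        assert dist.mass == {F(0): F(1, 3), F(1, 2): F(1, 3), F(1): F(1, 3)}
        assert dist.n_sites == 3

    def test_single_site(self):
        dist = observed_distribution(sites_of([(5, 3)]))
        assert dist.mass == {F(3, 5): F(1)}

    def test_equal_fractions_merge(self):
        dist = observed_distribution(sites_of([(2, 1), (4, 2)]))
        assert dist.mass == {F(1, 2): F(1)}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            observed_distribution([])

    @given(pairs=site_lists)
    def test_normalization_exact(self, pairs):
        dist = observed_distribution(sites_of(pairs))
        assert dist.total() == 1


class TestMeanMethylation:
    def test_per_site(self, toy_sites):
        assert mean_methylation(toy_sites) == F(1, 2)

    def test_pooled(self, toy_sites):
        assert mean_methylation(toy_sites, mode="pooled") == F(1, 2)

    def test_modes_differ(self):
        sites = sites_of([(10, 10), (2, 0)])
        assert mean_methylation(sites, "per_site") == F(1, 2)
        assert mean_methylation(sites, "pooled") == F(10, 12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_methylation([])

    def test_unknown_mode_rejected(self, toy_sites):
        with pytest.raises(ValueError):
            mean_methylation(toy_sites, mode="median")


class TestBinomialPmf:
    @pytest.mark.parametrize(
        "t,n,p,expected",
        [(2, 1, 0.5, F(1, 2)), (4, 2, 0.5, F(3, 8)), (3, 0, 0, F(1))],
    )
    def test_examples(self, t, n, p, expected):
        assert binomial_pmf(t, n, p) == expected

    def test_degenerate_p_one(self):
        assert binomial_pmf(3, 3, 1) == 1
        assert binomial_pmf(3, 2, 1) == 0

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            binomial_pmf(3, 4, 0.5)

    @given(
        t=st.integers(1, 20),
        p=st.fractions(min_value=0, max_value=1, max_denominator=20),
    )
    def test_sums_to_one_exactly(self, t, p):
        assert sum(binomial_pmf(t, n, p) for n in range(t + 1)) == 1


class TestRandomDistribution:
    def test_toy_profile(self):
        dist = random_distribution(DepthProfile({2: 2, 4: 1}), F(1, 2))
        assert dist.mass == TOY_RRAN

    def test_degenerate_p_zero(self):
        dist = random_distribution(DepthProfile({2: 100}), 0)
        assert dist.mass == {F(0): F(1)}

    def test_single_depth_symmetry_at_half(self):
        dist = random_distribution(DepthProfile({7: 3}), F(1, 2))
        for beta, mass in dist.mass.items():
            assert dist[1 - beta] == mass

    @given(
        depths=st.dictionaries(
            st.integers(1, 15), st.integers(1, 10), min_size=1, max_size=5
        ),
        p=st.fractions(min_value=0, max_value=1, max_denominator=10),
    )
    @settings(max_examples=50)
    def test_mass_one_and_mean_p_exact(self, depths, p):
        dist = random_distribution(DepthProfile(depths), p)
        assert dist.total() == 1
        assert dist.mean() == p

    def test_endpoint_mass_decreases_with_depth(self):
        # single-depth null mass at 0 is (1-p)^T, strictly decreasing in T
        p = F(3, 10)
        masses = [
            random_distribution(DepthProfile({t: 1}), p)[F(0)]
            for t in range(1, 12)
        ]
        for t, m in enumerate(masses, start=1):
            assert m == (1 - p) ** t
        assert all(a > b for a, b in zip(masses, masses[1:]))


class TestRestrictToDepth:
    def test_basic(self, toy_sites):
        sub = restrict_to_depth(toy_sites, 2)
        assert [(s.depth, s.meth_count) for s in sub] == [(2, 2), (2, 0)]

    def test_empty_result(self, toy_sites):
        assert restrict_to_depth(toy_sites, 16) == []

    def test_then_observed(self):
        sub = restrict_to_depth(sites_of([(4, 1), (4, 3), (2, 1)]), 4)
        dist = observed_distribution(sub)
        assert dist.mass == {F(1, 4): F(1, 2), F(3, 4): F(1, 2)}


class TestSampleRandomMethylome:
    def test_close_to_analytic(self):
        profile = DepthProfile({2: 1000})
        dist = sample_random_methylome(profile, 0.5, draws=1, seed=7)
        for beta, expected in [(F(0), 0.25), (F(1, 2), 0.5), (F(1), 0.25)]:
            se = (expected * (1 - expected) / 1000) ** 0.5
            assert abs(float(dist[beta]) - expected) < 3 * se

    def test_deterministic(self):
        profile = DepthProfile({3: 50, 5: 20})
        a = sample_random_methylome(profile, 0.3, draws=10, seed=11)
        b = sample_random_methylome(profile, 0.3, draws=10, seed=11)
        assert a.mass == b.mass

    def test_degenerate_p_one(self):
        dist = sample_random_methylome(DepthProfile({4: 10}), 1.0, draws=5, seed=0)
        assert dist.mass == {F(1): 1.0}


class TestBetaDistributionValidation:
    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            BetaDistribution({F(0): F(1, 2)}, 1)

    def test_rejects_out_of_range_support(self):
        with pytest.raises(ValueError):
            BetaDistribution({F(3, 2): F(1)}, 1)

    def test_rejects_negative_mass(self):
        with pytest.raises(ValueError):
            BetaDistribution({F(0): F(3, 2), F(1): F(-1, 2)}, 1)
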