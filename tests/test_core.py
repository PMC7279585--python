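"""Core decomposition algebra: examples, allocation, and invariants."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agedecomp import (
    AgeSchedule,
    Attribution,
    PartitionError,
    ValidationError,
    attribute,
    decompose_terms,
    ordering_oracle,
    relative_contribution,
)
from conftest import random_schedule_pair

TWO = ("0-4", "5-9")


def sched(N, s, m, labels=TWO):
    return AgeSchedule(labels=labels, N=N, s=np.asarray(s), m=np.asarray(m))


class TestDecomposeTerms:
    def test_identical_schedules_give_all_zero_terms(self):
        g = sched(100, (0.5, 0.5), (0.1, 0.3))
        t = decompose_terms(g, g)
        assert (t.Mp, t.Ma, t.Mm, t.Ipa, t.Ipm, t.Iam, t.Ipam) == (0,) * 7

    def test_growth_only_change_is_pure_main_effect(self):
        g1 = sched(100, (0.5, 0.5), (0.1, 0.3))
        g2 = sched(200, (0.5, 0.5), (0.1, 0.3))
        t = decompose_terms(g1, g2)
        assert t.Mp == pytest.approx(20.0)
        assert (t.Ma, t.Mm, t.Ipa, t.Ipm, t.Iam, t.Ipam) == (0,) * 6

    def test_frozen_hand_expansion(self):
        # expected values computed independently term by term from the
        # finite-difference formulas anchored on the baseline schedule
        g1 = sched(1000, (0.8, 0.2), (0.01, 0.1))
        g2 = sched(1200, (0.7, 0.3), (0.008, 0.09))
        t = decompose_terms(g1, g2)
        assert t.Mp == pytest.approx(5.6)
        assert t.Ma == pytest.approx(9.0)
        assert t.Mm == pytest.approx(-3.6)
        assert t.Ipa == pytest.approx(1.8)
        assert t.Ipm == pytest.approx(-0.72)
        assert t.Iam == pytest.approx(-0.8)
        assert t.Ipam == pytest.approx(-0.16)
        assert t.total == pytest.approx(g2.deaths - g1.deaths, rel=1e-12)
        assert g2.deaths - g1.deaths == pytest.approx(11.12)

    def test_mismatched_partitions_rejected(self):
        g1 = sched(100, (0.5, 0.5), (0.1, 0.3))
        g2 = sched(100, (0.5, 0.5), (0.1, 0.3), labels=("0-4", "10-14"))
        with pytest.raises(PartitionError):
            decompose_terms(g1, g2)


class TestAttribute:
    def test_zero_terms_give_zero_attribution(self):
        g = sched(100, (0.5, 0.5), (0.1, 0.3))
        a = attribute(decompose_terms(g, g))
        assert (a.A, a.P, a.M) == (0.0, 0.0, 0.0)

    def test_pure_growth_goes_entirely_to_p(self):
        g1 = sched(100, (0.5, 0.5), (0.1, 0.3))
        g2 = sched(200, (0.5, 0.5), (0.1, 0.3))
        a = attribute(decompose_terms(g1, g2))
        assert (a.A, a.P, a.M) == (0.0, pytest.approx(20.0), 0.0)

    def test_frozen_hand_allocation(self):
        # Ma + Ipa/2 + Iam/2 + Ipam/3 etc. on the frozen example above
        g1 = sched(1000, (0.8, 0.2), (0.01, 0.1))
        g2 = sched(1200, (0.7, 0.3), (0.008, 0.09))
        a = attribute(decompose_terms(g1, g2))
        assert a.A == pytest.approx(9.0 + 0.9 - 0.4 - 0.16 / 3)
        assert a.P == pytest.approx(5.6 + 0.9 - 0.36 - 0.16 / 3)
        assert a.M == pytest.approx(-3.6 - 0.36 - 0.4 - 0.16 / 3)
        assert a.total == pytest.approx(11.12, rel=1e-12)


class TestRelativeContribution:
    def test_published_positive_cell(self):
        # 1.735e6 ageing-attributed deaths on a 24.9e6 baseline -> 7.0%
        a = relative_contribution(
            Attribution(A=1.735e6, P=0, M=0, baseline_deaths=24.9e6)
        )
        assert round(a.rel_A, 1) == 7.0

    def test_published_negative_cell(self):
        a = relative_contribution(
            Attribution(A=-3.90e5, P=0, M=0, baseline_deaths=24.9e6)
        )
        assert round(a.rel_A, 1) == -1.6

    def test_zero_attribution_is_zero_percent(self):
        a = relative_contribution(Attribution(A=0, P=1, M=-1, baseline_deaths=5.0))
        assert a.rel_A == 0.0

    def test_override_denominator(self):
        a = relative_contribution(
            Attribution(A=5.0, P=0, M=0, baseline_deaths=10.0), baseline_deaths=100.0
        )
        assert a.rel_A == pytest.approx(5.0)

    def test_nonpositive_baseline_flags_undefined(self):
        a = relative_contribution(Attribution(A=5.0, P=0, M=0, baseline_deaths=0.0))
        assert not a.relative_defined
        assert a.rel_A is None and a.A == 5.0


class TestOrderingOracle:
    def test_trivial_cases(self):
        g = sched(100, (0.5, 0.5), (0.1, 0.3))
        o = ordering_oracle(g, g)
        assert (o.A, o.P, o.M) == (0.0, 0.0, 0.0)
        g2 = sched(200, (0.5, 0.5), (0.1, 0.3))
        o = ordering_oracle(g, g2)
        assert (o.A, o.P, o.M) == (0.0, pytest.approx(20.0), 0.0)

    def test_matches_weighted_allocation_on_random_pairs(self, pair_factory):
        for _ in range(200):
            g1, g2 = pair_factory()
            a = attribute(decompose_terms(g1, g2))
            o = ordering_oracle(g1, g2)
            scale = max(abs(g1.deaths), abs(g2.deaths), 1.0)
            assert abs(a.A - o.A) <= 1e-9 * scale
            assert abs(a.P - o.P) <= 1e-9 * scale
            assert abs(a.M - o.M) <= 1e-9 * scale


class TestInvariants:
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_additivity_and_antisymmetry(self, seed):
        g1, g2 = random_schedule_pair(np.random.default_rng(seed))
        fwd = attribute(decompose_terms(g1, g2))
        rev = attribute(decompose_terms(g2, g1))
        scale = max(abs(g1.deaths), abs(g2.deaths), 1.0)
        assert abs(fwd.total - (g2.deaths - g1.deaths)) <= 1e-6 * scale
        for x, y in ((fwd.A, rev.A), (fwd.P, rev.P), (fwd.M, rev.M)):
            assert abs(x + y) <= 1e-9 * scale

    def test_null_factors_are_exact_zeros(self, rng):
        labels = tuple(f"{5 * i}-{5 * i + 4}" for i in range(4))
        s = rng.dirichlet(np.ones(4))
        s2 = rng.dirichlet(np.ones(4))
        m = rng.uniform(0, 0.4, 4)
        m2 = rng.uniform(0, 0.4, 4)
        same_s = attribute(
            decompose_terms(
                AgeSchedule(labels, 1e5, s, m), AgeSchedule(labels, 2e5, s, m2)
            )
        )
        assert same_s.A == 0.0
        same_m = attribute(
            decompose_terms(
                AgeSchedule(labels, 1e5, s, m), AgeSchedule(labels, 2e5, s2, m)
            )
        )
        assert same_m.M == 0.0
        same_n = attribute(
            decompose_terms(
                AgeSchedule(labels, 1e5, s, m), AgeSchedule(labels, 1e5, s2, m2)
            )
        )
        assert same_n.P == 0.0

    def test_scale_equivariance(self, pair_factory):
        g1, g2 = pair_factory()
        base = attribute(decompose_terms(g1, g2))
        c = 3.5
        g1c = AgeSchedule(g1.labels, g1.N * c, g1.s, g1.m)
        g2c = AgeSchedule(g2.labels, g2.N * c, g2.s, g2.m)
        scaled = attribute(decompose_terms(g1c, g2c))
        assert scaled.A == pytest.approx(c * base.A, rel=1e-12)
        assert scaled.P == pytest.approx(c * base.P, rel=1e-12)
        assert scaled.M == pytest.approx(c * base.M, rel=1e-12)


class TestAgeSchedule:
    def test_proportions_renormalized_within_tolerance(self):
        g = sched(100, (0.5 + 4e-7, 0.5), (0.1, 0.3))
        assert g.s.sum() == pytest.approx(1.0, abs=1e-15)

    def test_proportions_rejected_beyond_tolerance(self):
        with pytest.raises(ValidationError):
            sched(100, (0.52, 0.5), (0.1, 0.3))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=-5, s=(0.5, 0.5), m=(0.1, 0.3)),
            dict(N=np.inf, s=(0.5, 0.5), m=(0.1, 0.3)),
            dict(N=100, s=(0.5, 0.5), m=(0.1, -0.3)),
            dict(N=100, s=(-0.5, 1.5), m=(0.1, 0.3)),
            dict(N=100, s=(0.5, 0.5), m=(np.nan, 0.3)),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            sched(**kwargs)

    def test_unordered_age_labels_rejected(self):
        with pytest.raises(ValidationError):
            sched(100, (0.5, 0.5), (0.1, 0.3), labels=("5-9", "0-4"))

    def test_from_counts_recomputes_rates_and_proportions(self):
        g = AgeSchedule.from_counts(TWO, [800.0, 200.0], [8.0, 20.0])
        assert g.N == 1000
        assert g.s == pytest.approx([0.8, 0.2])
        assert g.m == pytest.approx([0.01, 0.1])
        assert g.deaths == pytest.approx(28.0)

    def test_from_counts_zero_population_group_warns_and_zeroes_rate(self):
        with pytest.warns(UserWarning, match="zero population"):
            g = AgeSchedule.from_counts(TWO, [1000.0, 0.0], [10.0, 0.0])
        assert g.m[1] == 0.0

    def test_from_counts_deaths_without_population_rejected(self):
        with pytest.raises(ValidationError):
            AgeSchedule.from_counts(TWO, [1000.0, 0.0], [10.0, 1.0])
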