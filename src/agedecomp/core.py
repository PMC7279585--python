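"""Three-factor decomposition of change in total death counts.

The difference in total deaths between two age-structured populations is
split into contributions of population growth (change in total size ``N``),
population ageing (change in the age-composition vector ``s``), and change
in the age-specific mortality schedule ``m``.  Total deaths are the
multilinear function

    D(N, s, m) = N * sum_i s_i * m_i

so the difference ``D2 - D1`` expands exactly into three main effects and
four interaction terms, all anchored on the baseline population:

    Mp   = (N2 - N1) * sum_i s_i1 m_i1
    Ma   = N1 * sum_i (s_i2 - s_i1) m_i1
    Mm   = N1 * sum_i s_i1 (m_i2 - m_i1)
    Ipa  = (N2 - N1) * sum_i (s_i2 - s_i1) m_i1
    Ipm  = (N2 - N1) * sum_i s_i1 (m_i2 - m_i1)
    Iam  = N1 * sum_i (s_i2 - s_i1)(m_i2 - m_i1)
    Ipam = (N2 - N1) * sum_i (s_i2 - s_i1)(m_i2 - m_i1)

Allocation gives each factor its main effect plus half of each two-way
interaction it takes part in and a third of the three-way interaction:

    A = Ma + Ipa/2 + Iam/2 + Ipam/3      (ageing)
    P = Mp + Ipa/2 + Ipm/2 + Ipam/3      (growth)
    M = Mm + Ipm/2 + Iam/2 + Ipam/3      (mortality change)

These are the Shapley values of the three factors for the multilinear
``D``, hence identical to the average over all six orders of sequential
one-factor-at-a-time decomposition and antisymmetric under swapping the
two populations.  :func:`ordering_oracle` computes the order average by
brute force and is kept as an independent check of that algebra.

All counts are in persons; rates are deaths per person per year.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ValidationError",
    "PartitionError",
    "AgeSchedule",
    "DecompositionTerms",
    "Attribution",
    "decompose_terms",
    "attribute",
    "relative_contribution",
    "ordering_oracle",
]

from .ages import age_lower_bound


class ValidationError(ValueError):
    """Raised for non-finite, negative, or inconsistent demographic inputs."""


class PartitionError(ValueError):
    """Raised when two schedules or tables do not share an age partition."""


_S_SUM_TOL = 1e-6  # tolerated drift of sum(s) from 1 before rejection


@dataclass(frozen=True)
class AgeSchedule:
    """Demographic state of one population: size, composition, mortality.

    Parameters
    ----------
    labels
        Ordered age-group identifiers (youngest first).
    N
        Total population size in persons, > 0.
    s
        Age-composition proportions, one per group; must sum to 1 within
        1e-6 (renormalized exactly on construction).
    m
        Age-specific mortality rates (deaths per person per year), >= 0.
    """

    labels: tuple
    N: float
    s: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        s = np.asarray(self.s, dtype=float)
        m = np.asarray(self.m, dtype=float)
        if not (len(labels) == s.size == m.size) or s.ndim != 1 or m.ndim != 1:
            raise ValidationError(
                f"labels ({len(labels)}), s ({s.size}) and m ({m.size}) must "
                "be one-dimensional and of equal length"
            )
        if len(labels) == 0:
            raise ValidationError("at least one age group is required")
        if len(set(labels)) != len(labels):
            raise ValidationError("age-group labels must be unique")
        bounds = [age_lower_bound(x) for x in labels]
        if all(b is not None for b in bounds) and any(
            b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])
        ):
            raise ValidationError(f"age groups not ordered youngest-first: {labels}")
        if not math.isfinite(self.N) or self.N <= 0:
            raise ValidationError(f"population size must be finite and > 0, got {self.N}")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValidationError("composition proportions must be finite and >= 0")
        if abs(s.sum() - 1.0) > _S_SUM_TOL:
            raise ValidationError(
                f"composition proportions sum to {s.sum():.8f}, not 1"
            )
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValidationError("mortality rates must be finite and >= 0")
        s = s / s.sum()
        s.flags.writeable = False
        m.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "N", float(self.N))
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "m", m)

    @classmethod
    def from_counts(cls, labels, population, deaths) -> "AgeSchedule":
        """Build a schedule from per-group population and death counts.

        Proportions and rates are recomputed from the counts; groups with
        zero population get rate 0 (with a warning) and must have zero
        deaths.
        """
        pop = np.asarray(population, dtype=float)
        dth = np.asarray(deaths, dtype=float)
        if pop.shape != dth.shape:
            raise ValidationError("population and deaths must have equal length")
        if not np.all(np.isfinite(pop)) or np.any(pop < 0):
            raise ValidationError("population counts must be finite and >= 0")
        if not np.all(np.isfinite(dth)) or np.any(dth < 0):
            raise ValidationError("death counts must be finite and >= 0")
        if np.any((pop == 0) & (dth > 0)):
            raise ValidationError("deaths recorded in an age group with zero population")
        total = pop.sum()
        if total <= 0:
            raise ValidationError("total population must be > 0")
        if np.any(pop == 0):
            warnings.warn(
                "age group(s) with zero population: mortality rate set to 0",
                stacklevel=2,
            )
        m = np.divide(dth, pop, out=np.zeros_like(dth), where=pop > 0)
        return cls(labels=tuple(labels), N=total, s=pop / total, m=m)

    @property
    def deaths(self) -> float:
        """Implied total deaths D = N * sum_i s_i m_i."""
        return float(self.N * (self.s @ self.m))


@dataclass(frozen=True)
class DecompositionTerms:
    """Seven raw terms of one baseline -> comparison decomposition (persons)."""

    Mp: float
    Ma: float
    Mm: float
    Ipa: float
    Ipm: float
    Iam: float
    Ipam: float
    baseline_deaths: float
    comparison_deaths: float

    @property
    def total(self) -> float:
        """Sum of all seven terms; equals ``comparison - baseline`` deaths."""
        return self.Mp + self.Ma + self.Mm + self.Ipa + self.Ipm + self.Iam + self.Ipam


@dataclass(frozen=True)
class Attribution:
    """Allocated death-count contributions for one comparison.

    ``A`` (ageing), ``P`` (growth) and ``M`` (mortality change) are in
    persons and sum to the total change in deaths.  ``rel_*`` are signed
    percentages of baseline deaths, present only when the baseline is
    positive (``relative_defined``).
    """

    A: float
    P: float
    M: float
    baseline_deaths: float
    rel_A: float | None = None
    rel_P: float | None = None
    rel_M: float | None = None

    @property
    def relative_defined(self) -> bool:
        return self.rel_A is not None

    @property
    def total(self) -> float:
        return self.A + self.P + self.M


def _check_pair(g1: AgeSchedule, g2: AgeSchedule) -> None:
    if g1.labels != g2.labels:
        raise PartitionError(
            f"age partitions differ: {g1.labels} vs {g2.labels}"
        )


def decompose_terms(g1: AgeSchedule, g2: AgeSchedule) -> DecompositionTerms:
    """Main effects and interactions of the change in deaths from g1 to g2.

    Both schedules must share an identical age partition.  The returned
    seven terms sum exactly (to float precision) to ``g2.deaths - g1.deaths``.
    """
    _check_pair(g1, g2)
    dN = g2.N - g1.N
    ds = g2.s - g1.s
    dm = g2.m - g1.m
    return DecompositionTerms(
        Mp=float(dN * (g1.s @ g1.m)),
        Ma=float(g1.N * (ds @ g1.m)),
        Mm=float(g1.N * (g1.s @ dm)),
        Ipa=float(dN * (ds @ g1.m)),
        Ipm=float(dN * (g1.s @ dm)),
        Iam=float(g1.N * (ds @ dm)),
        Ipam=float(dN * (ds @ dm)),
        baseline_deaths=g1.deaths,
        comparison_deaths=g2.deaths,
    )


def attribute(terms: DecompositionTerms) -> Attribution:
    """Allocate interactions to the three factors (half/half/third weights)."""
    A = terms.Ma + terms.Ipa / 2.0 + terms.Iam / 2.0 + terms.Ipam / 3.0
    P = terms.Mp + terms.Ipa / 2.0 + terms.Ipm / 2.0 + terms.Ipam / 3.0
    M = terms.Mm + terms.Ipm / 2.0 + terms.Iam / 2.0 + terms.Ipam / 3.0
    return Attribution(A=A, P=P, M=M, baseline_deaths=terms.baseline_deaths)


def relative_contribution(attr: Attribution, baseline_deaths: float | None = None) -> Attribution:
    """Fill relative contributions: attributed deaths / baseline deaths x 100.

    The denominator is the total number of deaths in the baseline year
    (optionally overriding the one carried by ``attr``, e.g. to express a
    cause-specific attribution against the all-cause total).  Signs are
    preserved.  A non-positive denominator leaves the relative fields unset
    (``relative_defined`` False).
    """
    base = attr.baseline_deaths if baseline_deaths is None else float(baseline_deaths)
    if not math.isfinite(base) or base <= 0:
        return replace(attr, baseline_deaths=base, rel_A=None, rel_P=None, rel_M=None)
    return replace(
        attr,
        baseline_deaths=base,
        rel_A=attr.A / base * 100.0,
        rel_P=attr.P / base * 100.0,
        rel_M=attr.M / base * 100.0,
    )


def ordering_oracle(g1: AgeSchedule, g2: AgeSchedule) -> Attribution:
    """Order-averaged sequential decomposition (brute force).

    For each of the six orderings of the factors (size, composition,
    mortality), moves one factor at a time from its baseline to its
    comparison value and records the induced change in deaths; returns the
    per-factor average over orderings.  Agrees with
    ``attribute(decompose_terms(g1, g2))`` to floating-point precision and
    serves as an independent check of the allocation weights.
    """
    _check_pair(g1, g2)
    base = {"p": g1.N, "a": g1.s, "m": g1.m}
    comp = {"p": g2.N, "a": g2.s, "m": g2.m}
    totals = {"p": 0.0, "a": 0.0, "m": 0.0}
    for order in itertools.permutations("pam"):
        state = dict(base)
        d_prev = state["p"] * (state["a"] @ state["m"])
        for f in order:
            state[f] = comp[f]
            d = state["p"] * (state["a"] @ state["m"])
            totals[f] += d - d_prev
            d_prev = d
    return Attribution(
        A=totals["a"] / 6.0,
        P=totals["p"] / 6.0,
        M=totals["m"] / 6.0,
        baseline_deaths=g1.deaths,
    )
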