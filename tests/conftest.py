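import numpy as np
import pandas as pd
import pytest

from agedecomp import AgeSchedule


def random_schedule(rng, labels):
    n = len(labels)
    return AgeSchedule(
        labels=labels,
        N=float(rng.uniform(1e3, 1e8)),
        s=rng.dirichlet(np.ones(n)),
        m=rng.uniform(0.0, 0.5, n),
    )


def random_schedule_pair(rng, n_max=8):
    n = int(rng.integers(2, n_max + 1))
    labels = tuple(f"{5 * i}-{5 * i + 4}" for i in range(n))
    return random_schedule(rng, labels), random_schedule(rng, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def pair_factory(rng):
    return lambda: random_schedule_pair(rng)


def toy_panel(n_locations=1, sexes=("male",), causes=("all",), years=(1990, 2017),
              ages=("<30", "30-64", ">=65")):
    """Small hand-built panel with an ageing shift and mortality decline."""
    rows = []
    base_s = np.array([0.55, 0.35, 0.10])
    m0 = np.array([0.002, 0.006, 0.05])
    for i in range(n_locations):
        for sx in sexes:
            for year in years:
                t = year - years[0]
                n_tot = 1e6 * (1 + 0.4 * i) * 1.01 ** t
                s = base_s + t * np.array([-0.002, 0.001, 0.001])
                s = s / s.sum()
                for k, cause in enumerate(causes):
                    w = (k + 1) / sum(range(1, len(causes) + 1))
                    pop = n_tot * s
                    deaths = pop * m0 * 0.99 ** t * w
                    for a, p, d in zip(ages, pop, deaths):
                        rows.append(
                            {
                                "location": f"loc{i}",
                                "income_category": ["high", "low"][i % 2],
                                "sex": sx,
                                "cause": cause,
                                "year": year,
                                "age_group": a,
                                "population": p,
                                "deaths": d,
                            }
                        )
    return pd.DataFrame(rows)
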