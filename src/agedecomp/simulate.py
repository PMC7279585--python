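"""Synthetic multi-stratum demographic panels with known dynamics.

Generates tidy (location, sex, cause, year, age-group) panels of population
and death counts whose ground-truth dynamics are controlled by three dials
matching the three factors of the decomposition:

* ``growth_rate`` — multiplicative per-year growth of total population;
* ``ageing_shift`` — per-year increment (in years) of the mean age of the
  composition, realised by exponential tilting of a fixed baseline
  composition toward older groups;
* ``mortality_trend`` — multiplicative per-year change of every
  age-specific rate (< 1 for secular mortality decline).

With noise disabled (the default) deaths are exact expectations
``population x rate``, so single-factor scenarios have exactly one nonzero
attributed component downstream.  With ``noise=True`` rates get small
seeded lognormal jitter and deaths are Poisson draws.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ages import age_midpoint
from .core import ValidationError

__all__ = [
    "DEFAULT_AGE_GROUPS",
    "INCOME_CATEGORIES",
    "PANEL_COLUMNS",
    "MortalityCurve",
    "ScenarioConfig",
    "generate_panel",
    "validate_panel",
]

#: The study's 20 five-year age groups, youngest first.
DEFAULT_AGE_GROUPS: tuple = ("<5",) + tuple(
    f"{lo}-{lo + 4}" for lo in range(5, 95, 5)
) + ("95+",)

#: World Bank style income categories used for round-robin assignment.
INCOME_CATEGORIES: tuple = ("high", "upper-middle", "lower-middle", "low")

#: Canonical column order of a tidy stratum panel.
PANEL_COLUMNS = [
    "location",
    "income_category",
    "sex",
    "cause",
    "year",
    "age_group",
    "population",
    "deaths",
]

# decay (per year of age) of the baseline composition; gives a young,
# roughly stable-population age pyramid with mean age ~ 30 years
_COMPOSITION_DECAY = 0.03


@dataclass(frozen=True)
class MortalityCurve:
    """Baseline age-specific mortality: Gompertz senescence plus a
    childhood component decaying with age.

    rate(x) = senescent_scale * exp(senescent_slope * x)
              + childhood_scale * exp(-x / childhood_decay)

    Defaults give ~7 per 1000 under age 5, a minimum near age 10, and
    ~0.3 per person-year at 95+ — the familiar J-shape of human mortality.
    """

    senescent_scale: float = 5e-5
    senescent_slope: float = 0.09
    childhood_scale: float = 0.01
    childhood_decay: float = 5.0

    def rate(self, age_years) -> np.ndarray:
        x = np.asarray(age_years, dtype=float)
        return (
            self.senescent_scale * np.exp(self.senescent_slope * x)
            + self.childhood_scale * np.exp(-x / self.childhood_decay)
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study scenario (see module docstring)."""

    n_locations: int = 4
    years: tuple = (1990, 2017)
    sexes: tuple = ("male", "female")
    causes: tuple = ("circulatory", "neoplasms", "infectious")
    age_partition: tuple = DEFAULT_AGE_GROUPS
    growth_rate: float = 1.015
    ageing_shift: float = 0.15
    mortality_trend: float = 0.985
    base_schedule: MortalityCurve = field(default_factory=MortalityCurve)
    base_population: float = 5e6
    noise: bool = False
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "years", (int(self.years[0]), int(self.years[1])))
        object.__setattr__(self, "sexes", tuple(self.sexes))
        object.__setattr__(self, "causes", tuple(self.causes))
        object.__setattr__(self, "age_partition", tuple(self.age_partition))
        if isinstance(self.base_schedule, dict):
            object.__setattr__(self, "base_schedule", MortalityCurve(**self.base_schedule))
        self.validate()

    def validate(self) -> None:
        if self.n_locations < 1:
            raise ValidationError("n_locations must be >= 1")
        if self.years[1] < self.years[0]:
            raise ValidationError(f"invalid year range {self.years}")
        if not self.sexes or not self.causes or not self.age_partition:
            raise ValidationError("sexes, causes and age_partition must be nonempty")
        if not self.growth_rate > 0:
            raise ValidationError("growth_rate must be > 0")
        if not self.mortality_trend > 0:
            raise ValidationError("mortality_trend must be > 0")
        if self.base_population <= 0:
            raise ValidationError("base_population must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        mids = [age_midpoint(a) for a in self.age_partition]
        if any(m is None for m in mids):
            raise ValidationError(f"unparseable age-group labels in {self.age_partition}")

    @property
    def locations(self) -> list:
        return [f"location_{i:02d}" for i in range(self.n_locations)]

    def income_map(self) -> pd.DataFrame:
        """Round-robin location -> income-category mapping table."""
        return pd.DataFrame(
            {
                "location": self.locations,
                "income_category": [
                    INCOME_CATEGORIES[i % len(INCOME_CATEGORIES)]
                    for i in range(self.n_locations)
                ],
            }
        )

    # -- flat-file round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["sexes"] = list(self.sexes)
        d["causes"] = list(self.causes)
        d["age_partition"] = list(self.age_partition)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown scenario config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def _composition(cfg: ScenarioConfig, t: int) -> np.ndarray:
    """Age composition at elapsed time t, tilted toward older ages.

    The tilt parameter is mapped from the requested mean-age increment by
    the first-order relation d(mean age)/d(tilt) = Var(age), so the mean
    age rises by approximately ``ageing_shift`` years per calendar year.
    """
    mids = np.array([age_midpoint(a) for a in cfg.age_partition])
    s0 = np.exp(-_COMPOSITION_DECAY * mids)
    s0 /= s0.sum()
    if cfg.ageing_shift == 0 or t == 0:
        return s0
    mean0 = s0 @ mids
    var0 = s0 @ (mids - mean0) ** 2
    theta = cfg.ageing_shift * t / var0
    s = s0 * np.exp(theta * mids)
    return s / s.sum()


def generate_panel(cfg: ScenarioConfig) -> pd.DataFrame:
    """Generate a tidy stratum panel for the scenario.

    Deterministic given ``cfg.seed``.  Returns a DataFrame with columns
    ``PANEL_COLUMNS``; population is shared across causes within a
    (location, sex, year, age group) cell and deaths are split across
    causes by fixed weights.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mids = np.array([age_midpoint(a) for a in cfg.age_partition])
    base_m = cfg.base_schedule.rate(mids)
    n_sex = len(cfg.sexes)
    # deterministic level differences between locations and sexes
    loc_size = {loc: cfg.base_population * (1.0 + 0.5 * i) for i, loc in enumerate(cfg.locations)}
    if n_sex > 1:
        sex_mult = {sx: 1.1 - 0.2 * j / (n_sex - 1) for j, sx in enumerate(cfg.sexes)}
    else:
        sex_mult = {cfg.sexes[0]: 1.0}
    cause_w = np.arange(1, len(cfg.causes) + 1, dtype=float)
    cause_w /= cause_w.sum()
    income = dict(zip(cfg.income_map()["location"], cfg.income_map()["income_category"]))

    years = range(cfg.years[0], cfg.years[1] + 1)
    frames = []
    for year in years:
        t = year - cfg.years[0]
        s_t = _composition(cfg, t)
        trend = cfg.mortality_trend ** t
        for loc in cfg.locations:
            n_tot = loc_size[loc] * cfg.growth_rate ** t
            for sx in cfg.sexes:
                pop = n_tot / n_sex * s_t
                m = np.clip(base_m * sex_mult[sx] * trend, 0.0, 1.0)
                if cfg.noise and cfg.noise_sd > 0:
                    m = np.clip(
                        m * rng.lognormal(0.0, cfg.noise_sd, size=m.size), 0.0, 1.0
                    )
                for cause, w in zip(cfg.causes, cause_w):
                    lam = pop * m * w
                    if cfg.noise:
                        deaths = np.minimum(
                            rng.poisson(lam).astype(float), np.floor(pop)
                        )
                    else:
                        deaths = lam
                    frames.append(
                        pd.DataFrame(
                            {
                                "location": loc,
                                "income_category": income[loc],
                                "sex": sx,
                                "cause": cause,
                                "year": year,
                                "age_group": list(cfg.age_partition),
                                "population": pop,
                                "deaths": deaths,
                            }
                        )
                    )
    panel = pd.concat(frames, ignore_index=True)[PANEL_COLUMNS]
    validate_panel(panel)
    return panel


def validate_panel(panel: pd.DataFrame) -> None:
    """Check the tidy-panel contract (columns, non-negativity, completeness)."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValidationError(f"panel missing columns: {missing}")
    if len(panel) == 0:
        raise ValidationError("panel is empty")
    if panel[["population", "deaths"]].lt(0).any().any():
        raise ValidationError("negative population or death counts")
    bad = panel["deaths"] > panel["population"] * (1 + 1e-9)
    if bad.any():
        rows = panel.loc[bad].head(3).to_dict("records")
        raise ValidationError(f"deaths exceed population, e.g. {rows}")
    keys = ["location", "sex", "cause", "year", "age_group"]
    if panel.duplicated(keys).any():
        raise ValidationError("duplicate stratum keys in panel")
    n_expected = 1
    for k in keys:
        n_expected *= panel[k].nunique()
    if len(panel) != n_expected:
        raise ValidationError(
            f"panel is not a complete key crossing: {len(panel)} rows, "
            f"expected {n_expected}"
        )
    years = np.sort(panel["year"].unique())
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        # sparse panels (e.g. endpoint-only comparisons) are allowed but flagged
        warnings.warn(f"panel years are not contiguous: {years.tolist()}", stacklevel=2)
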