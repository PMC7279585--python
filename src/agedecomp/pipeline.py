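"""Stratified analysis over a tidy demographic panel.

Runs the study design on a StratumPanel (location x sex x cause x year x
age-group counts): decompose every stratum's death change from a fixed
baseline year into growth / ageing / mortality-change contributions, then
derive the summary products — cause rankings by ageing-attributed deaths,
counts of locations per attributed-proportion bin, and the
mortality-change vs ageing ratio R with its classification.

Per-cause decompositions use the cause-specific mortality schedule with
the shared all-cause population size and age composition, so cause-level
attributions add up exactly to the all-cause attribution.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .ages import order_age_groups
from .core import (
    AgeSchedule,
    PartitionError,
    ValidationError,
    attribute,
    decompose_terms,
    relative_contribution,
)
from .simulate import PANEL_COLUMNS, validate_panel

__all__ = [
    "ingest",
    "aggregate",
    "decompose_series",
    "cause_ranking",
    "country_bins",
    "mortality_vs_ageing_ratio",
    "panel_summary",
    "BIN_LABELS",
    "SERIES_COLUMNS",
]

logger = logging.getLogger(__name__)

STRATUM_KEYS = ["location", "income_category", "sex", "cause"]
SERIES_COLUMNS = STRATUM_KEYS + [
    "year",
    "baseline_deaths",
    "deaths",
    "delta_deaths",
    "A",
    "P",
    "M",
    "rel_A",
    "rel_P",
    "rel_M",
]

#: Attributed-proportion bins (integer percent, inclusive bounds).
BIN_LABELS = ["1-4", "5-9", "10-14", "15-19", ">=20"]
_BIN_EDGES = [(1, 4), (5, 9), (10, 14), (15, 19), (20, np.inf)]


def ingest(deaths_table, population_table, income_map=None, scale: float = 1.0) -> pd.DataFrame:
    """Join deaths, population, and income-mapping CSVs into a StratumPanel.

    Parameters
    ----------
    deaths_table
        CSV path with columns location, sex, cause, year, age_group, deaths.
    population_table
        CSV path with columns location, sex, year, age_group, population.
    income_map
        Optional CSV path with columns location, income_category; unmapped
        locations are kept with category ``"unclassified"``.
    scale
        Multiplier applied to both counts (e.g. 1e6 for tables in millions).

    Raises hard errors (with row context) on duplicate keys, age labels
    missing from the population table, or deaths exceeding population.
    """
    deaths = pd.read_csv(deaths_table)
    pop = pd.read_csv(population_table)
    _require(deaths, ["location", "sex", "cause", "year", "age_group", "deaths"], "deaths table")
    _require(pop, ["location", "sex", "year", "age_group", "population"], "population table")

    dkeys = ["location", "sex", "cause", "year", "age_group"]
    pkeys = ["location", "sex", "year", "age_group"]
    for df, keys, name in ((deaths, dkeys, "deaths"), (pop, pkeys, "population")):
        dup = df.duplicated(keys, keep=False)
        if dup.any():
            raise ValidationError(
                f"duplicate keys in {name} table, e.g. "
                f"{df.loc[dup, keys].head(3).to_dict('records')}"
            )

    extra = set(deaths["age_group"].astype(str)) - set(pop["age_group"].astype(str))
    if extra:
        raise PartitionError(
            f"age groups present in deaths but not in population table: {sorted(extra)}"
        )

    panel = deaths.merge(pop, on=pkeys, how="left", validate="many_to_one")
    if panel["population"].isna().any():
        missing = panel.loc[panel["population"].isna(), pkeys].head(3).to_dict("records")
        raise ValidationError(f"deaths rows without matching population, e.g. {missing}")

    panel["deaths"] = panel["deaths"].astype(float) * scale
    panel["population"] = panel["population"].astype(float) * scale

    bad = panel["deaths"] > panel["population"] * (1 + 1e-9)
    if bad.any():
        rows = panel.loc[bad, dkeys + ["deaths", "population"]].head(3).to_dict("records")
        raise ValidationError(f"deaths exceed population, e.g. {rows}")

    if income_map is not None:
        imap = pd.read_csv(income_map)
        _require(imap, ["location", "income_category"], "income map")
        if imap.duplicated("location").any():
            raise ValidationError("duplicate locations in income map")
        panel = panel.merge(imap, on="location", how="left")
        panel["income_category"] = panel["income_category"].fillna("unclassified")
    else:
        panel["income_category"] = "unclassified"

    panel = panel[PANEL_COLUMNS]
    validate_panel(panel)
    return panel


def _require(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} is missing columns {missing}")


def aggregate(panel: pd.DataFrame, by) -> pd.DataFrame:
    """Sum a panel's counts over collapsed stratum keys.

    ``by`` lists the stratum keys to KEEP among location, income_category,
    sex, cause (year and age_group are always kept).  Deaths are summed
    over collapsed keys; population is deduplicated across causes before
    summation so it is never double-counted.  Collapsed keys are labelled
    ``"all"``.  Rates and proportions downstream are recomputed from the
    summed counts, never averaged.
    """
    by = list(by)
    unknown = set(by) - set(STRATUM_KEYS)
    if unknown:
        raise ValidationError(f"unknown aggregation keys: {sorted(unknown)}")
    keep = [k for k in STRATUM_KEYS if k in by]
    if "location" in keep and "income_category" not in keep:
        keep.insert(keep.index("location") + 1, "income_category")

    deaths = panel.groupby(keep + ["year", "age_group"], as_index=False, sort=False)[
        "deaths"
    ].sum()
    pop_src = panel.drop_duplicates(["location", "sex", "year", "age_group"])
    pkeep = [k for k in keep if k != "cause"]
    pop = pop_src.groupby(pkeep + ["year", "age_group"], as_index=False, sort=False)[
        "population"
    ].sum()
    out = deaths.merge(pop, on=pkeep + ["year", "age_group"], how="left")
    if len(out) == 0:
        raise ValidationError("aggregation produced an empty panel")
    for k in STRATUM_KEYS:
        if k not in keep:
            out[k] = "all"
    return out[PANEL_COLUMNS]


def decompose_series(panel: pd.DataFrame, baseline_year: int = 1990) -> pd.DataFrame:
    """Decompose every stratum's death change from the baseline year.

    For each (location, income_category, sex, cause) stratum and every
    year other than the baseline, builds baseline and comparison
    AgeSchedules from the counts and applies the three-factor
    decomposition.  Relative contributions are percentages of the
    stratum's own baseline deaths.  Strata lacking baseline rows are
    skipped with a warning.
    """
    years = np.sort(pd.unique(panel["year"]))
    if baseline_year not in years:
        raise ValidationError(
            f"baseline year {baseline_year} not present in panel (years "
            f"{years.min()}–{years.max()})"
        )
    rows = []
    for key, g in panel.groupby(STRATUM_KEYS, sort=True, observed=True):
        order = order_age_groups(g["age_group"].unique())
        wide_p = g.pivot(index="age_group", columns="year", values="population").reindex(order)
        wide_d = g.pivot(index="age_group", columns="year", values="deaths").reindex(order)
        if baseline_year not in wide_p.columns or wide_p[baseline_year].isna().any():
            warnings.warn(
                f"stratum {key} lacks complete baseline-year rows; skipped",
                stacklevel=2,
            )
            continue
        g1 = AgeSchedule.from_counts(
            order, wide_p[baseline_year].to_numpy(), wide_d[baseline_year].to_numpy()
        )
        for year in wide_p.columns:
            if year == baseline_year or wide_p[year].isna().any():
                continue
            g2 = AgeSchedule.from_counts(
                order, wide_p[year].to_numpy(), wide_d[year].to_numpy()
            )
            attr = relative_contribution(attribute(decompose_terms(g1, g2)))
            rows.append(
                dict(
                    zip(STRATUM_KEYS, key),
                    year=int(year),
                    baseline_deaths=g1.deaths,
                    deaths=g2.deaths,
                    delta_deaths=g2.deaths - g1.deaths,
                    A=attr.A,
                    P=attr.P,
                    M=attr.M,
                    rel_A=attr.rel_A,
                    rel_P=attr.rel_P,
                    rel_M=attr.rel_M,
                )
            )
    if not rows:
        raise ValidationError("no stratum could be decomposed")
    return pd.DataFrame(rows)[SERIES_COLUMNS]


def _filter_year(series: pd.DataFrame, year) -> tuple[pd.DataFrame, int]:
    year = int(series["year"].max()) if year is None else int(year)
    sub = series[series["year"] == year]
    if len(sub) == 0:
        raise ValidationError(f"no series rows at year {year}")
    return sub, year


def cause_ranking(series: pd.DataFrame, sex: str, year=None, k: int = 10) -> pd.DataFrame:
    """Top-k and bottom-k causes by deaths attributed to population ageing.

    Attributed deaths are summed over locations per cause; the attributed
    proportion divides by the sex's ALL-cause baseline deaths (the sum of
    cause-specific baselines), matching the study's denominators.  Ties
    are broken by cause label so the ordering is deterministic.
    """
    sub, year = _filter_year(series, year)
    sub = sub[sub["sex"] == sex]
    if len(sub) == 0:
        raise ValidationError(f"no series rows for sex {sex!r} at year {year}")
    per_cause = (
        sub.groupby("cause", as_index=False)
        .agg(A=("A", "sum"), baseline_deaths=("baseline_deaths", "sum"))
        .sort_values(["A", "cause"], ascending=[False, True], ignore_index=True)
    )
    denom = per_cause["baseline_deaths"].sum()
    per_cause["attributed_pct"] = per_cause["A"] / denom * 100.0
    n = len(per_cause)
    if k > n:
        warnings.warn(f"k={k} exceeds the {n} causes available; truncated", stacklevel=2)
        k = n
    per_cause["rank"] = np.arange(1, n + 1)
    top = per_cause.head(k).assign(direction="increase")
    bottom = per_cause.tail(k).assign(direction="decrease")
    out = pd.concat([top, bottom], ignore_index=True).drop_duplicates("cause")
    out.insert(0, "sex", sex)
    out.insert(1, "year", year)
    return out[
        ["sex", "year", "rank", "direction", "cause", "A", "attributed_pct"]
    ]


def country_bins(series: pd.DataFrame, sex: str, cause: str, year=None) -> pd.DataFrame:
    """Count locations per attributed-proportion bin for one sex and cause.

    The cause-specific attributed proportion per location divides the
    cause's attributed deaths by the location's all-cause baseline deaths,
    is rounded to the nearest integer percent, and binned into 1–4, 5–9,
    10–14, 15–19 and >=20.  Proportions below 1% (including negatives) are
    not counted.
    """
    sub, year = _filter_year(series, year)
    sub = sub[sub["sex"] == sex]
    if len(sub) == 0:
        raise ValidationError(f"no series rows for sex {sex!r} at year {year}")
    denom = sub.groupby("location")["baseline_deaths"].sum()
    focal = sub[sub["cause"] == cause].set_index("location")
    if len(focal) == 0:
        raise ValidationError(f"cause {cause!r} absent from series")
    pct = (focal["A"] / denom.loc[focal.index] * 100.0).to_numpy()
    rounded = np.floor(pct + 0.5)  # round half up, away from the omitted <1% zone
    counts = [
        int(np.sum((rounded >= lo) & (rounded <= hi))) for lo, hi in _BIN_EDGES
    ]
    return pd.DataFrame(
        {
            "sex": sex,
            "cause": cause,
            "year": year,
            "bin": BIN_LABELS,
            "n_locations": counts,
        }
    )


def mortality_vs_ageing_ratio(series: pd.DataFrame, year=None) -> pd.DataFrame:
    """Ratio R = M / A per stratum, with classification.

    Computed only where ageing increased deaths (A > 0); strata with
    A <= 0 are flagged ``excluded``.  Classes: ``R<=-1`` (mortality
    decline outweighed ageing), ``-1<R<=0`` (partial offset), ``R>0``
    (both increased deaths).
    """
    sub, year = _filter_year(series, year)
    out = sub[STRATUM_KEYS + ["year", "A", "M"]].copy()
    a = out["A"].to_numpy(float)
    m = out["M"].to_numpy(float)
    r = np.where(a > 0, m / np.where(a > 0, a, 1.0), np.nan)
    cls = np.select(
        [a <= 0, r <= -1.0, r <= 0.0],
        ["excluded", "R<=-1", "-1<R<=0"],
        default="R>0",
    )
    out["R"] = r
    out["r_class"] = cls
    return out.reset_index(drop=True)


def panel_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Counts and shares by sex and by age group per location and year.

    For each (location, year) and each of population and deaths, reports
    every sex's and every age group's count and its percent of the
    location-year total — the shape of the study's descriptive summary
    table, recomputed from counts.
    """
    rows = []
    for (loc, year), g in panel.groupby(["location", "year"], sort=True):
        pop_cell = g.drop_duplicates(["sex", "age_group"])
        for measure, df, val in (
            ("population", pop_cell, "population"),
            ("deaths", g, "deaths"),
        ):
            for dim in ("sex", "age_group"):
                totals = df.groupby(dim, sort=False)[val].sum()
                if dim == "age_group":
                    totals = totals.reindex(order_age_groups(totals.index))
                grand = totals.sum()
                for grp, n in totals.items():
                    rows.append(
                        {
                            "location": loc,
                            "year": year,
                            "measure": measure,
                            "dimension": dim,
                            "group": grp,
                            "number": n,
                            "percent": n / grand * 100.0 if grand > 0 else np.nan,
                        }
                    )
    return pd.DataFrame(rows)
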