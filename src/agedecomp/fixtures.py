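"""Published summary tables packaged as fixtures.

Two small published tables from the global 1990–2017 mortality-ageing
study are embedded here for worked examples and arithmetic consistency
checks:

* a population/deaths summary (counts in millions and percents) by sex and
  by three coarse age bands, globally and for four World Bank income
  categories, in 1990 and 2017;
* the top/bottom-10 causes of death ranked by deaths attributed to
  population ageing 1990→2017 (counts in thousands and attributed
  proportions of each sex's 1990 all-cause deaths).

Printed counts are rounded (0.1 million / 1 thousand), so a percent
recomputed naively from them can differ from the printed percent by more
than half of the printed precision.  :func:`percent_consistent` therefore
checks *interval* consistency: the printed percent (± half ulp) must
overlap the range of percents reachable when every printed count is
perturbed by ± half of its own ulp.
"""
from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .core import Attribution, relative_contribution
from .simulate import PANEL_COLUMNS

__all__ = [
    "summary_fixture_printed",
    "summary_fixture_panel",
    "summary_fixture_consistency",
    "cause_ranking_printed",
    "cause_ranking_consistency",
    "RANKING_BASELINE_MILLIONS",
    "percent_consistent",
]

# measure, dimension, group, location, count (millions) and percent for
# 1990 and 2017; transcribed from the published summary table
_SUMMARY_CSV = """\
measure,dimension,group,location,n_1990,pct_1990,n_2017,pct_2017
population,sex,male,global,2717.5,50.4,3834.5,50.2
population,sex,male,high,491.8,49.2,591.5,49.7
population,sex,male,upper-middle,1067.3,50.6,1322.2,50.2
population,sex,male,lower-middle,983.7,51.0,1576.3,50.5
population,sex,male,low,162.5,49.3,330.1,49.5
population,sex,female,global,2677.2,49.6,3806.0,49.8
population,sex,female,high,508.8,50.8,598.1,50.3
population,sex,female,upper-middle,1044.1,49.4,1312.7,49.8
population,sex,female,lower-middle,945.6,49.0,1544.5,49.5
population,sex,female,low,167.1,50.7,336.7,50.5
population,age,<30,global,3237.4,60.0,3815.1,49.9
population,age,<30,high,447.1,44.7,417.8,35.1
population,age,<30,upper-middle,1256.9,59.5,1096.3,41.6
population,age,<30,lower-middle,1282.4,66.5,1819.3,58.3
population,age,<30,low,236.8,71.9,470.6,70.6
population,age,30-64,global,1829.8,33.9,3151.7,41.3
population,age,30-64,high,431.9,43.2,563.1,47.3
population,age,30-64,upper-middle,735.5,34.8,1268.1,48.1
population,age,30-64,lower-middle,571.8,29.6,1130.9,36.2
population,age,30-64,low,82.1,24.9,175.4,26.3
population,age,>=65,global,327.6,6.1,673.7,8.8
population,age,>=65,high,121.5,12.1,208.6,17.5
population,age,>=65,upper-middle,119.0,5.6,270.5,10.3
population,age,>=65,lower-middle,75.1,3.9,170.6,5.5
population,age,>=65,low,10.7,3.2,20.8,3.1
deaths,sex,male,global,24.9,53.6,30.4,54.3
deaths,sex,male,high,4.5,51.9,5.3,50.9
deaths,sex,male,upper-middle,8.0,54.4,10.7,56.4
deaths,sex,male,lower-middle,9.8,53.7,11.6,54.2
deaths,sex,male,low,2.6,53.7,2.6,54.1
deaths,sex,female,global,21.6,46.4,25.6,45.7
deaths,sex,female,high,4.1,48.1,5.2,49.1
deaths,sex,female,upper-middle,6.7,45.6,8.3,43.6
deaths,sex,female,lower-middle,8.5,46.3,9.8,45.8
deaths,sex,female,low,2.2,46.3,2.2,45.9
deaths,age,<30,global,15.6,33.5,8.2,14.6
deaths,age,<30,high,0.4,4.8,0.2,1.9
deaths,age,<30,upper-middle,3.5,24.0,1.1,5.8
deaths,age,<30,lower-middle,8.6,47.1,4.6,21.6
deaths,age,<30,low,3.0,62.2,2.2,46.1
deaths,age,30-64,global,11.8,25.4,15.5,27.8
deaths,age,30-64,high,1.9,22.4,1.9,17.7
deaths,age,30-64,upper-middle,4.3,29.2,5.3,28.0
deaths,age,30-64,lower-middle,4.6,24.9,7.0,32.5
deaths,age,30-64,low,1.0,20.8,1.3,27.3
deaths,age,>=65,global,19.1,41.1,32.2,57.6
deaths,age,>=65,high,6.3,72.8,8.4,80.4
deaths,age,>=65,upper-middle,6.9,46.8,12.5,66.1
deaths,age,>=65,lower-middle,5.1,27.9,9.8,45.8
deaths,age,>=65,low,0.8,17.0,1.3,26.5
"""

# sex, rank, cause, deaths attributed to ageing 1990->2017 (thousands),
# printed attributed proportion (% of the sex's 1990 all-cause deaths)
_RANKING_CSV = """\
sex,rank,cause,attributed_thousands,pct_printed
male,1,Ischemic heart disease,1735,7.0
male,2,Stroke,1126,4.5
male,3,Chronic obstructive pulmonary disease,771,3.1
male,4,"Tracheal, bronchial, and lung cancer",379,1.5
male,5,Alzheimer disease and other types of dementia,356,1.4
male,6,Tuberculosis,227,0.9
male,7,Cirrhosis and other chronic liver diseases,214,0.9
male,8,Stomach cancer,199,0.8
male,9,Diabetes mellitus,170,0.7
male,10,Chronic kidney disease,169,0.7
male,160,Typhoid and paratyphoid,-15,-0.1
male,161,Whooping cough,-17,-0.1
male,162,Drowning,-20,-0.1
male,163,Sexually transmitted infections excluding HIV,-21,-0.1
male,164,Protein-energy malnutrition,-22,-0.1
male,165,Meningitis,-28,-0.1
male,166,Malaria,-53,-0.2
male,167,Measles,-55,-0.2
male,168,Congenital birth defects,-100,-0.4
male,169,Neonatal disorders,-390,-1.6
female,1,Ischemic heart disease,1470,6.8
female,2,Stroke,1067,4.9
female,3,Alzheimer disease and other types of dementia,621,2.9
female,4,Chronic obstructive pulmonary disease,516,2.4
female,5,Hypertensive heart disease,172,0.8
female,6,Diabetes mellitus,170,0.8
female,7,Breast cancer,146,0.7
female,8,Chronic kidney disease,137,0.6
female,9,"Tracheal, bronchial, and lung cancer",135,0.6
female,10,Colon and rectum cancer,120,0.6
female,160,Typhoid and paratyphoid,-14,-0.1
female,161,Drowning,-14,-0.1
female,162,Tetanus,-14,-0.1
female,163,Whooping cough,-21,-0.1
female,164,Meningitis,-26,-0.1
female,165,Protein-energy malnutrition,-27,-0.1
female,166,Malaria,-51,-0.2
female,167,Measles,-57,-0.3
female,168,Congenital birth defects,-91,-0.4
female,169,Neonatal disorders,-314,-1.5
"""

#: Printed 1990 all-cause deaths (millions) used as ranking denominators.
RANKING_BASELINE_MILLIONS = {"male": 24.9, "female": 21.6}


def summary_fixture_printed() -> pd.DataFrame:
    """Printed summary-table cells as a tidy DataFrame (counts in millions)."""
    return pd.read_csv(io.StringIO(_SUMMARY_CSV))


def cause_ranking_printed() -> pd.DataFrame:
    """Printed attributed-deaths ranking as a tidy DataFrame."""
    return pd.read_csv(io.StringIO(_RANKING_CSV))


def summary_fixture_panel() -> pd.DataFrame:
    """The summary table's age-band rows as a coarse StratumPanel.

    Three age bands (<30, 30-64, >=65), sexes aggregated (``sex='both'``),
    all causes combined, locations 'global' plus the four income
    categories, years 1990 and 2017; counts converted from millions to
    persons.  The 'global' row is the published aggregate of all
    countries/territories (including any unclassified by income), not the
    sum of the four income-category rows.
    """
    printed = summary_fixture_printed()
    age = printed[printed["dimension"] == "age"]
    pop = age[age["measure"] == "population"].set_index(["location", "group"])
    dth = age[age["measure"] == "deaths"].set_index(["location", "group"])
    rows = []
    for year, ncol in ((1990, "n_1990"), (2017, "n_2017")):
        for (loc, grp), r in pop.iterrows():
            rows.append(
                {
                    "location": loc,
                    "income_category": "all" if loc == "global" else loc,
                    "sex": "both",
                    "cause": "all",
                    "year": year,
                    "age_group": grp,
                    "population": r[ncol] * 1e6,
                    "deaths": dth.loc[(loc, grp), ncol] * 1e6,
                }
            )
    return pd.DataFrame(rows)[PANEL_COLUMNS]


def percent_consistent(count, siblings, printed_pct, count_ulp, pct_ulp=0.1):
    """Is a printed percent consistent with printed rounded counts?

    ``count`` is the numerator cell, ``siblings`` the other cells of the
    same breakdown (the denominator is their joint total), all on the
    printed scale with resolution ``count_ulp``.  Returns (low, high,
    consistent): the reachable percent interval when every count moves by
    ± half its ulp, and whether it overlaps ``printed_pct`` ± half the
    percent ulp.
    """
    h = count_ulp / 2.0
    sib = float(np.sum(siblings))
    k = len(np.atleast_1d(siblings))
    lo = (count - h) / ((count - h) + sib + k * h) * 100.0
    hi = (count + h) / ((count + h) + max(sib - k * h, 0.0)) * 100.0
    ok = (lo <= printed_pct + pct_ulp / 2.0) and (hi >= printed_pct - pct_ulp / 2.0)
    return lo, hi, ok


def summary_fixture_consistency() -> pd.DataFrame:
    """Interval-consistency of every printed percent with its printed counts.

    One row per (measure, dimension, group, location, year) cell with the
    reachable percent interval and a boolean ``consistent``.
    """
    printed = summary_fixture_printed()
    out = []
    for (measure, dim, loc), block in printed.groupby(["measure", "dimension", "location"]):
        for ncol, pcol, year in (("n_1990", "pct_1990", 1990), ("n_2017", "pct_2017", 2017)):
            counts = block[ncol].to_numpy(float)
            for i, (_, row) in enumerate(block.iterrows()):
                sib = np.delete(counts, i)
                lo, hi, ok = percent_consistent(
                    counts[i], sib, row[pcol], count_ulp=0.1, pct_ulp=0.1
                )
                out.append(
                    {
                        "measure": measure,
                        "dimension": dim,
                        "group": row["group"],
                        "location": loc,
                        "year": year,
                        "printed_pct": row[pcol],
                        "pct_low": lo,
                        "pct_high": hi,
                        "consistent": ok,
                    }
                )
    return pd.DataFrame(out)


def cause_ranking_consistency() -> pd.DataFrame:
    """Recompute the ranking table's attributed proportions from its counts.

    Routes each printed attributed-death count through the package's
    relative-contribution operation against the printed sex-specific 1990
    all-cause totals and compares with the printed percent at 1 d.p.
    """
    printed = cause_ranking_printed()
    out = []
    for _, row in printed.iterrows():
        base = RANKING_BASELINE_MILLIONS[row["sex"]] * 1e6
        attr = Attribution(
            A=row["attributed_thousands"] * 1e3, P=0.0, M=0.0, baseline_deaths=base
        )
        rel = relative_contribution(attr)
        out.append(
            {
                "sex": row["sex"],
                "cause": row["cause"],
                "pct_printed": row["pct_printed"],
                "pct_recomputed": rel.rel_A,
                "abs_diff": abs(rel.rel_A - row["pct_printed"]),
            }
        )
    return pd.DataFrame(out)
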