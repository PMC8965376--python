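"""Colony-level bycatch impact: observed versus expected percentages.

Each colony's share of assigned bycatch is compared with its share of the
metapopulation census using a 1-df Pearson goodness-of-fit test on rounded
integer percentages treated as counts out of 100, with Holm's sequential
Bonferroni adjustment across colonies.  That percent-as-count statistic is
the default because it reproduces the published per-colony statistics
exactly; a conventional count-based mode (true assigned counts against
census-proportion expectations) is provided as ``mode="counts"`` because
the percent test ignores the real sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ObserverRecord


@dataclass(frozen=True)
class ImpactTestResult:
    colony: str
    observed_pct: float
    expected_pct: float
    chi2: float
    df: int
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False


@dataclass
class ImpactReport:
    tests: pd.DataFrame
    seasonal: pd.DataFrame


# ---------------------------------------------------------------------------
# percentages
# ---------------------------------------------------------------------------

def bycatch_percentages(assignments: pd.DataFrame,
                        observers: Sequence[ObserverRecord] | None = None
                        ) -> pd.DataFrame:
    """Per-colony counts and percentages among threshold-passing birds.

    ``assignments`` needs columns sample_id, map_colony, assigned.  With
    observer records, per-season counts are added for birds whose collection
    date (hence season) is known; birds without season data stay in the
    overall percentages but drop out of the seasonal split.
    """
    ok = assignments[assignments["assigned"].astype(bool)]
    if ok.empty:
        raise ValueError("no individuals passed the assignment threshold")
    counts = ok.groupby("map_colony").size().rename("n_assigned")
    out = counts.reset_index().rename(columns={"map_colony": "colony"})
    out["percent"] = 100.0 * out["n_assigned"] / out["n_assigned"].sum()
    if observers is not None:
        season = pd.Series({r.sample_id: r.season for r in observers})
        ok = ok.assign(season=ok["sample_id"].map(season).fillna("unknown"))
        known = ok[ok["season"] != "unknown"]
        by_season = (known.groupby(["map_colony", "season"]).size()
                     .rename("n").reset_index()
                     .rename(columns={"map_colony": "colony"}))
        with_season = known.groupby("map_colony").size().rename("n_with_season")
        out = out.merge(with_season.reset_index()
                        .rename(columns={"map_colony": "colony"}),
                        on="colony", how="left")
        out.attrs["by_season"] = by_season
    return out


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def chi2_percent_test(observed_pct: float, expected_pct: float
                      ) -> ImpactTestResult:
    """1-df Pearson test on rounded percentages treated as counts of 100.

    chi2 = (o - e)^2 / e + ((100 - o) - (100 - e))^2 / (100 - e) with o, e
    the integer-rounded observed and expected percentages.
    """
    o = round(float(observed_pct))
    e = round(float(expected_pct))
    if not 0 < e < 100:
        raise ValueError(f"expected percentage must be in (0, 100), got {e}")
    if not 0 <= o <= 100:
        raise ValueError(f"observed percentage out of range: {o}")
    chi2 = (o - e) ** 2 / e + (o - e) ** 2 / (100 - e)
    p = float(stats.chi2.sf(chi2, df=1))
    return ImpactTestResult(colony="", observed_pct=o, expected_pct=e,
                            chi2=float(chi2), df=1, p_raw=p)


def chi2_count_test(observed_n: int, total_n: int, expected_fraction: float
                    ) -> ImpactTestResult:
    """Conventional 1-df goodness-of-fit on true assigned counts."""
    if not 0 < expected_fraction < 1:
        raise ValueError("expected_fraction must be in (0, 1)")
    e1 = total_n * expected_fraction
    e2 = total_n - e1
    o1, o2 = observed_n, total_n - observed_n
    chi2 = (o1 - e1) ** 2 / e1 + (o2 - e2) ** 2 / e2
    p = float(stats.chi2.sf(chi2, df=1))
    return ImpactTestResult(colony="", observed_pct=100 * o1 / total_n,
                            expected_pct=100 * expected_fraction,
                            chi2=float(chi2), df=1, p_raw=p)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm's sequentially rejective Bonferroni adjustment (original order)."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def impact_report(census: pd.DataFrame, assignments: pd.DataFrame,
                  observers: Sequence[ObserverRecord] | None = None,
                  alpha: float = 0.05, mode: str = "percent") -> ImpactReport:
    """One chi-squared test per colony, Holm-adjusted across the colony set.

    ``census`` needs columns colony, population_estimate, percent_of_total.
    Seasonal within-colony percentages are computed over birds with known
    season.  ``mode`` is "percent" (default, percent-as-count statistic) or
    "counts" (conventional test on true counts).
    """
    pct = bycatch_percentages(assignments, observers)
    census = census.set_index("colony")
    missing = set(pct["colony"]) - set(census.index)
    if missing:
        raise ValueError(f"colonies absent from census: {sorted(missing)}")
    total_assigned = int(pct["n_assigned"].sum())
    rows = []
    for row in pct.itertuples():
        expected = float(census.loc[row.colony, "percent_of_total"])
        if mode == "percent":
            t = chi2_percent_test(row.percent, expected)
        elif mode == "counts":
            t = chi2_count_test(int(row.n_assigned), total_assigned,
                                expected / 100.0)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append({"colony": row.colony, "n_assigned": row.n_assigned,
                     "observed_pct": t.observed_pct,
                     "expected_pct": t.expected_pct,
                     "chi2": t.chi2, "df": t.df, "p_raw": t.p_raw})
    tests = pd.DataFrame(rows)
    tests["p_adjusted"] = holm_adjust(tests["p_raw"])
    tests["significant"] = tests["p_adjusted"] < alpha

    seasonal = pd.DataFrame(columns=["colony", "season", "n",
                                     "pct_within_colony"])
    by_season = pct.attrs.get("by_season")
    if by_season is not None and not by_season.empty:
        totals = by_season.groupby("colony")["n"].transform("sum")
        seasonal = by_season.assign(
            pct_within_colony=100.0 * by_season["n"] / totals)
    return ImpactReport(tests=tests, seasonal=seasonal)
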