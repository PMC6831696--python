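"""Published products: posterior sample tables, summary tables, species trends.

From the raw MCMC output three deliverables are produced: (1) 1000 joint
samples of annual occupancy per region (one table per species), (2) a
summary table of mean / 95% credible interval / SD / Rhat per region-year,
and (3) a single trend table giving each species' long-term percentage
annual growth rate with credible interval and precision (1/variance of the
sample trends).  Species with fewer than 50 records, or with an interior
run of more than 10 recordless years, are excluded from the trend products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorDraws


@dataclass(frozen=True)
class InclusionRule:
    """Record-count and gap thresholds for trend inclusion."""

    min_records: int = 50
    max_gap_years: int = 10

    def __post_init__(self):
        if self.min_records < 1 or self.max_gap_years < 1:
            raise ValueError("inclusion thresholds must be positive")


@dataclass
class TrendRow:
    """One species' long-term occupancy trend (percentage annual growth)."""

    group: str
    species: str
    n_years: int
    first_year: int
    last_year: int
    n_records: int
    mean_growth_rate: float
    lower_CI: float
    upper_CI: float
    precision: float
    n_zero_start_excluded: int = 0


class UndefinedGrowthError(ValueError):
    """Growth rate is undefined when starting occupancy is zero."""


def thin_to_1000(draws: PosteriorDraws, rng: np.random.Generator,
                 group: str, species: str, n_samples: int = 1000) -> pd.DataFrame:
    """Randomly select ``n_samples`` posterior draws (without replacement).

    The same draw indices are used for every region and year of the
    species, so each sampled iteration is a coherent joint state and
    downstream quantities (trends) propagate the joint uncertainty.
    """
    pooled = draws.pooled_psi()        # (N, R, T)
    if pooled.shape[0] < n_samples:
        raise ValueError(
            f"only {pooled.shape[0]} pooled draws; need {n_samples} — "
            "lengthen the chains or reduce thinning"
        )
    idx = rng.choice(pooled.shape[0], size=n_samples, replace=False)
    sel = pooled[idx]                  # (n, R, T)
    rows = []
    for r, region in enumerate(draws.region_labels):
        frame = pd.DataFrame(sel[:, r, :], columns=[str(y) for y in draws.years])
        frame.insert(0, "Iteration", np.arange(1, n_samples + 1))
        frame.insert(0, "Region", region)
        frame.insert(0, "Species", species)
        frame.insert(0, "Group", group)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def summarise(draws: PosteriorDraws, group: str, species: str) -> pd.DataFrame:
    """Region-year summary over the complete pooled posterior: mean, 95%
    credible interval (2.5%/97.5% quantiles, type-7), SD and Rhat."""
    pooled = draws.pooled_psi()
    rows = []
    for r, region in enumerate(draws.region_labels):
        for t, year in enumerate(draws.years):
            x = pooled[:, r, t]
            rows.append({
                "Group": group,
                "Species": species,
                "Region": region,
                "Year": int(year),
                "Mean": float(np.mean(x)),
                "Lower_CI": float(np.quantile(x, 0.025)),
                "Upper_CI": float(np.quantile(x, 0.975)),
                "Standard_deviation": float(np.std(x, ddof=1)),
                "Rhat": float(draws.rhat_psi[r, t])
                if draws.rhat_psi is not None else np.nan,
            })
    return pd.DataFrame(rows)


def first_last_record_years(clean: pd.DataFrame, species: str) -> tuple[int, int]:
    """First and last calendar year with a record of the species (among the
    records surviving standardisation and the site filter)."""
    yrs = clean.loc[clean["species"] == species, "year"]
    if len(yrs) == 0:
        raise ValueError(f"no records of {species!r}")
    return int(yrs.min()), int(yrs.max())


def annual_growth_rate(f: float, s: float, y: int) -> float:
    """Percentage annual growth rate, ((f/s)^(1/y) - 1) * 100.

    ``s`` is occupancy in the starting year, ``f`` in the final year, ``y``
    the number of years.  Undefined when s = 0.
    """
    if y < 1:
        raise ValueError("y must be >= 1")
    if s == 0:
        raise UndefinedGrowthError("starting occupancy is zero")
    return ((f / s) ** (1.0 / y) - 1.0) * 100.0


def apply_inclusion_rules(record_years: pd.Series | np.ndarray,
                          rule: InclusionRule = InclusionRule()) -> tuple[bool, str]:
    """Decide whether a species' output is reliable enough to publish.

    Excluded if the total record count is below ``min_records``, or if any
    run of consecutive recordless years strictly between the first and last
    record years exceeds ``max_gap_years``.  Gaps before the first or after
    the last record do not trigger exclusion (the trend span is clipped to
    the record span instead).
    """
    years = np.sort(np.unique(np.asarray(record_years, dtype=int)))
    n_records = len(np.asarray(record_years))
    if n_records < rule.min_records:
        return False, "min_records"
    if len(years) > 1:
        gaps = np.diff(years) - 1
        if gaps.max() > rule.max_gap_years:
            return False, "gap"
    return True, ""


def species_trend(sample_table: pd.DataFrame, first_year: int, last_year: int,
                  region: str, group: str, species: str, n_records: int,
                  year_count: str = "inclusive") -> TrendRow:
    """Growth-rate trend from the 1000-sample table for one region.

    Per sample: growth from that sample's occupancy at ``first_year`` (s)
    to ``last_year`` (f).  Samples with s = 0 are excluded (and counted),
    since the growth rate is undefined there.  ``year_count`` picks the y
    convention: "inclusive" (last - first + 1, the published N_Years) or
    "span" (last - first).
    """
    if first_year > last_year:
        raise ValueError("first_year must be <= last_year")
    sub = sample_table[sample_table["Region"] == region]
    if len(sub) == 0:
        raise ValueError(f"no samples for region {region!r}")
    s = sub[str(first_year)].to_numpy(dtype=float)
    f = sub[str(last_year)].to_numpy(dtype=float)
    n_years = last_year - first_year + 1
    y = n_years if year_count == "inclusive" else max(last_year - first_year, 1)

    ok = s > 0
    growth = ((f[ok] / s[ok]) ** (1.0 / y) - 1.0) * 100.0
    if len(growth) == 0:
        raise UndefinedGrowthError("every sample has zero starting occupancy")
    var = float(np.var(growth, ddof=1)) if len(growth) > 1 else 0.0
    return TrendRow(
        group=group,
        species=species,
        n_years=n_years,
        first_year=first_year,
        last_year=last_year,
        n_records=n_records,
        mean_growth_rate=float(np.mean(growth)),
        lower_CI=float(np.quantile(growth, 0.025)),
        upper_CI=float(np.quantile(growth, 0.975)),
        precision=(1.0 / var) if var > 0 else math.inf,
        n_zero_start_excluded=int(np.sum(~ok)),
    )


# ---------------------------------------------------------------------------
# exports (published file layouts; numeric values rounded to 3 dp on disk)

def write_sample_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    year_cols = [c for c in out.columns if c.isdigit()]
    out[year_cols] = out[year_cols].round(5)
    out.to_csv(path, index=False)


def write_summary_table(summary: pd.DataFrame, path) -> None:
    out = summary.copy()
    for c in ("Mean", "Lower_CI", "Upper_CI", "Standard_deviation", "Rhat"):
        out[c] = out[c].round(3)
    out.to_csv(path, index=False)


_TREND_COLUMNS = ["Group", "Species", "N_Years", "First_Year", "Last_year",
                  "N_Records", "Mean_growth_rate", "Lower_CI", "Upper_CI",
                  "Precision"]


def trends_frame(rows: list[TrendRow]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=_TREND_COLUMNS)
    return pd.DataFrame([{
        "Group": r.group,
        "Species": r.species,
        "N_Years": r.n_years,
        "First_Year": r.first_year,
        "Last_year": r.last_year,
        "N_Records": r.n_records,
        "Mean_growth_rate": r.mean_growth_rate,
        "Lower_CI": r.lower_CI,
        "Upper_CI": r.upper_CI,
        "Precision": r.precision,
    } for r in rows])


def write_species_trends(rows: list[TrendRow], path) -> None:
    out = trends_frame(rows)
    if len(out):
        for c in ("Mean_growth_rate", "Lower_CI", "Upper_CI", "Precision"):
            out[c] = out[c].round(3)
    out.to_csv(path, index=False)


def write_species_names(decisions: pd.DataFrame | None, fitted: set[str],
                        included: set[str], group: str, all_species: set[str],
                        path) -> None:
    """Species-name metadata table: name origin, whether in the final
    dataset, and why not where applicable."""
    rows = []
    dec = {} if decisions is None else {
        str(r.raw_name): r for r in decisions.itertuples(index=False)
    }
    for sp in sorted(all_species):
        d = dec.get(sp)
        action = str(d.action) if d is not None else "keep"
        if sp in included:
            reason = "NA"
        elif action == "exclude":
            reason = "Excluded by scheme advice"
        elif action == "retain_no_model":
            reason = "Retained to inform list length only"
        elif sp in fitted:
            reason = "Didn't meet criteria"
        else:
            reason = "Not modelled"
        rows.append({
            "Group": group,
            "Species": sp,
            "Name_origin": "Direct from scheme dataset" if d is None
            else str(getattr(d, "details", "") or "Decision table"),
            "In_final_dataset": "Yes" if sp in included else "No",
            "Reason_not_included": reason,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
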