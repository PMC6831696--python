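"""Visits, list lengths and per-species detection histories.

Clean records are reorganised into *visits* — unique (1 km cell, date)
combinations — the replication unit of the detection submodel.  The list
length of a visit (number of distinct species recorded) proxies sampling
effort and is used categorically: length 1, 2-3, or 4+.  Non-detections of
a focal species are inferred from visits where other species in the group
were recorded.  Sites (cells) with visits in fewer than ``nyr`` distinct
years are dropped, since within-year replication is what identifies
detectability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

CATEGORIES = ("LL1", "LL2_3", "LL4plus")


class EmptyHistoryError(ValueError):
    """Raised when filtering leaves no sites/visits to model."""


def categorise_list_length(L: int) -> str:
    """Map a list length to its effort category (1 / 2-3 / 4+)."""
    if L < 1:
        raise ValueError(f"list length must be >= 1, got {L}")
    if L == 1:
        return "LL1"
    if L <= 3:
        return "LL2_3"
    return "LL4plus"


def build_visits(clean: pd.DataFrame) -> pd.DataFrame:
    """Collapse clean records into one row per (cell, date) visit.

    List length counts distinct species including retain-no-model names.
    Rows are ordered by (cell label, date) so outputs are byte-stable.
    """
    if len(clean) == 0:
        return pd.DataFrame(
            columns=["cell", "date", "year", "region", "list_length", "category"]
        )
    g = clean.groupby(["cell", "date"], sort=True)
    visits = g.agg(
        year=("year", "first"),
        region=("region", "first"),
        list_length=("species", "nunique"),
    ).reset_index()
    visits["category"] = visits["list_length"].map(categorise_list_length)
    return visits


def apply_nyr_filter(visits: pd.DataFrame, nyr: int = 2) -> pd.DataFrame:
    """Drop sites (cells) with visits in fewer than ``nyr`` distinct years.

    Applied to the shared, whole-dataset visit set: list length and site
    survival are group-level quantities, identical for every focal species.
    """
    if nyr < 1:
        raise ValueError("nyr must be >= 1")
    years_per_site = visits.groupby("cell")["year"].nunique()
    surviving = years_per_site.index[years_per_site >= nyr]
    return visits[visits["cell"].isin(set(surviving))].reset_index(drop=True)


@dataclass
class DetectionHistory:
    """Model-ready detection history for one focal species.

    Arrays are index-aligned: sites 0..S-1 (``site_labels``), years 0..T-1
    (``years``), visits 0..V-1.  ``y`` is the 0/1 detection of the focal
    species per visit; ``visit_cat`` is 0/1/2 for list length 1 / 2-3 / 4+.
    """

    focal_species: str
    site_labels: np.ndarray        # (S,) cell labels
    site_region: np.ndarray        # (S,) int index into region_labels
    region_labels: tuple[str, ...]
    years: np.ndarray              # (T,) calendar years modelled
    visit_site: np.ndarray         # (V,) int
    visit_year: np.ndarray         # (V,) int index into years
    visit_cat: np.ndarray          # (V,) int in {0,1,2}
    visit_cell: np.ndarray         # (V,) cell labels (for export)
    visit_date: np.ndarray         # (V,) dates (for export)
    y: np.ndarray                  # (V,) 0/1 focal detection

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_visits(self) -> int:
        return len(self.visit_site)

    def detected(self) -> np.ndarray:
        """(S, T) boolean: any focal detection in that site-year."""
        d = np.zeros((self.n_sites, self.n_years), dtype=bool)
        np.logical_or.at(d, (self.visit_site, self.visit_year), self.y.astype(bool))
        return d


def build_detection_history(
    visits: pd.DataFrame,
    clean: pd.DataFrame,
    focal_species: str,
    years: tuple[int, int] | None = None,
) -> DetectionHistory:
    """Assemble the focal species' 0/1 history over the shared visit set.

    ``years`` fixes the modelled year axis (default: the span of the visit
    years); occupancy is estimated for every year on the axis even where no
    visits fall.
    """
    focal = clean[clean["species"] == focal_species]
    if len(focal) == 0:
        raise ValueError(f"focal species {focal_species!r} has no records")
    if len(visits) == 0:
        raise EmptyHistoryError("no visits to build a history from")

    v = visits.sort_values(["cell", "date"]).reset_index(drop=True)
    if years is None:
        years = (int(v["year"].min()), int(v["year"].max()))
    year_axis = np.arange(years[0], years[1] + 1)

    site_labels, site_idx = np.unique(v["cell"].to_numpy(), return_inverse=True)
    region_labels = tuple(sorted(v["region"].unique()))
    region_index = {r: i for i, r in enumerate(region_labels)}
    site_region = np.zeros(len(site_labels), dtype=np.int64)
    for cell, reg in zip(v["cell"], v["region"]):
        site_region[np.searchsorted(site_labels, cell)] = region_index[reg]

    visit_year = v["year"].to_numpy() - years[0]
    cat_idx = v["category"].map({c: i for i, c in enumerate(CATEGORIES)}).to_numpy()

    detected_keys = set(zip(focal["cell"], focal["date"]))
    y = np.fromiter(
        ((c, d) in detected_keys for c, d in zip(v["cell"], v["date"])),
        dtype=np.int8,
        count=len(v),
    )

    return DetectionHistory(
        focal_species=focal_species,
        site_labels=site_labels,
        site_region=site_region,
        region_labels=region_labels,
        years=year_axis,
        visit_site=site_idx.astype(np.int64),
        visit_year=visit_year.astype(np.int64),
        visit_cat=cat_idx.astype(np.int64),
        visit_cell=v["cell"].to_numpy(),
        visit_date=v["date"].to_numpy(),
        y=y,
    )


def filter_sites_by_years(history: DetectionHistory, nyr: int = 2) -> DetectionHistory:
    """Drop sites with visits in fewer than ``nyr`` distinct years; re-pack indices.

    Survival depends on visit years at the site, not on focal detections.
    """
    if nyr < 1:
        raise ValueError("nyr must be >= 1")
    if nyr == 1:
        return history
    n_years_per_site = np.zeros(history.n_sites, dtype=np.int64)
    for s in range(history.n_sites):
        n_years_per_site[s] = len(np.unique(history.visit_year[history.visit_site == s]))
    keep_sites = np.flatnonzero(n_years_per_site >= nyr)
    if len(keep_sites) == 0:
        raise EmptyHistoryError(f"no sites with >= {nyr} years of visits")
    site_map = -np.ones(history.n_sites, dtype=np.int64)
    site_map[keep_sites] = np.arange(len(keep_sites))
    vmask = site_map[history.visit_site] >= 0
    return replace(
        history,
        site_labels=history.site_labels[keep_sites],
        site_region=history.site_region[keep_sites],
        visit_site=site_map[history.visit_site[vmask]],
        visit_year=history.visit_year[vmask],
        visit_cat=history.visit_cat[vmask],
        visit_cell=history.visit_cell[vmask],
        visit_date=history.visit_date[vmask],
        y=history.y[vmask],
    )


def dataset_information(
    clean: pd.DataFrame,
    visits_raw: pd.DataFrame,
    visits_filtered: pd.DataFrame,
    group: str,
    scheme_name: str = "synthetic recording scheme",
    n_species_outputs: int | None = None,
) -> dict:
    """Summary row of a standardised dataset (records, species, sites, visits,
    and the list-length partition), in the layout of the published
    dataset-information table.  Site counts are reported both before and
    after the minimum-years filter.
    """
    cats = visits_filtered["category"].value_counts()
    countries = sorted(clean["region"].unique())
    coverage = "UK" if "Northern Ireland" in countries else "GB"
    return {
        "Group": group,
        "Country coverage": coverage,
        "First_Year": int(clean["year"].min()) if len(clean) else None,
        "Last_Year": int(clean["year"].max()) if len(clean) else None,
        "Scheme_Name": scheme_name,
        "N_Records": int(len(clean)),
        "N_Species": int(clean["species"].nunique()),
        "N_Species_Outputs": n_species_outputs,
        "N_Sites_prefilter": int(visits_raw["cell"].nunique()),
        "N_Sites": int(visits_filtered["cell"].nunique()),
        "N_Visits": int(len(visits_filtered)),
        "LL_1": int(cats.get("LL1", 0)),
        "LL_2-3": int(cats.get("LL2_3", 0)),
        "LL4+": int(cats.get("LL4plus", 0)),
    }


def export_detection_history(
    visits: pd.DataFrame, clean: pd.DataFrame, focal_species: list[str] | None = None
) -> pd.DataFrame:
    """Visit table with optional 0/1 columns per requested focal species."""
    out = visits.copy()
    out.insert(0, "visit_id", out["cell"].astype(str) + "_" + out["date"].astype(str))
    for sp in focal_species or []:
        keys = set(zip(clean.loc[clean["species"] == sp, "cell"],
                       clean.loc[clean["species"] == sp, "date"]))
        out[sp] = [int((c, d) in keys) for c, d in zip(out["cell"], out["date"])]
    return out
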