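import datetime as dt

import numpy as np
import pandas as pd
import pytest

from occtrend.detection import DetectionHistory


@pytest.fixture
def toy_records() -> pd.DataFrame:
    """Five clean records over two cells and two days (the worked example
    used throughout the visit-formatting tests)."""
    rows = [
        ("Ants", "Species A", "SU0101", dt.date(1990, 5, 1), 1990, "England", True),
        ("Ants", "Species B", "SU0101", dt.date(1990, 5, 1), 1990, "England", True),
        ("Ants", "Species C", "SU0101", dt.date(1990, 5, 1), 1990, "England", True),
        ("Ants", "Species A", "SU0202", dt.date(1990, 5, 1), 1990, "England", True),
        ("Ants", "Species A", "SU0101", dt.date(1991, 6, 2), 1991, "England", True),
    ]
    return pd.DataFrame(
        rows,
        columns=["group", "species", "cell", "date", "year", "region", "modelled"],
    )


def make_history(visit_site, visit_year, y, n_sites=None, n_years=None,
                 site_region=None, region_labels=("England",), visit_cat=None):
    """Hand-build a DetectionHistory from index arrays."""
    visit_site = np.asarray(visit_site, dtype=np.int64)
    visit_year = np.asarray(visit_year, dtype=np.int64)
    y = np.asarray(y, dtype=np.int8)
    S = n_sites or int(visit_site.max()) + 1
    T = n_years or int(visit_year.max()) + 1
    V = len(y)
    return DetectionHistory(
        focal_species="Focal species",
        site_labels=np.array([f"S{i:02d}" for i in range(S)]),
        site_region=(np.zeros(S, dtype=np.int64) if site_region is None
                     else np.asarray(site_region, dtype=np.int64)),
        region_labels=tuple(region_labels),
        years=np.arange(1990, 1990 + T),
        visit_site=visit_site,
        visit_year=visit_year,
        visit_cat=(np.zeros(V, dtype=np.int64) if visit_cat is None
                   else np.asarray(visit_cat, dtype=np.int64)),
        visit_cell=np.array([f"S{i:02d}" for i in visit_site]),
        visit_date=np.array([dt.date(1990, 1, 1) + dt.timedelta(days=int(i))
                             for i in range(V)]),
        y=y,
    )


@pytest.fixture
def history_factory():
    return make_history
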