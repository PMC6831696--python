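"""Synthetic recording-scheme data with known truth.

Emulates the statistical structure the occupancy model assumes — regional
random-walk year effects, site effects, list-length-dependent detection —
plus the messiness real scheme data carry: uneven visit intensity, heavily
LL1-skewed list lengths, coarse grid references, vague dates, duplicates.
Every simulated quantity is recorded in a truth bundle so pipeline output
can be scored against it, and every degradation is written to a manifest so
rejection counts are predictable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from .model import derived_occupancy
from .gridrefs import cell_from_label

# one 100 km square per region; Northern Ireland is on the Irish grid,
# exercising both parsers
REGION_SQUARES = {
    "England": "SU",
    "Scotland": "NO",
    "Wales": "SH",
    "Northern Ireland": "J",
}


@dataclass
class Scenario:
    """Study conditions for one synthetic recording scheme.

    Defaults give the mid-size setting used for end-to-end checks: 150
    sites over three GB countries, the full 1970-2015 window, a gently
    declining focal species, about half a visit per site-year, and a
    zero-truncated negative-binomial background richness that reproduces
    the heavy skew toward single-species lists seen in real schemes.
    """

    group: str = "Synthetic insects"
    focal_name: str = "Focalia exemplaris"
    n_sites: dict[str, int] = field(
        default_factory=lambda: {"England": 60, "Scotland": 50, "Wales": 40})
    years: tuple[int, int] = (1970, 2015)
    # state model truth
    b1_mean: dict[str, float] = field(
        default_factory=lambda: {"England": 0.2, "Scotland": -0.2, "Wales": 0.0})
    rw_sd: dict[str, float] = field(
        default_factory=lambda: {"England": 0.12, "Scotland": 0.12, "Wales": 0.12})
    drift: dict[str, float] = field(default_factory=dict)  # per-year logit drift
    sigma_u: float = 0.8
    # detection model truth
    a_mean: float = -0.3
    a_sd: float = 0.4
    beta1: float = 0.6
    beta2: float = 1.2
    # effort
    visits_per_site_year: float | list[float] = 0.5
    background_pool: int = 60
    ll_nb_mean: float = 1.6      # negative-binomial mean before zero truncation
    ll_nb_k: float = 0.9         # NB dispersion; small k -> heavy LL1 skew
    # degradation rates
    coarse_frac: float = 0.0
    vague_date_frac: float = 0.0
    duplicate_frac: float = 0.0
    pre1970_frac: float = 0.0

    @property
    def regions(self) -> list[str]:
        return list(self.n_sites)

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    def intensity(self) -> np.ndarray:
        v = self.visits_per_site_year
        if np.isscalar(v):
            return np.full(self.n_years, float(v))
        arr = np.asarray(v, dtype=float)
        if len(arr) != self.n_years:
            raise ValueError("visit intensity must be scalar or one value per year")
        return arr

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dict(self.__dict__)
        d["years"] = list(self.years)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class TruthBundle:
    """Everything the generator knows: parameters, latent states, psi_fs."""

    scenario: Scenario
    site_labels: np.ndarray          # (S,)
    site_region: np.ndarray          # (S,) index into region_labels
    region_labels: tuple[str, ...]
    b: np.ndarray                    # (T, R)
    u: np.ndarray                    # (S,)
    a: np.ndarray                    # (T,)
    z: np.ndarray                    # (S, T)
    psi: np.ndarray                  # (S, T) occupancy probabilities
    psi_fs_labels: list[str]
    psi_fs: np.ndarray               # (R_out, T) exact proportion occupied

    def region_lookup(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_label": self.site_labels,
            "region": [self.region_labels[r] for r in self.site_region],
        })


def _site_cells(scenario: Scenario, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Unique 1 km cells per region, on each region's 100 km square."""
    labels, region_idx = [], []
    for r, region in enumerate(scenario.regions):
        n = scenario.n_sites[region]
        sq = REGION_SQUARES[region]
        coords = rng.choice(100 * 100, size=n, replace=False)
        for c in coords:
            e, nn = divmod(int(c), 100)
            labels.append(f"{sq}{e:02d}{nn:02d}")
            region_idx.append(r)
    labels = np.array(labels)
    for lab in labels[:1]:
        cell_from_label(lab)  # sanity: emitted labels must be parseable
    return labels, np.array(region_idx, dtype=np.int64)


def simulate_truth(scenario: Scenario, seed: int) -> TruthBundle:
    """Draw the latent world: random-walk year effects, site effects and the
    true occupancy matrix, plus the exact psi_fs it implies."""
    rng = np.random.default_rng([int(seed), 0])
    T, R = scenario.n_years, len(scenario.regions)
    region_labels = tuple(scenario.regions)

    site_labels, site_region = _site_cells(scenario, rng)
    S = len(site_labels)

    b = np.zeros((T, R))
    for r, region in enumerate(region_labels):
        drift = scenario.drift.get(region, 0.0)
        b[0, r] = scenario.b1_mean[region]
        steps = rng.normal(drift, scenario.rw_sd[region], size=T - 1)
        b[1:, r] = b[0, r] + np.cumsum(steps)

    u = rng.normal(0.0, scenario.sigma_u, size=S) if scenario.sigma_u > 0 \
        else np.zeros(S)
    a = rng.normal(scenario.a_mean, scenario.a_sd, size=T) if scenario.a_sd > 0 \
        else np.full(T, scenario.a_mean)

    eta = b[:, site_region].T + u[:, None]
    psi = 1.0 / (1.0 + np.exp(-eta))
    z = (rng.random((S, T)) < psi).astype(np.int8)

    labels, psi_fs = derived_occupancy(z, site_region, region_labels)
    return TruthBundle(scenario=scenario, site_labels=site_labels,
                       site_region=site_region, region_labels=region_labels,
                       b=b, u=u, a=a, z=z, psi=psi,
                       psi_fs_labels=labels, psi_fs=psi_fs)


def _zt_negbin(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial by rejection (resampling zeros)."""
    p = k / (k + mean)
    out = rng.negative_binomial(k, p, size=size)
    while np.any(out == 0):
        idx = out == 0
        out[idx] = rng.negative_binomial(k, p, size=int(idx.sum()))
    return out


def simulate_records(truth: TruthBundle, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate visits and raw records from the latent truth.

    Per site-year, a Poisson number of visits; per visit, a target list
    length from the zero-truncated negative binomial, a focal detection
    y ~ Bernoulli(z * p) with logit p = a_t + beta1/beta2 by category, and
    background species filling the list.  Returns (raw records, per-visit
    truth table).
    """
    sc = truth.scenario
    rng = np.random.default_rng([int(seed), 1])
    T = sc.n_years
    S = len(truth.site_labels)
    intensity = sc.intensity()
    year0 = sc.years[0]

    n_visits = rng.poisson(np.broadcast_to(intensity, (S, T)))
    background = [f"Backgroundia species{i:03d}" for i in range(sc.background_pool)]

    rec_rows, visit_rows = [], []
    for s in range(S):
        cell = truth.site_labels[s]
        for t in range(T):
            year = year0 + t
            if n_visits[s, t] == 0:
                continue
            days = rng.choice(365, size=n_visits[s, t], replace=False) \
                if n_visits[s, t] <= 365 else rng.choice(365, size=365, replace=False)
            for d in np.sort(days):
                day = date(year, 1, 1) + timedelta(days=int(d))
                L = int(_zt_negbin(rng, sc.ll_nb_mean, sc.ll_nb_k, 1)[0])
                cat = 0 if L == 1 else (1 if L <= 3 else 2)
                logit_p = truth.a[t] + (sc.beta1 if cat == 1 else 0.0) \
                    + (sc.beta2 if cat == 2 else 0.0)
                p = 1.0 / (1.0 + np.exp(-logit_p))
                y = int(truth.z[s, t] == 1 and rng.random() < p)
                n_bg = L - y if L - y > 0 else (0 if y else 1)
                names = list(rng.choice(background, size=min(n_bg, len(background)),
                                        replace=False))
                if y:
                    names.append(sc.focal_name)
                for name in names:
                    rec_rows.append((sc.group, name, cell, day.isoformat()))
                visit_rows.append((cell, day.isoformat(), year, len(names), y,
                                   int(truth.z[s, t]), p))

    raw = pd.DataFrame(rec_rows, columns=["group", "species", "gridref", "date"])
    visit_truth = pd.DataFrame(
        visit_rows, columns=["cell", "date", "year", "list_length", "y_focal",
                             "z_true", "p_true"])
    return raw, visit_truth


def degrade(raw: pd.DataFrame, scenario: Scenario, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject the precision problems the standardiser must reject.

    Disjoint record subsets are coarsened to 10 km grid references, given
    year-only dates, or moved before 1970; a further subset of untouched
    records is duplicated verbatim.  Counts are round(rate * n) exactly and
    every alteration is listed in the returned manifest.
    """
    rng = np.random.default_rng([int(seed), 2])
    out = raw.reset_index(drop=True).copy()
    n = len(out)
    n_coarse = round(scenario.coarse_frac * n)
    n_vague = round(scenario.vague_date_frac * n)
    n_pre = round(scenario.pre1970_frac * n)
    n_dup = round(scenario.duplicate_frac * n)

    perm = rng.permutation(n)
    coarse_idx = perm[:n_coarse]
    vague_idx = perm[n_coarse:n_coarse + n_vague]
    pre_idx = perm[n_coarse + n_vague:n_coarse + n_vague + n_pre]
    clean_pool = perm[n_coarse + n_vague + n_pre:]
    dup_idx = clean_pool[:n_dup]

    manifest = []
    for i in coarse_idx:
        ref = out.at[i, "gridref"]
        letters = ref[:2] if ref[1].isalpha() else ref[:1]
        digits = ref[len(letters):]
        h = len(digits) // 2
        out.at[i, "gridref"] = f"{letters}{digits[0]}{digits[h]}"  # 10 km square
        manifest.append((int(i), "coarse_gridref"))
    for i in vague_idx:
        out.at[i, "date"] = out.at[i, "date"][:4]
        manifest.append((int(i), "vague_date"))
    for i in pre_idx:
        old = out.at[i, "date"]
        out.at[i, "date"] = f"{1969 - int(old[:4]) % 5}{old[4:]}"
        manifest.append((int(i), "pre1970_date"))
    dups = out.loc[dup_idx].copy()
    for i in dup_idx:
        manifest.append((int(i), "duplicate"))
    out = pd.concat([out, dups], ignore_index=True)

    manifest_df = pd.DataFrame(manifest, columns=["record_index", "alteration"])
    return out, manifest_df


def truth_psi_frame(truth: TruthBundle) -> pd.DataFrame:
    """psi_fs truth as a long table (region, year, value)."""
    rows = []
    for k, lab in enumerate(truth.psi_fs_labels):
        for t in range(truth.scenario.n_years):
            rows.append({"region": lab,
                         "year": truth.scenario.years[0] + t,
                         "psi_fs": truth.psi_fs[k, t]})
    return pd.DataFrame(rows)
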