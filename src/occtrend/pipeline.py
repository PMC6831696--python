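"""End-to-end orchestration: simulate -> standardise -> format -> fit -> products.

Each stage is a pure function of (inputs, config, seed) writing plain-CSV
intermediates, so a later stage re-run from stored files equals the
end-to-end run.  Per-species MCMC seeds are derived from the master seed
and the species name, making results independent of execution order.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, products, simulate
from .model import McmcConfig, PriorConfig, run_mcmc
from .standardise import standardise as _standardise


def species_seed(master_seed: int, species: str) -> int:
    """Stable per-species seed (< 2^31), independent of worker count/order."""
    h = zlib.crc32(species.encode("utf-8"))
    return (int(master_seed) * 1_000_003 + h) % (2**31)


@dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    stages: dict = field(default_factory=dict)   # stage -> {seconds, counts}

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, outdir) -> None:
        Path(outdir, "run_manifest.json").write_text(
            json.dumps(asdict(self), indent=2, default=str))


def stage_simulate(scenario: simulate.Scenario, seed: int, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate.simulate_truth(scenario, seed)
    raw, visit_truth = simulate.simulate_records(truth, seed)
    degraded, manifest = simulate.degrade(raw, scenario, seed)
    degraded.to_csv(outdir / "raw_records.csv", index=False)
    manifest.to_csv(outdir / "degradation_manifest.csv", index=False)
    truth.region_lookup().to_csv(outdir / "region_lookup.csv", index=False)
    simulate.truth_psi_frame(truth).to_csv(outdir / "truth_psi_fs.csv", index=False)
    visit_truth.to_csv(outdir / "truth_visits.csv", index=False)
    return {"n_raw_records": len(degraded)}


def stage_standardise(records_path, decisions_path, lookup_path,
                      outdir: Path, year_window=(1970, 2015)) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    raw = pd.read_csv(records_path)
    decisions = pd.read_csv(decisions_path) if decisions_path else None
    lookup = pd.read_csv(lookup_path) if lookup_path else None
    clean, log = _standardise(raw, decisions, lookup, year_window)
    clean.to_csv(outdir / "clean_records.csv", index=False)
    log.to_frame().to_csv(outdir / "rejection_log.csv", index=False)
    pd.DataFrame(log.audit, columns=["row", "reason", "detail"]).to_csv(
        outdir / "rejection_audit.csv", index=False)
    return {"n_raw": len(raw), "n_clean": len(clean), **log.counts}


def stage_format(clean_path, outdir: Path, nyr: int = 2, group: str = "Synthetic",
                 scheme_name: str = "synthetic recording scheme") -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    clean = pd.read_csv(clean_path, parse_dates=["date"])
    clean["date"] = clean["date"].dt.date
    visits_raw = detection.build_visits(clean)
    visits = detection.apply_nyr_filter(visits_raw, nyr)
    keys = set(zip(visits["cell"], visits["date"]))
    clean_f = clean[[k in keys for k in zip(clean["cell"], clean["date"])]]
    visits.to_csv(outdir / "visits.csv", index=False)
    clean_f.to_csv(outdir / "clean_records_filtered.csv", index=False)
    info = detection.dataset_information(clean_f, visits_raw, visits, group,
                                         scheme_name)
    pd.DataFrame([info]).to_csv(outdir / "Dataset_Information.csv", index=False)
    return {"n_visits": len(visits), "n_sites": visits["cell"].nunique()}


def stage_fit(visits_path, clean_path, outdir: Path, seed: int,
              mcmc: McmcConfig | None = None, priors: PriorConfig = PriorConfig(),
              species: list[str] | None = None,
              years: tuple[int, int] | None = None) -> dict:
    """Fit the occupancy model per modelled focal species and store draws."""
    outdir.mkdir(parents=True, exist_ok=True)
    visits = pd.read_csv(visits_path, parse_dates=["date"])
    visits["date"] = visits["date"].dt.date
    clean = pd.read_csv(clean_path, parse_dates=["date"])
    clean["date"] = clean["date"].dt.date

    if species is None:
        species = sorted(clean.loc[clean["modelled"], "species"].unique())
    fitted = {}
    for sp in species:
        hist = detection.build_detection_history(visits, clean, sp, years=years)
        cfg = (mcmc or McmcConfig()).__class__(**{
            **asdict(mcmc or McmcConfig()), "seed": species_seed(seed, sp)})
        draws = run_mcmc(hist, cfg, priors)
        _save_draws(draws, outdir / f"draws_{_slug(sp)}.npz")
        fitted[sp] = draws
    return {"n_species_fitted": len(fitted)}


def stage_products(draws_dir: Path, clean_path, outdir: Path, seed: int,
                   group: str, rule: products.InclusionRule | None = None,
                   headline_region: str | None = None,
                   decisions_path=None) -> dict:
    """1000-sample tables, summaries and the trend table with inclusion rules."""
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "POSTERIOR_SAMPLES").mkdir(exist_ok=True)
    (outdir / "SUMMARY_TABLES").mkdir(exist_ok=True)
    rule = rule or products.InclusionRule()
    clean = pd.read_csv(clean_path, parse_dates=["date"])
    clean["date"] = clean["date"].dt.date

    trend_rows, excluded = [], []
    draws_files = sorted(Path(draws_dir).glob("draws_*.npz"))
    for path in draws_files:
        draws, sp = _load_draws(path)
        rng = np.random.default_rng([species_seed(seed, sp), 3])
        table = products.thin_to_1000(draws, rng, group, sp)
        products.write_sample_table(table,
                                    outdir / "POSTERIOR_SAMPLES" / f"{_slug(sp)}.csv")
        summary = products.summarise(draws, group, sp)
        products.write_summary_table(summary,
                                     outdir / "SUMMARY_TABLES" / f"{_slug(sp)}.csv")

        sp_years = clean.loc[clean["species"] == sp, "year"]
        ok, reason = products.apply_inclusion_rules(sp_years, rule)
        if not ok:
            excluded.append({"Species": sp, "Reason": reason})
            continue
        first, last = products.first_last_record_years(clean, sp)
        region = headline_region or draws.region_labels[0]
        trend_rows.append(products.species_trend(
            table, first, last, region, group, sp, n_records=len(sp_years)))

    products.write_species_trends(trend_rows, outdir / "Species_Trends.csv")
    pd.DataFrame(excluded, columns=["Species", "Reason"]).to_csv(
        outdir / "Excluded_Species.csv", index=False)
    decisions = pd.read_csv(decisions_path) if decisions_path else None
    products.write_species_names(
        decisions,
        fitted={_load_draws(p)[1] for p in draws_files},
        included={r.species for r in trend_rows},
        group=group,
        all_species=set(clean["species"]),
        path=outdir / "Species_Names.csv")
    return {"n_trends": len(trend_rows), "n_excluded": len(excluded)}


def run_all(scenario: simulate.Scenario, seed: int, outdir,
            mcmc: McmcConfig | None = None, priors: PriorConfig = PriorConfig(),
            nyr: int = 2, rule: products.InclusionRule | None = None) -> RunManifest:
    """The full workflow on a synthetic scenario, with provenance manifest."""
    outdir = Path(outdir)
    manifest = RunManifest(seed=seed, config={
        "scenario": {**scenario.__dict__, "years": list(scenario.years)},
        "mcmc": asdict(mcmc or McmcConfig()), "priors": asdict(priors),
        "nyr": nyr,
        "inclusion": asdict(rule or products.InclusionRule()),
    })
    stages = [
        ("simulate", lambda: stage_simulate(scenario, seed, outdir)),
        ("standardise", lambda: stage_standardise(
            outdir / "raw_records.csv", None, outdir / "region_lookup.csv",
            outdir, year_window=scenario.years)),
        ("format", lambda: stage_format(outdir / "clean_records.csv", outdir,
                                        nyr=nyr, group=scenario.group)),
        ("fit", lambda: stage_fit(outdir / "visits.csv",
                                  outdir / "clean_records_filtered.csv",
                                  outdir, seed, mcmc, priors,
                                  species=[scenario.focal_name],
                                  years=scenario.years)),
        ("products", lambda: stage_products(outdir, outdir / "clean_records_filtered.csv",
                                            outdir, seed, scenario.group, rule)),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        counts = fn()
        manifest.stages[name] = {"seconds": round(time.perf_counter() - t0, 3),
                                 **counts}
    manifest.write(outdir)
    return manifest


# ---------------------------------------------------------------------------
# draw (de)serialisation — plain npz under the run directory

def _slug(species: str) -> str:
    return species.replace(" ", "_").replace("/", "_")


def _save_draws(draws, path) -> None:
    np.savez_compressed(
        path,
        psi=draws.psi,
        region_labels=np.array(draws.region_labels),
        years=draws.years,
        z_mean=draws.z_mean,
        rhat_psi=draws.rhat_psi if draws.rhat_psi is not None else np.array([]),
        param_names=np.array(list(draws.params)),
        param_values=np.stack([draws.params[k] for k in draws.params]),
    )


def _load_draws(path):
    from .model import PosteriorDraws

    path = Path(path)
    with np.load(path, allow_pickle=False) as f:
        params = {str(k): v for k, v in zip(f["param_names"], f["param_values"])}
        draws = PosteriorDraws(
            psi=f["psi"],
            region_labels=[str(x) for x in f["region_labels"]],
            years=f["years"],
            params=params,
            z_mean=f["z_mean"],
            rhat_psi=f["rhat_psi"] if f["rhat_psi"].size else None,
        )
    species = path.stem.removeprefix("draws_").replace("_", " ")
    return draws, species
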