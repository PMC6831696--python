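# occtrend

Occupancy-detection trend modelling for unstructured biological records:
from raw presence-only occurrence data to annual regional occupancy
posteriors and long-term growth-rate trends.

## The problem

Volunteer recording schemes accumulate millions of presence-only records —
a *what, when and where* per observation — but no information about where a
species was looked for and not found. Estimating long-term status change
from such data must contend with imperfect detection, uneven effort per
visit, and uneven recording intensity over space and time. Occupancy
models address this by separating the *state* process (is site *i* occupied
in year *t*?) from the *observation* process (was the species detected on
visit *v*, given it was present?), with non-detections inferred from visits
on which other species in the taxonomic group were recorded.

`occtrend` implements this workflow end to end for UK-style recording
schemes (British/Irish grid references, country-level reporting), together
with a synthetic recording-scheme generator with known truth, so every
stage is testable without access to any scheme database.

## The model

State model, with a region-specific random walk on the year effects:

    z_it ~ Bernoulli(psi_it)
    logit(psi_it) = b_{t,r(i)} + u_i
    b_{1,r} ~ Normal(mu_br, sigma_1^2)         (vague, sigma_1 = 100)
    b_{t,r} ~ Normal(b_{t-1,r}, sigma_br^2)    for t > 1
    u_i ~ Normal(0, sigma_u^2)

Observation model with categorical list length (1 / 2–3 / 4+ species per
visit) as the effort proxy:

    y_itv | z_it ~ Bernoulli(p_itv * z_it)
    logit(p_itv) = a_t + beta1 * [L_itv in 2–3] + beta2 * [L_itv >= 4]
    a_t ~ Normal(mu_a, sigma_a^2)

Standard-deviation parameters get half-Cauchy priors (|Student-t, 1 df|);
location hyperparameters get vague normals. The random walk shares
information between adjacent years, which is what makes annual estimates
workable at low recording intensity. Fitting is by a data-augmented
Metropolis-within-Gibbs sampler (the latent `z` has an exact closed-form
conditional); annual occupancy per region is the derived proportion of
occupied sites, `psi_fs[r,t] = mean_{i in r} z_it`, and long-term trends
are percentage annual growth rates

    growth = ((f / s)^(1/y) - 1) * 100

computed per posterior sample between the first and last years with
records of the species.

## Worked example

Run the whole workflow on a bundled-style synthetic scenario:

```python
from occtrend.pipeline import run_all
from occtrend.simulate import Scenario
from occtrend.model import McmcConfig

scenario = Scenario(
    n_sites={"England": 25, "Wales": 15}, years=(1990, 2005),
    b1_mean={"England": 0.6, "Wales": 0.2},
    rw_sd={"England": 0.1, "Wales": 0.1},
    drift={"England": -0.05, "Wales": -0.05},   # gently declining species
    visits_per_site_year=2.0,
    coarse_frac=0.05, vague_date_frac=0.05, duplicate_frac=0.03)

run_all(scenario, seed=1, outdir="run1",
        mcmc=McmcConfig(n_iterations=4000, burn_in=1500, thinning=3))
```

or equivalently from the shell:

    occtrend all --scenario scenario.yaml --seed 1 --out run1 \
        --iterations 4000 --burn-in 1500

`run1/` then contains the standardised records with a rejection audit
(`clean_records.csv`, `rejection_log.csv`), the visit table with list
lengths (`visits.csv`), 1000 posterior samples of annual occupancy per
region (`POSTERIOR_SAMPLES/`), summary tables with means, 95% credible
intervals and Rhat (`SUMMARY_TABLES/`), and the trend table
(`Species_Trends.csv`). For the scenario above, seed 1, the trend row for
the focal species reads

    Group, Species, N_Years, First_Year, Last_year, N_Records, Mean_growth_rate, Lower_CI, Upper_CI, Precision
    Synthetic insects, Focalia exemplaris, 16, 1990, 2005, 303, -2.915, -4.942, -0.656, 0.810

i.e. an estimated decline of 2.9% of occupied sites per year over
1990–2005 (95% CI −4.9% to −0.7%), based on 303 records; the generator's
true GB growth rate for this realisation, −3.61%/year, falls inside the
interval. Precision is 1/variance of the 1000 sample trends.

## Layout

- `occtrend.gridrefs` — British/Irish grid-reference parsing, precision
  inference, 1 km truncation
- `occtrend.standardise` — record standardisation: dates, windows, name
  decisions, deduplication, rejection accounting
- `occtrend.detection` — visits, list-length categories, detection
  histories, minimum-years site filter
- `occtrend.model` — the hierarchical model, sampler, Rhat, derived
  regional occupancy
- `occtrend.products` — 1000-sample tables, summaries, trends, inclusion
  rules, published file layouts
- `occtrend.simulate` — synthetic recording-scheme generator with truth
  bundle and degradation manifest
- `occtrend.validation` — enumeration oracle, SBC, truth-recovery
  experiments
- `occtrend.pipeline` / `occtrend.cli` — staged workflow and the
  `occtrend` command
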