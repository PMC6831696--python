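"""Model-validation experiments: enumeration oracle, simulation-based
calibration, and truth-recovery on synthetic data.

These are the package's correctness instruments.  The enumeration oracle
computes the latent-occupancy posterior on tiny instances by brute force
from first principles (its own Bernoulli arithmetic, independent of the
sampler's conditional); SBC checks that posterior ranks of prior-drawn
parameters are uniform; the recovery experiment scores credible-interval
coverage and bias of the derived occupancy against generator truth.
"""

from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .detection import DetectionHistory, build_detection_history, build_visits, \
    apply_nyr_filter
from .model import (
    McmcConfig,
    ModelState,
    PriorConfig,
    run_mcmc,
)
from .simulate import Scenario, simulate_records, simulate_truth
from .standardise import standardise


# ---------------------------------------------------------------------------
# brute-force enumeration oracle

def enumerate_z_posterior(data: DetectionHistory,
                          state: ModelState) -> tuple[np.ndarray, np.ndarray]:
    """Exact P(z_it = 1 | y, fixed parameters) and E[psi_fs] by summing the
    joint probability over all 2^(S*T) occupancy configurations.

    Computes every probability from scratch (plain Bernoulli products), so
    it is independent of the sampler's closed-form conditional.
    """
    S, T = data.n_sites, data.n_years
    if S * T > 20:
        raise ValueError("enumeration only feasible for <= 20 site-years")

    psi = expit(state.b[:, data.site_region].T + state.u[:, None])  # (S, T)
    p_visit = expit(state.a[data.visit_year]
                    + state.beta1 * (data.visit_cat == 1)
                    + state.beta2 * (data.visit_cat == 2))

    post_z = np.zeros((S, T))
    exp_psi_fs = 0.0
    total = 0.0
    for bits in itertools.product((0, 1), repeat=S * T):
        z = np.array(bits).reshape(S, T)
        prob = float(np.prod(np.where(z == 1, psi, 1 - psi)))
        zv = z[data.visit_site, data.visit_year]
        like = np.where(data.y == 1, p_visit * zv, 1 - p_visit * zv)
        prob *= float(np.prod(like))
        total += prob
        post_z += prob * z
        exp_psi_fs += prob * z.mean()
    return post_z / total, exp_psi_fs / total


@dataclass
class OracleResult:
    max_se_units: float          # worst |MCMC - enumeration| in MC-SE units
    max_abs_diff: float
    psi_fs_se_units: float
    n_draws: int


def oracle_comparison(seed: int, n_iterations: int = 24_000) -> OracleResult:
    """2-site x 2-year instance, continuous parameters fixed: compare the
    sampler's marginal P(z_it = 1) and mean psi_fs with enumeration."""
    y = np.array([0, 1, 0, 0], dtype=np.int8)
    data = DetectionHistory(
        focal_species="sp",
        site_labels=np.array(["A", "B"]),
        site_region=np.array([0, 0]),
        region_labels=("England",),
        years=np.array([1990, 1991]),
        visit_site=np.array([0, 0, 1, 1]),
        visit_year=np.array([0, 1, 0, 1]),
        visit_cat=np.array([0, 1, 2, 0]),
        visit_cell=np.array(["A", "A", "B", "B"]),
        visit_date=np.array([dt.date(1990, 1, 1 + i) for i in range(4)]),
        y=y,
    )
    fixed = ModelState(
        b=np.array([[0.3], [-0.1]]), u=np.array([0.2, -0.4]),
        a=np.array([-0.2, 0.1]), beta1=0.5, beta2=1.0,
        mu_b=np.zeros(1), sigma_b=np.ones(1), sigma_u=1.0, mu_a=0.0,
        sigma_a=1.0, z=np.ones((2, 2), dtype=np.int8))

    exact_z, exact_psi = enumerate_z_posterior(data, fixed)

    cfg = McmcConfig(n_iterations=n_iterations, burn_in=1000, thinning=1,
                     n_chains=1, seed=int(seed) % 2**31)
    d = run_mcmc(data, cfg, fixed_params=fixed)
    n = d.n_draws
    mc_z = d.z_mean[0]

    se_z = np.sqrt(np.maximum(exact_z * (1 - exact_z), 1e-12) / n)
    free = ~data.detected()   # detected cells are exactly 1 on both routes
    se_units = np.abs(mc_z - exact_z)[free] / se_z[free]

    region = d.region_labels.index("England")
    mc_psi = float(d.psi[0, :, region, :].mean())
    psi_draw_sd = float(d.psi[0, :, region, :].mean(axis=(1,)).std(ddof=1))
    psi_se = max(psi_draw_sd / np.sqrt(n), 1e-12)
    return OracleResult(
        max_se_units=float(se_units.max()),
        max_abs_diff=float(np.abs(mc_z - exact_z)[free].max()),
        psi_fs_se_units=abs(mc_psi - exact_psi) / psi_se,
        n_draws=n,
    )


# ---------------------------------------------------------------------------
# simulation-based calibration

SBC_PRIORS = PriorConfig(b1_sd=1.0, mu_b_sd=1.0, sigma_b_scale=0.5,
                         sigma_u_scale=0.5, mu_a_sd=1.0, sigma_a_scale=0.5,
                         beta_sd=1.0)


def _sbc_design(n_sites: int, n_years: int, visits_per_site_year: int):
    vs, vy, vc = [], [], []
    for s in range(n_sites):
        for t in range(n_years):
            for k in range(visits_per_site_year):
                vs.append(s)
                vy.append(t)
                vc.append(k % 3)
    return np.array(vs), np.array(vy), np.array(vc)


def _sbc_history(y, vs, vy, vc, n_sites, n_years):
    return DetectionHistory(
        focal_species="sp",
        site_labels=np.array([f"s{i}" for i in range(n_sites)]),
        site_region=np.zeros(n_sites, dtype=np.int64),
        region_labels=("England",),
        years=np.arange(1970, 1970 + n_years),
        visit_site=vs, visit_year=vy, visit_cat=vc,
        visit_cell=np.array([f"s{i}" for i in vs]),
        visit_date=np.array([dt.date(1970, 1, 1)] * len(vs)),
        y=y,
    )


def _draw_from_prior(rng, priors: PriorConfig, n_sites, n_years, vs, vy, vc):
    """Sample (theta, y) from the model's own prior predictive on a fixed
    visit design — the generator half of SBC."""
    mu_b = rng.normal(0, priors.mu_b_sd)
    sigma_b = abs(rng.standard_cauchy()) * priors.sigma_b_scale
    b = np.empty(n_years)
    b[0] = rng.normal(mu_b, priors.b1_sd)
    b[1:] = b[0] + np.cumsum(rng.normal(0, sigma_b, n_years - 1))
    sigma_u = abs(rng.standard_cauchy()) * priors.sigma_u_scale
    u = rng.normal(0, sigma_u, n_sites)
    mu_a = rng.normal(0, priors.mu_a_sd)
    sigma_a = abs(rng.standard_cauchy()) * priors.sigma_a_scale
    a = rng.normal(mu_a, sigma_a, n_years)
    beta1, beta2 = rng.normal(0, priors.beta_sd, 2)
    z = (rng.random((n_sites, n_years)) < expit(b[None, :] + u[:, None]))
    lo = a[vy] + beta1 * (vc == 1) + beta2 * (vc == 2)
    y = ((rng.random(len(vs)) < expit(lo)) & z[vs, vy]).astype(np.int8)
    theta = {"mu_b": mu_b, "sigma_u": sigma_u, "beta1": beta1, "mu_a": mu_a}
    return theta, y


@dataclass
class SbcResult:
    ranks: dict[str, np.ndarray]
    chi2: dict[str, float]
    p_values: dict[str, float]
    n_replicates: int
    n_ranks: int


def simulation_based_calibration(seed: int, n_replicates: int = 200,
                                 n_sites: int = 20, n_years: int = 10,
                                 visits_per_site_year: int = 3,
                                 n_ranks: int = 19,
                                 n_iterations: int = 2400,
                                 burn_in: int = 900) -> SbcResult:
    """Rank-uniformity check of the sampler.

    Each replicate draws parameters and data from the prior predictive,
    fits the model, and records the rank of each true parameter among
    ``n_ranks`` well-separated posterior draws.  If the sampler targets the
    correct posterior, ranks are uniform on {0..n_ranks}; uniformity is
    scored by a chi-squared test over the n_ranks+1 bins.
    """
    vs, vy, vc = _sbc_design(n_sites, n_years, visits_per_site_year)
    thin = (n_iterations - burn_in) // n_ranks
    monitored = {"mu_b": "mu_b[England]", "sigma_u": "sigma_u",
                 "beta1": "beta1", "mu_a": "mu_a"}
    ranks = {k: np.zeros(n_replicates, dtype=int) for k in monitored}

    for rep in range(n_replicates):
        rng = np.random.default_rng([int(seed) % 2**31, rep])
        theta, y = _draw_from_prior(rng, SBC_PRIORS, n_sites, n_years, vs, vy, vc)
        hist = _sbc_history(y, vs, vy, vc, n_sites, n_years)
        cfg = McmcConfig(n_iterations=n_iterations, burn_in=burn_in,
                         thinning=thin, n_chains=1,
                         seed=int(rng.integers(2**31)))
        d = run_mcmc(hist, cfg, SBC_PRIORS)
        for k, name in monitored.items():
            draws = d.params[name][0][:n_ranks]
            ranks[k][rep] = int(np.sum(draws < theta[k]))

    chi2, pvals = {}, {}
    expected = n_replicates / (n_ranks + 1)
    for k, r in ranks.items():
        obs = np.bincount(r, minlength=n_ranks + 1)
        c = float(((obs - expected) ** 2 / expected).sum())
        chi2[k] = c
        pvals[k] = float(1 - stats.chi2.cdf(c, n_ranks))
    return SbcResult(ranks=ranks, chi2=chi2, p_values=pvals,
                     n_replicates=n_replicates, n_ranks=n_ranks)


# ---------------------------------------------------------------------------
# truth recovery on the mid-size synthetic scenario

@dataclass
class RecoveryResult:
    coverage: float              # 95% CI coverage of psi_fs truth
    mean_bias: float             # mean (posterior mean - truth) over region-years
    mean_abs_error: float
    rhat_max: float
    n_region_years: int
    n_replicates: int
    per_replicate_bias: list[float]


def recovery_experiment(seed: int, n_replicates: int = 3,
                        scenario: Scenario | None = None,
                        mcmc: McmcConfig | None = None) -> RecoveryResult:
    """Fit the full pipeline on replicate mid-size datasets and score the
    derived occupancy against the generator's truth.

    Coverage counts region-years whose truth falls in the central 95%
    credible interval; bias is averaged over region-years and replicates
    (averaging over replicates separates systematic error from the
    single-realisation Monte-Carlo spread).
    """
    scenario = scenario or Scenario()
    covered, biases, abs_errs, rep_bias = [], [], [], []
    rhat_max = 0.0
    n_ry = 0
    for rep in range(n_replicates):
        rep_seed = (int(seed) * 7919 + rep) % 2**31
        truth = simulate_truth(scenario, rep_seed)
        raw, _ = simulate_records(truth, rep_seed)
        clean, _ = standardise(raw, None, truth.region_lookup(), scenario.years)
        visits = apply_nyr_filter(build_visits(clean), 2)
        hist = build_detection_history(visits, clean, scenario.focal_name,
                                       years=scenario.years)
        cfg = mcmc or McmcConfig(n_iterations=9000, burn_in=4000, thinning=5,
                                 n_chains=3, seed=rep_seed)
        d = run_mcmc(hist, cfg)
        pooled = d.pooled_psi()
        lo = np.quantile(pooled, 0.025, axis=0)
        hi = np.quantile(pooled, 0.975, axis=0)
        mean = pooled.mean(axis=0)
        this_bias = []
        for k, lab in enumerate(d.region_labels):
            kt = truth.psi_fs_labels.index(lab)
            t_true = truth.psi_fs[kt]
            covered.extend(((t_true >= lo[k]) & (t_true <= hi[k])).tolist())
            biases.extend((mean[k] - t_true).tolist())
            abs_errs.extend(np.abs(mean[k] - t_true).tolist())
            this_bias.extend((mean[k] - t_true).tolist())
            n_ry += len(t_true)
        rep_bias.append(float(np.mean(this_bias)))
        rhat_max = max(rhat_max, float(np.nanmax(d.rhat_psi)))
    return RecoveryResult(
        coverage=float(np.mean(covered)),
        mean_bias=float(np.mean(biases)),
        mean_abs_error=float(np.mean(abs_errs)),
        rhat_max=rhat_max,
        n_region_years=n_ry,
        n_replicates=n_replicates,
        per_replicate_bias=rep_bias,
    )
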