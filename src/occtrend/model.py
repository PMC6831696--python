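"""Hierarchical Bayesian occupancy-detection model with random-walk year effects.

State model: z_it ~ Bernoulli(psi_it), logit(psi_it) = b_{t,r(i)} + u_i,
with a region-specific random walk on the year effects,
b_{1,r} ~ N(mu_br, b1_sd^2), b_{t,r} ~ N(b_{t-1,r}, sigma_br^2), which
shares information between adjacent years and stabilises estimates from
sparse data.

Observation model: y_itv | z_it ~ Bernoulli(p_itv * z_it), with
logit(p_itv) = a_t + beta1*[L in 2-3] + beta2*[L >= 4]; detection varies by
year and by categorical list length (effort).  No false positives: a
detection forces z_it = 1.

Hyperpriors: site effects u_i ~ N(0, sigma_u^2); detection year effects
a_t ~ N(mu_a, sigma_a^2); standard-deviation parameters get half-Cauchy
priors (|Student-t, 1 df|); location parameters get vague normals.

Fitting is by data-augmented Metropolis-within-Gibbs: the latent z_it have
an exact closed-form conditional; continuous parameters move by adaptive
random-walk Metropolis (year effects on an odd/even checkerboard so the
random-walk neighbour structure stays valid under vectorised updates).
Annual occupancy per region is the derived finite-sample proportion of
occupied sites, psi_fs[r, t] = mean_{i in r} z_it, recorded at every
retained iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, log_expit

from .detection import DetectionHistory

UK_REGIONS = ("England", "Scotland", "Wales", "Northern Ireland")
GB_MEMBERS = ("England", "Scotland", "Wales")


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PriorConfig:
    """Prior scales (all are standard deviations / half-Cauchy scales).

    Defaults reproduce the vague setting used for national recording-scheme
    data: first-year effect SD 100, its mean SD 10, half-Cauchy scale 1 on
    every SD parameter, and SD 10 on the list-length offsets.
    """

    b1_sd: float = 100.0          # SD of b_{1,r} around mu_br
    mu_b_sd: float = 10.0         # SD of mu_br prior
    sigma_b_scale: float = 1.0    # half-Cauchy scale for the RW step SD
    sigma_u_scale: float = 1.0    # half-Cauchy scale for the site-effect SD
    mu_a_sd: float = 10.0         # SD of mu_a prior
    sigma_a_scale: float = 1.0    # half-Cauchy scale for the a_t SD
    beta_sd: float = 10.0         # SD of beta1, beta2 priors


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run lengths.  The default (40,000 / 20,000 / 3) is the
    small-dataset setting; ``large_preset`` gives the 20,000 / 10,000 / 3
    compromise used for data-rich groups."""

    n_iterations: int = 40_000
    burn_in: int = 20_000
    thinning: int = 3
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @classmethod
    def large_preset(cls, seed: int = 0, n_chains: int = 3) -> "McmcConfig":
        return cls(n_iterations=20_000, burn_in=10_000, thinning=3,
                   n_chains=n_chains, seed=seed)


@dataclass
class ModelState:
    """One point in the parameter space (all model unknowns)."""

    b: np.ndarray          # (T, R) year effects per region, logit scale
    u: np.ndarray          # (S,) site effects
    a: np.ndarray          # (T,) detection year effects
    beta1: float
    beta2: float
    mu_b: np.ndarray       # (R,) first-year means
    sigma_b: np.ndarray    # (R,) RW step SDs
    sigma_u: float
    mu_a: float
    sigma_a: float
    z: np.ndarray          # (S, T) latent occupancy


# ---------------------------------------------------------------------------
# densities

def _log_halfcauchy(x: float | np.ndarray, scale: float) -> float | np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(
            x > 0,
            math.log(2.0 / math.pi) - np.log(scale) - np.log1p((x / scale) ** 2),
            -np.inf,
        )
    return out if out.ndim else float(out)


def _log_normal(x, mu, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2 * np.pi * sd**2) - (x - mu) ** 2 / (2 * sd**2)


def _visit_logit_p(state: ModelState, data: DetectionHistory) -> np.ndarray:
    return (
        state.a[data.visit_year]
        + state.beta1 * (data.visit_cat == 1)
        + state.beta2 * (data.visit_cat == 2)
    )


def log_joint(state: ModelState, data: DetectionHistory,
              priors: PriorConfig = PriorConfig()) -> float:
    """Log of the joint density of (data, z, parameters).

    Returns -inf for impossible states (a detection at a site-year with
    z = 0) and for out-of-support SDs.
    """
    if np.any(state.z[data.detected()] == 0):
        return -np.inf
    if state.sigma_u <= 0 or state.sigma_a <= 0 or np.any(state.sigma_b <= 0):
        return -np.inf

    # state model: z_it ~ Bern(psi_it)
    eta = state.b[:, data.site_region].T + state.u[:, None]  # (S, T)
    lp = float(np.sum(np.where(state.z == 1, log_expit(eta), log_expit(-eta))))

    # observation model: only visits at occupied site-years carry information
    zv = state.z[data.visit_site, data.visit_year]
    lo = _visit_logit_p(state, data)
    obs = np.where(data.y == 1, log_expit(lo), log_expit(-lo))
    lp += float(np.sum(obs[zv == 1]))
    # visits at z=0 site-years: y must be 0 (checked above), likelihood 1

    # random-walk prior on b, and hyperpriors
    lp += float(np.sum(_log_normal(state.b[0], state.mu_b, priors.b1_sd)))
    if data.n_years > 1:
        steps = np.diff(state.b, axis=0)
        lp += float(np.sum(_log_normal(steps, 0.0, state.sigma_b[None, :])))
    lp += float(np.sum(_log_normal(state.mu_b, 0.0, priors.mu_b_sd)))
    lp += float(np.sum(_log_halfcauchy(state.sigma_b, priors.sigma_b_scale)))
    lp += float(np.sum(_log_normal(state.u, 0.0, state.sigma_u)))
    lp += float(_log_halfcauchy(state.sigma_u, priors.sigma_u_scale))
    lp += float(np.sum(_log_normal(state.a, state.mu_a, state.sigma_a)))
    lp += float(_log_normal(state.mu_a, 0.0, priors.mu_a_sd))
    lp += float(_log_halfcauchy(state.sigma_a, priors.sigma_a_scale))
    lp += float(_log_normal(state.beta1, 0.0, priors.beta_sd))
    lp += float(_log_normal(state.beta2, 0.0, priors.beta_sd))
    return lp


def conditional_z(state: ModelState, data: DetectionHistory) -> np.ndarray:
    """(S, T) matrix of P(z_it = 1 | parameters, data).

    Detected site-years are 1; unvisited site-years equal psi_it; otherwise
    Bayes' rule with the probability of the all-zero detection record.
    """
    eta = state.b[:, data.site_region].T + state.u[:, None]
    log_psi, log_1mpsi = log_expit(eta), log_expit(-eta)

    lo = _visit_logit_p(state, data)
    logq = np.zeros((data.n_sites, data.n_years))
    np.add.at(logq, (data.visit_site, data.visit_year), log_expit(-lo))

    log_num = log_psi + logq
    p1 = np.exp(log_num - np.logaddexp(log_num, log_1mpsi))
    p1[data.detected()] = 1.0
    return p1


# ---------------------------------------------------------------------------
# initial values

def initial_values(data: DetectionHistory, rng: np.random.Generator,
                   priors: PriorConfig = PriorConfig()) -> ModelState:
    """Starting state: z is 1 wherever detected and Bernoulli(0.5) elsewhere;
    continuous parameters start near zero (small-variance normals), SD
    parameters near but above zero."""
    S, T, R = data.n_sites, data.n_years, len(data.region_labels)
    z = (rng.random((S, T)) < 0.5).astype(np.int8)
    z[data.detected()] = 1
    return ModelState(
        b=rng.normal(0.0, 0.1, size=(T, R)),
        u=rng.normal(0.0, 0.1, size=S),
        a=rng.normal(0.0, 0.1, size=T),
        beta1=float(rng.normal(0.0, 0.1)),
        beta2=float(rng.normal(0.0, 0.1)),
        mu_b=rng.normal(0.0, 0.1, size=R),
        sigma_b=np.abs(rng.normal(0.0, 0.1, size=R)) + 0.5,
        sigma_u=float(abs(rng.normal(0.0, 0.1)) + 0.5),
        mu_a=float(rng.normal(0.0, 0.1)),
        sigma_a=float(abs(rng.normal(0.0, 0.1)) + 0.5),
        z=z,
    )


# ---------------------------------------------------------------------------
# Gibbs / Metropolis updates

def _bern_loglik(z, eta):
    return np.where(z == 1, log_expit(eta), log_expit(-eta))


class _Sampler:
    """Single-chain sampler with adaptive Metropolis step sizes."""

    def __init__(self, data: DetectionHistory, priors: PriorConfig,
                 rng: np.random.Generator,
                 fixed_params: ModelState | None = None):
        self.data = data
        self.priors = priors
        self.rng = rng
        self.fixed = fixed_params is not None
        d = data
        self.detected = d.detected()
        self.region_of_site = d.site_region
        self.S, self.T, self.R = d.n_sites, d.n_years, len(d.region_labels)
        self.is_cat1 = (d.visit_cat == 1)
        self.is_cat2 = (d.visit_cat == 2)
        self.region_onehot = np.equal.outer(
            d.site_region, np.arange(self.R)).astype(float)  # (S, R)
        # checkerboard parities over the year axis
        self.parities = (np.arange(0, self.T, 2), np.arange(1, self.T, 2))
        # adaptive step sizes (log scale), targeting ~0.44 acceptance
        self.step_b = np.full((self.T, self.R), 0.5)
        self.step_u = np.full(self.S, 0.5)
        self.step_a = np.full(self.T, 0.5)
        self.step_beta = np.full(2, 0.2)
        self.step_sig = {"sigma_b": np.full(self.R, 0.5), "sigma_u": 0.5, "sigma_a": 0.5}
        self.step_scale = {"u": 0.3, "a": 0.3, "b": np.full(self.R, 0.3)}
        self._adapt_count = 0

        if fixed_params is not None:
            self.state = replace(fixed_params, z=fixed_params.z.copy())
        else:
            self.state = initial_values(data, rng, priors)
            for _ in range(10):
                if np.isfinite(log_joint(self.state, data, priors)):
                    break
                self.state = initial_values(data, rng, priors)
            else:
                raise RuntimeError("could not find a finite starting state")

    # -- helpers ------------------------------------------------------------

    def _state_eta(self, b=None, u=None):
        st = self.state
        b = st.b if b is None else b
        u = st.u if u is None else u
        return b[:, self.region_of_site].T + u[:, None]

    def _adapt(self, step, accepted, scale=1.0):
        """Robbins-Monro adaptation of log step sizes during burn-in."""
        gamma = scale / math.sqrt(1 + self._adapt_count)
        return step * np.exp(gamma * (accepted - 0.44))

    # -- updates ------------------------------------------------------------

    def update_z(self):
        p1 = conditional_z(self.state, self.data)
        z = (self.rng.random(p1.shape) < p1).astype(np.int8)
        z[self.detected] = 1
        self.state.z = z

    def update_b(self, adapt: bool):
        st = self.state
        for par in self.parities:
            b_old = st.b[par]                                   # (P, R)
            b_new = b_old + self.rng.normal(size=b_old.shape) * self.step_b[par]

            # state-likelihood delta, summed over sites by region
            zp = st.z[:, par]                                   # (S, P)
            eta_old = b_old[:, self.region_of_site].T + st.u[:, None]
            eta_new = b_new[:, self.region_of_site].T + st.u[:, None]
            dll = _bern_loglik(zp, eta_new) - _bern_loglik(zp, eta_old)
            dll_tr = dll.T @ self.region_onehot                 # (P, R)

            # random-walk prior delta (neighbours are on the other parity, fixed)
            mu_prev = np.where((par == 0)[:, None], st.mu_b[None, :],
                               st.b[np.maximum(par - 1, 0)])
            sd_prev = np.where((par == 0)[:, None], self.priors.b1_sd,
                               st.sigma_b[None, :])
            dpr = _log_normal(b_new, mu_prev, sd_prev) - \
                _log_normal(b_old, mu_prev, sd_prev)
            has_next = par + 1 < self.T
            if np.any(has_next):
                nxt = st.b[par[has_next] + 1]
                dpr[has_next] += (
                    _log_normal(nxt, b_new[has_next], st.sigma_b[None, :])
                    - _log_normal(nxt, b_old[has_next], st.sigma_b[None, :]))

            accept = np.log(self.rng.random(b_old.shape)) < dll_tr + dpr
            st.b[par] = np.where(accept, b_new, b_old)
            if adapt:
                self.step_b[par] = self._adapt(self.step_b[par], accept)
        self._adapt_count += adapt

    def update_u(self, adapt: bool):
        st = self.state
        prop_u = st.u + self.rng.normal(size=self.S) * self.step_u
        eta_old = self._state_eta()
        eta_new = self._state_eta(u=prop_u)
        dll = (_bern_loglik(st.z, eta_new) - _bern_loglik(st.z, eta_old)).sum(axis=1)
        dll += (_log_normal(prop_u, 0.0, st.sigma_u)
                - _log_normal(st.u, 0.0, st.sigma_u))
        accept = np.log(self.rng.random(self.S)) < dll
        st.u = np.where(accept, prop_u, st.u)
        if adapt:
            self.step_u = self._adapt(self.step_u, accept)

    def _active_visits(self):
        """Visits whose site-year is occupied: the only ones informing detection."""
        d = self.data
        return self.state.z[d.visit_site, d.visit_year] == 1

    def update_a(self, adapt: bool):
        st, d = self.state, self.data
        act = self._active_visits()
        prop_a = st.a + self.rng.normal(size=self.T) * self.step_a
        lo_old = _visit_logit_p(st, d)[act]
        lo_new = lo_old + (prop_a - st.a)[d.visit_year[act]]
        y = d.y[act]
        dvis = np.where(y == 1, log_expit(lo_new) - log_expit(lo_old),
                        log_expit(-lo_new) - log_expit(-lo_old))
        dll = np.bincount(d.visit_year[act], weights=dvis,
                          minlength=self.T).astype(float)
        dll += (_log_normal(prop_a, st.mu_a, st.sigma_a)
                - _log_normal(st.a, st.mu_a, st.sigma_a))
        accept = np.log(self.rng.random(self.T)) < dll
        st.a = np.where(accept, prop_a, st.a)
        if adapt:
            self.step_a = self._adapt(self.step_a, accept)

    def update_betas(self, adapt: bool):
        st, d = self.state, self.data
        act = self._active_visits()
        for k, (name, mask) in enumerate(
                (("beta1", self.is_cat1), ("beta2", self.is_cat2))):
            cur = getattr(st, name)
            prop = cur + self.rng.normal() * self.step_beta[k]
            sel = act & mask
            lo_old = _visit_logit_p(st, d)[sel]
            lo_new = lo_old + (prop - cur)
            y = d.y[sel]
            dll = float(np.sum(np.where(y == 1,
                                        log_expit(lo_new) - log_expit(lo_old),
                                        log_expit(-lo_new) - log_expit(-lo_old))))
            dll += float(_log_normal(prop, 0.0, self.priors.beta_sd)
                         - _log_normal(cur, 0.0, self.priors.beta_sd))
            accept = math.log(self.rng.random()) < dll
            if accept:
                setattr(st, name, float(prop))
            if adapt:
                self.step_beta[k] = self._adapt(self.step_beta[k], float(accept))

    def update_mu_b(self):
        """Conjugate normal update given b_{1,r}."""
        st, pr = self.state, self.priors
        prec = 1.0 / pr.mu_b_sd**2 + 1.0 / pr.b1_sd**2
        mean = (st.b[0] / pr.b1_sd**2) / prec
        st.mu_b = self.rng.normal(mean, 1.0 / math.sqrt(prec), size=self.R)

    def update_mu_a(self):
        st, pr = self.state, self.priors
        prec = 1.0 / pr.mu_a_sd**2 + self.T / st.sigma_a**2
        mean = (st.a.sum() / st.sigma_a**2) / prec
        st.mu_a = float(self.rng.normal(mean, 1.0 / math.sqrt(prec)))

    def _mh_log_sigma(self, cur, step, ss, n, hc_scale):
        """MH on log(sigma) for a half-Cauchy SD with n normal residuals
        of summed squares ss.  Returns (new value, accepted?)."""
        prop = cur * math.exp(self.rng.normal() * step)
        def logpost(s):
            return (-n * math.log(s) - ss / (2 * s * s)
                    + float(_log_halfcauchy(s, hc_scale)) + math.log(s))  # + jacobian
        dll = logpost(prop) - logpost(cur)
        if math.log(self.rng.random()) < dll:
            return prop, 1.0
        return cur, 0.0

    def update_sigmas(self, adapt: bool):
        st, pr = self.state, self.priors
        # RW step SDs, per region
        if self.T > 1:
            steps = np.diff(st.b, axis=0)
            for r in range(self.R):
                ss = float(np.sum(steps[:, r] ** 2))
                new, acc = self._mh_log_sigma(
                    float(st.sigma_b[r]), self.step_sig["sigma_b"][r], ss,
                    self.T - 1, pr.sigma_b_scale)
                st.sigma_b[r] = new
                if adapt:
                    self.step_sig["sigma_b"][r] = float(
                        self._adapt(self.step_sig["sigma_b"][r], acc))
        # site-effect SD
        ss = float(np.sum(st.u**2))
        new, acc = self._mh_log_sigma(st.sigma_u, self.step_sig["sigma_u"], ss,
                                      self.S, pr.sigma_u_scale)
        st.sigma_u = new
        if adapt:
            self.step_sig["sigma_u"] = float(self._adapt(self.step_sig["sigma_u"], acc))
        # detection year-effect SD
        ss = float(np.sum((st.a - st.mu_a) ** 2))
        new, acc = self._mh_log_sigma(st.sigma_a, self.step_sig["sigma_a"], ss,
                                      self.T, pr.sigma_a_scale)
        st.sigma_a = new
        if adapt:
            self.step_sig["sigma_a"] = float(self._adapt(self.step_sig["sigma_a"], acc))

    def update_scales(self, adapt: bool):
        """Joint scale (interweaving) moves along each (effects, SD) funnel.

        Proposes (x, sigma) -> (c*x, c*sigma) with log c ~ Normal(0, step^2).
        The Gaussian prior's quadratic term is invariant under the map, so
        the acceptance ratio reduces to the data-likelihood change, the
        half-Cauchy prior change, and a single +log c from the Jacobian net
        of the prior's normalisation — the same form for site effects,
        detection year effects (scaled about mu_a) and each region's
        random-walk increments (scaled about b_1).  These moves traverse
        the sigma-effects funnel that single-parameter updates cross only
        diffusively.
        """
        st, pr, d = self.state, self.priors, self.data

        # site effects (u, sigma_u)
        c = math.exp(self.rng.normal() * self.step_scale["u"])
        u_new = c * st.u
        dll = float(np.sum(_bern_loglik(st.z, self._state_eta(u=u_new))
                           - _bern_loglik(st.z, self._state_eta())))
        dll += float(_log_halfcauchy(c * st.sigma_u, pr.sigma_u_scale)
                     - _log_halfcauchy(st.sigma_u, pr.sigma_u_scale)) + math.log(c)
        acc = float(math.log(self.rng.random()) < dll)
        if acc:
            st.u, st.sigma_u = u_new, c * st.sigma_u
        if adapt:
            self.step_scale["u"] = float(self._adapt(self.step_scale["u"], acc))

        # detection year effects (a - mu_a, sigma_a)
        c = math.exp(self.rng.normal() * self.step_scale["a"])
        a_new = st.mu_a + c * (st.a - st.mu_a)
        act = self._active_visits()
        lo_old = _visit_logit_p(st, d)[act]
        lo_new = lo_old + (a_new - st.a)[d.visit_year[act]]
        y = d.y[act]
        dll = float(np.sum(np.where(y == 1, log_expit(lo_new) - log_expit(lo_old),
                                    log_expit(-lo_new) - log_expit(-lo_old))))
        dll += float(_log_halfcauchy(c * st.sigma_a, pr.sigma_a_scale)
                     - _log_halfcauchy(st.sigma_a, pr.sigma_a_scale)) + math.log(c)
        acc = float(math.log(self.rng.random()) < dll)
        if acc:
            st.a, st.sigma_a = a_new, c * st.sigma_a
        if adapt:
            self.step_scale["a"] = float(self._adapt(self.step_scale["a"], acc))

        # random-walk increments per region (b - b_1, sigma_b)
        if self.T > 1:
            for r in range(self.R):
                c = math.exp(self.rng.normal() * self.step_scale["b"][r])
                b_new = st.b.copy()
                b_new[:, r] = st.b[0, r] + c * (st.b[:, r] - st.b[0, r])
                sites = self.region_of_site == r
                eta_old = self._state_eta()[sites]
                eta_new = self._state_eta(b=b_new)[sites]
                dll = float(np.sum(_bern_loglik(st.z[sites], eta_new)
                                   - _bern_loglik(st.z[sites], eta_old)))
                dll += float(_log_halfcauchy(c * st.sigma_b[r], pr.sigma_b_scale)
                             - _log_halfcauchy(st.sigma_b[r], pr.sigma_b_scale)) \
                    + math.log(c)
                acc = float(math.log(self.rng.random()) < dll)
                if acc:
                    st.b = b_new
                    st.sigma_b[r] = c * st.sigma_b[r]
                if adapt:
                    self.step_scale["b"][r] = float(
                        self._adapt(self.step_scale["b"][r], acc))

    def sweep(self, adapt: bool):
        self.update_z()
        if self.fixed:
            return
        self.update_b(adapt)
        self.update_u(adapt)
        self.update_a(adapt)
        self.update_betas(adapt)
        self.update_mu_b()
        self.update_mu_a()
        self.update_sigmas(adapt)
        self.update_scales(adapt)


# ---------------------------------------------------------------------------
# derived occupancy and output regions

def output_regions(region_labels: tuple[str, ...]) -> list[str]:
    """Published output regions: the modelled countries plus GB (England,
    Scotland, Wales aggregate) and, for UK-scale datasets (those covering
    Northern Ireland), UK."""
    out = []
    if "Northern Ireland" in region_labels:
        out.append("UK")
    if any(r in region_labels for r in GB_MEMBERS):
        out.append("GB")
    out.extend(r for r in UK_REGIONS if r in region_labels)
    return out


def derived_occupancy(z: np.ndarray, site_region: np.ndarray,
                      region_labels: tuple[str, ...]) -> tuple[list[str], np.ndarray]:
    """Finite-sample occupancy psi_fs per output region from latent z.

    ``z`` has shape (..., S, T); returns (labels, array of shape
    (..., R_out, T)) where each entry is the proportion of the region's
    sites with z = 1 that year.
    """
    z = np.asarray(z, dtype=float)
    labels = output_regions(region_labels)
    out = np.empty(z.shape[:-2] + (len(labels), z.shape[-1]))
    for k, lab in enumerate(labels):
        if lab == "UK":
            members = np.ones(len(site_region), dtype=bool)
        elif lab == "GB":
            gb_idx = [i for i, r in enumerate(region_labels) if r in GB_MEMBERS]
            members = np.isin(site_region, gb_idx)
        else:
            members = site_region == region_labels.index(lab)
        out[..., k, :] = z[..., members, :].mean(axis=-2)
    return labels, out


# ---------------------------------------------------------------------------
# convergence diagnostic

def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  Uses the classic between/within
    variance form: sqrt(((n-1)/n * W + B/n) / W).  Degenerate chains (zero
    within-chain variance everywhere) report 1.0; see :func:`rhat_full`.
    """
    return rhat_full(chains)[0]


def rhat_full(chains: np.ndarray) -> tuple[float, bool]:
    """Rhat plus a flag marking the degenerate all-constant case."""
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2 or n < 4:
        raise ValueError("rhat needs >= 2 chains with >= 4 draws each")
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if W == 0.0:
        return 1.0, True
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W)), False


# ---------------------------------------------------------------------------
# driver

@dataclass
class PosteriorDraws:
    """Retained MCMC output for one species.

    ``psi`` holds the derived occupancy draws, shape
    (n_chains, n_draws, n_output_regions, n_years); ``params`` maps
    monitored scalar names to (n_chains, n_draws) arrays; ``z_mean`` is the
    per-chain posterior mean of each latent z_it.
    """

    psi: np.ndarray
    region_labels: list[str]
    years: np.ndarray
    params: dict[str, np.ndarray]
    z_mean: np.ndarray               # (n_chains, S, T)
    rhat_psi: np.ndarray = field(default=None)       # (R_out, T)
    rhat_params: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.psi.shape[0]

    @property
    def n_draws(self) -> int:
        return self.psi.shape[1]

    def pooled_psi(self) -> np.ndarray:
        """(n_chains * n_draws, R_out, T) draws pooled across chains."""
        return self.psi.reshape(-1, *self.psi.shape[2:])


def run_mcmc(data: DetectionHistory, config: McmcConfig,
             priors: PriorConfig = PriorConfig(),
             fixed_params: ModelState | None = None) -> PosteriorDraws:
    """Fit the model by MCMC and return retained draws.

    ``fixed_params`` freezes every continuous parameter at the given state
    and samples only the latent z — the configuration used to compare the
    z-conditional against exhaustive enumeration on tiny instances.
    Reproducible: chain c uses generator seeded from (seed, c).
    """
    if data.n_visits == 0:
        raise ValueError("empty detection history")
    span = config.n_iterations - config.burn_in
    n_ret = (span + config.thinning - 1) // config.thinning
    labels = output_regions(data.region_labels)

    psi = np.empty((config.n_chains, n_ret, len(labels), data.n_years))
    params: dict[str, np.ndarray] = {
        name: np.empty((config.n_chains, n_ret))
        for name in ["mu_a", "sigma_a", "sigma_u", "beta1", "beta2"]
    }
    for r, lab in enumerate(data.region_labels):
        params[f"mu_b[{lab}]"] = np.empty((config.n_chains, n_ret))
        params[f"sigma_b[{lab}]"] = np.empty((config.n_chains, n_ret))
    z_mean = np.zeros((config.n_chains, data.n_sites, data.n_years))

    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        smp = _Sampler(data, priors, rng, fixed_params=fixed_params)
        k = 0
        for it in range(config.n_iterations):
            smp.sweep(adapt=it < config.burn_in)
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                st = smp.state
                _, psi[c, k] = derived_occupancy(st.z, data.site_region,
                                                 data.region_labels)
                for name in ("mu_a", "sigma_a", "sigma_u", "beta1", "beta2"):
                    params[name][c, k] = getattr(st, name)
                for r, lab in enumerate(data.region_labels):
                    params[f"mu_b[{lab}]"][c, k] = st.mu_b[r]
                    params[f"sigma_b[{lab}]"][c, k] = st.sigma_b[r]
                z_mean[c] += st.z
                k += 1
        z_mean[c] /= max(k, 1)

    out = PosteriorDraws(psi=psi, region_labels=labels, years=data.years,
                         params=params, z_mean=z_mean)
    if config.n_chains >= 2 and n_ret >= 4:
        out.rhat_psi = np.array(
            [[rhat(psi[:, :, r, t]) for t in range(data.n_years)]
             for r in range(len(labels))]
        )
        out.rhat_params = {name: rhat(arr) for name, arr in params.items()}
    return out
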