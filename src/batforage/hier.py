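"""Hierarchical Bayesian models of foraging distance and bearing.

Per colony × season × provenance group, foraging-location distances and
angles to the roost are modelled with individual random intercepts:

    distance:  d_ij ~ Normal(μ_d + b_i, σ_d),   b_i ~ Normal(0, τ_d)
    angle:     θ_ij ~ VonMises(μ_θ + a_i, κ),   a_i ~ Normal(0, τ_θ)

with weakly regularizing priors μ_d ~ N(20, 20) km, σ_d, τ_d ~
HalfNormal(10) km, μ_θ ~ N(0, 2) rad, κ ~ HalfNormal(10), τ_θ ~
HalfNormal(1) rad.  The two components are conditionally independent
given the individual index.

Three group-level quantities are reported: the population mean (μ), the
*effective standard deviation* — the spread of the marginal predictive
observation distribution, sqrt(σ_d² + τ_d²) for distance and the circular
SD of the von Mises/normal mixture for angle — and the *individual-level
variability* τ (the random-intercept SD).

Sampling uses an affine-invariant ensemble sampler over the marginal
likelihood: the random intercepts are integrated out analytically
(distance) or by Gauss–Hermite quadrature (angle), so each component has
only three free parameters and converges quickly.  Scale parameters are
sampled unconstrained and folded (τ = |t|), which is equivalent to the
half-normal prior and avoids the log-scale funnel when the posterior
piles up at zero.  Split-R̂ and effective sample size are computed over
walkers; a fit with any R̂ > 1.05 raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import special

from .geometry import bearing_to_compass_degrees, circular_mean, wrap_angle

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(25)
_LOG_GH_W = np.log(_GH_WEIGHTS / np.sqrt(np.pi))


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PriorSpec:
    mu_d_loc: float = 20.0
    mu_d_scale: float = 20.0
    sigma_d_scale: float = 10.0
    tau_d_scale: float = 10.0
    mu_theta_scale: float = 2.0
    kappa_scale: float = 10.0
    tau_theta_scale: float = 1.0


@dataclass
class SamplerConfig:
    n_walkers: int = 24
    n_steps: int = 3500
    n_burn: int = 1000
    thin: int = 5
    rhat_threshold: float = 1.05
    check_convergence: bool = True


@dataclass
class HierFit:
    """Posterior draws and summaries for one group."""

    label: str
    draws: pd.DataFrame  # per-draw mu_d, sigma_d, tau_d, mu_theta, kappa,
    # tau_theta, eff_sd_d, eff_circ_sd
    rhat: dict
    ess: dict
    n_individuals: int
    n_locations: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in ("mu_d", "sigma_d", "tau_d", "eff_sd_d",
                    "kappa", "tau_theta", "eff_circ_sd"):
            v = self.draws[col].to_numpy()
            rows.append((col, v.mean(), *np.percentile(v, [2.5, 97.5])))
        m, lo, hi = _circular_summary(self.draws["mu_theta"].to_numpy())
        rows.append(("mu_theta", m, lo, hi))
        rows.append(
            (
                "mu_theta_deg",
                float(bearing_to_compass_degrees(m)),
                float(bearing_to_compass_degrees(lo)),
                float(bearing_to_compass_degrees(hi)),
            )
        )
        return pd.DataFrame(rows, columns=["parameter", "mean", "q2.5", "q97.5"])


def _circular_summary(draws: np.ndarray):
    """Posterior mean and central 95% interval of an angle, wrap-safe."""
    centre = circular_mean(draws)
    dev = wrap_angle(draws - centre)
    return (
        float(wrap_angle(centre + dev.mean())),
        float(wrap_angle(centre + np.percentile(dev, 2.5))),
        float(wrap_angle(centre + np.percentile(dev, 97.5))),
    )


# ---------------------------------------------------------------------------
# marginal log-likelihoods (random intercepts integrated out)


def _distance_loglik(mu, sigma, tau, n_i, ybar_i, ss_i):
    """Marginal Normal likelihood per individual (intercept integrated)."""
    s2 = sigma**2
    v = s2 + n_i * tau**2
    return -0.5 * np.sum(
        n_i * np.log(2 * np.pi)
        + (n_i - 1) * np.log(s2)
        + np.log(v)
        + ss_i / s2
        + n_i * (ybar_i - mu) ** 2 / v
    )


def _log_bessel_i0(kappa):
    return np.log(special.ive(0, kappa)) + kappa


def _angle_loglik(mu, kappa, tau, n_i, c0_i, s0_i):
    """Von Mises likelihood with Normal intercepts via Gauss–Hermite.

    Uses the per-individual sufficient statistics C_i = Σ_j cos θ_ij,
    S_i = Σ_j sin θ_ij only, so the cost is n_individuals × n_nodes.
    """
    # rotate sufficient stats by mu
    c_i = c0_i * np.cos(mu) + s0_i * np.sin(mu)
    s_i = s0_i * np.cos(mu) - c0_i * np.sin(mu)
    a_k = np.sqrt(2.0) * tau * _GH_NODES  # (K,)
    # (n_ind, K): sum_j cos(theta_ij - mu - a_k)
    proj = c_i[:, None] * np.cos(a_k)[None, :] + s_i[:, None] * np.sin(a_k)[None, :]
    logint = special.logsumexp(_LOG_GH_W[None, :] + kappa * proj, axis=1)
    return float(
        np.sum(logint - n_i * (np.log(2 * np.pi) + _log_bessel_i0(kappa)))
    )


def _half_normal_logpdf(x, scale):
    return -0.5 * (x / scale) ** 2  # up to a constant; folding handled by |·|


def fit_hier(
    locations: pd.DataFrame,
    label: str = "",
    priors: PriorSpec | None = None,
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
) -> HierFit:
    """Fit the distance and angle components for one group of locations.

    ``locations`` needs columns ``individual_id``, ``distance_km`` and
    ``angle_rad``.  Callers analysing island-roosting colonies normally
    pass only off-island locations (the overwhelming share of foraging);
    see :func:`fit_groups`.
    """
    pr = priors or PriorSpec()
    cfg = sampler_config or SamplerConfig()
    if len(locations) < 3:
        raise ValueError("need at least 3 foraging locations")
    ind, ind_idx = np.unique(locations["individual_id"], return_inverse=True)
    if len(ind) < 2:
        warnings.warn(
            "single individual: individual-level variability (τ) is "
            "prior-dominated",
            stacklevel=2,
        )
    d = locations["distance_km"].to_numpy(float)
    theta = locations["angle_rad"].to_numpy(float)

    n_i = np.bincount(ind_idx).astype(float)
    ybar_i = np.bincount(ind_idx, weights=d) / n_i
    ss_i = np.bincount(ind_idx, weights=(d - ybar_i[ind_idx]) ** 2)
    c0_i = np.bincount(ind_idx, weights=np.cos(theta))
    s0_i = np.bincount(ind_idx, weights=np.sin(theta))

    log2pi = np.log(2 * np.pi)

    def logpost_d(p):
        """Vectorized over walkers: p has shape (W, 3)."""
        p = np.atleast_2d(p)
        mu, sigma, tau = p[:, 0], np.abs(p[:, 1]), np.abs(p[:, 2])
        s2 = np.maximum(sigma, 1e-6)[:, None] ** 2  # (W, 1)
        v = s2 + n_i[None, :] * tau[:, None] ** 2
        ll = -0.5 * np.sum(
            n_i * log2pi
            + (n_i - 1)[None, :] * np.log(s2)
            + np.log(v)
            + ss_i[None, :] / s2
            + n_i[None, :] * (ybar_i[None, :] - mu[:, None]) ** 2 / v,
            axis=1,
        )
        lp = (
            -0.5 * ((mu - pr.mu_d_loc) / pr.mu_d_scale) ** 2
            + _half_normal_logpdf(sigma, pr.sigma_d_scale)
            + _half_normal_logpdf(tau, pr.tau_d_scale)
        )
        out = lp + ll
        out[sigma < 1e-6] = -np.inf
        return out if len(out) > 1 else float(out[0])

    def logpost_a(p):
        p = np.atleast_2d(p)
        mu, kappa, tau = p[:, 0], np.abs(p[:, 1]), np.abs(p[:, 2])
        kap = np.clip(kappa, 1e-6, 1e4)
        c_i = c0_i[None, :] * np.cos(mu)[:, None] + s0_i[None, :] * np.sin(mu)[:, None]
        s_i = s0_i[None, :] * np.cos(mu)[:, None] - c0_i[None, :] * np.sin(mu)[:, None]
        a_k = np.sqrt(2.0) * tau[:, None] * _GH_NODES[None, :]  # (W, K)
        proj = (
            c_i[:, :, None] * np.cos(a_k)[:, None, :]
            + s_i[:, :, None] * np.sin(a_k)[:, None, :]
        )  # (W, I, K)
        logint = special.logsumexp(
            _LOG_GH_W[None, None, :] + kap[:, None, None] * proj, axis=2
        )
        ll = np.sum(logint, axis=1) - n_i.sum() * (log2pi + _log_bessel_i0(kap))
        lp = (
            -0.5 * (mu / pr.mu_theta_scale) ** 2
            + _half_normal_logpdf(kappa, pr.kappa_scale)
            + _half_normal_logpdf(tau, pr.tau_theta_scale)
        )
        out = lp + ll
        out[(kappa < 1e-6) | (kappa > 1e4)] = -np.inf
        return out if len(out) > 1 else float(out[0])

    rng = np.random.default_rng([int(seed), 2971]) if np.ndim(seed) == 0 else np.random.default_rng(seed)

    # data-driven initial ball
    mu0_d = d.mean()
    sig0 = max(d.std(ddof=1) if len(d) > 1 else 1.0, 0.5)
    tau0 = max(np.std(ybar_i, ddof=1) if len(ybar_i) > 1 else 0.5, 0.3)
    mu0_t = circular_mean(theta)
    r = np.clip(np.hypot(np.cos(theta).mean(), np.sin(theta).mean()), 1e-3, 0.999)
    kappa0 = float(np.clip(r * (2 - r**2) / (1 - r**2), 0.5, 50.0))

    chains_d = _run_ensemble(logpost_d, [mu0_d, sig0, tau0], cfg, rng)
    chains_a = _run_ensemble(logpost_a, [mu0_t, kappa0, 0.3], cfg, rng)

    rhat, ess = {}, {}
    names_d = ["mu_d", "sigma_d", "tau_d"]
    names_a = ["mu_theta", "kappa", "tau_theta"]
    for chains, names in ((chains_d, names_d), (chains_a, names_a)):
        for j, name in enumerate(names):
            arr = np.abs(chains[:, :, j]) if name in (
                "sigma_d", "tau_d", "kappa", "tau_theta") else chains[:, :, j]
            rhat[name] = float(az.rhat(arr))
            ess[name] = float(az.ess(arr))
    if cfg.check_convergence:
        bad = {k: v for k, v in rhat.items() if v > cfg.rhat_threshold}
        if bad:
            raise ConvergenceError(f"split-R̂ above {cfg.rhat_threshold}: {bad}")

    flat_d = chains_d.reshape(-1, 3)
    flat_a = chains_a.reshape(-1, 3)
    draws = pd.DataFrame(
        {
            "mu_d": flat_d[:, 0],
            "sigma_d": np.abs(flat_d[:, 1]),
            "tau_d": np.abs(flat_d[:, 2]),
            "mu_theta": wrap_angle(flat_a[:, 0]),
            "kappa": np.abs(flat_a[:, 1]),
            "tau_theta": np.abs(flat_a[:, 2]),
        }
    )
    draws["eff_sd_d"] = np.sqrt(draws["sigma_d"] ** 2 + draws["tau_d"] ** 2)
    draws["eff_circ_sd"] = effective_circular_sd_closed_form(
        draws["kappa"].to_numpy(), draws["tau_theta"].to_numpy()
    )
    return HierFit(
        label=label,
        draws=draws,
        rhat=rhat,
        ess=ess,
        n_individuals=len(ind),
        n_locations=len(locations),
    )


def _run_ensemble(logpost, centre, cfg: SamplerConfig, rng) -> np.ndarray:
    ndim = len(centre)
    centre = np.asarray(centre, float)
    p0 = centre[None, :] * (1 + 0.1 * rng.standard_normal((cfg.n_walkers, ndim)))
    p0 += 0.05 * rng.standard_normal((cfg.n_walkers, ndim))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        cfg.n_walkers, ndim, logpost, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2**31 - 1))
    ).get_state()
    sampler.run_mcmc(
        p0, cfg.n_burn + cfg.n_steps, progress=False, skip_initial_state_check=True
    )
    chain = sampler.get_chain(discard=cfg.n_burn, thin=cfg.thin)
    return np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)


# ---------------------------------------------------------------------------
# effective circular SD


def effective_circular_sd(
    kappa: float, tau_theta: float, n_mc: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo circular SD of the marginal angle predictive.

    Simulates a_i ~ Normal(0, τ_θ) and θ ~ VonMises(a_i, κ) and returns
    sqrt(−2 ln R̄) of the pooled sample.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, tau_theta, size=n_mc) if tau_theta > 0 else np.zeros(n_mc)
    theta = rng.vonmises(a, kappa)
    rbar = np.hypot(np.cos(theta).mean(), np.sin(theta).mean())
    return float(np.sqrt(-2.0 * np.log(max(rbar, 1e-300))))


def effective_circular_sd_closed_form(kappa, tau_theta):
    """Closed form of the same quantity: sqrt(−2 ln A(κ) + τ²).

    The marginal mean resultant length of θ = a + ε with a ~ N(0, τ) and
    ε ~ VonMises(0, κ) factorizes as A(κ)·exp(−τ²/2), where A(κ) =
    I₁(κ)/I₀(κ).
    """
    kappa = np.asarray(kappa, float)
    a_k = special.ive(1, kappa) / special.ive(0, kappa)
    out = np.sqrt(-2.0 * np.log(np.clip(a_k, 1e-300, 1.0)) + np.asarray(tau_theta, float) ** 2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# contrasts and group driver


def contrasts(fit_a: HierFit, fit_b: HierFit) -> pd.DataFrame:
    """Draw-wise posterior contrasts (a − b) between two fits.

    Angular means are differenced on the circle (wrapped to (−π, π]).
    If draw counts differ the longer set is thinned with a warning.
    """
    na, nb = len(fit_a.draws), len(fit_b.draws)
    n = min(na, nb)
    if na != nb:
        warnings.warn(f"draw counts differ ({na} vs {nb}); using first {n}",
                      stacklevel=2)
    da = fit_a.draws.iloc[:n]
    db = fit_b.draws.iloc[:n]
    rows = []
    for col in ("mu_d", "eff_sd_d", "tau_d", "eff_circ_sd", "tau_theta", "kappa"):
        diff = da[col].to_numpy() - db[col].to_numpy()
        rows.append((col, diff.mean(), *np.percentile(diff, [2.5, 97.5])))
    dtheta = wrap_angle(da["mu_theta"].to_numpy() - db["mu_theta"].to_numpy())
    rows.append(("mu_theta", dtheta.mean(), *np.percentile(dtheta, [2.5, 97.5])))
    return pd.DataFrame(rows, columns=["parameter", "mean", "q2.5", "q97.5"])


def fit_groups(
    locations: pd.DataFrame,
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
    off_island_only: bool = True,
) -> dict[tuple, HierFit]:
    """Fit every colony × season × provenance group in a location table."""
    df = locations
    if off_island_only and "on_home_island" in df.columns:
        df = df[~df["on_home_island"].astype(bool)]
    fits = {}
    for gi, (key, grp) in enumerate(
        sorted(df.groupby(["colony_id", "season", "provenance"]))
    ):
        if grp["individual_id"].nunique() < 2 or len(grp) < 3:
            warnings.warn(f"group {key}: too little data; skipped", stacklevel=2)
            continue
        fits[key] = fit_hier(
            grp,
            label="/".join(key),
            sampler_config=sampler_config,
            seed=[int(seed), gi],
        )
    return fits


def prior_predictive_distances(
    priors: PriorSpec | None = None, n: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Draw observation-level distances from the prior (sanity check)."""
    pr = priors or PriorSpec()
    rng = np.random.default_rng(seed)
    mu = rng.normal(pr.mu_d_loc, pr.mu_d_scale, size=n)
    sigma = np.abs(rng.normal(0, pr.sigma_d_scale, size=n))
    tau = np.abs(rng.normal(0, pr.tau_d_scale, size=n))
    b = rng.normal(0, tau)
    return rng.normal(mu + b, sigma)
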