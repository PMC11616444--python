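"""Brute-force oracles kept independent of the library's recursions."""

import itertools

import numpy as np
from scipy import stats


def _emission_prob(kernel, state, step, angle):
    p = 1.0
    if np.isfinite(step):
        p *= stats.gamma.pdf(step, kernel.gamma_shape[state],
                             scale=kernel.gamma_scale[state])
    if np.isfinite(angle):
        rho = kernel.wc_rho[state]
        mu = kernel.wc_mu[state]
        p *= (1 / (2 * np.pi)) * (1 - rho**2) / (
            1 + rho**2 - 2 * rho * np.cos(angle - mu)
        )
    return p


def brute_force_loglik(kernel, steps, angles):
    """Sum over every state path by explicit enumeration."""
    T = len(steps)
    n = kernel.n_states
    total = 0.0
    for path in itertools.product(range(n), repeat=T):
        p = kernel.delta[path[0]] * _emission_prob(kernel, path[0], steps[0], angles[0])
        for t in range(1, T):
            p *= kernel.tmat[path[t - 1], path[t]] * _emission_prob(
                kernel, path[t], steps[t], angles[t]
            )
        total += p
    return np.log(total)


def brute_force_viterbi(kernel, steps, angles):
    """Most probable state path by explicit enumeration."""
    T = len(steps)
    n = kernel.n_states
    best, best_p = None, -np.inf
    for path in itertools.product(range(n), repeat=T):
        p = kernel.delta[path[0]] * _emission_prob(kernel, path[0], steps[0], angles[0])
        for t in range(1, T):
            p *= kernel.tmat[path[t - 1], path[t]] * _emission_prob(
                kernel, path[t], steps[t], angles[t]
            )
        if p > best_p:
            best_p, best = p, path
    return np.array(best)


def random_kernel(rng, n_states=2):
    from batforage.hmm import MovementKernel

    shape = rng.uniform(0.5, 5.0, n_states)
    scale = rng.uniform(20.0, 800.0, n_states)
    mu = rng.uniform(-np.pi, np.pi, n_states)
    rho = rng.uniform(0.0, 0.95, n_states)
    tmat = rng.dirichlet(np.ones(n_states) * 2, size=n_states)
    return MovementKernel(shape, scale, mu, rho, tmat)


def random_observations(rng, T):
    """Steps/angles with occasional missing entries."""
    steps = rng.gamma(2.0, 300.0, size=T)
    angles = rng.uniform(-np.pi, np.pi, size=T)
    miss = rng.uniform(size=T) < 0.2
    steps[miss] = np.nan
    angles[miss] = np.nan
    angles[rng.uniform(size=T) < 0.15] = np.nan
    return steps, angles


def series_from_obs(steps, angles, interval=120.0):
    """Wrap raw observation arrays as a StepSeries (slot 0 is empty)."""
    import pandas as pd

    from batforage.preprocessing import StepSeries

    T = len(steps)
    times = pd.DatetimeIndex(
        pd.Timestamp("2022-03-01 23:00", tz="UTC")
        + pd.to_timedelta(np.arange(T + 1) * interval, "s")
    )
    # x/y are placeholders; likelihood code reads only step/angle
    return StepSeries(
        track=None,
        interval=interval,
        times=times,
        x=np.zeros(T + 1),
        y=np.zeros(T + 1),
        step=np.concatenate([[np.nan], steps]),
        angle=np.concatenate([[np.nan], angles]),
    )
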