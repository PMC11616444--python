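"""Hidden Markov segmentation of step/turn series into behavioural states.

The model is the standard movement-ecology construction: per hidden state
a gamma distribution for step length and a wrapped Cauchy distribution for
turning angle, a homogeneous transition matrix Γ, and the stationary
distribution of Γ as the initial distribution.  With two states the
biological reading is "foraging" (short, tortuous movement, including any
resting) versus "commuting" (long, directed movement); states are always
relabelled after fitting so that state 1 has the smaller mean step.

Missing observations (gaps inserted during regularization) contribute
emission probability 1, i.e. the forward recursion takes a pure transition
step across them.

Fitting is by direct numerical maximization of the pooled forward
log-likelihood over all series, with log/logit transforms of the
constrained parameters, best of ``n_restarts`` random initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats

from .preprocessing import StepSeries


class DegeneracyError(ValueError):
    """Raised when the data cannot identify a non-degenerate model."""


class FitError(RuntimeError):
    pass


FORAGING, COMMUTING = 0, 1  # state indices after canonical relabelling


def wrapped_cauchy_density(phi, mu: float, rho: float):
    """Wrapped Cauchy density on (−π, π].

    ``f(φ) = (1/2π) · (1 − ρ²) / (1 + ρ² − 2ρ cos(φ − μ))`` with location
    μ and concentration ρ ∈ [0, 1); ρ = 0 is the circular uniform.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"wrapped Cauchy concentration must be in [0,1), got {rho}")
    phi = np.asarray(phi, dtype=float)
    out = (1.0 / (2.0 * np.pi)) * (1.0 - rho**2) / (
        1.0 + rho**2 - 2.0 * rho * np.cos(phi - mu)
    )
    return out if out.ndim else float(out)


def sample_wrapped_cauchy(mu: float, rho: float, size, rng) -> np.ndarray:
    """Inverse-CDF sampling of the wrapped Cauchy (ρ = 0 → uniform)."""
    u = rng.uniform(size=size)
    if rho == 0.0:
        draws = 2.0 * np.pi * (u - 0.5)
    else:
        draws = 2.0 * np.arctan(((1.0 - rho) / (1.0 + rho)) * np.tan(np.pi * (u - 0.5)))
    return np.mod(mu + draws + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class MovementKernel:
    """Emission and transition parameters of an N-state movement HMM.

    Arrays are indexed by state: gamma shape/scale (step length, metres
    per interval), wrapped Cauchy location/concentration (turning angle),
    an N×N transition matrix and initial distribution.
    """

    gamma_shape: np.ndarray
    gamma_scale: np.ndarray
    wc_mu: np.ndarray
    wc_rho: np.ndarray
    tmat: np.ndarray
    delta: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("gamma_shape", "gamma_scale", "wc_mu", "wc_rho"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        self.tmat = np.atleast_2d(np.asarray(self.tmat, float))
        if not np.allclose(self.tmat.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.gamma_shape <= 0) or np.any(self.gamma_scale <= 0):
            raise ValueError("gamma parameters must be positive")
        if np.any((self.wc_rho < 0) | (self.wc_rho >= 1)):
            raise ValueError("wrapped Cauchy rho must be in [0,1)")
        if self.delta is None:
            self.delta = stationary_distribution(self.tmat)
        self.delta = np.asarray(self.delta, float)
        if not np.isclose(self.delta.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.gamma_shape)

    @property
    def mean_step(self) -> np.ndarray:
        return self.gamma_shape * self.gamma_scale

    def relabelled_by_mean_step(self) -> "MovementKernel":
        """Canonical state order: ascending mean step (1 = foraging)."""
        order = np.argsort(self.mean_step, kind="stable")
        return MovementKernel(
            gamma_shape=self.gamma_shape[order],
            gamma_scale=self.gamma_scale[order],
            wc_mu=self.wc_mu[order],
            wc_rho=self.wc_rho[order],
            tmat=self.tmat[np.ix_(order, order)],
            delta=self.delta[order],
        )


def stationary_distribution(tmat: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    n = tmat.shape[0]
    a = np.vstack([tmat.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 1e-12, None) / np.clip(pi, 1e-12, None).sum()


@dataclass
class HmmModel:
    """A fitted movement HMM: kernel plus fit metadata."""

    kernel: MovementKernel
    log_likelihood: float = np.nan
    n_parameters: int = 0
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.kernel.n_states

    @property
    def aic(self) -> float:
        return 2.0 * self.n_parameters - 2.0 * self.log_likelihood


@dataclass
class StateSequence:
    """Viterbi decoding and smoothing posteriors for one series."""

    states: np.ndarray  # decoded state per slot (canonical labels, 0-based)
    posteriors: np.ndarray  # (n_slots, n_states); NaN rows where imputed
    imputed: np.ndarray  # True where slot had no observation

    def __len__(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# emissions


def _prepared_obs(series: StepSeries) -> tuple[np.ndarray, np.ndarray]:
    """Steps/angles for slots 1..T−1 (slot 0 has no step by construction).

    Zero steps are nudged to half the minimum positive step so the gamma
    density stays finite for shape < 1.
    """
    steps = series.step[1:].copy()
    angles = series.angle[1:].copy()
    pos = steps[np.isfinite(steps) & (steps > 0)]
    if pos.size:
        steps[np.isfinite(steps) & (steps == 0.0)] = pos.min() / 2.0
    return steps, angles


def _log_emissions(kernel: MovementKernel, steps, angles) -> np.ndarray:
    """(T, N) log emission matrix; missing components contribute 0."""
    T = len(steps)
    n = kernel.n_states
    logb = np.zeros((T, n))
    step_ok = np.isfinite(steps)
    ang_ok = np.isfinite(angles)
    for s in range(n):
        if step_ok.any():
            logb[step_ok, s] += stats.gamma.logpdf(
                steps[step_ok], kernel.gamma_shape[s], scale=kernel.gamma_scale[s]
            )
        if ang_ok.any():
            logb[ang_ok, s] += np.log(
                wrapped_cauchy_density(angles[ang_ok], kernel.wc_mu[s], kernel.wc_rho[s])
            )
    if not np.all(np.isfinite(logb)):
        raise ValueError("non-finite emission log-density")
    return logb


# ---------------------------------------------------------------------------
# forward / backward / Viterbi


def _batched_loglik(kernel: MovementKernel, logb_batch: np.ndarray) -> float:
    """Scaled forward recursion over a padded batch of series.

    ``logb_batch`` is (B, T, N); padded slots carry logb = 0 (emission
    probability 1), which contributes exactly nothing to the total
    because the scaled forward weights stay normalized across a pure
    transition step.
    """
    B, T, n = logb_batch.shape
    mx = logb_batch.max(axis=2, keepdims=True)
    b = np.exp(logb_batch - mx)  # (B, T, N), max 1 per slot
    total = mx[:, :, 0].sum()
    alpha = kernel.delta[None, :] * b[:, 0, :]
    norm = alpha.sum(axis=1)
    total += np.log(norm).sum()
    alpha /= norm[:, None]
    tmat = kernel.tmat
    for t in range(1, T):
        alpha = (alpha @ tmat) * b[:, t, :]
        norm = alpha.sum(axis=1)
        if np.any(norm <= 0):
            return -np.inf
        total += np.log(norm).sum()
        alpha /= norm[:, None]
    return float(total)


def _pad_logb(kernel: MovementKernel, prepared: list) -> np.ndarray:
    """Stack per-series (T_i, N) emission matrices into one padded batch."""
    mats = [_log_emissions(kernel, s, a) for s, a in prepared]
    T = max(m.shape[0] for m in mats)
    out = np.zeros((len(mats), T, kernel.n_states))
    for i, m in enumerate(mats):
        out[i, : m.shape[0], :] = m
    return out


def log_likelihood(model: HmmModel | MovementKernel, series: StepSeries) -> float:
    """Forward-algorithm log-likelihood of one regularized series."""
    kernel = model.kernel if isinstance(model, HmmModel) else model
    steps, angles = _prepared_obs(series)
    logb = _log_emissions(kernel, steps, angles)
    return _batched_loglik(kernel, logb[None, :, :])


def decode(model: HmmModel | MovementKernel, series: StepSeries) -> StateSequence:
    """Viterbi path plus forward–backward smoothing probabilities.

    Slots with no observation at either end of a step (missing locations)
    still receive a Viterbi state via the transition structure and are
    flagged ``imputed``.  The returned arrays cover all ``n_slots`` grid
    slots; slot 0 (no step defined) inherits the first decoded state.
    """
    kernel = model.kernel if isinstance(model, HmmModel) else model
    steps, angles = _prepared_obs(series)
    logb = _log_emissions(kernel, steps, angles)
    with np.errstate(divide="ignore"):
        log_tmat = np.log(kernel.tmat)
        log_delta = np.log(kernel.delta)
    T, n = logb.shape

    # Viterbi
    v = log_delta + logb[0]
    back = np.zeros((T, n), dtype=int)
    for t in range(1, T):
        cand = v[:, None] + log_tmat
        back[t] = np.argmax(cand, axis=0)
        v = cand[back[t], np.arange(n)] + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(v))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]

    # forward-backward in log space
    la = np.empty((T, n))
    la[0] = log_delta + logb[0]
    for t in range(1, T):
        la[t] = special.logsumexp(la[t - 1][:, None] + log_tmat, axis=0) + logb[t]
    lb = np.zeros((T, n))
    for t in range(T - 2, -1, -1):
        lb[t] = special.logsumexp(log_tmat + (logb[t + 1] + lb[t + 1])[None, :], axis=1)
    post = la + lb
    post -= special.logsumexp(post, axis=1, keepdims=True)
    post = np.exp(post)

    observed = np.isfinite(steps) | np.isfinite(angles)
    states = np.concatenate([[path[0]], path])
    posteriors = np.vstack([post[0], post])
    imputed = np.concatenate([[not observed[0] if T else True], ~observed])
    return StateSequence(states=states, posteriors=posteriors, imputed=imputed)


# ---------------------------------------------------------------------------
# fitting


def _pack(kernel: MovementKernel) -> np.ndarray:
    n = kernel.n_states
    parts = [
        np.log(kernel.gamma_shape),
        np.log(kernel.gamma_scale),
        kernel.wc_mu,
        special.logit(np.clip(kernel.wc_rho, 1e-6, 1 - 1e-6)),
    ]
    if n > 1:
        # off-diagonal logits, row-wise multinomial reference = diagonal
        offdiag = []
        for i in range(n):
            row = kernel.tmat[i]
            for jj in range(n):
                if jj != i:
                    offdiag.append(np.log(max(row[jj], 1e-10) / max(row[i], 1e-10)))
        parts.append(np.array(offdiag))
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, n: int) -> MovementKernel:
    shp = np.exp(theta[0:n])
    scl = np.exp(theta[n : 2 * n])
    mu = np.mod(theta[2 * n : 3 * n] + np.pi, 2 * np.pi) - np.pi
    rho = special.expit(theta[3 * n : 4 * n])
    if n > 1:
        off = theta[4 * n :]
        tmat = np.empty((n, n))
        k = 0
        for i in range(n):
            logits = np.zeros(n)
            for jj in range(n):
                if jj != i:
                    logits[jj] = off[k]
                    k += 1
            row = np.exp(logits - special.logsumexp(logits))
            tmat[i] = row
    else:
        tmat = np.ones((1, 1))
    return MovementKernel(shp, scl, mu, rho, tmat)


def n_hmm_parameters(n_states: int) -> int:
    return 4 * n_states + n_states * (n_states - 1)


def _random_init(series_list, n_states, rng) -> MovementKernel:
    steps = np.concatenate([_prepared_obs(s)[0] for s in series_list])
    steps = steps[np.isfinite(steps) & (steps > 0)]
    qs = np.quantile(steps, np.linspace(0.15, 0.85, n_states))
    qs = qs * rng.uniform(0.6, 1.6, size=n_states)
    shape = rng.uniform(0.8, 3.0, size=n_states)
    scale = qs / shape
    rho = rng.uniform(0.05, 0.9, size=n_states)
    mu = np.zeros(n_states)
    stay = rng.uniform(0.7, 0.97)
    tmat = np.full((n_states, n_states), (1 - stay) / max(n_states - 1, 1))
    np.fill_diagonal(tmat, stay if n_states > 1 else 1.0)
    return MovementKernel(shape, scale, mu, rho, tmat)


def fit(
    series_list: list[StepSeries],
    n_states: int = 2,
    n_restarts: int = 5,
    seed: int | None = None,
    maxiter: int = 400,
) -> HmmModel:
    """Maximum-likelihood HMM fit pooled over one or more series.

    Parameters are shared across series; each series starts from the
    stationary distribution of Γ.  The best of ``n_restarts`` random
    initializations is returned, with states relabelled so state 1 is the
    short-step ("foraging") state.
    """
    if isinstance(series_list, StepSeries):
        series_list = [series_list]
    n_obs = sum(int(np.isfinite(s.step[1:]).sum()) for s in series_list)
    if n_obs < 10:
        raise InsufficientObservations(f"need ≥ 10 observed steps, got {n_obs}")
    all_steps = np.concatenate([_prepared_obs(s)[0] for s in series_list])
    all_steps = all_steps[np.isfinite(all_steps)]
    if np.ptp(all_steps) < 1e-9:
        raise DegeneracyError("all step lengths identical; gamma scale degenerate")

    prepared = [_prepared_obs(s) for s in series_list]
    rng = np.random.default_rng(seed)

    def nll(theta):
        try:
            kernel = _unpack(theta, n_states)
            logb = _pad_logb(kernel, prepared)
        except ValueError:
            return 1e12
        total = _batched_loglik(kernel, logb)
        return -total if np.isfinite(total) else 1e12

    best = None
    for _ in range(max(1, n_restarts)):
        theta0 = _pack(_random_init(series_list, n_states, rng))
        res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise FitError("all restarts failed to produce a finite likelihood")

    kernel = _unpack(best.x, n_states).relabelled_by_mean_step()
    return HmmModel(
        kernel=kernel,
        log_likelihood=-float(best.fun),
        n_parameters=n_hmm_parameters(n_states),
        converged=bool(best.success),
        extra={"n_series": len(series_list), "n_obs": n_obs},
    )


class InsufficientObservations(ValueError):
    pass


def simulate_series(
    kernel: MovementKernel,
    n_slots: int,
    seed,
    interval: float = 120.0,
) -> tuple[StepSeries, np.ndarray]:
    """Sample a gap-free step/turn series directly from an HMM kernel.

    Returns the series and the hidden state path (0-based labels).  The
    positions are reconstructed by dead reckoning so the series is fully
    consistent with its own steps and turning angles.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    states = np.empty(n_slots, dtype=int)
    states[0] = int(rng.choice(kernel.n_states, p=kernel.delta))
    for t in range(1, n_slots):
        states[t] = int(rng.choice(kernel.n_states, p=kernel.tmat[states[t - 1]]))

    step = np.full(n_slots, np.nan)
    angle = np.full(n_slots, np.nan)
    x = np.zeros(n_slots)
    y = np.zeros(n_slots)
    heading = rng.uniform(-np.pi, np.pi)
    for t in range(1, n_slots):
        s = states[t]
        if t >= 2:
            turn = float(sample_wrapped_cauchy(kernel.wc_mu[s], kernel.wc_rho[s], 1, rng)[0])
            angle[t] = turn
            heading = np.mod(heading + turn + np.pi, 2 * np.pi) - np.pi
        step[t] = rng.gamma(kernel.gamma_shape[s], kernel.gamma_scale[s])
        x[t] = x[t - 1] + step[t] * np.cos(heading)
        y[t] = y[t - 1] + step[t] * np.sin(heading)

    times = pd.DatetimeIndex(
        pd.Timestamp("2022-03-01 23:00", tz="UTC")
        + pd.to_timedelta(np.arange(n_slots) * interval, "s")
    )
    return (
        StepSeries(
            track=None, interval=interval, times=times, x=x, y=y,
            step=step, angle=angle,
        ),
        states,
    )


def kernel_to_dict(kernel: MovementKernel) -> dict:
    return {
        "gamma_shape": kernel.gamma_shape.tolist(),
        "gamma_scale": kernel.gamma_scale.tolist(),
        "wc_mu": kernel.wc_mu.tolist(),
        "wc_rho": kernel.wc_rho.tolist(),
        "tmat": kernel.tmat.tolist(),
        "delta": kernel.delta.tolist(),
    }


def kernel_from_dict(d: dict) -> MovementKernel:
    return MovementKernel(
        gamma_shape=np.array(d["gamma_shape"]),
        gamma_scale=np.array(d["gamma_scale"]),
        wc_mu=np.array(d["wc_mu"]),
        wc_rho=np.array(d["wc_rho"]),
        tmat=np.array(d["tmat"]),
        delta=np.array(d.get("delta")) if d.get("delta") is not None else None,
    )
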