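"""Stochastic competition model of five cell lineages.

Each lineage *i* is described by its outer (marginal) cell count ``O_i`` and
inner cell count ``I_i``.  Outer cells divide at baseline rate ``r``; a
division is anticlinal or periclinal with equal probability, so half of the
outer divisions add an outer cell and half add an inner cell.  Inner cells
divide at the reduced rate ``gamma*r`` and always add inner cells.  Division
activity of a lineage is scaled by a piecewise Hill-type inhibition factor
``h_i`` in (0, 1] that depends on the marginal cell counts of the other
lineages (see :func:`division_multipliers`).  The resulting system of SDEs,

    dO_i = 1/2 r h_i O_i dt + sigma g(O_i) dW_i
    dI_i = (1/2 r h_i O_i + gamma r h_i I_i) dt + sigma g(I_i) dW'_i

is integrated with the Euler-Maruyama scheme; counts are real-valued and
clamped at zero after every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import InvalidInputError, ModelParams

__all__ = [
    "LineageState",
    "LineageTrajectory",
    "NumericalFailureError",
    "leading_lineage",
    "division_multipliers",
    "drift",
    "em_step",
    "simulate_trajectory",
    "uninhibited_outer",
    "uninhibited_inner",
    "uninhibited_total",
]


class NumericalFailureError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass
class LineageState:
    """Per-lineage outer/inner cell counts at one time point."""

    outer: np.ndarray
    inner: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.outer = np.asarray(self.outer, dtype=float)
        self.inner = np.asarray(self.inner, dtype=float)
        if self.outer.shape != self.inner.shape or self.outer.ndim != 1:
            raise InvalidInputError("outer and inner must be 1-D and congruent")
        if np.any(self.outer < 0) or np.any(self.inner < 0):
            raise InvalidInputError("cell counts must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.outer + self.inner


@dataclass
class LineageTrajectory:
    """One stochastic realization on the full integration grid.

    ``outer`` and ``inner`` have shape (n_times, n_lineages) and align with
    ``times``; ``seed`` records the RNG seed that produced the run.
    """

    times: np.ndarray
    outer: np.ndarray
    inner: np.ndarray
    seed: int
    params: ModelParams = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def total(self) -> np.ndarray:
        return self.outer + self.inner

    @property
    def n_lineages(self) -> int:
        return self.outer.shape[1]

    def state_at(self, index: int) -> LineageState:
        return LineageState(
            outer=self.outer[index].copy(),
            inner=self.inner[index].copy(),
            t=float(self.times[index]),
        )


def leading_lineage(outer_counts, alpha: float):
    """Index of the lineage leading all others by at least ``alpha`` marginal
    cells, or ``None`` if no lineage holds that margin.

    With ``alpha == 0`` a tie at the maximum is broken toward the lowest
    index.  Lead status carries no hysteresis; callers re-evaluate each step.
    """
    outer = np.asarray(outer_counts, dtype=float)
    if outer.ndim != 1 or outer.size < 2:
        raise InvalidInputError("need at least two lineages")
    if np.any(outer < 0):
        raise InvalidInputError("marginal counts must be non-negative")
    if alpha < 0:
        raise InvalidInputError("alpha must be >= 0")
    order = np.argsort(outer)[::-1]
    top, second = outer[order[0]], outer[order[1]]
    if top - second >= alpha:
        # lowest index among the (possibly tied) maxima
        return int(np.argmax(outer))
    return None


def _hill(x, K: float, m: float):
    return K**m / (K**m + np.asarray(x, dtype=float) ** m)


def division_multipliers(outer_counts, params: ModelParams) -> np.ndarray:
    """Inhibition factor h_i in (0, 1] for every lineage.

    Threshold version: without a leading lineage all factors are 1; with a
    lead, the lead keeps factor 1 and every other lineage is suppressed by
    ``K^m / (K^m + O_lead^m)``.  Mutual version: each lineage is suppressed
    by the pooled marginal count of all the others,
    ``K^m / (K^m + (sum_{j != i} O_j)^m)``.
    """
    outer = np.asarray(outer_counts, dtype=float)
    if np.any(outer < 0):
        raise InvalidInputError("marginal counts must be non-negative")
    K, m = params.K_hill, params.m_hill
    if params.version == "threshold":
        factors = np.ones_like(outer)
        lead = leading_lineage(outer, params.alpha)
        if lead is not None:
            factors[:] = _hill(outer[lead], K, m)
            factors[lead] = 1.0
        return factors
    others = outer.sum() - outer
    return _hill(others, K, m)


def drift(state: LineageState, multipliers, params: ModelParams):
    """Deterministic rates (dO/dt, dI/dt) for every lineage.

    Anticlinal outer divisions (probability 1/2) add an outer cell, periclinal
    outer divisions add an inner cell, and inner divisions (rate gamma*r) add
    inner cells; the lineage's inhibition factor scales all of its division
    terms.
    """
    h = np.asarray(multipliers, dtype=float)
    outer_div = 0.5 * params.r * h * state.outer
    d_outer = outer_div
    d_inner = outer_div + params.gamma * params.r * h * state.inner
    return d_outer, d_inner


def _diffusion(x: np.ndarray, noise_model: str) -> np.ndarray:
    if noise_model == "multiplicative":
        return x
    if noise_model == "additive":
        return np.ones_like(x)
    return np.sqrt(x)  # demographic


def em_step(state: LineageState, params: ModelParams, noise_draws) -> LineageState:
    """One Euler-Maruyama update.

    ``noise_draws`` holds one standard-normal value per state component,
    shape (n_lineages, 2) with column 0 feeding the outer equation and
    column 1 the inner equation.  Components are clamped at 0 from below.
    """
    z = np.asarray(noise_draws, dtype=float)
    if z.shape != (state.outer.size, 2):
        raise InvalidInputError(
            f"noise_draws must have shape ({state.outer.size}, 2), got {z.shape}"
        )
    h = division_multipliers(state.outer, params)
    d_outer, d_inner = drift(state, h, params)
    sqdt = np.sqrt(params.dt)
    outer = (
        state.outer
        + params.dt * d_outer
        + params.sigma * _diffusion(state.outer, params.noise_model) * sqdt * z[:, 0]
    )
    inner = (
        state.inner
        + params.dt * d_inner
        + params.sigma * _diffusion(state.inner, params.noise_model) * sqdt * z[:, 1]
    )
    outer = np.maximum(outer, 0.0)
    inner = np.maximum(inner, 0.0)
    t_new = state.t + params.dt
    if not (np.all(np.isfinite(outer)) and np.all(np.isfinite(inner))):
        raise NumericalFailureError(f"non-finite state at t={t_new:.3f} h")
    return LineageState(outer=outer, inner=inner, t=t_new)


def _multipliers_batch(outer: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorized :func:`division_multipliers` over axis 0 (simulations)."""
    K, m = params.K_hill, params.m_hill
    if params.version == "threshold":
        part = np.partition(outer, -2, axis=1)
        top, second = part[:, -1], part[:, -2]
        has_lead = (top - second) >= params.alpha
        lead_idx = np.argmax(outer, axis=1)
        factors = np.ones_like(outer)
        if np.any(has_lead):
            rows = np.nonzero(has_lead)[0]
            o_lead = outer[rows, lead_idx[rows]]
            factors[rows, :] = _hill(o_lead, K, m)[:, None]
            factors[rows, lead_idx[rows]] = 1.0
        return factors
    others = outer.sum(axis=1, keepdims=True) - outer
    return _hill(others, K, m)


def _simulate_batch(params: ModelParams, seeds) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one trajectory per seed, vectorized across simulations.

    Per-seed noise is drawn from ``numpy.random.default_rng(seed)`` as a
    single block, so a batch of size one reproduces the scalar path
    bit-for-bit.

    Returns (times, outer, inner) with outer/inner of shape
    (n_seeds, n_times, n_lineages).
    """
    seeds = list(seeds)
    n_sims = len(seeds)
    n, steps = params.n_lineages, params.n_steps
    z = np.empty((n_sims, steps, n, 2))
    for k, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        z[k] = rng.standard_normal((steps, n, 2))

    times = np.linspace(0.0, params.n_steps * params.dt, params.n_steps + 1)
    outer = np.empty((n_sims, steps + 1, n))
    inner = np.empty((n_sims, steps + 1, n))
    O = np.ones((n_sims, n))
    I = np.zeros((n_sims, n))
    outer[:, 0], inner[:, 0] = O, I

    r, gamma, sigma, dt = params.r, params.gamma, params.sigma, params.dt
    sqdt = np.sqrt(dt)
    # overflow is detected explicitly below and reported with the seed
    with np.errstate(over="ignore", invalid="ignore"):
        for s in range(steps):
            h = _multipliers_batch(O, params)
            outer_div = 0.5 * r * h * O
            d_outer = outer_div
            d_inner = outer_div + gamma * r * h * I
            O = O + dt * d_outer + sigma * _diffusion(O, params.noise_model) * sqdt * z[:, s, :, 0]
            I = I + dt * d_inner + sigma * _diffusion(I, params.noise_model) * sqdt * z[:, s, :, 1]
            O = np.maximum(O, 0.0)
            I = np.maximum(I, 0.0)
            if not (np.all(np.isfinite(O)) and np.all(np.isfinite(I))):
                bad = np.nonzero(~(np.isfinite(O).all(axis=1) & np.isfinite(I).all(axis=1)))[0][0]
                raise NumericalFailureError(
                    f"non-finite state at step {s + 1} (t={times[s + 1]:.3f} h), "
                    f"seed {seeds[bad]}"
                )
            outer[:, s + 1], inner[:, s + 1] = O, I
    return times, outer, inner


def simulate_trajectory(params: ModelParams, seed: int) -> LineageTrajectory:
    """Integrate one realization from O_i = 1, I_i = 0 at t = 0 to t_end.

    Lead status and inhibition factors are recomputed at every step from the
    current state.  Fully determined by ``seed``.
    """
    times, outer, inner = _simulate_batch(params, [seed])
    return LineageTrajectory(
        times=times, outer=outer[0], inner=inner[0], seed=int(seed), params=params
    )


def uninhibited_outer(t, r: float):
    """Closed-form noise-free outer count with inhibition off: exp(r t / 2)."""
    return np.exp(r * np.asarray(t, dtype=float) / 2.0)


def uninhibited_inner(t, r: float):
    """Closed-form noise-free inner count at gamma = 1/2: (r t / 2) exp(r t / 2)."""
    t = np.asarray(t, dtype=float)
    return (r * t / 2.0) * np.exp(r * t / 2.0)


def uninhibited_total(t, r: float):
    """Closed-form noise-free total (1 + r t / 2) exp(r t / 2) at gamma = 1/2."""
    t = np.asarray(t, dtype=float)
    return (1.0 + r * t / 2.0) * np.exp(r * t / 2.0)
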