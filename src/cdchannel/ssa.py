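"""Exact stochastic simulation of the telegraph central dogma system.

Gillespie's direct method over the six reactions

    (O=0) -> (O=1)   at kON          (O=1) -> (O=0)   at kOFF
    (O=1) -> (O=1)+m at k_m           m -> 0           at kd_m * m
    m -> m + g       at k_g * m       g -> 0           at kd_g * g

realizing the exact continuous-time Markov chain of the master
equations.  The state is recorded by last-event carry-forward at fixed
grid times, which is what downstream binning and time-integration
expect.  This module doubles as the synthetic-data generator for every
study in the package (no experimental data required), including the
fluctuating-input protocol in which the input level is redrawn i.i.d.
from a prescribed distribution at every period boundary while the
transcript copy number evolves continuously across boundaries.

The event loops are numba-compiled; a given (parameters, seed) pair
produces a bitwise-identical trajectory on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import (
    InputGrid,
    PromoterControl,
    RateConstants,
    ideal_integration_trajectory,
    integration_kernel,
    promoter_rates,
)

__all__ = [
    "ReactionSystem",
    "Trajectory",
    "FluctuationProtocol",
    "FluctuationRun",
    "simulate",
    "simulate_transcription_only",
    "simulate_fluctuating_input",
    "derive_seed",
]


def derive_seed(master_seed: int, *keys: int) -> int:
    """Deterministic per-task seed below 2**31 derived from a master seed.

    Uses numpy's SeedSequence so that (master, keys) pairs give
    well-separated streams whether tasks run serially or in parallel.
    """
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class ReactionSystem:
    """Promoter control plus the four central dogma rates."""

    ctrl: PromoterControl
    rates: RateConstants
    initial_state: tuple[int, int, int] = (0, 0, 0)  # (O, m, g)

    def __post_init__(self) -> None:
        O, m, g = self.initial_state
        if O not in (0, 1) or m < 0 or g < 0:
            raise ValueError(f"invalid initial state {self.initial_state}")


@dataclass(frozen=True)
class Trajectory:
    """State samples on a uniform time grid (last-event carry-forward)."""

    times: np.ndarray  # min
    O_series: np.ndarray
    m_series: np.ndarray
    g_series: np.ndarray
    seed: int
    burn_in: float  # min, discarded before the first sample

    def __len__(self) -> int:
        return self.times.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_min": self.times,
                "O": self.O_series,
                "m": self.m_series,
                "g": self.g_series,
            }
        )


@dataclass(frozen=True)
class FluctuationProtocol:
    """Piecewise-constant input redrawn i.i.d. every tau_X minutes."""

    tau_X: float  # fluctuation period, min
    grid: InputGrid
    input_dist: np.ndarray  # probability of each grid level at a period boundary
    n_periods: int

    def __post_init__(self) -> None:
        if not self.tau_X > 0:
            raise ValueError("tau_X must be > 0")
        p = np.asarray(self.input_dist, dtype=float)
        if p.size != self.grid.n_levels or p.size == 0:
            raise ValueError("input_dist must match the input grid")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("input_dist must be a probability distribution")
        if self.n_periods < 100:
            raise ValueError("need at least 100 input periods")
        object.__setattr__(self, "input_dist", p)


@dataclass(frozen=True)
class FluctuationRun:
    """Output of the fluctuating-input protocol.

    ``g_ideal`` is shorter than ``m_series`` by the integration-kernel
    warm-up; ``paired_x`` / ``paired_x_index`` give, for each retained
    g_ideal sample, the input level active at that sample instant.
    """

    period_inputs: np.ndarray  # X drawn at each period boundary
    times: np.ndarray
    m_series: np.ndarray
    x_index_series: np.ndarray  # grid index active at each sample instant
    g_ideal: np.ndarray
    paired_x_index: np.ndarray
    paired_x: np.ndarray
    seed: int


@njit(cache=True)
def _ssa_fixed_input(
    k_on, k_off, k_m, kd_m, k_g, kd_g, O0, m0, g0, t0, sample_dt, n_samples, seed
):  # pragma: no cover - compiled
    """Direct-method SSA; record state at t0 + i*sample_dt, i = 1..n_samples."""
    np.random.seed(seed)
    O = O0
    m = m0
    g = g0
    t = 0.0
    out_O = np.empty(n_samples, np.int64)
    out_m = np.empty(n_samples, np.int64)
    out_g = np.empty(n_samples, np.int64)
    idx = 0
    next_t = t0 + sample_dt
    while idx < n_samples:
        a1 = k_on * (1 - O)
        a2 = k_off * O
        a3 = k_m * O
        a4 = kd_m * m
        a5 = k_g * m
        a6 = kd_g * g
        a_tot = a1 + a2 + a3 + a4 + a5 + a6
        if a_tot <= 0.0:
            # absorbing state: carry current state to all remaining samples
            while idx < n_samples:
                out_O[idx] = O
                out_m[idx] = m
                out_g[idx] = g
                idx += 1
            break
        t_next = t + np.random.exponential(1.0 / a_tot)
        while idx < n_samples and next_t <= t_next:
            out_O[idx] = O
            out_m[idx] = m
            out_g[idx] = g
            idx += 1
            next_t += sample_dt
        t = t_next
        u = np.random.random() * a_tot
        if u < a1:
            O = 1
        elif u < a1 + a2:
            O = 0
        elif u < a1 + a2 + a3:
            m += 1
        elif u < a1 + a2 + a3 + a4:
            m -= 1
        elif u < a1 + a2 + a3 + a4 + a5:
            g += 1
        else:
            g -= 1
    return out_O, out_m, out_g


@njit(cache=True)
def _ssa_fluctuating(
    kon_levels, koff_levels, x_draws, k_m, kd_m, tau, sample_dt, n_samples, seed
):  # pragma: no cover - compiled
    """Transcription-only SSA with the input redrawn every tau minutes.

    ``x_draws`` holds the grid index active during each period; the
    transcript state carries over continuously across boundaries.
    Samples at i*sample_dt, i = 1..n_samples, with the active index.
    """
    np.random.seed(seed)
    O = 0
    m = 0
    t = 0.0
    out_m = np.empty(n_samples, np.int64)
    out_x = np.empty(n_samples, np.int64)
    idx = 0
    next_t = sample_dt
    n_periods = x_draws.size
    for period in range(n_periods):
        t_end = (period + 1) * tau
        xi = x_draws[period]
        k_on = kon_levels[xi]
        k_off = koff_levels[xi]
        while t < t_end and idx < n_samples:
            a1 = k_on * (1 - O)
            a2 = k_off * O
            a3 = k_m * O
            a4 = kd_m * m
            a_tot = a1 + a2 + a3 + a4
            if a_tot <= 0.0:
                t_next = t_end + 1.0  # no reaction can fire before the boundary
            else:
                t_next = t + np.random.exponential(1.0 / a_tot)
            if t_next > t_end:
                t_next = t_end  # propensities change at the boundary; memoryless restart
                while idx < n_samples and next_t <= t_next:
                    out_m[idx] = m
                    out_x[idx] = xi
                    idx += 1
                    next_t += sample_dt
                t = t_end
                break
            while idx < n_samples and next_t <= t_next:
                out_m[idx] = m
                out_x[idx] = xi
                idx += 1
                next_t += sample_dt
            t = t_next
            u = np.random.random() * a_tot
            if u < a1:
                O = 1
            elif u < a1 + a2:
                O = 0
            elif u < a1 + a2 + a3:
                m += 1
            else:
                m -= 1
        if idx >= n_samples:
            break
    return out_m, out_x


def _run(
    system: ReactionSystem,
    X: float,
    duration: float,
    sample_interval: float,
    seed: int,
    burn_in: float,
    transcription_only: bool,
    pin_operator: int | None,
) -> Trajectory:
    if sample_interval <= 0 or duration <= 0:
        raise ValueError("duration and sample_interval must be > 0")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if duration <= burn_in + sample_interval:
        raise ValueError("duration must exceed burn_in + sample_interval")
    r = system.rates
    if pin_operator is None:
        k_on, k_off = promoter_rates(X, system.ctrl)
        O0, m0, g0 = system.initial_state
    else:
        if pin_operator not in (0, 1):
            raise ValueError("pin_operator must be 0 or 1")
        k_on, k_off = 0.0, 0.0
        _, m0, g0 = system.initial_state
        O0 = pin_operator
    k_g = 0.0 if transcription_only else r.k_g
    kd_g = 0.0 if transcription_only else r.kd_g
    n_samples = int(np.floor((duration - burn_in) / sample_interval))
    out_O, out_m, out_g = _ssa_fixed_input(
        k_on, k_off, r.k_m, r.kd_m, k_g, kd_g,
        O0, m0, g0, burn_in, sample_interval, n_samples, seed,
    )
    times = burn_in + sample_interval * np.arange(1, n_samples + 1)
    return Trajectory(times, out_O, out_m, out_g, seed=seed, burn_in=burn_in)


def simulate(
    system: ReactionSystem,
    X: float,
    duration: float,
    sample_interval: float,
    seed: int,
    burn_in: float | None = None,
    pin_operator: int | None = None,
) -> Trajectory:
    """Exact SSA trajectory of the full system (operator, transcript, protein).

    ``burn_in`` (default 10 protein response times, 10/kd_g) is
    simulated but discarded so that samples are stationary regardless
    of the initial state.  ``pin_operator`` freezes the operator in the
    given state (switching disabled), used for relaxation studies.
    """
    if burn_in is None:
        burn_in = 10.0 / system.rates.kd_g
    return _run(system, X, duration, sample_interval, seed, burn_in,
                transcription_only=False, pin_operator=pin_operator)


def simulate_transcription_only(
    system: ReactionSystem,
    X: float,
    duration: float,
    sample_interval: float | None = None,
    seed: int = 0,
    burn_in: float | None = None,
    pin_operator: int | None = None,
) -> Trajectory:
    """SSA trajectory of the telegraph + transcription subsystem (m only).

    Translation and protein decay are disabled; the default sampling
    interval is one transcript response time, 1/kd_m, and the default
    burn-in is 10/kd_m (the slowest remaining relaxation time, times 10).
    """
    if sample_interval is None:
        sample_interval = 1.0 / system.rates.kd_m
    if burn_in is None:
        burn_in = 10.0 / system.rates.kd_m
    return _run(system, X, duration, sample_interval, seed, burn_in,
                transcription_only=True, pin_operator=pin_operator)


def simulate_fluctuating_input(
    system: ReactionSystem,
    protocol: FluctuationProtocol,
    kd_g: float,
    seed: int,
    kernel_span: float = 4.0,
    sample_interval: float | None = None,
) -> FluctuationRun:
    """Transcript trajectory under a piecewise-constant fluctuating input.

    At every period boundary a new input level is drawn i.i.d. from the
    protocol's distribution and the switching rates update; the
    transcript count evolves continuously across boundaries.  The ideal
    integration output is the exponential-kernel convolution of the
    sampled transcript trajectory, and each retained g_ideal sample is
    paired with the input level active at its sample instant.
    """
    if not kd_g > 0:
        raise ValueError("kd_g must be > 0")
    r = system.rates
    if sample_interval is None:
        sample_interval = 1.0 / r.kd_m
    grid = protocol.grid.as_array()
    kon = np.empty(grid.size)
    koff = np.empty(grid.size)
    for i, x in enumerate(grid):
        kon[i], koff[i] = promoter_rates(float(x), system.ctrl)

    rng = np.random.default_rng(derive_seed(seed, 0))
    x_draws = rng.choice(grid.size, size=protocol.n_periods, p=protocol.input_dist)
    total_time = protocol.n_periods * protocol.tau_X
    n_samples = int(np.floor(total_time / sample_interval)) - 1
    if n_samples < 2:
        raise ValueError("protocol too short for the sampling interval")
    out_m, out_x = _ssa_fluctuating(
        kon, koff, x_draws, r.k_m, r.kd_m,
        protocol.tau_X, sample_interval, n_samples, derive_seed(seed, 1),
    )
    times = sample_interval * np.arange(1, n_samples + 1)
    n_warmup = integration_kernel(kd_g, sample_interval, kernel_span).size - 1
    if n_samples <= n_warmup:
        raise ValueError("trajectory shorter than the integration kernel")
    g_ideal = ideal_integration_trajectory(
        out_m.astype(float), kd_g, sample_interval, kernel_span
    )
    paired_idx = out_x[n_warmup:]
    return FluctuationRun(
        period_inputs=grid[x_draws],
        times=times,
        m_series=out_m,
        x_index_series=out_x,
        g_ideal=g_ideal,
        paired_x_index=paired_idx,
        paired_x=grid[paired_idx],
        seed=seed,
    )
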