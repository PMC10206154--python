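"""Analytic model of a telegraph-promoter central dogma system.

A gene is driven by a two-state (on/off) operator whose switching rates
encode a scalar environmental input ``X`` in [0, 1]:

    kON  = alpha * ((1 - l) * X + l)
    kOFF = alpha * (1 - l) * (1 - X)

so that ``kON + kOFF = alpha`` for every input.  ``alpha`` sets the
switching frequency (1/min) and the leakiness ``l`` sets the residual
on-probability at X = 0.  Transcription (rate ``k_m``) happens only from
the on state; transcripts decay at ``kd_m``, are translated at ``k_g``
and proteins decay at ``kd_g`` (all first order, units 1/min).

The stationary transcript copy-number distribution of this system is
negative binomial (or Poisson in the fast-switching / fully-on limits),
with mean and Fano factor

    <m> = kON / (kON + kOFF) * k_m / kd_m
    b   = 1 + kd_m * kOFF * <m> / (kON * (kON + kOFF + kd_m))

Translation low-pass filters the transcript signal with the exponential
kernel ``exp(-kd_g t)``; over one protein response time it integrates
``T = kd_m / kd_g`` transcript correlation times.  The noise-free
("ideal") integration output of a NB(r, p) transcript channel is
NB(r*T, p), and Pois(lam) becomes Pois(lam*T), which is what makes the
ideal channel capacity cheap to compute for any integration time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

__all__ = [
    "PromoterControl",
    "RateConstants",
    "InputGrid",
    "CountDistribution",
    "promoter_rates",
    "transcript_distribution",
    "ideal_output_distribution",
    "mean_transcript_relaxation",
    "mean_protein_relaxation",
    "ideal_integration_trajectory",
]

#: cumulative mass retained when truncating analytic pmfs
TRUNCATION_MASS = 1.0 - 1e-9
#: Fano factors within this distance of 1 are treated as Poisson
POISSON_FANO_TOL = 1e-9


@dataclass(frozen=True)
class PromoterControl:
    """Input coupling of the operator: switching frequency and leakiness."""

    alpha: float  # total switching rate kON + kOFF, 1/min
    leak: float  # leakiness l, dimensionless

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not 0 <= self.leak < 1:
            raise ValueError(f"leak must be in [0, 1), got {self.leak}")


@dataclass(frozen=True)
class RateConstants:
    """The four central dogma rate constants (1/min)."""

    k_m: float  # transcription
    kd_m: float  # transcript decay
    k_g: float  # translation
    kd_g: float  # protein decay

    def __post_init__(self) -> None:
        if not (self.kd_m > 0 and self.kd_g > 0):
            raise ValueError("kd_m and kd_g must be > 0")
        # zero production rates are permitted only for degenerate tests
        if self.k_m < 0 or self.k_g < 0:
            raise ValueError("k_m and k_g must be >= 0")

    @property
    def transcription_power(self) -> float:
        """Steady-state mean transcript count per active promoter, k_m/kd_m."""
        return self.k_m / self.kd_m

    @property
    def translation_power(self) -> float:
        """Steady-state mean protein count per transcript copy, k_g/kd_g."""
        return self.k_g / self.kd_g

    @property
    def integration_time(self) -> float:
        """Dimensionless integration time T = kd_m/kd_g."""
        return self.kd_m / self.kd_g


@dataclass(frozen=True)
class InputGrid:
    """Ordered grid of input levels X in [0, 1]."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("input grid must be a 1-D sequence")
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("input levels must lie in [0, 1]")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("input levels must be strictly increasing")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    @classmethod
    def uniform(cls, n_levels: int) -> "InputGrid":
        """n_levels equispaced inputs including both endpoints 0 and 1."""
        if n_levels < 2:
            raise ValueError("uniform grid needs at least 2 levels")
        return cls(tuple(np.linspace(0.0, 1.0, n_levels)))

    @property
    def n_levels(self) -> int:
        return len(self.values)

    @property
    def entropy_bits(self) -> float:
        """H(X) of the uniform distribution on this grid."""
        return math.log2(self.n_levels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class CountDistribution:
    """Analytic copy-number distribution: negative binomial or Poisson.

    The negative binomial is parameterized by the number of failures
    ``r`` (real-valued; gamma-function pmf) and the failure probability
    ``p``, so that mean = r p/(1-p) and Fano factor = 1/(1-p).
    """

    family: str  # "negative_binomial" | "poisson"
    r: float = float("nan")
    p: float = float("nan")
    lam: float = float("nan")
    support_max: int = field(default=0)

    def __post_init__(self) -> None:
        if self.family == "negative_binomial":
            if not (self.r > 0 and 0 < self.p < 1):
                raise ValueError(f"invalid NB parameters r={self.r}, p={self.p}")
        elif self.family == "poisson":
            if not self.lam > 0:
                raise ValueError(f"Poisson mean must be > 0, got {self.lam}")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if self.support_max == 0:
            object.__setattr__(self, "support_max", self._default_support())

    def _frozen(self):
        if self.family == "negative_binomial":
            # scipy's success probability is our 1 - p (failure probability)
            return stats.nbinom(self.r, 1.0 - self.p)
        return stats.poisson(self.lam)

    def _default_support(self) -> int:
        return int(self._frozen().ppf(TRUNCATION_MASS))

    @classmethod
    def negative_binomial(cls, r: float, p: float) -> "CountDistribution":
        return cls(family="negative_binomial", r=r, p=p)

    @classmethod
    def poisson(cls, lam: float) -> "CountDistribution":
        return cls(family="poisson", lam=lam)

    @property
    def mean(self) -> float:
        if self.family == "negative_binomial":
            return self.r * self.p / (1.0 - self.p)
        return self.lam

    @property
    def fano(self) -> float:
        """Variance-to-mean ratio b; 1 for Poisson, 1/(1-p) for NB."""
        if self.family == "negative_binomial":
            return 1.0 / (1.0 - self.p)
        return 1.0

    @property
    def variance(self) -> float:
        return self.fano * self.mean

    def pmf(self, k: np.ndarray | int) -> np.ndarray:
        return self._frozen().pmf(k)

    def pmf_vector(self, support_max: int | None = None) -> np.ndarray:
        """pmf over the integer support [0, support_max]."""
        top = self.support_max if support_max is None else int(support_max)
        return self._frozen().pmf(np.arange(top + 1))

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=size, random_state=rng)

    def to_json(self) -> str:
        payload = {"family": self.family, "support_max": self.support_max}
        if self.family == "negative_binomial":
            payload.update(r=self.r, p=self.p)
        else:
            payload.update(lam=self.lam)
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CountDistribution":
        payload = json.loads(text)
        return cls(**payload)


def promoter_rates(X: float, ctrl: PromoterControl) -> tuple[float, float]:
    """Operator switching rates (kON, kOFF) for input level X.

    kON = alpha((1-l)X + l), kOFF = alpha(1-l)(1-X); their sum is alpha
    for every X, so the input modulates the duty cycle (1-l)X + l without
    changing the switching frequency.
    """
    if not 0.0 <= X <= 1.0:
        raise ValueError(f"input level must be in [0, 1], got {X}")
    k_on = ctrl.alpha * ((1.0 - ctrl.leak) * X + ctrl.leak)
    k_off = ctrl.alpha * (1.0 - ctrl.leak) * (1.0 - X)
    return k_on, k_off


def transcript_distribution(
    k_on: float, k_off: float, k_m: float, kd_m: float
) -> CountDistribution:
    """Stationary transcript distribution of the telegraph gene.

    Mean and Fano factor:

        <m> = k_on/(k_on+k_off) * k_m/kd_m
        b   = 1 + kd_m * k_off * <m> / (k_on * (k_on + k_off + kd_m))

    Over-dispersed (b > 1) gives NB(r, p) with p = (b-1)/b and
    r = <m>/(b-1); b = 1 (e.g. k_off = 0) gives Pois(<m>).
    """
    if not k_on > 0:
        raise ValueError("k_on must be > 0 (Fano factor undefined at k_on = 0)")
    if k_off < 0:
        raise ValueError("k_off must be >= 0")
    if not (k_m > 0 and kd_m > 0):
        raise ValueError("k_m and kd_m must be > 0")

    mean = k_on / (k_on + k_off) * k_m / kd_m
    b = 1.0 + kd_m * k_off * mean / (k_on * (k_on + k_off + kd_m))
    if b - 1.0 < POISSON_FANO_TOL:
        return CountDistribution.poisson(mean)
    return CountDistribution.negative_binomial(r=mean / (b - 1.0), p=(b - 1.0) / b)


def ideal_output_distribution(d: CountDistribution, T: float) -> CountDistribution:
    """Distribution of the noise-free time-integration output at integration time T.

    The ideal output accumulates T i.i.d. copies of the transcript level
    (one per transcript correlation time inside the protein response
    time), so NB(r, p) -> NB(r T, p) and Pois(lam) -> Pois(lam T); real
    T is allowed through the gamma-function pmf.
    """
    if not T > 0:
        raise ValueError(f"integration time must be > 0, got {T}")
    if d.family == "negative_binomial":
        return CountDistribution.negative_binomial(r=d.r * T, p=d.p)
    return CountDistribution.poisson(lam=d.lam * T)


def mean_transcript_relaxation(
    t: float | np.ndarray, O: int, k_m: float, kd_m: float
) -> float | np.ndarray:
    """Ensemble-mean transcript count at time t from m(0)=0, operator fixed at O.

    <m|O>(t) = (k_m O / kd_m) (1 - exp(-kd_m t)); relaxation time 1/kd_m.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if O not in (0, 1):
        raise ValueError("operator state must be 0 or 1")
    out = (k_m * O / kd_m) * (1.0 - np.exp(-kd_m * t))
    return float(out) if out.ndim == 0 else out


def mean_protein_relaxation(
    t: float | np.ndarray, m: float, k_g: float, kd_g: float
) -> float | np.ndarray:
    """Ensemble-mean protein count at time t from g(0)=0 at fixed transcript count m.

    <g|m>(t) = (k_g m / kd_g) (1 - exp(-kd_g t)); relaxation time 1/kd_g.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if m < 0:
        raise ValueError("transcript count must be nonnegative")
    out = (k_g * m / kd_g) * (1.0 - np.exp(-kd_g * t))
    return float(out) if out.ndim == 0 else out


def integration_kernel(kd_g: float, dt: float, kernel_span: float = 4.0) -> np.ndarray:
    """Discrete exponential integration kernel on tau in [0, kernel_span/kd_g].

    Zero-order-hold weights: the transcript trajectory is piecewise
    constant between samples, so each sample m_j contributes
    integral(exp(-kd_g tau) dtau) over its dt slot,

        w_j = exp(-kd_g j dt) (1 - exp(-kd_g dt)) / kd_g.

    A constant input m0 then yields m0 (1 - exp(-kernel_span)) / kd_g,
    converging to the exact stationary value m0/kd_g as the span grows.
    """
    if kernel_span < 1:
        raise ValueError("kernel_span must be >= 1")
    n_taps = int(math.ceil(kernel_span / (kd_g * dt)))
    j = np.arange(n_taps)
    return np.exp(-kd_g * j * dt) * (-np.expm1(-kd_g * dt)) / kd_g


def ideal_integration_trajectory(
    m_traj: np.ndarray, kd_g: float, dt: float, kernel_span: float = 4.0
) -> np.ndarray:
    """Noise-free translation output: convolve m(t) with exp(-kd_g t).

    g_ideal(t) = integral_0^t m(tau) exp(-kd_g (t - tau)) dtau, evaluated
    by discrete convolution at the trajectory's sampling step dt with the
    kernel truncated at kernel_span/kd_g.  Samples inside the kernel
    warm-up window are discarded, so the output is shorter than the
    input by the kernel length minus one.  The translation rate k_g is
    deliberately omitted: it rescales the output without adding noise
    and therefore cannot change any capacity computed from it.
    """
    m_traj = np.asarray(m_traj, dtype=float)
    if m_traj.ndim != 1:
        raise ValueError("transcript trajectory must be 1-D")
    kernel = integration_kernel(kd_g, dt, kernel_span)
    if m_traj.size < kernel.size:
        raise ValueError(
            f"trajectory ({m_traj.size} samples) shorter than the "
            f"integration kernel ({kernel.size} taps)"
        )
    # 'valid' keeps only full-overlap lags: warm-up is dropped automatically
    out = signal.fftconvolve(m_traj, kernel, mode="valid")
    return np.maximum(out, 0.0)
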