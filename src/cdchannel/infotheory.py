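"""Discrete mutual information, Blahut-Arimoto capacity, and bias correction.

A channel is the row-stochastic matrix Q of conditional output
distributions P(output | X), one row per input level.  Mutual
information for an input distribution p is

    I(p, Q) = sum_j p_j sum_k Q_jk log2( Q_jk / q_k ),   q = p @ Q

and the channel capacity c = max_p I(p, Q) is computed with the
Blahut-Arimoto alternating maximization, which provably converges to
the capacity of any discrete memoryless channel.  Empirical channels
are built by equal-width binning of output samples; the finite-sampling
(combing) bias of binned estimates is removed by subsampling fractions
of the data and extrapolating capacity linearly in inverse sample size
to the infinite-data limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import CountDistribution, InputGrid

__all__ = [
    "Channel",
    "InputDistribution",
    "CapacityEstimate",
    "mutual_information",
    "mutual_information_from_samples",
    "blahut_arimoto",
    "empirical_channel",
    "analytic_channel",
    "capacity_from_analytic",
    "bias_corrected_capacity",
    "bin_count_rule",
    "mi_landscape",
]

_ROW_SUM_TOL = 1e-9
_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class Channel:
    """Input grid plus conditional output distributions P(output | X)."""

    inputs: np.ndarray  # input levels, one per row of Q
    Q: np.ndarray  # (J, K) row-stochastic transition matrix
    bin_edges: np.ndarray | None = None  # K+1 edges for binned channels

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2 or inputs.ndim != 1 or Q.shape[0] != inputs.size:
            raise ValueError("Q must be (J, K) with one row per input level")
        if np.any(Q < 0):
            raise ValueError("transition matrix entries must be nonnegative")
        if np.any(np.abs(Q.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("every row of Q must sum to 1")
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "Q", Q)

    @property
    def n_inputs(self) -> int:
        return self.Q.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.Q.shape[1]

    def drop_empty_outputs(self) -> "Channel":
        """Remove output columns with zero mass under every input."""
        occupied = self.Q.sum(axis=0) > 0
        if occupied.all():
            return self
        return Channel(self.inputs, self.Q[:, occupied], None)


@dataclass(frozen=True)
class InputDistribution:
    """Probability distribution over an input grid."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1:
            raise ValueError("input distribution must be 1-D")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("input distribution must be nonnegative and sum to 1")
        object.__setattr__(self, "p", p)

    @classmethod
    def uniform(cls, n: int) -> "InputDistribution":
        return cls(np.full(n, 1.0 / n))

    def mean(self, grid: np.ndarray) -> float:
        return float(np.dot(self.p, grid))

    def std(self, grid: np.ndarray) -> float:
        mu = self.mean(grid)
        return float(np.sqrt(np.dot(self.p, (np.asarray(grid) - mu) ** 2)))


@dataclass
class CapacityEstimate:
    """Channel capacity in bits with optimizer and bias-correction metadata."""

    capacity_bits: float
    optimal_input: InputDistribution
    n_iterations: int = 0
    converged: bool = True
    nb: int | None = None  # bin count used for empirical channels
    bias_record: dict = field(default_factory=dict)


def _xlogy_ratio(Q: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Rows of Q times log2(Q/q) with 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(Q > 0, Q / q[np.newaxis, :], 1.0)
        return np.where(Q > 0, Q * np.log(ratio), 0.0) / _LOG2


def mutual_information(
    p: InputDistribution | np.ndarray, Q: Channel | np.ndarray
) -> float:
    """I(X; output) in bits for input distribution p over channel Q."""
    p_arr = p.p if isinstance(p, InputDistribution) else np.asarray(p, dtype=float)
    Q_arr = Q.Q if isinstance(Q, Channel) else np.asarray(Q, dtype=float)
    if Q_arr.shape[0] != p_arr.size:
        raise ValueError(
            f"input distribution has {p_arr.size} levels but channel has "
            f"{Q_arr.shape[0]} rows"
        )
    q = p_arr @ Q_arr
    return float(max(p_arr @ _xlogy_ratio(Q_arr, q).sum(axis=1), 0.0))


def mutual_information_from_samples(
    x_index: np.ndarray, y: np.ndarray, nb: int
) -> float:
    """Plug-in I(X; Y) in bits from paired samples, binning Y into nb equal-width bins.

    The input marginal is the empirical frequency of each x label; the
    conditional distributions are per-label histograms of y over a
    common set of edges spanning the pooled range.
    """
    x_index = np.asarray(x_index)
    y = np.asarray(y, dtype=float)
    if x_index.size != y.size or x_index.size == 0:
        raise ValueError("x_index and y must be nonempty and the same length")
    labels, counts = np.unique(x_index, return_counts=True)
    edges = _bin_edges(y, nb)
    Q = np.vstack(
        [np.histogram(y[x_index == lab], bins=edges)[0] for lab in labels]
    ).astype(float)
    Q /= Q.sum(axis=1, keepdims=True)
    return mutual_information(counts / counts.sum(), Q)


def blahut_arimoto(
    Q: Channel | np.ndarray, tol: float = 1e-6, max_iter: int = 10_000
) -> CapacityEstimate:
    """Channel capacity of a discrete memoryless channel, in bits.

    Alternates the optimal reverse channel R*_{j|k} = p_j Q_{k|j} / q_k
    with the input update p_j ~ exp(sum_k Q_{k|j} log R_{j|k}) from a
    uniform start.  The collapsed form iterates

        D_j = sum_k Q_jk log2(Q_jk / q_k),   p <- p 2^D / Z

    whose lower/upper capacity bounds log2(sum p 2^D) and log2(max 2^D)
    bracket the capacity; iteration stops when the bracket is narrower
    than ``tol`` bits.  The objective is nondecreasing every iteration.
    """
    channel = Q if isinstance(Q, Channel) else Channel(np.arange(np.asarray(Q).shape[0]), Q)
    channel = channel.drop_empty_outputs()
    Qm = channel.Q
    J = Qm.shape[0]
    p = np.full(J, 1.0 / J)

    capacity = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = p @ Qm
        D = _xlogy_ratio(Qm, q).sum(axis=1)  # bits
        lower = np.log2(np.dot(p, np.exp2(D)))
        upper = D.max()
        # multiplicative update; renormalize for stability
        p = p * np.exp2(D - upper)
        p /= p.sum()
        capacity = lower
        if upper - lower < tol:
            converged = True
            break

    return CapacityEstimate(
        capacity_bits=float(max(capacity, 0.0)),
        optimal_input=InputDistribution(p),
        n_iterations=it,
        converged=converged,
    )


def _bin_edges(pooled: np.ndarray, nb: int) -> np.ndarray:
    lo, hi = float(np.min(pooled)), float(np.max(pooled))
    if hi <= lo:  # all samples identical: one occupied bin
        hi = lo + 1.0
    return np.linspace(lo, hi, nb + 1)


def empirical_channel(
    samples: Sequence[np.ndarray],
    nb: int,
    inputs: np.ndarray | None = None,
) -> Channel:
    """Binned channel P(output | X) from output samples per input level.

    Equal-width bins span the pooled [min, max] over all inputs; each
    row is the normalized histogram of that input's samples.
    """
    if nb < 2:
        raise ValueError("need at least 2 bins")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) == 0 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 samples for every input level")
    edges = _bin_edges(np.concatenate(arrays), nb)
    Q = np.vstack([np.histogram(a, bins=edges)[0] for a in arrays]).astype(float)
    Q /= Q.sum(axis=1, keepdims=True)
    if inputs is None:
        inputs = np.arange(len(arrays), dtype=float)
    return Channel(inputs, Q, edges)


def analytic_channel(
    dists: Sequence[CountDistribution],
    inputs: np.ndarray | InputGrid | None = None,
    support_max: int | None = None,
) -> Channel:
    """Exact channel from analytic count distributions on a common integer support.

    The support defaults to the widest per-input truncation bound; an
    explicit ``support_max`` that loses more than 1e-6 of any input's
    mass is rejected.
    """
    if len(dists) < 2:
        raise ValueError("need at least 2 input levels")
    if support_max is None:
        support_max = max(d.support_max for d in dists)
    Q = np.vstack([d.pmf_vector(support_max) for d in dists])
    mass = Q.sum(axis=1)
    if np.any(mass < 1.0 - 1e-6):
        raise ValueError("truncated support loses more than 1e-6 probability mass")
    Q /= mass[:, np.newaxis]
    if inputs is None:
        inputs = np.arange(len(dists), dtype=float)
    elif isinstance(inputs, InputGrid):
        inputs = inputs.as_array()
    return Channel(np.asarray(inputs, dtype=float), Q, None)


def capacity_from_analytic(
    dists: Sequence[CountDistribution],
    inputs: np.ndarray | InputGrid | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> CapacityEstimate:
    """Blahut-Arimoto capacity of the exact analytic channel (no binning, no bias)."""
    return blahut_arimoto(analytic_channel(dists, inputs), tol=tol, max_iter=max_iter)


def bin_count_rule(c_ideal: float, eta: float) -> int:
    """Bin count nb = ceil(2^(c_ideal + eta)): more bins than 2^c_ideal by margin eta."""
    if c_ideal < 0:
        raise ValueError("c_ideal must be >= 0")
    if not eta > 0:
        raise ValueError("eta must be > 0")
    return max(int(np.ceil(2.0 ** (c_ideal + eta))), 2)


def _naive_capacity(
    samples: list[np.ndarray], nb: int, tol: float, max_iter: int
) -> CapacityEstimate:
    est = blahut_arimoto(empirical_channel(samples, nb), tol=tol, max_iter=max_iter)
    est.nb = nb
    return est


def _extrapolated_capacity(
    samples: list[np.ndarray],
    nb: int,
    fractions: Sequence[float],
    n_replicates: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[float, dict]:
    """Intercept of the least-squares fit of capacity vs inverse sample size."""
    inv_n: list[float] = []
    caps: list[float] = []
    record: dict[float, list[float]] = {}
    for frac in fractions:
        reps = n_replicates if frac < 1.0 else 1
        record[frac] = []
        for _ in range(reps):
            sub = [
                s[rng.choice(s.size, size=max(int(round(frac * s.size)), 2), replace=False)]
                for s in samples
            ]
            cap = _naive_capacity(sub, nb, tol, max_iter).capacity_bits
            record[frac].append(cap)
            inv_n.append(1.0 / sum(s.size for s in sub))
            caps.append(cap)
    if len(set(inv_n)) == 1:
        return float(np.mean(caps)), {"per_fraction": record, "slope": 0.0}
    slope, intercept = np.polyfit(inv_n, caps, 1)
    # capacity is nonnegative; the linear extrapolation may slightly undershoot
    return float(max(intercept, 0.0)), {"per_fraction": record, "slope": float(slope)}


def bias_corrected_capacity(
    samples: Sequence[np.ndarray],
    nb: int | None = None,
    fractions: Sequence[float] = (0.5, 0.625, 0.75, 0.875, 1.0),
    n_replicates: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    nb_plateau_tol: float = 0.05,
) -> CapacityEstimate:
    """Finite-sampling-unbiased capacity from output samples per input level.

    For each sampling fraction the data are subsampled without
    replacement (``n_replicates`` times), a binned channel is built and
    its Blahut-Arimoto capacity computed; the capacities are fit by
    least squares against inverse sample size and extrapolated to the
    infinite-data intercept.  With ``nb=None`` the bin count is swept
    upward (doubling from 4) until the unbiased capacity changes by
    less than ``nb_plateau_tol`` bits, selecting enough bins to capture
    the variance without combing the histograms.
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 samples for every input level")
    fractions = sorted(fractions)
    if not all(0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    min_count = min(a.size for a in arrays)
    if int(fractions[0] * min_count) < 2:
        raise ValueError("smallest fraction leaves fewer than 2 samples per input")
    rng = np.random.default_rng(seed)

    if nb is not None:
        cap, record = _extrapolated_capacity(
            arrays, nb, fractions, n_replicates, rng, tol, max_iter
        )
        naive = _naive_capacity(arrays, nb, tol, max_iter)
        return CapacityEstimate(
            capacity_bits=cap,
            optimal_input=naive.optimal_input,
            n_iterations=naive.n_iterations,
            converged=naive.converged,
            nb=nb,
            bias_record=record,
        )

    # bin-count sweep: stop when the unbiased estimate plateaus
    prev_cap = None
    nb_try = 4
    history: dict[int, float] = {}
    while True:
        cap, record = _extrapolated_capacity(
            arrays, nb_try, fractions, n_replicates, rng, tol, max_iter
        )
        history[nb_try] = cap
        if prev_cap is not None and abs(cap - prev_cap) < nb_plateau_tol:
            break
        if nb_try >= 512:
            break
        prev_cap = cap
        nb_try *= 2
    naive = _naive_capacity(arrays, nb_try, tol, max_iter)
    record["nb_sweep"] = history
    return CapacityEstimate(
        capacity_bits=cap,
        optimal_input=naive.optimal_input,
        n_iterations=naive.n_iterations,
        converged=naive.converged,
        nb=nb_try,
        bias_record=record,
    )


def mi_landscape(
    Q: Channel,
    mean_grid: np.ndarray,
    std_grid: np.ndarray,
) -> np.ndarray:
    """Mutual-information landscape over (mean, std) of the input distribution.

    Each (mean, std) cell is a discretized truncated normal on the
    channel's input grid (density weights renormalized on the grid);
    std = 0 degenerates to a point mass on the nearest grid level.
    Every landscape value is bounded above by the channel capacity.
    Returns a (len(std_grid), len(mean_grid)) matrix.
    """
    grid = Q.inputs
    out = np.empty((len(std_grid), len(mean_grid)))
    for i, sd in enumerate(std_grid):
        for j, mu in enumerate(mean_grid):
            if sd <= 0:
                w = np.zeros(grid.size)
                w[np.argmin(np.abs(grid - mu))] = 1.0
            else:
                w = np.exp(-0.5 * ((grid - mu) / sd) ** 2)
                w /= w.sum()
            out[i, j] = mutual_information(w, Q)
    return out
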