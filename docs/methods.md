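# Methods

## Reaction system and analytic channels

The model is the minimal central dogma system: a two-state operator
O ∈ {0, 1} switching at rates kON/kOFF, transcription at k_m from the
on state, first-order transcript decay kd_m, translation at k_g per
transcript, and first-order protein decay kd_g.  The input X ∈ [0, 1]
enters only through the operator rates, kON = α((1−l)X + l) and
kOFF = α(1−l)(1−X); their sum is the switching frequency α for every
X, so X sets the duty cycle (1−l)X + l without changing the switching
timescale.  The leakiness l is the duty cycle at X = 0.

The stationary transcript law for fixed X is negative binomial with
mean ⟨m⟩ = duty · k_m/kd_m and Fano factor
b = 1 + kd_m·kOFF·⟨m⟩/(kON(kON + kOFF + kd_m)); we map (⟨m⟩, b) to
NB(r = ⟨m⟩/(b−1), p = (b−1)/b).  Fano factors within 1e−9 of 1 are
treated as Poisson — the exact b = 1 boundary (e.g. kOFF = 0) sends
r → ∞ and p → 0, which the Poisson limit represents without parameter
blow-up.  kON = 0 (zero leak at X = 0) is rejected rather than
special-cased: b is undefined there.

Time integration: translation responds on 1/kd_g, so it integrates
T = kd_m/kd_g transcript correlation times.  Treating those as i.i.d.
draws from P(m|X), the ideal (noise-free) integration output is the
T-fold convolution: NB(r, p) → NB(rT, p) and Pois(λ) → Pois(λT).
Real-valued T uses the gamma-function NB pmf.  Mean scales by T and
the relative standard deviation by T^−0.5, which is the mechanism of
information gain.

Analytic channels truncate each pmf at its 1 − 1e−9 quantile and share
the support [0, max over inputs]; rows are renormalized (relative
corrections ≤ 1e−9).  A caller-supplied support that loses more than
1e−6 of any input's mass is rejected.

## Capacity estimation

Mutual information is Eq. I(p, Q) = Σ_j p_j Σ_k Q_jk log2(Q_jk/q_k)
with q = pQ and 0·log 0 = 0; log base 2 throughout.  Capacity is the
Blahut–Arimoto fixed point from a uniform start: with
D_j = Σ_k Q_jk log2(Q_jk/q_k), the update p ← p·2^D/Z is the collapsed
form of alternating the optimal reverse channel and the input update.
log2(Σ p_j 2^D_j) and max_j D_j are lower/upper capacity bounds;
iteration stops when the bracket is below `tol` (default 1e−6 bits,
max 10⁴ iterations; non-convergence is flagged on the estimate, never
silently returned).  All-zero output columns are dropped before
iterating; inputs are never dropped.  For degenerate channels with
multiple optima the uniform-start fixed point is the one reported.

Empirical channels bin output samples into nb equal-width bins over
the pooled [min, max] of all inputs.  Finite sampling inflates binned
capacity estimates ("combing"); the corrected estimate subsamples
fractions {0.5, 0.625, 0.75, 0.875, 1.0} of the data without
replacement (10 replicates per fraction by default), fits capacity
against inverse sample size by least squares, and reports the
intercept (clamped at 0).  When no bin count is given, nb is swept
upward (doubling from 4) until the corrected capacity moves by less
than 0.05 bits — enough bins to capture the variance, not enough to
comb the histograms.  The rule nb = ceil(2^(c_ideal + η)), η > 0, is
also provided for channels whose target capacity is known in advance.

### Bin resolution for integrator outputs

Two estimation regimes matter and the package is deliberate about
which one each analysis uses:

- The *ideal output* is a per-count observable.  When validating the
  NB(rT, p) approximation against numerically convolved trajectories,
  the convolution output is rescaled to count units (the closed-form
  scale is (1 − e^(−span))·Δt per count) and binned at one-count
  resolution, capped at 256 bins at long T.  Substantially finer bins
  stop measuring the per-count output and start resolving the
  sub-count smoothing structure of the short exponential kernel —
  effectively a tuple of correlated transcript samples, a different
  (and more informative) observable whose capacity legitimately
  exceeds the scalar ideal channel at small T.
- Protein-level capacities from full simulations use a bin schedule
  rising linearly in log T from 8 bins at T = 1 to 32 at T = 1000
  (clipped to [8, 64]), which keeps the histogram at roughly the
  output-count scale of the matching ideal channel across the curve.

Mutual-information landscapes evaluate I over a family of input
distributions parameterized by (mean, std): a normal density
discretized on the input grid and renormalized, with std = 0 a point
mass on the nearest level.  Every landscape value is bounded by the
BA capacity; the bound is attained by the family only where the
capacity-achieving input is approximately unimodal (low-power
telegraph channels have bimodal optima that no unimodal member can
reach — the landscape then shows an honest gap).

## Stochastic simulation

Trajectories come from Gillespie's direct method over the six
propensities kON(1−O), kOFF·O, k_m·O, kd_m·m, k_g·m, kd_g·g — exact
CTMC sampling, no tau-leaping.  State is recorded by last-event
carry-forward at fixed grid times.  The default initial state is
(0, 0, 0) with a burn-in of ten slowest relaxation times (10/kd_g for
the full system, 10/kd_m for transcription-only runs) simulated and
discarded, guaranteeing stationary samples regardless of the start.
Transcription-only runs sample at 1/kd_m by default; full runs at
10 min.  The event loops are numba-compiled; a given (parameters,
seed) pair is bitwise reproducible, and per-task seeds are derived
from one master seed through `numpy.random.SeedSequence` so serial
and parallel execution agree.  An `operator_pinned` mode freezes O for
ensemble-relaxation studies against the closed-form mean curves
⟨m|O⟩(t) = (k_m·O/kd_m)(1 − e^(−kd_m t)) and its translation analogue.

Deterministic time integration of a sampled trajectory uses
zero-order-hold quadrature: the trajectory is piecewise constant
between samples, so sample m_j contributes
w_j = e^(−kd_g·jΔt)(1 − e^(−kd_g·Δt))/kd_g, and a constant input m0
converges to m0/kd_g exactly as the kernel span grows.  The default
span is 4/kd_g (kernel mass 1 − e^−4 ≈ 0.982); spans of 4 and larger
leave capacities unchanged within 0.1 bits.  Samples inside the
kernel warm-up window are discarded.  k_g is omitted from the
operator — it rescales the output without adding noise and cannot
affect any capacity.

Under the fluctuating-input protocol the input is redrawn i.i.d. from
a prescribed distribution every τ_X minutes (propensities update at
the boundary; the exponential clock restarts, which is exact by
memorylessness) while m evolves continuously.  Each retained
integrator sample is paired with the input active at its sample
instant (grid-point pairing; per-period pairing would discard most of
the trajectory).  The mutual information of the paired samples is
binned at one-count resolution and bias-corrected by the same
1/N-extrapolation as capacities — at the shortest periods only ~10³
pairs exist and the plug-in bias (~0.2 bits) would otherwise swamp the
tiny true information.

## Species integration times

Per-gene tables of paired decay constants give the distribution of
T = kd_m/kd_g per species.  For dilution-dominated turnover (the
E. coli convention) an optional doubling time replaces the tabulated
kd_g by ln2/t_double for every gene — dilution only, no added
degradation term.  Percentiles use rank-based linear interpolation;
medians are additionally reported rounded to the nearest integer,
following the field's reporting convention.  A seeded synthetic
generator produces stand-in tables with log-normal gene-to-gene
spread of kd_m and of T (decay-rate compilations are approximately
log-normal across genes); its sample median converges to the
configured median and zero spread collapses every gene onto it.

## Synthetic data: what it does and does not emulate

All studies run on model-generated data: analytic NB/Poisson channels
and exact SSA trajectories of the four-rate telegraph system.  These
capture promoter, transcription and translation noise exactly within
the model, but not measurement noise, extrinsic cell-to-cell
variability, feedback regulation, bursty translation beyond the
four-rate model, or cell-division mechanics beyond an effective decay
rate.  Passing tests therefore certify the estimators and the model's
internal consistency, not agreement with any particular experimental
system.  Synthetic species tables reproduce the *shape* of published
integration-time distributions, not their per-gene values.

## Default study conditions and problem sizes

- Validation system: k_m = kd_m = 0.5/min, α = 1/min, l = 0.01,
  11 inputs {0, 0.1, …, 1}, T ∈ {1, 2.5, 5, 10, 25, 50, 100, 250,
  500, 1000, 2500}; 10⁴ trajectory samples per input at interval
  1/kd_m for convolution studies.
- Gain curves: k_m = kd_m = 0.1/min; input schedule 16 levels for
  T ≤ 20, 64 above; 10⁴ protein samples per input at 10-min
  intervals.
- Fluctuation study: T = 10 system, τ_X = {0.1 … 200}/kd_g, 10³
  input periods per τ_X.
- Bias correction: fractions {0.5, 0.625, 0.75, 0.875, 1.0}; 3–10
  replicates depending on the study.

These are the package defaults; every size is a keyword argument, and
the larger trajectory counts used in the original studies (10⁵–10⁶
samples, 10⁴ periods) are reproduced by raising them.

## Known limitations

- The NB(rT, p) ideal output is an i.i.d.-sum approximation; at small
  T the true convolution output carries slightly different information
  (see the bin-resolution discussion above).
- The 1/N bias extrapolation is first order; strongly combed channels
  (bins ≫ samples) are outside its regime.
- The landscape input family (discretized normal) is one choice of
  unimodal family; capacities, not landscapes, are the primary
  quantities.
- No feedback, no extrinsic noise, no multi-gene coupling.
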