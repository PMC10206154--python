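# cdchannel

Information-channel analysis of central dogma gene expression: how many
bits about its environment can a cell read out from transcript and
protein copy numbers, and how much of that information does translation
gain by time integration — or lose to its own stochasticity?

The package is for systems/synthetic biologists and biophysicists who
want to compute channel capacities of gene expression systems from
model rate constants or simulated trajectories, without experimental
single-cell data.

## Model

A gene is driven by a two-state (telegraph) promoter whose switching
rates encode a scalar input X ∈ [0, 1]:

    kON = α((1−l)X + l),   kOFF = α(1−l)(1−X),   kON + kOFF = α

with switching frequency α and leakiness l.  Transcription (k_m) occurs
from the on state; transcripts decay at kd_m, are translated at k_g,
and proteins decay at kd_g.  The stationary transcript copy number is
negative binomial with

    ⟨m⟩ = kON/(kON+kOFF) · k_m/kd_m,
    b   = σ²/⟨m⟩ = 1 + kd_m·kOFF·⟨m⟩ / (kON(kON+kOFF+kd_m)),

NB(r, p) with p = (b−1)/b, r = ⟨m⟩/(b−1), degenerating to
Pois(⟨m⟩) when b = 1 (e.g. at full induction).

Translation low-pass filters the transcript signal with the kernel
e^(−kd_g·t): over one protein response time it integrates
T = kd_m/kd_g transcript correlation times.  The noise-free ("ideal")
integration output of an NB(r, p) transcript channel is NB(rT, p), so
the **ideal channel capacity** c_ideal(T) = c(X; g_ideal) is computed
analytically for any T.  Capacities are obtained with the
Blahut–Arimoto algorithm on the transition matrix P(output | X);
empirical channels from simulated trajectories are binned and the
finite-sampling bias removed by extrapolating capacity against inverse
sample size.  The **translation loss** c_ideal(T) − c(X; g) measures
the information forfeited to stochasticity in translation, with
c(X; g) estimated from exact Gillespie simulations of the full
reaction system.

## Worked example

```python
from cdchannel import (InputGrid, PromoterControl, capacity_from_analytic,
                       promoter_rates, transcript_distribution)

ctrl = PromoterControl(alpha=1.0, leak=0.01)   # 1/min, 1% leak
grid = InputGrid.uniform(16)                   # X = 0, 1/15, ..., 1
dists = [transcript_distribution(*promoter_rates(x, ctrl), k_m=0.1, kd_m=0.1)
         for x in grid.values]
est = capacity_from_analytic(dists, grid)
print(f"c(X;m) = {est.capacity_bits:.4f} bits")
```

prints

```
c(X;m) = 0.4023 bits
```

the transcript-level capacity of a weakly expressed gene
(transcription power k_m/kd_m = 1): the copy number distinguishes
fewer than 2 input states despite 16 applied levels, because the
conditional distributions overlap heavily.  Time integration recovers
information: for the same gene `ideal_gain_curve` gives
c_ideal(10) ≈ 1.18 bits and c_ideal(1000) ≈ 3.31 bits (11 inputs),
approaching the input entropy.  The scripts in `examples/` walk
through each capability (analytic channels, gain curves, exact SSA
validation, bias correction, translation loss, fluctuating inputs,
species integration times) and print the numbers they compute.

A thin CLI mirrors the library:

```
cdchannel ideal-curve --km 0.1 --kdm 0.1 --alpha 1 --leak 0.01 \
    --t 1,10,100 --inputs 16 --out curve.csv
```

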