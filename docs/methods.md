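# Methods

## Model

### Elastic latency

Each neuron has a response latency that grows linearly with the number of
spikes it has evoked:

```
l(q) = l0 + q·Δ
```

with `l0` the initial latency and Δ the per-spike increment. Δ is stored in
ms/spike; physiologically plausible values are 0.002–0.007 ms (2–7 µs) per
spike, and the gate constructions here use 0.004–0.006 ms (the population
model uses 0.04 ms per population hop). `q` counts **evoked spikes only**: a
stimulation that fails to evoke a spike — sub-threshold summation, an active
inhibition veto, refractoriness, or a probabilistically skipped delivery —
does not stretch the latency. Latencies can be restored explicitly
(`reset_latencies`); no spontaneous recovery kinetics are modeled.

A feedforward chain of `n` such neurons (the stimulated input neuron plus
its relays, excluding the output) therefore delivers its stimulation to the
output after

```
τ(q) = τ0 + n·q·Δ
```

— a *delay line* with intercept `τ0` and slope `n·Δ`.

### Firing rules

- **Strong (supra-threshold) links** evoke a spike 1:1 at the target.
- **Weak links** carry a strength < threshold θ (default 0.5 against θ = 1);
  the target fires when the strengths arriving within a sliding summation
  window `w` reach θ. The window is half-open: an arrival at time `t` sums
  with earlier arrivals in `(t − w, t]`, i.e. two weak inputs coincide iff
  their lag is strictly less than `w` (~0.4–0.5 ms).
- **Inhibition** delivered at time `T` vetoes excitatory firing during the
  closed window `[T + 1, T + 7]` ms. A graded (strength-dependent) profile
  is available but off by default.
- **Refractoriness** blocks a spike whose gap to the neuron's previous spike
  is strictly less than `r` = 4 ms.

### Knife-edge convention (`TIME_EPS`)

All three rule sites (core predicates, the event engine, and the analytic
single-round evaluator) apply the same guard `TIME_EPS = 1e-9` ms: summation
uses `t_j > t − w + ε`, refractoriness `gap < r − ε`, and the veto
`T + 1 − ε ≤ t ≤ T + 7 + ε`. Without it, a lag that equals `w` *exactly* (it
occurs at integer `q` whenever `w` is a multiple of the slope difference)
can be resolved differently by the two engines purely through floating-point
rounding of the event engine's large absolute clock. With the guard, exact
boundaries resolve by convention, identically everywhere, and the engines
agree round-for-round on every deterministic run (verified exhaustively on
200 random gates up to 2000 stimulations).

## Engines

- **Analytic engine** (`dlg.analytic`): closed forms. Pairwise crossing of
  two delay lines at `q* = (τ0_i − τ0_j)/(s_j − s_i)`; a pair's firing
  region is `|Δτ(q)| < w`, a band of half-width `w/|s_i − s_j|` around `q*`;
  inhibition regions solve `1 ≤ d0 + s·q ≤ 7` for the excitatory–inhibitory
  arrival gap. Truth tables are evaluated per subset of active inputs by
  topological replay of one stimulation round; the mode timeline labels
  every integer `q` and compresses runs into intervals.
- **Event engine** (`dlg.events`): a priority queue of timed arrivals over
  repeated stimulation rounds (default 10 Hz), with per-input delivery
  probabilities and moderation windows, per-neuron state (latency counters,
  last spike, inhibition history), and per-round summaries including
  predicted vs. observed chain delays.

Both engines are written independently and cross-checked; their exact
agreement under deterministic protocols is an acceptance property of the
test suite.

## Gate constructions

Builders produce AND, OR (strong links; DOUBLE → OR under refractoriness),
NOT (excitatory drive plus an inhibition chain and a constitutive outer
drive), XOR (cross-inhibition between two excitatory chains), generalized
AND (k weak chains, optional per-chain strengths), and a multimode gate (two
inhibition chains of different lengths plus an outer drive) whose
construction validates the slope ordering needed for the two veto sweeps to
stagger. A seeded random-gate generator yields structurally valid
coincidence gates (2–4 inputs, distinct slopes, strictly decreasing delays
in general position) for the equivalence property.

Region boundaries scale exactly with Δ (a gate with Δ' has the same regions
at `q·Δ/Δ'`), and gates whose pairwise chain-length differences and initial
delay differences match are *synfire-equivalent* — identical mode-transition
counts — which is how long chains of short synaptic delays reproduce the
behavior of short chains of long delays.

## Hodgkin–Huxley population gate

Populations of 40 standard squid-axon HH neurons (C = 1 µF/cm²,
g_Na = 120, g_K = 36, g_L = 0.3 mS/cm², E_Na = 50, E_K = −77,
E_L = −54.4 mV) with alpha-function synaptic conductances
(τ_syn = 2 ms, E_syn = 0 mV) are integrated with fixed-step RK4 at
dt = 0.01 ms (numba-compiled when available; a pure-Python fallback gives
identical results). Spikes are upward 0 mV crossings, linearly interpolated,
with a 2 ms minimum separation. Halving dt changes spike times by well under
0.01 ms in the regimes used (measured ~7·10⁻⁶ ms for the calibration
stimulus).

Connectivity between populations is diluted at p = 0.1 (expected 8 weak
inputs per output neuron from two 40-neuron sources) with Gaussian delay
jitter σ = 0.15 ms truncated at zero. The nominal weak conductance is scaled
by a calibration factor 0.10 chosen **before** running the acceptance
trajectories, by measuring the single-neuron coincidence threshold: at scale
0.10 a neuron needs 7 simultaneous weak inputs to fire (scales 0.12 and 0.14
give 6 and 5), so a single source population's ~4 coincident inputs stay
sub-threshold while a two-population volley fires — the population-level
coincidence detector. The unscaled nominal value is supra-threshold for even
one input and cannot act as a "weak" synapse under these kinetics.

The **static gate** measures the fraction of output neurons firing vs. the
lag γ between the two source volleys (high for sub-millisecond lags,
collapsing by ~5 ms). The **dynamic gate** relays one input through a chain
of three populations with strong synapses and the other directly; each
evoked spike adds 0.04 ms to its neuron's outgoing delays, so a 2 ms initial
lead erodes at 2 × 0.04 ms per stimulation and the mean inter-arrival lag
reaches its minimum at stimulation 25 (mean over 10 seeds in the acceptance
script: 25.0). The output firing fraction is elevated around the lag
minimum and lower at both ends; with the physiological jitter and diluted
connectivity the off-coincidence states are partially rather than fully
silent (see limitations).

## Edge detector

A row of identical relay chains (default 3 neurons, 30 ms, Δ = 0.006 ms);
adjacent chains share a two-input coincidence gate. Charging delivers
stimulations proportional to normalized brightness, either deterministically
(`round(duration · b/b_max)`) or stochastically (per-round Bernoulli with
probability `b/b_max` on a common clock, giving binomial counts with the
same mean and variance `duration·p(1−p)`). Probing stimulates all inputs
simultaneously and applies the core summation rule to each pair; a pair
whose accumulated delay difference exceeds `w` is NULL — an edge. The probe
evaluates a cloned state, so it is non-perturbing and repeatable, and
`reset` restores all latencies for reuse. Stochastic charging can produce
false positives when binomial fluctuations across a uniform region exceed
`w/(chain_length·Δ)` counts; the deterministic variant is exact.

## Fixtures and provenance

All reference configurations are generated programmatically by
`dlg.fixtures` (no stored data files). Parameters not fixed by the
construction (e.g. the four-chain gate's initial delays) are chosen strictly
decreasing and in general position — no two delay lines parallel, no three
concurrent, distinct crossing abscissae — which the random-gate generator
and a concurrency check enforce. Every CLI run emits a manifest (config
hash, seed, version, timestamps, outputs). All randomness derives from
explicit seeds via `numpy.random.SeedSequence` child streams, so toggling
one stochastic feature does not shift the draws of another.

## Limitations

- The linear latency law covers only the intermediate regime; the initial
  fast-rise and the late intermittency/plateau phases are out of scope, as
  is spontaneous latency recovery (modeled only as an explicit reset).
- The exact HH parameter set and synapse kinetics behind the population
  results are not published; the module reproduces the *trends* and the
  lag-minimum index, not waveforms. The weak-synapse scale is a calibrated
  quantity, not a measured one.
- In the population dynamic gate the off-coincidence firing fraction does
  not drop to zero: with 0.15 ms jitter and ~8 diluted inputs per neuron,
  part of the output population still reaches threshold at millisecond
  lags. The NULL → AND → NULL character shows as a peak of the firing
  fraction at the lag minimum, not as a hard gate.
- Summation-window heterogeneity across neurons is supported per neuron but
  defaults to a single value per circuit; no synaptic depression/facilitation
  or learning rules are modeled.
- The analytic engine assumes deterministic 1:1 stimulation of all inputs;
  stochastic protocols (probabilistic delivery, moderation windows) are the
  event engine's domain and are compared to closed forms only in expectation.
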