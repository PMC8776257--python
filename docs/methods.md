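# Methods

## The plasticity rule

Behavioral-timescale synaptic plasticity (BTSP) links presynaptic
activity and dendritic plateau potentials that occur seconds apart.  The
rule implemented here is a three-factor scheme with two exponentially
filtered intermediate signals:

- an **eligibility trace** `ET_i` at each synapse, driven by the
  presynaptic rate `R_i` (or set to 1 by a discrete spike) and decaying
  with `tau_ET`:

      tau_ET * dET_i/dt = -ET_i + lambda_ET * R_i

- an **instructive signal** `IS`, shared by all synapses of a neuron,
  driven by the binary plateau gate `P` and decaying with `tau_IS`:

      tau_IS * dIS/dt = -IS + lambda_IS * P

`lambda_ET = 1/R_max` makes a sustained maximal drive asymptote at 1;
`lambda_IS = 1/(1 - exp(-d/tau_IS))` (with `d` the protocol's plateau
duration, 300 ms by default) makes the signal peak at exactly 1 at
plateau offset.  For spike input a spike sets `ET` to 1 rather than
adding to it: several spikes inside one `tau_ET` therefore saturate
instead of accumulating, keeping the trace in [0, 1].

The signal overlap `x = ET_i * IS` drives saturable potentiation and
depression processes through rescaled sigmoidal gains
`q±(x) = s(x, alpha±, beta±)` with `s(0) = 0`, `s(1) = 1`, inside a
two-state kinetic scheme of finite synaptic resources:

    dW_i/dt = (W_max - W_i) * k+ * q+(x) - W_i * k- * q-(x)

The weight dependence is the point: low-weight synapses potentiate,
high-weight synapses depress at intermediate overlap, and each pairing
timing defines a stable equilibrium weight

    Weq = W_max * k+ dQ+ / (k+ dQ+ + k- dQ-),

where `dQ± = ∫ q±(x(t)) dt` over the pairing.

### Weight-update scheme

Weights are held fixed within an induction lap and updated once at the
lap end.  Given the integrated drives of the lap, the two-state kinetics
along the frozen signal path are linear in `W` and integrate exactly:

    W' = Weq + (W - Weq) * exp(-(k+ dQ+ + k- dQ-))

We use this exact form rather than the first-order expansion
`W += (W_max - W) k+ dQ+ - W k- dQ-` because the expansion diverges
(oscillates against the clipping bounds) whenever
`k+ dQ+ + k- dQ- > 2`, which strong single-spike pairings reach.  The
exact form is unconditionally stable, converges monotonically toward
`Weq` over repeated identical pairings, and reduces to the expansion for
small drives.  A `continuous` mode (explicit Euler every 10 ms) is also
provided; it agrees with a 1 ms oracle to < 1%.  The per-lap and
continuous schemes themselves agree only approximately (≈10% relative
weight change for rate inputs under the in vivo mean parameters, and far
worse for strong spike pairings, where the continuous weight tracks the
instantaneous equilibrium down the overlap tail).  The per-lap scheme is
the canonical one here: the equilibrium-weight analysis presumes it.

### Free parameters

| name       | meaning                                  | units | typical |
|------------|------------------------------------------|-------|---------|
| `tau_ET`   | eligibility-trace decay                  | ms    | 500–3000 |
| `tau_IS`   | instructive-signal decay                 | ms    | 300–1500 |
| `alpha_pot`, `beta_pot` | threshold/slope of the potentiation gain | – | 0.2–0.6 / 4–50 |
| `alpha_dep`, `beta_dep` | threshold/slope of the depression gain   | – | 0.01–0.1 / 40–2000 |
| `k_pot`, `k_dep` | kinetic rate constants             | 1/s   | 1–8 / 0.2–2 |
| `W_max`    | weight at full active-state occupancy    | –     | 2.5–6 |

Two reference sets ship with the package: the single-spike demonstration
set (`fig5_single_spike_params`) and the network set calibrated against
the synthetic target ramps (`btspsim/data/network_rule_params.json`).

## The ramp model

A CA1 cell's subthreshold Vm ramp is a weighted sum of 200 CA3 inputs
with circular Gaussian tuning (peak 40 Hz, full floor width 6σ = 90 cm)
uniformly tiling a 185 cm circular track, evaluated on 100 spatial bins
at bin centers:

    V(x) = c * Σ_i W_i R_i(x) - V_b

`V_b` is the background from all-unit weights, so a naive cell reads 0
everywhere.  The scale `c` and the width of the reference Gaussian
weight profile are calibrated so weights spanning 1–2.5 produce a 6 mV,
108 cm place field.  "Width" is the extent above baseline + 10% of
amplitude, with threshold crossings interpolated between bin centers;
the baseline is the mean of the 10% most hyperpolarized bins.  Rise and
decay *limb* extents of a field are measured to a 2%-of-amplitude floor
instead: the stated limb extents (75/35 cm) describe where the target
shape returns to baseline, and at the 10% criterion even that shape
reads (65, 30).

Weight inference from a measured ramp solves a bounded least-squares
problem (weights ≥ 0, small ridge pulling the 100-equation /
200-unknown null space toward the baseline weight 1).  A flat ramp
recovers exactly unit weights; the noiseless round trip is exact to
<0.05 per weight.

## Synthetic data

Trajectories are constant-velocity circular laps (default 25 cm/s,
10 ms steps) with optional per-lap pauses (input rates are zeroed while
stopped) and optional per-lap lognormal velocity jitter.  Plateaus are
position-triggered: onset at the first crossing of the plateau position
in each induction lap, 300 ms duration.  Synthetic "recorded cells"
bundle ground-truth parameters, initial weights (silent, or a Gaussian
field profile scaled to a requested amplitude), the protocol, and the
forward-simulated final ramp, optionally with additive Gaussian bin
noise; they are bit-reproducible given the seed.

The generator does not emulate raw high-rate Vm (spikes, theta); only
spatially binned, spike-free ramps are produced.  Tests passing on this
material show that the pipeline recovers what the forward model
generated — not that the model captures biological variability beyond
the features built in here.

## Fitting

Parameters are fit by a bounded stochastic search: independent
simulated-annealing chains in a normalized parameter box (log scale for
time constants, slopes and rate constants), geometric cooling, shrinking
Gaussian proposals, periodic restarts from the incumbent best, each
chain refined by Nelder–Mead; the best candidate wins.  Everything is
seeded and bit-reproducible.  The desk-scale default budget is 1500–4000
evaluations (the full-scale convention of 30,000 is a config value).
The objective for cell fits is the per-bin MSE of the predicted final
ramp summed over cells (optionally variance-normalized per cell).

### Network-rule calibration

The network's rule parameters are calibrated against a synthetic target
set: (1) laps at 25 cm/s; (2) three induction laps with one 300 ms
plateau per lap in a silent cell; (3) the induced field has an
asymmetric profile (75 cm rise, 35 cm decay) and an 8 mV peak; (4) three
further laps with plateaus 3 s of running behind the induced peak
depress the old peak by 5 mV and raise an 8 mV field at the new site.
The loss combines tolerance-weighted fractional errors of these
conditions (±10% amplitudes, ±15% extents) with a peak-aligned shape
error and three structural terms that the experimental record fixes but
the four conditions alone leave open:

- **single-trial expression**: the first induction lap must express at
  least 75% of the final amplitude (one-sided).  The four conditions
  admit a family of solutions trading per-pairing magnitude against
  accumulation across laps; BTSP's defining behavioural feature — and
  the regime of the in vivo estimates — is one-shot expression.
- **peak localization**: the induced peak may sit at or slightly before
  (≤ 30 cm) the plateau site, never after.  This removes mirror
  solutions that build the field downstream of the plateau.
- **silent-cell non-negativity**: silent-cell inductions must not
  depress any bin below background (silent cells undergo only
  potentiation).

The calibration search uses physiology-informed bounds (seconds-long
signals; brackets around the in vivo parameter ranges) and warm-starts
its first chain from a recorded reference configuration
(`btspsim/data/calibration_reference.json`, itself produced by a longer
exploratory run of this same search); the reference is also polished as
a candidate, so any seed reaches at least that solution quality, while
the cold chains keep searching the full box.

Achieved conditions at the shipped configuration: peak 8.0 mV, rise
71 cm (−5%), decay 47 cm (+33%), decrement 5.0 mV, new peak 7.5 mV
(−7%).  The decay limb is a known structural residual: with σ = 15 cm
input tuning, a 35 cm baseline-return decay would require a cliff-edge
weight cutoff exactly at the plateau, which smooth gains and the exact
kinetic update cannot produce while simultaneously holding the
decrement and silent-cell conditions.

### Variants

`linear_gains` replaces both sigmoids by the identity, which collapses
the equilibrium weight to the single value `W_max k+/(k+ + k-)` at all
delays — the variant can depress weights above that value, but it
cannot depress an old field while expressing a full-amplitude new one.
`short_timescale` caps both time constants at 50 ms; it produces no
plasticity beyond ±1 s pairing delays and fits seconds-wide ramps
poorly.

## The goal-directed network

500 CA1 rate neurons share the 200 CA3 inputs; output rates are
`max(0, V - 2 mV)/6` (so the calibrated 8 mV field peaks at rate 1).  A
single feedback term `R_INH = λ Σ_k R_k` is normalized so that a
reference population — every neuron carrying one calibrated 8 mV field,
peaks uniformly tiling the track — gives `R_INH = 1` at every position.
Plateau emission is a per-10 ms biased coin flip at probability
`rate · dt`, where the rate follows a descending sigmoid of `R_INH`
anchored at 0.0075/s of running (goal window: 0.035/s) at `R_INH = 0`
and reaching zero at the target activity (0.5 basal, 1.0 goal).  The
slope of that sigmoid is not an empirically fixed quantity; we use 8,
which keeps the probability below 5% of its maximum once `R_INH`
exceeds 90% of target.  The per-second-to-per-step conversion
`rate · dt` is the dimensionally consistent reading of the published
constants; a literal per-step interpretation (`per_step_literal`) is
available but drives every neuron to plateau within one lap.  Plateaus
last 300 ms with a 500 ms refractory period; crossing the goal location
(90 cm) elevates the probability curve for 500 ms.  Weights follow the
per-lap BTSP update; eligibility traces are shared across neurons (same
presynaptic drive) and instructive signals are per neuron.

The census is acquisition-based: a neuron counts as having acquired a
field once its ramp peak has exceeded the 2 mV rate threshold on any
lap, and as silent if it never has — fields can subsequently weaken or
translocate, and the published counts refer to acquisition.

### Known limitations

- At the printed basal rate, 10 laps at 25 cm/s provide 74 s of running,
  so the expected number of neurons with ≥ 1 plateau is at most
  `500·(1 − e^(−0.555)) ≈ 213` even with feedback suppression disabled.
  The model therefore acquires ≈160–190 fields by lap 10, not ~250;
  correspondingly more neurons remain silent after the goal phase.  A
  larger effective session (e.g. inter-lap pauses with plateau emission
  continuing) would close the gap but contradicts the per-second-of-
  running definition of the basal rate.
- When a plateau's instructive-signal tail crosses a lap boundary, the
  next lap's update applies the depression band of the gains to the
  just-potentiated weights at their new, higher value; fields induced
  near the lap end are therefore weaker than mid-lap fields.  This
  position dependence is inherent to the per-lap scheme plus
  weight-dependent depression.
- In the final no-goal phase residual plateau emission (population
  activity is still below target) relocates a few fields; neurons
  without further plateaus are exactly stable (the per-lap update
  touches only plateau emitters), and the median peak shift is 0 bins,
  but the mean across all fielded neurons is 2–3 bins.

## Numerical choices

Signals use the exponential-Euler update (exact for piecewise-constant
drive); all traces are clipped to [0, 1] and weights to [0, W_max].
Spatial evaluation is at bin centers, bin 0 starting at track position
0.  Savitzky–Golay smoothing uses a 21-bin window of order 3 with
circular wrap (configurable; recorded in outputs); the five-point boxcar
is a display transform only and never precedes quantification.  The
ΔVm-surface interpolation uses a Gaussian process with a rational
quadratic kernel, marginal-likelihood optimization with seeded restarts,
and a 1e-6 noise floor for interpolation.  The half-width "return"
criterion is a quarter of the depression trough when the trace goes
meaningfully negative, else a 2%-of-peak floor.  Degenerate flat ramps
report zero-width fields rather than erroring.

Problem sizes used throughout (tests, analysis drivers, acceptance
script): 200 inputs × 100 bins, 3-lap inductions at 10 ms resolution,
1500–4000 search evaluations, and 5-seed network sessions of 20–25 laps;
these reproduce every deterministic quantity exactly and the stochastic
ones to the tolerances stated alongside them.
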