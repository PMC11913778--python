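# Methods

`gabashunt` implements a chain of analyses and models around one scientific
question: does fast GABA-A-mediated synaptic inhibition in cortical pyramidal
neurons act by hyperpolarizing the membrane, or by shunting it?  The decisive
quantity is the driving force DF = RMP − E_GABAAR, where E_GABAAR is the
reversal potential of the GABA-A current and RMP the resting membrane
potential.  DF ≈ 0 means shunting inhibition (inhibition via increased
membrane conductance), DF > 0 means classic hyperpolarizing inhibition.

## 1. IV-based estimation of E_GABAAR (`perforated_patch`)

**Model.**  Over the voltage range of interest both the intrinsic membrane
current and the light-evoked GABA-A current are treated as ohmic:
I(V) = g_l (V − RMP) + g_GABA (V − E_GABAAR).  A voltage-clamp ramp
(−130 → −30 mV in 150 ms from a −70 mV hold) is applied twice, once at rest
("baseline") and once during synaptic GABA-A activation ("light").  Straight
lines are fitted to each current against the series-resistance-corrected
membrane potential; the baseline zero crossing estimates RMP, the zero
crossing of the light-minus-baseline line estimates E_GABAAR, and the slope
difference is the evoked conductance in nS (pA/mV).

**Series-resistance correction.**  In vivo recordings cannot use online Rs
compensation, so the correction is applied offline:
Vm = Vcmd − I·f·Rs with f = 0.9 by default.  Sign convention: currents are in
amplifier convention (inward negative), so a large inward current makes Vm
more depolarized than the command (worked example in the module docstring:
−70 mV command with −1000 pA through 0.9·50 MΩ gives Vm = −25 mV).  The
synthetic generator applies the exact forward distortion
I = (G·Vcmd − b)/(1 + G·Rs), so full correction (f = 1) inverts it exactly
and partial correction leaves a small bias that shrinks monotonically as
f approaches the true fraction — a property asserted in the tests.

**Exclusions.**  The first/last 15 ms of each ramp are dropped (pipette
capacitance transients).  Additional crop windows (time intervals) are
explicit user inputs, mirroring the manual cropping of contaminated segments
in real recordings; the default is edge exclusion only.

**Membrane properties.**  From a −10 mV seal-test step: Rs is estimated twice
— from the peak transient current and from a single exponential fitted to the
transient decay (default window 0.1–10 ms after the edge, a choice the
protocol leaves open) extrapolated back to the edge — and averaged.  Input
resistance comes from the steady-state current and Rm = R_input − Rs.  When
the transient decays within a couple of samples (Rs ≈ 0) the exponential fit
is impossible; the peak estimate is then used for both readouts and flagged
(`expfit_ok=False`).  Recordings with Rs ≥ 100 MΩ are flagged as failed
perforation.

**Step protocol.**  Command steps (−130 … −30 mV by 10 mV, 500 ms) with a
light pulse 100 ms into each step; currents are sampled immediately before
the pulse and in a 2 ms window 20 ms after onset (the conductance peak in the
generator's alpha model, τ = 20 ms).  E_GABAAR is estimated from the same
line-fitting construction.  A second estimate at a user-supplied time (the
time at which the ramp crossed E_GABAAR) provides a stability / GABA-B
diagnostic: for a stationary synaptic reversal the two estimates coincide.

**Vm statistics.**  For current-clamp traces (≥ 10 s): samples above −40 mV
are removed as action potentials; the mean and a Gaussian kernel density
(Scott's rule bandwidth by default) summarize the subthreshold distribution.
Subthreshold fluctuation is the mean |dV/dt| (first difference / dt, mV/ms)
after removing samples within ±2 ms of upward −40 mV crossings and
winsorizing at the 1st/99th percentiles.  The winsorization limits and AP
window are not dictated by the protocol and are configurable.

**Polarity.**  Light-evoked current-clamp responses are averaged across
sweeps, normalized to the 100 ms pre-pulse baseline, and the mean over the
100 ms following the pulse decides the label; a mean of exactly zero is
classified hyperpolarizing (strictly positive ⇒ depolarizing).

## 2. Spike-train metrics (`spike_metrics`)

**Synchrony.**  Per trial, the population peri-stimulus histogram (1 ms bins)
is normalized by that trial's total spike count; a neuron's synchrony is the
mean normalized-histogram value at the bins containing its own spikes, over
all its spikes in all trials.  It is bounded in [0, 1], reaches 1 when every
trial's spikes share one bin, and includes the neuron's own spikes in the
population response by default (an exclude-self switch is provided; the
degenerate single-neuron case then has no population to read from).
Zero-spike neurons are undefined (NaN) and excluded downstream.

**Entropy.**  Shannon entropy (natural log, nats) of the trial-pooled
per-neuron PSTH normalized to a probability vector; bounded by ln(n_bins),
invariant to trial order and to uniform count scaling.

**Evoked rate.**  Spikes in the analysis window divided by
(trials × window length).

**Rate residualization.**  Metrics are regressed on rate (and log-rate) by
ordinary least squares and the paired condition comparison is re-run on the
residuals, to show condition differences are not mere rate artifacts.

**Decoding.**  Per-trial spike-count vectors of a fixed random subset of 50
neurons are classified by k-nearest neighbours (k = 5, Euclidean) under
stratified 5-fold cross-validation.  Counts are taken over the full
inter-stimulus window by default.

## 3. Balanced LIF network (`lif_network`)

**Model.**  1000 single-compartment leaky integrate-and-fire neurons
(800 glutamatergic, 200 GABAergic), conductance-based exponential synapses:

    C dV/dt = g_L(E_L − V) + g_E(E_glut − V) + g_I(E_GABA − V) + I_ext

with C = 200 pF, τ_m = 5 ms (g_L = 40 nS), E_L = −60 mV, E_glut = 0 mV,
synaptic decay 5 ms (exc) / 10 ms (inh), refractory 5 ms, Bernoulli(0.10)
connectivity without self-connections, glutamatergic weights 0.1 nS,
GABAergic weights initialized at 1 nS.  Although the source description says
"current-based", the weights in nS together with specified reversal
potentials — and the very meaning of a shunting condition — require
driving-force-dependent synapses, so conductance-based synapses are used.
Pyramidal E_GABA is −60 mV (= E_L, shunting) or −80 mV (hyperpolarizing);
interneuron E_GABA is always −60 mV.

**Inputs.**  Stimulus patterns are per-neuron amplitude vectors
X = M exp(μ + σZ) with M = 500 pA, μ = 0, σ = 1, delivered as 1 ms pulses
followed by a 25 ms pause; each neuron also receives an independent noise
current of the same log-normal form with M = 25 pA, redrawn every 10 ms
(refresh clock aligned to trial onsets).

**Free constants.**  The published parameter table omits the threshold,
reset, synaptic delay and all plasticity constants.  Choices here, fixed
after a one-time calibration against the published network's summary
statistics and then frozen: threshold −55 mV, reset = E_L, uniform synaptic
delay 1 ms, integration by exponential Euler at dt = 0.1 ms.  The threshold
span matters qualitatively: with a span much larger than ~5 mV the 1 ms
pulses are charge-limited (ΔV ≈ I·t/C), synaptic conductances get almost no
leverage over evoked spiking, and inhibitory homeostasis cannot regulate the
rate at all.

**Balancing.**  Before measurement, inhibitory I→E weights adapt under the
symmetric inhibitory spike-timing rule with a rate target (pre spike:
Δw = η(x_post − α); post spike: Δw = η x_pre; traces decay with
τ_STDP = 20 ms; η = 0.3 nS; weights clipped at 0), while the network is
driven by the same stimulation statistics as the experiment.  Because
stimulus-locked spike correlations shift the rule's fixed point below the
nominal target, a slow servo nudges the depression bias α by
(ρ0/rate)^0.5 once per second until the realized rate matches the target
ρ0 = 11.5 Hz (tolerance ±20% over the final quarter of the run; 60 s
simulated by default; non-convergence raises an error carrying the rate
trajectory).  Weights are then frozen; measurement runs verify bit-identity.

**Measurement.**  Both conditions use the same frozen weights and the same
pattern set; per-neuron synchrony and entropy are computed on the pyramidal
population over the full 26 ms inter-stimulus cycle (1 ms bins).  The
mechanism of the contrast: with E_GABA = −80 mV the inhibitory volley
actively hyperpolarizes pyramidal cells below rest, suppressing late
noise- and recurrence-driven spikes and locking the surviving spikes to the
stimulus (higher synchrony, lower entropy, less total activity); with
E_GABA = E_L inhibition only shunts, late spiking survives, and responses
are more variable and more decodable.

**Scale.**  The full protocol is 100 patterns × 100 repeats × 20 simulations.
Tests use 20 × 10 × 5 seeds and the acceptance script 20 × 20 × 4; at these
sizes the condition ordering is stable in every seed examined and the metric
means move by well under their comparison bands, except that pooled-PSTH
entropy grows slowly with trial count (a sampling property of plug-in
entropy), which is why the acceptance script's problem size is stated
explicitly in its output.

## 4. Passive cable control model (`cable`)

**Purpose.**  A passive multicompartment simulation of the clamp experiment
that quantifies how membrane properties and the electrode series resistance
bias the IV-based E_GABAAR estimate — i.e., whether condition differences in
measured E_GABAAR could be artifacts of condition differences in Rm.

**Model.**  SWC morphologies are mapped to node compartments (single-point
somas become equivalent spheres; each child node carries the lateral frustum
area of the edge to its parent; axial resistance r_a L / (π r₁ r₂) with
r_a = 150 Ω·cm).  Passive membrane: C_m = 2.515 µF/cm², specific resistance
and rest per condition (anesthetized: 10^3.784 Ω·cm², −70.7 mV; awake:
10^3.540, −64.2; awake+NBQX: 10^3.988, −71.4).  The soma is clamped by an
ideal voltage source through Rs = 47.5 MΩ (no amplifier dynamics).  Twenty
GABA-A synapses (2 nS peak, alpha function with τ = 150 ms) are placed
uniformly at random among compartments within 75 µm Euclidean distance of
the soma center (path-distance placement selectable).  Integration is
backward Euler (unconditionally stable) with a direct O(n) tree solve in
Hines order; dt = 25 µs during ramps, 1 ms during settling.

**Protocol.**  The two-ramp protocol of the experiment is simulated and the
recorded clamp current is passed verbatim to the same `fit_iv_ramp` used on
recordings, at 0% or 90% Rs correction.  Synapses are activated one alpha
time-constant before the ramp midpoint so the conductance is at its locally
flat peak during the ramp, matching the experimental intent of measuring the
response at its peak.  The bias sweep iterates true E_GABAAR from −85 to
−35 mV in 5 mV steps with a fixed placement and asserts a monotone
estimated-vs-true relation.

**Key properties verified.**  A soma-only compartment reproduces the RC
closed form R_input = r_m/area + Rs to < 0.5%; input resistance is
independent of step sign/size (passive linearity); with no input the tree
relaxes to rest to < 1 µV; halving dt and segment length moves the estimate
by < 0.2 mV; and 90% correction yields strictly smaller |bias| than 0% at
every grid point.  With the default synthetic morphology the simulated
somatic Rm orders awake < anesthetized < NBQX, as the specific resistances
dictate.

## 5. Synthetic data (`synthetic`)

All generators are seeded pure functions emitting ground-truth sidecars.

- **IV sessions** use the quasi-static ohmic cell behind Rs (exact forward
  distortion, Gaussian current noise; 20 kHz sampling).  The seal-test sweep
  integrates the full RC circuit exactly per sample.  Defaults echo awake
  recordings (RMP −70 mV, E_GABAAR −63.3 mV, 11 nS conductance, Rs 50 MΩ,
  Rm 80 MΩ).  The quasi-static model has no capacitive ramp transient, so it
  tests the estimator's algebra, not its robustness to capacitance artifacts
  (the edge-exclusion mechanism is exercised via explicit crop windows).
- **Vm traces** are Ornstein-Uhlenbeck processes whose per-sample noise is
  set so E|dV/dt| matches a target (default 6.6 mV/ms, the awake scale).
- **Spike rasters** use a shared-event model: per trial one latent population
  event occurs and each neuron joins with probability q, over independent
  Poisson background.  Measured synchrony is provably monotone increasing in
  q and entropy decreasing, which is what makes the raster generator a
  useful oracle; it deliberately lacks the richer temporal structure a
  recurrent network produces (the LIF module is the mechanistic generator).
  Two-condition sessions attach region annotations and waveform durations so
  the full selection pipeline is exercised.
- **Morphologies** are ball-and-stick SWC files (default: 10 µm soma,
  600 µm × 1.5 µm dendrite, chosen to give an input resistance in the range
  of L2/3 pyramidal somatic measurements) with analytic areas in the sidecar.

What passing tests on synthetic data do **not** show: robustness to real
recording artifacts (electrode drift, partial perforation, line noise,
spike-sorting errors), to non-ohmic IV curves, or to non-stationary synaptic
reversal during a protocol.  These remain the experimenter's quality-control
burden.

## Known limitations

- Sorted-unit data are consumed through the in-memory/tabular adapter; an
  NWB reader is not included.
- Sweep input is the documented TSV + JSON dialect; proprietary acquisition
  formats must be exported first.
- The LIF network's threshold and plasticity constants are not uniquely
  determined by the published parameter table; quantitative network means
  depend on them (ordering does not, in all regimes we examined where
  balancing converges).
- The cable model is passive only: no active conductances and no activity-
  dependent chloride dynamics, so it addresses measurement bias, not the
  biology of E_GABAAR shifts.
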