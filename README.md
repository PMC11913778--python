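# gabashunt

Tools for asking whether fast GABA-A synaptic inhibition in cortical
pyramidal neurons is *hyperpolarizing* or *shunting*, and what that
distinction does to network computation.

The decisive quantity is the GABA-A driving force

    DF_GABAAR = RMP − E_GABAAR

where E_GABAAR is the reversal potential of the GABA-A current and RMP the
resting membrane potential.  DF ≈ 0 means inhibition acts by increasing
membrane conductance (shunting); DF > 0 means classic hyperpolarization.
Measuring E_GABAAR in vivo requires gramicidin perforated-patch recordings
(which preserve native chloride), voltage-ramp IV protocols, and careful
offline correction for the electrode series resistance — and interpreting the
result requires controls for what a passive neuron plus electrode would do,
plus network models of what a shunting vs. hyperpolarizing reversal implies
for population activity.  This package implements that entire chain:

- **`gabashunt.perforated_patch`** — IV analysis of voltage-clamp ramp and
  step protocols: offline Rs correction (`Vm = Vcmd − I·f·Rs`), straight-line
  fits of baseline and GABA-evoked currents, RMP / E_GABAAR / DF / synaptic
  conductance estimates, seal-test membrane properties (Rs, R_input, Rm),
  subthreshold Vm statistics, and response-polarity classification.
- **`gabashunt.spike_metrics`** — per-neuron trial-normalized population
  synchrony, peri-stimulus-histogram entropy (nats), evoked rates, rate
  residualization, and k-NN population decoding.
- **`gabashunt.lif_network`** — a balanced 800E/200I conductance-based LIF
  network.  Inhibitory weights are shaped by homeostatic inhibitory STDP and
  frozen; the pyramidal GABA-A reversal is then set to −60 mV (= rest,
  shunting) or −80 mV (hyperpolarizing) and the network is driven with
  log-normal input patterns.  Shunting inhibition desynchronizes evoked
  responses and makes them more diverse and more decodable.
- **`gabashunt.npx`** — paired awake-vs-anesthetized analysis of sorted-unit
  recordings: region / waveform-duration / evoked-rate unit selection and
  per-neuron paired synchrony/entropy comparison on the 2–12 ms
  post-stimulus window.
- **`gabashunt.cable`** — a passive multicompartment model of the clamp
  measurement itself (SWC morphology, somatic clamp through Rs, perisomatic
  alpha-function GABA synapses) quantifying how Rs and membrane properties
  bias the E_GABAAR estimate, and showing 90% Rs correction strictly shrinks
  that bias across the full −85…−35 mV sweep.
- **`gabashunt.synthetic`** — seeded generators with ground-truth sidecars
  for every input: noisy IV sessions, Ornstein-Uhlenbeck Vm traces, PSP
  sweeps, two-condition spike rasters with a synchrony knob, and
  ball-and-stick SWC morphologies.

## Worked example

Estimate E_GABAAR from a synthetic perforated-patch session with known ground
truth (RMP −70 mV, E_GABAAR −63.3 mV, 11 nS conductance, Rs 50 MΩ, 10 pA
current noise):

```python
from gabashunt import synthetic, perforated_patch as pp
from gabashunt.sweeps import CorrectionConfig

truth = synthetic.SweepGroundTruth(egaba_mV=-63.3, rs_MOhm=50.0,
                                   noise_pA=10.0, seed=7)
sess = synthetic.gen_iv_session(truth)

props = pp.estimate_membrane_properties(sess.seal)
print(f"Rs = {props.rs_MOhm:.1f} MOhm, Rm = {props.rm_MOhm:.1f} MOhm, "
      f"perforation_ok = {props.perforation_ok}")

res = pp.fit_iv_ramp(sess.ramp_baseline, sess.ramp_light,
                     CorrectionConfig(rs_MOhm=props.rs_MOhm, rs_fraction=0.9))
print(f"RMP      = {res.rmp_mV:.1f} mV")
print(f"E_GABAAR = {res.egaba_mV:.1f} mV")
print(f"DF       = {res.df_mV:.1f} mV")
print(f"g_GABA   = {res.g_gaba_nS:.1f} nS")
```

prints

```
Rs = 48.5 MOhm, Rm = 77.7 MOhm, perforation_ok = True
RMP      = -70.0 mV
E_GABAAR = -62.7 mV
DF       = -7.3 mV
g_GABA   = 8.9 nS
```

The seal test recovers the electrode and membrane resistances from the −10 mV
step transient; the ramp fit then recovers the reversal to within ~1 mV of
the ground truth despite 50 MΩ of series resistance, because the measured
currents are re-referenced to the Rs-corrected membrane potential before the
lines are fitted.  A DF near zero (here −7.3 mV, i.e. E_GABAAR just above
rest) is the signature of shunting inhibition.

A command-line interface mirrors the library:
`gabashunt fit-ramp`, `fit-step`, `membrane-props`, `vm-stats`, `polarity`,
`metrics`, `simulate`, `cable-bias`, `synth` (see `gabashunt --help`).

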