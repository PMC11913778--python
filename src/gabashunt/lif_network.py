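"""Recurrent balanced LIF network contrasting shunting vs. hyperpolarizing
synaptic inhibition.

The model is a 1000-neuron network (800 glutamatergic, 200 GABAergic) of
single-compartment leaky integrate-and-fire neurons with conductance-based
exponential synapses:

    C dV/dt = g_L (E_L - V) + g_E(t) (E_glut - V) + g_I(t) (E_GABA - V) + I_ext(t)

Connectivity is Bernoulli(p = 0.10) per ordered pair (no self-connections).
Glutamatergic weights are 0.1 nS; GABAergic weights start at 1 nS and are
shaped by homeostatic inhibitory spike-timing plasticity (symmetric rule with
a target rate) until excitatory/inhibitory inputs balance, then frozen.

The experiment delivers 1-ms depolarizing current pulses (per-neuron
amplitudes drawn log-normally around 500 pA, one fixed amplitude vector per
input pattern) followed by a 25-ms pause, with independent log-normal noise
currents (around 25 pA) refreshed every 10 ms.  The pyramidal-cell GABA-A
reversal is -60 mV (= E_L, shunting) in one condition and -80 mV
(hyperpolarizing) in the other; interneurons always use -60 mV.

Membrane integration uses exponential-Euler with a fixed 0.1 ms step; the
spiking threshold (-50 mV) and reset (= E_L) are configurable because they
are not part of the published parameter table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .spike_metrics import SpikeRaster

__all__ = [
    "NetworkConfig",
    "InputSpec",
    "BalanceParams",
    "Network",
    "SimResult",
    "ConvergenceError",
    "build_network",
    "balance_inhibition",
    "run_conditions",
    "population_vectors",
]


class ConvergenceError(RuntimeError):
    """Inhibitory balancing failed to reach the target rate."""

    def __init__(self, message: str, rate_trajectory_Hz: np.ndarray | None = None):
        super().__init__(message)
        self.rate_trajectory_Hz = rate_trajectory_Hz


@dataclass
class NetworkConfig:
    n_exc: int = 800
    n_inh: int = 200
    p_conn: float = 0.10
    w_exc_nS: float = 0.1
    w_inh_init_nS: float = 1.0
    e_leak_mV: float = -60.0  # leak reversal, equivalent to RMP
    e_glut_mV: float = 0.0
    egaba_inh_mV: float = -60.0  # GABA-A reversal in interneurons (fixed)
    tau_exc_syn_ms: float = 5.0
    tau_inh_syn_ms: float = 10.0
    c_m_pF: float = 200.0
    tau_m_ms: float = 5.0
    t_refractory_ms: float = 5.0
    # leak-to-threshold span: 5 mV.  With a larger span the 1-ms input pulses
    # are capacitance-limited and synaptic inhibition has almost no leverage
    # over evoked spiking, which defeats the homeostatic balancing.
    v_threshold_mV: float = -55.0
    v_reset_mV: float = -60.0  # = e_leak
    syn_delay_ms: float = 1.0  # uniform axonal+synaptic transmission delay
    dt_ms: float = 0.1

    # GABA-A reversal in pyramidal cells per condition
    egaba_exc_by_condition: dict = field(
        default_factory=lambda: {"shunting": -60.0, "hyperpolarizing": -80.0}
    )

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def g_leak_nS(self) -> float:
        return self.c_m_pF / self.tau_m_ms  # pF/ms = nS

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_conn <= 1.0):
            raise ValueError("p_conn must be within [0, 1]")
        for tau in (self.tau_exc_syn_ms, self.tau_inh_syn_ms, self.tau_m_ms):
            if tau <= 0:
                raise ValueError("time constants must be positive")
        assert abs(self.g_leak_nS - 40.0) < 1e-9 or self.c_m_pF != 200.0


@dataclass
class InputSpec:
    """Stimulus and noise drive; amplitudes are X = M * exp(mu + sigma*Z)."""

    m_stim_pA: float = 500.0
    m_noise_pA: float = 25.0
    mu: float = 0.0
    sigma: float = 1.0
    pulse_ms: float = 1.0
    pause_ms: float = 25.0
    noise_refresh_ms: float = 10.0
    n_patterns: int = 100
    n_repeats: int = 100

    @property
    def trial_ms(self) -> float:
        return self.pulse_ms + self.pause_ms

    def scaled(self, scale: float) -> "InputSpec":
        """Proportionally reduce patterns/repeats for desk-scale runs."""
        return replace(
            self,
            n_patterns=max(int(round(self.n_patterns * scale)), 2),
            n_repeats=max(int(round(self.n_repeats * scale)), 2),
        )


@dataclass
class BalanceParams:
    """Homeostatic inhibitory plasticity (symmetric STDP with a rate target)."""

    rho0_Hz: float = 11.5  # target excitatory-neuron rate; must lie below the
    # network's uninhibited stimulus-driven rate, which inhibition then trims
    eta_nS: float = 0.3  # weight change per pairing event
    tau_stdp_ms: float = 20.0
    duration_s: float = 60.0
    tolerance: float = 0.2  # final-window mean rate within +/- 20% of rho0
    final_window_frac: float = 0.25
    # slow servo on the depression bias: stimulus-locked spike correlations
    # shift the rule's fixed point below rho0, so the bias is nudged by
    # (rho0 / rate)^gain once per ~1 s block until the realized rate matches
    control_gain: float = 0.5
    control_step_max: float = 1.3

    @property
    def alpha(self) -> float:
        # depression bias: 2 * rho0 * tau_stdp (rate in Hz, tau in s)
        return 2.0 * self.rho0_Hz * self.tau_stdp_ms * 1e-3


@dataclass
class Network:
    cfg: NetworkConfig
    indptr: np.ndarray  # CSR by presynaptic source
    targets: np.ndarray
    weights: np.ndarray  # nS, mutable until frozen
    inh_in_indptr: np.ndarray  # per target: synapse ids with inhibitory source
    inh_in_syn: np.ndarray
    inh_in_src: np.ndarray
    seed: int
    frozen: bool = False
    # persistent dynamic state
    v: np.ndarray | None = None
    g_exc: np.ndarray | None = None
    g_inh: np.ndarray | None = None
    ref_left: np.ndarray | None = None
    q_exc: np.ndarray | None = None
    q_inh: np.ndarray | None = None

    @property
    def n_synapses(self) -> int:
        return int(self.targets.size)

    @property
    def delay_steps(self) -> int:
        return int(round(self.cfg.syn_delay_ms / self.cfg.dt_ms))

    def reset_state(self) -> None:
        n = self.cfg.n_total
        self.v = np.full(n, self.cfg.e_leak_mV)
        self.g_exc = np.zeros(n)
        self.g_inh = np.zeros(n)
        self.ref_left = np.zeros(n, dtype=np.int64)
        self.q_exc = np.zeros((self.delay_steps + 1, n))
        self.q_inh = np.zeros((self.delay_steps + 1, n))


@dataclass
class SimResult:
    raster: SpikeRaster  # pyramidal (excitatory) neurons only
    condition: str
    pattern_labels: np.ndarray  # pattern id per trial
    weights: np.ndarray  # frozen synaptic weights used
    seed: int
    n_spikes_exc: int = 0
    n_spikes_inh: int = 0


def build_network(cfg: NetworkConfig, seed: int) -> Network:
    """Sample Bernoulli connectivity and assign class-dependent weights."""
    rng = np.random.default_rng(seed)
    n = cfg.n_total
    indptr = np.zeros(n + 1, dtype=np.int64)
    all_targets = []
    for i in range(n):
        if cfg.p_conn >= 1.0:
            tgt = np.delete(np.arange(n), i)
        elif cfg.p_conn <= 0.0:
            tgt = np.empty(0, dtype=np.int64)
        else:
            tgt = np.flatnonzero(rng.random(n) < cfg.p_conn)
            tgt = tgt[tgt != i]  # no self-connections
        all_targets.append(tgt.astype(np.int64))
        indptr[i + 1] = indptr[i] + tgt.size
    targets = (
        np.concatenate(all_targets) if all_targets else np.empty(0, dtype=np.int64)
    )
    weights = np.empty(targets.size)
    for i in range(n):
        w = cfg.w_exc_nS if i < cfg.n_exc else cfg.w_inh_init_nS
        weights[indptr[i] : indptr[i + 1]] = w

    # reverse map: for each target, the synapse ids with inhibitory sources
    src_of_syn = np.repeat(np.arange(n), np.diff(indptr))
    inh_mask = src_of_syn >= cfg.n_exc
    syn_ids = np.flatnonzero(inh_mask)
    order = np.argsort(targets[syn_ids], kind="stable")
    syn_sorted = syn_ids[order]
    tgt_sorted = targets[syn_sorted]
    inh_in_indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(inh_in_indptr[1:], tgt_sorted, 1)
    inh_in_indptr = np.cumsum(inh_in_indptr)
    net = Network(
        cfg=cfg,
        indptr=indptr,
        targets=targets,
        weights=weights,
        inh_in_indptr=inh_in_indptr,
        inh_in_syn=syn_sorted.astype(np.int64),
        inh_in_src=src_of_syn[syn_sorted].astype(np.int64),
        seed=seed,
    )
    net.reset_state()
    return net


@njit(cache=True)
def _run_trials(
    indptr,
    targets,
    w,
    n_exc,
    inh_in_indptr,
    inh_in_syn,
    inh_in_src,
    v,
    g_exc,
    g_inh,
    ref_left,
    e_inh,  # per-neuron inhibitory reversal (mV)
    g_leak,
    e_leak,
    e_glut,
    c_m,
    dt,
    tau_e,
    tau_i,
    v_th,
    v_reset,
    ref_steps,
    stim_amps,  # (n_trials, n) pulse amplitude per neuron
    noise_amps,  # (n_trials, n_chunks, n)
    pulse_steps,
    steps_per_trial,
    chunk_steps,
    delay_steps,
    q_exc,  # (delay_steps+1, n) delayed-conductance queues
    q_inh,
    plastic,
    eta,
    alpha,
    tau_stdp,
    x_trace,
    spk_neuron,  # output buffers
    spk_trial,
    spk_time,
):
    """Simulate a sequence of stimulus trials; returns the spike count.

    State arrays (v, conductances, refractory counters, plasticity traces and
    weights) are updated in place, so consecutive calls continue the same
    simulation.
    """
    n = v.size
    dec_e = np.exp(-dt / tau_e)
    dec_i = np.exp(-dt / tau_i)
    dec_x = np.exp(-dt / tau_stdp)
    n_trials = stim_amps.shape[0]
    count = 0
    max_spikes = spk_neuron.size
    q_len = delay_steps + 1
    slot = 0  # queue slot for the current step
    for trial in range(n_trials):
        for s in range(steps_per_trial):
            chunk = s // chunk_steps
            if chunk >= noise_amps.shape[1]:
                chunk = noise_amps.shape[1] - 1
            for j in range(n):
                g_exc[j] = g_exc[j] * dec_e + q_exc[slot, j]
                g_inh[j] = g_inh[j] * dec_i + q_inh[slot, j]
                q_exc[slot, j] = 0.0
                q_inh[slot, j] = 0.0
                if plastic:
                    x_trace[j] *= dec_x
            for j in range(n):
                if ref_left[j] > 0:
                    ref_left[j] -= 1
                    v[j] = v_reset
                    continue
                i_ext = noise_amps[trial, chunk, j]
                if s < pulse_steps:
                    i_ext += stim_amps[trial, j]
                g_tot = g_leak + g_exc[j] + g_inh[j]
                v_inf = (
                    g_leak * e_leak
                    + g_exc[j] * e_glut
                    + g_inh[j] * e_inh[j]
                    + i_ext
                ) / g_tot
                v[j] = v_inf + (v[j] - v_inf) * np.exp(-g_tot * dt / c_m)
                if v[j] > 200.0 or v[j] < -200.0:
                    return -1  # numerical instability
            # threshold crossings and propagation
            for j in range(n):
                if ref_left[j] == 0 and v[j] >= v_th:
                    if count < max_spikes:
                        spk_neuron[count] = j
                        spk_trial[count] = trial
                        spk_time[count] = s * dt
                        count += 1
                    v[j] = v_reset
                    ref_left[j] = ref_steps
                    dslot = (slot + delay_steps) % q_len
                    for k in range(indptr[j], indptr[j + 1]):
                        tgt = targets[k]
                        if j < n_exc:
                            q_exc[dslot, tgt] += w[k]
                        else:
                            q_inh[dslot, tgt] += w[k]
                    if plastic:
                        x_trace[j] += 1.0
                        # the homeostatic rule acts on I->E synapses only
                        if j >= n_exc:
                            # presynaptic inhibitory spike
                            for k in range(indptr[j], indptr[j + 1]):
                                if targets[k] < n_exc:
                                    w[k] += eta * (x_trace[targets[k]] - alpha)
                                    if w[k] < 0.0:
                                        w[k] = 0.0
                        else:
                            # postsynaptic update on incoming inhibitory synapses
                            for m in range(inh_in_indptr[j], inh_in_indptr[j + 1]):
                                k = inh_in_syn[m]
                                w[k] += eta * x_trace[inh_in_src[m]]
                                if w[k] < 0.0:
                                    w[k] = 0.0
            slot = (slot + 1) % q_len
    return count


def _lognormal_amps(
    rng: np.random.Generator, m: float, mu: float, sigma: float, shape
) -> np.ndarray:
    return m * np.exp(mu + sigma * rng.standard_normal(shape))


def _simulate_block(
    net: Network,
    inputs: InputSpec,
    stim_amps: np.ndarray,
    rng: np.random.Generator,
    e_gaba_exc: float,
    plastic: bool = False,
    bal: BalanceParams | None = None,
    x_trace: np.ndarray | None = None,
    alpha_override: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run one block of trials; returns (spk_neuron, spk_trial, spk_time_ms)."""
    cfg = net.cfg
    n = cfg.n_total
    n_trials = stim_amps.shape[0]
    steps_per_trial = int(round(inputs.trial_ms / cfg.dt_ms))
    pulse_steps = int(round(inputs.pulse_ms / cfg.dt_ms))
    chunk_steps = int(round(inputs.noise_refresh_ms / cfg.dt_ms))
    n_chunks = int(np.ceil(steps_per_trial / chunk_steps))
    noise = _lognormal_amps(
        rng, inputs.m_noise_pA, inputs.mu, inputs.sigma, (n_trials, n_chunks, n)
    )
    e_inh = np.full(n, e_gaba_exc)
    e_inh[cfg.n_exc :] = cfg.egaba_inh_mV
    cap = max(int(n * n_trials * 2.0), 10_000)
    spk_neuron = np.empty(cap, dtype=np.int64)
    spk_trial = np.empty(cap, dtype=np.int64)
    spk_time = np.empty(cap)
    if x_trace is None:
        x_trace = np.zeros(n)
    count = _run_trials(
        net.indptr,
        net.targets,
        net.weights,
        cfg.n_exc,
        net.inh_in_indptr,
        net.inh_in_syn,
        net.inh_in_src,
        net.v,
        net.g_exc,
        net.g_inh,
        net.ref_left,
        e_inh,
        cfg.g_leak_nS,
        cfg.e_leak_mV,
        cfg.e_glut_mV,
        cfg.c_m_pF,
        cfg.dt_ms,
        cfg.tau_exc_syn_ms,
        cfg.tau_inh_syn_ms,
        cfg.v_threshold_mV,
        cfg.v_reset_mV,
        int(round(cfg.t_refractory_ms / cfg.dt_ms)),
        stim_amps,
        noise,
        pulse_steps,
        steps_per_trial,
        chunk_steps,
        net.delay_steps,
        net.q_exc,
        net.q_inh,
        plastic,
        bal.eta_nS if bal else 0.0,
        (alpha_override if alpha_override is not None else bal.alpha) if bal else 0.0,
        bal.tau_stdp_ms if bal else 20.0,
        x_trace,
        spk_neuron,
        spk_trial,
        spk_time,
    )
    if count < 0:
        raise RuntimeError("numerical instability: |V| exceeded 200 mV")
    if count >= cap:
        raise RuntimeError("spike buffer overflow; network is pathologically active")
    return spk_neuron[:count], spk_trial[:count], spk_time[:count]


def balance_inhibition(
    net: Network,
    bal: BalanceParams | None = None,
    inputs: InputSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Adapt inhibitory weights with the homeostatic rule, then freeze them.

    The network is driven by the same stimulation statistics as the
    experiment (fresh random input patterns plus noise) while the symmetric
    inhibitory STDP rule pushes excitatory-neuron rates toward the target
    ``rho0``.  Returns the per-second excitatory population rate trajectory;
    raises :class:`ConvergenceError` (with the trajectory attached) when the
    final-window mean rate misses the target by more than the tolerance.
    Balancing is performed with the shunting (default) pyramidal E_GABAAR.
    """
    bal = bal or BalanceParams()
    inputs = inputs or InputSpec()
    cfg = net.cfg
    rng = np.random.default_rng(seed)
    trial_s = inputs.trial_ms * 1e-3
    n_trials = int(round(bal.duration_s / trial_s))
    trials_per_block = max(int(round(1.0 / trial_s)), 1)  # ~1 s blocks
    x_trace = np.zeros(cfg.n_total)
    rates = []
    done = 0
    e_shunt = cfg.egaba_exc_by_condition["shunting"]
    alpha_eff = bal.alpha
    while done < n_trials:
        block = min(trials_per_block, n_trials - done)
        stim = _lognormal_amps(
            rng, inputs.m_stim_pA, inputs.mu, inputs.sigma, (block, cfg.n_total)
        )
        neu, _, _ = _simulate_block(
            net, inputs, stim, rng, e_shunt, plastic=not net.frozen, bal=bal,
            x_trace=x_trace, alpha_override=alpha_eff,
        )
        n_exc_spikes = int(np.count_nonzero(neu < cfg.n_exc))
        r_block = n_exc_spikes / (cfg.n_exc * block * trial_s)
        rates.append(r_block)
        done += block
        step = (bal.rho0_Hz / max(r_block, 0.2)) ** bal.control_gain
        step = min(max(step, 1.0 / bal.control_step_max), bal.control_step_max)
        alpha_eff *= step
    rates = np.asarray(rates)
    n_final = max(int(round(bal.final_window_frac * rates.size)), 1)
    final_rate = float(rates[-n_final:].mean())
    if not (abs(final_rate - bal.rho0_Hz) <= bal.tolerance * bal.rho0_Hz):
        raise ConvergenceError(
            f"balancing did not converge: final mean excitatory rate "
            f"{final_rate:.2f} Hz vs target {bal.rho0_Hz:.2f} Hz "
            f"(+/- {bal.tolerance:.0%})",
            rate_trajectory_Hz=rates,
        )
    net.frozen = True
    return rates


def run_conditions(
    net: Network,
    inputs: InputSpec | None = None,
    seed: int = 0,
    conditions: tuple[str, ...] = ("shunting", "hyperpolarizing"),
) -> dict[str, SimResult]:
    """Deliver every input pattern ``n_repeats`` times under each condition.

    Pattern amplitude vectors are drawn once (shared across conditions and
    repeats); trial order is shuffled; noise is refreshed every 10 ms.  The
    raster covers the pyramidal (excitatory) neurons over the full
    inter-stimulus cycle (0 to pulse+pause ms), with the pattern id as trial
    label.  Weights must be frozen (balanced) beforehand.
    """
    if not net.frozen:
        raise RuntimeError("balance the network (freeze weights) before measuring")
    inputs = inputs or InputSpec()
    cfg = net.cfg
    rng = np.random.default_rng(seed)
    patterns = _lognormal_amps(
        rng, inputs.m_stim_pA, inputs.mu, inputs.sigma, (inputs.n_patterns, cfg.n_total)
    )
    labels = np.repeat(np.arange(inputs.n_patterns), inputs.n_repeats)
    order = rng.permutation(labels.size)
    labels = labels[order]
    stim = patterns[labels]
    results = {}
    for condition in conditions:
        e_gaba = cfg.egaba_exc_by_condition[condition]
        net.reset_state()
        cond_rng = np.random.default_rng(rng.integers(2**31))
        w_before = net.weights.copy()
        neu, trial, time = _simulate_block(net, inputs, stim, cond_rng, e_gaba)
        assert np.array_equal(w_before, net.weights), "weights changed while frozen"
        n_trials = stim.shape[0]
        spikes: list[list[list[float]]] = [
            [[] for _ in range(n_trials)] for _ in range(cfg.n_exc)
        ]
        n_exc_spk = 0
        for j, tr, t in zip(neu, trial, time):
            if j < cfg.n_exc:
                spikes[j][tr].append(t)
                n_exc_spk += 1
        raster = SpikeRaster(
            [[np.array(ts) for ts in per] for per in spikes],
            window=(0.0, inputs.trial_ms),
            trial_labels=labels,
            condition=condition,
        )
        results[condition] = SimResult(
            raster=raster,
            condition=condition,
            pattern_labels=labels,
            weights=net.weights.copy(),
            seed=seed,
            n_spikes_exc=n_exc_spk,
            n_spikes_inh=int(neu.size - n_exc_spk),
        )
    return results


def population_vectors(
    result: SimResult, n_sample: int = 50, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial spike counts of a fixed random subset of pyramidal neurons.

    Returns (vectors, labels) ready for :func:`spike_metrics.decode_patterns`.
    """
    rng = np.random.default_rng(seed)
    raster = result.raster
    idx = rng.choice(raster.n_neurons, size=n_sample, replace=False)
    t0, t1 = raster.window
    vecs = np.zeros((raster.n_trials, n_sample))
    for col, j in enumerate(idx):
        for trial in range(raster.n_trials):
            t = raster.spikes[j][trial]
            vecs[trial, col] = np.count_nonzero((t >= t0) & (t < t1))
    return vecs, result.pattern_labels
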