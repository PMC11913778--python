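"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with a
machine-readable ground-truth sidecar, so all stages are testable without any
recorded data: noisy linear IV sessions (ramp, step and seal-test sweeps with
known RMP / E_GABAAR / Rs / Rm), current-clamp traces with controllable
subthreshold fluctuation, light-evoked postsynaptic potential sweeps,
two-condition spike rasters with a controllable shared-event synchrony knob,
and ball-and-stick SWC morphologies.

All generators are seeded pure functions: the same ground truth (including
its seed) yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sweeps import Sweep
from .spike_metrics import SpikeRaster

__all__ = [
    "SweepGroundTruth",
    "IVSession",
    "gen_iv_session",
    "gen_vm_trace",
    "gen_polarity_session",
    "RasterGroundTruth",
    "gen_raster",
    "gen_two_condition_raster",
    "gen_ballstick_swc",
]

SAMPLE_RATE_HZ = 20_000.0  # acquisition rate emulated by all sweep generators


# ---------------------------------------------------------------------------
# IV sessions (voltage clamp)


@dataclass
class SweepGroundTruth:
    """Ground truth for one synthetic voltage-clamp session."""

    rmp_mV: float = -70.0
    egaba_mV: float = -63.3  # awake-like default
    g_gaba_nS: float = 11.0
    rs_MOhm: float = 50.0
    rm_MOhm: float = 80.0
    cm_pF: float = 100.0
    noise_pA: float = 0.0
    seed: int = 0

    @property
    def g_leak_nS(self) -> float:
        return 1e3 / self.rm_MOhm

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IVSession:
    ramp_baseline: Sweep
    ramp_light: Sweep
    seal: Sweep
    steps: list[Sweep]
    truth: SweepGroundTruth


def _quasi_static_current(
    vcmd: np.ndarray, g_gaba: np.ndarray, truth: SweepGroundTruth
) -> np.ndarray:
    """Steady-state clamp current (pA) of an ohmic cell behind Rs.

    The membrane sits behind the uncompensated series resistance, so the
    membrane voltage solves V = Vcmd - I*Rs with
    I = g_l*(V - RMP) + g_gaba*(V - E_gaba); eliminating V gives
    I = (G*Vcmd - b) / (1 + G*Rs*1e-3) with G = g_l + g_gaba (nS),
    b = g_l*RMP + g_gaba*E_gaba (pA).
    """
    g_l = truth.g_leak_nS
    G = g_l + g_gaba
    b = g_l * truth.rmp_mV + g_gaba * truth.egaba_mV
    return (G * vcmd - b) / (1.0 + G * truth.rs_MOhm * 1e-3)


def _ramp_command(
    hold_mV: float = -70.0,
    span: tuple[float, float] = (-130.0, -30.0),
    ramp_ms: float = 150.0,
    pre_ms: float = 50.0,
    post_ms: float = 50.0,
    dt: float = 1.0 / SAMPLE_RATE_HZ,
) -> tuple[np.ndarray, int, int]:
    n_pre = int(round(pre_ms * 1e-3 / dt))
    n_ramp = int(round(ramp_ms * 1e-3 / dt))
    n_post = int(round(post_ms * 1e-3 / dt))
    lo, hi = span
    cmd = np.concatenate(
        [
            np.full(n_pre, hold_mV),
            np.linspace(lo, hi, n_ramp),
            np.full(n_post, hold_mV),
        ]
    )
    return cmd, n_pre, n_pre + n_ramp


def gen_iv_session(truth: SweepGroundTruth) -> IVSession:
    """Generate ramp (baseline + light), seal-test and step-protocol sweeps.

    Series-resistance distortion is applied forward (the inverse of the
    offline correction) and Gaussian current noise of ``truth.noise_pA`` is
    added.  With zero noise and zero Rs the ramp analysis recovers the ground
    truth to machine precision.
    """
    if truth.rs_MOhm >= 1000.0:
        raise ValueError("rs_MOhm must be < 1 GOhm for a usable recording")
    rng = np.random.default_rng(truth.seed)
    dt = 1.0 / SAMPLE_RATE_HZ

    # --- ramps: light conductance on from ramp start onward (evoked at ramp onset)
    cmd, i0, i1 = _ramp_command(dt=dt)
    g_off = np.zeros_like(cmd)
    g_on = np.zeros_like(cmd)
    g_on[i0:] = truth.g_gaba_nS
    sweeps = {}
    for name, g in (("baseline", g_off), ("light", g_on)):
        i = _quasi_static_current(cmd, g, truth)
        i = i + rng.normal(0.0, truth.noise_pA, i.size)
        sweeps[name] = Sweep(
            dt=dt,
            command=cmd,
            recorded=i,
            mode="VC",
            light_onset=i0 * dt if name == "light" else None,
            light_duration=0.010 if name == "light" else None,
            sweep_id=f"ramp_{name}",
        )

    # --- seal test: -10 mV step, full RC dynamics (exact exponential update)
    seal = _seal_sweep(truth, rng, dt)

    # --- step protocol: light pulse 100 ms into each 500 ms step,
    #     alpha-function GABA conductance peaking (= g_gaba) 20 ms after onset
    steps = []
    tau_alpha_ms = 20.0
    for v_step in np.arange(-130.0, -20.0, 10.0):
        n_pre = int(round(0.100 / dt))
        n_step = int(round(0.500 / dt))
        n_post = int(round(0.200 / dt))
        cmd_s = np.concatenate(
            [np.full(n_pre, -70.0), np.full(n_step, v_step), np.full(n_post, -70.0)]
        )
        t_ms = np.arange(cmd_s.size) * dt * 1e3
        on_ms = 200.0
        rel = np.maximum(t_ms - on_ms, 0.0) / tau_alpha_ms
        g = truth.g_gaba_nS * rel * np.exp(1.0 - rel)
        i = _quasi_static_current(cmd_s, g, truth)
        i = i + rng.normal(0.0, truth.noise_pA, i.size)
        steps.append(
            Sweep(
                dt=dt,
                command=cmd_s,
                recorded=i,
                mode="VC",
                light_onset=on_ms * 1e-3,
                light_duration=0.100,
                sweep_id=f"step_{v_step:+.0f}mV",
            )
        )

    return IVSession(
        ramp_baseline=sweeps["baseline"],
        ramp_light=sweeps["light"],
        seal=seal,
        steps=steps,
        truth=truth,
    )


def _seal_sweep(truth: SweepGroundTruth, rng: np.random.Generator, dt: float) -> Sweep:
    hold, amp = -70.0, -10.0
    n_pre = int(round(0.050 / dt))
    n_step = int(round(0.200 / dt))
    n_post = int(round(0.050 / dt))
    cmd = np.concatenate(
        [np.full(n_pre, hold), np.full(n_step, hold + amp), np.full(n_post, hold)]
    )
    dt_ms = dt * 1e3
    rs, rm, cm, e = truth.rs_MOhm, truth.rm_MOhm, truth.cm_pF, truth.rmp_mV
    i = np.empty_like(cmd)
    if rs > 1e-9:
        # membrane node behind Rs: exact exponential relaxation per sample
        r_par = rs * rm / (rs + rm)
        tau_ms = cm * r_par * 1e-3  # pF * MOhm -> ms
        decay = math.exp(-dt_ms / tau_ms)
        vc = (hold / rs + e / rm) * r_par  # steady state at hold
        for k in range(cmd.size):
            i[k] = (cmd[k] - vc) / rs * 1e3  # mV/MOhm -> nA -> pA
            v_inf = (cmd[k] / rs + e / rm) * r_par
            vc = v_inf + (vc - v_inf) * decay
    else:
        # ideal clamp: ohmic current plus one-sample capacitive spikes
        i = (cmd - e) / rm * 1e3
        i[1:] += cm * np.diff(cmd) / dt_ms  # pF*mV/ms = pA
    i = i + rng.normal(0.0, truth.noise_pA, i.size)
    return Sweep(dt=dt, command=cmd, recorded=i, mode="VC", sweep_id="seal_test")


# ---------------------------------------------------------------------------
# current-clamp traces


def gen_vm_trace(
    duration_s: float = 300.0,
    mean_vm_mV: float = -60.3,
    target_dvdt_mV_per_ms: float = 6.6,
    tau_ms: float = 10.0,
    seed: int = 0,
    dt: float = 1.0 / SAMPLE_RATE_HZ,
) -> Sweep:
    """Awake-like subthreshold membrane-potential trace (Ornstein-Uhlenbeck).

    The per-sample noise amplitude is set so that the expected mean absolute
    first derivative equals ``target_dvdt_mV_per_ms`` (the increment is
    Gaussian, so E|dV/dt| = sigma_w * sqrt(2/pi) / sqrt(dt)).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    dt_ms = dt * 1e3
    sigma_w = target_dvdt_mV_per_ms * math.sqrt(math.pi / 2.0) * math.sqrt(dt_ms)
    theta = dt_ms / tau_ms
    incr = sigma_w * math.sqrt(dt_ms) * rng.standard_normal(n)
    v = np.empty(n)
    v[0] = mean_vm_mV
    for k in range(1, n):
        v[k] = v[k - 1] + theta * (mean_vm_mV - v[k - 1]) + incr[k]
    cmd = np.zeros(n)  # no injected current
    return Sweep(dt=dt, command=cmd, recorded=v, mode="IC", sweep_id="vm_spontaneous")


def gen_polarity_session(
    amplitude_mV: float = -2.0,
    noise_sd_mV: float = 0.5,
    n_sweeps: int = 15,
    rmp_mV: float = -65.0,
    tau_ms: float = 20.0,
    seed: int = 0,
    dt: float = 1.0 / SAMPLE_RATE_HZ,
) -> list[Sweep]:
    """One-second IC sweeps with a light-evoked PSP of known polarity.

    The response is an alpha-shaped deflection of peak ``amplitude_mV``
    starting at the light pulse (10 ms, onset 0.4 s), on top of Gaussian
    membrane noise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(1.0 / dt))
    t_ms = np.arange(n) * dt * 1e3
    onset_ms = 400.0
    rel = np.maximum(t_ms - onset_ms, 0.0) / tau_ms
    psp = amplitude_mV * rel * np.exp(1.0 - rel)
    sweeps = []
    for k in range(n_sweeps):
        v = rmp_mV + psp + rng.normal(0.0, noise_sd_mV, n)
        sweeps.append(
            Sweep(
                dt=dt,
                command=np.zeros(n),
                recorded=v,
                mode="IC",
                light_onset=onset_ms * 1e-3,
                light_duration=0.010,
                sweep_id=f"polarity_{k}",
            )
        )
    return sweeps


# ---------------------------------------------------------------------------
# spike rasters


@dataclass
class RasterGroundTruth:
    """Shared-event raster model: per trial one latent population event occurs
    and each neuron joins it with probability ``q`` (the synchrony knob), on
    top of independent Poisson background spiking."""

    n_neurons: int = 50
    n_trials: int = 200
    window_ms: tuple[float, float] = (0.0, 12.0)
    q: float = 0.5
    background_rate_Hz: float = 20.0
    event_time_ms: float = 5.5
    event_jitter_ms: float = 0.0  # trial-to-trial jitter of the event time
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must be within [0, 1]")


def gen_raster(truth: RasterGroundTruth, condition: str = "") -> SpikeRaster:
    rng = np.random.default_rng(truth.seed)
    t0, t1 = truth.window_ms
    span_s = (t1 - t0) * 1e-3
    spikes: list[list[np.ndarray]] = [[] for _ in range(truth.n_neurons)]
    for _trial in range(truth.n_trials):
        ev = truth.event_time_ms + truth.event_jitter_ms * rng.standard_normal()
        ev = float(np.clip(ev, t0 + 0.5, t1 - 0.5))
        joins = rng.random(truth.n_neurons) < truth.q
        for j in range(truth.n_neurons):
            ts = []
            if joins[j]:
                # within-bin placement only, so q = 1 gives synchrony 1 exactly
                ts.append(math.floor(ev) + 0.1 + 0.8 * rng.random())
            n_bg = rng.poisson(truth.background_rate_Hz * span_s)
            ts.extend(t0 + (t1 - t0) * rng.random(n_bg))
            spikes[j].append(np.sort(np.array(ts)))
    return SpikeRaster(spikes, truth.window_ms, condition=condition)


@dataclass
class SyntheticSession:
    """Two-condition synthetic spike data in the shape of a sorted-unit session."""

    rasters: dict  # condition -> SpikeRaster
    truths: dict  # condition -> RasterGroundTruth
    units: pd.DataFrame  # unit_id, region, waveform_duration_ms
    stimulated_area: str
    stim_onsets_s: dict  # condition -> stimulus onset times (s)


def gen_two_condition_raster(
    awake: RasterGroundTruth | None = None,
    anesthetized: RasterGroundTruth | None = None,
    stimulated_area: str = "SS",
    frac_fast_spiking: float = 0.2,
    seed: int = 0,
) -> SyntheticSession:
    """Awake-like (low synchrony, high rate) vs anesthetized-like (high
    synchrony, low rate) rasters plus unit/session tables so the selection
    pipeline can be exercised end to end."""
    rng = np.random.default_rng(seed)
    if awake is None:
        awake = RasterGroundTruth(
            q=0.3, background_rate_Hz=60.0, seed=int(rng.integers(2**31))
        )
    if anesthetized is None:
        anesthetized = RasterGroundTruth(
            n_neurons=awake.n_neurons,
            n_trials=awake.n_trials,
            window_ms=awake.window_ms,
            q=0.8,
            background_rate_Hz=10.0,
            seed=int(rng.integers(2**31)),
        )
    if awake.n_neurons != anesthetized.n_neurons:
        raise ValueError("conditions must share the neuron population")
    rasters = {
        "awake": gen_raster(awake, "awake"),
        "anesthetized": gen_raster(anesthetized, "anesthetized"),
    }
    n = awake.n_neurons
    regions = {"SS": ["SSp-ll", "SSp-tr"], "MO": ["MOs"]}[stimulated_area]
    is_fs = rng.random(n) < frac_fast_spiking
    units = pd.DataFrame(
        {
            "unit_id": np.arange(n),
            "region": [regions[k % len(regions)] for k in range(n)],
            "waveform_duration_ms": np.where(
                is_fs, rng.uniform(0.15, 0.35, n), rng.uniform(0.45, 0.9, n)
            ),
        }
    )
    onsets = {
        cond: 1.0 + np.arange(truth.n_trials) * 1.0
        for cond, truth in (("awake", awake), ("anesthetized", anesthetized))
    }
    return SyntheticSession(
        rasters=rasters,
        truths={"awake": awake, "anesthetized": anesthetized},
        units=units,
        stimulated_area=stimulated_area,
        stim_onsets_s=onsets,
    )


# ---------------------------------------------------------------------------
# morphologies


def gen_ballstick_swc(
    soma_radius_um: float = 10.0,
    dend_length_um: float = 600.0,
    dend_radius_um: float = 1.5,
    n_dend_nodes: int = 40,
    path: str | Path | None = None,
) -> tuple[str, dict]:
    """Ball-and-stick SWC morphology with an analytic-surface-area sidecar.

    The soma is a single node (sphere, area 4*pi*r^2); the dendrite is a
    uniform cylinder along +x starting at the soma surface, area
    2*pi*r*L.  With ``n_dend_nodes=0`` a soma-only morphology is emitted.
    Returns (swc text, sidecar dict); writes the text to ``path`` if given.
    """
    if soma_radius_um <= 0 or dend_radius_um <= 0 or dend_length_um < 0:
        raise ValueError("dimensions must be positive")
    lines = ["# synthetic ball-and-stick morphology"]
    lines.append(f"1 1 0.0 0.0 0.0 {soma_radius_um:.6g} -1")
    if n_dend_nodes > 0:
        seg = dend_length_um / n_dend_nodes
        for k in range(1, n_dend_nodes + 1):
            x = soma_radius_um + k * seg
            parent = 1 if k == 1 else k
            lines.append(f"{k + 1} 3 {x:.6g} 0.0 0.0 {dend_radius_um:.6g} {parent}")
    text = "\n".join(lines) + "\n"
    sidecar = {
        "soma_area_um2": 4.0 * math.pi * soma_radius_um**2,
        "dend_area_um2": 2.0 * math.pi * dend_radius_um * dend_length_um
        if n_dend_nodes
        else 0.0,
        "soma_radius_um": soma_radius_um,
        "dend_length_um": dend_length_um,
        "dend_radius_um": dend_radius_um,
    }
    if path is not None:
        Path(path).write_text(text)
    return text, sidecar
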