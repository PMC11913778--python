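"""Analysis of perforated patch-clamp sweeps.

Turns raw voltage-/current-clamp sweeps into membrane properties, resting
membrane-potential statistics, GABAergic response polarity, and IV-based
estimates of the GABA-A reversal potential (E_GABAAR) with offline
series-resistance correction.

Conventions
-----------
Currents follow amplifier convention (inward negative).  The series-resistance
correction estimates the true membrane potential as

    Vm = Vcmd - I * f * Rs

with ``I`` the recorded current and ``f`` the correction fraction.  Worked
example: Vcmd = -70 mV, I = -1000 pA, Rs = 50 MOhm, f = 0.9 gives a voltage
drop of -1000 pA * 0.9 * 50 MOhm = -45 mV, hence Vm = -70 - (-45) = -25 mV.
With currents in pA and resistances in MOhm the drop in mV is
``I_pA * f * Rs_MOhm * 1e-3``.

Fitting currents (pA) against corrected voltages (mV) yields slopes directly
in nS; the zero crossing of the baseline line is the resting membrane
potential, the zero crossing of the light-minus-baseline line is E_GABAAR,
and its slope is the evoked GABA-A conductance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .sweeps import CorrectionConfig, ProtocolDescriptor, Sweep

__all__ = [
    "FitError",
    "NoIntersectionError",
    "InsufficientDataError",
    "MembraneProperties",
    "IVFit",
    "EgabaResult",
    "VmStats",
    "PolarityResult",
    "correct_series_resistance",
    "estimate_membrane_properties",
    "fit_iv_ramp",
    "fit_iv_step",
    "vm_statistics",
    "classify_polarity",
    "find_ramp_epoch",
]

RS_ACCEPTANCE_MOHM = 100.0  # perforation quality criterion: Rs must be below this


class FitError(RuntimeError):
    """A required fit could not be performed (e.g., no detectable transient)."""


class NoIntersectionError(FitError):
    """Baseline and light IV lines are parallel within tolerance."""


class InsufficientDataError(ValueError):
    """Too few samples/points remain after exclusion windows."""


# ---------------------------------------------------------------------------
# result containers


@dataclass
class MembraneProperties:
    rs_peak_MOhm: float
    rs_expfit_MOhm: float
    rs_MOhm: float  # mean of the two estimates
    r_input_MOhm: float
    rm_MOhm: float  # r_input - rs
    tau_ms: float
    perforation_ok: bool = True  # rs below the 100 MOhm acceptance criterion
    steady_state_ok: bool = True  # steady window spans >= 3 time constants
    expfit_ok: bool = True  # False when the decay was too fast to fit and
    # the peak estimate was used for both Rs readouts


@dataclass
class IVFit:
    slope_nS: float
    intercept_pA: float
    reversal_mV: float
    fit_voltage_window_mV: tuple[float, float]
    n_points: int


@dataclass
class EgabaResult:
    rmp_mV: float
    egaba_mV: float
    df_mV: float  # driving force, rmp - egaba by definition
    g_gaba_nS: float
    protocol: str  # ramp | step20ms | stepAtRampTime
    baseline_fit: IVFit | None = None
    diff_fit: IVFit | None = None
    g_gaba_nonnegative: bool = True

    @classmethod
    def from_fits(cls, baseline: IVFit, diff: IVFit, protocol: str) -> "EgabaResult":
        rmp = baseline.reversal_mV
        egaba = diff.reversal_mV
        return cls(
            rmp_mV=rmp,
            egaba_mV=egaba,
            df_mV=rmp - egaba,
            g_gaba_nS=diff.slope_nS,
            protocol=protocol,
            baseline_fit=baseline,
            diff_fit=diff,
            g_gaba_nonnegative=diff.slope_nS >= 0,
        )


@dataclass
class VmStats:
    mean_vm_mV: float
    density_grid_mV: np.ndarray
    density: np.ndarray  # probability density over the grid
    mean_abs_dvdt_mV_per_ms: float
    n_samples_included: int


@dataclass
class PolarityResult:
    mean_post_light_mV: float
    label: str  # depolarizing | hyperpolarizing

    @classmethod
    def from_mean(cls, mean_post: float) -> "PolarityResult":
        # strict > 0 for depolarizing: a tie at exactly zero is hyperpolarizing
        label = "depolarizing" if mean_post > 0 else "hyperpolarizing"
        return cls(mean_post_light_mV=mean_post, label=label)


# ---------------------------------------------------------------------------
# series-resistance correction


def correct_series_resistance(sweep: Sweep, cfg: CorrectionConfig) -> np.ndarray:
    """Return the Rs-corrected membrane-potential trace (mV) for a VC sweep.

    Vm(t) = Vcmd(t) - I(t) * rs_fraction * rs_MOhm, with I in pA and Rs in
    MOhm (the product is scaled by 1e-3 to express the drop in mV).
    """
    sweep.require_mode("VC")
    drop_mV = sweep.recorded * cfg.rs_fraction * cfg.rs_MOhm * 1e-3
    return sweep.command - drop_mV


# ---------------------------------------------------------------------------
# seal-test membrane properties


def _detect_step(command: np.ndarray, min_step_mV: float = 2.0) -> tuple[int, int, float]:
    """Locate the first command step: (onset index, offset index, amplitude)."""
    d = np.diff(command)
    jumps = np.flatnonzero(np.abs(d) >= min_step_mV)
    if jumps.size == 0:
        raise FitError("no command step found in seal-test sweep")
    onset = jumps[0] + 1
    later = jumps[jumps > jumps[0]]
    offset = later[0] + 1 if later.size else command.size
    amp = command[onset] - command[onset - 1]
    return onset, offset, amp


def estimate_membrane_properties(
    seal_sweep: Sweep,
    step_mV: float = -10.0,
    fit_window_ms: tuple[float, float] = (0.1, 10.0),
    peak_search_ms: float = 5.0,
) -> MembraneProperties:
    """Estimate Rs, input resistance and Rm from a voltage-step (seal test) sweep.

    Rs is taken both from the peak transient current and from the
    extrapolated peak of a single exponential fitted to the decay of the
    transient (default window 0.1-10 ms after the step edge); the mean of the
    two is the final Rs.  Input resistance comes from the steady-state current
    change, and Rm = R_input - Rs.
    """
    seal_sweep.require_mode("VC")
    i = seal_sweep.recorded
    dt_ms = seal_sweep.dt * 1e3
    onset, offset, amp = _detect_step(seal_sweep.command)
    if abs(amp) < 1e-9:
        raise FitError("zero-amplitude step")

    # baseline: pre-step samples away from the edge
    n_base = max(int(2.0 / dt_ms), 2)
    i_base = float(np.mean(i[max(onset - n_base, 0) : onset]))

    # steady state: final 20% of the step epoch
    n_step = offset - onset
    ss_lo = onset + int(0.8 * n_step)
    i_ss = float(np.mean(i[ss_lo:offset]))
    di_ss = i_ss - i_base
    if abs(di_ss) < 1e-12:
        raise FitError("no steady-state current change")
    r_input = abs(amp / di_ss) * 1e3  # mV/pA -> MOhm

    # peak transient within the first few ms of the step
    n_peak = min(onset + max(int(peak_search_ms / dt_ms), 1), offset)
    seg = i[onset:n_peak] - i_base
    k_peak = int(np.argmax(np.abs(seg)))
    di_peak = float(seg[k_peak])
    if abs(di_peak) <= abs(di_ss) * (1 + 1e-9):
        raise FitError("no detectable capacitive transient in seal test")
    rs_peak = abs(amp / di_peak) * 1e3

    # exponential fit to the decay, extrapolated to the step edge.  When the
    # transient decays within a couple of samples (Rs near zero) the fit is
    # impossible; fall back to the peak estimate and flag it.
    lo = onset + max(int(fit_window_ms[0] / dt_ms), 1)
    hi = min(onset + int(fit_window_ms[1] / dt_ms), offset)
    t_fit = (np.arange(lo, hi) - onset) * dt_ms
    y_fit = i[lo:hi] - i_ss
    sgn = np.sign(di_peak)
    pos = sgn * y_fit > max(0.02 * sgn * di_peak, 0.0)
    rs_expfit = None
    tau = float("nan")
    if pos.sum() >= 4:
        t_sub, y_sub = t_fit[pos], y_fit[pos]
        # log-linear initialization, then nonlinear refinement
        b, log_a = np.polyfit(t_sub, np.log(sgn * y_sub), 1)
        tau0 = -1.0 / b if b < 0 else 1.0
        a0 = sgn * np.exp(log_a)
        try:
            popt, _ = optimize.curve_fit(
                lambda t, a, tau: a * np.exp(-t / tau),
                t_sub,
                y_sub,
                p0=(a0, max(tau0, dt_ms)),
                maxfev=5000,
            )
            a_fit, tau = float(popt[0]), float(abs(popt[1]))
            di_peak_fit = (i_ss + a_fit) - i_base  # extrapolated current at the edge
            if abs(di_peak_fit) > abs(di_ss):
                rs_expfit = abs(amp / di_peak_fit) * 1e3
        except RuntimeError:
            rs_expfit = None
    expfit_ok = rs_expfit is not None
    if not expfit_ok:
        rs_expfit = rs_peak
        tau = dt_ms if not np.isfinite(tau) else tau

    rs = 0.5 * (rs_peak + rs_expfit)
    step_span_ms = n_step * dt_ms
    return MembraneProperties(
        rs_peak_MOhm=rs_peak,
        rs_expfit_MOhm=rs_expfit,
        rs_MOhm=rs,
        r_input_MOhm=r_input,
        rm_MOhm=r_input - rs,
        tau_ms=tau,
        perforation_ok=rs < RS_ACCEPTANCE_MOHM,
        steady_state_ok=step_span_ms >= 3.0 * tau,
        expfit_ok=expfit_ok,
    )


# ---------------------------------------------------------------------------
# IV fitting (ramp and step protocols)


def find_ramp_epoch(sweep: Sweep, min_duration_ms: float = 20.0) -> tuple[int, int]:
    """Locate the voltage-ramp epoch in a VC sweep's command trace.

    Returns (start, stop) sample indices of the longest run of strictly
    increasing command samples with sub-mV per-sample increments (i.e., a ramp
    rather than a step edge).
    """
    d = np.diff(sweep.command)
    is_ramp = (d > 1e-12) & (d < 1.0)
    best = (0, 0)
    start = None
    for k, flag in enumerate(np.append(is_ramp, False)):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            if k - start > best[1] - best[0]:
                best = (start, k + 1)
            start = None
    if (best[1] - best[0]) * sweep.dt * 1e3 < min_duration_ms:
        raise FitError("no voltage ramp found in command trace")
    return best


def _apply_crops(
    mask: np.ndarray, time_s: np.ndarray, crop_windows: list[tuple[float, float]] | None
) -> np.ndarray:
    if crop_windows:
        for t0, t1 in crop_windows:
            mask &= ~((time_s >= t0) & (time_s <= t1))
    return mask


def _fit_line(v: np.ndarray, i: np.ndarray, min_points: int = 10) -> IVFit:
    if v.size < max(min_points, 2):
        raise InsufficientDataError(
            f"only {v.size} IV points remain after exclusion (need >= {min_points})"
        )
    slope, intercept = np.polyfit(v, i, 1)
    reversal = -intercept / slope if slope != 0 else np.nan
    return IVFit(
        slope_nS=float(slope),
        intercept_pA=float(intercept),
        reversal_mV=float(reversal),
        fit_voltage_window_mV=(float(v.min()), float(v.max())),
        n_points=int(v.size),
    )


def fit_iv_ramp(
    baseline: Sweep,
    light: Sweep,
    cfg: CorrectionConfig,
    proto: ProtocolDescriptor | None = None,
    crop_windows: list[tuple[float, float]] | None = None,
    min_conductance_nS: float = 1e-3,
    min_points: int = 10,
) -> EgabaResult:
    """Estimate RMP, E_GABAAR, driving force and GABA conductance from ramps.

    Both sweeps are Rs-corrected and their currents fitted as straight lines
    against the corrected membrane potential, after excluding the first/last
    ``edge_exclusion_ms`` of the ramp and any user ``crop_windows`` (time
    intervals in seconds to discard).  RMP is the baseline line's zero
    crossing; E_GABAAR the zero crossing of the light-minus-baseline line
    (equivalently the intersection of the two fitted lines); the GABA
    conductance is the slope difference.
    """
    proto = proto or ProtocolDescriptor()
    for s in (baseline, light):
        s.require_mode("VC")

    fits = []
    for sweep in (baseline, light):
        lo, hi = find_ramp_epoch(sweep)
        edge = int(round(proto.edge_exclusion_ms * 1e-3 / sweep.dt))
        mask = np.zeros(sweep.n_samples, dtype=bool)
        mask[lo + edge : hi - edge] = True
        mask = _apply_crops(mask, sweep.time, crop_windows)
        vm = correct_series_resistance(sweep, cfg)
        fits.append(_fit_line(vm[mask], sweep.recorded[mask], min_points))
    base_fit, light_fit = fits

    g = light_fit.slope_nS - base_fit.slope_nS
    if abs(g) < min_conductance_nS:
        raise NoIntersectionError(
            f"baseline and light IV lines are parallel (|delta slope| = {abs(g):.2g} nS)"
        )
    egaba = -(light_fit.intercept_pA - base_fit.intercept_pA) / g
    diff_fit = IVFit(
        slope_nS=g,
        intercept_pA=light_fit.intercept_pA - base_fit.intercept_pA,
        reversal_mV=float(egaba),
        fit_voltage_window_mV=base_fit.fit_voltage_window_mV,
        n_points=base_fit.n_points,
    )
    return EgabaResult.from_fits(base_fit, diff_fit, protocol="ramp")


def fit_iv_step(
    steps: list[Sweep],
    cfg: CorrectionConfig,
    proto: ProtocolDescriptor | None = None,
    t_measure_ms: float = 20.0,
    t_ramp_ms: float | None = None,
    baseline_window_ms: float = 5.0,
    measure_window_ms: float = 2.0,
    min_conductance_nS: float = 1e-3,
) -> tuple[EgabaResult, dict]:
    """Estimate E_GABAAR from the voltage-step protocol.

    Each sweep holds one command step with a light pulse delivered during the
    step.  The baseline current is averaged immediately before the light; the
    light current is averaged in a short window centred ``t_measure_ms`` after
    light onset (20 ms, the conductance peak).  Lines are then fitted against
    the Rs-corrected voltages exactly as in the ramp protocol.

    If ``t_ramp_ms`` is given (the post-light time at which the ramp estimate
    crossed E_GABAAR in the same cell), a second estimate is computed there and
    the difference between the two is returned as a stability / GABA-B
    diagnostic in the info dict.
    """
    proto = proto or ProtocolDescriptor(kind="step")
    if not steps:
        raise InsufficientDataError("no step sweeps provided")

    def measure(at_ms: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v_base, i_base, i_light, v_light = [], [], [], []
        for sweep in steps:
            sweep.require_mode("VC")
            if sweep.light_onset is None:
                raise ValueError(f"step sweep {sweep.sweep_id!r} lacks light metadata")
            vm = correct_series_resistance(sweep, cfg)
            t = sweep.time
            on = sweep.light_onset
            pre = (t >= on - baseline_window_ms * 1e-3) & (t < on)
            mid = np.abs(t - (on + at_ms * 1e-3)) <= measure_window_ms * 1e-3 / 2
            if pre.sum() < 1 or mid.sum() < 1:
                raise InsufficientDataError(
                    f"measurement windows empty in sweep {sweep.sweep_id!r}"
                )
            v_base.append(vm[pre].mean())
            i_base.append(sweep.recorded[pre].mean())
            v_light.append(vm[mid].mean())
            i_light.append(sweep.recorded[mid].mean())
        return (np.array(v_base), np.array(i_base), np.array(v_light), np.array(i_light))

    def estimate(at_ms: float, tag: str) -> EgabaResult:
        v_b, i_b, v_l, i_l = measure(at_ms)
        base_fit = _fit_line(v_b, i_b, min_points=2)
        light_fit = _fit_line(v_l, i_l, min_points=2)
        g = light_fit.slope_nS - base_fit.slope_nS
        if abs(g) < min_conductance_nS:
            raise NoIntersectionError(
                f"step IV lines are parallel (|delta slope| = {abs(g):.2g} nS)"
            )
        egaba = -(light_fit.intercept_pA - base_fit.intercept_pA) / g
        diff_fit = IVFit(
            slope_nS=g,
            intercept_pA=light_fit.intercept_pA - base_fit.intercept_pA,
            reversal_mV=float(egaba),
            fit_voltage_window_mV=base_fit.fit_voltage_window_mV,
            n_points=base_fit.n_points,
        )
        return EgabaResult.from_fits(base_fit, diff_fit, protocol=tag)

    result = estimate(t_measure_ms, "step20ms")
    info: dict = {"n_steps": len(steps)}
    grid = {round(float(s.command.max()), 1) for s in steps}
    expected = set(proto.step_grid_mV)
    if proto.step_grid_mV and not expected.issubset({round(g, 1) for g in grid}):
        info["partial_grid"] = True
    if t_ramp_ms is not None:
        at_ramp = estimate(t_ramp_ms, "stepAtRampTime")
        info["egaba_at_ramp_time_mV"] = at_ramp.egaba_mV
        info["step_time_diff_mV"] = result.egaba_mV - at_ramp.egaba_mV
    return result, info


# ---------------------------------------------------------------------------
# current-clamp statistics


def vm_statistics(
    ic_trace: Sweep,
    ap_threshold_mV: float = -40.0,
    ap_exclusion_ms: float = 2.0,
    winsor_limits: tuple[float, float] = (0.01, 0.01),
    grid_mV: np.ndarray | None = None,
    bw_method: str | float = "scott",
    min_duration_s: float = 10.0,
) -> VmStats:
    """Membrane-potential statistics from a continuous current-clamp trace.

    Samples above ``ap_threshold_mV`` (action potentials) are excluded from
    the mean and the Gaussian kernel-density estimate.  The rate of change of
    the subthreshold potential (dV/dt, first difference over dt) is computed
    after excluding samples within ``ap_exclusion_ms`` of upward threshold
    crossings, winsorized (1st/99th percentile by default), and the mean of
    its modulus reported in mV/ms.
    """
    ic_trace.require_mode("IC")
    if ic_trace.duration < min_duration_s:
        raise InsufficientDataError(
            f"trace of {ic_trace.duration:.1f} s is shorter than {min_duration_s} s"
        )
    v = ic_trace.recorded
    dt_ms = ic_trace.dt * 1e3
    sub = v <= ap_threshold_mV
    if not sub.any():
        raise InsufficientDataError("no subthreshold samples below the AP threshold")
    v_sub = v[sub]
    mean_vm = float(v_sub.mean())

    if grid_mV is None:
        lo = min(v_sub.min() - 15.0, -100.0)
        hi = ap_threshold_mV + 10.0
        grid_mV = np.linspace(lo, hi, 512)
    kde = stats.gaussian_kde(v_sub, bw_method=bw_method)
    density = kde(grid_mV)

    dvdt = np.diff(v) / dt_ms
    keep = np.ones(dvdt.size, dtype=bool)
    crossings = np.flatnonzero((v[:-1] <= ap_threshold_mV) & (v[1:] > ap_threshold_mV))
    half = max(int(round(ap_exclusion_ms / dt_ms)), 1)
    for c in crossings:
        keep[max(c - half, 0) : c + half + 1] = False
    keep &= sub[:-1] & sub[1:]
    dvdt = dvdt[keep]
    if dvdt.size == 0:
        raise InsufficientDataError("no subthreshold dV/dt samples remain")
    dvdt = np.asarray(stats.mstats.winsorize(dvdt, limits=winsor_limits))
    return VmStats(
        mean_vm_mV=mean_vm,
        density_grid_mV=grid_mV,
        density=density,
        mean_abs_dvdt_mV_per_ms=float(np.abs(dvdt).mean()),
        n_samples_included=int(v_sub.size),
    )


def classify_polarity(
    ic_sweeps: list[Sweep],
    baseline_ms: float = 100.0,
    response_ms: float = 100.0,
) -> PolarityResult:
    """Classify a light-evoked GABAergic response as de- or hyperpolarizing.

    Sweeps are averaged, normalized to the mean potential in the 100 ms
    preceding the light pulse, and the mean normalized potential over the
    100 ms following the pulse determines the label (strictly positive ->
    depolarizing; zero or negative -> hyperpolarizing).
    """
    if not ic_sweeps:
        raise InsufficientDataError("no sweeps provided")
    ref = ic_sweeps[0]
    if ref.light_onset is None:
        raise ValueError("sweeps lack light metadata")
    for s in ic_sweeps:
        s.require_mode("IC")
        if s.n_samples != ref.n_samples:
            raise ValueError("all sweeps must share the same length")
    avg = np.mean([s.recorded for s in ic_sweeps], axis=0)
    t = ref.time
    onset = ref.light_onset
    offset = onset + (ref.light_duration or 0.0)
    pre = (t >= onset - baseline_ms * 1e-3) & (t < onset)
    post = (t >= offset) & (t < offset + response_ms * 1e-3)
    if pre.sum() == 0 or post.sum() == 0:
        raise InsufficientDataError("baseline or response window is empty")
    mean_post = float(avg[post].mean() - avg[pre].mean())
    return PolarityResult.from_mean(mean_post)
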