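"""Passive multicompartment model of the somatic voltage-clamp experiment.

Quantifies how a neuron's passive membrane properties and the clamp's series
resistance bias IV-based estimates of the GABA-A reversal potential.  An SWC
morphology is discretized into node compartments, a passive membrane with
specific capacitance/resistance is attached, GABA-A synapses (alpha-function
conductances) are distributed near the soma, and an ideal voltage source in
series with the electrode resistance drives the soma through the same ramp
protocol used experimentally.  The recorded clamp current is then analyzed
verbatim by :func:`gabashunt.perforated_patch.fit_iv_ramp`.

Time integration is implicit (backward Euler, unconditionally stable) with a
direct O(n) tree solve (Hines ordering); the default step is 25 us during
ramps.  Single-point somas are treated as equivalent spheres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .perforated_patch import EgabaResult, fit_iv_ramp
from .sweeps import CorrectionConfig, Sweep

__all__ = [
    "Morphology",
    "PassiveParams",
    "SynapsePlacement",
    "SWCError",
    "SteadyStateError",
    "read_swc",
    "parse_swc",
    "place_synapses",
    "somatic_input_resistance",
    "simulate_clamped_ramp",
    "run_bias_sweep",
    "alpha_conductance",
]


class SWCError(ValueError):
    """Malformed SWC morphology (cycles, orphans, nonpositive radii...)."""


class SteadyStateError(RuntimeError):
    """Simulation did not reach steady state within the simulated horizon."""


@dataclass
class Morphology:
    """Node-compartment tree derived from an SWC reconstruction.

    Nodes are stored in Hines order (every parent precedes its children);
    ``parent[0] == -1``.  ``area_um2`` is the membrane area assigned to each
    node (sphere for a single-point soma, lateral frustum of the edge to the
    parent otherwise) and ``axial_gfactor_cm`` the geometry factor
    ``pi*r1*r2/L`` (cm) such that the axial conductance to the parent is
    ``axial_gfactor_cm / r_axial``.
    """

    parent: np.ndarray
    xyz_um: np.ndarray
    radius_um: np.ndarray
    ntype: np.ndarray
    area_um2: np.ndarray
    axial_gfactor_cm: np.ndarray  # 0 for the root

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def soma_index(self) -> int:
        soma = np.flatnonzero(self.ntype == 1)
        return int(soma[0]) if soma.size else 0

    def euclidean_from_soma_um(self) -> np.ndarray:
        center = self.xyz_um[self.soma_index]
        return np.linalg.norm(self.xyz_um - center, axis=1)

    def path_from_soma_um(self) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            p = self.parent[i]
            d[i] = d[p] + np.linalg.norm(self.xyz_um[i] - self.xyz_um[p])
        return d

    def total_area_um2(self) -> float:
        return float(self.area_um2.sum())


@dataclass
class PassiveParams:
    """Passive constants; named conditions carry the fitted per-state values."""

    c_m_uF_cm2: float = 2.515
    r_axial_ohm_cm: float = 150.0
    e_pas_mV: float = -70.7
    r_m_ohm_cm2: float = 10**3.784
    clamp_rs_MOhm: float = 47.5

    def __post_init__(self) -> None:
        for v in (self.c_m_uF_cm2, self.r_axial_ohm_cm, self.r_m_ohm_cm2):
            if v <= 0:
                raise ValueError("passive constants must be positive")

    @classmethod
    def conditions(cls) -> dict:
        """The three fitted network states (anesthetized / awake / awake+NBQX)."""
        return {
            "anesthetized": cls(e_pas_mV=-70.7, r_m_ohm_cm2=10**3.784),
            "awake": cls(e_pas_mV=-64.2, r_m_ohm_cm2=10**3.540),
            "nbqx": cls(e_pas_mV=-71.4, r_m_ohm_cm2=10**3.988),
        }


@dataclass
class SynapsePlacement:
    node_ids: np.ndarray  # synapse sites (node indices)
    gpeak_nS: float = 2.0
    tau_ms: float = 150.0
    radius_um: float = 75.0
    metric: str = "euclidean"


# ---------------------------------------------------------------------------
# SWC parsing


def parse_swc(text: str) -> Morphology:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCError(f"malformed SWC line: {line!r}")
        rows.append(
            (
                int(parts[0]),
                int(parts[1]),
                float(parts[2]),
                float(parts[3]),
                float(parts[4]),
                float(parts[5]),
                int(parts[6]),
            )
        )
    if not rows:
        raise SWCError("empty SWC file")
    ids = {r[0] for r in rows}
    if len(ids) != len(rows):
        raise SWCError("duplicate node ids")
    roots = [r for r in rows if r[6] == -1]
    if len(roots) != 1:
        raise SWCError(f"expected a single root, found {len(roots)}")
    for r in rows:
        if r[5] <= 0:
            raise SWCError(f"nonpositive radius at node {r[0]}")
        if r[6] != -1 and r[6] not in ids:
            raise SWCError(f"orphan node {r[0]} (parent {r[6]} missing)")

    # Hines (topological) ordering via BFS from the root; leftovers = cycles
    children: dict[int, list[int]] = {r[0]: [] for r in rows}
    by_id = {r[0]: r for r in rows}
    for r in rows:
        if r[6] != -1:
            children[r[6]].append(r[0])
    order = []
    stack = [roots[0][0]]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(reversed(children[nid]))
    if len(order) != len(rows):
        raise SWCError("cyclic or disconnected SWC tree")
    index = {nid: k for k, nid in enumerate(order)}

    n = len(rows)
    parent = np.empty(n, dtype=np.int64)
    xyz = np.empty((n, 3))
    radius = np.empty(n)
    ntype = np.empty(n, dtype=np.int64)
    for nid, k in index.items():
        r = by_id[nid]
        parent[k] = -1 if r[6] == -1 else index[r[6]]
        ntype[k] = r[1]
        xyz[k] = r[2:5]
        radius[k] = r[5]

    soma_nodes = np.flatnonzero(ntype == 1)
    single_point_soma = soma_nodes.size == 1
    area = np.zeros(n)
    gfac = np.zeros(n)
    for i in range(1, n):
        p = parent[i]
        length = float(np.linalg.norm(xyz[i] - xyz[p]))
        r_i = radius[i]
        if single_point_soma and ntype[p] == 1:
            # connect at the soma surface; use the child's own radius
            length = max(length - radius[p], 0.1)
            r_p = r_i
        else:
            r_p = radius[p]
        area[i] = math.pi * (r_p + r_i) * math.hypot(length, r_p - r_i)
        gfac[i] = math.pi * (r_p * 1e-4) * (r_i * 1e-4) / (length * 1e-4)  # cm
    if single_point_soma:
        s = soma_nodes[0]
        area[s] = 4.0 * math.pi * radius[s] ** 2
    return Morphology(parent, xyz, radius, ntype, area, gfac)


def read_swc(path: str | Path) -> Morphology:
    """Read an SWC morphology (NeuroMorpho dialect) into node compartments."""
    return parse_swc(Path(path).read_text())


def place_synapses(
    morph: Morphology,
    n_synapses: int = 20,
    radius_um: float = 75.0,
    gpeak_nS: float = 2.0,
    tau_ms: float = 150.0,
    seed: int = 0,
    metric: str = "euclidean",
) -> SynapsePlacement:
    """Randomly place GABA-A synapses within ``radius_um`` of the soma center.

    Distance is Euclidean from the soma center by default; ``metric='path'``
    selects path distance along the tree instead.
    """
    rng = np.random.default_rng(seed)
    dist = (
        morph.euclidean_from_soma_um()
        if metric == "euclidean"
        else morph.path_from_soma_um()
    )
    eligible = np.flatnonzero(dist <= radius_um)
    if eligible.size == 0:
        raise ValueError("no compartments within the placement radius")
    nodes = rng.choice(eligible, size=n_synapses, replace=eligible.size < n_synapses)
    return SynapsePlacement(
        node_ids=np.sort(nodes),
        gpeak_nS=gpeak_nS,
        tau_ms=tau_ms,
        radius_um=radius_um,
        metric=metric,
    )


def alpha_conductance(t_s: np.ndarray | float, onset_s: float, tau_s: float) -> np.ndarray:
    """Alpha-function conductance time course, normalized to peak 1 at t = onset + tau."""
    rel = np.maximum(np.asarray(t_s, float) - onset_s, 0.0) / tau_s
    return rel * np.exp(1.0 - rel)


# ---------------------------------------------------------------------------
# implicit solver


@njit(cache=True)
def _clamp_kernel(
    parent,
    c_over_dt,  # F/s per node
    g_pas,  # S
    e_pas,  # V
    g_ax,  # S, conductance to parent (0 at root)
    soma,
    g_clamp,  # S
    vcmd,  # (T,) V
    dt,
    t0,  # absolute time of first step (s)
    syn_node,
    syn_gpeak,  # S
    syn_onset,  # s (absolute)
    syn_tau,
    e_syn,  # V
    v,  # (n,) state, updated in place
    i_rec,  # (T,) output clamp current (A)
):
    n = v.size
    T = vcmd.size
    diag = np.empty(n)
    rhs = np.empty(n)
    g_syn = np.zeros(n)
    for step in range(T):
        t = t0 + (step + 1) * dt  # implicit: evaluate sources at t+dt
        for j in range(n):
            g_syn[j] = 0.0
        for s in range(syn_node.size):
            rel = (t - syn_onset[s]) / syn_tau[s]
            if rel > 0.0:
                g_syn[syn_node[s]] += syn_gpeak[s] * rel * np.exp(1.0 - rel)
        for j in range(n):
            diag[j] = c_over_dt[j] + g_pas[j] + g_syn[j]
            rhs[j] = c_over_dt[j] * v[j] + g_pas[j] * e_pas + g_syn[j] * e_syn
            if j > 0:
                diag[j] += g_ax[j]
                diag[parent[j]] += g_ax[j]
        diag[soma] += g_clamp
        rhs[soma] += g_clamp * vcmd[step]
        # Hines elimination (children have larger indices than parents)
        for j in range(n - 1, 0, -1):
            f = g_ax[j] / diag[j]
            diag[parent[j]] -= f * g_ax[j]
            rhs[parent[j]] += f * rhs[j]
        v[0] = rhs[0] / diag[0]
        for j in range(1, n):
            v[j] = (rhs[j] + g_ax[j] * v[parent[j]]) / diag[j]
        i_rec[step] = (vcmd[step] - v[soma]) * g_clamp
    return 0


@dataclass
class _CableArrays:
    parent: np.ndarray
    c: np.ndarray  # F
    g_pas: np.ndarray  # S
    g_ax: np.ndarray  # S
    soma: int


def _assemble(morph: Morphology, params: PassiveParams) -> _CableArrays:
    area_cm2 = morph.area_um2 * 1e-8
    c = params.c_m_uF_cm2 * 1e-6 * area_cm2
    g_pas = area_cm2 / params.r_m_ohm_cm2
    g_ax = morph.axial_gfactor_cm / params.r_axial_ohm_cm
    return _CableArrays(morph.parent, c, g_pas, g_ax, morph.soma_index)


def _simulate_phase(
    arr: _CableArrays,
    params: PassiveParams,
    vcmd_mV: np.ndarray,
    dt_s: float,
    v_state_V: np.ndarray,
    t0_s: float = 0.0,
    synapses: SynapsePlacement | None = None,
    syn_onset_s: float = 0.0,
    egaba_mV: float = -70.0,
) -> np.ndarray:
    """Run one protocol phase; returns clamp current in pA, state updated in place."""
    g_clamp = 1.0 / (params.clamp_rs_MOhm * 1e6)
    if synapses is not None and synapses.node_ids.size:
        syn_node = synapses.node_ids.astype(np.int64)
        syn_gpeak = np.full(syn_node.size, synapses.gpeak_nS * 1e-9)
        syn_onset = np.full(syn_node.size, syn_onset_s)
        syn_tau = np.full(syn_node.size, synapses.tau_ms * 1e-3)
    else:
        syn_node = np.empty(0, dtype=np.int64)
        syn_gpeak = np.empty(0)
        syn_onset = np.empty(0)
        syn_tau = np.empty(0)
    i_rec = np.empty(vcmd_mV.size)
    status = _clamp_kernel(
        arr.parent,
        arr.c / dt_s,
        arr.g_pas,
        params.e_pas_mV * 1e-3,
        arr.g_ax,
        arr.soma,
        g_clamp,
        vcmd_mV * 1e-3,
        dt_s,
        t0_s,
        syn_node,
        syn_gpeak,
        syn_onset,
        syn_tau,
        egaba_mV * 1e-3,
        v_state_V,
        i_rec,
    )
    assert status == 0
    return i_rec * 1e12  # A -> pA


def somatic_input_resistance(
    morph: Morphology,
    params: PassiveParams,
    hold_mV: float = -70.0,
    step_mV: float = -10.0,
    step_dur_s: float = 0.5,
    dt_s: float = 1e-4,
    rel_tol: float = 1e-3,
) -> dict:
    """Input and membrane resistance from a somatic voltage step through the clamp.

    A -10 mV, 500 ms step is applied from the holding potential; the input
    resistance is the command change over the steady-state current change,
    and the membrane resistance is that minus the electrode series
    resistance.  Raises :class:`SteadyStateError` when the current has not
    settled (final two 20-ms windows differing by more than ``rel_tol`` of
    the step response).
    """
    arr = _assemble(morph, params)
    v = np.full(morph.n_nodes, params.e_pas_mV * 1e-3)
    n_hold = int(round(step_dur_s / dt_s))
    i_hold = _simulate_phase(arr, params, np.full(n_hold, hold_mV), dt_s, v)
    i_step = _simulate_phase(
        arr, params, np.full(n_hold, hold_mV + step_mV), dt_s, v
    )
    n_win = max(int(round(0.02 / dt_s)), 1)
    di = i_step[-n_win:].mean() - i_hold[-n_win:].mean()
    settle = abs(i_step[-n_win:].mean() - i_step[-2 * n_win : -n_win].mean())
    if settle > rel_tol * abs(di):
        raise SteadyStateError("clamp current not steady at the end of the step")
    r_input = abs(step_mV / di) * 1e3  # mV/pA -> MOhm
    return {
        "r_input_MOhm": float(r_input),
        "r_membrane_MOhm": float(r_input - params.clamp_rs_MOhm),
        "clamp_rs_MOhm": params.clamp_rs_MOhm,
    }


def _ramp_protocol(dt_s: float) -> tuple[np.ndarray, int, int]:
    """Command for the pre-ramp hold at -130 mV, the 150 ms ramp to -30 mV and
    a short tail; returns (command mV, ramp start idx, ramp stop idx)."""
    n_pre = int(round(0.05 / dt_s))
    n_ramp = int(round(0.15 / dt_s))
    n_post = int(round(0.02 / dt_s))
    cmd = np.concatenate(
        [
            np.full(n_pre, -130.0),
            np.linspace(-130.0, -30.0, n_ramp),
            np.full(n_post, -70.0),
        ]
    )
    return cmd, n_pre, n_pre + n_ramp


def simulate_clamped_ramp(
    morph: Morphology,
    params: PassiveParams,
    placement: SynapsePlacement,
    egaba_mV: float,
    correction_fraction: float = 0.9,
    dt_s: float = 25e-6,
    settle_s: float = 0.3,
    _baseline_cache: dict | None = None,
) -> EgabaResult:
    """Simulate the two-ramp voltage-clamp protocol and analyze it verbatim.

    One ramp is run without synaptic conductance and one with the GABA-A
    synapses activated at ramp onset; both recorded clamp currents are fed to
    :func:`fit_iv_ramp` with the requested series-resistance correction
    fraction (the electrode Rs itself is the physical ``params.clamp_rs_MOhm``).
    """
    arr = _assemble(morph, params)
    cmd, k0, _k1 = _ramp_protocol(dt_s)
    sweeps = {}
    for name in ("baseline", "light"):
        if _baseline_cache is not None and name == "baseline" and _baseline_cache:
            sweeps[name] = _baseline_cache["sweep"]
            continue
        v = np.full(morph.n_nodes, params.e_pas_mV * 1e-3)
        # settle at the holding potential with a coarse step (implicit, stable)
        _simulate_phase(
            arr, params, np.full(int(round(settle_s / 1e-3)), -70.0), 1e-3, v
        )
        # synapses activate one alpha time-constant before the ramp midpoint
        # so the conductance is at its (locally flat) peak during the ramp,
        # mirroring the experimental design of evoking the GABA response at
        # its peak during the measurement ramp
        syn = placement if name == "light" else None
        mid = k0 * dt_s + 0.075  # ramp midpoint (150 ms ramp)
        onset = mid - placement.tau_ms * 1e-3
        i_pA = _simulate_phase(
            arr,
            params,
            cmd,
            dt_s,
            v,
            t0_s=0.0,
            synapses=syn,
            syn_onset_s=onset,
            egaba_mV=egaba_mV,
        )
        sweeps[name] = Sweep(
            dt=dt_s,
            command=cmd,
            recorded=i_pA,
            mode="VC",
            light_onset=k0 * dt_s if name == "light" else None,
            light_duration=0.01 if name == "light" else None,
            sweep_id=f"sim_ramp_{name}",
        )
        if _baseline_cache is not None and name == "baseline":
            _baseline_cache["sweep"] = sweeps[name]
    cfg = CorrectionConfig(
        rs_MOhm=params.clamp_rs_MOhm, rs_fraction=correction_fraction
    )
    return fit_iv_ramp(sweeps["baseline"], sweeps["light"], cfg)


def run_bias_sweep(
    morph: Morphology,
    params: PassiveParams,
    placement: SynapsePlacement,
    egaba_grid_mV: np.ndarray | None = None,
    corrections: tuple[float, ...] = (0.0, 0.9),
    dt_s: float = 25e-6,
):
    """Estimated vs. true E_GABAAR over the -85..-35 mV grid at each correction.

    The synapse placement is fixed across the sweep; the baseline ramp is
    shared (it does not depend on the synaptic reversal).  Returns a
    DataFrame with columns egaba_true_mV, correction, egaba_est_mV, bias_mV.
    """
    import pandas as pd

    if egaba_grid_mV is None:
        egaba_grid_mV = np.arange(-85.0, -30.0, 5.0)
    cache: dict = {}
    rows = []
    for eg in egaba_grid_mV:
        for frac in corrections:
            res = simulate_clamped_ramp(
                morph,
                params,
                placement,
                egaba_mV=float(eg),
                correction_fraction=frac,
                dt_s=dt_s,
                _baseline_cache=cache,
            )
            rows.append(
                {
                    "egaba_true_mV": float(eg),
                    "correction": frac,
                    "egaba_est_mV": res.egaba_mV,
                    "bias_mV": res.egaba_mV - float(eg),
                }
            )
    df = pd.DataFrame(rows)
    # estimated-vs-true relation should be monotone within each correction
    for frac, grp in df.groupby("correction"):
        est = grp.sort_values("egaba_true_mV")["egaba_est_mV"].to_numpy()
        if np.any(np.diff(est) <= 0):
            raise RuntimeError(
                f"estimated E_GABAAR not monotone in truth at correction {frac}"
            )
    return df
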