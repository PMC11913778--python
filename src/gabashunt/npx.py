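"""Paired awake-vs-anesthetized analysis of sorted-unit recordings.

Starts from spike-sorted units (spike times, a brain-region annotation and a
spike-waveform duration per unit) plus per-condition stimulus onset times,
mirroring the structure of public high-density probe datasets.  Units are
retained when they lie in the stimulated area's annotation set (somatosensory
"SSp-ll"/"SSp-tr" or secondary motor "MOs"), have a regular-spiking waveform
(duration >= 0.4 ms) and an evoked rate between 0.1 and 200 Hz in both
conditions (computed on the 2-12 ms post-stimulus window, which also excludes
stimulation artifacts and late re-entrant activity).  Synchrony and
peri-stimulus histogram entropy are then compared pairwise per neuron.

File-format adapters are deliberately thin: the synthetic generator emits the
same in-memory structures, so the pipeline is testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import spike_metrics as sm
from .spike_metrics import SpikeRaster

__all__ = [
    "UnitRecord",
    "SessionData",
    "REGION_SETS",
    "WAVEFORM_MIN_MS",
    "RATE_BOUNDS_HZ",
    "ANALYSIS_WINDOW_MS",
    "align_spikes",
    "select_units",
    "paired_metrics",
    "session_from_synthetic",
]

REGION_SETS = {"SS": {"SSp-ll", "SSp-tr"}, "MO": {"MOs"}}
WAVEFORM_MIN_MS = 0.4  # regular-spiking units
RATE_BOUNDS_HZ = (0.1, 200.0)
ANALYSIS_WINDOW_MS = (2.0, 12.0)


@dataclass
class UnitRecord:
    unit_id: int
    region: str
    waveform_duration_ms: float
    spike_times_s: dict  # condition -> sorted absolute spike times (s)

    def __post_init__(self) -> None:
        if self.waveform_duration_ms <= 0:
            raise ValueError("waveform duration must be positive")
        for cond, t in self.spike_times_s.items():
            t = np.asarray(t, float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"spike times not sorted for condition {cond!r}")
            self.spike_times_s[cond] = t


@dataclass
class SessionData:
    session_id: str
    stimulated_area: str  # key of REGION_SETS
    stim_onsets_s: dict  # condition -> strictly increasing onset times (s)

    def __post_init__(self) -> None:
        if self.stimulated_area not in REGION_SETS:
            raise KeyError(
                f"unknown stimulated area {self.stimulated_area!r}; "
                f"expected one of {sorted(REGION_SETS)}"
            )
        for cond, on in self.stim_onsets_s.items():
            on = np.asarray(on, float)
            if np.any(np.diff(on) <= 0):
                raise ValueError(f"onsets must be strictly increasing ({cond})")
            self.stim_onsets_s[cond] = on


def align_spikes(
    spike_times_s: np.ndarray,
    onsets_s: np.ndarray,
    window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
) -> list[np.ndarray]:
    """Spike times (ms, stimulus-aligned) per trial, restricted to window."""
    t0, t1 = window_ms
    out = []
    for on in onsets_s:
        rel = (spike_times_s - on) * 1e3
        out.append(np.sort(rel[(rel >= t0) & (rel < t1)]))
    return out


def build_raster(
    units: list[UnitRecord],
    session: SessionData,
    condition: str,
    window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
) -> SpikeRaster:
    onsets = session.stim_onsets_s[condition]
    spikes = [
        align_spikes(u.spike_times_s[condition], onsets, window_ms) for u in units
    ]
    return SpikeRaster(spikes, window_ms, condition=condition)


def _evoked_rates(
    units: list[UnitRecord],
    session: SessionData,
    window_ms: tuple[float, float],
) -> dict:
    rates = {}
    for cond in session.stim_onsets_s:
        raster = build_raster(units, session, cond, window_ms)
        rates[cond] = np.array(
            [sm.evoked_rate(raster, j) for j in range(len(units))]
        )
    return rates


def select_units(
    units: list[UnitRecord],
    session: SessionData,
    window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
) -> list[UnitRecord]:
    """Apply the region, waveform-duration and evoked-rate filters.

    The three filters commute (each is a per-unit predicate), so retained
    sets are order-independent.
    """
    regions = REGION_SETS[session.stimulated_area]
    lo, hi = RATE_BOUNDS_HZ
    rates = _evoked_rates(units, session, window_ms)
    keep = []
    for j, u in enumerate(units):
        if u.region not in regions:
            continue
        if u.waveform_duration_ms < WAVEFORM_MIN_MS:
            continue
        if any(not (lo <= rates[c][j] <= hi) for c in rates):
            continue
        keep.append(u)
    return keep


def paired_metrics(
    sessions: list[tuple[list[UnitRecord], SessionData]],
    window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
    bin_ms: float = 1.0,
    conditions: tuple[str, str] = ("awake", "anesthetized"),
) -> tuple[pd.DataFrame, dict]:
    """Per-neuron paired synchrony/entropy/rate table plus test summaries.

    Each element of ``sessions`` is (units, session); units are filtered with
    :func:`select_units`, metrics computed per condition on the analysis
    window, and paired t-tests run on synchrony and entropy across all
    retained neurons.  Sessions missing a condition are skipped (logged in
    the summary).
    """
    rows = []
    skipped = []
    per_session_counts = {}
    for units, session in sessions:
        if not all(c in session.stim_onsets_s for c in conditions):
            skipped.append(session.session_id)
            continue
        retained = select_units(units, session, window_ms)
        per_session_counts[session.session_id] = len(retained)
        if not retained:
            continue
        metrics = {}
        for cond in conditions:
            raster = build_raster(retained, session, cond, window_ms)
            metrics[cond] = sm.all_neuron_metrics(raster, bin_ms)
        a, b = conditions
        for j, u in enumerate(retained):
            rows.append(
                {
                    "session_id": session.session_id,
                    "unit_id": u.unit_id,
                    f"synchrony_{a}": metrics[a].synchrony[j],
                    f"synchrony_{b}": metrics[b].synchrony[j],
                    f"entropy_{a}": metrics[a].entropy_nats[j],
                    f"entropy_{b}": metrics[b].entropy_nats[j],
                    f"rate_{a}": metrics[a].evoked_rate_Hz[j],
                    f"rate_{b}": metrics[b].evoked_rate_Hz[j],
                }
            )
    table = pd.DataFrame(rows)
    a, b = conditions
    summary: dict = {
        "n_neurons": len(table),
        "per_session_counts": per_session_counts,
        "median_per_session": float(np.median(list(per_session_counts.values())))
        if per_session_counts
        else float("nan"),
        "skipped_sessions": skipped,
    }
    if len(table) >= 2:
        summary["synchrony_test"] = sm.paired_test(
            table[f"synchrony_{a}"].to_numpy(), table[f"synchrony_{b}"].to_numpy()
        )
        summary["entropy_test"] = sm.paired_test(
            table[f"entropy_{a}"].to_numpy(), table[f"entropy_{b}"].to_numpy()
        )
    return table, summary


def session_from_synthetic(synthetic_session, session_id: str = "synthetic-0"):
    """Adapt a :class:`gabashunt.synthetic.SyntheticSession` to the pipeline's
    (units, session) input structure."""
    ss = synthetic_session
    conds = list(ss.rasters)
    units = []
    for _, row in ss.units.iterrows():
        j = int(row["unit_id"])
        times = {}
        for cond in conds:
            onsets = ss.stim_onsets_s[cond]
            raster = ss.rasters[cond]
            abs_times = []
            for trial, on in enumerate(onsets):
                abs_times.extend(on + raster.spikes[j][trial] * 1e-3)
            times[cond] = np.sort(np.array(abs_times))
        units.append(
            UnitRecord(
                unit_id=j,
                region=row["region"],
                waveform_duration_ms=float(row["waveform_duration_ms"]),
                spike_times_s=times,
            )
        )
    session = SessionData(
        session_id=session_id,
        stimulated_area=ss.stimulated_area,
        stim_onsets_s={c: np.asarray(v, float) for c, v in ss.stim_onsets_s.items()},
    )
    return units, session
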