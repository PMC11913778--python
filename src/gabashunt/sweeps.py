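"""Clamp-sweep containers and the plain tabular sweep dialect.

A :class:`Sweep` holds one stimulus epoch of patch-clamp data: the command
waveform (mV in voltage clamp, pA in current clamp), the recorded signal
(pA in VC, mV in IC), the sample interval, and optional light-pulse metadata.

On disk a sweep is a TSV with columns ``time_s``, ``command``, ``recorded``
plus a JSON sidecar (same stem, ``.json``) carrying ``mode``, ``light_onset_s``,
``light_duration_s`` and ``sweep_id``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Sweep",
    "ProtocolDescriptor",
    "CorrectionConfig",
    "read_sweep_tsv",
    "write_sweep_tsv",
    "ModeError",
]


class ModeError(ValueError):
    """Raised when an operation receives a sweep in the wrong clamp mode."""


@dataclass
class Sweep:
    dt: float  # seconds per sample
    command: np.ndarray  # mV (VC) or pA (IC)
    recorded: np.ndarray  # pA (VC) or mV (IC)
    mode: str  # "VC" | "IC"
    light_onset: float | None = None  # s, relative to sweep start
    light_duration: float | None = None  # s
    sweep_id: str = ""

    def __post_init__(self) -> None:
        self.command = np.asarray(self.command, dtype=float)
        self.recorded = np.asarray(self.recorded, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.command.shape != self.recorded.shape:
            raise ValueError(
                "command and recorded traces must have the same length: "
                f"{self.command.shape} vs {self.recorded.shape}"
            )
        if self.mode not in ("VC", "IC"):
            raise ModeError(f"mode must be 'VC' or 'IC', got {self.mode!r}")
        if self.light_onset is not None:
            dur = self.light_duration or 0.0
            if not (0.0 <= self.light_onset and self.light_onset + dur <= self.duration):
                raise ValueError("light pulse must lie within the sweep span")

    @property
    def n_samples(self) -> int:
        return self.command.size

    @property
    def duration(self) -> float:
        """Sweep span in seconds."""
        return self.n_samples * self.dt

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(self.n_samples) * self.dt

    def require_mode(self, mode: str) -> None:
        if self.mode != mode:
            raise ModeError(f"expected {mode} sweep, got {self.mode}")


@dataclass
class ProtocolDescriptor:
    """Geometry of the voltage-clamp ramp / step protocols.

    The ramp protocol holds at ``hold_mV``, then sweeps the command from 60 mV
    below to 40 mV above the holding potential (-130 to -30 mV) in
    ``ramp_duration_ms``.  The first and last ``edge_exclusion_ms`` of each
    ramp are discarded during analysis to avoid pipette-capacitance transients.
    """

    kind: str = "ramp"  # ramp | step | seal_test
    hold_mV: float = -70.0
    ramp_span_mV: tuple[float, float] = (-130.0, -30.0)
    ramp_duration_ms: float = 150.0
    edge_exclusion_ms: float = 15.0
    step_grid_mV: tuple[float, ...] = tuple(float(v) for v in range(-130, -20, 10))
    step_duration_ms: float = 500.0
    light_pulse_ms: float = 10.0  # 10 ms for ramps, 100 ms for steps

    @property
    def ramp_rate_mV_per_ms(self) -> float:
        lo, hi = self.ramp_span_mV
        return (hi - lo) / self.ramp_duration_ms

    def __post_init__(self) -> None:
        if self.edge_exclusion_ms >= self.ramp_duration_ms / 2:
            raise ValueError("edge exclusion must be < half the ramp duration")


@dataclass
class CorrectionConfig:
    """Offline series-resistance correction settings.

    ``rs_fraction`` is the fraction of the measured series resistance used in
    the correction (0.9 in the experimental analysis); ``rs_MOhm`` the series
    resistance itself.
    """

    rs_MOhm: float = 0.0
    rs_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.rs_fraction <= 1.0):
            raise ValueError("rs_fraction must be within [0, 1]")
        if not np.isfinite(self.rs_MOhm) or self.rs_MOhm < 0:
            raise ValueError("rs_MOhm must be finite and non-negative")


def write_sweep_tsv(sweep: Sweep, path: str | Path) -> None:
    """Write a sweep as TSV + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": sweep.time, "command": sweep.command, "recorded": sweep.recorded}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {
        "mode": sweep.mode,
        "dt_s": sweep.dt,
        "light_onset_s": sweep.light_onset,
        "light_duration_s": sweep.light_duration,
        "sweep_id": sweep.sweep_id,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_sweep_tsv(path: str | Path) -> Sweep:
    """Read a sweep from the tabular dialect (TSV + JSON sidecar)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    t = df["time_s"].to_numpy()
    dt = meta.get("dt_s") or float(np.median(np.diff(t)))
    return Sweep(
        dt=dt,
        command=df["command"].to_numpy(),
        recorded=df["recorded"].to_numpy(),
        mode=meta["mode"],
        light_onset=meta.get("light_onset_s"),
        light_duration=meta.get("light_duration_s"),
        sweep_id=meta.get("sweep_id", path.stem),
    )
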