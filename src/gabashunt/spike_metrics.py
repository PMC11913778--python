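"""Per-neuron synchrony, peri-stimulus histogram entropy, evoked rates,
rate residualization and k-NN population decoding on spike rasters.

The synchrony measure relates each neuron's spiking to the population on a
trial-by-trial basis: per trial, the all-neuron peri-stimulus histogram
(1-ms bins) is normalized by that trial's total spike count, and a neuron's
synchrony is the mean normalized-histogram value at the bins containing its
own spikes, over all its spikes in all trials.  It is bounded in [0, 1] and
equals 1 when every trial's spikes fall into a single shared bin.

Entropy is the Shannon entropy (natural log, nats) of each neuron's
trial-pooled peri-stimulus histogram normalized to a probability vector.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "SpikeRaster",
    "NeuronMetrics",
    "synchrony_per_neuron",
    "psth",
    "psth_entropy",
    "evoked_rate",
    "all_neuron_metrics",
    "regress_out_rate",
    "paired_test",
    "decode_patterns",
    "write_raster",
    "read_raster",
]


@dataclass
class SpikeRaster:
    """Stimulus-aligned spike times (ms) per neuron per trial.

    ``spikes[neuron][trial]`` is a sorted array of spike times relative to
    stimulus onset, in ms.  ``window`` is the (t0, t1) analysis window in ms.
    """

    spikes: list[list[np.ndarray]]
    window: tuple[float, float]
    trial_labels: np.ndarray | None = None  # optional pattern id per trial
    condition: str = ""

    def __post_init__(self) -> None:
        self.spikes = [
            [np.asarray(t, dtype=float) for t in per_neuron] for per_neuron in self.spikes
        ]
        counts = {len(per_neuron) for per_neuron in self.spikes}
        if len(counts) > 1:
            raise ValueError("trial count must be consistent across neurons")
        if self.trial_labels is not None:
            self.trial_labels = np.asarray(self.trial_labels)
            if self.trial_labels.size != self.n_trials:
                raise ValueError("trial_labels length must equal n_trials")

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    @property
    def n_trials(self) -> int:
        return len(self.spikes[0]) if self.spikes else 0

    def restrict(self, window: tuple[float, float]) -> "SpikeRaster":
        """Return a copy keeping only spikes inside ``window``."""
        t0, t1 = window
        spikes = [
            [t[(t >= t0) & (t < t1)] for t in per_neuron] for per_neuron in self.spikes
        ]
        return SpikeRaster(spikes, window, self.trial_labels, self.condition)

    def bin_edges(self, bin_ms: float = 1.0) -> np.ndarray:
        t0, t1 = self.window
        n_bins = int(round((t1 - t0) / bin_ms))
        return t0 + np.arange(n_bins + 1) * bin_ms


@dataclass
class NeuronMetrics:
    synchrony: np.ndarray  # nan for zero-spike neurons
    entropy_nats: np.ndarray  # nan for zero-spike neurons
    evoked_rate_Hz: np.ndarray
    n_spikes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "synchrony": self.synchrony,
                "entropy_nats": self.entropy_nats,
                "evoked_rate_Hz": self.evoked_rate_Hz,
                "n_spikes": self.n_spikes,
            }
        )


def synchrony_per_neuron(
    raster: SpikeRaster, bin_ms: float = 1.0, include_self: bool = True
) -> np.ndarray:
    """Trial-normalized population synchrony per neuron.

    Neurons with zero spikes get NaN (undefined).  Trials with zero total
    spikes contribute nothing.  With ``include_self=False`` the neuron's own
    spikes are removed from the population histogram it reads from before
    normalizing.
    """
    if raster.n_neurons == 0 or raster.n_trials == 0:
        raise ValueError("empty raster")
    edges = raster.bin_edges(bin_ms)
    n_bins = edges.size - 1
    n = raster.n_neurons
    acc = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    for trial in range(raster.n_trials):
        per_neuron_bins = []
        hist = np.zeros(n_bins)
        for j in range(n):
            t = raster.spikes[j][trial]
            t = t[(t >= edges[0]) & (t < edges[-1])]
            b = np.floor((t - edges[0]) / bin_ms).astype(int)
            per_neuron_bins.append(b)
            np.add.at(hist, b, 1.0)
        total = hist.sum()
        if total == 0:
            continue
        for j, b in enumerate(per_neuron_bins):
            if b.size == 0:
                continue
            if include_self:
                vals = hist[b] / total
            else:
                own = np.zeros(n_bins)
                np.add.at(own, b, 1.0)
                rest = total - b.size
                if rest <= 0:
                    continue
                vals = (hist[b] - own[b]) / rest
            acc[j] += vals.sum()
            cnt[j] += b.size
    out = np.full(n, np.nan)
    nz = cnt > 0
    out[nz] = acc[nz] / cnt[nz]
    return out


def psth(
    raster: SpikeRaster, neuron: int, bin_ms: float = 1.0, normalize: str = "raw"
) -> np.ndarray:
    """Peri-stimulus histogram of one neuron pooled over trials.

    ``normalize``: 'raw' (counts) or 'probability' (sums to 1; all-zero
    histograms are returned as zeros).
    """
    edges = raster.bin_edges(bin_ms)
    counts = np.zeros(edges.size - 1)
    for trial in range(raster.n_trials):
        t = raster.spikes[neuron][trial]
        t = t[(t >= edges[0]) & (t < edges[-1])]
        counts += np.histogram(t, bins=edges)[0]
    if normalize == "probability":
        s = counts.sum()
        return counts / s if s > 0 else counts
    return counts


def psth_entropy(raster: SpikeRaster, neuron: int, bin_ms: float = 1.0) -> float:
    """Shannon entropy (nats) of the neuron's normalized peri-stimulus histogram.

    NaN for neurons without any spike in the window (undefined).
    """
    counts = psth(raster, neuron, bin_ms)
    if counts.sum() == 0:
        return float("nan")
    return float(stats.entropy(counts))  # scipy normalizes and uses natural log


def evoked_rate(raster: SpikeRaster, neuron: int) -> float:
    """Mean evoked firing rate in Hz: spikes in window / (trials x window)."""
    t0, t1 = raster.window
    span_s = (t1 - t0) * 1e-3
    if span_s <= 0:
        raise ValueError("window length must be positive")
    n_spk = sum(
        int(np.count_nonzero((t >= t0) & (t < t1))) for t in raster.spikes[neuron]
    )
    return n_spk / (raster.n_trials * span_s)


def all_neuron_metrics(raster: SpikeRaster, bin_ms: float = 1.0) -> NeuronMetrics:
    """Synchrony, entropy, evoked rate and spike count for every neuron."""
    sync = synchrony_per_neuron(raster, bin_ms)
    ent = np.array([psth_entropy(raster, j, bin_ms) for j in range(raster.n_neurons)])
    rate = np.array([evoked_rate(raster, j) for j in range(raster.n_neurons)])
    nspk = np.array(
        [sum(t.size for t in raster.spikes[j]) for j in range(raster.n_neurons)]
    )
    return NeuronMetrics(sync, ent, rate, nspk)


def regress_out_rate(values: np.ndarray, rates: np.ndarray) -> dict:
    """Residualize a metric against firing rate (and log-rate).

    Least-squares linear fits of metric on rate and on log10(rate + eps) are
    both reported; residuals retain the metric's dependence on anything but
    rate.  Raises on (near-)constant rates, where the fit is degenerate.
    """
    values = np.asarray(values, float)
    rates = np.asarray(rates, float)
    if values.size != rates.size or values.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.std(rates) < 1e-12:
        raise np.linalg.LinAlgError("rates are constant; rate fit is degenerate")
    out = {}
    for name, x in (("rate", rates), ("log_rate", np.log10(rates + 1e-12))):
        slope, intercept = np.polyfit(x, values, 1)
        out[f"residuals_{name}"] = values - (slope * x + intercept)
        out[f"slope_{name}"] = float(slope)
    return out


def paired_test(a: np.ndarray, b: np.ndarray) -> dict:
    """Paired t-test summary for two matched metric vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    t, p = stats.ttest_rel(a[ok], b[ok])
    return {
        "mean_a": float(a[ok].mean()),
        "mean_b": float(b[ok].mean()),
        "mean_diff": float((a[ok] - b[ok]).mean()),
        "t": float(t),
        "p": float(p),
        "n": int(ok.sum()),
    }


def decode_patterns(
    vectors: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    folds: int = 5,
    seed: int | None = 0,
) -> dict:
    """k-NN pattern decoding with stratified cross-validation.

    ``vectors`` is (n_trials, n_neurons) spike counts, ``labels`` the pattern
    id per trial.  Majority vote over the ``k`` Euclidean nearest neighbours;
    returns mean held-out accuracy, per-fold accuracies and the summed
    confusion matrix.
    """
    vectors = np.asarray(vectors, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to decode")
    if counts.min() < folds:
        raise ValueError(
            f"stratification infeasible: smallest class has {counts.min()} < {folds} members"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    class_index = {c: i for i, c in enumerate(classes)}
    for train, test in skf.split(vectors, labels):
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(vectors[train], labels[train])
        pred = clf.predict(vectors[test])
        accs.append(float(np.mean(pred == labels[test])))
        for yt, yp in zip(labels[test], pred):
            confusion[class_index[yt], class_index[yp]] += 1
    return {
        "accuracy": float(np.mean(accs)),
        "fold_accuracies": accs,
        "confusion": confusion,
        "classes": classes,
        "k": k,
        "chance": 1.0 / classes.size,
    }


# ---------------------------------------------------------------------------
# raster I/O: gzipped TSV event table + JSON header


def write_raster(raster: SpikeRaster, path: str | Path) -> None:
    """Write a raster as a gzipped TSV event table plus a JSON header."""
    path = Path(path)
    rows = []
    for j in range(raster.n_neurons):
        for trial in range(raster.n_trials):
            for t in raster.spikes[j][trial]:
                rows.append((j, trial, float(t)))
    df = pd.DataFrame(rows, columns=["neuron_id", "trial", "t_ms"])
    with gzip.open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)
    header = {
        "n_neurons": raster.n_neurons,
        "n_trials": raster.n_trials,
        "window_ms": list(raster.window),
        "condition": raster.condition,
        "trial_labels": None
        if raster.trial_labels is None
        else [int(x) for x in raster.trial_labels],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))


def read_raster(path: str | Path) -> SpikeRaster:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with gzip.open(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t")
    n, m = header["n_neurons"], header["n_trials"]
    spikes = [[np.empty(0) for _ in range(m)] for _ in range(n)]
    for (j, trial), grp in df.groupby(["neuron_id", "trial"]):
        spikes[int(j)][int(trial)] = np.sort(grp["t_ms"].to_numpy())
    labels = header.get("trial_labels")
    return SpikeRaster(
        spikes,
        tuple(header["window_ms"]),
        None if labels is None else np.asarray(labels),
        header.get("condition", ""),
    )
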