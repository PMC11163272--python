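"""Extracellular spike-train processing and per-unit metrics.

The processing chain mirrors standard in vivo single-unit workflows:

1. zero-phase band-pass of the raw voltage trace (300-6000 Hz),
2. threshold detection at 5 SD from the mean (negative deflections by
   default, absolute-deviation mode available),
3. k-means partitioning of detected waveforms on their leading principal
   components,
4. per-unit metrics: mean waveform, trough-to-peak duration, putative
   pyramidal/interneuron label (boundary 440 us, strict), 1-ms binary
   raster, firing rate, inter-spike intervals, 0-50 ms autocorrelogram and
   burstiness index BI = (50 ms - dt) / 50 ms, where dt is the lag at
   which the cumulative autocorrelogram reaches half its 50-ms total.

Lag 0 is excluded from the autocorrelogram: self-pairs carry no
information about temporal structure and would pin dt at zero. Cluster
aggregation/merging beyond k-means is out of scope; externally curated
spike-to-unit assignments can be passed straight to the metrics layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import signal

PYR_LABEL = "pPYR"
IN_LABEL = "pIN"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Recording:
    """A single-channel extracellular voltage trace."""

    samples: np.ndarray   # voltage, arbitrary units
    rate: float = 20000.0  # samples / s

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 12000:
            raise ValueError("sampling rate must exceed 12 kHz (Nyquist for 6 kHz band edge)")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.rate

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.rate


@dataclass(frozen=True)
class EphysConfig:
    """Processing parameters; defaults follow the conventions above."""

    band: Tuple[float, float] = (300.0, 6000.0)
    filter_order: int = 3          # Butterworth order (zero-phase -> 6th effective)
    detect_sd: float = 5.0
    detect_mode: str = "negative"  # "negative" | "absolute"
    refractory_ms: float = 1.0
    waveform_pre_ms: float = 0.6
    waveform_post_ms: float = 1.0
    raster_bin_ms: float = 1.0
    acg_max_lag_ms: int = 50
    pyr_ttp_threshold_us: float = 440.0
    subsample_refine: bool = True
    n_pca: int = 3
    kmeans_seed: int = 0

    def __post_init__(self) -> None:
        if self.detect_sd <= 0:
            raise ValueError("detect_sd must be positive")
        if self.detect_mode not in ("negative", "absolute"):
            raise ValueError("detect_mode must be 'negative' or 'absolute'")


@dataclass
class SortedUnit:
    """One isolated unit with its spike train and derived metrics."""

    unit_id: int
    spike_times_ms: np.ndarray
    mean_waveform: np.ndarray
    ttp_us: float                 # NaN when undefined
    unit_class: str               # pPYR / pIN / unclassified
    firing_rate_hz: float
    isi_ms: np.ndarray
    acg: np.ndarray               # counts at lags 1..acg_max_lag_ms
    burstiness: float             # NaN when undefined


# ---------------------------------------------------------------------------
# signal conditioning and detection

def bandpass(rec: Recording, cfg: EphysConfig = EphysConfig()) -> Recording:
    """Zero-phase Butterworth band-pass; removes DC, preserves length."""
    lo, hi = cfg.band
    nyq = rec.rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {cfg.band} outside (0, Nyquist={nyq:g})")
    sos = signal.butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    return Recording(signal.sosfiltfilt(sos, rec.samples), rec.rate)


def detect_spikes(rec: Recording, cfg: EphysConfig = EphysConfig()) -> np.ndarray:
    """Detect spike times (ms) by thresholding a filtered trace.

    The threshold is ``detect_sd`` standard deviations from the mean.
    Default polarity is negative (extracellular somatic spikes deflect
    downward): events where the trace drops below mean - k*SD, aligned to
    the local extremum of each sub-threshold excursion. ``absolute`` mode
    thresholds |x - mean| instead. Events closer than the refractory
    period to an accepted event are discarded (first-come).
    """
    x = rec.samples
    if len(x) == 0:
        return np.array([])
    mu, sd = float(np.mean(x)), float(np.std(x))
    if sd == 0:
        warnings.warn("zero-variance signal: no spikes detectable")
        return np.array([])
    if cfg.detect_mode == "negative":
        dev = -(x - mu)
    else:
        dev = np.abs(x - mu)
    over = dev > cfg.detect_sd * sd
    if not over.any():
        return np.array([])
    # contiguous supra-threshold excursions -> one event each, at the extremum
    bounded = np.concatenate(([0], over.view(np.int8), [0]))
    d = np.diff(bounded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    peaks = np.array([s + int(np.argmax(dev[s:e])) for s, e in zip(starts, ends)])
    times_ms = peaks / rec.rate * 1000.0
    # refractory enforcement
    kept: List[float] = []
    last = -np.inf
    for t in times_ms:
        if t - last >= cfg.refractory_ms:
            kept.append(t)
            last = t
    return np.asarray(kept)


def extract_waveforms(
    rec: Recording, spike_times_ms: np.ndarray, cfg: EphysConfig = EphysConfig()
) -> Tuple[np.ndarray, np.ndarray]:
    """Cut waveform snippets around spike times.

    Returns ``(waveforms, kept_times)``; spikes whose window would run off
    either end of the trace are dropped.
    """
    pre = int(round(cfg.waveform_pre_ms * rec.rate / 1000.0))
    post = int(round(cfg.waveform_post_ms * rec.rate / 1000.0))
    idx = np.round(np.asarray(spike_times_ms) * rec.rate / 1000.0).astype(int)
    ok = (idx - pre >= 0) & (idx + post < len(rec.samples))
    snippets = np.array([rec.samples[i - pre : i + post + 1] for i in idx[ok]])
    return snippets, np.asarray(spike_times_ms)[ok]


# ---------------------------------------------------------------------------
# clustering and waveform classification

def cluster_waveforms(waveforms: np.ndarray, k: int, cfg: EphysConfig = EphysConfig()) -> np.ndarray:
    """k-means labels for waveform snippets, on leading principal components.

    Seeded and deterministic for a fixed config seed.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    waveforms = np.asarray(waveforms, dtype=float)
    n = len(waveforms)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n_waveforms, got k={k}, n={n}")
    n_comp = min(cfg.n_pca, waveforms.shape[1], n)
    scores = PCA(n_components=n_comp, random_state=cfg.kmeans_seed).fit_transform(waveforms)
    km = KMeans(n_clusters=k, n_init=10, random_state=cfg.kmeans_seed)
    return km.fit_predict(scores)


def _parabolic_vertex(y: np.ndarray, i: int) -> float:
    """Sub-sample extremum position via 3-point parabola around index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def trough_to_peak(mean_waveform: np.ndarray, rate: float, refine: bool = True) -> float:
    """Trough-to-peak duration of a mean waveform, in microseconds.

    Time from the global trough to the maximum that follows it, with
    optional parabolic sub-sample refinement of both extrema. Returns NaN
    when undefined: trough at the last sample, or no turning point after
    the trough (monotone tail).
    """
    y = np.asarray(mean_waveform, dtype=float)
    if len(y) < 3 or np.all(y == y[0]):
        return float("nan")
    trough = int(np.argmin(y))
    if trough >= len(y) - 1:
        return float("nan")
    after = y[trough + 1 :]
    peak_rel = int(np.argmax(after))
    peak = trough + 1 + peak_rel
    if peak == len(y) - 1 and y[-1] > y[-2]:
        return float("nan")  # still rising at the edge: peak not contained
    t_tr = _parabolic_vertex(y, trough) if refine else float(trough)
    t_pk = _parabolic_vertex(y, peak) if refine else float(peak)
    return (t_pk - t_tr) / rate * 1e6


def classify_unit(ttp_us: float, cfg: EphysConfig = EphysConfig()) -> str:
    """Putative pyramidal (strictly > 440 us trough-to-peak) vs interneuron."""
    if ttp_us is None or np.isnan(ttp_us):
        return UNCLASSIFIED
    return PYR_LABEL if ttp_us > cfg.pyr_ttp_threshold_us else IN_LABEL


# ---------------------------------------------------------------------------
# spike-train metrics

def rasterize(spike_times_ms: Sequence[float], duration_ms: float, bin_ms: float = 1.0) -> np.ndarray:
    """Binary raster: bin floor(t / bin) set to 1; multiple spikes collapse."""
    times = np.asarray(spike_times_ms, dtype=float)
    if times.size and (times.min() < 0 or times.max() >= duration_ms):
        raise ValueError("spike times must lie in [0, duration_ms)")
    n_bins = int(np.ceil(duration_ms / bin_ms))
    raster = np.zeros(n_bins, dtype=np.int8)
    raster[np.floor(times / bin_ms).astype(int)] = 1
    return raster


def firing_rate(spike_times_ms: Sequence[float], duration_s: float) -> float:
    """Mean rate in spikes per second."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(spike_times_ms) / duration_s


def isi(spike_times_ms: Sequence[float]) -> np.ndarray:
    """Successive inter-spike intervals, in ms."""
    return np.diff(np.asarray(spike_times_ms, dtype=float))


def autocorrelogram(raster: np.ndarray, max_lag_ms: int = 50) -> np.ndarray:
    """Spike-pair counts at lags 1..max_lag (bins of the raster).

    ``acg[l-1] = sum_t raster[t] * raster[t+l]``. Lag 0 (self-pairs) is
    excluded. A raster shorter than the maximum lag is handled over the
    available lags with a warning; missing lags count 0.
    """
    raster = np.asarray(raster)
    n = len(raster)
    if n <= max_lag_ms:
        warnings.warn(f"raster of {n} bins shorter than max lag {max_lag_ms}; tail lags are 0")
    acg = np.zeros(max_lag_ms, dtype=np.int64)
    for lag in range(1, min(max_lag_ms, n - 1) + 1):
        acg[lag - 1] = int(np.dot(raster[:-lag].astype(np.int64), raster[lag:]))
    return acg


def burstiness(acg: np.ndarray) -> float:
    """Burstiness index BI = (L - dt) / L over an L-lag autocorrelogram.

    dt is the smallest lag at which the cumulative autocorrelogram reaches
    at least half its total (ties broken toward smaller dt); NaN when the
    autocorrelogram is empty (no spike pairs within the window).
    """
    acg = np.asarray(acg, dtype=float)
    L = len(acg)
    total = acg.sum()
    if total <= 0:
        return float("nan")
    cum = np.cumsum(acg)
    dt = int(np.argmax(cum >= total / 2.0)) + 1  # lags are 1-based
    return (L - dt) / L


# ---------------------------------------------------------------------------
# recording I/O and the end-to-end pipeline

def read_recording(path, rate: Optional[float] = None) -> Recording:
    """Load a recording from single-column CSV or raw float32 LE binary.

    Binary files require the rate, either passed explicitly or from a YAML
    sidecar ``<file>.meta`` with a ``rate`` key (``channels`` optional,
    must be 1).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        samples = np.loadtxt(path, dtype=float)
        return Recording(samples, rate or 20000.0)
    meta_path = path.with_suffix(path.suffix + ".meta")
    if rate is None:
        if not meta_path.exists():
            raise FileNotFoundError(f"no rate given and no sidecar {meta_path}")
        meta = yaml.safe_load(meta_path.read_text())
        if int(meta.get("channels", 1)) != 1:
            raise ValueError("only single-channel recordings are supported")
        rate = float(meta["rate"])
    samples = np.fromfile(path, dtype="<f4").astype(float)
    return Recording(samples, rate)


def write_recording(rec: Recording, path) -> None:
    """Write raw float32 LE binary plus a YAML sidecar with the rate."""
    path = Path(path)
    rec.samples.astype("<f4").tofile(path)
    meta_path = path.with_suffix(path.suffix + ".meta")
    meta_path.write_text(yaml.safe_dump({"rate": float(rec.rate), "channels": 1}))


def _unit_metrics(
    unit_id: int,
    spike_times_ms: np.ndarray,
    waveforms: np.ndarray,
    rec: Recording,
    cfg: EphysConfig,
) -> SortedUnit:
    mean_wf = waveforms.mean(axis=0) if len(waveforms) else np.zeros(1)
    ttp = trough_to_peak(mean_wf, rec.rate, refine=cfg.subsample_refine)
    raster = rasterize(spike_times_ms, rec.duration_ms, cfg.raster_bin_ms)
    acg = autocorrelogram(raster, cfg.acg_max_lag_ms)
    return SortedUnit(
        unit_id=unit_id,
        spike_times_ms=spike_times_ms,
        mean_waveform=mean_wf,
        ttp_us=ttp,
        unit_class=classify_unit(ttp, cfg),
        firing_rate_hz=firing_rate(spike_times_ms, rec.duration),
        isi_ms=isi(spike_times_ms),
        acg=acg,
        burstiness=burstiness(acg),
    )


def sort_units(
    rec: Recording,
    k: int = 2,
    cfg: EphysConfig = EphysConfig(),
    labels: Optional[np.ndarray] = None,
) -> List[SortedUnit]:
    """Run the full chain: filter, detect, cluster, per-unit metrics.

    ``labels`` may carry externally curated spike-to-unit assignments (one
    integer per detected spike, in detection order), bypassing k-means.
    Returns units ordered by their label index.
    """
    filtered = bandpass(rec, cfg)
    times = detect_spikes(filtered, cfg)
    waveforms, times = extract_waveforms(filtered, times, cfg)
    if len(times) == 0:
        return []
    if labels is None:
        labels = cluster_waveforms(waveforms, k, cfg)
    labels = np.asarray(labels)
    if len(labels) != len(times):
        raise ValueError("one label per detected spike required")
    units = []
    for uid in sorted(set(int(l) for l in labels)):
        mask = labels == uid
        units.append(_unit_metrics(uid, times[mask], waveforms[mask], rec, cfg))
    return units


def unit_table(units: Sequence[SortedUnit]):
    """Per-unit summary as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "n_spikes": [len(u.spike_times_ms) for u in units],
            "firing_rate_hz": [u.firing_rate_hz for u in units],
            "ttp_us": [u.ttp_us for u in units],
            "class": [u.unit_class for u in units],
            "burstiness": [u.burstiness for u in units],
        }
    )


def plot_unit(unit: SortedUnit, rate: float = 20000.0):
    """Diagnostic figure: mean waveform, ISI histogram, autocorrelogram."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    t_ms = np.arange(len(unit.mean_waveform)) / rate * 1000.0
    axes[0].plot(t_ms, unit.mean_waveform)
    axes[0].set(title=f"unit {unit.unit_id} ({unit.unit_class})", xlabel="ms")
    if len(unit.isi_ms):
        axes[1].hist(unit.isi_ms, bins=50)
    axes[1].set(title="ISI", xlabel="ms")
    axes[2].bar(np.arange(1, len(unit.acg) + 1), unit.acg, width=1.0)
    axes[2].set(title=f"ACG (BI={unit.burstiness:.2f})", xlabel="lag (ms)")
    fig.tight_layout()
    return fig
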