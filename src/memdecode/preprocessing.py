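"""Clusterless spike extraction from broadband microwire traces.

Pipeline: line-noise notch bank and 300-Hz high-pass (both zero-phase
Butterworth), per-channel symmetric threshold at three times the
minimum-across-epochs standard deviation, polarity-split event
extraction (one event per maximal supra-threshold run, at its
extremum), bundle-level coincidence rejection, amplitude discretization
into half-SD bins, 5-ms binning inside non-overlapping 250-ms windows,
and per-bundle/per-polarity z-scoring.

Amplitudes are carried in units of the detection standard deviation, so
the discretized event trains are invariant to any positive rescaling of
the input trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

FS_DEFAULT = 32_000.0
WINDOW_S = 0.25
BIN_S = 0.005
NOTCH_CENTERS_HZ = np.arange(300.0, 3000.0 + 1, 60.0)
NOTCH_BANDWIDTH_HZ = 4.0
HIGHPASS_HZ = 300.0
THRESHOLD_SDS = 3.0
BIN_EDGE_LOW = 3.5
BIN_EDGE_HIGH = 30.0
COINCIDENT_WINDOW_S = 0.004
COINCIDENT_MIN_CHANNELS = 6


@dataclass
class ThresholdSpec:
    """Per-channel detection thresholds.

    ``sd_per_epoch[channel][epoch]`` holds the filtered-trace SD for each
    task epoch; the operative SD is the minimum across epochs and the
    symmetric threshold is ``3 * SD``, applied to every epoch.
    """

    sd_per_epoch: dict
    sd: dict = field(init=False)
    threshold: dict = field(init=False)

    def __post_init__(self):
        self.sd = {ch: min(v.values()) for ch, v in self.sd_per_epoch.items()}
        self.threshold = {ch: THRESHOLD_SDS * s for ch, s in self.sd.items()}

    def dead_channels(self) -> list:
        return [ch for ch, s in self.sd.items() if s == 0.0]


@dataclass
class AmplitudeTrain:
    """Polarity-split threshold-crossing events for one channel.

    Times are sample indices; amplitudes are signed trace values until
    :func:`discretize` converts them to binned magnitudes in SD units
    (sign is carried by polarity-list membership).
    """

    channel: int
    sd: float                       # operative detection SD of this channel
    neg_times: np.ndarray
    neg_amps: np.ndarray
    pos_times: np.ndarray
    pos_amps: np.ndarray
    discretized: bool = False

    def n_events(self) -> int:
        return len(self.neg_times) + len(self.pos_times)


def notch_filter_bank(x: np.ndarray, fs: float = FS_DEFAULT) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-stops at 300..3000 Hz in
    60-Hz steps, 4-Hz bandwidth, to remove line-noise harmonics in the
    spike band."""
    highest = NOTCH_CENTERS_HZ[-1] + NOTCH_BANDWIDTH_HZ / 2
    if fs < 2 * highest:
        raise ValueError(
            f"sample rate {fs} Hz too low for notch center {NOTCH_CENTERS_HZ[-1]} Hz")
    y = np.asarray(x, dtype=np.float64)
    for fc in NOTCH_CENTERS_HZ:
        lo, hi = fc - NOTCH_BANDWIDTH_HZ / 2, fc + NOTCH_BANDWIDTH_HZ / 2
        sos = signal.butter(2, [lo, hi], btype="bandstop", fs=fs, output="sos")
        y = signal.sosfiltfilt(sos, y, axis=-1)
    return y


def highpass(x: np.ndarray, fs: float = FS_DEFAULT,
             cutoff_hz: float = HIGHPASS_HZ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass isolating spiking."""
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples in trace")
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def compute_thresholds(filtered_epochs: dict) -> ThresholdSpec:
    """``filtered_epochs``: epoch name -> array (n_channels, n_samples).

    SD is computed per channel per epoch; the minimum across epochs sets
    one symmetric +-3*SD threshold per channel for all epochs.
    """
    if not filtered_epochs:
        raise ValueError("at least one epoch required")
    sd_per_epoch: dict = {}
    for epoch, arr in filtered_epochs.items():
        arr = np.atleast_2d(np.asarray(arr))
        if arr.shape[1] == 0:
            raise ValueError(f"epoch {epoch!r} is empty")
        for ch in range(arr.shape[0]):
            sd_per_epoch.setdefault(ch, {})[epoch] = float(arr[ch].std())
    return ThresholdSpec(sd_per_epoch)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) spans of True runs."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_events(filtered: np.ndarray, channel: int,
                  spec: ThresholdSpec) -> AmplitudeTrain:
    """One event per maximal contiguous supra-threshold run, recorded at
    the run's extremum (minimum for negative, maximum for positive
    crossings). Dead channels (SD = 0) emit no events."""
    x = np.asarray(filtered, dtype=np.float64)
    thr = spec.threshold[channel]
    sd = spec.sd[channel]
    if thr == 0.0:
        warnings.warn(f"channel {channel} has zero SD (dead); no events emitted")
        empty = np.array([], dtype=np.int64)
        return AmplitudeTrain(channel, 0.0, empty, np.array([]), empty.copy(),
                              np.array([]))
    neg_t, neg_a, pos_t, pos_a = [], [], [], []
    for a, b in _runs(x < -thr):
        i = a + int(np.argmin(x[a:b]))
        neg_t.append(i)
        neg_a.append(x[i])
    for a, b in _runs(x > thr):
        i = a + int(np.argmax(x[a:b]))
        pos_t.append(i)
        pos_a.append(x[i])
    return AmplitudeTrain(channel, sd,
                          np.asarray(neg_t, dtype=np.int64), np.asarray(neg_a),
                          np.asarray(pos_t, dtype=np.int64), np.asarray(pos_a))


def remove_coincident(trains: list[AmplitudeTrain], fs: float = FS_DEFAULT,
                      window_s: float = COINCIDENT_WINDOW_S,
                      min_channels: int = COINCIDENT_MIN_CHANNELS,
                      ) -> list[AmplitudeTrain]:
    """Bundle-level artifact rejection.

    Both polarities are pooled to count distinct channels; any event in a
    group of events on >= ``min_channels`` distinct channels whose times
    all fall within a ``window_s`` span is removed from both polarity
    lists. Bundles with fewer than ``min_channels`` channels pass through
    unchanged with a warning.
    """
    if len(trains) < min_channels:
        warnings.warn(
            f"bundle has {len(trains)} channels (<{min_channels}); "
            "coincidence rejection skipped")
        return trains
    span = int(round(window_s * fs))
    times, chans = [], []
    for tr in trains:
        for tarr in (tr.neg_times, tr.pos_times):
            times.append(tarr)
            chans.append(np.full(len(tarr), tr.channel))
    times = np.concatenate(times) if times else np.array([], dtype=np.int64)
    chans = np.concatenate(chans) if chans else np.array([], dtype=np.int64)
    order = np.argsort(times, kind="stable")
    times_s, chans_s = times[order], chans[order]
    remove = np.zeros(len(times), dtype=bool)
    j = 0
    n = len(times_s)
    for i in range(n):
        if j < i + 1:
            j = i + 1
        while j < n and times_s[j] - times_s[i] <= span:
            j += 1
        # window [t_i, t_i + span]; every qualifying span starts at some event
        if len(np.unique(chans_s[i:j])) >= min_channels:
            remove[order[i:j]] = True
    # map removal flags back through the flattened order
    out = []
    kept_masks = {}
    offset = 0
    for ti, tr in enumerate(trains):
        for pol, tarr in (("neg", tr.neg_times), ("pos", tr.pos_times)):
            kept_masks[(ti, pol)] = ~remove[offset:offset + len(tarr)]
            offset += len(tarr)
    for ti, tr in enumerate(trains):
        mneg, mpos = kept_masks[(ti, "neg")], kept_masks[(ti, "pos")]
        out.append(AmplitudeTrain(tr.channel, tr.sd,
                                  tr.neg_times[mneg], tr.neg_amps[mneg],
                                  tr.pos_times[mpos], tr.pos_amps[mpos],
                                  discretized=tr.discretized))
    return out


def discretize(train: AmplitudeTrain) -> AmplitudeTrain:
    """Map absolute amplitudes (in SD units) into half-width bins
    {3.5, 4.0, ..., 30.0}, replacing each value by the left bin edge.

    Values in [3, 3.5) -- emitted by the 3*SD detector but below the
    lowest bin -- map up to 3.5; values >= 30.5 clip down to 30.0.
    """
    if train.discretized:
        return train

    def disc(a: np.ndarray) -> np.ndarray:
        mag = np.abs(a) / train.sd if train.sd > 0 else np.abs(a)
        b = np.floor(mag * 2.0) / 2.0
        return np.clip(b, BIN_EDGE_LOW, BIN_EDGE_HIGH)

    return AmplitudeTrain(train.channel, train.sd,
                          train.neg_times, disc(train.neg_amps),
                          train.pos_times, disc(train.pos_amps),
                          discretized=True)


def bin_segments(trains: list[AmplitudeTrain], n_samples: int,
                 fs: float = FS_DEFAULT, window_s: float = WINDOW_S,
                 bin_s: float = BIN_S) -> np.ndarray:
    """Sum discretized amplitudes into 5-ms bins within non-overlapping
    250-ms windows tiling the epoch from its start.

    Returns ``(n_windows, 2, n_channels, B)`` with polarity index 0 =
    negative, 1 = positive; a trailing partial window is discarded.
    """
    samples_per_window = int(round(window_s * fs))
    samples_per_bin = int(round(bin_s * fs))
    if samples_per_window % samples_per_bin:
        raise ValueError("window must be an integer number of bins")
    n_bins = samples_per_window // samples_per_bin
    n_windows = int(n_samples // samples_per_window)
    if n_windows == 0:
        raise ValueError("epoch shorter than one window")
    out = np.zeros((n_windows, 2, len(trains), n_bins), dtype=np.float32)
    tiled = n_windows * samples_per_window
    for ci, tr in enumerate(trains):
        if not tr.discretized:
            raise ValueError("bin_segments expects discretized trains")
        for pol, (tarr, aarr) in enumerate(
                ((tr.neg_times, tr.neg_amps), (tr.pos_times, tr.pos_amps))):
            if len(tarr) == 0:
                continue
            if tarr.min() < 0 or tarr.max() >= n_samples:
                raise ValueError("event outside epoch bounds")
            keep = tarr < tiled
            t, a = tarr[keep], aarr[keep]
            w = t // samples_per_window
            b = (t - w * samples_per_window) // samples_per_bin
            np.add.at(out, (w, pol, ci, b), a.astype(np.float32))
    return out


def bundle_zscore_stats(tensor: np.ndarray, bundle_of_channel: np.ndarray) -> dict:
    """Pooled mean/SD per (bundle, polarity) over all windows, bins and
    bundle channels of the normalization span tensor
    ``(n_windows, 2, Ne, B)``."""
    bundle_of_channel = np.asarray(bundle_of_channel)
    stats = {}
    for b in np.unique(bundle_of_channel):
        chans = np.flatnonzero(bundle_of_channel == b)
        for pol in (0, 1):
            vals = tensor[:, pol, chans, :]
            m, s = float(vals.mean()), float(vals.std())
            if s == 0.0:
                raise ValueError(f"zero SD in bundle {b}, polarity {pol}")
            stats[(int(b), pol)] = (m, s)
    return stats


def apply_bundle_zscore(tensor: np.ndarray, bundle_of_channel: np.ndarray,
                        stats: dict) -> np.ndarray:
    out = np.array(tensor, dtype=np.float32, copy=True)
    bundle_of_channel = np.asarray(bundle_of_channel)
    for (b, pol), (m, s) in stats.items():
        chans = np.flatnonzero(bundle_of_channel == b)
        out[:, pol, chans, :] = (out[:, pol, chans, :] - m) / s
    return out


def zscore_bundle(tensors: dict, bundle_of_channel: np.ndarray,
                  span_epochs: tuple = None) -> dict:
    """Z-score windowed tensors per (bundle, polarity).

    ``tensors``: epoch name -> ``(n_windows, 2, Ne, B)``. Statistics are
    pooled over ``span_epochs`` (default: all epochs, i.e. the entire
    experimental period) and the same statistics are applied everywhere.
    """
    span = list(tensors) if span_epochs is None else list(span_epochs)
    if not span:
        raise ValueError("empty normalization span")
    pooled = np.concatenate([tensors[e] for e in span], axis=0)
    stats = bundle_zscore_stats(pooled, bundle_of_channel)
    return {e: apply_bundle_zscore(t, bundle_of_channel, stats)
            for e, t in tensors.items()}


def preprocess_events(trains: list[AmplitudeTrain], n_samples: dict,
                      bundle_of_channel: np.ndarray = None,
                      fs: float = FS_DEFAULT) -> np.ndarray:
    """Convenience: discretize + bin one epoch of event trains."""
    disc = [discretize(t) for t in trains]
    return bin_segments(disc, n_samples, fs=fs)
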