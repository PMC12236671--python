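"""Region ablations, the circular-shift surrogate-model control, and the
macrowire spectral baseline.

Ablation models retrain the decoder on channel subsets defined by
anatomical region (whole bundles only): removing or keeping the medial
temporal lobe (MTL = hippocampus, amygdala, parahippocampal and
entorhinal cortex), the hippocampus alone, or frontal cortex (FC =
prefrontal + anterior cingulate). The circular-shift control rotates the
viewing windows in time while leaving the labels fixed, retrains, and
scores recall: it preserves within- and across-window autocorrelation
but destroys label alignment, so the real model's pooled Z is compared
against the surrogate Z distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as ssig

MTL_REGIONS = {"HPC", "AMY", "PHC", "ENT"}
FC_REGIONS = {"PFC", "ACC"}
ABLATION_MODES = ("full", "no_mtl", "no_hpc", "no_fc", "only_mtl", "only_fc")


@dataclass
class ChannelMap:
    """channel -> (bundle, region). Bundles are the unit of inclusion."""

    bundle: dict      # channel -> bundle id
    region: dict      # channel -> region label

    def channels(self) -> list:
        return sorted(self.bundle)

    def bundles(self) -> dict:
        out: dict = {}
        for ch, b in self.bundle.items():
            out.setdefault(b, []).append(ch)
        return {b: sorted(chs) for b, chs in out.items()}

    def region_of_bundle(self) -> dict:
        out = {}
        for ch, b in self.bundle.items():
            r = self.region[ch]
            if b in out and out[b] != r:
                raise ValueError(f"bundle {b} spans regions {out[b]} and {r}")
            out[b] = r
        return out

    def subset(self, channels: list) -> "ChannelMap":
        chans = set(channels)
        return ChannelMap({c: b for c, b in self.bundle.items() if c in chans},
                          {c: r for c, r in self.region.items() if c in chans})


def select_channels(cmap: ChannelMap, mode: str) -> list:
    """Channel subset for an ablation mode; whole bundles are kept or
    dropped together. An empty result (e.g. removing MTL from a
    participant with only MTL coverage) is an error: such a participant
    cannot run that model."""
    if not cmap.bundle:
        raise ValueError("empty channel map")
    if mode not in ABLATION_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {ABLATION_MODES}")
    rb = cmap.region_of_bundle()

    def keep(region: str) -> bool:
        if mode == "full":
            return True
        if mode == "no_mtl":
            return region not in MTL_REGIONS
        if mode == "no_hpc":
            return region != "HPC"
        if mode == "no_fc":
            return region not in FC_REGIONS
        if mode == "only_mtl":
            return region in MTL_REGIONS
        return region in FC_REGIONS  # only_fc

    chans = [ch for ch, b in sorted(cmap.bundle.items()) if keep(rb[b])]
    if not chans:
        raise ValueError(f"mode {mode!r} removes every channel")
    return chans


def circular_shift(windows: np.ndarray, shift_s: float,
                   window_s: float = 0.25) -> np.ndarray:
    """Rotate the window sequence by ``round(shift_s / window_s)``
    windows, identically for all channels; content beyond the end wraps
    to the beginning. Labels are untouched by construction (only the
    neural tensor is passed in)."""
    windows = np.asarray(windows)
    n = windows.shape[0]
    k = int(round(shift_s / window_s)) % n
    return np.roll(windows, k, axis=0)


def shift_test(train_and_score, viewing: dict, n_perm: int = 100,
               min_shift_s: float = 60.0, seed: int = 0,
               shared_shift: bool = False, window_s: float = 0.25) -> dict:
    """Circular-shift permutation test of a full decoding pipeline.

    ``viewing``: participant -> (region_inputs, labels) where
    ``region_inputs`` is the per-region list of window tensors.
    ``train_and_score``: callable mapping such a dict to one pooled Z
    (train on the viewing data, infer on untouched recall, pool MCS).

    Per permutation each participant's window sequence is rotated by a
    random amount >= ``min_shift_s`` (independently per participant by
    default; ``shared_shift=True`` applies one magnitude to everyone),
    the pipeline is retrained and scored. Returns the real Z, the
    surrogate Z distribution, and the real Z's midrank percentile.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    z_real = float(train_and_score(viewing))
    z_surr = np.empty(n_perm)
    shifts: list = []
    for k in range(n_perm):
        shifted = {}
        shared = None
        perm_shifts = {}
        for pid, (regions, labels) in viewing.items():
            period_s = regions[0].shape[0] * window_s
            if period_s <= 2 * min_shift_s:
                raise ValueError("viewing period too short for the minimum shift")
            if shared_shift:
                if shared is None:
                    shared = rng.uniform(min_shift_s, period_s - min_shift_s)
                s = shared
            else:
                s = rng.uniform(min_shift_s, period_s - min_shift_s)
            perm_shifts[pid] = float(s)
            shifted[pid] = ([circular_shift(x, s, window_s) for x in regions],
                            labels)
        z_surr[k] = float(train_and_score(shifted))
        shifts.append(perm_shifts)
    below = np.count_nonzero(z_surr < z_real)
    ties = np.count_nonzero(z_surr == z_real)
    pct = 100.0 * (below + 0.5 * ties) / n_perm
    return {"z_real": z_real, "z_surrogate": z_surr, "percentile": pct,
            "shifts_s": shifts}


def morlet_band_centers(n_bands: int = 8, f_lo: float = 3.0,
                        f_hi: float = 180.0) -> np.ndarray:
    """Geometrically spaced band centers from 3 to 180 Hz."""
    return f_lo * (f_hi / f_lo) ** (np.arange(n_bands) / (n_bands - 1))


def _morlet_kernel(s: float, w: float, m: int) -> np.ndarray:
    """Complex Morlet wavelet of scale ``s`` (samples) and ``w`` cycles."""
    x = np.arange(-(m // 2), m // 2 + 1) / s
    return (np.exp(1j * w * x) * np.exp(-0.5 * x ** 2)
            * np.pi ** -0.25 / np.sqrt(s))


def macro_features(bipolar: np.ndarray, fs: float = 2000.0,
                   n_bands: int = 8, cycles: float = 6.0,
                   window_s: float = 0.25, t_per_window: int = 50) -> np.ndarray:
    """Morlet-wavelet band power features from bipolar-referenced iEEG.

    ``bipolar``: (n_pairs, n_samples) at ``fs``. Instantaneous power is
    extracted in eight log-spaced bands (3-180 Hz, Morlet with
    ``cycles`` cycles), decimated to ``t_per_window`` samples per 250-ms
    window, and arranged as ``(n_windows, 1, n_pairs * n_bands, T)`` --
    the macro analogue of the clusterless window tensor, consumed by the
    same model with (1, 10) patches.
    """
    bipolar = np.atleast_2d(np.asarray(bipolar, dtype=float))
    centers = morlet_band_centers(n_bands)
    if centers[-1] >= fs / 2:
        raise ValueError(
            f"band center {centers[-1]:.1f} Hz at or above Nyquist ({fs / 2} Hz)")
    n_pairs, n_samples = bipolar.shape
    spw = int(round(window_s * fs))
    n_windows = n_samples // spw
    if n_windows == 0:
        raise ValueError("recording shorter than one window")
    if spw % t_per_window:
        raise ValueError("samples per window must be divisible by T")
    dec = spw // t_per_window
    power = np.empty((n_pairs, n_bands, n_samples))
    for bi, f in enumerate(centers):
        s = cycles * fs / (2 * np.pi * f)
        m = min(int(10 * s) | 1, n_samples | 1)
        wav = _morlet_kernel(s, cycles, m)
        for pi in range(n_pairs):
            coef = ssig.fftconvolve(bipolar[pi], wav, mode="same")
            power[pi, bi] = np.abs(coef) ** 2
    # average-pool down to T samples per window
    tiled = power[:, :, :n_windows * spw]
    pooled = tiled.reshape(n_pairs, n_bands, n_windows, t_per_window, dec).mean(-1)
    # (n_windows, 1, n_pairs * n_bands, T)
    out = pooled.transpose(2, 0, 1, 3).reshape(n_windows, n_pairs * n_bands,
                                               t_per_window)
    return out[:, None, :, :].astype(np.float32)
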