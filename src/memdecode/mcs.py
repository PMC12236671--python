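"""Memory Confidence Score (MCS) and pooled population statistics.

The decoder emits, per concept, an activation in (0, 1) every 250 ms
over the recall period. The MCS asks whether activation rises above its
recall-wide baseline specifically in the 4 s before vocalizations of
that concept. The observed statistic ``A_real`` is the mean, over the
concept's (deduplicated, >= 3) vocalization onsets, of the area of the
smoothed activation above baseline inside the pre-onset window. A
surrogate distribution is built by drawing, 1500 times, the same number
of onsets from the pool of all *other* word onsets (other concepts
included) and recomputing the mean area. The MCS is the midrank
percentile of ``A_real`` within the surrogates: 50 = chance, 100 =
stronger pre-vocalization activation than every surrogate draw.

The score is invariant to positive affine transforms of the timeline
and, for onset-independent activations, uniform on [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

STEP_S = 0.25
SMOOTH_STEPS = 4              # 1-s trailing moving average at 250 ms
DEFAULT_WINDOW_S = (-4.0, 0.0)
N_SURROGATES = 1500
MIN_VOCALIZATIONS = 3


@dataclass
class ActivationTimeline:
    """Per-concept activation sampled every 250 ms over the pooled
    (free + cued) recall period."""

    values: np.ndarray          # (n_steps, n_concepts)
    step_s: float = STEP_S
    smoothed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite activation values")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_steps * self.step_s


@dataclass
class MCSResult:
    concept: int
    a_real: float
    a_surrogate: np.ndarray
    mcs: float
    n_vocalizations: int
    window_s: tuple = DEFAULT_WINDOW_S


def smooth(timeline: ActivationTimeline) -> ActivationTimeline:
    """Trailing 1-s (4-step) moving average per concept; the leading
    edge averages only the samples available so far (causal: a value at
    time t never sees activations after t)."""
    if timeline.smoothed:
        raise ValueError("timeline already smoothed")
    v = timeline.values
    csum = np.cumsum(v, axis=0)
    out = np.empty_like(v)
    k = SMOOTH_STEPS
    n = v.shape[0]
    for i in range(min(k, n)):
        out[i] = csum[i] / (i + 1)
    if n > k:
        out[k:] = (csum[k:] - csum[:-k]) / k
    return ActivationTimeline(out, timeline.step_s, smoothed=True)


def _window_steps(n_steps: int, onset_s: float, window_s: tuple,
                  step_s: float) -> np.ndarray:
    """Indices of the 250-ms steps inside [onset+w0, onset+w1),
    truncated to the recall period (identically for real and surrogate
    onsets)."""
    a = int(np.floor((onset_s + window_s[0]) / step_s))
    b = int(np.floor((onset_s + window_s[1]) / step_s))
    a, b = max(a, 0), min(b, n_steps)
    return np.arange(a, b)


def area_above_baseline(timeline: ActivationTimeline, concept: int,
                        onset_s: float, window_s: tuple = DEFAULT_WINDOW_S,
                        baseline: float = None) -> float:
    """Area (activation - baseline, clipped at 0, times 0.25 s) of the
    smoothed timeline within the pre-onset window. Baseline defaults to
    the concept's mean over the entire recall period."""
    v = timeline.values[:, concept]
    if baseline is None:
        baseline = float(v.mean())
    idx = _window_steps(timeline.n_steps, onset_s, window_s, timeline.step_s)
    if idx.size == 0:
        raise ValueError("window empty after truncation to the recall period")
    return float(np.maximum(v[idx] - baseline, 0.0).sum() * timeline.step_s)


def mcs(timeline: ActivationTimeline, concept: int,
        concept_onsets_s: np.ndarray, other_onsets_s: np.ndarray,
        window_s: tuple = DEFAULT_WINDOW_S, n_surrogates: int = N_SURROGATES,
        seed: int = 0, pre_smoothed: bool = False) -> MCSResult:
    """Memory Confidence Score for one concept.

    ``concept_onsets_s`` must already be deduplicated; fewer than three
    onsets makes the concept ineligible (ValueError). Each surrogate
    draw samples the same number of onsets from ``other_onsets_s``
    without replacement.
    """
    concept_onsets_s = np.asarray(concept_onsets_s, dtype=float)
    other_onsets_s = np.asarray(other_onsets_s, dtype=float)
    n = len(concept_onsets_s)
    if n < MIN_VOCALIZATIONS:
        raise ValueError(
            f"concept vocalized {n} (<{MIN_VOCALIZATIONS}) times: ineligible")
    if len(other_onsets_s) < n:
        raise ValueError("surrogate pool smaller than the vocalization count")
    tl = timeline if pre_smoothed else smooth(timeline)
    base = float(tl.values[:, concept].mean())

    def mean_area(onsets: np.ndarray) -> float:
        areas = []
        for t in onsets:
            idx = _window_steps(tl.n_steps, t, window_s, tl.step_s)
            if idx.size == 0:
                continue  # onset with no usable window: excluded
            areas.append(np.maximum(tl.values[idx, concept] - base, 0.0).sum()
                         * tl.step_s)
        if not areas:
            raise ValueError("no usable windows for any onset")
        return float(np.mean(areas))

    a_real = mean_area(concept_onsets_s)
    rng = np.random.default_rng(seed)
    surr = np.empty(n_surrogates)
    for k in range(n_surrogates):
        surr[k] = mean_area(rng.choice(other_onsets_s, size=n, replace=False))
    # midrank percentile; equality up to float rounding counts as a tie
    # (a constant timeline must score exactly 50)
    tol = 1e-12 + 1e-9 * abs(a_real)
    below = np.count_nonzero(surr < a_real - tol)
    ties = np.count_nonzero(np.abs(surr - a_real) <= tol)
    score = 100.0 * (below + 0.5 * ties) / n_surrogates
    return MCSResult(concept, a_real, surr, score, n, window_s)


def stepwise_mcs(timeline: ActivationTimeline, concept: int,
                 concept_onsets_s: np.ndarray, other_onsets_s: np.ndarray,
                 centers_s: np.ndarray = None, width_s: float = 4.0,
                 n_surrogates: int = N_SURROGATES, seed: int = 0) -> dict:
    """MCS over a family of 4-s windows centered from -9 to +5 s around
    vocalization onsets (the -2 s center reproduces the primary
    [-4, 0] s score). Returns center -> MCSResult."""
    if centers_s is None:
        centers_s = np.arange(-9.0, 5.0 + 1e-9, 1.0)
    tl = smooth(timeline)
    out = {}
    for c in centers_s:
        win = (c - width_s / 2.0, c + width_s / 2.0)
        out[float(c)] = mcs(tl, concept, concept_onsets_s, other_onsets_s,
                            window_s=win, n_surrogates=n_surrogates, seed=seed,
                            pre_smoothed=True)
    return out


def score_recall(timeline: ActivationTimeline, log, concepts: list = None,
                 n_surrogates: int = N_SURROGATES, seed: int = 0,
                 window_s: tuple = DEFAULT_WINDOW_S) -> dict:
    """MCS for every eligible concept of a vocalization log.

    ``log``: :class:`~memdecode.annotation.VocalizationLog` whose concept
    entries are integer or string concept ids matching timeline columns
    (integers index columns directly). Returns concept -> MCSResult.
    """
    eligible = log.eligible_concepts(MIN_VOCALIZATIONS)
    if concepts is not None:
        eligible = [c for c in eligible if c in concepts]
    tl = smooth(timeline)
    results = {}
    for c in eligible:
        col = c if isinstance(c, (int, np.integer)) else list(concepts).index(c)
        results[c] = mcs(tl, int(col), log.concept_onsets(c),
                         log.other_onsets(c), window_s=window_s,
                         n_surrogates=n_surrogates, seed=seed,
                         pre_smoothed=True)
    return results


def wilcoxon_z(values: np.ndarray, mu: float = 0.0) -> float:
    """Wilcoxon signed-rank Z for values vs ``mu``: zero differences
    dropped, midrank ties, normal approximation with tie correction.
    Positive Z means values above ``mu``."""
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 0.0
    ranks = sstats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    if var == 0:
        return 0.0
    return float((w_plus - mean) / np.sqrt(var))


def pooled_test(mcs_values: np.ndarray, chance: float = 50.0) -> dict:
    """Population-level test of MCS values against chance: Wilcoxon
    signed-rank Z and p (normal approximation) plus one-sample Cohen's D
    = mean(MCS - 50) / SD(MCS)."""
    x = np.asarray(mcs_values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one MCS value")
    if np.all(x == chance):
        import warnings
        warnings.warn("all values equal chance; Z undefined, reported as 0")
        return {"z": 0.0, "p": 1.0, "d": 0.0, "n": int(x.size)}
    z = wilcoxon_z(x, mu=chance)
    p = 2.0 * sstats.norm.sf(abs(z))
    sd = x.std(ddof=1)
    d = float((x - chance).mean() / sd) if sd > 0 else np.inf
    return {"z": z, "p": float(p), "d": d, "n": int(x.size)}


def paired_test(a: np.ndarray, b: np.ndarray) -> dict:
    """Paired model comparison: signed-rank on the differences and
    Cohen's D for paired samples (mean diff / SD diff)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return {"z": 0.0, "p": 1.0, "d": 0.0, "n": int(a.size)}
    z = wilcoxon_z(diff)
    p = 2.0 * sstats.norm.sf(abs(z))
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else np.inf
    return {"z": z, "p": float(p), "d": d, "n": int(a.size)}
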