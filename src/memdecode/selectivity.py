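"""Character-selectivity analysis on sorted units.

For each unit and character, firing rates in the 1-s windows before and
after character onsets (solo appearances of >= 1 s only) are compared
with a paired t-statistic whose null is built by randomly sign-flipping
each appearance's pre-to-post difference (one-tailed, increases only).
A unit is *selective* when it (1) fires at least one spike in more than
30% of post-onset windows, (2) beats 99% of the sign-flip null, and
(3) does so for exactly one character; *responsive* units satisfy (1)
and (2) for at least one character. Units averaging under 0.5 spikes/s
over the viewing period are excluded up front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

MIN_VIEWING_RATE_HZ = 0.5
MIN_APPEARANCE_S = 1.0
COVERAGE_FRACTION = 0.30
N_PERMUTATIONS = 1000
ALPHA = 0.01


@dataclass
class SortedUnit:
    unit_id: int
    spike_times_s: np.ndarray
    participant: str = ""

    def viewing_rate_hz(self, viewing_duration_s: float) -> float:
        n = np.count_nonzero(
            (self.spike_times_s >= 0) & (self.spike_times_s < viewing_duration_s))
        return n / viewing_duration_s


@dataclass
class CharacterAppearance:
    character: str
    onset_s: float
    offset_s: float
    solo: bool = True

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SelectivityVerdict:
    unit_id: int
    character: str
    t: float
    p: float
    coverage: float
    significant: bool


def filter_units(units: list, viewing_duration_s: float) -> list:
    """Drop units firing below 0.5 spikes/s across the viewing period."""
    return [u for u in units
            if u.viewing_rate_hz(viewing_duration_s) >= MIN_VIEWING_RATE_HZ]


def valid_appearances(appearances: list) -> list:
    """Solo appearances of at least one second, with a full pre-window in
    the recording; overlapping analysis windows drop the later
    appearance."""
    apps = sorted((a for a in appearances
                   if a.solo and a.duration_s >= MIN_APPEARANCE_S
                   and a.onset_s >= 1.0),
                  key=lambda a: a.onset_s)
    kept: list = []
    for a in apps:
        if kept and a.onset_s - kept[-1].onset_s < 2.0:
            import warnings
            warnings.warn(
                f"appearance at {a.onset_s:.2f}s overlaps previous window; dropped")
            continue
        kept.append(a)
    return kept


def pre_post_rates(unit: SortedUnit, appearances: list) -> np.ndarray:
    """Per appearance: firing rate in [-1, 0) and [0, 1) s around onset
    (half-open windows: a spike exactly at onset counts as post).
    Returns (n_appearances, 2)."""
    t = np.asarray(unit.spike_times_s)
    out = []
    for a in valid_appearances(appearances):
        pre = np.count_nonzero((t >= a.onset_s - 1.0) & (t < a.onset_s))
        post = np.count_nonzero((t >= a.onset_s) & (t < a.onset_s + 1.0))
        out.append((pre, post))
    return np.asarray(out, dtype=float)


def _paired_t(diff: np.ndarray) -> float:
    sd = diff.std(ddof=1)
    if sd == 0.0:
        m = diff.mean()
        return 0.0 if m == 0 else np.inf * np.sign(m)
    return float(diff.mean() / (sd / np.sqrt(len(diff))))


def sign_flip_test(rates: np.ndarray, n_perm: int = N_PERMUTATIONS,
                   seed: int = 0) -> tuple:
    """Paired t on (post - pre) with a sign-flip permutation null.

    One-tailed for rate increases: p = (1 + #{t_perm >= t_obs}) /
    (1 + n_perm), including the observed statistic in the null count so
    p is always in (0, 1].
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 2 or rates.shape[0] < 2:
        raise ValueError("need >= 2 appearances of (pre, post) rates")
    diff = rates[:, 1] - rates[:, 0]
    if np.all(diff == 0.0):
        return 0.0, 1.0
    t_obs = _paired_t(diff)
    rng = np.random.default_rng(seed)
    n = len(diff)
    flips = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    flipped = flips * diff
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(sds > 0, means / (sds / np.sqrt(n)),
                          np.where(means == 0, 0.0, np.inf * np.sign(means)))
    # tolerance absorbs float rounding so p is exactly invariant to any
    # common positive rescaling of the rates
    tol = 0.0 if np.isinf(t_obs) else 1e-9 * max(1.0, abs(t_obs))
    p = (1 + np.count_nonzero(t_perm >= t_obs - tol)) / (1 + n_perm)
    return float(t_obs), float(p)


def coverage_fraction(unit: SortedUnit, appearances: list) -> float:
    """Fraction of post-onset windows with at least one spike."""
    apps = valid_appearances(appearances)
    if not apps:
        return 0.0
    t = np.asarray(unit.spike_times_s)
    hit = sum(np.any((t >= a.onset_s) & (t < a.onset_s + 1.0)) for a in apps)
    return hit / len(apps)


def score_unit_character(unit: SortedUnit, appearances: list,
                        n_perm: int = N_PERMUTATIONS,
                        seed: int = 0) -> SelectivityVerdict:
    apps = valid_appearances(appearances)
    character = apps[0].character if apps else "?"
    rates = pre_post_rates(unit, appearances)
    t, p = sign_flip_test(rates, n_perm=n_perm, seed=seed)
    cov = coverage_fraction(unit, appearances)
    sig = (cov > COVERAGE_FRACTION) and (p < ALPHA)
    return SelectivityVerdict(unit.unit_id, character, t, p, cov, sig)


def classify_units(verdicts: list) -> dict:
    """unit id -> 'selective' | 'responsive' | 'none'.

    Selective: significant for exactly one character; responsive:
    significant for one or more (selective units are also responsive).
    """
    per_unit: dict = {}
    for v in verdicts:
        per_unit.setdefault(v.unit_id, []).append(v)
    out = {}
    for uid, vs in per_unit.items():
        n_sig = sum(v.significant for v in vs)
        out[uid] = ("selective" if n_sig == 1
                    else "responsive" if n_sig >= 1 else "none")
    return out


def psth(unit: SortedUnit, appearances: list, bin_s: float = 0.1,
         step_s: float = 0.05, window_s: tuple = (-1.0, 2.0),
         zscore_stats: tuple = None) -> dict:
    """Peri-onset firing rate on a sliding grid (100-ms bins, 50-ms
    overlap over [-1, +2] s by default): mean and SE across appearances.

    ``zscore_stats``: optional (mean, sd) of the unit's 100-ms binned
    rate over the full episode, for the z-scored variant.
    """
    apps = valid_appearances(appearances)
    if not apps:
        raise ValueError("no valid appearances")
    starts = np.arange(window_s[0], window_s[1] - bin_s + 1e-9, step_s)
    centers = starts + bin_s / 2.0
    t = np.asarray(unit.spike_times_s)
    rates = np.empty((len(apps), len(starts)))
    for i, a in enumerate(apps):
        rel = t - a.onset_s
        for j, s in enumerate(starts):
            rates[i, j] = np.count_nonzero((rel >= s) & (rel < s + bin_s)) / bin_s
    if zscore_stats is not None:
        m, sd = zscore_stats
        rates = (rates - m) / sd
    return {"centers_s": centers,
            "mean": rates.mean(axis=0),
            "se": rates.std(axis=0, ddof=1) / np.sqrt(len(apps)),
            "n": len(apps)}


def episode_rate_stats(unit: SortedUnit, duration_s: float,
                       bin_s: float = 0.1) -> tuple:
    """Mean and SD of the 100-ms binned firing rate across the episode
    (for z-scored PSTHs)."""
    edges = np.arange(0.0, duration_s + bin_s, bin_s)
    counts, _ = np.histogram(unit.spike_times_s, bins=edges)
    rate = counts / bin_s
    return float(rate.mean()), float(rate.std())


def mcs_unit_correlation(unit_counts: np.ndarray, mcs_values: np.ndarray) -> dict:
    """Pearson correlation between per-(concept, participant) selective
    (or responsive) unit counts and MCS; r is undefined (nan) when either
    variable has zero variance."""
    x = np.asarray(unit_counts, dtype=float)
    y = np.asarray(mcs_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired arrays required")
    if x.std() == 0 or y.std() == 0:
        return {"r": float("nan"), "p": float("nan"), "n": int(x.size)}
    r, p = sstats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}
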