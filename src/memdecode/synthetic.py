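"""Synthetic viewing/recall studies with known ground truth.

The generator emulates the statistical structure the decoder assumes:

* per-channel, per-polarity background threshold-crossing events as a
  homogeneous Poisson process with heavy-tailed (truncated log-normal)
  amplitudes spanning the full discretization range;
* concept-locked modulation: while a concept is on screen, the event
  rate on its assigned channels is scaled by ``1 + gamma`` and its
  bundle-mates are compensated down so each bundle's total rate is
  unchanged -- the label information lives in the within-bundle pattern,
  never in gross rate (otherwise shift/permutation controls would be
  confounded by global excitability);
* recall with timestamped word vocalizations, where each concept
  vocalization is preceded by the same rate-preserving channel pattern
  during the ``reinstatement_lead_s`` seconds before onset;
* sorted-unit Poisson spike trains with character-locked rate gains for
  the selectivity analysis.

At ``gamma = 0`` every output is label-independent by construction, so
the downstream pipeline must perform at chance. One global seed expands
into per-channel substreams via counter-keyed seed sequences, so a
channel-subset simulation reproduces the full run's events exactly.

The generator makes no attempt at biophysical realism (no bursting,
refractoriness or field-potential spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import VocalizationEvent, VocalizationLog, labels_from_schedule
from .preprocessing import AmplitudeTrain

AMP_LOW, AMP_HIGH = 3.0, 35.0  # SD units; spans the bin range incl. clipping


@dataclass
class SimulationSpec:
    n_regions: int = 3
    bundles_per_region: int = 1          # 8 channels per bundle
    episode_duration_s: float = 2435.0
    sample_rate_hz: float = 32000.0
    n_concepts: int = 8
    concept_schedule: list = field(default_factory=list)  # (concept_idx, on_s, off_s)
    effect_size: float = 1.0             # gamma >= 0
    background_rate_hz: float = 4.0      # per channel per polarity
    reinstatement_lead_s: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect size gamma must be >= 0")
        seen = set()
        for entry in self.concept_schedule:
            c, on, off = entry
            if not (0 <= on < off <= self.episode_duration_s):
                raise ValueError(
                    f"schedule interval ({on}, {off}) outside episode bounds")
            key = (c, float(on), float(off))
            if key in seen:
                raise ValueError(f"duplicate schedule entry {key}")
            seen.add(key)

    @property
    def n_bundles(self) -> int:
        return self.n_regions * self.bundles_per_region

    @property
    def n_channels(self) -> int:
        return 8 * self.n_bundles

    def bundle_of_channel(self) -> np.ndarray:
        return np.arange(self.n_channels) // 8

    def channel_concept_map(self) -> np.ndarray:
        """Round-robin channel -> concept assignment, so every concept's
        pattern is spread across bundles."""
        return np.arange(self.n_channels) % self.n_concepts


@dataclass
class GroundTruthManifest:
    seed: int
    channel_concept: np.ndarray
    n_background: int
    n_injected: int
    schedule: list
    vocalizations: list = field(default_factory=list)  # (time_s, word, concept)
    # (channel, polarity) -> bool array aligned with the event train
    # (True = concept-driven / injected, False = background)
    injected: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return self.n_background + self.n_injected


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def random_schedule(n_concepts: int, duration_s: float, seed: int,
                    on_s: float = 5.0, mean_gap_s: float = 18.0,
                    min_gap_s: float = 4.0) -> list:
    """Aperiodic concept schedule: per concept, on-intervals of ``on_s``
    separated by jittered exponential gaps. Aperiodicity matters for the
    circular-shift control: a periodic schedule would re-align with its
    own labels under many shifts."""
    rng = _rng(seed, 13)
    sched = []
    for c in range(n_concepts):
        t = float(rng.uniform(0, mean_gap_s))
        while t + on_s < duration_s:
            sched.append((c, round(t, 3), round(t + on_s, 3)))
            t += on_s + min_gap_s + float(rng.exponential(mean_gap_s - min_gap_s))
    return sched


def _amplitudes(rng: np.random.Generator, n: int) -> np.ndarray:
    """Truncated log-normal amplitudes on [3, 35] SD units (rejection)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mean=np.log(5.0), sigma=0.5, size=max(n - filled, 16))
        draw = draw[(draw >= AMP_LOW) & (draw <= AMP_HIGH)]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _poisson_events(rng: np.random.Generator, rate_hz: float, t0: float,
                    t1: float) -> np.ndarray:
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def _channel_events(spec: SimulationSpec, channel: int, polarity: int,
                    stream: int, duration: float, factor_intervals: list,
                    own_intervals: list) -> tuple:
    """(times_s, amps_sd, n_background, n_injected, injected) for one
    channel/polarity.

    ``factor_intervals``: (t0, t1, factor) spans multiplying the
    background rate; overlapping spans combine multiplicatively. The
    train is realized by thinning a homogeneous process at the peak
    rate, which yields an exact inhomogeneous Poisson process. Events
    inside ``own_intervals`` (the channel's own concept on-spans) are
    marked concept-driven in the provenance flags.
    """
    rng = _rng(spec.seed, stream, channel, polarity)
    fmax = max(1.0, 1.0 + spec.effect_size)
    t = _poisson_events(rng, spec.background_rate_hz * fmax, 0.0, duration)
    f = np.ones(len(t))
    for t0, t1, factor in factor_intervals:
        sel = (t >= t0) & (t < t1)
        f[sel] *= factor
    keep = rng.uniform(0.0, 1.0, len(t)) < f / fmax
    t = t[keep]
    injected = np.zeros(len(t), dtype=bool)
    for t0, t1 in own_intervals:
        injected |= (t >= t0) & (t < t1)
    amps = _amplitudes(rng, len(t))
    n_inj = int(injected.sum())
    return t, amps, len(t) - n_inj, n_inj, injected


def _pattern_factors(spec: SimulationSpec, assign: np.ndarray,
                     intervals_of_concept: dict) -> tuple:
    """Per-channel rate-factor spans for bundle-rate-preserving concept
    patterns.

    While concept ``c`` is active its assigned channels fire at
    ``(1 + gamma) * background`` and the remaining channels of each
    bundle are scaled down so the bundle's total expected rate is
    unchanged (clipped at zero for extreme gamma). Gross bundle rate
    therefore carries no label information -- only the within-bundle
    pattern does, which is what keeps the circular-shift control honest.
    """
    bundles = spec.bundle_of_channel()
    factors: dict[int, list] = {ch: [] for ch in range(spec.n_channels)}
    own: dict[int, list] = {ch: [] for ch in range(spec.n_channels)}
    g = spec.effect_size
    if g == 0:
        return factors, own
    for c, ivs in intervals_of_concept.items():
        for b in np.unique(bundles):
            in_bundle = np.flatnonzero(bundles == b)
            assigned = in_bundle[assign[in_bundle] == c]
            others = in_bundle[assign[in_bundle] != c]
            if len(assigned) == 0:
                continue
            k, n = len(assigned), len(in_bundle)
            d = max(0.0, (n - k * (1.0 + g)) / (n - k)) if k < n else 1.0
            for t0, t1 in ivs:
                for ch in assigned:
                    factors[ch].append((t0, t1, 1.0 + g))
                    own[ch].append((t0, t1))
                for ch in others:
                    factors[ch].append((t0, t1, d))
    return factors, own


def _to_trains(spec: SimulationSpec, per_channel: dict) -> list:
    """Package per-channel (neg, pos) event lists as AmplitudeTrains with
    SD 1, amplitudes in SD units (pre-discretization)."""
    fs = spec.sample_rate_hz
    trains = []
    for ch in range(spec.n_channels):
        (tn, an), (tp, ap) = per_channel[ch]
        trains.append(AmplitudeTrain(
            channel=ch, sd=1.0,
            neg_times=np.round(tn * fs).astype(np.int64),
            neg_amps=-an,       # negative polarity stores negative values
            pos_times=np.round(tp * fs).astype(np.int64),
            pos_amps=ap.copy()))
    return trains


def simulate_viewing(spec: SimulationSpec):
    """Generate viewing-epoch event trains, the 250-ms label matrix and a
    ground-truth manifest."""
    assign = spec.channel_concept_map()
    intervals_of_concept: dict[int, list] = {}
    for c, on, off in spec.concept_schedule:
        intervals_of_concept.setdefault(int(c), []).append((float(on), float(off)))
    factors, own = _pattern_factors(spec, assign, intervals_of_concept)
    per_channel = {}
    prov = {}
    n_bg = n_inj = 0
    for ch in range(spec.n_channels):
        res = {}
        for pol in (0, 1):
            t, a, b, i, inj = _channel_events(
                spec, ch, pol, 0, spec.episode_duration_s,
                factors[ch], own[ch])
            res[pol] = (t, a)
            prov[(ch, pol)] = inj
            n_bg += b
            n_inj += i
        per_channel[ch] = (res[0], res[1])
    labels = labels_from_schedule(
        [(int(c), on, off) for c, on, off in spec.concept_schedule],
        spec.episode_duration_s, list(range(spec.n_concepts)))
    manifest = GroundTruthManifest(spec.seed, assign, n_bg, n_inj,
                                   list(spec.concept_schedule), injected=prov)
    return _to_trains(spec, per_channel), labels, manifest


def simulate_recall(spec: SimulationSpec, vocab: list,
                    n_concept_vocalizations: dict,
                    min_word_gap_s: float = 2.0,
                    mean_extra_gap_s: float = 3.0,
                    word_times: np.ndarray = None):
    """Generate a recall epoch: word vocalizations with minimum inter-word
    gaps, concept-pattern injections in the ``reinstatement_lead_s``
    window before each concept vocalization, and background events
    elsewhere.

    ``n_concept_vocalizations``: concept index -> count. At least one
    concept needs >= 3 vocalizations (downstream scoring eligibility).
    Returns (event trains, VocalizationLog, GroundTruthManifest).
    """
    if not any(n >= 3 for n in n_concept_vocalizations.values()):
        raise ValueError("at least one concept needs >= 3 vocalizations")
    rng = _rng(spec.seed, 9)
    word_list = []
    for c, n in sorted(n_concept_vocalizations.items()):
        word_list += [("concept", int(c))] * int(n)
    word_list += [("word", w) for w in vocab]
    rng.shuffle(word_list)
    n_words = len(word_list)
    if word_times is None:
        gaps = min_word_gap_s + rng.exponential(mean_extra_gap_s, n_words)
        word_times = spec.reinstatement_lead_s + 1.0 + np.cumsum(gaps)
    else:
        word_times = np.sort(np.asarray(word_times, dtype=float))
        if len(word_times) != n_words:
            raise ValueError("word_times length must match total word count")
        if np.diff(word_times).size and np.diff(word_times).min() < min_word_gap_s:
            raise ValueError(
                f"vocalizations closer than the minimum gap {min_word_gap_s} s")
    duration = float(word_times[-1] + 5.0) if n_words else 30.0

    assign = spec.channel_concept_map()
    events, vocal_sched = [], []
    for (kind, val), t in zip(word_list, word_times):
        if kind == "concept":
            events.append(VocalizationEvent(float(t), f"concept_{val}", val))
            vocal_sched.append((float(t), val))
        else:
            events.append(VocalizationEvent(float(t), str(val), None))
    log = VocalizationLog(sorted(events, key=lambda e: e.time_s))

    reinstate: dict[int, list] = {}
    for t, c in vocal_sched:
        reinstate.setdefault(int(c), []).append(
            (max(t - spec.reinstatement_lead_s, 0.0), t))
    factors, own = _pattern_factors(spec, assign, reinstate)
    per_channel = {}
    prov = {}
    n_bg = n_inj = 0
    for ch in range(spec.n_channels):
        res = {}
        for pol in (0, 1):
            t, a, b, i, inj = _channel_events(spec, ch, pol, 1, duration,
                                              factors[ch], own[ch])
            res[pol] = (t, a)
            prov[(ch, pol)] = inj
            n_bg += b
            n_inj += i
        per_channel[ch] = (res[0], res[1])
    manifest = GroundTruthManifest(
        spec.seed, assign, n_bg, n_inj, [],
        vocalizations=[(t, f"concept_{c}", c) for t, c in vocal_sched],
        injected=prov)
    manifest.recall_duration_s = duration
    return _to_trains(spec, per_channel), log, manifest


def simulate_units(n_units: int, duration_s: float, base_rate_hz: float,
                   character_schedule: dict, rate_gain: float, seed: int,
                   unit_character: dict = None):
    """Inhomogeneous-Poisson sorted units for the selectivity analysis.

    ``character_schedule``: character -> list of (onset_s, offset_s).
    ``unit_character``: unit index -> character whose appearances drive a
    rate gain of ``rate_gain`` on that unit (default: none, a pure null).
    Returns (list of spike-time arrays, character_schedule).
    """
    if base_rate_hz < 0:
        raise ValueError("base rate must be >= 0")
    if rate_gain < 0:
        raise ValueError("rate gain must be >= 0")
    unit_character = unit_character or {}
    spikes = []
    for u in range(n_units):
        rng = _rng(seed, 7, u)
        char = unit_character.get(u)
        peak = base_rate_hz * max(1.0, rate_gain if char else 1.0)
        if peak == 0:
            spikes.append(np.array([]))
            continue
        t = _poisson_events(rng, peak, 0.0, duration_s)
        # thin down to the local rate
        rate = np.full(len(t), base_rate_hz)
        if char is not None:
            on = np.zeros(len(t), dtype=bool)
            for a, b in character_schedule.get(char, []):
                on |= (t >= a) & (t < b)
            rate[on] = base_rate_hz * rate_gain
        keep = rng.uniform(0, 1, len(t)) < rate / peak
        spikes.append(t[keep])
    return spikes, character_schedule


def render_to_trace(trains: list, n_samples: int, fs: float = 32000.0,
                    noise_sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Render event trains into continuous voltage traces: each event
    places a fixed 1-ms biphasic template (unit main lobe, 0.4 opposite
    lobe) scaled by ``amplitude * noise_sd``, on top of white Gaussian
    noise. Exercises the filtering/threshold path with a closed-form
    oracle (the injected schedule)."""
    width = int(round(1e-3 * fs))
    half = width // 2
    t1 = np.sin(np.linspace(0, np.pi, half, endpoint=False))
    template = np.concatenate([t1, -0.4 * np.sin(np.linspace(0, np.pi, width - half,
                                                             endpoint=False))])
    out = np.empty((len(trains), n_samples))
    for i, tr in enumerate(trains):
        rng = _rng(seed, 11, tr.channel)
        x = rng.normal(0.0, noise_sd, n_samples)
        for times, amps, sign in ((tr.neg_times, tr.neg_amps, -1.0),
                                  (tr.pos_times, tr.pos_amps, +1.0)):
            for ts, amp in zip(times, amps):
                a = int(ts) - half // 2
                b = a + width
                if a < 0 or b > n_samples:
                    continue
                # main lobe extremum lands at the event time
                x[a:b] += sign * abs(amp) * noise_sd * template
        out[i] = x
    return out
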