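# Methods

`memdecode` implements a pipeline for decoding recalled concepts from
intracranial microwire recordings: clusterless spike extraction, a
per-participant multi-region attention decoder trained on a single
episode viewing, and a permutation-based Memory Confidence Score (MCS)
that detects concept reinstatement in the seconds before recall
vocalizations. This note documents the models, the numerical choices,
the synthetic study that makes everything testable without patient
data, and what the tests do and do not establish.

## Clusterless spike extraction

Broadband microwire traces (32 kHz) are notch-filtered (4th-order
Butterworth band-stops, centers 300–3000 Hz in 60-Hz steps, 4-Hz
bandwidth) and high-pass filtered at 300 Hz (4th-order Butterworth).
Both filters are applied forward–backward (`sosfiltfilt`), so the
specified "4th-order, zero-phase" behaviour is realized as an
8th-order magnitude response with zero group delay — the only
realizable reading of that combination.

Per channel, the filtered-trace SD is computed separately for each task
epoch and the *minimum* across epochs sets a symmetric ±3·SD threshold
used in every epoch. Each maximal contiguous supra-threshold run yields
one event at its extremum (minimum for negative, maximum for positive
crossings); defining events per run rather than per crossing sample
avoids sample-rate-dependent duplicates. Dead channels (SD = 0) emit no
events, are flagged, and keep their all-zero rows so tensor shapes are
stable.

Bundle-level artifact rejection removes any event belonging to a group
of events on ≥6 of the 8 bundle channels within a 4-ms span. The span
is slid over the merged event list with both polarities pooled when
counting distinct channels; pooling is the stricter reading and the
operation is idempotent and only ever removes events.

Amplitudes are expressed in units of the detection SD and discretized
into half-width bins {3.5, 4.0, …, 30.0}, each value replaced by its
left bin edge. Two boundary rules close gaps the binning grid leaves
open: amplitudes in [3, 3.5) — emitted by the 3·SD detector but below
the lowest bin — map up to 3.5, and amplitudes ≥ 30.5 clip down to
30.0, bounding the model's input magnitude. Because amplitudes are in
SD units, the discretized trains are exactly invariant to rescaling the
input trace.

Events are summed (discretized amplitudes, per polarity, per channel)
into 50 bins of 5 ms inside non-overlapping 250-ms windows tiling each
epoch from its start; a trailing partial window is discarded, which is
what makes a 2,435-s viewing epoch yield exactly 9,740 windows. Window
tensors are z-scored per (bundle, polarity) with statistics pooled over
the entire experimental period (default: viewing + recall epochs
together) and the same statistics applied everywhere, so viewing and
recall live on a common scale.

**Amplitude fidelity of threshold detection.** Detection records the
extremum over the supra-threshold run, so the recovered amplitude is
biased upward by the extreme value of the noise across the run's few
samples. At background noise SD 1 this bias is ≈ 0.7–1.4 SD — one to
three discretization bins — and no detector of this form can do better.
The tests therefore check *event recovery* (≥99% of isolated events
with amplitude ≥ 4 SD are found at the right time under noise SD 1) and
verify one-bin amplitude agreement in the low-noise regime (SD 0.3)
where the extreme-value bias is provably below half a bin.

## Concept labels and vocalization logs

Per-second multi-hot annotations are expanded to four identical 250-ms
rows. Temporary label gaps caused by camera cuts are filled per concept
when a zero-run shorter than `max_gap_s` (default 10 s; the qualitative
rule is "present for the whole scene", so the horizon is configurable)
is flanked by ones *within one scene*; filling never clears a one, is
idempotent, and never extends past scene boundaries.

Recall transcripts are matched token-wise, case-insensitively, against
a synonym ontology (the shipped default encodes eight concepts —
persons, places, organizations and abstract concepts from a single
televised episode — and the ten on-screen characters used by the
selectivity analysis; synonym sets must be pairwise disjoint).
Unmatched words are retained with no concept: they form the surrogate
pool. Same-concept mentions within 5 s are deduplicated against the
last *kept* mention, which guarantees retained onsets are ≥5 s apart;
pronouns must arrive pre-resolved by the annotator (a human judgment,
passed as an explicit override column).

## The multi-region attention decoder

Each 8-wire bundle is one region stream. Its 250-ms window tensor
(2 polarities × 8 channels × 50 bins) is cut into (1, 5) patches with
polarity as the convolution input channels — 80 patches — linearly
projected to the hidden size, prefixed with a learnable class token and
given learnable positional embeddings (81 tokens per region). Each of
`depth` blocks then runs, per region, a pre-norm transformer block
(multi-head self-attention + GELU feed-forward, residuals) over the
region's own tokens (region-wise self-attention, RSA), extracts the
class tokens, and updates each region's class token by cross-attending
to the *other* regions' class tokens (cross-region attention, CRA;
pre-norm, residual; identity when only one region exists). The updated
class token is written back into its sequence for the next block —
discarding patch tokens after attention yet stacking several blocks is
only well-defined with this reinsertion. After the last block the class
tokens are averaged across regions and one linear head plus element-wise
sigmoids yields eight independent per-concept activations in (0, 1);
they are multi-label scores and deliberately do not sum to one. RSA and
CRA weights are shared across regions (embeddings, class and positional
tokens are region-specific), so parameters do not grow with electrode
coverage.

Full-scale defaults: hidden 396, feed-forward 792, depth 6, 6 heads,
patch (1, 5); training with per-concept binary cross-entropy, Adam,
learning rate 1e-4 for 49 epochs with step decay (default halving every
16 epochs — the schedule's constants are exposed in config). Label
combinations with under 50 s of total screen time are excluded together
with their windows (a combination at exactly 50 s is retained), and each
epoch's batches are stratified: windows are interleaved by within-
combination quantile position so every batch approximately preserves
combination proportions (batch size 64 by default). The entire viewing
epoch is used for training — no held-out split — because viewing and
recall are drawn from different distributions with only a limited
shared component, and the surrogate statistics downstream, not a
viewing validation score, judge generalization.

The model is implemented directly on NumPy with a small reverse-mode
automatic-differentiation engine (`model/autodiff.py`), gradient-checked
against finite differences in the test suite. Arrays are float32;
inference runs with graph construction disabled.

**Initialization.** Dense weights use Xavier/Glorot initialization;
class and positional tokens use the conventional 0.02-SD truncated
normal. At the small hidden sizes used for desk-scale studies a global
0.02-SD init leaves attention logits so close to uniform that
optimization settles into a degenerate solution; Xavier keeps
activation scale stable through the stack and trains reliably at every
size tested.

**Logistic baseline.** The control model flattens the full window
tensor into one vector and maps it through a single linear layer +
sigmoids, trained with identical settings. It is the reference point
for what linear read-out of per-channel rates achieves; the attention
model must beat it exactly on patterns that require cross-channel
interaction (the tests include a two-channel exclusive-or construction
that the linear model provably cannot separate).

**Macrowire spectral path.** Bipolar iEEG at 2 kHz is decomposed with
Morlet wavelets (6 cycles by default) into eight log-spaced bands from
3 to 180 Hz (ratio (180/3)^(1/7) ≈ 1.795); instantaneous power is
average-pooled to T = 50 samples per 250-ms window and arranged as
(1, pairs × 8, T), consumed by the same architecture with (1, 10)
patches. T and the wavelet width are configuration, not physiology: the
250-ms window's temporal sampling is underdetermined and T = 50 keeps
the macro and clusterless token counts comparable.

## Memory Confidence Score

Per concept, the recall activation timeline (250-ms steps, free and
cued recall concatenated in that order) is smoothed with a *trailing*
4-step (1-s) moving average — a centered 1-s window does not exist at
250-ms resolution, and the trailing form respects the causality of
"activation before vocalization". The baseline is the concept's mean
smoothed activation over the entire recall period. For each
(deduplicated) vocalization of the concept, the area of the smoothed
activation above baseline inside the 4-s pre-onset window is computed
(dips below baseline contribute zero); `A_real` is the mean over the
concept's onsets. Concepts need ≥3 vocalizations after deduplication to
be scored. Each of 1,500 surrogate draws samples the same number of
onsets — without replacement, so the enumeration oracle over all
subsets is well-defined — from the pool of every *other* word onset
(other concepts' vocalizations included, unmatched words undeduplicated),
and the MCS is the midrank percentile of `A_real` in the surrogate
distribution: ties count half, so a constant timeline scores exactly 50
(equality is taken up to float rounding). Onsets whose window truncates
at the recall boundary are truncated identically for real and surrogate
draws. The MCS is exactly invariant to positive affine transforms of
the timeline, and for activations independent of the onsets it is
uniform on [0, 100] (verified by Kolmogorov–Smirnov against the uniform
over 500 null runs).

The stepwise profile repeats the scoring for 4-s windows centered at
−9 … +5 s (15 centers); the −2 s center is by construction the primary
[−4, 0] s score.

**Population tests.** MCS values pooled over concepts and participants
are tested against chance (50) with the Wilcoxon signed-rank test: zero
differences dropped, midrank ties, normal approximation with the tie
correction, Z signed so that values above chance give positive Z;
effect size is one-sample Cohen's D, mean(MCS − 50)/SD(MCS). Model
comparisons use the paired signed-rank on per-concept differences with
Cohen's D for paired samples. Both match exact sign-flip enumeration on
small vectors to 1e-9 and scipy's approximation on larger ones.

## Region ablations and the circular-shift control

Channels are ablated by anatomical region with whole bundles kept or
dropped together: removing or retaining the medial temporal lobe
(hippocampus, amygdala, parahippocampal, entorhinal), the hippocampus
alone, or frontal cortex (prefrontal + anterior cingulate). A mode that
leaves no channels is an error — a participant without coverage outside
the removed region simply cannot run that model. The package ships a
per-participant microwire region-count table as a fixture for the set
algebra of these modes.

The circular-shift control rotates each participant's viewing window
sequence by a random amount (≥60 s by default at full scale; whole
windows only, since sub-window shifts would break the binning
alignment), keeps labels fixed, retrains the full decoder, infers on
untouched recall and recomputes the pooled Z. The real model's
percentile among 100 surrogate Z values measures whether decoding
reflects label alignment rather than temporal structure. Whether one
shift magnitude is shared across participants within a permutation is
ambiguous at full scale; both modes exist behind a flag, with
independent per-participant shifts as the default.

## Character selectivity on sorted units

Sorted units firing below 0.5 spikes/s over viewing are excluded.
Appearances enter the analysis when the character is alone on screen
for ≥1 s, the onset has a full 1-s pre-window, and the analysis windows
do not overlap a previous appearance (the later one is dropped).
Windows are half-open: a spike exactly at onset is post-onset. Per
appearance the paired rates in [−1, 0) and [0, 1) s are compared with a
paired t statistic on post − pre (zero-variance differences map to
±∞ handled as the null's extreme); the null flips each appearance's
difference sign at random (1,000 permutations), one-tailed for
increases, with the add-one convention p = (1 + #{t⊥ ≥ t}) / (1 + n)
so p is always valid, and a float tolerance in the comparison so p is
exactly invariant to rescaling the rates. A unit is *selective* when it
fires in more than 30% of post-onset windows (strict inequality),
exceeds 99% of the null, and does so for exactly one character;
*responsive* units clear the first two rules for one or more
characters. PSTHs use 100-ms bins sliding by 50 ms over [−1, +2] s
(59 centers), mean ± SE over appearances, with an optional z-scored
variant using the unit's 100-ms statistics over the full episode.
The unit-count/MCS relationship is a Pearson correlation, undefined
(NaN) under zero variance.

## The synthetic study

The generator produces the statistical structure the pipeline assumes,
with full ground truth: per-channel, per-polarity background events as
homogeneous Poisson processes (4 Hz default) with truncated log-normal
amplitudes on [3, 35] SD units (median ≈ 5 SD; heavy right tail spans
the whole discretization range including the clipping branch); concept
schedules with jittered exponential gaps (aperiodic by design — a
periodic schedule re-aligns with its own labels under circular shifts);
and word-level recall with a 2-s minimum inter-word gap so surrogate
pools are never degenerate.

Concept patterns are **bundle-rate-preserving**: while concept *c* is
on screen (or during the 4 s before a vocalization of *c*), its
assigned channels fire at (1 + γ)× background and the remaining
channels of each bundle are compensated down so the bundle's total
expected rate is unchanged (realized by thinning a homogeneous process
at the peak rate, which is an exact inhomogeneous Poisson construction).
This matters: if injections simply added events, gross excitability —
not the cross-channel pattern — would carry the labels, misaligned
(circularly shifted) models would still score far above chance, and the
shift control could not distinguish real from surrogate models. With
rate-preserving patterns, γ = 0 yields exactly label-independent data,
and the only decodable signal at γ > 0 is the within-bundle pattern.
Channel→concept assignment is round-robin so every concept's pattern
spans all bundles. One global seed expands into per-channel,
per-polarity substreams through spawn-keyed seed sequences, so a
channel subset of a simulation reproduces the full run's events
bit-exactly, and the manifest records the assignment, per-event
provenance flags and the vocalization schedule (event counts partition
exactly into background + concept-driven).

Events can be rendered into continuous voltage traces — a fixed 1-ms
biphasic template (unit main lobe, 0.4 opposite lobe) scaled by the
target amplitude, on white Gaussian noise — to exercise the filtering
and thresholding path against the known schedule. Sorted units are
inhomogeneous Poisson trains (thinning) with character-locked rate
gains on designated units.

What the generator does **not** emulate: bursting, refractoriness,
waveform variability, field-potential spectra, electrode drift, sleep
physiology, or any correlation structure between channels beyond the
planted patterns. Passing tests therefore establish that the pipeline
recovers the statistical structure it is designed for — not that real
recordings contain that structure.

## Desk-scale study sizes

The validation suite and the acceptance script run everything at sizes
a laptop CPU handles in minutes, chosen once as the package's test-bed
conditions:

* end-to-end decoding: 2 bundles × 8 channels, 168-s viewing, 4
  concepts at γ = 2, 3 concepts vocalized 5× in recall; decoder hidden
  48, feed-forward 96, depth 2, 4 heads, 8 epochs at learning rate
  2e-3; three seeds per condition. Expected outcomes: held-out viewing
  AUC > 0.7 for every concept (measured 0.80–0.99), pooled recall MCS
  median > 90 at γ = 2, AUC ≈ 0.5 and MCS median ≤ 60 at γ = 0.
* circular-shift control: two simulated participants, hidden 32,
  depth 1, 4 epochs, 10 permutations, minimum shift 40 s. The
  correctly-aligned model's Z sits at the 100th percentile at γ = 2 and
  strictly inside the surrogate distribution at γ = 0.
* selectivity calibration: 2,000 null unit×character tests (type-I
  rate 1% within four binomial SDs at p < 0.01), power > 0.9 at rate
  gain 3 with 50 appearances, exact agreement with the 2⁵ sign-flip
  enumeration on 5-appearance cases.

## Known limitations

* The decoder's full-scale configuration (hidden 396, depth 6,
  49 epochs) is faithful to the analysis defaults but is not exercised
  end-to-end in the test suite; correctness at that size rests on the
  architecture tests (shapes, attention semantics, parameter
  accounting, gradient checks) being size-independent.
* Amplitude values recovered from rendered traces carry the
  extreme-value bias described above; applications needing unbiased
  amplitudes would require template fitting, which is out of scope.
* The macrowire path's temporal sampling (T = 50) and Morlet width
  (6 cycles) are conventions, not fitted values.
* Pronoun resolution, audio transcription, spike sorting and electrode
  localization are upstream of this package; their outputs are inputs
  here.
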