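# Methods

This note documents the models, rules and numerical choices behind
`swimencode`, what the synthetic-session generator does and does not
emulate, and the design decisions taken where more than one reading was
defensible.

## Behavioral segmentation

**Tail trace and sign convention.** The substrate is a uniformly sampled
signed tail angle in degrees at 300 Hz. Positive angle means a leftward
tail deflection; consequently a turn whose largest bend is positive is a
*left* turn. The camera-side convention is arbitrary but must be fixed; it
is documented here and applied consistently in the generator and the
classifier.

**Bend detection.** Bends are local extrema of the angle trace after a
3-sample median prefilter, kept when their magnitude exceeds
`min_amp_deg` (default 5°). Two consecutive same-sign extrema are merged
(the larger wins) only when the signal never crossed zero nor returned
below half the amplitude threshold in between; this suppresses ripple
within a half-cycle without fusing genuine bends across quiet gaps between
bouts. Grid sampling plus the median filter attenuate a sampled sine peak
by a few percent; bend amplitudes are therefore read as estimates with a
sub-degree bias, which none of the 25°/60° decision rules are sensitive to
at the margins the generator uses.

**Bouts.** A bout is a maximal interval where the filtered |angle| exceeds
`motion_threshold_deg` (3°), with intervals merged when separated by less
than `min_quiet_s` (100 ms) and discarded when shorter than 50 ms (tracking
noise). Both values are configurable; the motion threshold sits well below
the smallest generated bend (≈ 6.5°) and well above the 1° noise level the
tests exercise. Intervals are half-open `[start, end)` with time origin at
the first sample.

**Cycles.** One oscillation = two consecutive opposite-sign bends;
`n_oscillations = floor(n_bends / 2)`. The instantaneous tail-beat
frequency of cycle *i* uses same-side bend spacing, `1/(t_i − t_{i−2})`;
instantaneous amplitude is |amp| per bend. Summaries are medians over
cycles/bends.

**Episodes.** Three rules segment a bout's bend sequence:

1. runs of sub-25° bends with ≥ 3 oscillations are *forward* episodes;
2. a rare isolated supra-25° bend flanked by ≥ 2 sub-threshold oscillations
   on each side is absorbed into the surrounding forward episode (at most
   one absorbed bend per 6 sub-threshold oscillations — the "rare" rule
   quantified; configurable);
3. remaining supra-25° bends form *struggle* episodes, split where
   successive supra-threshold bends are more than 100 ms apart.

Leftover sub-threshold runs too short for rule 1 are merged into the
temporally nearest episode of the bout, or dropped when the bout produced
no episode at all. Episode boundaries snap to bend times (zero crossings
would be an equally defensible choice; bend times are what the bend list
provides without re-touching the raw trace). Note a deliberate nuance: a
forward episode may contain absorbed supra-threshold bends under rule 2, so
the invariant "forward ⇒ all bends < 25°" is enforced on the non-absorbed
bends, and the absorbed indices are carried in the episode record.
"Symmetry" of forward swims is enforced only through the 25° amplitude
gate, not through a left/right balance statistic.

**Classification and indices.** Bout classes: < 25° forward, 25–60° turn
(side from the sign of the maximum-magnitude bend; ties broken toward the
earlier bend by strict comparison), > 60° discarded. The per-trial forward
index is `(n_forward − n_struggle)/n_total` over the episodes starting
inside the train; the site median filters trials to 10-Hz trains at 1–2 µA
and returns NaN when none qualify. Bouts starting inside a train are
*evoked*; bouts within 60 s after a train are excluded from the spontaneous
pool.

## Fluorescence preprocessing

Corrected fluorescence is `F = F_raw − 0.7·F_neuropil` (neuropil factor
configurable in [0, 1)); subtraction precedes baseline selection. ΔF/F uses
either the median of F over an inactivity interval (single-plane mode; the
pipeline picks the longest bout-free stretch of at least 3 s) or the median
of the lowest 10th percentile of F (volumetric mode, also the fallback when
no quiet stretch exists). Noise σ is the sample s.d. of ΔF/F over the same
inactivity interval. A nonpositive baseline raises rather than silently
producing unbounded ΔF/F. Smoothing is a centered 3-frame running mean
(edges shrink to the available neighbors, so constants are preserved) or a
zero-phase first-order low-pass for display/regression. Artifact frames are
replaced by linear interpolation between the nearest good frames; unmasked
frames are returned bit-identical and the mask is retained.

## Spike inference

Spike rates are the nonnegative series *r* minimizing ‖k∗r − ΔF/F‖² with
k(t) = exp(−t/1.8 s) sampled on the imaging grid. Because convolution with
a single exponential is an order-1 recursive filter, the operator and its
adjoint run in O(n); the bounded least-squares problem is solved with a
trust-region solver through that operator (dense active-set NNLS for traces
up to 600 frames, also used as the test oracle). An optional L2 sparsity
weight (default 0) and a fast exact autoregressive inversion
(`solver="ar"`, r[t] = ΔF/F[t] − γ·ΔF/F[t−1] clipped at zero — identical to
NNLS on noise-free nonnegative-generating input) are provided for large
batch runs.

## Recruitment statistics

Per pulse: responded ⇔ max ΔF/F in [t, t+3 s] > mean ΔF/F over [t−1.5 s, t)
+ 3σ. Reliability across graded intensities: the recruitment threshold I*
is the lowest intensity with any response, and a cell is *reliable* when
every trial at every intensity ≥ I* responded (a tolerance for occasional
failures is exposed, default 0); *non-recruited* when it responded nowhere;
*unreliable* otherwise. This reading of "systematically once an intensity
was reached" anchors I* at the first response, so an isolated response below
a later-systematic block counts against reliability.

Onset/peak of an evoked transient are automated (the upstream workflow
annotated them semi-automatically): the transient is the first
post-stimulus frame exceeding baseline + 1σ that stays above threshold for
two further frames; the onset is the preceding frame (the last one at
baseline), which keeps the peak strictly after the onset even for rises
completed within one frame. The rising slope is
`(ΔF/F_peak − ΔF/F_onset)/(t_peak − t_onset)` computed on raw (unfiltered)
ΔF/F, since filtering lags the signal.

Per episode: the corrected maximum is max ΔF/F over
[start − 0.5 s, end + 2 s] minus the median ΔF/F over the 300 ms before the
episode (removing residual decay of earlier events); recruited ⇔ corrected
max ≥ 5σ. The forward activity index is `(A_f − A_s)/(A_f + A_s)` with A_f,
A_s the means over forward/struggle episodes of the per-episode corrected
maxima floored at zero (keeping the index in [−1, 1]); a variant using
per-episode mean ΔF/F is exposed as `mode="mean"` since both readings of
the definition are defensible. The forward cluster is found by Ward-linkage
agglomerative clustering on z-scored ΔF/F (the distance/linkage is fixed
here for reproducibility and configurable); among 3–6 clusters, the one
with the highest mean forward activity index is the forward cluster, and a
non-positive best mean raises.

## Regressors and encoding model

Frame-level kinematics at imaging rate: iTBA = max |angle| over the
behavior samples in each half-open frame interval; iTBF = mean of the cycle
frequencies whose midpoints fall in the frame (0 when none). Binary-rise
regressors are the Heaviside of the first difference after a 5-frame
running mean. The four motor regressors are these series convolved with
k(t) = exp(−t/1.5 s) at the frame rate and z-scored. Vigor (50-ms sliding
s.d. of the tail angle) and bout/stimulus on-off regressors are built at
the behavior rate, convolved there, and downsampled by taking the
instantaneous convolved value at each frame time. The kernel is sampled on
the source grid and deliberately not normalized to unit sum — z-scoring
before regression removes the scale anyway.

The encoding model is OLS of ΔF/F on [1, x₁…x₄]; masked frames are dropped
from both fit and permutations (not interpolated, to avoid leakage), a
rank-deficient design raises naming the collinear pair, and at least 5×
more frames than parameters are required. Significance is one-sided by
circular time-shifts of ΔF/F (offsets uniform in [10τ, T − 10τ] frames),
which preserve the autocorrelation a calcium trace carries;
p = (1 + #{null α ≥ α})/(1 + n_perm) with n_perm = 999 by default (199 in
the batch validation runs), and significance requires α > 0 and p < 0.05.
No correction across neurons is applied by default (matching the per-neuron
rule); Benjamini–Hochberg is available off by default. Motor/vigor
correlation classes: motor-correlated above the per-fish 75th percentile of
motor correlations; vigor-correlated when the motor correlation beats the
stimulus correlation and the vigor correlation reaches the 75th percentile
of vigor correlations over all ROIs (a candidates-only percentile pool is
exposed as an option). The episode-level size model regresses maximum ΔF/F
on ln(n_oscillations), the log taming the right-skewed oscillation counts.

## Bout-type mapping

Rest frames are those whose mean absolute (median-filtered) tail angle
stays below 0.5° and that overlap no bout — the per-frame mean makes "the
tail angle was zero" robust to tracking noise. Activity per bout type pools
spike rates over [start − 200 ms, end] across all bouts of the type and
runs a one-sided rank-sum test against rest (exact enumeration for tie-free
samples of ≤ 20, otherwise the tie-corrected normal approximation) at
P = 0.01; fewer than 3 bouts of a type yields an undefined marker, not an
error. Groups: forward-component = active in all three types; left/right
steering = active for that side and not forward; everything else *other*
(forward-component takes precedence, so groups partition the population).
Sessions qualify with ≥ 50 bouts and ≥ 1 bout per class.

## Synthetic sessions and what they do (not) capture

The generator renders bouts as concatenated half-sine half-cycles whose
midpoints are the ground-truth bend times: forward bouts at 15–22 Hz with
amplitudes 10–21° and a mild decay envelope (≥ 3 oscillations, duration a
few hundred ms), turns as one signed 30–55° initial bend followed by a
forward component, struggles as ≥ 2 alternating > 27° bends at 6–10 Hz with
a decaying envelope (so the largest bend, and hence the turn side label, is
unambiguous), mixed bouts as forward+struggle chains, and evoked forward
episodes seconds long inside stimulation trains. Sessions start with ≥ 6 s
of quiet so baseline/noise estimation always has an inactivity period;
optional Gaussian angle noise models tracking error. Calcium traces come
from archetype-driven spikes (iTBF-coders, rise-coders,
oscillation-counters with amplitude ∝ ln(n_osc), forward-component/steering
cells, stimulation-reliable/unreliable/non-recruited cells, constant-rate
nulls) convolved with the 1.8-s kernel, embedded as
F = F0·(1 + ΔF/F) + 0.7·neuropil + Gaussian noise so the standard
correction recovers the planted trace exactly. Pixel movies plant disks of
pixels sharing one latent event trace over i.i.d. background noise.

Everything is reproducible bit-for-bit from seed + parameters. The
generator does *not* emulate: tracking dropouts or segmentation errors
beyond additive angle noise, bend-amplitude asymmetries within forward
swims, photobleaching or slow drifts beyond a gentle neuropil oscillation,
shot noise (a Poisson mode exists but Gaussian is the default), movement
artifacts coupled to behavior, or overlapping/merging somata in pixel
movies. Passing the closed-loop tests therefore demonstrates correctness
of the rules and estimators under the stated noise models, not robustness
to every failure mode of real recordings.

## Validation scales and numerical choices

The validation runs use 1,000 scheduled bouts (in chunks of 250 per
session) for the kinematics closed loop at 0° and 1° angle noise; 500
random episode multisets against brute-force counting; 200 noise-free
recruitment archetypes plus 1,000 pure-noise traces against a 20,000-draw
Monte-Carlo estimate of the 3σ windowed-max exceedance; 200 planted
(α₃ = 0.5·σ_ΔF/F, 3,000 frames) and 500 null encoding neurons at
n_perm = 199; 100 noise-free spike transients; 1,000 null bout-type
neurons; and two planted 12-µm² ROI disks in a 40×40-px, 400-frame movie.
These sizes give binomial standard errors comfortably below the margins
being checked while keeping the whole validation run around a minute on
one CPU. Degenerate inputs raise informative errors throughout (empty
traces, nonpositive baselines, all-masked frames, zero-variance series,
rank-deficient designs, overlapping schedules); undefined-but-legal
outcomes (no qualifying site trials, < 3 bouts of a type, zero-variance
correlation traces) return NaN/None markers for downstream exclusion
rather than raising.
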