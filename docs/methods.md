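# Methods

`popcode` reimplements, as a tested library, the analysis chain used to ask
whether a genetic manipulation of cortical inhibition (astrocytic GABA
transporter knockout) changes how visual cortex encodes stimuli: single-neuron
response metrics, an encoding GLM, population decoding, and the group
statistics that compare conditions. Because the original recordings are not
packaged, every stage is validated against a synthetic session generator with
known ground truth; this note documents the models, the defaults and why, and
what the synthetic validation does and does not establish.

## Session model

A session is a neurons × frames fluorescence matrix at 16 Hz with a matched
neuropil channel, running-speed and pupil-diameter series, and a stimulus
protocol: 640 s of gray screen, or 16 trials of 8 drifting-grating directions
(2 s ON, 3 s OFF each), or 32 trials of 7 consecutive 2 s movie clips after a
3 s OFF period. Protocols are exact frame schedules; trials of a condition
are its presentations in session order.

## Synthetic generator

Spike counts are inhomogeneous Poisson at frame resolution with rate

r_i(t) = b + j_{i,p} · g · A_i · exp(κ(cos(θ_t − φ_i) − 1)) · e_{i,c}(t)
       + w_i·z(behavior(t)) + Λ_i·l(t),   floored at 0,

where b is the spontaneous baseline (1 Hz control), g the condition gain
factor, A_i the neuron's peak evoked rate, κ the von Mises concentration,
φ_i the preferred direction (uniform over the 8 protocol directions), j_{i,p}
a unit-mean log-normal per-presentation gain jitter, w_i linear weights on
the z-scored running/pupil series (two mean-reverting processes with 3 s and
8 s timescales), and Λ_i·l(t) a low-dimensional shared latent (OU processes,
1 s timescale). For movie protocols each (neuron, clip) pair additionally has
a smooth, trial-invariant temporal envelope (mean exactly 1), which is what
makes repeated movie trials correlate in time. Fluorescence is the causal
exponential convolution of the spikes (τ = 0.5 s, single-event ΔF/F ≈ 0.2 on
a unit baseline), plus a shared low-pass neuropil signal mixed into the raw
channel with per-neuron coupling around 0.7, sensor noise on both channels,
and a separately emitted neuropil trace.

Neurons are partitioned into disjoint tuned / behavior-coupled / pure-noise /
untuned groups by the config fractions (defaults 0.6 / 0.2 / 0.1, remainder
untuned). Pure-noise neurons carry no latent loading, so setting
`latent_dim=0` and zeroing behavior weights makes spike trains exactly
independent across neurons (a tested property).

Defaults were calibrated once to realistic awake-V1 statistics and then
frozen: peak evoked rate 10 Hz (log-normal spread 0.2) so that strongly
driven neurons reach peak ΔF/F ≈ 1; κ = 1.5, giving a median OSI ≈ 0.4–0.6;
trial-gain jitter log-sd 0.4 with half its variance shared across neurons
(population gain fluctuation, active only when a latent is enabled); latent
loadings ≈ 0.8 Hz. These produce noise correlations ≈ 0.15 and movie
reliability medians ≈ 0.2–0.35, in the range reported for layer-2/3
populations. Without the shared variability, 8-way decoding saturates at
AUROC ≈ 0.99 for any population size — a regime no cortical dataset shows —
and condition differences become invisible.

The knockout condition differs along exactly three axes, mirroring the
reported phenotype (lower firing, lower maximal response, lower trial
reliability): gain factor 0.6, baseline 0.7 Hz, trial jitter log-sd 1.0.
Tuning preferences and the latent structure are untouched, consistent with
preserved pairwise correlations in the original study.

## Preprocessing

Somatic signal is F_ROI = F_raw − 0.7·F_neuropil. The baseline F0 is the
mode of a Gaussian KDE of the corrected trace (Silverman bandwidth, 512-point
grid over the data range); the mode tracks the most frequently occupied
fluorescence level, so sparse transients barely move it. ΔF/F is
(F_ROI − F0)/F0; neurons with F0 ≤ 0 are excluded and logged, not clamped.

Event inference solves min ‖ΔF/F − K·e‖² s.t. e ≥ 0 for the causal
exponential kernel K (decay exp(−1/(τ·f)), τ = 0.5 s default). Writing
c = K·e, the feasible set is exactly {c₀ ≥ 0, c_t ≥ γ·c_{t−1}}, and a
pool-adjacent-violators pass solves the problem exactly in O(T); tests
verify optimality against dense NNLS and an exhaustive active-set
enumeration oracle. Firing rate is the fraction of frames with event
amplitude above threshold (default 0: any event) per second — amplitudes are
not summed, so the statistic is a thresholded event-frame rate.

## Response metrics

Trial responses are window means from stimulus onset (2 s default).
Responsiveness: one-way ANOVA across the 8 conditions plus the pre-onset
blank, p < 0.01, and the best condition must exceed the blank mean; the
null false-positive rate of this criterion is verified ≤ 0.015 by
simulation. Tuning curves are trial means per direction; preference is the
argmax with ties to the lowest index. OSI collapses opposite directions
into 4 orientations (flooring the curve at 0) and is
(R_pref − R_orth)/(R_pref + R_orth), clipped to [0, 1]; an optional
per-neuron baseline (mean blank response) is subtracted first, because an
additive offset common to all directions dilutes the index and breaks its
invariance to evoked-gain scaling. Reliability is the mean Pearson
correlation over all trial pairs of the within-window time courses at the
neuron's preferred (highest mean response) stimulus; pairs with a
zero-variance trial are skipped, not zero-filled. Pairwise correlations use
concatenated stimulus-ON activity (whole trace for gray sessions); signal
correlations correlate trial-averaged condition vectors; noise correlations
z-score trial responses within condition before concatenating, which
removes tuning (verified: tuned neurons with independent noise give signal
correlation 1 and noise correlation ≈ 0).

## Encoding GLM

The design matrix has one 0/1 column per (direction, frame-lag) pair over a
[0, 2] s onset window (8 × 32 = 256 columns at 16 Hz) plus z-scored pupil
and running columns. The behavioral series are z-scored once at construction
(they are exogenous, slowly varying covariates); predictor-neuron traces in
the population model, which carry the predictive signal, are z-scored with
training-block statistics only. The lasso objective is
(1/2n)‖y − Xβ − ε‖² + λ‖β‖₁ with λ = 1e-3; cross-validation uses 10
contiguous temporal blocks, because frame-shuffled folds interleave
autocorrelated calcium signal between train and test and inflate held-out
R². Significance of a predictor group is a two-sided paired t-test of
fold-wise R² between the full model and a partial model refit with the
group's columns removed, Holm-corrected over the three groups (stimulus,
pupil, running), requiring the full model to win on average. Under the null
the lasso usually prunes an irrelevant group entirely, making full and
partial fits identical (p = 1), so the test is conservative; its family-wise
error is verified ≤ 0.07 on 1000 stimulus-independent calcium-like traces.

One consequence of λ = 1e-3 on sparse onset indicators is a hard
detectability floor: a column active at m frames out of n enters the model
only when its (centered) response amplitude exceeds ≈ λn/m (≈ 0.64 ΔF/F for
the grating protocols). The generator's evoked scale is set above this
floor; neurons far below it are genuinely invisible to this encoding model.

The population-activity GLM regresses a target neuron's trace on k randomly
sampled other neurons (target excluded), averaging 10 random draws; the
signed maximum lasso weight is binned at 0.05 / 0.1.

## Decoding

Features are per-neuron window-mean ΔF/F per presentation (2 s gratings,
3 s movies — for movies this crosses into the next clip, as the printed
window does). Splits equalize per-class trial counts (seeded first-k
downsampling), hold out ⌈33%⌉ per class, and keep priors identical on both
sides. The classifier is a linear SVM with per-neuron standardization using
training statistics; C is grid-searched over 10⁻³..10³ (7 log-spaced values)
by stratified 3-fold accuracy. Performance is one-vs-rest macro AUROC of
the held-out decision scores (verified against the Mann–Whitney U/(n₁n₂)
identity). Shuffle controls permute the labels and rerun the entire
pipeline. The population sweep decodes random subsets of 5..25 neurons
(step 5), each with a paired shuffle null; group comparisons use a two-way
ANOVA on group × size.

## Group statistics

Neuron-level metrics from multiple animals are nested; the primary
comparison is a mixed-effects model (value ~ group, random intercept per
animal). The fixed-effect p-value uses a t reference with
df = (number of animals − 2) rather than the fitting library's normal
approximation, which at 4+4 animals yields a measured null false-positive
rate near 0.10; with the between-animal df it is ≈ 0.04 (both measured by
simulation). The df used is recorded on every result. Mann–Whitney,
Kolmogorov–Smirnov and unpaired t wrappers cover non-nested comparisons; a
fully tied Mann–Whitney comparison returns p = 1 with a warning.

## Problem sizes and numerical choices

Simulation-based tests use populations of 60–100 neurons and full-length
protocols, except the encoding false-positive calibration, which uses a
4-trial grating schedule (2560 frames): the t-test/Holm calibration is a
property of the fold comparison, not of session length, and the short
schedule makes the 1000-neuron null affordable. Decoder sweeps in tests use
12 random subsets per population size (50 is the library default).
Tie-breaks everywhere go to the lowest index; undefined correlations are
skipped and counted; degenerate traces (constant y, zero-variance behavior)
are flagged or dropped with warnings rather than patched.

## What passing tests do and do not show

The synthetic validation establishes that each statistic computes what it
claims (exactness oracles), that the pipeline's calibration is honest
(null false-positive rates), and that planted condition effects of known
size are recovered through the full chain (gain ratio ≈ 0.6, reliability
monotone in trial jitter, decoding gap). It does not establish anything
about segmentation, motion, or slow drift — the generator has stationary
baselines and perfect ROIs — nor that real knockout tissue behaves like the
three-knob phenotype; the generator's effect sizes are calibration choices,
not measurements.
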