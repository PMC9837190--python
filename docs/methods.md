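# Methods

`popdecode` re-implements, as a tested pipeline on synthetic data, an
analysis style used with human single-unit recordings during natural
movie viewing: deep decoders predict which characters are visually
present from windowed population firing rates, knockout perturbations
rank the brain regions carrying that information, and the trained
decoders are interrogated during a recognition-memory test.

## The decoding model

Each training sample is a 60-step x N-unit matrix of firing rates
covering one second before and after a movie frame (rates sampled at
30 Hz, so a 2-s window holds exactly 60 samples). The target is a
4 x 3 label matrix: for each of the four decoded characters, a one-hot
distribution over {YES, NO, DNK}. DNK ("do not know") marks frames
inside ambiguity intervals — dialogue passages where the camera
alternates between partners, so a listed but momentarily off-screen
character cannot be called absent. The loss is, per character,

    KL(one-hot truth || prediction) = -log p(true label),

averaged over the four characters, with DNK-labelled characters
contributing exactly zero (the printed formula with the arguments in
the opposite order diverges for one-hot truth; the orientation used
here is the one that is finite and equals cross-entropy). No class
weighting is applied despite the ~10%/88%/2% YES/NO/DNK imbalance.

Two architectures are provided, both implemented on a small numpy
reverse-mode autograd engine written for this package (`popdecode.nn`;
gradients are verified against numerical differentiation in the test
suite):

* **LSTM** — two stacked layers (128 units each by default), final
  hidden state into two fully-connected layers with batch
  normalisation and leaky-ReLU, reshaped to 4 x 3 and row-softmaxed.
* **CNN** — the window treated as a one-channel image through
  convolutions (Gaussian(0, 0.1) weight init) with batch norm and
  leaky-ReLU, max pooling, then the same fully-connected head. Kernel
  and per-block pool shapes are configurable; the default is 3 x 3 with
  a pool after every block (keeping activation maps small on a CPU).
  Because the unit axis carries no topology, the benchmark
  configuration uses purely temporal (3 x 1) kernels with time-only
  pooling, which preserves per-unit identity up to the flatten and
  converges markedly better on rate-coded data than square kernels that
  mix arbitrary neighbouring units.

Training uses Adam (learning rate 1e-3 to 3e-3, optional per-epoch
decay, batch 64-256 depending on problem size), up to 100 epochs,
keeping the epoch checkpoint with the best mean validation F1. Cross-validation follows a shuffled 5-fold
plan: per fold 20% test, and of the remainder 87.5% train / 12.5%
validation (70/10/20 overall). Inputs are standardised per unit with
training-split statistics; knockout zeros are inserted in raw rate
space before this transform, so a knocked-out unit looks like a silent
unit, not like an average one (mean-imputation is available as an
alternative through the same code path by imputing before calling the
predictor).

The chance model retrains the same architecture after permuting whole
4-character label vectors across samples — a stricter null than
independent per-character shuffling because it preserves label
co-occurrence. Classical baselines (prior-sampling "Naive Bayes",
logistic regression, linear SVM on flattened windows) use the same
folds.

## Knockout importance and the synergy statistic

A trained decoder is re-evaluated with the rate columns of a unit group
zeroed: all units of a region, or all units on one 8-microwire
electrode. ΔKLD = loss(knocked) - loss(intact), computed per character
on a fixed evaluation set and averaged over fold models; the normalized
form divides by group size. Region importance summaries report, per
region, the percentage of normalized ΔKLD values above 0.5 pooled over
participants and characters, with exact Clopper-Pearson 95% intervals.
Knockout evaluation uses a fixed random subsample of the training
windows (2,000-2,500) rather than all of them; the ΔKLD estimates are
means over thousands of windows either way and the subsample keeps the
20-run experiments tractable.

The synergy statistic is region ΔKLD minus the sum of its electrodes'
ΔKLDs, both un-normalized (the neuron counts on the two sides of the
subtraction are equal). For a region whose single electrode carries all
its units the statistic is exactly zero by construction.

Empirically — and this is worth stating precisely because it is easy to
get wrong — the sign of this statistic for a *fixed* trained nonlinear
decoder is governed by the covariance of the electrode-level knockout
responses, not directly by the information content of the region. A
second-order expansion of the evaluation loss around the intact input
gives

    synergy ≈ Σ_{e≠e'} E[ s_e s_e' ] x curvature,

where s_e is the loss-relevant response shift caused by zeroing
electrode e. Three regimes follow, all reproduced by the simulator:
with every electrode tuned to the same character, the *signal* itself
correlates the shifts and synergy is positive even with independent
noise; with one character per electrode and strong shared noise the
decoder learns common-mode rejection, single-electrode knockouts corrupt
the region average, and synergy turns negative; with a distributed code
in which each region carries a modest share of each character's
evidence, independent units stay near additivity (|median| < 0.05 in
ΔKLD units) while a shared slow within-region gain fluctuation makes the
statistic significantly positive. The synergy experiment uses the third
regime as its study condition. The shared fluctuation is a log-normal
multiplicative gain drawn per region in 3-s blocks (parameter `rho` sets
its log-sd); drawing it independently per 100-ms bin does not work — it
averages out within the 2-s window and leaves nothing for the statistic
to detect.

## Memory-test analyses

The decoder trained on movie viewing is slid over the memory-session
recording; the per-character probability of YES is the "model
activation". Per clip, activation is summed over a 2-s window from clip
onset (variants: from clip offset, or the 2 s before the response) and
averaged across fold models. A Gaussian-identity GLM (the family is a
package choice; the analysis is robust to it at these noise levels)
models that summed activation as a function of character-in-clip,
clip-marked-seen, and clip-is-target, with optional presence x seen
interaction and an appearance-frequency covariate. The design matrix is
checked for rank; constant or collinear columns raise errors naming the
columns. The MTL knockout variant re-evaluates (never retrains) the
decoder with MTL unit columns zeroed and fits the same GLM.

For clip-level decoding accuracy (the prominence-threshold sweeps) a
character counts as detected when its *time-averaged* activation over
the clip exceeds 0.5; the phase-*maximum* rule defines "activated" only
for the coactivation counting, where a single confident excursion is
the event of interest.

Character associations are conditional probabilities over scenes:
p(c_i | c_j) = duration of scenes with both characters / duration of
scenes with c_j. Model coactivation is the analogous trial-count ratio
with "activated" defined as the phase-maximum activation exceeding 0.5;
entries conditioned on a never-activated character are undefined and are
dropped pairwise from the Spearman correlation (off-diagonal entries
only) and the clip-vs-response sign-rank comparison, never imputed.

## The synthetic-data generator

The generator is the package's definition of the study conditions.

**Timeline.** Scenes are generated first. Each scene draws a character
subset from an explicit distribution — with probability p0 the scene is
empty, otherwise an anchor character is drawn and every other character
joins with the pairwise co-occurrence weight — whose implied conditional
probabilities are computed exactly by enumeration: these are the planted
values the association analysis must recover. Subset counts over scenes
are balanced by largest-remainder rounding, and gamma(2) scene durations
are rescaled within each subset group so that screen-time shares match
count shares; this removes duration-weighting noise from the
co-occurrence statistics while leaving individual scene lengths
variable. Scenes are tiled by cuts (gamma(2), mean 4 s, minimum 1 s).
Characters in a scene are visible per cut with probability 0.8, with at
least one visible cut per scene member (so observed scene sets equal
planted subsets); anchors' inclusion probabilities are solved linearly
so empirical prevalence matches the configured target (default 0.10 per
character, at most ~0.20), including an iterated analytic correction for
dialogue alternation. Dialogue cuts (1.2 per minute, giving ~8% of
screen time and hence ~2% DNK labels at 4 characters) alternate a
character pair in ~1-s blocks and emit the corresponding ambiguity
interval. Character size per (cut, character) is Beta(2, 5) scaled to
[0, 0.5] (reference: half the frame).

**Spiking.** Units fire as inhomogeneous Poisson processes on a 100-ms
rate grid: rate = baseline x Π_present gain_c^m(size), with
m(size) = clip(size / 0.15, 0, 2), so the nominal gain applies at a
typical character size and larger on close-ups; an optional latency
shifts the occupancy the unit sees. Within-region correlation is the
slow shared gain described above. Global synchronous bursts can be
injected as artifact fixtures for the detector. Defaults (baseline
2 Hz, gain 3 for a tuned unit, 8 microwires per region) are in the
range of human MTL/neocortical unit recordings; the underlying study
reports no quantitative tuning strengths, so effect sizes are exposed
as parameters and the defaults were fixed once when the experiments
were designed.

**Memory session.** Clips are drawn half from the "watched" timeline
(targets) and half from a disjoint lure timeline, in random order, each
followed by a response window and a gap. Responses follow a
two-parameter confusion model (hit rate 0.8, false-alarm rate 0.2).
For clips the simulated participant marks "seen", MTL-tagged units
re-express a fraction (reinstatement gain, default 0.6) of their tuned
log-gain for the clip's content characters during both clip and
response; an optional associative drive adds, during the response phase
only, gain for characters associated with the clip's content in
proportion to the planted conditionals.

**Embeddings.** Identity centroids are Gaussian with per-coordinate
scale `separation x noise_sd` (default separation 10, which at d = 128
puts inter-identity distances far above the within-identity crop-noise
floor of ~sqrt(2d) x noise_sd). Most clusters sit at small offsets from
their identity centroid; an outlier fraction (default 25%) has
per-coordinate offset scale equal to noise_sd — these model poor
tracking conditions and are what the candidate-absorption stage has to
recover. Same-identity clusters have disjoint frame spans; different
identities overlap, feeding the graph-pruning rule.

**What the generator does not emulate:** refractory periods, bursting
and rate adaptation, cross-region noise correlations, non-stationary
baselines, eye movements and attention, lure similarity structure, and
any pixel-level variability behind the embeddings. Passing tests
therefore show that the analysis code recovers planted structure under
Poisson statistics with the stated correlation model — not that the
biological claims hold.

## Identity clustering (supernode stage)

Cluster features are means of per-crop face embeddings; clusters losing
more than 80% of crops for lack of a face are dropped. k-means with
k = 3 x expected identities partitions the features; super-clusters with
within-cluster mean squared distance to centroid (the distortion metric;
the source method names the metric but not its formula) below a
threshold become supernodes, the rest dissolve into candidates. The
cluster distance from A to B pools, for each crop in A, its K = 5
nearest Euclidean distances to crops of B and takes the median (the
alternative reading — the K smallest per-member nearest distances — is
available as `distance_mode="nearest_k"`). Candidates join the nearest
supernode when that distance is below the assignment radius, iterating
while any supernode's crop count grows by more than 10%; afterwards a
complete centroid graph is pruned by edge weight and by frame-span
overlap (two clusters on screen simultaneously cannot be one person) and
its connected components are the identities. All radii are calibrated
from the data's own distance scale (`default_config`): the median
nearest-neighbour feature distance d_nn sets the distortion gate
(1.2 d_nn)^2 and the pruning radius 6 d_nn, and the median
nearest-cluster *crop* distance sets the assignment radius (x1.5) —
feature distances and crop distances live on very different scales
because feature averaging cancels crop noise.

## Problem sizes and numerical choices

The benchmark experiments (`popdecode.experiments`) fix the study
conditions: decoder recovery uses the full 42-min timeline (18,900
frames) with 40 units, training on a 6,000-window (LSTM) or
8,000-window (CNN) subsample for up to 8 epochs with reduced widths
(hidden 32; CNN channels 8/16, temporal kernels) — at gain 3 the
problem is decodable well before the full configuration would
converge. The 10 shuffled-chance retrainings use the same LSTM
protocol on 3,000-window subsamples (a label-permuted model's F1 does
not depend on training-set size at this scale); the knockout and
synergy experiments use 8-10-minute sessions,
24-48 units and hidden size 16. Probabilities are clipped at 1e-8
before logs; batch-norm epsilon is 1e-5; Adam moments are kept in
float64 while parameters are float32. All generators and training loops
are deterministic given their seeds; every randomised stage derives its
generator from an explicit seed argument.

## Known limitations

* The 15-Hz output rate printed in the source method's text conflicts
  with its 60-step / 2-s window; 30 Hz is the default here, 15 Hz is a
  parameter.
* The cut-aggregation filter implements the length-conditional reading
  of the two (superficially contradictory) published sentences: cuts
  ≤ 1.3 s use the 12-frame rule, longer cuts the 40% rule; both
  thresholds are parameters, and detections are counted on the 30-fps
  grid.
* The synergy statistic's ρ contrast is qualitative (sign and
  significance), not monotone in magnitude — see the discussion above.
* Whether "important region" means median normalized ΔKLD above 0.5 is
  a package convention; only the 0.5 figure threshold is sourced.
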