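# Methods

`eegability` implements an individual-differences EEG analysis pipeline:
given trial-epoched multichannel EEG from a cohort of super-recognizers
and typical recognizers, it (1) decodes group membership and continuous
face-recognition ability from single trials over time, (2) characterizes
each participant's stimulus representation as a time-resolved
representational dissimilarity matrix (RDM) built from cross-validated
pairwise decoding, and (3) localizes, in time, where the representational
match to visual-model, semantic-model and behavioral reference geometries
differs between ability groups, using Gaussian-copula mutual information
and cluster-based permutation inference. A synthetic-cohort generator
with planted, ability-coupled geometries makes every stage verifiable
without recorded data.

## The synthetic forward model

A trial showing stimulus *s* produces, at channel *c* and time *t*,

```
x[c,t] = Σ_k  w_k(t) · ( A_k ( g_k (f_k[s] + e_k) + σ_j η ) )[c]  +  σ_n ε[c,t]
```

per planted geometry *k*:

* **f_k[s]** — per-stimulus score vectors obtained by classical
  (Torgerson) MDS of the geometry's target RDM into ≤ 10 dimensions.
  Geometries are constructed from explicit low-dimensional point
  configurations, so the embedding is exact (residual MDS stress is
  recorded in the cohort metadata and is ~0 by construction).
* **e_k** — a stimulus-independent evoked offset in a dedicated latent
  dimension (default magnitude 1). MDS scores are centered, so without
  this term the two ability groups would have *identical class means*
  and across-participant group decoding would be impossible by
  construction; with it, the evoked response amplitude scales with
  ability, which is the signal the group decoder uses.
* **g_k = 1 + β_k z** — the participant's gain, with *z* their
  standardized ability score (CFMT+-scale, 0–102; super-recognizers drawn
  uniform-integer in [92, 100], typicals in [50, 85], mirroring the
  emulated study's printed ranges without assuming a distribution) and
  β_k the geometry's `ability_coupling` in gain units per ability SD
  (default 0.5 for the two coupled geometries).
* **σ_j η** — per-trial representational jitter in latent space
  (default σ_j = 1), deliberately *not* scaled by g_k: higher-ability
  participants carry a crisper geometry relative to trial-to-trial
  variability. Without this term, zero sensor noise would make every
  stimulus pair perfectly separable (all pairwise AUC = 1) and the RDM
  would be structureless.
* **A_k** — a fixed random spatial pattern (channels × latent dims),
  standard normal entries; the latent scores are rescaled so the
  per-channel signal SD at the profile peak is the geometry's
  `amplitude` (default 1).
* **w_k(t)** — a Gaussian time profile (peak 1) with center and width
  (SD) in ms. Defaults plant a "midlevel visual" geometry at 150 ± 20 ms
  (face/nonface block structure with graded within-block dissimilarity)
  and a "semantic" geometry at 650 ± 50 ms (category-cluster structure),
  the two latencies at which the emulated study located group
  differences.
* **σ_n ε** — i.i.d. Gaussian sensor noise per channel × sample
  (default σ_n = 2, i.e. single-trial SNR ½ at the profile peak), with
  optional moving-average temporal smoothing to emulate autocorrelated
  EEG noise.

Channels sit on a Fibonacci lattice over the unit hemisphere with a
vertex reference ("Cz"); searchlight adjacency is Euclidean k-nearest
neighbours on these coordinates, so no vendor montage file is needed.
Trial schedules emulate a one-back task: each non-initial trial repeats
its predecessor with probability 0.1, responses occur on repeat trials
with a configurable hit rate (default 0.85), and trials split evenly
across two sessions.

What this generator deliberately does *not* emulate: eye blinks and
artifacts, volume-conduction-realistic topographies, 1/f spectra,
session-to-session nonstationarity, or any image-level stimulus
properties. Passing tests therefore demonstrate the correctness and
calibration of the *analysis machinery* under a controlled generative
model, not performance claims about recorded EEG.

## Preprocessing

Rereference to Cz, zero-phase band-pass 0.01–80 Hz, crop to
−200..1,100 ms, polyphase resample to 256 Hz; trial counts are then
matched across participants by uniform subsampling to the minimum count.
Numerical choices:

* The band-pass is a cascade of a 2nd-order Butterworth high-pass and a
  6th-order Butterworth low-pass, each applied forward–backward
  (zero-phase), giving ~94% attenuation of a 100 Hz tone. A high-pass
  whose cutoff period exceeds twice the epoch duration (0.01 Hz on a
  1.3 s epoch) cannot be realized as a stable IIR on that support — the
  filter pole decays over tens of thousands of samples and padding
  transients dominate — so in that regime the high-pass is realized
  exactly as per-epoch DC removal, which is all such a filter can do on
  an epoch.
* Resampling is `scipy.signal.resample_poly` at the exact rational rate.
* Baseline correction is available but off by default.

## Decoding

**Group decoding.** Trials are pooled across participants (all channels
as features, label = the participant's group) and a Fisher linear
discriminant with Ledoit–Wolf-shrunk pooled covariance is evaluated per
time sample under repeated stratified k-fold cross-validation (default
5 × 5), per session, with AUC averaged over folds, repetitions and
sessions. Folds stratify over trials within participant by default (every
participant contributes to train and test, matching a trial-by-trial
prediction reading); a participant-grouped fold option is provided
because trial-level folding lets a classifier exploit participant
identity. The shrinkage intensity is estimated from the *label-free*
(grand-centered) training data of each fold, which keeps the statistic
exchangeable under label permutations and the permutation p-values
exact. The implementation evaluates the observed labeling and all
permuted labelings through one batched sufficient-statistics path
(pooled scatter = total scatter minus rank-one class-mean terms), so a
1,000-permutation null costs barely more than the observed analysis.
Cross-decoding trains on one stimulus condition (face/nonface) and tests
on the other; the shared fold structure guarantees no trial is reused.

**Searchlight.** Each channel's feature set is itself plus its 4 nearest
neighbours (default size 5) over all samples of the analysis window
(whole epoch, or 60 ms windows centered on 135/350/560/775 ms); every
channel uses the identical fold structure so maps are comparable and a
whole-scalp searchlight reproduces the whole-scalp value exactly.

**Ability decoding.** On typical recognizers only: per time sample,
fractional ridge regression (channels → ability score) is fit on a
random 60% of trials; among 20 norm-fractions linear in [0.001, 0.99]
the one with the best validation-set (30%) coefficient of determination
is selected and evaluated on the held-out 10%. Test-trial predictions are
averaged within participant and the across-participant Spearman
correlation is reported (the trial-level correlation is an option),
averaged over 10 repetitions with fresh splits and over sessions. The
fractional ridge solver works on the SVD of the centered design: for
each requested fraction γ of the OLS coefficient norm, the matching
penalty is located by bisection in log-penalty space (the norm–penalty
map is strictly decreasing), achieving the requested norm ratio to well
under 1%; γ = 1 reproduces the minimum-norm least-squares solution.

**Permutation inference.** Group labels are permuted at the participant
level (group sizes preserved); ability scores are shuffled across
participants. p = (1 + #{null ≥ observed}) / (n_perm + 1), so p is never
zero. Library default 1,000 permutations.

## RDMs

Brain RDMs: for every stimulus pair and time sample, the cross-validated
AUC of a pairwise shrinkage-LDA (channels as features) fills the cell;
5-fold × 5-repetition CV by default; sessions averaged at the matrix
level. The cv_auc diagonal is stored as NaN, never 0, so it cannot be
mistaken for a distance. A stimulus with fewer than 2·n_folds trials in
a session leaves its cells missing for that session (warned); missing
cells propagate through vectorization and are pairwise-deleted jointly
in downstream MI. Model RDMs: Pearson correlation distance over unit
activations (layer RDMs averageable within pooling blocks), cosine
distance between sentence embeddings (per-rater RDMs averaged), and
behavioral rater RDMs averaged after excluding raters whose vectorized
RDM lies more than 2 SDs above the mean distance-to-mean.

Pairwise-decoding AUC ranks — not magnitudes — carry the geometry;
ties in discriminant scores are resolved by average ranks (the fast
ordinal path is used only when scores are tie-free).

## Representational similarity statistics

Gaussian-copula MI: each vector is rank-transformed (average ranks for
ties), mapped through the standard normal quantile function, and
MI = −½·log₂(1 − r²) computed from the copula correlation; CMI uses the
partial correlation given the conditioning RDM. The estimator's small
positive bias is left uncorrected by default because the group contrasts
subtract it out; an analytic digamma-based correction is available.
Perfect dependence is capped just inside |r| = 1 with a warning.

Group contrasts: pointwise pooled-variance independent-samples t
statistics; clusters are maximal contiguous same-sign runs with
|t| > 1.96; the cluster statistic is run length; the null is the maximum
cluster size over both signs under random reassignment of participants
to groups; cluster p-values use the "+1" convention and significance is
p < α (default 0.05). No smoothing is applied to MI time courses.

## Problem sizes used in the test suite

All statistical validation runs at desk scale, chosen once as part of
the study design:

* **Null calibration**: 200 simulated null cohorts (8+8 participants,
  identical score distributions, no ability coupling; 16 channels,
  64 Hz, 150 trials over a 0–500 ms epoch), analysed with 2-fold CV,
  1 repetition and 199 permutations (199 makes α·(n+1) an integer, so
  the rejection rule p ≤ 0.05 has exact level 0.05 under the null).
  Pointwise rejection is checked against 0.05 within 3 binomial SDs and
  cluster familywise error against the 0.075 bound.
* **Planted-effect recovery**: 20 stimuli (10 faces + 10 nonfaces),
  8+8 participants, 480 trials each, 16 channels, 64 Hz, one session;
  couplings 0.5 at 150 ± 20 ms and 650 ± 50 ms and an uncoupled control
  geometry at 350 ms; ability decoding uses a separate 12-participant
  typical cohort with 200 trials each.
* Full paper-scale simulation (33 participants × 3,200 trials × 128
  channels) is supported in metadata-only mode for design bookkeeping;
  synthesizing the full signal tensor at that scale needs ~20 GB and is
  not exercised by the tests.

## Known limitations

* With few RDM cells, pairwise-decoding estimation noise is correlated
  across cells sharing a stimulus, and this correlation scales with a
  group's SNR; a group contrast can therefore couple weakly into an
  *unrelated* model RDM. With 190+ cells the effect is negligible in
  our studies, but analyses of small stimulus sets should treat
  CMI group contrasts with caution. (This is a property of
  pairwise-decoding RDMs generally, not of this implementation.)
* The copula-MI estimator is biased upward at small n; contrasts cancel
  the bias only insofar as both groups share n and dependence structure.
* Ordinal AUC ranks assume continuous scores; exact ties trigger the
  slower average-rank path.
* The cluster test controls familywise error under exchangeability of
  participants between groups; group-dependent variance (not mean)
  differences can also produce clusters, which is a property of the
  procedure itself.
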