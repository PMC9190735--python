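# Methods

This note documents the models, estimators and numerical choices behind
`chronodecode`, and what the synthetic-data generator does and does not
emulate.

## Synthetic epoch model

The generator stands in for recorded EEG. A session is defined by a
`DesignSpec` whose defaults are the emulated study conditions: 48 objects
crossed with 3 orthogonal binary category dimensions (24 objects per
level), 8 auditory and 6 visual runs, 5 presentations per stimulus per
run plus 20 % one-back repeat trials (300 trials per run, hence 40
auditory and 30 visual presentations per stimulus), epochs of −200 to
+800 ms sampled at 1000 Hz, analysed at 200 Hz, on 63 channels.

A trial of object *o* in modality *m* is generated as

    x(t) = snr · Q_m [ e_obj(t) · p_o + e_cat(t) · Σ_d p_{d, level_d(o)} ] + ε(t)

with:

- **Patterns** `p_o` (one per object) and `p_{d,l}` (one per dimension ×
  level), drawn once per participant as random unit-norm channel vectors,
  optionally rescaled by `object_strength` / `category_strength`.
- **Envelopes** `e(t)`: zero before the component's onset, a linear ramp
  of 20 ms (default), then either a sustained plateau (`sustain_level=1`,
  the default) or an exponential decay (time constant `decay_ms`) to a
  sustain level < 1, emulating transient evoked responses. The ramp avoids
  the ringing a hard step would cause under filtering; the decaying
  variant exists because peak-latency analyses need time courses with a
  unique, signal-determined maximum — a saturated plateau has no
  well-defined peak and its argmax would be set by noise.
- **Modality codes** `Q_m`: identity for all modalities when a shared
  cross-modal code is requested. Otherwise `Q_m = U_m V_mᵀ`, where the
  `U_m` span disjoint blocks of one random orthogonal channel basis and
  the `V_m` are independent random frames. The disjoint blocks make the
  two modalities' signal subspaces exactly orthogonal; the independent
  frames additionally decorrelate the planted pattern *identities* across
  modalities. Both parts are needed: with plain random rotations the
  residual pattern overlap is Θ(1/√C) and cross-decoding sits detectably
  above chance, while with a shared pattern vector merely projected into
  orthogonal subspaces, whitening-based pipelines measurably recouple the
  two images (the whitening metric does not preserve Euclidean
  orthogonality) and cross-decoding lands systematically *below* chance.
  With independent frames, measured cross-modal accuracy is 50 % to
  within sampling error, matching the null the generator is meant to
  emulate.
- **Noise** ε: Gaussian, white over time, with channel covariance
  `noise_cov` (default: unit-variance Toeplitz with correlation
  exp(−Δ/5) between channels Δ apart, mimicking the spatial correlation
  of scalp sensors).

One-back repeat trials carry the same signal as their source trial and
are excluded before any analysis stage (before artifact rejection).

What the generator does **not** emulate: inter-trial structure (ITIs,
fixation frames, stimulus durations — no analysis stage consumes them),
1/f spectra and temporally correlated noise, eye/muscle artifact
physiology, volume conduction from realistic head models, and
between-participant variation in onsets or SNR (patterns vary per
participant; onsets and gains are shared). Passing tests therefore
demonstrate the *pipeline's* correctness and calibration, not that real
EEG satisfies the model.

## Trial sequences

Per run, the unflagged presentations (each object exactly
`reps_per_stim_per_run` times) are shuffled under a no-immediate-repeat
constraint (repair-based: conflicting positions are swapped to random
compatible positions, with reshuffle-and-retry as fallback). One-back
repeats are then inserted after randomly chosen distinct base trials —
each base trial hosts at most one repeat, which structurally forbids two
consecutive flagged trials — until repeats make up `oneback_fraction` of
the run.

## Artifact rejection

The criterion mirrors a jump-artifact detector: per trial and channel,
the absolute deviation from the across-trial mean is summed over the
epoch; these scores are z-scored per channel across trials; a trial is
removed when its maximum over channels exceeds the threshold (default
20). Two consequences worth knowing: a *single* outlier trial's z-score
cannot exceed √n_trials (the outlier inflates the very standard deviation
it is measured against), so the threshold of 20 only bites in
session-scale data (hundreds of trials); and constant channels are
excluded from triggering (their deviation variance is zero). A warning is
emitted when more than 10 % of trials are removed; removing all trials is
an error.

## Downsampling

Integer-factor decimation with polyphase FIR anti-alias filtering
(`scipy.signal.resample_poly`, linear-edge padding so constant signals
are preserved exactly). Zero-phase filtering is acausal by nature: a
sharp onset is smeared backwards by roughly half the filter length.
Onset-recovery studies therefore generate epochs directly on the 200 Hz
analysis axis (`simulate_at_analysis_rate`); the 1000 Hz + decimation
path exists and is tested for its signal-processing properties, but any
±1-sample onset claim through an acausal filter would be meaningless.

## Super-trials

Conditions' exemplars are randomly partitioned into `n_groups = 3`
near-equal groups and averaged; when counts are not divisible the
remainders land in random groups. Provenance (which trials/objects formed
each super-trial) is retained, and in the category scheme guarantees that
no object contributes to more than one super-trial, so downstream folds
never train and test on the same object. The per-level partition RNG is
keyed by the member set rather than the level label, making the scheme
exactly invariant under relabeling a dimension's two levels.

A practical caveat established during validation: cross-set evaluation
(training on one modality's super-trials, testing on the other's) is
biased below chance when the partition produces *unequal* group sizes
(e.g. 4 objects per level → groups of 2, 1, 1), because the super-trials
are then heteroscedastic. The emulated full design (24 objects per level
→ 8, 8, 8) is free of this; desk-scale cross-modal checks use object
counts whose level size divides by 3.

## Multivariate noise normalization

Within-condition residuals (trial minus condition mean) are formed per
timepoint; their channel covariance is estimated with Ledoit–Wolf
analytic shrinkage toward a scaled identity (`assume_centered`), averaged
over timepoints, and inverted through its eigendecomposition to the
symmetric inverse square root. The normalizer is fit on single trials
(more samples → stabler covariance) and applied to super-trials; a
`normalized` flag guards against double application. Zero-variance
channels are an error. Shrinkage makes the estimate well-conditioned even
with few trials at the cost of exact scale equivariance (rescaling one
channel changes the shrinkage target), which is why equivariance holds
only up to a shrinkage-sized tolerance.

## Classification

The classifier contract is a linear maximum-margin decision rule with
cost C = 1 on single-timepoint channel patterns, no feature scaling
beyond noise normalization. Because time-resolved pairwise decoding
solves millions of tiny, identically shaped problems, the engine is a
batched solver: the SVM dual is optimized for an entire batch
simultaneously by vectorized SMO-style pair updates (sweeps over all
index pairs with exact analytic two-variable updates, stopping when every
problem's KKT gap is below 1e−8). The intercept is the mean KKT residual
over free support vectors, falling back to the margin midpoint. On random
tiny problems the predictions agree with libsvm (whose own stopping
tolerance is 1e−3); the test suite also checks fold-level accuracies
against an independent geometric hard-margin oracle on 2-channel
problems. Classification runs at every sample of the 200 Hz axis (5 ms
steps).

Scheme details:

- *Object level*: all object pairs; 3-fold leave-one-super-trial-out;
  default 100 repetitions with fresh partitions; accuracies averaged over
  pairs, folds, repetitions.
- *Category level*: per dimension, the two levels form one pair (3
  super-trials each, built from object averages); the reported time
  course averages the three dimensions.
- *Leave-one-object-out category variant*: train on all object averages
  but one, labeled by level; test on the held-out average; average over
  held-out objects. Deterministic (no random partition). Known property:
  holding out an object leaves its class one exemplar short, and with
  strong idiosyncratic object patterns this imbalance biases the
  intercept toward the majority class, pushing null-data accuracy *below*
  chance — the scheme is conservative, never anticonservative, under the
  null. At the full design's 48 objects the bias is small.
- *Cross-modal / temporal generalization*: train on all super-trials of
  one modality, test on all of the other, both directions averaged;
  category-level super-trials by default (configurable to object-level).
  Temporal generalization fits one classifier per training timepoint and
  evaluates it at every test timepoint; its diagonal equals the
  cross-modal time course at the same seed by construction.

## Group inference

*Cluster test.* Accuracies are centered on the 50 % chance level. The
pointwise group statistic is the mean (a one-sample t is available; under
the sign-flip null both are valid, the mean is the default for its
robustness at small P). The null is built from `n_permutations` sign
assignments with the identity assignment always included as permutation
0, so p-values are bounded below by 1/n_permutations and match exhaustive
enumeration exactly when the flips are exhaustive. Cluster forming uses
the per-timepoint (1−α) null quantile (strict exceedance); candidate
clusters are scored by *size* (count of contiguous supra-threshold
samples) against the null distribution of the maximum cluster size; both
the forming and the cluster-level threshold are one-sided α = 0.05.
Note the resolution constraint: with P participants only 2^P distinct
assignments exist, so P ≥ 6 is needed before p < 0.05 is attainable at
all.

*Peak-latency bootstrap.* Participants are resampled with replacement
(the same resample applied to both conditions), group-mean curves are
formed, and the latency of each maximum recorded (ties broken to the
earliest timepoint; flat curves are flagged, not rejected). The one-
tailed p for "A later than B" is the fraction of bootstrap differences
strictly greater than zero; identical inputs therefore give p = 0 and are
flagged as degenerate.

*Null calibration.* The false-positive simulator draws AR(1) time courses
(coefficient 0.8, SD 2.5 points) around chance, mimicking the temporal
smoothness of real accuracy curves; family-wise error of the cluster test
on 200 such datasets stays at or below the nominal 0.05.

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → decode → infer per the
`RunConfig`, whose defaults carry the analysis constants (C = 1, 3
super-trials, 100 repetitions, 10,000 permutations, 1,000 bootstraps,
α = 0.05, chance 50 %). All stage randomness derives from the single
config seed through one generator consumed in a fixed serial order, so a
rerun with the same config is byte-identical; the manifest echoes the
config, seed, package version and stage timings. Output directories are
never silently overwritten. Stages run serially; per-stage seeds are
pre-drawn, so a parallel implementation would reproduce the same numbers.

Result tables are TSV (accuracies wide by timepoint; generalization
matrices long-format), epochs serialize to HDF5 (one group per
participant), and configs are YAML.

## Problem sizes used in validation

Desk-scale validation uses 8–24 objects, 12–24 channels, 100–200 Hz axes,
1–2 runs per modality, 2–10 super-trial repetitions, and 5–20 simulated
participants; inference checks use 1,000–10,000 permutations and 1,000
bootstrap samples. These sizes were chosen so the full validation suite
re-simulates everything from scratch in about a minute while keeping
every statistical check adequately powered; the defaults in `DesignSpec`
and `RunConfig` remain the full study conditions.

## Known limitations

- The noise model is Gaussian and white over time; temporally correlated
  or heavy-tailed noise would mainly affect the artifact-rejection
  calibration and the independence assumptions of the super-trial
  averages, not the inferential logic.
- Onset recovery to ±1 sample presumes no acausal filtering between
  signal generation and decoding (see Downsampling).
- The leave-one-object-out scheme's conservative bias (above) means its
  null distribution is not centered on 50 %; compare conditions within
  the scheme rather than against the nominal chance level.
- Decoding accuracies from schemes with different averaging depths
  (object vs category) are not directly comparable in absolute terms.
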