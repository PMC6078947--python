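# Methods

This note documents the models implemented in `compdrop`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not establish.

## Analysis model

### Localizer decoding

Features at window start *t* are per-channel means over the half-open
interval [*t*, *t* + 50 ms), start times on a 20 ms grid from stimulus
onset (both window length and step are parameters). The decoder is binary
L2-penalized logistic regression (scikit-learn, liblinear solver).

- **Regularization** C = 1.0 by default, config-exposed. Features are used
  on their native scale (no standardization by default): window means of a
  common-referenced voltage recording share one physical scale, so
  per-feature rescaling would only reweight channels by noise level. A
  `standardize` switch exists.
- **Cross-validation**: stratified k-fold (default 5), shuffled under an
  explicit seed, so fold assignment is independent of trial order. A fold
  that would lose a class is impossible by stratification; the minority
  class smaller than the fold count raises an error.
- **Within-subject significance**: a permutation test (default 100 label
  shuffles, each re-running the full CV) with the add-one estimator
  p = (1 + #{perm ≥ observed}) / (n_perm + 1), which keeps p in (0, 1].
- **Group combination**: p values are clipped to
  [1/(n_perm+1), 1 − 1/(n_perm+1)] — the attainable permutation grid — so
  the inverse-normal z = Φ⁻¹(1 − p) stays finite, then a one-sample
  one-sided t-test of z against 0 per timepoint, Bonferroni-corrected at
  α/T (α = 0.001). With all-identical z values the t statistic is 0/0; the
  implementation resolves that case by the sign of the mean.
- **Window selection**: a start time qualifies if group-significant *and*
  more than `sd_mult` (default 1.0) across-subject SDs above chance.
  Qualifying runs separated by gaps shorter than `bridge_ms` (default
  120 ms) are merged — the bridging rule formalizes keeping a brief
  mid-window accuracy dip inside the window rather than splitting it. The
  longest merged run wins; ties go to the earlier run.

### Patterns

The weight RDM is the cosine distance 1 − cos(wᵢ, wⱼ) between decoder
weight vectors at each pair of timepoints. The Haufe transform converts
weights to activation patterns, a = Σ_X w, with Σ_X the empirical
(maximum-likelihood, ddof = 0) covariance of the training features at that
timepoint; shrinkage is unnecessary here because patterns are only read up
to scale. Patterns are normalized to unit norm before averaging across
subjects and timepoints so high-variance subjects cannot dominate the
mean; the averaged pattern is therefore defined up to positive scale, and
recovery is assessed by |correlation| with the planted topography.

### Transfer and drop

Per selected train time, one decoder is fit on *all* localizer trials (no
held-out split) and applied at every test-session window start. The raw
logistic output is read as the competition probability; values are clipped
to [1e−6, 1 − 1e−6] for downstream arithmetic. No cross-session
recalibration is applied. Study-block trials run through the identical
path for the recall-specificity control.

The drop for an item at a grid square is P(first correct round) −
P(round 4). Items never correct or incorrect in round 4 are excluded
(counts logged). The RT-drop control uses the same retention rule, with
"last round" taken as round 4 for symmetry with the competition drop.
Within-subject z-scoring uses the n−1 SD denominator; subjects with fewer
than two retained items or zero variance are excluded.

### Cluster inference

Per square, a pooled (fixed-effects) two-sample Student t-test — pooled
variance by default, Welch behind a flag — compares remembered vs
forgotten drops, items pooled over subjects. The right tail (drop larger
for remembered) carries the directional hypothesis; the left tail is
reported descriptively. The right-tail p grid is thresholded at 0.10;
clusters are connected components under 4-connectivity (diagonal adjacency
does not connect) and cluster size is the number of member squares (no
t-mass option). Labels are permuted over the pooled item set with class
counts preserved (a within-subject-stratified variant exists behind a
flag); each permutation's maximum cluster size forms the null, and the
family-wise p per observed cluster uses the add-one estimator. The null
uses the same right-tail mask as the observed test, since the hypothesis
is directional. Permutation t grids are computed from sufficient
statistics vectorized over permutations; the observed grid is verified
against `scipy.stats.ttest_ind` in the tests. The Kolmogorov–Smirnov
normality check (against a normal with estimated moments) is reported as a
diagnostic, never as a gate. The subject bootstrap resamples participants
with replacement, re-runs the entire cluster analysis per draw, and
reports the per-square inclusion frequency in family-wise significant
clusters; single-class draws are skipped with the denominator adjusted.

### Behavior

Response configurations are 4-bit vectors (bit *i* = correct in round
*i*). The configuration classifier is the same L2 logistic regression with
stratified 5-fold CV on items pooled over subjects (the fold count is a
parameter; a grouped, subjects-held-out variant exists behind a flag), and
the permutation test shuffles delayed-recall labels before each CV re-run.
Round summaries use the mean-of-subject-means convention with SEM over
subject means, so subjects with unequal item counts contribute equally.

## Preprocessing

The voltage chain band-passes 2–200 Hz (zero-phase Hamming-window FIR,
length 3.3/band_lo seconds, applied forward–backward) with a 60 Hz notch
(second-order IIR, Q = 30, forward–backward; > 20 dB attenuation at the
notch), re-references to the whole-scalp average, epochs on stimulus
onsets, and subtracts the per-epoch baseline mean (default window
−100..0 ms; the baseline window and filter family are config-exposed
because no single convention is canonical). The theta chain band-passes
4–8 Hz (4th-order Butterworth, zero-phase) and takes the Hilbert
analytic-signal envelope with *power* = squared magnitude by default
(switchable to magnitude), with no baseline correction. Artifact handling
for recorded data is limited to an optional peak-to-peak epoch-rejection
hook; ICA-based blink removal is out of scope and synthetic data are
blink-free.

## Synthetic data model

Session 1 plants a class-mean difference of
`effect_size · topography ⊗ envelope`: a fixed unit-norm dipolar channel
loading times a temporal envelope supported exactly on `signal_window`.
The envelope is a Tukey window (30% taper): a component that rises
smoothly from zero at the window edges and sustains full amplitude over
the interior. A sustained (rather than peaked) component was chosen so
that the planted window is discriminative throughout — with a peaked
envelope the effective signal region is much narrower than the nominal
window, which makes window-recovery checks test the envelope shape rather
than the pipeline. Noise is Gaussian with channel covariance
exp(−|i−j|/λ) (λ = 5 channel indices; any positive-definite matrix may be
supplied) and stationary AR(1) temporal autocorrelation (coefficient 0.95
per sample at 512 Hz; configurations at other sampling rates should scale
the coefficient to preserve the time constant, as the reduced validation
design does with 0.95⁴ at 128 Hz). With unit noise SD, `effect_size` is
the peak signal amplitude in noise-SD units.

Session 2 items carry latent competition trajectories: c₁ ~ U(0.60, 0.95),
then per-round decrements drawn around an item-level mean (0.12 ± 0.08
across items, ± 0.05 across rounds, clipped at 0), giving
monotone-in-expectation decline with across-item variance in the total
drop — the quantity the analysis needs to vary. Retrieval epochs scale the
planted pattern by (c − 0.5), so latent 1 matches the high-competition
localizer mean and latent 0 the low-competition mean; study epochs use the
item's round-1 level in every round, so the study control carries no
round-dependent signal by construction.

Correctness follows a non-decreasing learning curve (defaults 0.30, 0.55,
0.75, 0.85) with a per-item ability random effect (SD 1.0 on the log-odds
scale), which reproduces the empirical regularity that items, once
recalled, tend to stay recalled. Delayed recall is Bernoulli with
log-odds α + β(drop − E[drop]) + γ(n_correct − E[n_correct]), where α sets
the marginal rate (default 0.5, so remembered/forgotten classes are
balanced), β = `drop_memory_coupling` (default 4) is the planted
neural-drop coupling, and γ = `accuracy_memory_coupling` (default 0.8) is
a behavioral coupling added so that response configurations carry
predictive signal, as they do empirically. Setting γ = 0 recovers the pure
drop link; all null-calibration and RT-control studies use γ = 0 because a
nonzero γ induces an indirect association between recall and any quantity
defined relative to the first-correct round (including the RT drop).
Reaction times are 2 s (the enforced response delay) plus a log-normal
with item SD 0.50, round slope −0.05 per round and residual SD 0.15 on the
log scale — item variance dominating the round trend — generated
independently of the delayed-recall outcome.

Determinism: every subject/session draws from a `SeedSequence` keyed by
(config seed, stream, subject), so identical configs give bit-identical
datasets and Session 2 does not depend on whether Session 1 was generated.

**What the synthetic model omits:** volume-conducted sources with a
realistic forward model, eye-blink/EMG artifacts, non-stationary noise,
oscillatory (e.g. theta-band-specific) signals, inter-subject topography
variability, and item difficulty effects correlated with competition.
Passing recovery tests therefore shows the *pipeline* is correct and
calibrated under its assumed data model, not that real EEG satisfies those
assumptions.

## Validation studies (`compdrop.validation`)

Replicate studies use a reduced design — 8–10 subjects, 16 channels,
128 Hz, −100..700 ms epochs, 5 categories × 4 exemplars, 30–40 items, a
40 ms feature step, 200 cluster permutations — chosen to preserve the
statistical structure of the full analysis while keeping hundreds of
replicates cheap. The transfer/drop/cluster path trains on the planted
window directly; the localizer permutation pipeline is validated in its
own study (6 subjects, 33 permutations per timepoint).

- **Null calibration** (β = γ = 0): the family-wise significant-cluster
  rate and the behavioral permutation test's rejection rate at α = 0.05
  sit at the nominal level within binomial error.
- **Planted effect** (effect 3.0, β = 12, 10 subjects × 40 items): a
  family-wise significant cluster overlapping the planted window appears
  in ≳ 90% of replicates; the study-trial control and the RT-drop
  predictor stay null.
- **Pattern recovery**: the subject- and time-averaged Haufe pattern
  correlates |r| > 0.9 with the planted topography at high SNR.

One structural observation worth recording: because an item's drop score
is constant across grid squares up to measurement noise, the planted drop
variance acts as a grid-block-correlated component of the permutation
null. Very high SNR therefore does *not* monotonically increase cluster
power — it inflates the null's maximum-cluster tail as fast as the
observed cluster. Power comes from many items (per-square t grows as √n)
with moderate per-square SNR, which is also the regime of the real
analysis.

## Numerical conventions

Window membership uses half-open intervals on the sample-time grid.
Permutation and bootstrap p values use the add-one estimator and are never
zero. Probabilities are clipped to [1e−6, 1 − 1e−6]. Degenerate cases are
explicit: zero-variance t statistics resolve to 0, all-equal z values
resolve by sign, single-class bootstrap draws are skipped and counted, and
subjects that cannot be z-scored are excluded and logged. All randomness
flows through named integer seeds.

## Known limitations

- The pooled grid t-test is fixed-effects, as in the original procedure;
  its per-square p values are liberal and only the cluster-level inference
  is calibrated. The within-subject z-scoring option removes
  between-subject variance but not item-level confounding.
- The KS normality check uses estimated moments (a Lilliefors-type
  situation), so its p values are approximate; it is reported as a
  diagnostic only.
- Real-data ingestion expects continuous arrays plus onset samples; vendor
  formats (e.g. BDF) and ICA artifact removal are out of scope.
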