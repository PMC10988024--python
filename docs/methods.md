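# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices and the known limitations of `neuralign`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Analysis model

### Multiset CCA as spatial filtering

Each subject i contributes a standardized channels × samples matrix Xᵢ
(C channels, T samples). A spatial filter wᵢ ∈ ℝᶜ maps the sensor array to
one component series yᵢ = wᵢᵀXᵢ. Multiset CCA chooses (w₁, …, w_M) to make
the yᵢ maximally correlated across the M subjects of a group.

With within-subject covariances Cᵢᵢ = (1/T)XᵢXᵢᵀ and cross-covariances
Cᵢⱼ = (1/T)XᵢXⱼᵀ, the stacked filter v = (w₁, …, w_M) solves

    R v = λ D v,

where R ∈ ℝ^{MC×MC} holds all blocks Cᵢⱼ and D = blockdiag(C̃₁₁, …, C̃_MM)
holds the ridge-regularized within blocks C̃ᵢᵢ = Cᵢᵢ + γ·tr(Cᵢᵢ)/C·I.
After renormalizing each wᵢ to unit component variance (wᵢᵀC̃ᵢᵢwᵢ = 1),
eigenvalues are recomputed as Rayleigh quotients, which makes

    ρ̄ = (λ − 1)/(M − 1)

exactly the mean pairwise train correlation at γ = 0. For M = 2 the
eigenproblem is classical CCA and ρ̄ its first canonical correlation (the
test suite verifies this against an independent whitened-SVD CCA).

The eigenproblem maximizes the sum of pairwise *covariances* under a summed
variance constraint. That relaxation can land measurably below the maximizer
of the sum of pairwise *correlations* (per-subject unit variance, SUMCOR) —
the acceptance study measures the gap against a black-box numerical
maximizer. The fit therefore refines the leading component by Horst's
fixed-point iteration (wᵢ ← C̃ᵢᵢ⁻¹ Σ_{j≠i} Cᵢⱼwⱼ, renormalized; monotone in
the objective) from the eigenvector initialization, which reaches the
brute-force optimum to machine precision on the studied instances. Higher
components are reported from the eigenproblem as usual: an unconstrained
SUMCOR iteration has a single attractor, so refinement is only meaningful
for the top component, and only the top component is used downstream.

Conditioning: band-limited data make channels ≫ effective rank, so D is
near-singular at γ = 0. Default γ = 0.05 (as a fraction of the mean
eigenvalue of each within block). An alternative route — per-subject PCA
retaining a given variance fraction (`pca_var`, e.g. 0.99) before solving —
is exposed as well; with full-rank data and `pca_var=1.0` the two routes
agree. At γ = 0 on full-rank data the fit is invariant to any invertible
channel-space transform per subject (property-tested); the ridge breaks this
invariance mildly, as any regularizer must.

Sign convention: eigenvector signs are arbitrary per subject, so each
subject's filter is flipped to correlate positively with the across-subject
mean series, then a global flip makes the largest-magnitude entry of
subject 0's filter positive. This makes fits bit-reproducible.

### Activation patterns

A spatial filter is a backward model; its channel weights are not
interpretable as a topography. The interpretable object is the activation
pattern aᵢ = Cᵢᵢwᵢ (normalized to unit norm), the covariance-mapped forward
model of the component; this is the vector one would feed to an anatomical
source localizer. Source localization itself (head models, inverse
operators, template anatomy) is out of scope here; recovery of aᵢ is instead
validated against the planted mixing vectors of the generator.

A caveat the recovery studies respect: per-channel standardization rescales
the sensor space, so the planted mixing direction is only preserved when
channel noise is homoscedastic. Pattern-recovery studies therefore
mean-center but do not variance-scale their channels; with heteroscedastic
real data the pattern estimates the mixing vector *of the standardized
space*, which is the space actually analyzed.

### Cross-validated ISC

Each timeslot's data are split into `n_folds = 3` contiguous temporal folds
(never shuffled samples — shuffling would leak autocorrelated signal between
train and test). Per fold: fit MCCA on the other folds, project the held-out
fold, standardize each projected series, and compute per-component test ISC
as the mean of the M(M−1)/2 pairwise Pearson correlations. The component
with the highest mean test ISC is selected; selection on test ISC rather
than train ISC keeps the reported group ISC honest against overfitting
(train ISC is also reported; on pure noise it exceeds test ISC, which is
property-tested).

Individual ISC for subject i is the mean over folds of the mean pairwise
correlation involving i; with that definition the subject-mean of individual
ISCs equals the group ISC as an arithmetic identity (asserted at 1e−10). The
one-vs-rest variant — corr(yᵢ, mean of the others' series) — is computed as
well and reported under a separate name (`individual_isc_one_vs_rest`),
never silently substituted.

Degenerate held-out projections (zero variance, e.g. a filter orthogonal to
the held-out subspace) are marked missing, excluded from the means and
logged rather than propagated as NaN.

### Circular-bootstrap significance

The null hypothesis is "no cross-subject alignment, autocorrelation intact".
Each null sample rotates every subject's component series by an independent
uniform nonzero offset and recomputes the pairwise ISC;
p = (1 + #{null ≥ observed})/(B + 1), which is never exactly zero
(B = 1000 by default in the pipeline). Rotation preserves each series' mean,
variance and circular autocorrelation exactly, so the null destroys only the
alignment.

By default the shifts act on the held-out component series with filters held
fixed; a `--refit-null` mode that rotates the sensor data and re-fits MCCA
inside every replicate is implemented for users who want the null to absorb
selection optimism, at roughly B × the fitting cost. Because the default
test statistic is the cross-validated (held-out, test-selected) ISC, its
optimism is already controlled by the fold design; the calibration study in
the acceptance suite measures the default test's empirical size on null data
(12 independent band-limited series, T = 3000, B = 200, 500 datasets) and
requires it to sit in [0.03, 0.07] at nominal α = 0.05.

A stationarity pitfall worth recording: zero-phase filtering of a finite
sequence leaves an inflated-variance transient at both edges. If every
series carries the same edge profile, their correlations acquire extra
variance that rotation cannot reproduce, and the test becomes seriously
anticonservative. The generator therefore filters padded sequences and keeps
only the stationary interior; a pipeline applied to externally filtered data
inherits whatever edge handling that data had.

### Group-level inference

Subject-level ISC trajectories (subjects × 3 timeslots) enter a two-way
mixed (split-plot) ANOVA: between factor group, within factor time. The
implementation partitions sums of squares explicitly — group, subjects
within groups (between-stratum error), time, group × time, time × subjects
(within-stratum error) — so the decomposition identity
SS_total = ΣSS is verifiable (asserted at 1e−8 on random unbalanced
instances; F values cross-checked against pingouin). With one between factor
and weighted (group-size) cell means the design needs no Type-III machinery.
Degrees of freedom for g groups, t times, N subjects:
group (g−1, N−g), time (t−1, (N−g)(t−1)), interaction ((g−1)(t−1),
(N−g)(t−1)) — i.e. (4, 234) for 120 subjects in 3 groups over 3 timeslots.
No sphericity correction is applied by default (t = 3 within-levels;
uncorrected dfs are what the design reports); per-group follow-ups use the
analogous one-way repeated-measures ANOVA.

Brain–behavior analysis correlates individual end-slot ISCs (primary band)
with the nine questionnaire T2−T1 changes (negativity, threat, feeling
thermometer, dehumanization, warmth, competence, support for measures,
positive affect, negative affect), Pearson, pairwise-complete, with
Benjamini–Hochberg FDR over the nine-measure family (family size
configurable). Zero-variance or n < 3 measures are reported missing rather
than dropped silently. The agreement end − beginning change is correlated
with the same family.

## Preprocessing

Order of operations: band-pass on the continuous recording → pause removal →
timeslot split → per-channel standardization. Filtering precedes
concatenation because filtering across splice points would ring at every
statement boundary.

* Band-pass: order-4 Butterworth, zero-phase (forward–backward `sosfiltfilt`),
  reflect padding of at least 3 periods of the band's low edge. The squared
  response attenuates one octave outside the band by far more than 20 dB
  while in-band sinusoid amplitude is preserved within 5% (both tested).
  Bands: delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–12 Hz.
* Pause removal keeps only statement segments, concatenated in order, and
  rewrites the event table onto the new sample grid.
* Timeslot split: `n_slots = 3` contiguous slots of ⌊T/n⌋ samples, remainder
  truncated from the end; boundaries are a function of the sample count
  only, hence identical across subjects of a group.
* Standardization: per-channel zero mean, unit population variance
  (divisor T). Constant channels cannot be standardized; they are dropped
  with a warning and a log entry.

Statements are assigned to timeslots by the slot containing the midpoint of
their audio segment on the pause-free grid, so behavioral and neural slot
definitions cannot drift apart.

## Synthetic-data generator

The generator is the package's study-design stand-in for non-shareable
recordings. It emulates: three groups (default 39/40/41 subjects — the
cohort sizes of the design it mirrors), 22 statements of 11–18 s with 3 s
pauses (~9-minute paradigm), 64 channels at 150 Hz (the analysis is
dimension-agnostic; defaults keep runtimes sensible and both are
configurable), and per-statement agreement ratings on the 1–3 scale plus the
questionnaire inventory (negativity 7 items 1–7 with reverse-keyed items,
threat 4 × 1–7, feeling thermometer 1–10, dehumanization 1–10, warmth and
competence 4 × 1–5, support for measures 3 × 1–7, eight emotion items 1–7
composited into positive and negative affect).

Latent model — deliberately the *minimal* structure under which the MCCA
objective is well-posed: per group and timeslot a single rank-1 shared
band-limited source (0.5–4 Hz by default), subject-specific unit-norm
random mixing vectors, a per-subject coupling scalar drawn uniformly from
[0.2, 1], and independent channel noise (band-limited by default so that SNR
is interpretable within the analysis band). Pauses contain noise only, so
pause removal is testable. `shared_snr_schedule[g][s]` is the per-channel
RMS signal-to-noise standard-deviation ratio of group g in timeslot s: the
signal term is coupling × SNR × √C × m ⊗ s with unit-norm m, making the
entry's meaning independent of the channel count.

Default schedule: (0, 0.03, 0.08) for the first group and all-zero for the
two controls — alignment absent early, emerging toward the end, and only in
one group; at the default cohort size this puts end-slot ISC near 0.1, the
order of magnitude such studies report. Default behavioral parameters follow
the same logic: agreement declines across slots in the two intervention-like
groups (slopes −0.4 and −0.25 per slot on the 1–3 scale, flat control,
baselines 2.4/2.0/2.2), the coupling → thermometer-change correlation
defaults to 0.436 and the agreement-change → support-for-measures
correlation to 0.474, the two correlation magnitudes reported for this
design. Behavioral links are planted on the ground-truth coupling, not on
any estimated quantity, so downstream recovery is a genuine inference test.
Ratings and items are integer-rounded and clipped to their printed scales;
the planted correlations hold for the continuous latents before
rounding/clipping (recovery after rounding is measured by the tests, e.g.
planted 0.9 at n = 39 recovers into [0.7, 0.98] in ≥ 90% of seeds).

What the generator does *not* emulate — hence what passing tests do not
show: realistic sensor geometry or forward-model physics, spatially
correlated or non-stationary noise, artifacts (blinks, cardiac,
movement), multi-source or time-varying mixing, non-Gaussian response
distributions, or item-level questionnaire psychometrics beyond range and
reverse-keying. Results on real recordings additionally depend on artifact
cleaning and sensor-type handling, which are out of scope.

Determinism: everything flows from one integer seed through named
substreams (`events`, `source{g}`, `latent{g}`, `noise{g}`, `behavior{g}`,
per-cell bootstrap streams), so identical configs are bit-identical and
changing, say, the bootstrap count cannot perturb the simulation draws.

## Numerical choices and degenerate inputs

* Ridge default γ = 0.05; `fit` raises a descriptive error at γ = 0 on
  singular within-covariances, pointing to γ or the PCA route.
* K = 10 components by default (capped at the channel count); only the
  strongest is used downstream.
* Fold geometry: contiguous thirds via rounded boundaries; minimum fold
  length 100 samples by default.
* Bootstrap requires B ≥ 100; p-values use the +1/(B+1) correction.
* Pearson correlations are undefined for constant series; these raise (ISC
  path) or are reported missing (behavior path) — never silently zeroed.
* Equal-length slot requirement: trailing remainder samples are discarded
  rather than padding or ragged slots.

## Problem sizes used in the shipped studies

The acceptance studies run at deliberately reduced scale chosen so the whole
suite completes in minutes on one CPU while keeping every Monte-Carlo
fraction's binomial error well inside its decision margin: oracle studies at
the instance sizes quoted above; calibration at 500 null datasets (12 × 3000
series, B = 200); recovery at M = 6, C = 16, T = 9000 (SNR 2) and a
50-seed, 3-point SNR grid; build-up at 100 replicates of a 3 × 6-subject,
8-channel cohort with an end-loaded schedule (per-channel SNR 1.0);
FDR selectivity at 100 replicates of n = 39. The full-size default cohort
(120 subjects, 64 channels) runs through the same code path and is exercised
at full scale only for the analytic df check, which costs nothing.

## Known limitations

* SUMCOR refinement applies to the top component only; higher components are
  relaxation eigenvectors without cross-subject orthogonality guarantees.
* The default bootstrap conditions on the fitted filters; absorbing
  selection optimism into the null requires `--refit-null` at substantial
  cost.
* The mixed ANOVA assumes the usual split-plot exchangeability; no
  sphericity correction is applied by default (Greenhouse–Geisser would be a
  straightforward extension, and t = 3 keeps the issue small).
* With heteroscedastic channels, activation patterns live in the
  standardized sensor space (see above).
* The generator's rank-1-per-band latent model is an explicit choice, not an
  empirical claim about any particular dataset.
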