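# Methods

## Task model

A figure-8 session interleaves two four-position odor sequences, 40
repeats each (S1 → S2 → S1 → …, 320 trials, 8 trial types).  Odor layout
S1 = (5+, 0−, 1−, 2+), S2 = (3+, 0−, 1−, 4+): positions P2/P3 share odors
across sequences, P1/P4 do not; exactly P1 and P4 are rewarded.  Event
timing follows the task rules: odor onset 0.5 s after port entry, 0.5-s
minimum hold, 2-s response window after port exit, reward 0.4–1.5 s after
well entry, inter-trial interval 4 s after correct and 8 s after error
trials, 5 s to initiate a trial after light onset.  A trial is *correct*
iff (rewarded ∧ go) ∨ (¬rewarded ∧ no-go); `reward_time` exists only on
rewarded correct go trials.  Trial types are numbered S1-P1 … S2-P4 = 1…8.

Epoch anchors per trial: ITI-a = light_on − 0.7 s; Light, Poke, Odor,
Unpoke = the corresponding events; Choice = well entry on rewarded correct
go trials, else port exit + 2 s; Outcome = reward delivery on rewarded
trials, else Choice + 0.7 s; postOut and ITI-b follow at 0.7-s steps.

## Synthetic sessions

The generator is the package's test bed: it produces complete sessions
with known ground truth under two population regimes.

**Rate model.**  Each unit fires as an inhomogeneous Poisson process with

```
rate(t) = baseline · [ 1 + Σ_e w_e(t)·(g_e − 1) ]  +  baseline · Σ_c u_c · A_c · profile_c(e(t)) · drift_c(τ)
```

where `w_e(t)` is a gain window per epoch anchor, `g_e` the unit's
epoch/position/sequence gain, and the second term the population's
*global motifs*: per-component epoch profile, slow drift over normalized
session time τ, amplitude `A_c`, and per-unit participation
`u_c ~ lognormal(0, 0.5)`.  Rates are floored at 0.  Spikes are drawn by
thinning a homogeneous process against the rate evaluated on a 10-ms grid
(≪ the 100-ms analysis bin), then quantized to the container's 1-µs
resolution.

Two deliberate choices differ from the most obvious construction:

* **Gain windows are tapered plateaus, not anchor-centered bumps**: flat
  over [+0.1, +0.6) s after each anchor with 150-ms cosine edges.  The
  analysis averages rates over exactly [+0.1, +0.6), so a planted gain g
  equals the measured rate ratio — a bump centered *on* the anchor would
  put most of its mass outside the analysis window and make every planted
  effect size uninterpretable.
* **Global motifs are additive**, scaled by the unit's baseline and
  participation rather than multiplying the tuned gain.  This makes each
  motif a genuine rank-1 term (unit weight ⊗ epoch profile ⊗ drift) that a
  CP decomposition can recover; a multiplicative motif would interact with
  position tuning and smear across components.

**Tuning sampler** (identical for both templates unless noted): baseline
~ lognormal, median 2 Hz, σ = 0.6 — low baselines relative to task
responses, as typical of cortical units, keep trial-type-independent
variance from dominating the tensor.  Each unit draws a preferred
position; each epoch there is "active" with probability 0.6 (gain
1 + Γ(2, 0.75)); off-preferred (position, epoch) cells are active with
probability 0.2 (gain 1 + Γ(2, 0.4)).  With probability 0.5 a unit adds
reward responses (gain + Γ(2, 1)) at the Choice/Outcome/postOut epochs of
P1 and P4, on both sequences.  The reward responses matter beyond realism:
without them the population is statistically exchangeable across
positions, and its mean evoked response forms a spurious
uniform-across-blocks tensor component in *both* regimes.

**Compressed template**: sequence gains are exactly 1 at P2/P3 (the
stimuli are physically identical there — this is enforced, not sampled)
and 1 everywhere else except the Odor epoch at P1/P4, where half the
units receive an odor-identity gain (ratio ~2, direction random) because
those odors genuinely differ.  Three global motifs are planted: a broad
early motif (no drift), a mid-trial motif with a linear session ramp, and
a late motif with a half-period sinusoidal drift.  Behavior has no
sequence dependence.

**Differentiated template**: 30% of units receive sequence gains (ratio
~2, direction random per cell) at P1 (Odor/Unpoke/Choice), late P3
(Outcome/postOut/ITI-b) and P4 (Poke…Outcome).  No global motifs.
Latencies shift by +0.15 log units on S2.

**Behavior model**: accuracy 0.92 (go types) / 0.85 (no-go types);
lognormal poke latency (median 0.4 s) and reaction time (median 0.7 s);
correct no-go trials have no well entry.  Aborted trials are representable
(flagged, excluded from all analyses) but the generator does not produce
them by default.

## Rate extraction

Bins are half-open, left-closed; a spike exactly at the anchor falls in
bin index 2 ([0, 0.1)).  Smoothing uses a discrete Gaussian (σ = 0.5 bins)
truncated at ±3σ and renormalized to unit sum; the convolution is
zero-padded, so mass is conserved except at window edges.  The epoch rate
averages bins 3–7 — the printed 100–600 ms window taken literally.
Trial selection (30 correct per type, shared by all nine epochs) uses one
RNG per (session, trial type) derived by hashing the master seed, so the
selection is independent of session order.  The trial tensor uses all 40
trials per type (errors included), entries are smoothed per-bin rates
soft-normalized per unit by (max + 1 Hz), and its trial mode is
position-major — P1-S1, P1-S2, …, P4-S2 — so rewarded trials occupy slots
1–80 and 241–320.

## Statistics

Per-unit S1-vs-S2 selectivity: two-sided Wilcoxon rank-sum at α = 0.05
(Welch t-test available), ≥ 5 trials per side required.  Group
comparisons of selective fractions: Pearson χ² on the 2 × 2 table, 1 df,
no continuity correction; zero-margin tables return χ² = 0, p = 1.  No
multiple-testing correction is applied across the 36 (epoch × position)
cells — fractions are reported per cell.  The two-way ANOVA is computed
from sums of squares on the balanced design the selection stage
guarantees, with partial η² = SS/(SS + SS_error); it matches the
statsmodels OLS ANOVA table exactly (tested).  Preferred positions are
argmax mean rates among units passing a one-way position ANOVA (p < 0.01)
on *both* sequences; the correlation treats positions as ordinal codes
1–4 (Pearson; Spearman available) pooled over epochs, and groups are
compared with Fisher's r-to-z,
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`.

## Decoding

Pseudoensembles permute within-type row order independently per
unit-source session; each unit's per-type rate multiset is preserved
exactly (property-tested).  The decoder is scikit-learn's LinearSVC with
hinge loss, C = 1, one-vs-rest, ties broken toward the lowest class
index, features z-scored with training-fold statistics only.  Its
predictions match a direct SLSQP solution of the soft-margin dual on a
small instance (tested).  Leave-one-out holds out one random trial per
class per repetition.  Nulls rerun the identical pipeline on permuted
labels; the 95% band is the 2.5/97.5 percentiles.  Position decoding uses
9-epoch rate profiles per unit as features (a 120 × 9 matrix per unit and
sequence), trains on S1 minus one held-out trial per position, and tests
either the held-out S1 trials or the index-matched S2 trials.

Because the two templates differ in overall decodability (planted
sequence-specific gains are extra discriminative features), the
cross-sequence comparison reported is the within-minus-across gap per
group, not raw across-sequence accuracies, and it is evaluated at small
ensembles (5 units) where 4-class accuracy is off ceiling.  The
compressed group retains a small gap from its Odor-epoch selectivity at
P1/P4, where the stimuli genuinely differ.

## CP decomposition

Nonnegative CP by HALS (default) or unconstrained ALS, seeded
uniform(0, 1) / standard-normal initialization, alternating mode updates
until the normalized reconstruction error
`‖X − X̂‖_F/‖X‖_F` changes by less than `tol` (default 1e-6 for single
fits) or `max_iter` sweeps.  The error is computed from factored inner
products and asserted non-increasing each sweep (slack 1e-7 covers
cancellation near exact fits).  Restart ensembles default to tol 1e-5 /
max_iter 300: the stability diagnostic measures agreement between optima,
which is insensitive to the final 1e-5 of the error tail, and this keeps
100 restarts to minutes.  Factor columns are normalized to unit length
with scales absorbed into λ.

Similarity between models: per-pair congruence = product over the three
modes of |cosine|; pairs matched by optimal assignment; score = matched
congruences weighted by ½(λ̂ᴬ + λ̂ᴮ).  Invariant to permutation and
rescaling; equals the exhaustive permutation search to 1e-6 (tested
against an independent brute-force implementation).  Cross-group
alignment matches components by temporal-factor cosine only, flagging
pairs below 0.5.

**Position-general diagnostic.**  A component counts as position-general
when (a) the coefficient of variation of its 8 trial-block mean loadings
is below 0.2 *and* (b) it is event-locked: mean temporal loading over the
post-event bins (3–7 of each epoch) at least 1.15 × the pre-event bins
(0–2).  Condition (b) exists because any nonnegative CP of all-positive
firing rates contains a population mean-rate component whose trial
loadings are flat across blocks in *every* population; that offset is
also flat within each peri-event window (ratio ≈ 1.0), while planted task
motifs arrive through the post-event response windows (ratio ≈ 1.3–1.5).
The conjunction identifies what "position-general" means scientifically —
a task-locked motif recruited uniformly across trial types — rather than
the inevitable offset.  Both thresholds are artifact-defined diagnostics,
exposed as parameters and recorded in outputs.

## Mutual information

Plug-in (histogram) MI in bits: trial loadings discretized into 8
equal-width bins, crossed with the 8 trial types or with the trial index
discretized into 8 equal-count bins ("time" = position in the session).
The raw plug-in estimator carries the standard first-order bias
≈ (k₁−1)(k₂−1)/(2K ln 2) ≈ 0.11 bits at K = 320 with an 8 × 8 table; a
Miller–Madow correction flag removes most of it (regression-tested
against the closed form).  Group contrasts and component orderings, which
are what the analysis interprets, are unaffected by this common additive
bias.  Restart models are aligned to the best-fit model by maximum total
congruence before averaging; restarts with mean matched congruence below
0.5 are dropped with a log entry.

## Behavioral metrics

Percent correct excludes aborted trials.  Reaction time is well entry −
port exit; trials without a well entry (correct no-go, and also missed go
responses — an extension of the stated rule, flagged here) receive the
full 2-s response window.  Poke latency is port entry − light onset.
Difference scores are |S1 − S2| of per-type session means at matched
positions, invariant to relabeling the sequences.

## Problem sizes and determinism

Everything derives from one master seed; per-stage seeds are SHA-256
hashes of (seed, stage name), so stages rerun independently and
identically.  The package defaults are desk-scale choices: tens of
pseudoensembles, 100 label shuffles, 10–50 leave-one-out repetitions, 300
units per simulated group, 20–100 CP restarts.  Publication-scale counts
(10,000 pseudoensembles, 200 repetitions) are plain arguments on the same
functions.  The analysis scripts and the acceptance computation each run
in minutes on one CPU at the default sizes.

## What the synthetic tests do and do not show

The generator emulates epoch-locked Poisson spiking, planted tuning and
sequence asymmetries, population-wide drift motifs, and lognormal
behavioral latencies.  It does not emulate spike-sorting noise,
non-Poisson variability (bursting, refractoriness), correlated
trial-to-trial noise within sessions, electrode drift of unit identity,
or any pharmacology.  Passing tests therefore demonstrate that the
*pipeline* detects, calibrates, and dissociates the planted structures at
realistic effect sizes — they do not certify conclusions about any real
recording, and absolute MI values in particular depend on the binning
conventions stated above.
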