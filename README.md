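# odorseq

Analysis pipeline for a question in behavioral neurophysiology: do neural
populations **compress** task states that share a hidden meaning?  In the
figure-8 odor-sequence task, rats run two alternating four-odor sequences
(S1 and S2) that share their middle odors — positions P2 and P3 present
physically identical stimuli in both sequences, while P1 and P4 carry
sequence-unique odors; P1 and P4 are rewarded (go), P2 and P3 are not
(no-go).  A population that *generalizes over* the shared hidden state
should be indistinguishable between S1 and S2 at P2/P3; a population that
*differentiates* the sequences should not.  `odorseq` implements the full
chain of analyses that separates these regimes, and a synthetic spike-train
generator that plants either regime so every analysis can be validated
against ground truth.

The pipeline:

1. **Epoch-aligned firing rates** — each trial is segmented into nine
   epochs (ITI-a, Light, Poke, Odor, Unpoke, Choice, Outcome, postOut,
   ITI-b); spikes are counted in eight 100-ms bins spanning −200 to
   +600 ms around each anchor, smoothed with a σ = 50 ms Gaussian, and the
   +100 to +600 ms bins are averaged into one rate per trial, unit, and
   epoch.  Thirty correct trials per trial type give 240-row trials × units
   matrices per epoch.
2. **Per-unit selectivity** — Wilcoxon rank-sum S1-vs-S2 tests per
   (epoch, position), selective-fraction curves, χ² group comparisons,
   two-way (sequence × position) ANOVA with partial η², and the
   cross-sequence correlation of preferred positions compared between
   groups with Fisher's r-to-z.
3. **Pseudoensemble decoding** — units recorded in different sessions are
   concatenated and within-type trial order is shuffled to destroy
   spurious correlations; a linear SVM (hinge loss, C = 1, one-vs-rest,
   features z-scored on training folds) is scored by leave-one-out-per-class
   cross-validation against a label-shuffled null band (2.5th–97.5th
   percentiles).  Includes S1-vs-S2 decoding per position and epoch,
   ensemble-size curves, and 4-way position decoding trained on S1 and
   tested either within S1 or on index-matched S2 trials.
4. **Tensor component analysis** — the units × time × trials array
   (N × 72 × 320: 9 epochs × 8 bins; 8 trial types × 40 trials,
   position-major so rewarded trials occupy slots 1–80 and 241–320) is
   decomposed with nonnegative canonical polyadic (CP) decomposition via
   HALS.  Stability is assessed over 100 random restarts by each model's
   scale-weighted congruence with the minimum-error model.
5. **Factor information** — plug-in mutual information (bits) between each
   component's trial loadings and (a) the 8 trial types, (b) session time,
   with spread over the restart ensemble.

## The core statistic

A rank-R CP model approximates the trial tensor
`X ≈ Σ_r λ_r · a_r ⊗ b_r ⊗ c_r` with unit factors `a_r`, temporal factors
`b_r`, trial factors `c_r`.  Between two fitted models the similarity is

```
sim(A, B) = Σ_matched pairs (i,j)  ½(λ̂ᴬᵢ + λ̂ᴮⱼ) · Π_modes |cos(fᴬᵢ, fᴮⱼ)|
```

with the pairing chosen by optimal assignment and `λ̂` the normalized
component scales.  Restart ensembles of a well-determined decomposition
score near 1; the headline check is that 100 restarts of the rank-10 fit
on a structured synthetic tensor keep the mean similarity ≥ 0.8.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data: one 300-unit session per template (compressed and differentiated),
identical analysis settings for both.

```bash
cd analysis
python 01_simulate_sessions.py   # sessions + ground truth -> scratch/
python 02_extract_rates.py       # rate matrices + tensors
python 03_unit_selectivity.py
python 04_population_decoding.py
python 05_tensor_components.py
python 06_factor_information.py
python 07_behavior.py
```

Output of the run shipped in `results/` (about 10 minutes end to end):

```
compressed: mean selective fraction at shared positions P2/P3 = 0.045 (alpha = 0.05); preferred-position r = 0.854 over 1132 (unit, epoch) pairs
differentiated: mean selective fraction at shared positions P2/P3 = 0.066 (alpha = 0.05); preferred-position r = 0.824 over 1620 (unit, epoch) pairs
group chi-squared: 11/36 cells differ at p < 0.05
Fisher r-to-z comparison of the correlations: z = 2.65, p = 0.0081
compressed: 0/18 P2/P3 cells decode S1 vs S2 above the null band
differentiated: 3/18 P2/P3 cells decode S1 vs S2 above the null band
compressed: position decoding within 0.812, across 0.806, gap +0.006
differentiated: position decoding within 0.961, across 0.918, gap +0.042
compressed: best error 0.672, mean restart similarity 0.813, 2 position-general component(s), 6 reward-preferring
differentiated: best error 0.790, mean restart similarity 0.855, 0 position-general component(s), 7 reward-preferring
compressed: MI with time mean 0.298 bits (max 0.533), MI with type mean 0.872 bits
differentiated: MI with time mean 0.064 bits (max 0.101), MI with type mean 1.130 bits
latency |S1-S2| difference: differentiated 0.064 s vs compressed 0.035 s (one-sided rank-sum p = 0.000164)
```

Reading these numbers: in the compressed population the S1-vs-S2
selective fraction at the shared positions sits at the test's false-positive
rate (≈ 0.05) and no P2/P3 cell decodes sequence above chance — the two
sequences are represented identically where they share a hidden state.
The differentiated population is selective and decodable at its planted
cells, pays a 4-point accuracy cost when a position decoder trained on S1
is tested on S2, lacks the position-general tensor components that the
compressed group shows, and its trial factors carry more trial-type but
far less session-time information.  Behavior mirrors this: latency
difference scores between matched positions are roughly twice as large
when sequence-dependent shifts are planted.

A single-command variant of the same pipeline (smaller, with figures) is

```bash
odorseq pipeline --seed 7 --out scratch/demo
```

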