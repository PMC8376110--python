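# Methods

## The model

`motifeffect` fits a multi-task sequence-activity classifier
F: x → (y_1, …, y_C), where x is a fixed-length DNA window (default
100 nt, one-hot encoded with columns A, C, G, T and N as uniform 0.25)
and y_c ∈ {0,1} records whether the window is active — accessible or
bound — in condition c. Labels are multi-hot: a window may be active in
several conditions or in none.

F is approximated by an ensemble of small convolutional networks that
share an architecture and differ in their second convolutional layer:

    one-hot input (L × 4)
      → conv layer 1 (n_filters × width, shared shape; ReLU)
      → conv layer 2 (member-specific n_filters × width; ReLU)
      → global max pooling over positions
      → dense layer, C sigmoid outputs

The ensemble prediction f_c(x) is the arithmetic mean of member
probabilities. Training minimizes mean binary cross-entropy with Adam;
each member trains independently on identical data with seed
`config.seed + member_index`, and early stopping monitors validation
loss on held-out chromosomes with patience 2, restoring the best-epoch
weights. First-layer filters can be initialized from a motif database
as log-odds against uniform background, log2((p + 0.01)/0.25), centered
in the filter with zero flanks, so the first layer starts as a motif
scanner but remains trainable.

The networks are implemented directly in numpy (im2col convolutions,
hand-derived backprop including gradients with respect to the input,
which power the per-base saliency scores); everything is
single-threaded and deterministic for a fixed seed. An analytic
gradient check against central differences is part of the test suite.

## Pattern effects

The effect of a DNA pattern p on class c is estimated by inserting p
into M background sequences x_m approximating the natural sequence
distribution and averaging the prediction ratio:

    α_c^p = (1/M) Σ_m f_c(x_m^p) / f_c(x_m)        (Expected Pattern Effect)

Significance is the normalized Wilcoxon signed-rank statistic of the
per-background log2 ratios,

    W = (1/M) Σ_m sign(log2 r_m) R_m,   |W| ≤ (M+1)/2,

with R_m the tie-averaged rank of |log2 r_m| among non-zero values;
zeros are dropped from ranking but M stays the original count. The
two-sided p-value uses the exact sign-flip null (a tie-aware
dynamic program over doubled ranks) for up to 25 non-zero values and a
normal approximation with continuity correction above. The differential
effect between classes,

    DEPE(p; c1, c2) = (1/M) Σ_m [log2 r_m(c1) − log2 r_m(c2)],

is tested the same way on the per-background differences and is exactly
antisymmetric in the class order. One-vs-rest mode replaces f_c2 with
the mean predicted probability of the remaining classes. The
difference-based estimator (1/M) Σ [f(x^p) − f(x)] from Global
Importance Analysis is included only as a comparator: ratios are
invariant to proportional rescaling of the two predictions, which is
what class imbalance mostly does to a sigmoid head, while differences
are reweighted by the baseline.

Numerical choices: predictions are clipped to [1e−6, 1−1e−6] before
ratios and logs (inert whenever predictions lie in [1e−4, 1−1e−4],
asserted by recomputation at ε/10); insertion defaults to the centered
position floor((L − len)/2), following the observation that effects are
stable everywhere except very early insertion sites; `*` characters in
a pattern template preserve the background base, so a spacing scan
measures geometry rather than spacer content; multiple-testing
correction is Bonferroni over the number of patterns in the screen
(Benjamini–Hochberg optional); consensus reduction of a PWM breaks
ties by fixed base order A < C < G < T.

## Windows, labels, splits

BED inputs are 0-based half-open everywhere. The genome is tiled into
non-overlapping L-nt windows (trailing partial windows dropped); a
window is labeled 1 for a class when its overlap with the union of that
class's regions exceeds L/2 strictly (exactly half ⇒ 0). Overlap is
computed against merged intervals, so labeling is invariant to peak
order and to splitting peaks into abutting pieces. Validation and test
sets are whole held-out chromosomes (defaults chr18 and chr19);
sequences without genomic provenance fall back to a seeded random
split. All-zero-label windows are subsampled to a configurable multiple
of the positive count (default 1×).

## The synthetic generator

Fixtures are i.i.d. background sequences at a configurable GC content
(default 0.5) into which class-defining grammars are embedded: one
motif, or a motif pair at a fixed wildcard gap, placed at the window
center ± a jitter (default 20 nt) in a configurable fraction of the
class's sequences (default 0.9). Embedded instances are sampled from
the PWM rather than fixed at the consensus (sharpness: dominant base
probability 0.85), so recovery is a statistical task rather than
substring matching. Negatives (all-zero labels) default to half the
mean class count. Fake chromosomes are assigned round-robin so the
held-out-chromosome machinery is exercised end to end. Decoy panels
for specificity screens resample any candidate whose consensus aligns
to an embedded motif with more than 4 of 8 positions matching, so a
"significant decoy" indicts the method, not an accidental
near-duplicate of a real motif.

What the generator does not emulate: repeat structure, CpG islands,
dinucleotide composition, chromatin domains, overlapping regulatory
grammar, or label noise. Passing recovery tests therefore shows the
estimator chain is sound under known ground truth, not that the model
captures real regulatory genomes.

## Desk-scale study conditions

All simulation-backed checks run on one CPU in minutes, with these
frozen problem sizes:

- Motif recovery: two classes of 1,500 sequences plus 750 negatives,
  one 8-mer per class, embed probability 0.9; screens use a 22-entry
  panel (the 2 embedded motifs + 20 dissimilar decoys) on M = 24
  grammar-free backgrounds; success means the embedded motifs rank
  top-positive/top-negative and are the only Bonferroni-significant
  hits, in at least 4 of 5 seeds.
- Spacing recovery: classes defined by the same motif pair (Sox2/Oct4
  core strings TTGT and ATGCAA) at gaps 3 vs 8, 800 sequences per
  class; the gap-0–10 scan must peak within {2, 3, 4}.
- Imbalance robustness: balanced (500, 500) vs 10× inflated
  (500, 5,000) datasets with a shared negative count; stability is the
  mean Spearman correlation of balanced-vs-imbalanced estimates over
  the three comparisons (per-class effects and the differential), for
  the ratio estimators (EPE/DEPE) vs the difference estimator.
- Model for these runs: 2 members with second layers (8, 5)/(16, 9),
  motif-initialized 32×12 first layer, ≤ 5 epochs, batch 32, Adam
  2e−3. The package-wide defaults (5 members up to (128, 21), 64×17
  first layer, batch 256, Adam 1e−3) are stand-ins for full-genome
  scale and are fully configurable.

## Known limitations

- Global max pooling makes each member a hard maximum over positions;
  the Bayes-optimal discriminator for jittered embedded motifs
  marginalizes softly over positions, so held-out AUROC on the fixture
  saturates near the max-scan information ceiling (≈ 0.90–0.92 at
  these conditions, split-dependent) rather than the soft-posterior
  ceiling (≈ 0.92–0.93). The test suite therefore also benchmarks the
  model against a true-motif max-scan oracle on the same split.
- The exact signed-rank null assumes exchangeable signs; with M = 24
  backgrounds the smallest attainable two-sided p is 2^−23, and
  Bonferroni over large panels will exhaust it.
- Reverse-complement handling is opt-in (`both_strands` takes the
  per-background maximum over orientations); training data are used
  forward-strand only.
- Saved models store weights in numpy `.npz` archives next to a
  plain-text config and manifest; persistence is bit-exact on the same
  platform, while cross-platform determinism is best-effort.
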