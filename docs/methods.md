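# Methods

## Coordinates and the cleavage-pattern representation

All positions are 1-based. A *bond index* `b` names the phosphodiester
bond between nucleotides `b` and `b+1`; this makes "a cleavage site at the
window centre" exact: the 14-nt window spanning nucleotides `b-6 .. b+7`
places bond `b` between window positions 7 and 8. An annotated molecule
therefore needs `7 <= bond <= L-7` for each of its two cleavage bonds.

The complementary sequence of a window is aligned *position-wise*: output
position `i` is the base paired with window position `i` (from the pair
table of the full-length dot-bracket string), or `O` where that position
is unpaired. It is not read as a contiguous opposite-strand segment; the
position-wise convention is the only one under which interior unpaired
positions produce interior `O` characters, as in the worked hsa-mir-4704
example used throughout the tests. Structures are assumed pseudoknot-free
(a single `()` bracket family), which is what RNAfold emits.

Channel orders are part of the trained-model contract and are stored in
every checkpoint: pattern and complementary blocks use `A C G U O`, the
local-structure block `( . )`, and the full-structure encoding `( ) . N`.
The `O` channel of the pattern block is structurally always zero (a window
sequence cannot contain `O`); it is kept so both sequence blocks share one
alphabet.

## Dataset construction

Each usable pre-miRNA yields exactly four entities: the two annotated
positive windows and one uniformly drawn negative window per arm. Two
points are underdetermined by the protocol and were fixed as follows:

* *What counts as a negative.* Default: the window's centre bond is not an
  annotated cleavage bond — the same centre-based property that defines
  positives. A stricter mode (`strict_negatives`) additionally requires
  that no annotated bond fall on any of the window's 13 interior bonds.
* *Arm membership of an arbitrary window.* The side of the terminal-loop
  midpoint its centre bond falls on, where the terminal loop is the
  unpaired run enclosed by the innermost base pair of the hairpin.

Splits draw fixed counts (800 positives and 800 negatives per arm for the
binary tasks; 800 per cell after relabelling 3' positives to class 2 for
the three-class task) without replacement under a seeded generator; the
complement is the test set. No sequence-similarity filtering is applied.
The 40–200 nt length filter for the autoencoder corpus uses inclusive
bounds.

## Model and training choices left open by the architecture sketch

Where the architecture is specified only at block level, this package
fixes (and exposes as configuration):

* activation: ReLU everywhere;
* convolution kernel 3 with same padding; CU1 convolutions preserve the
  channel count so the additive skip needs no projection, and the skip
  wraps each basic unit (`x <- ReLU(conv(x)) + x`, three times);
* autoencoder hidden widths 800 → 256 → 64, decoder mirrored, linear
  output layer (MSE against the one-hot input);
* module 2 treats the stacked features as 2 channels x width 64
  (1 x 64 for the no-embedding ablation);
* the three-class extra stage uses 64 filters and max-pool width 2;
* dropout rate 0.5 in both dense heads, disabled at inference;
* binary decision threshold fixed at 0.5;
* early stopping monitors validation accuracy with patience 5; the
  validation split is a seeded uniform 20% draw, unstratified;
* the returned snapshots are the `keep_top_k = 3` epoch-end states with
  the highest validation accuracy, best first; prediction uses the best.
  Replication studies re-run the whole procedure under independent seeds
  and report per-seed metrics, their mean, or the best, as needed.

The multi-class loss uses the weighted-mean convention
`Σ w_yi · (−log p_i[y_i]) / Σ w_yi`, so unit weights recover the plain
mean and the 0.5 weight on class 0 halves each negative sample's
contribution relative to a positive at equal predicted probability.

All tensors are float64 and every model runs on the package's own
reverse-mode autodiff core (`dicersite.nn`). This keeps the dependency
surface to numpy and makes gradient checks against central finite
differences part of the test suite. At the problem sizes involved
(inputs of 182–800 elements, ~10⁵ parameters) CPU float64 is more than
fast enough: a full 1600-pattern training run takes tens of seconds.

## The hairpin simulator

The simulator emulates the corpus the classifiers are meant for — hairpins
of 40–200 nt with two annotated cleavage bonds — while staying fully
synthetic and seed-reproducible:

* A molecule is a 5' stem strand (18–60 positions), a terminal loop (4–12
  nt), and the complementary 3' strand; paired bases are Watson–Crick with
  an 8% G·U wobble rate. Helix imperfections are *symmetric internal
  loops* (a stem position unpaired on both strands, probability 0.08),
  not one-sided bulges. This preserves the antiparallel register —
  position `i` pairs with `L+1-i` whenever paired — which keeps the
  planted signal (below) consistent with complementarity by construction.
  The dot-bracket structure is the construction's own pairing; nothing is
  re-folded, so the test suite needs no external folding engine.
* The 5' cleavage bond is drawn uniformly over the eligible bonds of the
  5' arm — the same support from which negative windows are later drawn,
  so that with the signal off, positive and negative windows are
  statistically exchangeable and a classifier cannot beat chance. The 3'
  bond is coupled as `bond3 = L + 2 − bond5`, which makes the two positive
  windows exact pairing partners (capped one bond short of the loop
  midpoint so the two planted regions can never collide).
* With per-molecule probability `signal_strength`, the 4-mer `GAUC` is
  written at window positions 5–8 of both positive windows and two stem
  positions under window positions 12–13 of the 5' window are opened into
  an internal loop (an unpaired-run cue). `GAUC` is a reverse-complement
  palindrome, so the two planted copies agree wherever the windows pair
  with each other; base-pair complementarity therefore holds for every
  generated molecule at any signal strength. At `signal_strength = 0` the
  motif appears only at its ~0.4% background frequency.

What passing the signal-recovery check does and does not show: with the
signal at full strength the full pipeline (autoencoder + classifier)
reaches ≥ 0.85 test accuracy on a 956-molecule corpus, and with no signal
it stays within [0.4, 0.6] — i.e. the machinery can extract a planted,
localised sequence/structure cue and does not hallucinate one. Synthetic
hairpins do not reproduce real pre-miRNA base composition, thermodynamic
folding, multi-branched structures, or the actual (partially
position-regular) distribution of Dicer sites, so performance numbers on
simulated corpora say nothing quantitative about performance on miRBase
data; reproducing the published benchmark requires downloading the real
corpus, folding it with RNAfold, and supplying the cleavage annotations
(see the real-data path in the README).

## Numerical and degenerate-input conventions

* An MCC whose denominator contains a zero factor is reported as 0.0 with
  a `mcc_degenerate` flag; specificity/sensitivity with an empty class are
  NaN with a flag. Per-class one-vs-all metrics are always emitted
  alongside the macro means so alternative summaries can be recomputed.
* ROC/PR curves group tied scores into a single threshold and use
  trapezoidal AUC; a single-class truth vector yields an empty, flagged
  curve. Macro accuracy is the unweighted mean of per-class one-vs-all
  accuracies.
* Probabilities are clipped by an additive 1e-12 inside the log losses.
* Batch normalisation keeps running statistics (momentum 0.1) for
  inference; validation and test passes never update them.

## Problem sizes used in the checks

The dataset-arithmetic and signal-recovery checks run at the published
corpus scale (956 molecules, 800/800 binary splits leaving 312 test
patterns, 3200/624 three-class splits); gradient checks and architecture
contracts run on small random tensors; the metric-identity checks use
1000 random confusion tables. The whole suite completes in a few minutes
on one CPU core.

## Known limitations

* No GPU path and no mini-batch parallelism; training beyond ~10⁴ patterns
  would be slow.
* The original trained weights are not reproduced; checkpoints are this
  package's own format.
* Deriving cleavage bonds from miRBase mature-miRNA coordinates is out of
  scope — annotations must be supplied explicitly.
* Joint fine-tuning of the autoencoder with the classifier is not
  implemented (the encoder stays frozen).
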