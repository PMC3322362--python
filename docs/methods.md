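# Methods

## Problem and model

`rpikit` addresses the partner-prediction form of the RNA–protein
interaction (RPI) problem: decide whether a given protein and RNA
interact, using nothing but their primary sequences. The underlying
assumption is that interaction propensity leaves a footprint in global
sequence composition — in the relative frequencies of short residue and
nucleotide words — rather than requiring structure or position-specific
motifs. That assumption is what the feature encoding operationalizes
and what the synthetic benchmark plants explicitly.

### Feature encoding

A protein is reduced to a 7-letter alphabet (classes grouped by dipole
moment and side-chain volume, in the fixed order {A,G,V}, {I,L,F,P},
{Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}) and described by the
normalized frequencies of all 343 class triads; an RNA by the
normalized frequencies of all 256 tetrads; a pair by the concatenation,
protein part first (599 features). Design choices worth recording:

* **Class order and index arithmetic.** The classes carry no canonical
  numbering, but a stable feature schema needs one; the printed order
  above is frozen, with triad (g₁,g₂,g₃) at index 49g₁+7g₂+g₃ and
  tetrad (b₁..b₄), A=0 C=1 G=2 U=3, at 64b₁+16b₂+4b₃+b₄.
* **Normalization denominator.** "Normalized frequency" is implemented
  as count / number of valid windows (= L−k+1 when all letters are
  standard), so each part sums to exactly 1 regardless of skipped
  windows.
* **Ambiguity handling.** Non-standard letters (N, X, B, Z,
  selenocysteine U in proteins) are kept in the sequence but flagged;
  any window touching one contributes to neither numerator nor
  denominator. Dropping whole sequences would be needlessly
  aggressive; silently counting junk would corrupt the frequencies. A
  sequence with no valid window at all raises an encoding error (and
  is skipped with a warning in batch network prediction).
* **Input tolerance.** RNA input may arrive DNA-style; T is mapped to
  U and case is folded, so the encoding is invariant to presentation.

### Classifiers

* **Random Forest**: 20 trees, 10 candidate features per split. The
  20/10 setting is the fast classification configuration; 500 trees is
  the large setting used for comparisons and for importance analysis.
  When `rf_features_per_split` is unset the fallback
  ⌊log₂ n_features⌋+1 applies. The reported probability is the exact
  fraction of trees voting positive (not averaged leaf frequencies),
  so a single-tree forest emits only {0, 1} and a 20-tree forest has
  granularity 1/20.
* **SVM**: soft margin with the *normalized* polynomial kernel of
  order 2, K(x,y) = (x·y+1)²/√((x·x+1)²(y·y+1)²), C = 1, tolerance
  10⁻³. The +1 lower-order term is included before normalization —
  the conventional form of this kernel family. Probabilities come from
  Platt scaling: a logistic model fitted to margins obtained by 3-fold
  internal cross-validation (fitting the logistic to resubstitution
  margins would be optimistically steep). The calibrated probability
  is a monotone function of the final model's margin. The SMO round-off
  parameter ε is recorded in the configuration for provenance; the
  quadratic-programming solver used here does not expose it.
* **Decision threshold** 0.50, inclusive (a probability of exactly
  0.50 is called interacting). Inclusive comparison also resolves the
  even-forest tie at 0.5 vote fraction.

A practical caveat from the kernel's geometry: normalized frequency
vectors have small norms (‖x‖² ≈ 0.02–0.1), so the +1 constant
dominates the Gram matrix and entries cluster near 1. With very few
training pairs the C = 1 margin underfits; at the dataset sizes the
pipeline targets (hundreds of pairs) this is immaterial, but toy
examples with fewer than ~10 pairs need a harder margin (larger C).

### Dataset construction

Positives are filtered to protein length > 25 and RNA length ≥ 15
(strict vs inclusive exactly as stated). Pair-level redundancy removal
is a greedy keep-first scan in input order: a pair is discarded iff
some retained pair matches it at ≥ 30 % identity on the protein AND
≥ 30 % on the RNA. Requiring similarity on both partners subsumes the
symmetric RNA-side phrasing of the rule. Greedy keep-first is the
simplest deterministic strategy; no clustering refinement is attempted.

Sequence identity is not further specified by the redundancy rule, so
it is pinned for reproducibility: global (Needleman–Wunsch) alignment
with match +1, mismatch 0, gap −1 per gapped column; identity =
identical columns / alignment length; arguments are ordered
lexicographically before alignment so the function is exactly
symmetric. At a 30 % cutoff the pipeline's decisions are insensitive
to reasonable variations of this scheme.

Negative sampling draws uniformly (seeded) from the observed
protein × RNA cross product, rejecting exact positives and any
candidate (A,B) for which a positive (C,B) exists with
identity(A,C) ≥ 30 %, until ratio × n_positives distinct negatives are
found; if the attempt budget is exhausted the error reports how many
admissible negatives actually exist. Rejection sampling was chosen
over enumerate-then-sample because the cross product grows
quadratically while the quota is linear.

### Evaluation

Stratified k-fold cross-validation (default 10) with a seeded shuffle;
every pair is scored exactly once while held out. Confusion counts are
pooled (micro-averaged) across folds — a single confusion table, a
single number per metric — rather than averaging per-fold metrics.
Stratification is the least surprising choice for balanced data;
leave-one-out is the k = n special case without stratification.
Metrics with zero denominators are reported as undefined (None), never
coerced to 0. AUC is the trapezoidal area under the ROC, which equals
the Mann–Whitney concordance probability with ties counted ½; the test
suite enforces agreement with a brute-force concordance oracle to
1e-12.

Splits are over *pairs*, not sequences: a protein appearing in several
pairs can occur on both sides of a split. For the question "can the
model generalize to unseen molecules" this is optimistic; results
should be read as performance on new *pairings* of partially seen
molecules.

### Networks

A trained model scores candidate pairs (an explicit list or the full
cross product); edges at probability ≥ threshold are the predicted
network. Evaluation against a catalogue of known interactions reports
recall plus band counts (probability ≥ 0.80 and [0.50, 0.80)) —
interaction catalogues carry no verified negatives, so percentages of
recovered known pairs are recall, not accuracy. Unencodable sequences
are skipped with a warning and listed in a sidecar, never failing a
whole run. Hubs are nodes whose predicted-positive degree reaches a
cutoff, sorted by degree then id.

## Synthetic data: what it emulates and what it does not

The generator produces balanced pair sets whose positives carry planted
compositional enrichment: background residues uniform over the
alphabet; scanning start positions left to right, with probability δ
(`signal_strength`) a signal k-mer is written over the next k letters —
a random residue realization of a signal triad for proteins, a signal
tetrad verbatim for RNA — and the scan then advances past the planted
k-mer, so planted motifs are never clobbered by later plants. Lengths
stay fixed. Defaults: 200 pairs per class, protein length 150, RNA
length 100, δ = 0.5, signal triad class {I,L,F,P}{A,G,V}{R,K} and
tetrads AUUC/AGUG/UUUU/UCAA — word classes reported as discriminative
in real RPI data, which ties the testbed to the biology the encoding
is meant to capture.

What passing tests on this generator show: the encoders measure
composition correctly, the classifiers detect compositional class
differences at realistic effect sizes, chance-level behaviour holds at
δ = 0, and importance ranking recovers planted words. What they do not
show: performance on real RPIs. Real sequences have skewed base and
residue composition, phylogenetic correlation, shared domains across
pairs, and label noise; none of that is simulated, and the pair-level
CV caveat above applies on top.

## Numerical and degenerate-input choices

* Identity of identical sequences short-circuits to 1.0 without
  alignment; empty sequences are rejected.
* Importance ranking breaks ties by schema order, making the ranking
  deterministic; impurity importances from small forests are noisy, so
  recovery analyses use the 500-tree setting.
* Greedy forward selection stops at `max_features`, on no improvement,
  or at a perfect score; its evaluator is a seeded stratified-CV
  random forest, and the score trace is monotone non-decreasing by
  construction of the stopping rule.
* All stochastic operations (generation, negative sampling, fold
  shuffling, forest training) take explicit seeds; identical seeds
  give byte-identical outputs.
* Model files are versioned; loading a file with a different format
  version or unreadable payload raises a clear error.

## Problem sizes

The test suite and the acceptance script run the reference conditions
at 200 pairs per class (learnability, recovery, monotonicity across
δ ∈ {0, 0.1, 0.3, 0.5} with 5 seeds each) and smaller toys elsewhere;
these sizes give stable statistics for the planted effect sizes while
keeping a full run in tens of seconds on one CPU.

## Known limitations

* Sequence-composition features ignore order beyond k-mers, structure
  and binding-site position; the method predicts partners, not
  interfaces.
* Pair-level CV optimism (above) — sequence-disjoint splitting is not
  implemented.
* The 30 % identity scheme is a pinned convention, not a claim about
  the best alignment parametrization.
* Negative pairs are presumed, not verified, non-interactions;
  training labels on real data inherit that assumption.
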