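# Methods

This note documents the models, conventions and design decisions behind
`recspot`, in the order data flows through the package.

## Sequence model and conventions

Records are strings over {A,C,G,T}; labels are `hotspot` (positive class,
numeric code 0) or `coldspot` (code 1). Input is uppercased on read;
ambiguity codes are rejected by default because every extractor assumes the
4-letter alphabet (`strip_ambiguous` drops and logs offending records
instead). All internal coordinates are 0-based half-open; the 1-based
positions conventional in the surrounding literature appear only in prose.
FASTA is written uppercase, wrapped at 60 columns, labels carried as a
`|label` header suffix (or a two-column id/label sidecar TSV), which makes
round-trips bit-stable.

## Synthetic data generator

The generator stands in for a curated hotspot/coldspot benchmark. A
sequence is a concatenation of independent trinucleotide draws (trimmed to
length). Coldspots use a background distribution `q` over the 64
trinucleotides, the product of per-base probabilities with GC content
`0.5 + gc_shift`; hotspots move a fraction `effect` of the probability mass
uniformly onto a planted trinucleotide set and scale the remainder by
`1 − effect`. Defaults: 478 + 572 records (the class sizes of the original
yeast benchmark), lengths uniform on 200–3000 nt (the benchmark's length
distribution is not published; this range is a recorded choice, not data),
`effect = 0.15` on {AAA, TTT}, `gc_shift = 0`, seed 0.

What it emulates: two classes distinguishable only by k-mer composition,
variable lengths, exchangeability at `effect = gc_shift = 0`, and an
analytically known signal — the expected hotspot-minus-coldspot frequency
of the planted set on the generator's triplet frame is
`effect × (1 − q_planted)`, which the tests verify by Monte Carlo. What it
does **not** emulate: positional motif structure, long-range correlation,
phylogenetic relatedness between records, GC heterogeneity along a
sequence, or any real determinants of recombination (PRDM9-like motifs,
chromatin). Passing tests therefore demonstrate that the pipeline recovers
compositional class differences without leakage — not that it would reach
any particular accuracy on real genomes.

## Feature extractors

**GDC.** Gap κ counts ordered pairs at positions `(i, i+κ+1)`; the
denominator is the number of pair positions `n(κ) = L − κ − 1`, so each
gap's 16 values sum to 1. The gap range {0..7} is pinned by the feature
count (128 = 16 × 8); whether the original method counted gaps from 0 or 1
is not determinable from its description, so κ = number of interposed bases
starting at 0 was adopted as the simplest consistent reading. Sequences too
short for a gap contribute zeros for that gap with a logged warning
(keeping matrices rectangular); a sequence too short for *every* gap is an
error.

**RCC.** Canonical classes merge each k-mer with its reverse complement
(lexicographic minimum under A<C<G<T); counts are divided by `L` — the
method's literal normalization — with a per-window option for users who
prefer frequencies that sum to 1. Class counts 32/136/512 for k = 3/4/5 are
fixed by combinatorics (odd k has no palindromes; k = 4 has 16).

**PseTNC.** λ = 2 is pinned by the 66-feature total (64 + λ); w = 0.1 is a
free default (the source method does not state one). The pairwise
correlation function Θ is the mean squared difference of standardized
property values — the standard pseudo-composition convention; the original
text does not define it explicitly, so this is a documented assumption. The
physicochemical table is configurable; the built-in default is three
arbitrary but frozen standardized columns, which exercise the machinery
fully without committing to unstated biology. Users with real
trinucleotide properties (bendability, stacking energy, ...) can supply a
64 × μ table; columns are standardized to mean 0 / variance 1 on input.

**k-mer bank.** Plain k = 1..5 compositions (1364 features,
window-normalized per k). The published method's 425-feature "H" block came
from an earlier tool whose exact feature list is not reconstructible from
the description; here H is defined as the top 425 bank features under
SVM-RFE (or any user-supplied precomputed matrix), preserving the hybrid
arithmetic and dimensions while being honest about provenance.

Feature-name registries are fixed a priori — every possible name is always
emitted, zeros included — so train/test matrices align by construction.
TSVs carry floats at 12 significant digits.

## Selection

SVM-RFE: standardize columns, fit a linear SVM (C = 1.0), score features by
squared weight, eliminate the lowest batch, repeat. Step: 1 feature per
iteration for blocks ≤ 200 features, 10% of the survivors (ceil) above
(speed; the ordering of the retained top is insensitive to this in
practice). Ties in squared weight are broken by original column order, and
exact-tie groups straddling the elimination cut leave in the same batch, so
duplicated columns occupy adjacent ranks deterministically. Default block
cuts: 5 (GDC), 12 (RCC), 66 (PseTNC — all of it; selection does not help a
66-vector), 425 (bank). Only the counts are normative; the identities of
the selected features depend on the data.

## Hybrid combination

`F = aG + λ(R + PseTNC) + (1−λ)H` is implemented as ranked-prefix
concatenation with take-counts `round_half_up(weight × block size)` — the
only reading that reproduces all nine cataloged group dimensions
(half-up vs ceiling-at-half is not distinguishable from those dimensions;
half-up was adopted and round-half-even provably fails). λ applies to R and
P separately (6 + 33 at λ = 0.5) rather than to their pooled 78 — both give
identical totals; per-block composes better. The mixing λ is named
`lam_mix` to keep it distinct from the PseTNC tier count λ, which shares
the symbol in the original notation. Hybrid columns carry provenance
prefixes (`G:`, `R:`, `P:`, `H:`).

## Classifier

Softmax cross-entropy loss (the source names softmax plus an unnamed
"error loss"); L2 penalty 1e-4 by default, dropout available but off.
Hidden activations: tanh (default), relu, sigmoid. Initialization: Xavier
normal, variance `2/(fan_in + fan_out)`, biases 0. The update combines the
advertised pieces — gradient descent whose per-parameter step is
Adagrad-scaled and then accumulated with momentum 0.9 — with plain
SGD-momentum as an option. Training is full-batch for 1000 iterations by
default (batch size configurable); the seed (default 6) drives weight
init, batch shuffling and dropout. A softmax tie predicts class 0
(hotspot) for determinism. The layer widths 430-413-318-251-182-96-2
resolve an internal inconsistency in the source description (which says
both "five hidden layers" and "4"): the width list is treated as
authoritative — input 430, five hidden layers, output 2.

The default architecture is sized for the 430-feature G3 input of the
original benchmark. The synthetic planted-signal study uses
`DnnConfig.small()` — two hidden layers (64, 32), 300 iterations — sized to
its 83-feature G4 hybrid input; the signal there is strong and a deeper net
adds nothing but runtime. Gradient correctness of the backpropagation is
verified against central finite differences (< 1e-5 max abs difference) for
all three activations.

## Evaluation

Metrics use the error-fraction formulation (ACC = 1 − errors/total,
SN = 1 − misses/H+, SP = 1 − false alarms/H−, and the two-factor MCC),
which is algebraically identical to the TP/TN/FP/FN textbook formulas —
the tests verify this exhaustively over every confusion table with class
totals ≤ 20. A zero factor under the MCC root yields MCC = 0 (logged),
never NaN; metrics on a single-class truth raise.

Cross-validation is stratified k-fold (k = 10), seeded. The default
`fold-internal-selection` mode re-fits SVM-RFE rankings and feature
standardization inside each training fold — the statistically correct
protocol; `whole-dataset-selection` ranks once up front, mimicking
protocols that select features before splitting (optimistic; provided for
replication of published numbers). Reported metrics are pooled over the
union of held-out predictions (per-fold values retained); the pooled
confusion equals the sum of per-fold confusions by construction. ROC curves
sweep unique score thresholds with ties grouped, AUC by trapezoid —
equivalent to the normalized Mann–Whitney U with half-credit for ties.

The grid search evaluates every (learning rate × activation) cell by
cross-validation; ties resolve to the lowest learning rate, then activation
order tanh, relu, sigmoid. A diverging cell scores 0 rather than aborting
the grid.

## Problem sizes and numerical choices

The planted-signal study used throughout (tests, acceptance script,
README example) is 200 + 200 sequences of 500 nt at effect 0.15 — large
enough that the 3-standard-error Monte-Carlo checks on the generator are
sharp and the pipeline's pooled accuracy sits well above 0.95, small enough
that a full fold-internal 10-fold run completes in minutes on one CPU. Unit
tests use 40 + 40 records. Normalization identities are asserted at 1e-12;
probability sums at 1e-9; the gradient oracle at 1e-5 with eps 1e-6.

## Known limitations

* The H block approximates an external tool's feature list by ranked k-mer
  bank selection; published benchmark accuracies are therefore expected to
  be approached, not matched digit-for-digit.
* The PseTNC property table defaults to placeholder columns; biological
  interpretability of the θ tiers requires a user-supplied table.
* No GPU path, no early stopping, no convolutional/recurrent
  architectures; training cost grows linearly in iterations × layer area.
* The generator's i.i.d. trinucleotide model makes the synthetic task
  easier than real hotspot discrimination; synthetic accuracies should not
  be read as expected field performance.
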