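# Methods

## Problem

Class A G protein-coupled receptors (GPCRs) bind their ligands inside the
seven-transmembrane (7TM) helical bundle, sometimes gated by extracellular
loop 2 (ECL2). Because the family is rich in orphan receptors,
protein-specific activity models are often impossible and compound-protein
interaction (CPI) prediction — a binary classifier over (compound, receptor)
pairs — is the natural formulation. Whole-sequence CPI encoders feed the
model long stretches of sequence (N/C termini, intracellular loops) that
cannot contact the ligand; those regions act as noise. This package
implements a region-restricted sequence encoder for class A GPCRs: only the
annotated TM1-TM7 subsequences (optionally plus ECL1/ECL2/ECL3) enter the
model, paired with a Transformer-style compound-protein decoder, plus the
dataset construction, evaluation statistics, attention attribution, and a
synthetic benchmark generator with a planted, region-localised binding rule.

## Dataset construction (`corpus`)

* Records carry (accession, canonical SMILES, affinity type, molar
  affinity). Only IC50/EC50 records are used. Affinity values are converted
  to mol/L via a per-file unit (or a `unit` column; nM, uM, mM, pM, M).
* Binary label: positive iff pAff = -log10(affinity [M]) >= 6 (inclusive;
  1 uM). Non-positive or non-finite affinities are rejected with a logged
  reason.
* Duplicate (accession, SMILES) pairs: agreeing labels collapse to one
  record; contradictory labels drop the pair entirely (treated as noise).
* Ligand-bias filter: compounds with a single interaction, or whose
  interactions all carry one label, are removed — such compounds would let
  a model predict from ligand identity alone. Removal is iterated to a
  fixed point because deleting one compound's records can create new
  single-interaction compounds.
* Splits: records are canonically sorted (accession, then SMILES) before a
  seeded shuffle, so partitions are independent of input file order.
  Test is 20% of records; validation is 20% of the remainder
  (100 records -> 64/16/20). `protein_disjoint` mode assigns whole
  accessions to the test side until it holds ~20% of records, supporting
  novel-protein evaluation. Splitting requires all three parts non-empty.

## Protein features (`protein_features`)

Regions are sliced exactly at their annotated 1-based inclusive UniProt-style
coordinates, ordered anatomically: TM1..TM7 with requested loops interleaved
(ECL1 between TM2/TM3, ECL2 between TM4/TM5, ECL3 between TM6/TM7). Each
segment is tokenised into overlapping 3-mers (stride 1), so a segment of L
residues yields p = L-2 tokens; "region length" always means tokenised
length here. Tokens are embedded by a skip-gram word2vec model with
negative sampling (window 5, 5 negatives, dimension 100 by default),
implemented directly in numpy and deterministic under a fixed seed. The
model is trained on the *training-split* segment corpus only, so no test
sequence influences the embedding. Out-of-vocabulary tokens map to the zero
vector (neutral and mask-friendly). Trained vectors are L2-normalised
before use — on a segment-sized corpus raw SGNS vectors remain near their
tiny initialisation scale, which would starve the downstream encoder of
protein signal; unit-norm token vectors give the convolution a
well-conditioned input.

## Compound features (`compound_features`)

SMILES are parsed with RDKit; each heavy atom becomes a 34-dimensional
vector (element one-hot over 14 symbols + other; degree one-hot 0-5;
formal charge; radical electrons; hybridisation one-hot SP/SP2/SP3/
SP3D/SP3D2; aromaticity flag; total-H one-hot 0-3 + more). Hydrogens are
implicit; stereochemistry is ignored. The adjacency matrix carries
self-loops and is row-normalised so each atom averages itself with its
neighbours. A light graph network — three rounds of
`h <- relu(A_norm h W + b)`, width 64, He-initialised (sqrt(2) gain)
because of the relu — produces the a x 64 atom embedding. The construction
is permutation-equivariant by design and is asserted as such in tests.

## Region encoder (`encoder`)

Per receptor, the R embedded regions (R = 7, or 8 with one loop) are
zero-padded at their tails to the receptor's maximum tokenised region
length p_max, giving an R x p_max x 100 stack with a validity mask. Each
region passes through its own block of one length-preserving
(same-padding) 1D convolution (kernel 3, 100 -> 128 channels) followed by
a gated linear unit, GLU(A, B) = A * sigmoid(B), down to 64 channels.
Region blocks have independent parameters (a config flag enables sharing
for ablation). Blocks are concatenated in anatomical order — a loop block
is inserted at its anatomical slot so residue order survives — and a
sinusoidal positional table over the concatenated axis is added. One
self-attention block (8 heads, feedforward width 256, residual + layer
norm after both sublayers) yields the (p_max x R) x 64 protein matrix,
with (region, within-region index) provenance per row. Padded rows are
excluded as attention keys by a -1e9 pre-softmax bias, which underflows to
exactly zero weight in float32.

Two numerical choices matter and are documented here:

* Content features are multiplied by sqrt(64) before the positional table
  is added (the standard transformer convention), and the table itself is
  scaled by `pe_scale = 0.1`. With equal amplitudes the position pattern —
  identical across receptors — dominates the content channels and the
  optimiser spends most of a typical training budget before the protein
  pathway breaks symmetry; a weak positional signal preserves order
  information without that stall.
* Padding sits at region tails and positions are computed on the padded
  concatenated axis, accepting phantom positions at padded slots; this is
  what makes the output row count exactly p_max x R.

The whole-sequence baseline encoder used in comparisons is the same
machinery with a single pseudo-region holding the full sequence (R = 1),
i.e. a conventional whole-sequence convolutional encoder.

## Interaction decoder (`decoder`)

Compound atoms are queries over the encoded protein (keys/values) through
3 cross-attention layers (8 heads), each followed by a feedforward with
residual + layer norm. Padded protein rows are masked pre-softmax. Atom
representations are pooled by a learned softmax attention over (real)
atoms, and a two-layer head maps the pooled vector to a logit; the
probability is its sigmoid and training minimises binary cross-entropy
(equivalent to the published two-way softmax formulation). Cross-attention
tensors (layers x heads x atoms x protein rows) can be retained per pair
for attribution. Scoring is order-preserving and batch-size invariant to
float tolerance: batch padding is inert at valid rows by construction.

## Training and evaluation (`training`)

Adam (lr 1e-3, batch 32 by default; both config-surfaced) on binary
cross-entropy, with a 3-epoch linear learning-rate warmup. The warmup is
load-bearing: at full rate from step one, the decoder head overfits
ligand identity (which the ligand-bias filter has made anti-predictive
out of sample) before the protein pathway contributes, and several
epochs of a typical training budget are spent escaping that basin.
Optional gradient clipping and decoupled weight decay are available but
off by default. After every epoch the validation AUC is computed; the
selected model is the parameter state at the best validation epoch, never
the last. AUC is the tie-aware Mann-Whitney rank statistic
P(s_pos > s_neg) + 0.5 P(tie), tested against exhaustive pair enumeration;
the ROC curve is also emitted for plots. Model comparisons across the five
split seeds (0-4 by convention) use a one-sided paired t-test with
df = n-1 (H1: the second model is better); zero-variance differences are
handled degenerately (p = 0 if the mean difference is positive, else 1,
with a warning). Per-subfamily AUC is computed within each subfamily's
records; single-label subfamilies are reported as undefined rather than
imputed.

## Synthetic benchmark (`synthetic`)

The generator emulates the structure of a GLASS-style corpus so every
module is testable without downloads:

* Receptors: random sequences over the 20 amino acids with seven TM
  annotations (default 18-30 residues each), ECL1-3 (8-16 residues)
  between TM2/3, TM4/5, TM6/7, and random N/C termini (10-40). One pocket
  motif (a random 4-6-mer from a library of K = 4 classes) is embedded in
  TM3 or TM6 — or in ECL2 for a configurable fraction of receptors, to
  emulate loop-dependent binding. Subfamily = motif class.
* Compounds: decorated template scaffolds, one scaffold per motif class.
  The default scaffolds are chosen chemically well-separated (benzene,
  cyclohexane, furan, piperidine) so the key class is recoverable from the
  graph, which the planted rule presumes.
* Interactions: distinct (receptor, compound) pairs, half class-matched;
  a pair is positive iff receptor motif class = compound class, flipped
  with probability eps (default 0.1). Affinities are drawn uniformly in
  pAff [6, 9] for positives and [3, 6) for negatives, so re-labelling
  through the threshold rule reproduces the planted labels exactly. The
  Bayes-optimal rule classifier has AUC (1-eps)^2 + eps(1-eps) = 0.90 at
  eps = 0.1, which bounds what any model can reach on this benchmark.
* Defaults are 50 receptors, 80 compounds, 2000 pairs; everything is
  deterministic under the config seed.

What the generator does *not* emulate: real binding-pocket chemistry and
SAR, sequence homology structure within subfamilies, affinity measurement
noise correlated with assay type, and the heavy class imbalance of real
corpora. Passing tests on this benchmark therefore demonstrates that the
pipeline can recover a region-localised signal end-to-end — not that it
reproduces published accuracies on GLASS-scale data, which are outside
desk-scale compute and external-download constraints.

## Attention attribution (`attention`)

Per scored pair, cross-attention is averaged over decoder layers, heads
and atom queries to a per-position profile aligned with the encoder's row
provenance. Region importance is the mean over the region's real
(non-padding) positions — mean rather than sum so long regions are not
favoured; summing and final-layer-only aggregation are available as
options. Test-case importance is the mean of per-pair region scores, and
normalised scores sum to 1 across regions. Aggregation is linear, so
averaging profiles before or after regionalisation agrees when profiles
share a layout; this is asserted numerically.

## Problem sizes used in the test suite

Training-behaviour tests run the full pipeline at reduced problem sizes
chosen as the package's own test-design points: the end-to-end
learnability check uses the generator defaults (2000 pairs, eps 0.1) with
a 30-epoch budget; architectural comparisons use 600-900 pairs, reduced
encoder widths where only the comparison (not the published dimensions)
is under test, and 3 seeds.

The split mode is chosen per comparison to match what it measures. The
ECL2-information comparison (TM+ECL2 vs TM-only on a loop-rule corpus)
runs on protein-disjoint splits with 40 receptors: under record-level
random splits a TM-only model matches a TM+ECL2 model by memorising
receptor identity from the TM sequences, and with too few receptors the
models learn receptor-specific features instead of the motif while the
disjoint test set is too small to score stably. The region-attention
contrast compares corpora: the same TM+ECL2 architecture trained on an
ECL2-rule corpus versus on a TM-rule corpus, with ECL2's mean normalised
attention share higher in the former. The TM-only
vs whole-sequence comparisons (non-inferiority, and degradation under
3x-length termini) instead use record-level random splits, where both
encoders see the same receptors and reach AUCs far above chance at these
sizes; the comparison then isolates how much of the shared learning
budget the uninformative termini consume, which is the property under
test. The acceptance script mirrors these designs and sizes.

## Known limitations

* Kernel size, heads, feedforward width, learning rate and batch size
  are this package's documented defaults; they are not taken from any
  published hyperparameter listing.
* The numpy implementation targets CPU determinism, not speed; GLASS-scale
  training is out of scope.
* The word2vec corpus is the training split's region segments; training
  it on whole sequences instead is equally defensible, and the choice
  here is declared, not derived from precedent.
* With eps = 0.1 the synthetic benchmark's ceiling is AUC 0.90; observed
  end-to-end AUCs should be read against that ceiling, not against 1.0.
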