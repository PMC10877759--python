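# Methods

## Problem setting

Drug repositioning is cast as link prediction on a heterogeneous
information graph with two node types (drugs, diseases) and three edge
types: experimentally validated drug–disease associations (a binary
n × m matrix A), drug–drug similarities (n × n, values in [0, 1]) and
disease–disease similarities (m × m).  Similarities are consumed as
given — the package does not compute chemical or phenotypic similarity
from raw structures or ontologies.

## Graph construction

Dense similarity matrices are noisy; each node keeps only its extended
k-nearest-neighbour set Ñ_k — itself plus its k most similar other nodes
(default k = 15, typical of neighbourhood-based methods at benchmark
sizes of a few hundred nodes).  Edges are kept if either endpoint selects
the other (union symmetrization), so adjacencies stay symmetric, which
the spectral normalization assumes.  Similarity ties are broken by
ascending node index for reproducibility.  Kept edges carry the original
similarity weight (a `binarize` flag switches to 0/1 weights).
Propagation uses D̃^{-1/2}(W + I)D̃^{-1/2}, where W is the sparsified
weighted adjacency with zero diagonal; self-loops guarantee positive
degrees, so the normalization is total.

## Encoder

Initial node features are the rows of the dense similarity matrix
projected linearly to the embedding dimension (64).  The featurization is
a design choice: similarity profiles are the only per-node information
available in this setting.

Two paths encode each similarity graph from the same projected input:

1. **Mixed aggregation** — `β·ReLU(Pool(XW, W)) + α·ReLU(S·XW)` with
   S the normalized adjacency.  `Pool(XW, W) = (W·XW)² − (W²⊙XW²)`
   (squares element-wise, `⊙` an element-wise square followed by a matrix
   product): per node i and channel c this equals
   Σ_{j≠k} W_ij W_ik x_jc x_kc, the sum of products over ordered pairs of
   distinct neighbours — second-order neighbourhood interactions that a
   mean aggregator cannot see.  This reading of the pooling formula is the
   only dimensionally consistent one and is verified against a
   brute-force pair-sum oracle in the tests.  α and β are learnable
   scalars initialized at 0.5 each, letting the model choose between the
   two convolution types during training.
2. **Graph transformer** — multi-head (default H = 4) scaled dot-product
   self-attention, masked to Ñ_k ∪ {self} (config `attention_scope` can
   widen it to all nodes), with scores and values sharing the per-head
   projection.  The attention block and a position-wise feed-forward
   block are applied in parallel to the same input and summed (config
   `transformer_block = sequential` restores the conventional residual
   ordering).  Head outputs are concatenated and projected back to 64.

The encoder output is `λ·transformer + (1−λ)·mixed` with λ fixed at 0.8,
followed by dropout (rate 0.3) during training only.

## NCF decoder

For a pair (r, d): drug and disease embeddings are linearly projected to
a common interaction dimension (64), multiplied element-wise and
L2-normalized per pair (guard ε = 1e-12 returns the zero vector for an
all-zero product).  Neighbour embeddings h̃_r, h̃_d are
similarity-weighted means over Ñ_k projected to 32 dimensions.  The
decoder input concatenates (interaction, interaction, h̃_r, h̃_d) — the
interaction block is deliberately duplicated, matching the published
pair-vector layout; a `duplicate_interaction` flag collapses it in case
the duplication is a typographical artefact.  The MLP has ReLU hidden
layers (64, 32) and a sigmoid output, with the output bias initialized to
the logit of the positive base rate — the standard companion of the focal
loss under heavy imbalance, so early training is not spent relearning the
marginal.

Ablations: `use_transformer=False` removes the transformer path (λ
effectively 0); `use_ncf=False` omits the neighbour- and
interaction-embedding steps and feeds the two concatenated encoder
representations (2 × 64) directly to a decoder of matching width.  The
interaction embedding is defined as the element-wise product step, so the
faithful "without NCF" bypass cannot itself contain a product; the
concatenation is the leanest pair-level input that remains.

## Training

The objective is an equally weighted sum (configurable) of four terms
over the training pairs: binary cross-entropy, focal loss
(−α(1−p)^γ log p for positives and the symmetric −(1−α)p^γ log(1−p) for
negatives; α = 0.5, γ = 2), mean squared error, and a pairwise margin
ranking loss (margin 1.0) between observed-pair scores and one unobserved
pair sampled per positive per epoch.  Predictions are clamped to
[1e-7, 1 − 1e-7] before logarithms.  Training pairs are every cell of the
training split: observed associations are positives and all unobserved
cells are negatives, with no subsampling — at benchmark sizes the full
matrix is tractable and the focal term exists precisely to absorb the
imbalance.

Optimization is full-batch Adam at base learning rate 5e-4 with a
triangular cyclic schedule between 5e-5 and 5e-4 (cycle 20 epochs,
starting at the upper bound).  Library defaults run up to 300 epochs with
early stopping on validation AUPR (patience 30, 10% stratified split);
setting `patience=None` disables the split and runs a fixed budget.  All
randomness — initialization, validation split, ranking-loss negative
sampling, dropout — derives from one integer seed through separate
generators, so runs replay exactly.

## Synthetic data generator

The generator emulates the statistical shape of the public benchmarks: a
sparse bipartite association matrix flanked by two informative similarity
matrices.  Drug factors U (n × r) and disease factors V (m × r) are
standard normal; association propensity is the logistic of U·Vᵀ/√r, and
the positives are exactly the top `density` fraction of propensities
(ties broken by cell index), so the positive count is deterministic.
Similarities are shifted cosines of the factor rows mapped to [0, 1]
with symmetric Gaussian noise (stddev `similarity_noise`) added off the
unit diagonal, clipped to [0, 1].  Defaults — 50 drugs × 40 diseases,
rank 4, density 3%, noise 0.05 — are the desk-scale study conditions used
by the tests and the acceptance script.

What the generator does not emulate: the heavy-tailed degree
distributions, block structure and non-linear similarity semantics of
real chemical/phenotypic data, or similarity matrices that are
uninformative about associations.  Passing the recoverability tests
therefore shows the pipeline can exploit side information tied to a
planted low-rank mechanism; it does not certify performance on real
benchmarks.

## Evaluation

Folds stratify all n × m pairs by label into ten near-equal parts; a
fold's positives are zeroed in the training adjacency and its cells are
excluded from the training pairs, while similarity edges are never masked
(side information, not labels).  AUROC and AUPR are micro (flattened pair
set, scikit-learn implementations; AUROC equals the Mann–Whitney
statistic).  Accuracy, precision and recall use pooled confusion counts
at threshold 0.5 (configurable); F1 is macro-averaged over diseases.
Zero-denominator ratios are 0 by convention and logged.  Candidate
ranking sorts a disease's column of the score matrix descending with ties
broken by drug identifier; known associations are excluded by default in
the discovery setting.

## Experiment sizes and numerical choices

Fixture-scale experiments (tests and the acceptance script) run 500
epochs per fold with early stopping disabled: at ~5 positives per
validation split the early-stopping signal is noise, and a fixed budget
keeps runs deterministic and comparable across model variants.  The
recoverability experiment uses three seeds (0–2); the label-permuted null
is summarized over all 30 fold values because a single fold holds only
~6 positives and its null AUROC has a standard deviation of roughly 0.12.
Each seed draws an independent permutation: a single permutation's
drug/disease marginals (some drugs receive several permuted positives)
are partially learnable by a model with per-node parameters, which biases
a one-permutation null upward; independent permutations average most of
this out, though a small positive residual (a few hundredths of AUROC)
can remain.

Known limitations: convergence of the full NCF head is slower than the
ablated variants at desk scale (the per-pair L2 normalization discards
the product magnitude, which on a planted low-rank mechanism is the
dominant signal), so fixed-budget comparisons at small n can favour the
concatenation bypass on AUPR; CPU-only full-batch training scales
quadratically in node count through the attention mask and is intended
for benchmark-sized problems (≤ ~800 nodes per type), not genome-scale
graphs.
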