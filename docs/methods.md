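# Methods

## Model and assumptions

The method rests on two assumptions. First, a gene set is *enriched* for
a phenotype contrast exactly when some mapping of its expression values
separates the phenotypes in a latent space — enrichment is equated with
discriminability, which turns GSE analysis into one classification task
per gene set. Second, each phenotype's latent distribution within a gene
set is a mixture of Gaussians, whose centers (the prototypes) and
variances are learned. The second assumption is what makes the model
interpretable: classification happens by proximity to explicit latent
points that can be plotted next to the cells they represent, rather than
by an opaque decision boundary.

The network is a shared multilayer backbone over masked expression plus
a linear per-set head, giving every gene set its own latent space while
sharing encoding knowledge across (potentially overlapping) sets. The
activation (tanh) is applied after every backbone layer; heads are
linear. Similarities, per-set posteriors and the aggregated prediction
are as given in the README. Numerical safeguards: the Gaussian exponent
is clamped at −50 before exponentiation (similarities stay strictly
positive in floating point), probabilities are floored at 1e-12 inside
logarithms, ties in nearest-prototype minima resolve to the lowest
index, and the variance used in a similarity is that of the
distance-minimizing prototype.

Class priors η_k are fixed to the empirical phenotype frequencies of
each training split, not learned — they are population proportions, not
model parameters. Aggregation weights ω_j are kept positive via a
softplus parameterization; ω₀ is unconstrained. Prototype variances are
learned as log σ² (initialized to 0, i.e. σ = 1).

## Training

The objective is λ₁L_clf + λ₂L_f + λ₃L_p2p + λ₄L_c2p + λ₅L_p2c:
per-set classification cross-entropy, final-prediction cross-entropy, a
prototype-separation hinge at minimum distance d_min = 1, a
cell-to-nearest-own-class-prototype pull, and a
prototype-to-assigned-centroid pull (ε = 1e-16 guards empty assignment
sets). Cross-entropy terms that sum over gene sets divide by the number
of cells only, so a T-set model contributes T per-set losses. Two
details are deliberate choices where the formulation was open:

- The separation hinge counts ordered pairs l ≠ t only. Including l = t
  pairs would add a constant d_min² with zero gradient and make the term
  non-vanishing even for a single prototype, contradicting its purpose
  (encouraging pairwise separation); with B = 1 the term is identically
  zero.
- In the unlabeled regime the assignment sets behind L_p2c are
  recomputed each minibatch from the current embeddings, and no gradient
  flows through the assignment itself (it is constant within a step);
  this keeps the term stable under the discrete argmin.

With per-cell biological labels (cell types), B becomes the number of
labels, the separation hinge is replaced by a cross-entropy that
predicts the label from prototype-assignment probabilities, the
cell-to-prototype pull targets the (phenotype, label)-indexed prototype
with no minimum, and assignment sets are defined by the labels.

Training is two-stage: stage 1 optimizes backbone, heads, prototypes and
variances with λ₂ forced to 0; stage 2 freezes them (verified bitwise in
the tests) and tunes only ω₀..ω_T, so the aggregation is fitted on
well-trained per-set encoders. A config flag allows joint fine-tuning in
stage 2 for ablations. Before stage 1, one warm-up epoch trains the
encoder alone and prototypes are then placed at the latent centroids of
their (phenotype[, label]) groups — random initialization can leave
prototypes dead in empty regions. Optimization is Adam; defaults are
learning rate 1e-3, batch size 128, 50 + 20 epochs, λ = (1, 1, 0.1,
0.1, 0.1). The λ defaults make classification dominant with mild
geometric regularization; when the goal is cleanly clustered latent
spaces for visualization (as in the labeled-mode demonstrations), larger
geometry weights (λ₃–λ₅ around 0.5–1) organize the space faster. No
early stopping by default — it would break run-to-run determinism.

Folds are stratified by phenotype (by (phenotype, label) pairs when
labels are present and every pair supports K folds); K = 1 means a
single stratified 80/20 split. Per-fold seeds derive from the run seed
via `SeedSequence` spawn keys; an identical configuration and seed
reproduces every output byte-for-byte on CPU.

The network and its training are implemented directly on NumPy with a
small reverse-mode autodiff engine (`protogsea._autograd`) providing
exactly the required operator set; its gradients are validated against
central finite differences in the test suite.

## Significance testing

Per class k, the one-sided Mann–Whitney U test compares held-out
similarity scores s_j[k] of class-k cells against all others
(alternative: class-k cells score higher). The test statistic satisfies
U/(n₁n₂) = auROC, aligning the test with the training objective. The
implementation uses the exact permutation distribution when n₁+n₂ ≤ 12
without ties and the tie-corrected normal approximation with continuity
correction otherwise; the two agree within 0.02 absolute for moderate
sizes. Tests use the raw similarities, not the posteriors: because η and
the selected σ vary across cells, the posterior is not a monotone
transform of the similarity across cells, so the two are not
rank-equivalent — the similarity, as the density estimate, is the
quantity the model was trained on.

Per-class p-values share one null hypothesis (equal mean ranks) and are
combined by Fisher's method (χ² with 2C df on −2Σ ln p, driven by the
smallest p). Fold-level p-values are combined by Pearson's method (χ²
with 2K df, lower tail, on −2Σ ln(1−p)), chosen for its sensitivity to
the *largest* p: a set is only called enriched if every independently
trained fold found it so. Benjamini–Hochberg correction is applied to
the across-fold combined p-values, one per gene set. p-values are
floored at 1e-300 before logs and combined values clipped to [0, 1].

To avoid overpowered tests on very large datasets, each fold's test uses
a single seeded draw of at most 500 held-out cells per phenotype
(configurable); when classes are smaller than the cap, this is a no-op.

For C = 2 the two per-class p-values are strongly dependent (the two
similarity columns order cells near-oppositely), so Fisher's
independence assumption is conservative-to-neutral territory rather than
exact; the null calibration of the full pipeline is therefore checked
empirically (see below) rather than assumed.

## Synthetic data

The generator emulates the standard gamma-Poisson single-cell scheme:
gene baseline means ~ Gamma(shape 0.6, rate 0.3); cell library sizes
~ LogNormal(ln 10⁴, 0.2); counts negative binomial (dispersion 0.5) with
mean libsize × normalized per-group gene mean. The defaults — 1000
cells, 2000 genes, two equal groups, a 100-gene enriched set with DE
probability 0.5 and factor law exp(N(1, 0.4²)) applied up- or
down-ward with equal probability, and a disjoint 100-gene irrelevant
set — constitute the standard design used throughout the tests and the
acceptance script; sweep drivers vary DE factor location, DE
probability, cell number and class balance. A factor location of 0
still yields factors ≠ 1 (the law is log-normal around 1), i.e. subtle
but real DE. Optional latent subpopulations add their own expression
factors on the enriched set in both groups, producing the multi-cluster
structure used to exercise cell-type-informed training.

Deliberately not modeled: zero-inflation/dropout beyond NB sampling,
batch effects, trajectories, and gene-gene correlation beyond the
library-size coupling. Passing tests on these data therefore demonstrate
the statistical machinery and the optimization, not robustness to the
full noise structure of real droplet data. All draws flow from one seed
through named substreams (means, DE, groups, library sizes, counts,
subpopulations).

## Problem sizes used in the checks

The automated checks run the full pipeline at the standard design size
(1000 × 2000) with a compact encoder (one 64-unit hidden layer, h_dim
32, z_dim 8), two folds and 8 + 3 epochs — a configuration that trains
in roughly two seconds per dataset and is already saturated on the
design's signal strength (held-out accuracy ≈ 1.0). The pure-null
specificity check uses 50 background sets of sizes 20/50/100 and a
smaller encoder. The interpretability check uses 400 cells, 500 genes,
two subpopulations, z_dim 2 and stronger geometry weights.

## Known limitations

- Enrichment direction is not reported; the test is two-group
  discriminability per class with a fixed "own class scores higher"
  alternative.
- The latent Gaussian-mixture assumption can be violated by strongly
  non-elliptic subpopulations; B must be chosen (or provided via labels)
  rather than inferred.
- On very small or strongly unbalanced datasets the discriminability
  criterion can latch onto spurious correlations; the fold-consistency
  (Pearson) combination mitigates but does not remove this.
- Checkpoints store dense parameter arrays; very large gene-set
  collections (thousands of sets) are better scored in batches of sets.
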