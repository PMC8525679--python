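# Methods

## Model and pipeline

`metprio` ranks candidate disease–metabolite associations for one focal
disease per run. The statistical premise is that similar diseases relate
to similar metabolites, so association signal should be recoverable from
the topology of two similarity networks:

* **Metabolite network.** Nodes are metabolites; the edge weight between
  i and j is the cosine of their chemical-descriptor vectors. Cosine is
  scale-invariant, so descriptor columns are used raw (no normalization by
  default); columns constant across all metabolites are dropped because
  they contribute a rank-one offset that inflates all similarities without
  discriminating pairs. The network is kept fully dense — no evidence
  supports any particular sparsification cutoff, though `min_similarity`
  can zero weak edges and `clamp_negative` can floor negative cosines.
* **Disease network.** Consumed as a precomputed similarity table (e.g.
  SemFunSim scores). The builder keeps the focal disease plus every
  disease paired with it; any supplied pair between included nodes becomes
  an edge, absent pairs get weight 0, and the diagonal is 1. A
  focal-vs-others table therefore yields a star; richer tables yield
  denser graphs, which only helps propagation.

### GCN encoding

Both networks are encoded with the propagation rule

    H^(l+1) = σ(S H^(l) W^(l)),    S = D^(−1/2) A D^(−1/2),   D_ii = Σ_j A_ij,

where S is the symmetric degree-normalized adjacency underlying
L_sym = I − S. No A + I self-loop augmentation is applied: a cosine
similarity network's diagonal already equals 1, so self-loops are built
in. Initial features default to X = A (each node's similarity profile);
one-hot features are available via `init_features="identity"`.

No supervision exists at encoding time, so the encoder trains as a
**graph autoencoder**: the inner-product decoder σ(h_i·h_j) is fit by mean
binary cross-entropy against the adjacency min-max rescaled to [0, 1].
This keeps the embeddings label-free, consistent with the pipeline order
encode → PCA → SVM. An `objective="untrained"` mode (pure propagation with
fixed random weights) is kept for ablation.

Defaults: 2 layers, hidden width 128, embedding width 64, tanh between
layers, linear output, 200 epochs of full-batch Adam at learning rate
0.01, Glorot-uniform initialization from a single integer seed. All are
configurable; none are dictated by the method. The hidden activation is
tanh rather than ReLU for a numerical reason: with an inner-product
decoder, Z = 0 is an exact stationary point, and on near-uniform graphs
(e.g. a no-signal similarity matrix) full-batch Adam can drive every ReLU
unit exactly dead, collapsing the embedding to a bit-exact constant matrix
that the downstream PCA must reject. tanh cannot die exactly, keeps the
degenerate regime well-posed, and performs identically on structured
graphs. Training raises immediately if the loss stops being finite, with
the advice to lower the learning rate.

Networks of any size ≥ 2 are encoded with the same machinery, including
tiny disease stars.

### PCA

Embeddings are compressed by SVD: X = U Σ Vᵀ, scores Y_r = U Σ_r, with r
the smallest count whose cumulative squared-singular-value fraction
reaches the variance threshold (default 0.99). Columns are mean-centered
first — retained-variance semantics presuppose centering — and
`center=False` reproduces the raw truncated SVD. Each component's sign is
fixed so its largest-magnitude loading is positive, removing the SVD sign
ambiguity for bit-reproducibility. Metabolite and disease embeddings are
reduced independently.

A note on double reduction: applying the reduction to its own output at
the same threshold is an identity (up to column signs) whenever the first
pass overshoots the threshold, i.e. frac_{r−1} < threshold · frac_r. This
holds for the low-effective-rank spectra GCN embeddings produce; for a
near-flat spectrum that barely clears the threshold, a second pass may
legitimately drop one tail component.

### Pairing, SVM and evaluation

A pair's feature vector is the concatenation of the focal disease's
reduced features and the metabolite's (element-wise product available via
`combine="product"`). Positives are all known focal associations;
negatives are sampled without replacement at `ratio` × positives (default
1:1) from the SP pool (metabolites associated with non-focal diseases,
minus focal positives — a strict set difference) or the SM pool
(metabolites with no known association). The classifier is an RBF-kernel
SVM (C = 1, gamma = "scale") on per-fold standardized features; the
standardizer is fitted on training folds only, so no information leaks
into held-out scores. Evaluation is stratified k-fold (default k = 10)
reporting per-fold and pooled AUC/AUPR; the pooled variant (metrics on
the concatenation of held-out scores) is the headline number because
per-fold metrics are noisy at these sample sizes. The final model is
trained on all pairs and scores every non-positive metabolite; ranking
ties break lexicographically by metabolite id, and scores above the SVM
margin (decision value > 0) are flagged "predicted associated".

## Randomness and determinism

One integer seed per run. Child seeds for weight initialization (one per
network), negative sampling, and fold shuffling are derived through
`numpy.random.SeedSequence`, so stages are decoupled: changing k does not
alter the negative sample, for example. All outputs (JSON with sorted
keys, TSV with fixed float formatting, no timestamps) are byte-identical
across reruns of the same config.

## Synthetic data generator

The generator emulates the statistical structure the method needs, not
chemistry. Metabolite descriptor vectors are isotropic Gaussian blobs:
coordinates are `baseline_offset` + centroid + unit noise, with centroid
coordinates drawn N(0, `cluster_separation`²). Under this scaling the
expected within-cluster cosine is ≈ sep²/(sep² + 1) independent of
descriptor width, so separation 4 gives a strong block structure (~0.94)
and separation 0 gives exactly no structure. The positive
`baseline_offset` (default 2) mirrors the predominantly nonnegative scale
of real chemical descriptor tables; it keeps all pairwise cosines — and
hence all weighted degrees — positive even in the no-structure regime,
where zero-mean blobs would produce an (correctly rejected) ill-posed
normalization.

Cluster 0 is focal-associated: its members are the positives, with each
metabolite's focal-association indicator flipped with probability
`assoc_noise`. Middle clusters are assigned round-robin to non-focal
diseases (forming the SP pool); the last cluster stays unassigned (the SM
pool). The disease table is a focal-centered star with similarities drawn
uniformly from `focal_similarity_range`.

Defaults — 200 metabolites, 100 descriptors, 4 clusters, separation 4,
no label noise, 4 diseases, similarity range (0.3, 0.9) — give 50
positives, a 100-metabolite SP pool and a 50-metabolite SM pool: small
enough for fast cycles, large enough for stable 10-fold metrics. A
`--padel-scale` flag widens descriptors to 2,325 columns, the width of a
full PaDEL-Descriptor vector.

What the generator does **not** emulate: descriptor correlation structure
and fingerprint bit distributions, heavy-tailed descriptor scales,
many-to-many disease–metabolite incidence, or biased/missing association
labels. Passing the synthetic benchmarks therefore demonstrates that the
pipeline is implemented correctly and recovers planted topology-correlated
signal at realistic sample sizes — not that it attains any particular
accuracy on real descriptor/association data.

## Numerical choices and edge cases

* Cosine matrices are symmetrized ((M + Mᵀ)/2) and the diagonal forced to
  exactly 1 to cancel floating-point asymmetry before the symmetry
  invariant (1e−10) is asserted.
* Zero-norm descriptor rows, non-positive weighted degrees, constant
  (zero-variance) embedding matrices, single-class training sets, empty
  candidate sets, and k above the minority class count all raise typed
  errors naming the offending entity; the CLI maps them to exit code 3.
* Missing descriptor values are rejected by default; column-mean
  imputation is opt-in.
* The permutation-null and pure-noise checks in the test suite use means
  over seed banks (20 fixture seeds, 100 permutations) because individual
  small-sample AUCs have standard deviation ≈ 0.05–0.07.

## Problem sizes used in tests

The test suite and the acceptance script run the full pipeline at the
generator defaults (200 metabolites, 100 descriptors, 100 pairs per mode)
and brute-force oracles at n ≤ 10; the whole suite completes in a couple
of minutes on one CPU. These sizes were chosen as the smallest at which
the evaluation statistics are stable.

## Known limitations

* The GCN is dense and full-batch: fine up to a few thousand nodes,
  inappropriate beyond (no minibatching, sampling, or GPU path).
* The trained objective is reconstruction, not link prediction against
  held-out associations; embeddings are generic topology summaries.
* One focal disease per run; multi-disease prediction is out of scope.
* The "predicted associated" cutoff (decision score > 0) is the SVM
  margin, not a calibrated probability threshold.
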