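# Methods

## Model

`scmosaic` fits a multimodal variational autoencoder to single-cell data in
which each cell carries any nonempty subset of three assays: RNA counts,
chromatin accessibility (ATAC fragment detections) and surface-protein counts.

**Observation models.** For cell *c*:

- RNA: `x_cg ~ NegBin(mean = l_c^R · rho_cg, inverse dispersion theta_g)`.
  `rho_c·` lies on the gene simplex (softmax decoder); `theta_g > 0` is a
  free per-gene parameter (`exp` of an unconstrained tensor); `l_c^R` is the
  observed per-cell total RNA count, fixed rather than learned.
- ATAC: the raw fragment count is binarized at `count > 0` and modelled as
  `y_cj ~ Bernoulli(l_c^A · p_cj · r_j)`. `p_cj ∈ (0,1)` is the decoded
  biological accessibility (sigmoid), `r_j ∈ (0,1)` a free region-specific
  detection factor shared by all cells (sigmoid of a J-vector), and
  `l_c^A ∈ (0,1)` a cell-specific detection factor produced by a sigmoid head
  on the ATAC encoder.
- Protein: a two-component negative-binomial mixture
  `x_cp ~ pi1 · NB(l_c^P·beta, theta^b) + (1-pi1) · NB(l_c^P·alpha·beta, theta^f)`
  separating ambient background from specific foreground signal. `beta`
  (exp), `alpha ≥ 0` (softplus) and `pi1 ∈ (0,1)` (sigmoid) are decoded per
  (cell, protein); the dispersions are free per-protein parameters. `l_c^P`
  is the observed per-cell total protein count scaled to mean 1 over
  protein-observed cells, fixed.

The cell-scaling choices resolve an ambiguity in how the single symbol `l_c`
is used across the three likelihoods: a `[0,1]`-valued network output only
makes sense for the Bernoulli factorization, while RNA means must live on the
count scale. We therefore fix the RNA and protein factors to observed library
sizes (point estimates computed from data) and learn the ATAC factor with a
sigmoid encoder head.

**Latent space and fusion.** Each observed modality has its own encoder
(2-layer MLP, width 128, layer norm, ReLU, dropout 0.1 by default) producing
a diagonal-Gaussian posterior `q(z^m | x_m, s)` with softplus-parameterized
variance (floor 1e-4); `s` is a one-hot batch covariate appended to the
input. The per-modality posteriors are fused by a convex combination whose
weights are renormalized over the modalities observed in each cell:

- `equal` (default): `w_m = 1/|observed|`;
- `global`: one learned weight per modality shared by all cells;
- `per_cell`: a learned scalar head per encoder, softmaxed over the cell's
  observed modalities.

Both the fused mean and the fused variance use the same weights, so the fused
object remains a valid diagonal Gaussian; a cell with a single observed
modality passes its posterior through unchanged. Precision weighting or
resampling were the alternatives; convex averaging was chosen because it is
the literal "average of representations" and keeps single-modality cells
exact.

**Objective.** The ELBO per minibatch decomposes into (i) reconstruction
negative log-likelihood per modality, computed only over each cell's observed
modalities (a masked modality contributes exactly zero — multiplicatively
masked, not approximately); (ii) KL to the N(0, I) prior for each observed
modality posterior; (iii) a consistency penalty over every pair of
modalities observed together in a cell — by default the Jeffreys divergence
(symmetric KL) in its diagonal-Gaussian closed form, alternatively an
RBF-kernel MMD on reparameterized posterior samples with median-heuristic
bandwidth; (iv) optionally, a negated adversarial cross-entropy (below).
Decoding uses a single reparameterized draw from the fused posterior per
cell per step; evaluation-time ELBOs decode at the posterior mean so the
early-stopping criterion is deterministic.

**Adversary.** A two-hidden-layer classifier (width 32) predicts a grouping
from the fused latent mean; its cross-entropy enters the model loss with a
negative sign (weight `adversarial_weight`), and the classifier itself is
updated on detached latents after every model step (alternating updates, no
ramp). The grouping defaults to the cell's modality-availability pattern —
the quantity whose separation the latent space should not encode — and can be
switched to the batch key; both groupings are useful in practice, so both
are exposed.

## Training

AdamW (betas 0.9/0.999, eps 1e-8 — standard values), learning rate 1e-4, weight decay 1e-3, minibatch 128. 90/10
train/validation split (simple random, `round(0.1·N)` floored at 1), at most
500 epochs, early stopping after 50 epochs without improvement of the
validation reconstruction loss — defined as the summed negative
log-likelihood of observed modalities, penalty terms excluded. The KL weight
ramps linearly as `min(epoch/50, 1)`. Training is bit-reproducible from the
two seeds (model init, shuffling/sampling) on a single thread. A non-finite
loss aborts training and restores the best parameters seen.

The networks run on a small reverse-mode automatic-differentiation engine
(`scmosaic._autograd`, numpy/float64) providing exactly the operator set the
model needs, including a `gammaln` primitive (digamma gradient) for the
negative-binomial terms; gradients are verified against finite differences in
the test suite.

## Inference

- **Latents**: fused posterior means, or one row per observed modality per
  cell (for rank-distance evaluation).
- **Imputation**: n = 15 draws from each cell's *fused posterior* (rather
  than the prior: the fused posterior keeps imputation cell-specific),
  decoded and
  summarized by mean and standard deviation per feature. RNA is returned as
  normalized frequencies, ATAC as accessibility probabilities, protein as the
  denoised foreground mean `(1-pi1)·l·alpha·beta` with the mixture components
  attached. Decoding uses the cell's own batch unless a transfer batch is
  requested.
- **Uncertainty calibration**: entries are pooled, binned by uncertainty
  decile, and the Spearman correlation between bin rank and bin mean squared
  error is reported.

## Differential analysis

The model route samples `n_pairs` (default 10,000) cell pairs — one cell
uniformly per group, one latent draw from its posterior — decodes normalized
values, and estimates `p = P(value_a > value_b)` ("vanilla") or
`p = P(|log2 FC| > delta)` ("change", default `delta = 0.25` log2, with a
1e-4 pseudocount). The Bayes factor is `ln(p/(1-p))`; the FDR rule sorts `p`
descending and rejects the longest prefix whose running mean of `(1-p)` stays
at or below the target (the posterior expectation of the FDR). `pi1` is
decoded per (cell, protein) rather than treated as a global point estimate —
the per-cell version lets the mixture adapt to cell state.

The held-out route normalizes RNA by per-cell totals and ATAC by TF-IDF
(term frequency = detection indicator / per-cell detected count; IDF =
`log(1 + C/(1+df))` — the name covers several dialects; this one is fixed and
used consistently), then applies the two-sided Wilcoxon rank-sum test with
Benjamini–Hochberg adjustment (zero-variance features get p = 1).
Concordance between routes is summarized by overlap fractions, hypergeometric
fold enrichment and effect-size correlation across thresholds.

## Evaluation metrics

All KNN computations are exact (brute force), Euclidean, exclude self, and
break ties by ascending cell index. LISI enrichment is the mean same-label
neighbor fraction divided by `sum_l p_l^2`. Rank distance is the minimal K at
which a cell's counterpart representation enters its K-NN, searched in the
union of both representations' point sets (the union is the convention
here — deterministic and the strictest reading); a symmetrized
`max(delta_ab, delta_ba)` variant is exposed. Smoothing references: ATAC via
TF-IDF → truncated SVD (30 components by default, overridable) →
neighbor-mean binary profile with k = 50; RNA via PCA on log1p of library-scaled counts →
neighbor-mean library-scaled expression.

## Synthetic data

The generator samples from the model's own generative process: cell-type
centroids in a 10-dimensional latent space (scale 3.0 vs unit within-type
noise), fixed random two-layer tanh maps from latent position to feature
logits (random *nonlinear* maps, so a fitted model cannot trivially invert a
linear generator), per-batch additive logit shifts (sd 0.3), and counts drawn
exactly per the three observation models (RNA library sizes lognormal with
mean 2,000 and sd 0.3 in log space; region factors Beta(4,2); cell detection
factors Beta(8,2); protein background mean 8 with a 0.4 background mixture
weight). The standard fixture is 2,000 cells × (200 genes, 500 regions,
20 proteins), 4 types, 2 batches, seed 0.

The two-population DE benchmark (`simulate_de_pair`) deliberately sets the
type separation to zero and plants all group signal as multiplicative fold
changes on 20 genes (default 4-fold), split between up- and down-regulated
sets whose probability masses are balanced exactly in expectation, so that
non-planted genes are genuinely null rather than inheriting a compositional
fold change from the softmax renormalization. Within-population
heterogeneity uses a reduced map scale (0.5) so that finite-sample group
differences of null genes stay well below the `delta = 0.25` detection
threshold; 600 cells per replicate.

What the generator does **not** emulate: real marker-gene structure, genomic
peak coordinates and co-accessibility, doublets, ambient RNA contamination,
batch effects that change library-size distributions, or protein panels with
isotype controls. Passing the recovery benchmarks therefore demonstrates
that the estimator inverts its own generative assumptions at realistic noise
levels — not that it resolves real-data artefacts outside those assumptions.

## Benchmark problem sizes

The repository's self-checks run end-to-end at desk scale: the
masked-modality imputation benchmark trains on the 2,000-cell fixture with
ATAC hidden for half the cells (up to 450 epochs, patience 50 — the
validation loss on this fixture typically improves throughout) and scores
imputed accessibility against the generator's true probabilities at
cell-type pseudobulk level; it also reports the uncertainty calibration —
the decile-level Spearman correlation between the Monte-Carlo sd and the
squared error against the generator's true probabilities (against raw binary
observations the Bernoulli sampling noise flattens the decile profile at
this data scale, so the truth oracle is the informative readout). The DE
benchmark runs 20 replicates of the 600-cell planted-DE simulation with the
full 500-epoch schedule. These sizes
are the package's standard configuration for its own validation; larger runs
scale linearly in cells × features.

## Known limitations

- The split between biological accessibility `p` and the detection factor
  `r` is identified only through regularization; at region level the model
  may trade one for the other, which is why detection-scale agreement
  (`p·r`) is also reported by the benchmarks.
- Per-cell mixing weights are a learned head on each encoder, which is one
  of several reasonable readings of "cell-specific learnable weights".
- The numpy engine is single-threaded and keeps dense minibatches; it is
  intended for datasets up to a few tens of thousands of cells, not
  atlas-scale corpora.
- The posterior-expectation FDR rule can admit a few moderate-probability
  features once many near-certain features fill the rejection set; the DE
  benchmark measures the realized (empirical) FDR rather than assuming the
  nominal level.
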