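# Methods

## Model

`netswarm` treats directed gene–gene influence estimation as a supervised
ensemble problem. Given a genes × samples matrix of log-scale expression
values, the method builds a *swarm* of small feed-forward networks: for each
Monte Carlo resample of the samples and each gene taken in turn as the
output, one single-hidden-layer perceptron is trained to predict that gene's
expression from all remaining genes. The ensemble replaces a single deep
model on explainability grounds: each member is small enough that its input
gradient is a meaningful, directly interpretable readout of how each
predictor gene drives the output gene.

The member network is

    yhat_j = W2' * act(W1' * x_{-j} + b1) + b2,     act in {tanh, linear}

trained by full-batch gradient descent on mean-squared error with classical
momentum, an L2 penalty on the weights (biases unpenalized), and early
stopping on the resample's held-out validation split (the returned parameters
are the best-validation snapshot). Full-batch descent was chosen over
stochastic variants because the intended inputs have tens of samples, where
batching buys nothing, and a deterministic trajectory makes bit-exact
reproducibility trivial.

**Influence.** The influence of input gene *i* on output gene *j* in one
member is the network's output gradient with respect to input *i*, averaged
over the training rows. For the linear activation this is exactly the weight
product `sum_h W1[i,h] * W2[h]`, independent of the data; for tanh it is the
data-weighted linearization. Gradients, not raw weights, are used because
they reduce to the weight-product reading in the linear case while remaining
well defined for saturating activations.

**Standardization.** Before each fit, all genes (inputs and output) are
z-scored using statistics of the training split only, applied unchanged to
the validation split. This puts every influence on the scale of "standard
deviations of gene *j* per standard deviation of gene *i*", which the
cross-gene ranking requires; constant-on-train genes pass through centred
with unit divisor.

**Integration.** Per-resample G × G matrices (diagonal forced to zero; both
edge orientations kept — they come from different models and are never
symmetrized) are aggregated element-wise: mean influence, sample standard
deviation across resamples, and sign consistency — the fraction of resamples
whose entry shares the sign of the mean (defined as 0 where the mean is 0).
Sign consistency is ~1 for stable edges and ~0.5 for noise, which makes it a
natural edge filter for export.

**Ranking.** Driver score = row L1 norm of |mean influence| (aggregate
outgoing), target score = column L1 norm (aggregate incoming). L1 was chosen
over L2 or max because it rewards both many moderate links and a few strong
ones and is stable on the standardized scale; ties are broken by ascending
gene id so every ordering is reproducible. Strongest-edge extraction sorts
off-diagonal entries by |mean influence| with a sign-consistency floor.

## Resampling

Monte Carlo cross-validation: `n_resamples` independent uniform splits of the
samples, `floor(n * train_fraction)` for training and the rest for validation
(defaults 25 and 0.8). Resampling is over samples only — subsetting genes
would leave influence entries undefined on some resamples. Defaults are the
package's own; 25 resamples is where the aggregate matrices stabilize at
desk scale while keeping a 30-gene run under a minute.

## Reproducibility and seeding

Every member's initial weights are drawn from a stream keyed by
`(base seed, resample index, crc32(output gene id), crc32(input gene id))`
via numpy `SeedSequence` spawn keys. Keying on gene *identities* rather than
matrix positions makes the whole inference equivariant under gene
permutation: reordering the input matrix's rows permutes all result matrices
identically (to one ULP, from re-ordered floating-point sums). It also makes
the loop order irrelevant, so parallel execution cannot change results. The
pipeline writes a manifest with the full configuration, the seeds, the seed
derivation rule and SHA-256 checksums of every output; runs with identical
configurations are byte-identical (gzip members are written with a zeroed
timestamp for this reason).

## Training hyperparameters

| parameter | default | notes |
|---|---|---|
| n_hidden | 2 | smallest width that can express non-additive structure; the unit stays interpretable |
| activation | tanh | bounded, smooth; `linear` exposes the closed-form regime |
| learning_rate | 0.05 | stable for z-scored inputs at desk-scale collinearity |
| momentum | 0.9 | classical momentum; accelerates the ill-conditioned directions |
| l2_penalty | 1e-3 | mild shrinkage against the p ≈ n regime (tens of samples, tens of genes) |
| max_epochs / patience | 400 / 30 | early stopping usually triggers long before the cap |
| init_scale | 0.5 | uniform(-s, s) weight initialization |
| early_stopping | on | off = train to convergence and return the final epoch |

The `early_stopping` switch exists because the two uses of the trainer pull
in opposite directions: inference wants the generalizing best-validation
snapshot, whereas the linear-regime equivalence check (below) requires full
convergence — a best-validation snapshot deliberately returns shrunken
weights for weak-signal genes, which is correct regularization but not
convergence.

## Synthetic benchmark

The generator plants a random DAG (uniform random topological order, edges
drawn without replacement among order-compatible pairs) with weights of
magnitude uniform in [0.8, 1.5], negative with probability 0.2 by default.
Expression follows a linear-Gaussian structural model: root genes are
standard normal per sample, every other gene is the weighted sum of its
parents plus Gaussian noise (default sd 0.5), evaluated in topological
order; group contrasts are additive mean shifts on chosen genes. This is the
simplest model under which the swarm's influence has a closed-form oracle —
ordinary least squares of each gene on all others — enabling exact
equivalence tests. The DAG restriction applies to generation only; the
inference engine makes no acyclicity assumption.

What the simulator deliberately omits: count noise (no negative-binomial
layer), library-size and batch effects, nonlinear regulation, feedback
cycles, and the >10,000-transcript scale of real arrays. Passing benchmarks
therefore show that the estimator recovers linear directed structure from
realistic sample counts — not that it resolves real regulatory biology,
where unmodeled confounding and scale dominate.

Reference benchmark conditions (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`): 30 genes, 15 planted edges, 60 samples, noise sd
0.5 (0.25 for the sign-recovery reading), 25 resamples — sized so the whole
benchmark suite runs in about a minute on one CPU. Recovery is summarized as
AUROC over all ordered gene pairs scored by |mean influence|, counting a
pair positive if either orientation was planted (an undirected correlation
footprint is visible both ways), plus the fraction of planted edges whose
inferred influence carries the planted sign. The linear-regime check uses a
10-gene chain with weight 0.7 and noise sd 1.0 — chosen so every
all-but-one regression is well posed and well conditioned — with one hidden
unit, linear activation, zero penalty, early stopping off, 1000 epochs, 25
resamples at train fraction 0.9; the worst column-wise relative error
against the OLS oracle is reported (≈2–5%, dominated by subset-vs-full-data
OLS spread, not by optimization error).

## Differential-expression prefilter and inclusion rule

The file reader rejects matrices with fewer than `min_transcripts` genes
(default 10,000), mirroring the dataset-inclusion rule of the study design
this pipeline serves; desk-scale synthetic runs override it explicitly. The
prefilter keeps the `n_keep` genes with the smallest Welch p-values between
the two groups (or the largest variances, for designs without two groups);
ties break by gene id and survivors keep their original order. The method is
configurable because no single differential-expression procedure is
canonical at this stage; Welch is the default for two-group designs.

## qPCR arithmetic

Relative quantification follows the comparative-Ct method: per sample,
ΔCT = Ct(target) − mean Ct over the reference genes; ΔΔCT subtracts the
calibrator group's mean ΔCT; RQ = 2^−ΔΔCT. Multiple reference genes are
averaged on the Ct scale, which generalizes the single-housekeeper design.
Two identities are enforced by tests: the calibrator group's RQs have
geometric mean exactly 1, and any per-sample additive Ct shift (pipetting/
input-amount offsets) cancels in ΔCT. Group comparisons use Welch's
unequal-variance t test (Satterthwaite degrees of freedom) for unpaired
designs and a one-sample t on per-subject differences for paired designs —
"paired with Welch's correction" is not a coherent combination, so the
standard paired test is used. No multiple-testing correction is applied by
default (per-gene reporting); a Benjamini–Hochberg helper is available.

## Numerical choices and degenerate inputs

- Divergent training (non-finite loss) raises an error naming the epoch and,
  from the swarm loop, the (resample, gene) member; it is never silently
  clipped.
- Zero-variance genes: sd is replaced by 1 in standardization (the centred
  column is all zeros); zero-variance groups make Welch/paired tests raise a
  degenerate-data error rather than return NaN.
- Aggregation with a single resample reports sd 0 (a one-point sample
  standard deviation is undefined; 0 states "no observed dispersion").
- Sign consistency uses the sign of the mean as reference and is set to 0
  where the mean is exactly 0.
- Readers use round-trip float parsing so writer/reader pairs are bit-exact
  inverses at 17 significant digits.

## Known limitations

Influences are conditional linear(ized) associations, not causal effects:
confounding by unmeasured genes, feedback loops and non-identifiable edge
directions are all attributed to whatever the regressions can see. The
benchmark's linear-Gaussian ground truth favors the estimator's own
assumptions; real transcriptome data will be harsher. Runtime scales as
(resamples × genes) network fits — fine for prefiltered matrices
(hundreds of genes), not for whole-transcriptome inputs without prior
reduction, which is what the prefilter is for.
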