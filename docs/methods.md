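# Methods

## The imputation problem

Taxonomic count matrices from shotgun or amplicon sequencing are dominated by
zeros — often 70–90% of all entries.  Some are biological (the taxon is truly
absent); many are non-biological: sampling zeros from limited sequencing depth
and technical zeros from extraction, amplification or batch effects.  Treating
every zero as a true absence biases downstream differential-abundance and
classification analyses.  mbSparse fills zeros by borrowing strength from
similar samples, without assuming any parametric count distribution, and never
modifies an observed non-zero count.

## Pipeline

Given a count matrix `M` (n samples × m taxa, non-negative reals):

1. **Normalization.** Each sample is total-sum scaled to a common library size
   `T` (default 10^6): `M'_ij = T · M_ij / Σ_j' M_ij'`, then
   `X_ij = log10(M'_ij + 1)`.  Zeros are fixed points of both maps, so the
   zero pattern of `X` equals that of `M`.  All subsequent stages operate on
   `X`; count-scale output is `10^X − 1`.
2. **Feature autoencoder.** An MLP autoencoder (encoder m→512→128, decoder
   128→512→m) is trained to reconstruct `X` under squared error.  The 128-d
   bottleneck activations are the per-sample embeddings `Z`.  ReLU is used
   between layers and on the bottleneck (embeddings are non-negative, like
   `X`); the reconstruction output uses softplus, which is non-negative but
   avoids the dead-gradient plateau ReLU has at exactly 0.
3. **Sample-correlation graph.** A directed exact KNN graph on `Z` under
   Euclidean distance: each sample keeps its k (default 5) nearest other
   samples, nearest first, ties broken by ascending sample index.  The graph
   is deliberately not symmetrized — the filling rule needs a fixed-size
   neighborhood per target sample.
4. **Conditional VAE.** For every directed edge v→u the CVAE models
   p(X_u | X_v).  The recognition network maps concat(X_u, X_v) through a
   256-unit hidden layer to a 10-d diagonal Gaussian posterior; the decoder
   consumes the 10-d latent concatenated with a learned 10-d linear projection
   of the condition (input width 20) and maps 20→256→m with a softplus output.
   Training maximizes the ELBO with a standard-normal prior and a
   fixed-unit-variance Gaussian likelihood in logged space (the reconstruction
   term is a mean squared error), using the reparameterization trick with one
   Monte-Carlo draw per pair (configurable).  After training, one conditional
   sample `X^c_v` per node is generated by decoding a prior draw z ~ N(0, I)
   with condition `X_v`, so conditional neighbors mirror the real neighborhood
   one-for-one.
5. **Zero filling.** For every `X_ij = 0`:
   `X_ij ← (1/2K) Σ_{k∈N_i} (X_kj + X^c_kj)`, K = |N_i| = k.
   Non-zero entries are retained bit-exactly.  A fill can be zero when every
   neighbor (real and conditional) is zero for that taxon — such entries are
   treated as plausible biological zeros.  Every zero is attempted; there is
   no pre-classification of zeros.

Ablation variants are first-class modes: `no_fae` builds the KNN graph on the
raw logged profiles; `no_cvae` reduces the fill to the real-neighbor mean
`(1/K) Σ X_kj`; `neither` applies both substitutions.

## Interpretation choices

Several architectural details admit more than one reading; the choices here
are documented as this package's interpretation:

* The fixed inner layer shapes (512×128 encoder / 128×512 decoder; 256×10
  encoder / 20×256 decoder) are read as the hidden→bottleneck dimensions, with
  the outer layers adapting to the taxon count m.
* The latent prior is a fixed N(0, I).  A learned conditional prior p(z|X_v)
  would also be consistent with the generation procedure; the fixed prior is
  the simpler model and matches the reparameterized noise e ~ N(0, I) used in
  training.
* The decoder consumes the condition through a learned linear 10-d projection,
  which is the only way a 20-wide decoder input can combine a 10-d latent with
  an m-d condition.
* One latent draw per node (not per edge) at generation time, so each sample
  has exactly one conditional profile.
* Imputed output is reported on the logged and normalized-count scales; rows
  are NOT re-normalized after filling (filling necessarily breaks the 10^6 row
  sum), and no attempt is made to return to the original-count scale.

## Training defaults

Both networks use Adam (lr 1e-3), batch size min(64, #rows or #pairs), and
150 epochs, all exposed in `FAEConfig` / `CVAEConfig`.  At microbiome cohort
sizes (tens to hundreds of samples) 150 epochs is fully converged: the FAE
reconstruction SSE typically drops by more than two orders of magnitude, and
quadrupling the CVAE epochs changes recovery metrics by less than 0.01.  The
autoencoder is used transductively (trained on the matrix it imputes); there
is no train/validation split.  Every stochastic stage draws its seed
deterministically from the global seed via
`sha256(global_seed:stage:replicate)`, so runs are bit-reproducible on one
device and changing one stage's configuration never perturbs another stage's
random stream.  The networks are implemented directly in numpy (explicit
forward/backward passes); the models are two-layer MLPs, small enough that a
deep-learning framework would add dependencies without capability.

## Synthetic data generator

`synthesize_count_matrix` emulates the sparsity regime of WGS species
profiles: a log-normal mean surface
`log μ = log(base_mean) + a_i + b_j + (UV)_ij`
with sample effects a_i ~ N(0, 0.4²), taxon effects b_j ~ N(0, 0.8²) and a
rank-r (default 5) interaction scaled to sd 0.6 — the low-rank term is what
makes samples genuinely similar to their neighbors and hence imputable;
negative-binomial counts via a gamma–Poisson mixture (dispersion 0.5,
variance μ + 0.5μ²); and independent extra zeroing of entries at rate
`zero_inflation`, which can drive total sparsity to the 90% regime reported
for real gut metagenomes.  With two groups, the first `n_da_taxa` taxa get a
log-scale shift of `effect_size` in the second group, emulating spiked-in
differentially abundant taxa.

What the generator does **not** emulate: structured (abundance- or
group-dependent) missingness — its extra zeros are independent of abundance,
which makes them maximally unpredictable; phylogenetic correlation between
taxa; compositional closure effects beyond TSS; batch effects.  Passing the
recovery benchmarks therefore demonstrates that the pipeline recovers
low-rank cross-sample structure under unstructured dropout, not that it
distinguishes biological from technical zeros in real data (no method can,
from the count matrix alone, when missingness is unstructured).

One consequence is worth stating explicitly because the benchmark reports
both numbers: with i.i.d. extra zeros in the reference matrix, filling *all*
zeros improves the masked error dramatically but can leave the mean per-taxon
Pearson correlation at or slightly below the non-imputed baseline — fills at
the unpredictable reference zeros add disagreement that offsets the
correlation recovered at the dropout coordinates.  On data whose zeros are
structured (real microbiome tables, or depth-downsampled matrices where zeros
concentrate at low counts), both the error and the correlation improve
together, as the depth benchmark shows.

## Corruption protocols and benchmarks

* **Complete-data extraction.**  Scheme 1 keeps the ⌈p·m⌉ taxa with fewest
  zeros and every sample on which all of them are non-zero (a zero-free
  submatrix, rejected if smaller than 2×2).  Scheme 2 additionally resamples
  each row multinomially at a fixed depth.  These are documented
  approximations: the binding contract is that the output contains no zeros.
* **Dropout injection** zeroes ⌊rate · #nonzero⌋ uniformly chosen non-zero
  entries and records the mask, giving ground truth for recovery scoring.
* **Depth downsampling** redraws each row as Multinomial(depth, row
  proportions) at depths 1,000–10,000 reads.
* **Outlier construction** rebuilds one sample from eligible low-abundance
  taxa (mean below the across-taxa median and ≥ 10 non-zero entries), drawing
  each value uniformly from the taxon's top-100 observed non-zero abundances
  (all of them when fewer than 100 exist) and zeroing every other taxon.

Scoring: masked MSE over the injected mask (or all entries), column-wise
Pearson/Spearman per taxon with zero-variance columns excluded and counted
(never silently zeroed), the identification rate (fraction of injected zeros
restored to non-zero), and SMA regression (slope sign(r)·sd(y)/sd(x)) for
taxon-pair relationships.  Comparisons default to the logged scale.

The depth benchmark's primary MSE is taken over **all** entries of
imputed-vs-complete: downsampling perturbs every entry, not only the zeroed
ones, and restricting to sampling-zero coordinates changes the composition of
the scored set across depths (deeper runs only zero the rarest taxa), which
makes the restricted metric non-monotone for any imputer.  The restricted
metric is still reported as `mse_sampling_zeros`.

The outlier benchmark excludes injected-mask coordinates that fall inside
outlier rows from scoring, since those rows are rebuilt from scratch and
carry no recoverable signal by construction.

## Problem sizes and replication

The shipped benchmarks use n=100 samples × m=300 taxa (30% extra zero
inflation, 20% dropout) for recovery/ablation/outlier runs and 60×200 dense
matrices for the depth sweep, with 10 replicates (6 for the outlier sweep,
which runs four pipeline configurations per replicate).  These sizes are
representative of single-cohort microbiome studies and keep a full benchmark
round to minutes on one CPU; all sizes and replicate counts are function
arguments.

## Numerical notes and limitations

* He initialisation for all dense layers; softplus evaluated via
  `logaddexp` for stability.
* Training aborts with the epoch index if a loss becomes non-finite rather
  than continuing from a poisoned state.
* KNN is exact; ties are resolved deterministically by sample index, so
  duplicated profiles yield reproducible graphs.
* Degenerate inputs are rejected with named coordinates: rows summing to
  zero (cannot be normalized), negative or non-numeric cells, duplicate
  labels, k ≥ n.
* The method assumes cross-sectional exchangeable samples; longitudinal
  dependence, batch structure and covariates are out of scope.
* Imputed values are neighborhood averages in logged space and are therefore
  conservative (shrunk toward neighborhood means); they restore structure for
  correlation- and distance-based analyses but should not be treated as
  observed counts.
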