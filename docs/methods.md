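# Methods

## Model

`cnaclone` clusters single cells into copy-number clones from segment-level
counts of one or two modalities (scRNA-seq and scATAC-seq), while inferring
each clone's integer copy number per genomic segment.

Counts are organised as cells × segments matrices, one per modality, where
a segment is a contiguous genomic interval (typically a chromosome arm)
assumed to carry a single copy-number state per clone. For cell *n*,
segment *i* and clone *k*, counts follow a Negative Binomial whose mean is
linear in the latent copy number:

```
mu[k,i,n] = rho_n * theta_i * sum_h Phi[k,i,h] * h        h = 1..H
x[n,i] | z_n=k  ~  NegBin(mean = mu[k,i,n], size = r_i)
```

- `rho_n` — observed per-cell library-size factor, defined as the cell's
  total count divided by the mean total count, so the factors average to 1
  and `theta` stays interpretable as counts **per copy** in an average
  cell.
- `theta_i > 0` — per-segment, per-modality rate, learnt.
- `r_i > 0` — per-segment, per-modality NB size (overdispersion), learnt;
  shared across clones, since the observation noise is a property of the
  assay at a locus rather than of a clone.
- `Phi[k,i,·]` — probability vector over the discrete copy states
  `1..H`. Copy states start at 1: a zero-copy state would zero the NB mean
  and make the observation model degenerate; homozygous deletions are out
  of scope. `H` defaults to `max(expected copies) + 2`, capped at 6 —
  higher states are not resolvable at current single-cell depths.

Marginalising the clone assignment `z_n` (mixing proportions `pi`) gives
the per-modality mixture likelihood

```
log p(X) = sum_n log sum_k pi_k * prod_i NegBin(x[n,i] | mu[k,i,n], r_i)
```

and the two modalities, which share `Phi`, are combined with the shrinkage
weight `lambda ∈ [0,1]` (default 0.5):

```
L = lambda * log p(X_RNA) + (1-lambda) * log p(X_ATAC)
```

`lambda` weights the log-likelihoods. The alternative reading — weighting
the likelihoods themselves inside the log — would make the combination a
mixture of datasets rather than a tempering of evidence; tempering matches
the intended use (down-weighting a noisy modality) and makes `lambda=0.5`
the unweighted joint model up to a factor 1/2.

Three integration modes:

- **flat** — independent assignment variables `z_R`, `z_A` per modality,
  separate `pi` per modality, shared `Phi`. For unpaired assays.
- **flat_shared_pi** — as flat but a single `pi`, forcing the same clone
  proportions in both modalities.
- **multiome** — paired assays: each physical cell has one `z` driving
  both its RNA and ATAC counts. The shared-assignment likelihood tempers
  each modality's per-cell log-likelihood inside the mixture:
  `sum_n log sum_k pi_k exp(lambda*s_R[n,k] + (1-lambda)*s_A[n,k])`,
  which reduces to the flat combination when assignments decouple.

### Prior on copy states

Each `Phi[k,i,·]` carries a Dirichlet prior. If `p` copies are expected
for a segment (default 2, or user-supplied per segment, e.g. from bulk
data), the concentration vector has 0.6 at state `p` and 0.1 elsewhere —
a sparse prior (all concentrations < 1) skewed towards the expected state.

## Inference

Parameters are learnt by stochastic variational inference written directly
on numpy with analytic gradients:

- The categorical over copy states is relaxed with a **Gumbel-Softmax
  (Concrete)** factor: `phi = softmax((logits + Gumbel noise)/tau)`,
  sampled fresh each step. The temperature `tau` anneals exponentially
  from 1.0 to 0.1 over the run. The single-sample ELBO includes the
  Concrete density's `-log q(phi)` term; this matters because the
  sparse Dirichlet prior density diverges at the simplex vertices and
  only the variational entropy keeps the objective bounded.
- `pi`, `theta` and `r` are point-estimated (delta factors) on
  softmax/log scales.
- Assignments `z` are never relaxed: the mixture is evaluated with `z`
  marginalised by enumeration over K, and posterior responsibilities are
  recovered exactly by Bayes' rule at the fitted parameters.
- Optimiser: Adam, learning rate 0.05, 1000 noisy steps by default
  (experiments in this repository use 400, which the convergence window
  usually reaches), followed by up to 200 **deterministic polish** steps
  on the noise-free objective — the noisy phase finds the basin, the
  polish sharpens the slowly-moving rate/overdispersion tail.
- Early stopping when the mean ELBO over the last 20 steps changes by
  less than 1e-5 relative to the previous window.

### Initialisation

Crude per-cell copy numbers `x/(rho*theta0)` (with `theta0` = mean count
per expected copy) from all modalities are stacked and clustered with
k-means, each row weighted by its modality's weight in the objective
(`lambda` for RNA), so the starting point reflects the same evidence
balance the fit optimises. Because copy number and rate are only
identified jointly (`mu = rho*theta*c`), each segment's initial cluster
copies are re-anchored to the integer grid: the heaviest cluster is
snapped to the integer state that minimises everyone's distance to the
grid (with a mild preference for the prior state) and the rescaling is
absorbed into `theta`. Overdispersion starts at a method-of-moments
estimate pooled within the initial clusters, so clone structure is not
mistaken for noise. Restarts differ in k-means seeding and logit jitter;
the best restart by final noise-free ELBO is returned. All randomness
flows from a single seed; identical seeds reproduce identical traces and
assignments bit-for-bit.

### Model selection

K is chosen by minimising (default) BIC:

```
BIC = v ln(n) - 2L      AIC = 2v - 2L      ICL = BIC + H(z)
```

with `L` the lambda-weighted log-likelihood above, `n` the total number
of cells observed across modalities, `H(z)` the entropy of the posterior
responsibilities, and the parameter count

```
v = (independent mixing weights) + K*I*(H-1) + (modalities)*I  [theta]
    + (modalities)*I  [overdispersion]
```

where the mixing weights contribute `2(K-1)` in flat mode with two
modalities and `K-1` otherwise. `select_model` visits K in increasing
order and warm-starts one restart of each fit from the best smaller model
with its heaviest cluster duplicated (jittered), which keeps the
log-likelihood near-monotone in K and helps discover small clones.
Clusters attracting less than one cell of responsibility mass are
reported, not pruned, so `v` stays consistent with the declared K.

## Input handling

- BED-like segmentations (3–5 columns, 0-based half-open), 10x-style
  MatrixMarket triplets and pre-aggregated cells × segments tables are
  read directly; gzip accepted.
- Features map to the segment containing their midpoint, so a
  boundary-spanning gene or peak is counted exactly once.
- Segments where more than 10% of cells (configurable) show zero counts
  in any modality are removed before inference, synchronised across
  modalities. Filtering is never applied inside the fit, so the segment
  set of a run is reproducible.
- Multiome pairing keeps the barcode intersection, identically ordered.

## Simulator

The generator reproduces the validation design: a random clonal tree
whose diploid root spawns K−1 clones, each altering 1–3 (configurable)
segments never touched on its root path, with new copy numbers uniform
over `{1..H}` minus the parent's value; mixing proportions from a uniform
Dirichlet; log-normal library factors (sd 0.2); NB counts with mean
`rho * theta_i * c[k,i]`.

Default per-segment baselines emulate arm-level aggregates of 10x-style
assays: rates log-normal around 60 (RNA) and 40 (ATAC) counts per copy
per average cell (≈5k UMIs or fragments spread over ~40 arms at diploidy)
and NB sizes log-normal around 50 (RNA) and 150 (ATAC). The sizes are
large because a segment sums hundreds of features whose aggregate is
near-Poisson; RNA keeps the larger residual dispersion of the two. An
optional flag pins the diploid root clone's proportion, emulating a
spiked-in normal population.

Deliberately not emulated: gene-level expression programs, batch
effects, cell-cycle signal, doublets, or feature-level dispersion
structure. Passing the recovery tests therefore shows the model recovers
clone structure under its own observation model with realistic segment
statistics — not that it is robust to every artefact of real assays.

## Evaluation

- **ARI** between true and inferred partitions (per modality, and pooled
  across modalities for a single headline number per dataset).
- **MAE**: inferred clusters are matched one-to-one to true clones by
  minimising the summed mean absolute copy-number difference (Hungarian
  algorithm, exact); the MAE averages |true − inferred| over matched
  clone/segment pairs only, so a mis-selected K is penalised once via the
  ARI rather than twice. Unmatched clones are reported separately.
  Segments are weighted equally, not by genomic length.

## Scaled validation experiments

The acceptance battery runs 12 datasets (K ∈ {2,3,4,6}, 3 replicates,
300 RNA + 300 ATAC cells, 20 segments) fitted with `lambda=0.5`, BIC,
K ≤ 8, 400 noisy + 200 polish steps and 2 restarts — sizes chosen so the
full battery completes in minutes on one CPU. At this scale BIC is
deliberately conservative: with the lambda-weighted likelihood, a clone
below roughly 10% of cells that differs in a single segment often cannot
justify the `I*(H-1)+2` extra parameters, and such clones merge into
their parent. This depresses the ARI on unlucky Dirichlet draws; median
recovery across the battery remains the headline metric.

## Known limitations

- No allele-specific states, zero-copy states, per-gene resolution or de
  novo segmentation; a segmentation must be supplied.
- `lambda` is a fixed hyperparameter; it is exposed but not optimised.
- Continuous (library-size-normalised real-valued) inputs are not
  supported; the observation model is count-only.
- The variational posterior over `Phi` is a point-ish Concrete factor;
  credible intervals on copy numbers are not provided.
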