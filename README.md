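# cnaclone

Copy-number clone inference from single-cell RNA and ATAC counts.

Tumours evolve as mixtures of clones distinguished by copy-number
alterations (CNAs). Both the transcriptional output of a locus
(scRNA-seq) and its open chromatin (scATAC-seq) scale with how many DNA
copies of it a cell carries, so both assays carry a shared latent signal:
the clone's copy-number profile. `cnaclone` exploits this to cluster
cells into CNA clones **while** inferring each clone's integer copy
number per genomic segment, from either assay alone, from unpaired
combinations of the two, or from paired multiome data. It is aimed at
anyone who wants tumour/normal deconvolution or subclone structure from
single-cell RNA/ATAC without matched single-cell DNA sequencing.

## Model

Counts are aggregated to cells × segments (segments are typically
chromosome arms). For cell *n* with observed library factor ρ<sub>n</sub>,
segment *i*, clone *k* and copy states h = 1..H with probabilities
Φ<sub>k,i,h</sub>:

```
x[n,i] | z_n = k   ~  NegBin( mean = ρ_n · θ_i · Σ_h Φ[k,i,h] · h ,  size = r_i )
```

with θ<sub>i</sub> a learnt per-segment rate (counts per copy) and
r<sub>i</sub> a learnt per-segment overdispersion, both per modality.
Marginalising the clone assignment z gives a K-component mixture with
proportions π, and the two modalities — which share Φ — combine through
a shrinkage weight λ ∈ [0, 1]:

```
L  =  λ · log p(X_RNA)  +  (1 − λ) · log p(X_ATAC)
```

Each Φ[k,i,·] has a Dirichlet prior with concentration 0.6 on the
expected copy number of the segment and 0.1 elsewhere. Fitting is
stochastic variational inference with a Gumbel-Softmax relaxation of the
copy-state tensor (analytic gradients, Adam); z is marginalised exactly.
The number of clones K is selected by BIC (default), AIC or ICL:
BIC = v·ln n − 2L, AIC = 2v − 2L, ICL = BIC + H(z). See
`docs/methods.md` for the full account.

## Worked example

`examples/simulate_and_fit.py` simulates three clones (300 RNA + 300
ATAC cells, 20 segments) and runs model selection:

```
true clone proportions: [0.762 0.156 0.082]

score table (BIC selects the minimum):
 K        loglik  n_params          BIC
 1 -24624.980844       140 50145.531840
 2 -24242.115902       202 49776.411594
 3 -24126.815697       264 49942.420823
 4 -24113.128934       326 50311.656935
 5 -24101.340753       388 50684.690212

selected K = 2
ARI=0.760  MAE=0.050  matched=2 cluster(s)
```

The two large clones are recovered exactly, and the inferred copy
numbers of the matched clones are almost error-free (MAE 0.05 copies per
segment). The 8% clone does not justify its extra parameters at this
sample size, so BIC merges it into its parent — the ARI of 0.76 prices
exactly that merge. More capability tours live in `examples/`:
segment aggregation from raw 10x-style input, the shrinkage weight
rescuing a noisy modality, and multiome-vs-flat consistency.

## Command line

```bash
cnaclone simulate --k 3 --cells 300 --seed 7 --outdir sim/
cnaclone fit --rna sim/rna_counts.tsv --atac sim/atac_counts.tsv \
             --kmin 1 --kmax 5 --outdir fit/
cnaclone evaluate --true-labels sim/true_labels.tsv \
                  --assignments fit/assignments.tsv
cnaclone benchmark --replicates 3 --kmin 2 --kmax 4 --cells 300 --outdir bench/
```

Every run writes a `provenance.json` with all parameters and the seed.

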