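# msnr

Multi-scale network regression: penalized modeling of a stack of subject-level
symmetric connectivity matrices as a shared low-rank mean plus sparse
community-level covariate effects.

The model for subject *i* with covariates *x<sub>i</sub>* is

```
A_i = Theta + sum_f x_if * W Gamma_f W^T + noise
```

where `Theta` (p×p, symmetric) is the covariate-free mean connectivity, `W`
(p×K, binary) maps nodes to predefined communities, and each `Gamma_f` (K×K,
symmetric) holds the community-level effect of covariate *f*. The estimator
minimizes a squared-Frobenius loss with a nuclear-norm penalty on `Theta`
(low rank) and an elementwise l1 penalty on the `Gamma_f` (sparsity), solved
by block coordinate descent with exact closed-form block minimizers
(eigenvalue soft-thresholding for `Theta`; decoupled per-community-pair
weighted lassos for `Gamma`). The problem is convex, so the solver reaches
the global optimum.

On top of the solver the package provides:

- **model selection** — train/validation split, five-fold cross-validation
  over a log-spaced (λ1, λ2) grid with iterative refinement, and a
  row-permutation test of the connectivity–covariate association;
- **baselines** — mass-univariate per-edge OLS and community-mean OLS with
  Benjamini–Hochberg (or Storey) FDR correction, scored with the same
  edge-level prediction-error routine as the main model;
- **synthetic data** — cohorts drawn from the generative model with known
  low-rank mean, sparse block effects, and seeded reproducibility;
- **summaries** — coefficient sparsity, within/between-community sign
  counts, and coefficient-vs-community-distance correlations;
- **io / cli** — HDF5 or delimited-text adjacency stacks, covariate /
  partition / coordinate tables, model serialization, and a `msnr` command.

## Command line

```sh
# synthetic cohort with known truth
msnr simulate --n 200 --p 60 --k 6 --d 3 --q 3 --seed 1 --out-dir sim/

# split + cross-validated penalty tuning + final fit + validation error
msnr cv --adjacency sim/adjacency.h5 --covariates sim/covariates.tsv \
        --partition sim/partition.tsv --out-dir cv_out/

# single fit at fixed penalties
msnr fit --adjacency sim/adjacency.h5 --covariates sim/covariates.tsv \
         --partition sim/partition.tsv --lambda1 1 --lambda2 1 --out-dir fit_out/

# permutation significance test
msnr permute --adjacency sim/adjacency.h5 --covariates sim/covariates.tsv \
             --partition sim/partition.tsv --n-perm 1000 --out-dir perm_out/

# single-scale comparators
msnr baseline --method edge --adjacency sim/adjacency.h5 \
              --covariates sim/covariates.tsv --partition sim/partition.tsv \
              --out-dir edge_out/

# interpretability summaries of a fitted model
msnr summarize --model-dir cv_out/model --coords coords.tsv --out-dir summary/
```

Every run writes a `provenance.json` (options, seeds, version) next to its
outputs.

## Data formats

- **Adjacency stack**: either one HDF5 file with datasets `/A` (n×p×p),
  `/subject_ids`, `/node_ids`, or a directory of per-subject tab-delimited
  square matrices named `<subject_id>.tsv` (optional `nodes.txt` with node
  ids). Slices must be symmetric within 1e-8; nonzero diagonals are zeroed
  with a logged warning.
- **Covariates**: delimited text, first column `subject_id`, remaining
  numeric columns with header names. Subjects are aligned to the adjacency
  stack by ID join; mismatches are an error.
- **Partition**: delimited text with columns `node_id`, `community_label`.
- **Coordinates** (optional): columns `node, x, y, z`.

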