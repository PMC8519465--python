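# cellstate

Cross-cell-type drug response translation with a denoising autoencoder:
one shared encoder maps a perturbation-response expression profile (e.g.
a z-scored L1000 landmark-gene signature) to a cell-neutral latent code,
and one decoder per cell type reconstructs the response the same drug
elicits in that cell type. A trained model predicts the transcriptional
response in a target cell line from the measured response in any other
cell line, including cell lines never seen in training.

The package covers the full workflow:

- **profiles** — read GCT / GCTX / TSV signature matrices, average
  replicates of the same drug across timepoints and doses, normalize the
  whole matrix into [-1, 1] by its global maximum, pair drugs measured
  in every cell type of interest, and convert external CAGE-count or
  mean-expression tables into landmark log2 fold-change profiles.
- **model** — the autoencoder itself (dropout 0.5 on the input, dense
  512/256 encoder, L1-regularized latent layer of 128, mirrored decoder,
  leaky-ReLU activations, tanh output with a learned per-gene skip leak
  from the input), implemented in NumPy with hand-written backprop and
  Adam; training is single-threaded and bit-reproducible from a seed.
- **training** — the three-stage protocol: (1) plain autoencoder
  pretraining over all cell types, (2) per-cell decoders copied from the
  shared decoder and trained round-robin with the encoder on cross-cell
  pairs, (3) encoder frozen, decoders trained to convergence; plus
  leave-one-drug-out transfer fine-tuning on small external sets. Early
  stopping (patience 5) on a by-drug validation split, best weights
  restored.
- **evaluation** — per-drug Pearson correlation against the observed
  target-cell response, the copy-the-other-cell baseline, fold-change
  over baseline, paired t-tests, drug-holdout k-fold cross-validation
  and drug-family holdout.
- **interpretation** — latent alignment matrices (same drug, two cell
  types), TF-target inference by gradient ascent on the model input,
  exact binomial enrichment of gene-set overlaps, and masked-subset
  decoder gene importance.
- **synthetic** — a cohort generator with a known shared-latent ground
  truth (drug codes shared across cells, correlated per-cell mixing
  maps, planted TF-target and driver-gene structures) so the entire
  pipeline is exercisable and testable offline.

## Command line

All commands work on plain TSV matrices (genes x samples) with a
metadata sidecar (`sample_id, pert_id, cell_id, pert_type, pert_time,
pert_dose`), so synthetic and real data follow the same path:

```bash
# generate a synthetic paired cohort
dcs simulate --drugs 300 --cells A,B --genes 200 --latent-true 16 \
    --shared 0.6 --noise 0.3 --seed 7 --out synth

# or ingest real signatures (gct/gctx/tsv) with averaging + normalization
dcs ingest --matrix sigs.gct --format gct --meta meta.tsv \
    --cells MCF7,PC3 --out paired

# train the three-stage model
dcs train --matrix synth.matrix.tsv --meta synth.meta.tsv --cells A,B \
    --latent 32 --widths 128,64 --epochs 60 --seed 1 --out model.npz

# cross-validate (optionally by drug family, optionally subsampling one cell)
dcs cv --matrix synth.matrix.tsv --meta synth.meta.tsv --cells A,B \
    --k 10 --latent 32 --widths 128,64 [--families fam.tsv] \
    [--subsample-cell B:0.3] --seed 1 --out cv

# predict, evaluate, fine-tune
dcs predict --model model.npz --input profile.tsv --target-cell B
dcs eval --model model.npz --matrix test.matrix.tsv --meta test.meta.tsv \
    --input-cells A --target-cell B --out report
dcs finetune --model model.npz --matrix small.matrix.tsv \
    --meta small.meta.tsv --cells A,B --loo-drug drug0003 --out tuned.npz

# interpretation
dcs interpret latent-matrix --model model.npz --matrix ... --meta ... --cells A,B --out al
dcs interpret tf-targets --model model.npz --tf g0010 --cell A
dcs interpret importance --model model.npz --matrix ... --meta ... \
    --input-cell A --cell B
```

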