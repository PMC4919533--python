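# convmap

Convergence-zone mapping: a testable pipeline that asks whether the same
voxels both carry *conjunctive* associative-memory information and act as
*connector hubs* between brain subnetworks.

The pipeline has five stages, exercised end-to-end on synthetic beta images
with planted effects:

1. **`convmap.synth`** — multi-subject synthetic 4-D beta-image sets for a
   paired-associate retrieval design (12 associations over face/house/body
   category pairs, 2 cue-associate orders, matched retrieval and
   inter-trial-interval regressors), with configurable conjunctive,
   perceptual, and hub-connectivity effects plus Gaussian noise, a synthetic
   atlas, and ground-truth annotations.
2. **`convmap.rsa`** — searchlight representational similarity analysis
   (default 4-voxel radius, ≥30 grey-matter voxels per sphere, Spearman
   pattern similarity) fitted to a balanced associative contrast. The
   contrast applies a *perception penalty*: same-association comparisons
   must cross cue-associate order, different-association comparisons must
   match both cue and associate categories; everything else is excluded, and
   the included-cell weight mean is exactly 0.
3. **`convmap.network`** — beta-series connectivity per phase (Pearson over
   spatially subsampled voxels, negatives zeroed, positive edges kept at
   BH-FDR *p* < 0.05), a region-level graph parcellated with Louvain
   modularity detection, and voxel-wise hubness as the participation
   coefficient (eigenvector centrality as a control), contrasted
   retrieval − ITI.
4. **`convmap.groupstats`** — voxel-wise one-sample t-tests with sign-flip
   permutation nulls (exhaustive when `2^n_subjects` fits the permutation
   budget), map binarization, and the post-hoc four-way similarity
   breakdown.
5. **`convmap.overlap`** — Dice coefficient and relative overlap of the two
   binarized group maps inside a target-region union, tested against a null
   that redraws random atlas-region pairs; plus the per-subject across-voxel
   Spearman correlation of the two metrics with a group Wilcoxon
   signed-rank test.

## CLI

```bash
convmap simulate --out sim/ --grid 16 --n-regions 8 --n-subjects 12 \
    --conjunctive-effect 1.5 --hub-effect 1.5 --seed 7
convmap rsa --betas sim/sub-00_betas.nii --labels sim/sub-00_labels.tsv \
    --mask sim/mask.nii --radius 4 --min-voxels 30 --out conj00.nii
convmap network --betas sim/sub-00_betas.nii --labels sim/sub-00_labels.tsv \
    --atlas sim/atlas.nii --mask sim/mask.nii --metric pc --subsample 2 \
    --out-prefix hub00
convmap group --maps conj00.nii --maps conj01.nii --maps conj02.nii \
    --n-perm 10000 --side greater --seed 0 --out-prefix group_conj
convmap overlap --conj conj_mask.nii --hub hub_mask.nii --atlas sim/atlas.nii \
    --targets 1 --n-perm 10000 --out overlap.json
convmap run-all --config config.yaml
```

`run-all` consumes a YAML `PipelineConfig` (see `convmap.io`); with a
`synthetic:` block it generates the data itself and writes subject maps,
group t/p maps, binarized masks, `overlap.json`, and a deterministic
`manifest.json` recording every seed and threshold.

## Conventions

- Volumes are NIfTI; condition labels and region tables are TSV; results and
  manifests are JSON; configs are YAML.
- Coordinates are 0-based voxel indices; synthetic grids use a scaled
  identity affine.
- All randomness flows from explicit integer seeds; identical configs yield
  byte-identical manifests.
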