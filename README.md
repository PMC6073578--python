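# amylearn

Sequence-derived protein feature encoders and a random-forest classification
pipeline for amyloid-protein prediction.

The package provides:

- **`sequence_io`** — FASTA reading/writing, residue sanitization
  (`reject` / `strip` / `map-to-ALA`), the minimum-length dataset filter,
  and a greedy identity-clustering fallback for redundancy reduction
  (a cheap k-mer-Jaccard proxy, *not* a CD-HIT replacement).
- **`ctd_features`** — the 188-D composition/physicochemical encoder:
  20 amino-acid composition features plus, for each of 8 three-class
  property partitions (hydrophobicity, van der Waals volume, polarity,
  polarizability, charge, surface tension, secondary structure, solvent
  accessibility), 3 class-composition + 3 transition + 15 distribution
  features. Partitions are overridable data tables; the feature ordering is
  frozen.
- **`pse_features`** — sequence-only pseudo-composition encoders: k-mer,
  distance-residue, distance-pair, autocorrelation (AC / CC / ACC / PDT) and
  pseudo amino-acid composition (PC-/SC-PseAAC and their General variants),
  plus a 22-entry method catalog in 5 groups in which profile-based and
  predicted-structure methods are flagged unsupported (they need PSSMs or
  structure predictors).
- **`baseline_features`** — n-gram and the 400-D gapped-dipeptide
  (skip-gram) baselines.
- **`model_eval`** — the full metric suite (SE, SP, ACC, MCC, precision,
  recall, F-measure), hand-rolled ROC/AUC, stratified 10-fold CV, 80/20
  external validation, balanced undersampling, a paired multi-classifier
  benchmark, and seeded random-forest training (500 trees, sqrt features
  per split by default).
- **`synthetic_data`** — seeded two-class sequence generators with
  controlled compositional bias, so the whole pipeline is testable without
  any external dataset.

## CLI

```sh
# generate a synthetic labeled dataset (165/382 imbalance by default)
amylearn synth --n-pos 165 --n-neg 382 --len 50:400 --enrich CLVIMFW:5 \
    --seed 7 --out data/

# feature matrix
amylearn extract --positive data/positive.fasta --negative data/negative.fasta \
    --encoder 188d+pse --out features.tsv

# stratified 10-fold cross-validation
amylearn cv --positive data/positive.fasta --negative data/negative.fasta \
    --encoder 188d+pse --k 10 --seed 0 --out report.json

# 80/20 external validation, balanced variant, classifier benchmark
amylearn eval-external --positive ... --negative ... --seed 0
amylearn cv --positive ... --negative ... --balance --seed 0
amylearn bench --positive ... --negative ... --k 10 --seed 0 --out bench.tsv

# train on everything and score new sequences
amylearn train --positive ... --negative ... --out model.joblib
amylearn predict --model model.joblib --fasta new.fasta
```

Encoders available via `--encoder`: `188d`, `pse`, `188d+pse` (default),
`ngram1`, `kmer2`, `skipgram400`. The default `pse` profile is
k-mer (k=2) + PC-PseAAC (λ=2, w=0.05); all parameters are exposed in the
Python API (`extract_pse_combined`).

## Notes

- Residue-to-class partitions and the physicochemical index tables
  (hydrophobicity, hydrophilicity, side-chain mass; standardized to mean 0 /
  sd 1 over the 20 residues) are conventional defaults and can be replaced
  via the Python API.
- All randomness (generation, splits, resampling, forests) is controlled by
  explicit seeds; a fixed seed reproduces bit-identical evaluation reports.
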