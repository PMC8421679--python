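# thncdf

Drug–target interaction (DTI) prediction over a drug–target–disease
tripartite network. The pipeline:

1. **Similarity** — Tanimoto similarity over 166-bit binary chemical
   fingerprints, plus Gaussian interaction-profile (GIP) kernels over drug
   interaction profiles, target interaction profiles and target–disease
   association profiles. Drug and target similarities are fused as convex
   combinations (default weight 0.5:0.5).
2. **Pair features** — each drug–target pair is encoded as the drug's full
   fused-similarity row concatenated with the target's full
   fused-similarity row; negatives are sampled from the zero cells of the
   adjacency matrix (1:1 by default, or all pairs).
3. **Cascade deep forest** — stacked levels of six tree ensembles (two
   completely-random tree forests, two gradient-boosting forests, two
   extra-randomized tree forests; 1,000 trees each by default, 6,000 per
   level). Each forest's class-probability vectors are generated
   out-of-fold by stratified 10-fold CV and appended to the raw features
   as the next level's input. Cascade depth is chosen automatically by
   early stopping on the out-of-fold AUPR.
4. **Evaluation** — AUC (Mann–Whitney) and AUPR (average precision) under
   stratified k-fold cross-validation over pairs.

A seeded synthetic generator plants block structure across all three data
channels so the whole pipeline is testable without external downloads.

## CLI

```sh
thncdf simulate --seed 1 -o data/                 # write synthetic inputs
thncdf similarity --interactions data/interactions.tsv \
    --fingerprints data/fingerprints.tsv \
    --target-disease data/target_disease.tsv -o sims/
thncdf fit --interactions data/interactions.tsv \
    --fingerprints data/fingerprints.tsv \
    --target-disease data/target_disease.tsv \
    --trees 50 --cv-folds 5 --seed 0 -o model/
thncdf predict --model-dir model/ --interactions data/interactions.tsv \
    -o predictions.tsv
thncdf cv --interactions data/interactions.tsv \
    --fingerprints data/fingerprints.tsv \
    --target-disease data/target_disease.tsv \
    --folds 10 --trees 50 --seed 0 -o cv.tsv
```

All inputs are plain TSV: a labelled binary adjacency matrix (benchmark
dialect, targets on rows / drugs on columns, auto-detected from identifier
prefixes), a two-column fingerprint table (drug id, 166-char bitstring),
and a two-column target–disease edge list. Every run writes a
`manifest.json` with the tool version, resolved config, seeds and input
digests. Config files (`--config`, YAML) are overridden by explicit CLI
flags.

The default profile (1,000 trees per forest) matches the published
configuration; use `--trees 30..100` for desk-scale experiments — results
are insensitive to the tree count well before 1,000.

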