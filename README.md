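# morf-mlp

Per-residue prediction of molecular recognition features (MoRFs) —
short disorder-to-order segments in intrinsically disordered proteins —
from two information sources:

- **sequence properties**: 15 amino-acid scale tables plus a topological
  (distinct-subword) entropy functional, averaged over sliding windows of
  10/45/90 residues and pooled back to residues (48 features);
- **evolutionary information**: the 20 rows of a PSI-BLAST PSSM averaged
  over the same windows (60 features).

Each branch feeds a 5-member ensemble of small 2-hidden-layer MLPs
(ReLU/sigmoid, inverted dropout, Adam on binary cross-entropy over a
class-balanced subsample); the two branch scores are combined by a
naive-Bayes posterior-odds product. Evaluation reports ROC/AUC and FPR at
fixed TPR, optionally stratified by MoRF region length (short ≤ 30 / long).

A synthetic fixture generator plants tunable MoRF signal in sequences and
matching PSSM files, so the entire train → fuse → evaluate loop runs with
zero downloads.

## CLI

```sh
# generate a synthetic dataset (FASTA + regions TSV + PSSM dir)
morf-mlp fixtures --n 50 --delta 1.5 --seed 7 --out-dir fixtures/

# per-residue features for one branch
morf-mlp featurize --fasta fixtures/sequences.fasta --branch properties --out f1.tsv
morf-mlp featurize --fasta fixtures/sequences.fasta --pssm-dir fixtures/pssm \
    --branch profile --out f2.tsv

# train one ensemble per branch (YAML config can override hyperparameters)
morf-mlp train --features f1.tsv --regions fixtures/regions.tsv \
    --branch properties --seed 17 --out m1.json
morf-mlp train --features f2.tsv --regions fixtures/regions.tsv \
    --branch profile --seed 17 --out m2.json

# fused per-residue scores and an evaluation report
morf-mlp predict --fasta fixtures/sequences.fasta --pssm-dir fixtures/pssm \
    --model1 m1.json --model2 m2.json --out pred.tsv
morf-mlp evaluate --pred pred.tsv --regions fixtures/regions.tsv \
    --strata short_long --out report.tsv

# or the whole pipeline on generated fixtures in one shot
morf-mlp run-all --out-dir demo/ --seed 7
```

All commands are deterministic given their seed; rerunning with the same
seed reproduces every output byte-for-byte.

## File formats

- **FASTA** — standard multi-record; ambiguity codes are canonicalized
  (B→D, Z→E, U→C, O→K; anything else → X, scored neutrally).
- **PSSM** — PSI-BLAST `-out_ascii_pssm` dialect; only the 20 log-odds
  columns are used. One `<sequence_id>.pssm` file per sequence.
- **Scales** — flat text, one block per scale: a `>name` line then 20
  `letter value` lines. A default file with 15 scales ships in the package
  (`morfmlp/data/default_scales.txt`); pass `--scales` to replace it.
- **Regions** — TSV `sequence_id  start  end`, 1-based inclusive; labels
  are the union of intervals.
- **Predictions** — TSV `sequence_id  position  residue  score  call`.
- **Models** — versioned JSON archive holding all 5 members' weights, the
  feature standardizer, and the hyperparameters; round-trips bit-exactly.

## Python API

```python
import morfmlp as mm

ds = mm.make_dataset(mm.FixtureConfig(n_sequences=10, seed=1))
fm = mm.property_features(ds.records[0], mm.default_scales())
model = mm.train(fm.values, ds.records[0].labels, mm.properties_config(seed=1))
scores = mm.predict(model, fm.values)
```
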