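# sisoboost

Supervised isometric feature mapping coupled to a gradient-boosted
decision-tree classifier, for predicting hot-spot residues in protein–DNA
binding interfaces from precomputed residue feature tables.

The pipeline:

1. **Label-aware dissimilarity** — within-class pairs are compressed with
   `sqrt(1 − exp(−d²/β))`, between-class pairs inflated with
   `exp(d²/(2β)) − α`.
2. **Neighbourhood graph** — k-nearest neighbours by dissimilarity
   (union-symmetrized), with an optional Euclidean ε-rule; disconnected
   graphs are repaired by adding minimum-dissimilarity bridging edges.
3. **Geodesics** — exact all-pairs shortest paths over the graph.
4. **Classical MDS** — embedding from the top eigenpairs of the
   double-centred squared-geodesic matrix; a Nyström-style out-of-sample
   extension maps unseen samples through the stored eigensystem.
5. **Classification** — gradient-boosted trees (default 500 trees,
   learning rate 0.1, max depth 30) on the embedded coordinates.

An evaluation harness (confusion-matrix metrics, ROC/AUC, repeated
stratified cross-validation with leakage-safe per-fold embedding) and
seeded synthetic-data generators make the whole pipeline testable without
any external downloads.

## Library quick start

```python
import sisoboost as sb

train, test = sb.make_benchmark_mimic(sb.BlobSpec(seed=1, separation=6.0))

# dimensionality reduction
emb = sb.sisomap_fit(train, sb.SISOMAPParams(k=7, alpha=0.5, beta="auto", d=3))
coords_test = sb.sisomap_transform(emb, test.X)

# classification + evaluation
clf = sb.fit_classifier(emb.Y, train.y, sb.BoostParams())
report = sb.evaluate_holdout(train, test)
print(report.as_dict())

# repeated stratified cross-validation (leakage-safe per-fold embedding)
res = sb.cross_validate(train, cv=sb.CVConfig(folds=10, repeats=5, base_seed=0))
print(res.mean, res.std)
```

## CLI

Feature tables are delimited text (CSV/TSV) with a header row; first
column is the sample id, last column the 0/1 label (override with
`--id-col` / `--label-col`). A `key = value` config file can seed any
parameter; explicit flags win.

```bash
# synthetic fixture with the benchmark's shape (train 62/88, test 26/38, 114 features)
sisoboost simulate --out-train train.csv --out-test test.csv --seed 1 --separation 6

# embedding only
sisoboost fit --train train.csv --model model.joblib --embedding emb.csv --d 3

# embedding + classifier in one archive, then score new samples
sisoboost train --train train.csv --model model.joblib
sisoboost predict --model model.joblib --table test.csv --out pred.csv

# evaluation
sisoboost holdout --train train.csv --test test.csv --out metrics.json
sisoboost cv --table train.csv --folds 10 --repeats 5 --seed 0 --out cv.json
```

All outputs are written atomically and carry a provenance record
(version, seed, config hash); identical configs and seeds reproduce
byte-identical metrics JSON.

## Layout

```
src/sisoboost/
  manifold.py    supervised/unsupervised embedding pipeline + out-of-sample
  classifier.py  boosted-tree classifier and grid-search tuning
  evaluation.py  metrics, ROC/AUC, repeated stratified CV, holdout
  synthetic.py   seeded blob-table and Swiss-roll generators
  io.py          table loaders/writers, config, model persistence
  cli.py         command-line entry points
```
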