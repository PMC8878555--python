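# ehgpred

Single-channel electrohysterogram (EHG) preterm-labor prediction pipeline:

1. **Preprocessing** — 4th-order Butterworth band-pass (0.08–4 Hz), removal
   of the first and last 180 s (filter transients), segmentation into 1-min
   windows (`ehgpred.data_io`).
2. **Decomposition** — empirical mode decomposition by cubic-spline sifting;
   the first two intrinsic mode functions (IMFs) are kept (`ehgpred.emd`).
3. **Features** — RMS, sample entropy (m=3, r=0.15·SD, Chebyshev distance)
   and mean Teager–Kaiser energy per IMF, averaged over a record's windows
   and z-scored column-wise (`ehgpred.features`).
4. **Classification** — kNN / SVM / decision tree under repeated stratified
   10-fold cross-validation with preterm (<37 weeks) as the positive class;
   sensitivity, specificity, accuracy and ROC/AUC (`ehgpred.classify`).
5. **Synthetic data** — a generator of WFDB/CSV EHG datasets whose
   preterm-class records carry stronger, higher-frequency contraction bursts,
   so the whole pipeline is testable without the clinical database
   (`ehgpred.synthetic`).

Records are read from a minimal WFDB-style header/signal pair (16-bit format,
as distributed for the TPEHG database) or from per-channel CSV, with
gestational metadata in header comments or a sidecar `metadata.csv`.

## CLI

```sh
# 1. generate a synthetic dataset (262 term + 38 preterm by default)
ehgpred simulate --out data/ --seed 1

# 2. extract the 6-feature table per record per channel
ehgpred extract --data data/ --out features.csv

# 3. cross-validate the classifier sweep and print the summary table
ehgpred evaluate --features features.csv --out results/ --seed 1

# reprint the summary of a previous run
ehgpred report --results results/
```

`--classifiers` takes a comma list of `knn:K`, `svm:KERNEL` (linear, rbf,
poly) and `dt:MIN_LEAF_SIZE` tokens; the default sweep mirrors the published
hyperparameter grids. Any option can also come from a YAML config file
(`--config`); explicit flags win. Every command writes a `manifest.json`
with the resolved options so runs are reproducible bit-for-bit.

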