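# msmce

Multi-channel embedding representations for classifying raw mass-spectrometry
data, as a tested library + CLI:

* **`msmce.ms_io`** — mzML reading (MS1, 32/64-bit, zlib) and an exact
  line-oriented JSON fixture format for synthetic data and tests.
* **`msmce.preprocess`** — TIC filtering (threshold 1e4), 0.1-Da m/z binning,
  10-s retention-time window averaging, feature-matrix assembly, row-wise TIC
  normalization.
* **`msmce.msmce`** — the embedding module itself: a fully connected encoder
  (Linear → LayerNorm → ReLU → Dropout → Linear) producing a global embedding
  `E` (B×d), a channel-embedding stage of two same-length 1-D convolutions
  (1 → C_mid → C channels) and the concatenation of `E` with the C
  convolutional channels into a (B, 1+C, d) representation.
* **`msmce.classifiers`** — small 1-D residual CNN, LSTM and transformer
  heads, each in baseline (raw-vector) and composed (embedding-consuming)
  form, trained end to end under a single loss.
* **`msmce.training`** — file-level stratified hold-out (90/10), instance
  stratified k-fold CV (k=6), inverse-frequency class weights, Adam
  (lr 1e-3, weight decay 1e-5), ReduceLROnPlateau (×0.1 after 5 stagnant
  epochs), early stopping (patience 10, max 64 epochs), best-weight restore,
  full seed determinism.
* **`msmce.evaluation`** — confusion matrices, macro-averaged metrics, the
  *exact* paired Wilcoxon signed-rank test (full 2^k enumeration, mid-ranks),
  percentile bootstrap CIs, relative-improvement reporting.
* **`msmce.profiling`** — closed-form MAC/parameter/size accounting for any
  composed model.
* **`msmce.synth`** — synthetic labeled runs (class peak templates,
  calibration jitter, log-normal intensities, baseline noise, sub-threshold
  scans, RT structure) and three named benchmark profiles
  (`easy`, `hard`, `collapse-prone`).

There is no deep-learning framework dependency: `msmce.nn` is a small NumPy
reverse-mode autograd engine (finite-difference-verified) with the layers,
Adam and the LR scheduler the pipeline needs.

## CLI

```bash
msmce simulate  --profile easy --seed 7 --out runs/        # synthetic runs
msmce preprocess --in runs/ --out fm.csv --mode spidermass \
                 --bin-width 0.1 --tic-threshold 1e4 --mass-range 100,300
msmce train     --config exp.yaml --out run1/              # k-fold CV + hold-out
msmce evaluate  --run-dir run1/
msmce ablate    --config exp.yaml --out abl/               # 4-variant ladder
msmce profile   --config exp.yaml --batch-size 64          # MACs/params/size
```

An experiment config is YAML with `seed`, `data` (named profile or run
directory + preprocessing parameters), `msmce`, `classifier` and `train`
sections; every command writes a reproducibility manifest.

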