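# histofed

Federated content-based retrieval of histopathology image patches.

Pathologists looking at a difficult H&E-stained breast-tissue patch often
want to see *similar, already-diagnosed cases*. A content-based image
retrieval system answers that: embed every archived patch into a feature
vector, embed the query, return the K nearest archived patches. Training a
good feature extractor needs many images — but hospitals cannot pool
patient images. `histofed` trains the extractor *federatedly*: each
simulated site keeps its images private and shares only model weights,
which a server averages each communication round.

The pieces, in the field's standard notation:

* **Feature extractor** — a convolutional auto-encoder trained to minimise
  the reconstruction error MSE(I, O). Encoder filters [32, 64, 128, 256]
  (strides [1, 2, 2, 2]), a residual bottleneck with filters
  [64, 32, 1, 256], decoder filters [128, 64, 32, 3]; every kernel is 3×3;
  one additive encoder→decoder skip connection. The encoder maps a
  224 × 224 × 3 patch to a 200-feature embedding F = {f₁, …, f₂₀₀}. The
  whole network, including reverse-mode gradients, is implemented in NumPy.
* **Federation** — per round r: broadcast ω_r, each client m runs E local
  SGD epochs (ω ← ω − η∇ℓ(ω; b)) on its private data D_m, the server
  aggregates ω_{r+1} = Σ_m (n_m/n) ω^m_{r+1} (FedAvg; FedAdagrad is
  available as an alternative strategy).
* **Retrieval** — offline, all training/validation embeddings are collected
  into a dictionary D = [F₁, …, F_n]; online, a query Q is embedded to F_Q
  and the K smallest Euclidean distances ‖F_Q − F_i‖₂ are returned
  (exhaustive, exact, stable ties).
* **Evaluation** — ACC@K = (1/N) Σ_i ε(α_i, TOP(ans_i[:K])) with K = 5: a
  query counts as correct when any top-K hit shares its label. Precision
  and F1 use a majority-vote label over the top-K hits (malignant
  positive).
* **Preprocessing** — rasters are tiled into non-overlapping 224 × 224
  patches; tiles with under 70% tissue (luminance mask) are dropped.
* **Synthetic data** — a seeded generator renders two-class H&E-like
  textures with per-client stain shift, class imbalance (2480:5429) and a
  magnification axis (40×–400×), so the whole pipeline runs and is tested
  without any external data.

## Worked example

Federated training of two simulated sites, then retrieval scoring
(`examples/02_federated_training.py` and
`examples/03_retrieval_and_evaluation.py`):

```text
$ python examples/02_federated_training.py
round 1 | final local MSE  client_1: 0.1067, client_2: 0.0938
round 2 | final local MSE  client_1: 0.1041, client_2: 0.0912
global model: 28868 parameters, schema 97f4082bf262266a

$ python examples/03_retrieval_and_evaluation.py
client_1: N=12  ACC@5=1.000  precision=0.833  F1=0.714
  confusion matrix (rows true, cols predicted):
  [[3, 1], [3, 5]]
client_2: N=12  ACC@5=1.000  precision=0.875  F1=0.875
  confusion matrix (rows true, cols predicted):
  [[3, 1], [1, 7]]

first query of client_2 -> nearest hits:
  1. client_2-val-0007  distance 0.012  label 0
  2. client_2-train-0010  distance 0.022  label 0
  ...
```

Each site's reconstruction loss falls across rounds while only weights
cross the site boundary. ACC@5 = 1.0 means every held-out query found at
least one same-label patch among its five nearest neighbours; the confusion
matrices count the majority-vote predicted label per query against the true
label. The run uses the reduced geometry (32-px patches, 16-feature
embedding) so it finishes in seconds on a CPU; the full 224-px / 200-feature
geometry is the default `CAEConfig()`.

The other examples show the synthetic generator's class statistics
(`01`), the tissue-filtered tiling of a raster slide (`04`), and
cross-magnification search, where a 40× query retrieves similar cases at
40×/100×/200×/400× from four single-magnification sites (`05`).

A thin CLI chains the same stages through a YAML config:
`histofed synth | train-fed | train-local | index | query | evaluate`.

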