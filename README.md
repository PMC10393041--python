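# heterbgp

Simultaneous multi-patient blood-glucose forecasting from heterogeneous
continuous glucose monitoring (CGM) records. The pipeline:

1. **Synthetic cohorts** (`heterbgp.synthetic`) — CGM records with unequal
   lengths, two diabetes-type classes with distinct volatility, circadian
   structure and postprandial spikes; deterministic under a seed.
2. **Alignment** (`heterbgp.alignment`) — per-record min–max normalization,
   sliding-window segmentation into (input, target) pairs, and alignment of
   unequal segment counts by **SSR** (cyclic subsequence repetition),
   zero-**PAD**ding, or **TRA** (truncation to the cohort minimum).
3. **Sparse relation graph** (`heterbgp.srgraph`) — pairwise dynamic time
   warping distances between (unequal-length) records, a directed top-K
   nearest-neighbour adjacency, self-loops, and symmetric degree
   normalization `D^{-1/2}(A+I)D^{-1/2}`.
4. **Forecasting network** (`heterbgp.model`) — two stacked graph
   convolutions over the patient graph, a convolution along the sample
   axis, temporal attention over the input window, a GRU over the
   attention-reweighted sequence, and temporal + spatial MLP heads fused
   with a linear residual map of the raw window. Implemented on a small
   bundled reverse-mode autodiff engine (`heterbgp.autodiff`) — no deep
   learning framework required.
5. **Training & evaluation** (`heterbgp.training`) — Adam on MSE in
   normalized space; MAE / MAPE / RMSE / Pearson on de-normalized
   predictions over the reserved test tail (144 points by default);
   persistence baseline, grid search, and sensitivity sweeps over the
   window size T and neighbour count K.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (DTW oracle
equivalence, SSR invariants, dense GCN oracle, residual wiring identity,
GRU hand computation, metric identities, end-to-end learning vs the
persistence baseline, protocol fidelity, pipeline determinism).

## CLI

```bash
# full pipeline: simulate -> align -> graph -> train -> evaluate
heterbgp run --config examples/config.yaml

# individual stages
heterbgp simulate --config examples/config.yaml --out cohort.csv
heterbgp align --input cohort.csv --out aligned/ --method ssr \
    --window 8 --horizon-steps 1 --test-points 144
heterbgp build-graph --input cohort.csv --k 25 --out graph/
heterbgp train --aligned aligned/ --graph graph/ --out model.npz
heterbgp evaluate --aligned aligned/ --graph graph/ --checkpoint model.npz

# sensitivity sweeps and method comparison
heterbgp sweep --config examples/config.yaml --axis T --values 4,8,16
heterbgp compare --config examples/config.yaml --alignments ssr,pad,tra
```

Stages are cached by content hash; re-running an unchanged configuration
skips completed stages. Identical config + seed produce byte-identical
results files.

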