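# retinasc

Spatial-contrast (SC) encoding models for retinal ganglion cells, exercisable
entirely on synthetic stimuli and simulated ground-truth cells.

The package implements the full analysis chain around the SC model:

- **`retinasc.core`** — domain containers (stimuli, spike trains, filters,
  receptive fields, gaze traces), spike binning, HDF5/CSV I/O.
- **`retinasc.stimgen`** — binary checkerboard white noise, contrast-reversing
  gratings, and surrogate naturalistic movies (1/f² spatial statistics, slow
  temporal correlations, simulated saccades/fixations/jitter, Weber-contrast
  conversion, frame-repeat schedules).
- **`retinasc.cellsim`** — ground-truth model ganglion cells: rectified-subunit
  LNLN cascades with biphasic temporal kernels and Poisson spiking; a linear
  subunit nonlinearity collapses the cell to an exact LN model.
- **`retinasc.rf_estimation`** — spatiotemporal spike-triggered averages,
  robust-threshold component extraction, elliptical Gaussian receptive-field
  fits (3-σ truncation, 1.5-σ size convention), autocorrelograms.
- **`retinasc.models`** — temporal convolution, I_mean/LSC computation
  (weighted mean / weighted SD of the temporally convolved stimulus), softplus
  output nonlinearities, Poisson maximum-likelihood fitting with L-BFGS-B,
  reliability metrics (FEV, symmetrized R²), Pearson evaluation, and the
  spatial-smoothing scale scan with parabolic peak interpolation.
- **`retinasc.subunits`** — spike-triggered covariance, eigenvector basis
  selection, the logical-OR subunit-recovery model (Bernoulli likelihood,
  mini-batch Adam, Group-Lasso, warm-up, pruning), and the two-stage LNLN
  subunit model (Poisson likelihood, L1 on pooling weights). Training is
  implemented with analytic gradients in NumPy — no deep-learning framework
  required.
- **`retinasc.analysis`** — reversing-grating index (F2/F1), 2D firing-rate
  histograms, softplus-family fits and LSC sensitivity (−1/slope with
  Local-Outlier-Factor cleanup), radially averaged power spectral density,
  and cell-feature clustering (PCA + KMeans++).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance suite (parameter
recovery, LN/SC model ordering, smoothing-scale recovery, brute-force oracle
equivalence, statistic correctness, and planted logical-OR subunit recovery).
The full suite takes a few minutes on one CPU; the other test modules are
fast.

## CLI

The `retinasc` entry point exposes the main operations:

```bash
# stimuli
retinasc simulate whitenoise --config wn.yaml --seed 1 --out wn.h5
retinasc simulate grating    --config grating.yaml --out grating.h5
retinasc simulate movie      --config movie.yaml --seed 1 --out movie.h5

# ground-truth cell responses (CSV spike times)
retinasc simulate cell --cell-config cell.yaml --stimulus wn.h5 \
    --trials 1 --seed 1 --out spikes.csv

# receptive-field estimation and model fitting
retinasc sta --stimulus wn.h5 --spikes spikes.csv --out sta.h5
retinasc fit --model sc --stimulus wn.h5 --spikes spikes.csv \
    --rf sta.h5 --out sc.json

# smoothing-scale scan and subunit recovery
retinasc scan --stimulus wn.h5 --spikes spikes.csv \
    --test-stimulus frozen.h5 --test-spikes frozen.csv \
    --rf sta.h5 --out scan.json
retinasc subunits --stimulus wn.h5 --spikes spikes.csv --rf sta.h5 \
    --seed 1 --out subunits.h5

# analyses
retinasc analyze rapsd --stimulus movie.h5 --out rapsd.csv
retinasc analyze rgi --psths psths.csv --out rgi.json
retinasc analyze lsc-sensitivity --stimulus wn.h5 --spikes spikes.csv \
    --rf sta.h5 --out lsc.json
retinasc analyze cluster --temporal tf.csv --rf-sizes rf.csv --acg acg.csv \
    --k 6 --seed 1 --out labels.csv
```

YAML configs mirror the dataclass fields of the corresponding generators
(`MovieConfig`, `GazeParams`, cell parameters); see `tests/test_cli.py` for
minimal working examples.

## Conventions

- Stimuli are `T×H×W` Weber-contrast arrays; binary checkerboards take values
  exactly {−1, +1}. Frame metadata carries `frame_rate_hz` and
  `pixel_size_um`.
- Spike counts are binned at the stimulus frame rate with half-open bins
  `[t_i, t_{i+1})`.
- Temporal filters are most-recent-first; convolution bins without full
  filter support are flagged and excluded from likelihoods and metrics.
- Model channels (I_mean, LSC) are Z-scored by training-segment statistics,
  which are frozen into the fitted parameters and reused at test time.
- Spatial scales follow the 3-σ convention (a smoothing of SD σ has scale
  3σ; receptive-field size is the equivalent-area diameter of the 1.5-σ
  ellipse).
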