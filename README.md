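# spectune

Spectral circuit mapping of effective cone inputs to retinal bipolar cells
(BCs), as a tested, synthetic-data-driven pipeline.

Starting from calcium responses of BC terminals to a sweep of 13 spectrally
narrow flashes (1.5 s On / 1.5 s Off, long to short wavelength), `spectune`:

1. **simulates** ground-truth data (`spectune.synthetic`): stimulus
   protocols, four cone spectral-tuning templates with controlled zero
   crossings (green ~523 nm, blue ~483 nm, UV ~450 nm, red non-opponent),
   four flash-locked temporal kernels, weight archetypes for six spectral
   groups, trial-resolved ROI traces, and triplane image stacks;
2. **preprocesses** (`spectune.preprocess`): detrending and 42 Hz resampling,
   IPL-band detection from time-SD images, per-pixel repeat-reliability
   quality index (QI = Var_t[mean_r C] / mean_r[Var_t C]), adaptive-threshold
   ROI placement, baseline z-scoring, and the QI >= 0.4 quality filter;
3. **clusters** (`spectune.cluster`): PCA (48 components by default, with a
   high-frequency component filter) + Gaussian-mixture models with BIC model
   selection, clusters ordered by IPL depth;
4. **decomposes** (`spectune.decompose`): NMF extraction of the four temporal
   components (light/dark x transient/sustained), per-flash least-squares
   projection into a 4 x 10 array over the central 10 LEDs, linear
   interpolation onto the 360-610 nm grid, and a lasso fit against the four
   cone tunings yielding 4 cones x 4 components = 16 signed weights per
   trace (positive = sign-inverting / "On"-like);
5. **analyzes tunings** (`spectune.tuning`): weight-derived bulk spectral
   tunings, zero crossings, opponency (>= 10% opposite-lobe criterion,
   inclusive), six spectral groups, ROI-abundance-weighted crossing
   histograms with randomization controls, reconstruction-quality metrics
   (across-cluster variance and 0.16-2 Hz band-limited Fourier power),
   weight statistics/correlations, and weight-by-IPL-depth histograms with
   polarity-violation summaries.

## CLI

One top-level command with per-stage subcommands (each runs the pipeline up
to and including that stage on synthetic data):

```bash
spectune all --seed 1 --out-dir out/            # full pipeline
spectune cluster --seed 1 --out-dir out/        # simulate+preprocess+cluster
spectune all --config my_config.yaml --qi-min 0.4 --lasso-lambda 1e-4
spectune report path/to/deposit/                # validate a deposited dataset
```

Outputs: per-ROI/cluster CSV tables, HDF5 traces, the 16-weight table,
spectral-group labels, fit-quality JSON, a BIC curve, and `manifest.json`
with config hash and per-output checksums (re-runs with the same seed are
bit-identical).

## Layout

```
src/spectune/
  synthetic.py    protocols, cone/temporal templates, populations, scenes
  preprocess.py   detrend/resample, QI, IPL detection, ROI placement, filters
  cluster.py      PCA + GMM/BIC clustering, cluster summaries
  decompose.py    NMF basis, flash decomposition, lasso cone weights,
                  normalization, reconstruction
  tuning.py       bulk tunings, opponency/groups, histograms, fit quality,
                  weight statistics
  pipeline.py     staged orchestration, config, run manifest
  io.py           HDF5/CSV/YAML I/O, deposited-dataset adapter
  cli.py          click CLI
```
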