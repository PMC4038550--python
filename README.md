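# darkbench

Benchmarking and correction of **dark noise** in bacterial fluorescent
promoter-reporter systems, with a fully synthetic single-cell microscopy
pipeline.

## The problem

A promoter-reporter fusion is only as quantitative as its background. Even
with no promoter inserted, a reporter strain fluoresces: untransformed cells
contribute cellular autofluorescence (**general dark noise**, AF), and the
"empty" vector itself adds expression of the fluorophore driven by spurious
transcription initiating upstream of the cloning site (**specific dark
noise**, measured in the empty-vector control strain, EV). For weak
promoters — the interesting ones in systems and synthetic biology — this
dark noise can dominate the signal, and worse, spurious and promoter-driven
transcription can *interfere* rather than add, making the fusion dimmer than
its own empty-vector control.

`darkbench` implements the benchmarking statistics used to characterize
reporter backbones, on single-cell intensity distributions pooled from
microscopy:

```
D = μ_EV / μ_AF        (dynamic-range cost)
S = σ_EV / σ_AF        (sensitivity cost)
```

An ideal reporter has D = S = 1: its empty-vector control is statistically
indistinguishable from autofluorescence. Terminator-carrying backbones
(read-through ρ ≈ 0) approach this ideal; terminator-less ones (ρ ≈ 1) show
D up to ~2 and S up to ~2.7 in stationary phase.

## What the package does

* **`scenarios`** — a generative model of per-cell fluorescence
  `F = A + ρ·g_s·X_s + g_p·X_p` (gamma-distributed autofluorescence,
  spurious, and promoter components; optional multiplicative interference
  suppression), with calibration of the spurious component directly from
  benchmark ratios: `spur_mean = (D−1)·μ_AF`, `spur_sd = σ_AF·√(S²−1)`.
  A built-in catalogue covers the common *B. subtilis*/*E. coli* vector
  panel across growth phases, plus weak-promoter (rapE) fusion scenarios.
* **`imaging`** — synthetic brightfield/fluorescence field pairs of
  rod-shaped bacteria (spherocylinders on an agarose pad) with PSF blur, a
  Poisson + read-noise camera, 2×2 binning and ground-truth label masks.
* **`segmentation`** — classical brightfield segmentation (closing-difference
  flattening, Otsu, distance-transform watershed splitting, shape filters)
  plus IoU-based scoring against ground truth.
* **`quantify`** — background-subtracted per-cell mean intensities pooled
  into per-condition distributions.
* **`benchmark`** — D and S with percentile-bootstrap CIs, across-replicate
  SEM aggregation, histogram export.
* **`promoter`** — interference detection (bootstrap CI on μ_fusion − μ_EV)
  and dark-noise deconvolution of the promoter signal, by moment subtraction
  and by regularized characteristic-function division.

Real data can enter at any stage: 16-bit TIFF image pairs, or CSV per-cell
intensity tables.

## Worked example

```pycon
>>> import darkbench as db
>>> cat = db.builtin_scenarios()
>>> ev, _ = db.imaging_condition(cat["pGFPamy@OD5"], 1500, seed=11)
>>> af, _ = db.imaging_condition(cat["AF_GFP"], 1500, seed=12)
>>> r = db.compute_DS(ev, af, seed=1)
>>> print(f"D = {r.D:.2f}  S = {r.S:.2f}")
D = 2.09  S = 2.04
```

1500 cells per condition were simulated from the stationary-phase
terminator-less GFP scenario (calibrated to D = 2.13, S = 2.15), rendered
into 512×512 fields, segmented from brightfield, background-subtracted and
pooled; the recovered ratios agree with the calibration within sampling and
imaging noise. The terminator-carrying equivalent comes out at D ≈ S ≈ 1.0:

```pycon
>>> ev2, _ = db.imaging_condition(cat["pGFP_Star@OD5"], 1500, seed=13)
>>> r2 = db.compute_DS(ev2, af, seed=1)
>>> print(f"D = {r2.D:.2f}  S = {r2.S:.2f}")
D = 1.00  S = 0.97
```

There is also a CLI (`darkbench demo`, `simulate`, `segment`, `quantify`,
`benchmark`, `promoter`); start from `darkbench init-config run.yaml`.

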