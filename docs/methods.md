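# Methods

## Generative model of single-cell fluorescence

Each cell's fluorescence (arbitrary units, AU) is the sum of three
nonnegative components:

    F_i = A_i + ρ · g_s,i · X_s,i + g_p,i · X_p,i

* `A_i` — cellular autofluorescence (general dark noise), present in every
  strain.
* `X_s,i` — expression driven by spurious transcription of the reporter
  cassette (specific dark noise). `ρ ∈ [0, 1]` is the terminator
  read-through fraction: ρ ≈ 1 for terminator-less backbones, ρ ≈ 0 when an
  upstream terminator blocks the spurious transcripts.
* `X_p,i` — promoter-driven expression, zero in empty-vector (EV) strains.

Each component is **gamma-distributed** with shape/scale matched to its
(mean, SD). The gamma family is the standard phenomenology for stochastic
protein expression — nonnegative, right-skewed, closed under the moments we
need — and nothing downstream depends on higher moments, so no heavier
mechanistic model (burst kinetics, maturation) is attempted.

`g_s,i` and `g_p,i` model **transcriptional interference** between the
spurious and promoter-driven processes. They are 1 unless spurious
transcription reaches the reporter (ρ > 0) *and* the promoter is active, in
which case `g = γ · L_i` with `γ ∈ [0, 1]` a mean suppression factor and
`L_i` lognormal with mean 1 and coefficient of variation
`interference_extra_cv`. This is deliberately a phenomenological stand-in:
it is the simplest coupling that reproduces the two observable signatures of
interference — a fusion mean *below* the EV mean, and a broader relative
spread — without claiming any mechanism (roadblock, occlusion, collision),
which single-snapshot intensity data cannot identify. Defaults are γ = 1,
extra CV = 0 (pure additivity).

### Calibration from benchmark ratios

EV scenarios are specified by the two benchmarking ratios rather than by
absolute component moments. With AF and spurious components independent,

    D = μ_EV/μ_AF  and  S = σ_EV/σ_AF

invert to `spur_mean = (D−1)·μ_AF` and `spur_sd = σ_AF·√(S²−1)`. Printed
ratios below 1 are unphysical for an additive nonnegative component and are
treated as measurement fluctuation around the ideal reporter: the component
clamps to 0 (with a warning), so forward simulation of such rows gives
D, S → 1. All ratios are invariant under rescaling of the AU baseline, so
the per-channel autofluorescence baselines (GFP 100 ± 25 AU by default, YFP
and CFP scaled by 0.5 and 1.5 to reflect channel-dependent
autofluorescence) affect nothing downstream; they are configurable.

The built-in catalogue carries one calibrated scenario per published
benchmark row (vector panel at stationary phase; growth-phase series at
OD₆₀₀ 0.3 / 3 / 5), keyed `vector@OD`. Growth-phase dependence is encoded
purely as separate per-OD calibrations — the data are snapshots, so no
growth model is fitted. The weak-promoter (rapE) fusion scenarios at OD 2.5
(repressed) and OD 6 (weakly active) have no published numeric
distributions; their sizes are illustrative (Star-backbone separation ≈ one
EV SD at OD 6; terminator-less backbone γ_s = γ_p = 0.7 with extra CV 0.2)
and every test against them is property-based (direction of effects, verdict
frequencies), never value-matched. The EV parameters at OD 2.5 and 6 are
interpolations between the calibrated OD 0.3/3/5 rows.

## Synthetic microscopy

Fields default to 512×512 px at 0.065 µm/px (100× on a typical sCMOS chip),
with cells 2–4 µm long and 0.8–1 µm wide — *B. subtilis* dimensions.
Spherocylinders are placed by rejection sampling with a minimum boundary gap
(default 6 px ≈ 0.4 µm) and a total attempt budget; saturated fields return
fewer cells with a warning. Cells are kept fully inside the field so the
segmentation border-discard policy does not deplete them. 100 cells per
field keeps rejection sampling fast (~23 % area coverage) and densities
realistic for a spread plate culture; pooling 3000 cells therefore takes
~30 fields.

The fluorescence photon-equivalent image is a uniform background (20 AU)
plus each cell's value over its footprint; brightfield is a bright
background with cells darker by a contrast factor (0.3), no phase halo —
the minimum appearance sufficient to exercise a real segmentation
algorithm. Both are blurred by a Gaussian PSF (σ = 2 px) and passed through
a linear camera: `counts = offset + gain·Poisson(signal) + N(0, σ_read)`,
then 2×2 **mean** binning. Mean (not sum) binning keeps the AU scale
binning-invariant, so scenario calibration is independent of binning. Truth
masks are the unblurred footprints, majority-binned (ties, including
all-distinct blocks, go to background). Saturated-pixel fractions are
reported; all default scenarios render with zero saturation.

A consequence worth stating: PSF blur and mean binning move signal from
footprint-edge pixels into the background, so the measured per-cell mean is
a multiplicative attenuation of the true value (~0.8 at defaults). This
cancels exactly in D and S (both conditions share the geometry and optics),
and it is how real microscopy behaves; the absolute-scale unbiasedness of
the *noise and background* chain is therefore verified with blur off and
binning 1, where corrected means must be unbiased to within Monte-Carlo
error.

## Segmentation

Classical and deterministic: Gaussian smoothing (σ = 1 px); background
flattening by morphological **closing difference** `closing(img) − img`
(closing with a disk larger than the cell half-width erases dark cells, and
the difference — unlike a closing *ratio* — is exactly invariant under
adding a constant to the image, which is the contract tested); Otsu
threshold, rejected if it does not clear 5 robust SDs of the residual noise
(otherwise a cell-free image would be split by Otsu's unimodal-histogram
pathology); hole filling; area floor (40 px); distance-transform watershed
with seeds found per connected component (at least one per component;
additional seeds require ≥ 24 px separation, just above the longest
single-cell ridge plateau, so single cells never oversplit while end-to-end
pairs do split); border-touching objects discarded; solidity ≥ 0.8.
Scoring against ground truth uses greedy one-to-one matching on descending
IoU with a 0.5 acceptance threshold; 0.7 is used as the "well-segmented"
bar in the pipeline-level property (≥ 95 % of non-touching cells at
default noise).

## Quantification

Per-cell raw means are taken over the segmented label's pixels; background
is estimated from pixels outside all masks dilated by 5 px, as a
**5σ-clipped mean** around the median (1.4826·MAD as the robust σ). The
clipped mean keeps the median's robustness to residual unsegmented cells
but, unlike the median itself, is unbiased under the right-skewed Poisson
shot noise of the camera — a plain median underestimates the background by
a fraction of a count, which is visible as a systematic offset when
averaging a thousand cells (a `median` mode is retained for heavily
contaminated fields). Corrected means `(raw − background)/gain` may be
negative and are never clipped; clipping would bias μ and σ near the
autofluorescence floor. Sample SDs use the n−1 denominator throughout.

## Benchmark statistics

D and S are ratios of the pooled sample means and SDs. Within-sample
uncertainty: percentile bootstrap over cells, resampling EV and AF
independently (they are different strains; no pairing exists), 2000
resamples by default, seeded. Across replicates: mean ± SEM
(SD/√k), flagged unavailable at k = 1. Reports label which uncertainty they
carry. Degenerate bootstrap resamples (zero reference SD) are dropped; more
than half degenerate is an error.

## Promoter assay

`detect_interference` classifies a fusion/EV pair by the two-sided
percentile-bootstrap CI (default α = 0.05, single planned comparison, no
multiplicity correction) of μ_fusion − μ_EV: entirely below zero →
INTERFERENCE (the additive model cannot produce this), entirely above →
ACTIVE_PROMOTER, otherwise INDISTINGUISHABLE.

Deconvolution of the promoter signal from the dark noise assumes linear
superposition and is offered twice so the assumption itself is testable:

* **Moments** — `μ_signal = μ_fusion − μ_EV`, `σ²_signal = σ²_fusion −
  σ²_EV`; negative results are returned but flagged invalid (interference
  or an unresolvably small signal).
* **Density** — empirical characteristic-function division with Tikhonov
  damping, `φ_X = φ_F·conj(φ_EV)/(|φ_EV|² + reg)`, a cos² taper to zero at
  a cutoff frequency chosen where |φ_EV| falls to its sampling-noise floor
  (max(2/√n, √reg)), inverted by quadrature on a fixed AU grid. Negative
  ripples are clipped and the density renormalized; the clipped mass is a
  diagnostic. The returned density is the signal density smoothed by a
  kernel of width ≈ π/t_max, so its *variance* is inflated by the kernel
  while its *mean* is preserved (the kernel is symmetric); recovered means
  agree with the moment route to within grid resolution, and with the true
  signal mean to a few percent at n = 10⁵.

## Problem sizes and determinism

Test-suite experiments run at desk scale: 1200 cells/condition through the
imaging route, 2·10⁴–10⁵ at the population level, 20–200 repeats for
verdict-frequency properties. The acceptance script runs the imaging
experiments at 3000 cells/condition and the vector panel at 10⁵. All
randomness flows from one master seed through `numpy.random.SeedSequence`
splitting (documented per function); condition and replicate streams are
independent; string-derived seeds use CRC-32, not Python's salted `hash`.

## Known limitations

* The interference coupling is a stand-in reproducing observable signatures,
  not a mechanistic model; its parameters for the rapE scenarios are
  illustrative.
* Synthetic brightfield lacks phase halos, uneven illumination, focus drift
  and debris; segmentation performance on real images will be worse than the
  ≥ 95 % property measured here, and the scoring tools exist precisely to
  quantify that on user data.
* Channel-dependent exposure scaling is not modeled beyond the per-channel
  AF baselines; only ratio statistics should be compared across channels.
* Sub-unity printed benchmark ratios are represented as the ideal reporter;
  the simulator cannot produce D or S below 1 in expectation.
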