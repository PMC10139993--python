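# Methods

This note documents the models, defaults, and numerical choices behind
`simpull`, and what the synthetic generators do and do not emulate.

## Trace model and simulator

Each immobilized spot carries `n` tagged molecules. The simulator maps
molecules to fluorophores in three stages:

1. **GFP self-dimerization.** With probability `self_dimer_fraction`
   (default **0.30**, matching the canonical GFP-only control that shows
   ~70% one-step / ~30% two-step spots) the spot gains exactly one extra
   GFP — one partner recruited through a GFP–GFP contact. The increment
   is capped at +1: chained self-association (dimer-of-dimers) is not
   modelled, consistent with treating self-dimerization as a weak
   pairwise contact.
2. **Dark fraction.** Each GFP is independently non-fluorescent with
   probability `dark_fraction` (default **0**: the standard analysis
   assumes every tag is counted; nonzero values exist only for
   robustness studies and no correction for them is applied by default).
3. **Bleaching.** Each active fluorophore's bleach frame is geometric
   with per-frame hazard `bleach_rate` (default **0.01**, i.e. an
   expected bleach time of 100 frames). Traces default to **800
   frames**, so a fluorophore survives the movie with probability
   ≈ 3 × 10⁻⁴, and two fluorophores on the same spot bleach in the same
   frame (rendering one double-height drop) with probability ≈ 0.5% per
   pair.

The recorded intensity is `background_level + unit_intensity · m(t)`
plus i.i.d. Gaussian noise of sd `noise_sd` per frame (an EMCCD
read-noise proxy). Defaults: `unit_intensity` 100 counts,
`background_level` 50 counts, `noise_sd` 5 counts, i.e. **SNR
(unit/noise) = 20**, the benchmark regime for all recovery claims.
No blinking, no PSF rendering, no intensity nonuniformity across the
field: passing the recovery tests shows the detector handles stepwise
bleaching under Gaussian noise, not that it is robust to fluorophore
blinking or drift, which real traces can contain (such traces are meant
to be caught by the upward-step rejection rule).

Ground truth (active fluorophore count and bleach frames) travels on
the `Trace` object, never influencing detection.

## Step detection

`detect_steps` fits a piecewise-constant staircase in four deterministic
stages:

1. **Noise estimate.** σ̂ = 1.4826 · MAD(Δy) / √2 — the median absolute
   deviation of first differences is insensitive to the sparse true
   steps; 1.4826 is the Gaussian consistency constant and √2 accounts
   for differencing.
2. **Greedy binary segmentation** on the residual sum of squares: the
   best single split (computed in closed form from prefix sums, ties
   broken toward the earliest frame) is added while the RSS reduction
   exceeds the penalty `penalty · σ̂² · log n` (default multiplier
   **3.0**; the null maximum of the split statistic scales like
   2σ̂² log n, so 3 gives a comfortable margin — measured false-positive
   rate on flat SNR-20 traces is < 0.1%, and the penalized objective is
   floored at 10⁻⁶ so noiseless traces cannot be split on float jitter).
3. **Merging** of adjacent segments whose level difference is below
   `min_step_size` (default **50 counts** = half a unit step at the
   default photophysics), smallest difference first.
4. **Polish**: coordinate descent over change-point locations, each an
   exact 1-D search between its neighbours. On well-separated steps
   this drives the fit to the global RSS optimum for its change-point
   count, which is what the exact dynamic-programming oracle
   (`brute_force_fit`) verifies.

Counting is **downward-only**: `step_count` is the number of downward
level transitions ≥ `min_step_size`. A double-height drop from two
fluorophores bleaching in the same frame is one visible transition and
counts once — the same undercount a human scorer makes, ~0.5–1% of
multi-fluorophore spots at the default bleach rate. Traces are marked
invalid (with a reason, never silently dropped) when any upward
transition exceeds `blink_tolerance` (default **0**: after merging, any
surviving upward level change rejects), when `step_count` exceeds
`max_steps` (default **8** — reported distributions extend to 6 steps;
two of headroom), or optionally when the final level stays more than
one step above the fitted minimum (`require_bleach_to_background`,
default off).

## Oligomer distributions and the GFP background correction

`build_distribution` tabulates step counts over **valid traces with ≥ 1
step**; empty spots and rejected traces are excluded before
normalization, so the reported N is the number of counted traces.

`correct_gfp_background` supports three modes:

- **`bin_shift`** (default): move `min(f₂, p)` of total mass from the
  2-step to the 1-step bin, `p` = `gfp_dimer_fraction` (default 0.30).
  This is the field's standard control subtraction; it maps the GFP-only
  control exactly onto a pure monomer and preserves the average step of
  any self-dimer-inflated population (the inflation adds exactly `p` to
  the mean).
- **`deconvolve`**: exact inverse of the +1-with-probability-p increment
  model, `d(k) = (f(k) − p·d(k−1)) / (1−p)`, clipped at zero and
  renormalized. For populations that are not purely monomeric the
  bin-shift cannot recover the underlying distribution bin-by-bin (the
  self-dimer increment convolves every bin, not just bin 2); the
  deconvolution can, at the price of noise amplification by 1/(1−p) per
  recursion step. `corrected_bin_ci` provides the matching delta-method
  sampling intervals from the multinomial covariance of the observed
  frequencies.
- **`none`**: identity.

`average_step` reports ⟨k⟩ = Σ k·f(k) with a nonparametric bootstrap
SEM over traces (default **1000 resamples**, seeded; when a correction
is supplied it is applied inside every resample so the SEM reflects the
full chain). `dissolution_difference` returns the per-bin difference of
two normalized distributions over the union of their supports
(after − before; sums to zero by construction), with an optional
bootstrap CI; the alternative normalization (difference scaled to the
pre-dissolution mass) was considered and not adopted because the
per-bin difference of normalized distributions is the directly
interpretable quantity and conserves mass exactly. Condition
comparisons use Welch's t-test, one-way ANOVA on per-trace counts, or
two-way ANOVA (condition × stress) via an OLS fit; pairwise p-values
can be Bonferroni/Holm adjusted and the adjustment is recorded in the
output. Whether per-trace counts or per-replicate means are the right
ANOVA unit is a judgement call; per-trace counts are the default here
because the package operates on pooled trace sets.

## Synthetic images and quantification

The image generator renders ellipse cells with ellipse nuclei on a
constant camera offset (default 100 counts): channel 1 is a nuclear
stain filling the nucleus, channel 2 distributes each cell's integrated
GFP signal (default **2 × 10⁶ counts**, placing even the dimmer
compartment well above the offset as in a realistically exposed
transfected cell) uniformly within nucleus and cytosol so that nuclear
pixels carry `nuclear_signal_fraction` of the total; granules are disks
that multiply the local diffuse intensity. Gaussian noise is added per
pixel. Pixel size defaults to **0.25 μm/px**. The recorded ground-truth
nuclear fraction is recomputed from the rendered noiseless image, so it
is exact up to rasterization even with granules present. Not emulated:
point-spread blur, shading/vignetting, touching cells, z-structure —
the segmentation recovery results therefore speak to well-separated,
evenly illuminated cells only.

Quantification:

- **Nucleus mask**: Otsu's threshold on the smoothed nuclear channel
  (cleanly bimodal).
- **Cell mask**: a robust-background intermeans threshold on the
  smoothed GFP channel — foreground floored at median + 6·MAD of the
  field, cut placed at the midpoint of the background and foreground
  medians. A class-variance criterion (Otsu or 3-class multi-Otsu)
  was tried first and routinely dropped the dim cytosol next to a
  bright nucleus on these background-dominated fields (Jaccard as low
  as 0.18 vs ≥ 0.99 for the intermeans rule); the midpoint cut also
  bisects the smoothed cell edge, making the mask nearly unbiased.
  Fixed absolute thresholds remain available (`method="fixed"`).
- **Localization**: background (off-cell median) is subtracted and
  clipped at zero; nuclear fraction = nuclear sum / whole-cell sum;
  cytosolic fraction is its complement, so the two sum to 1 per cell by
  construction. Cells with zero net signal are flagged undefined.
- **Granules**: connected components brighter than `granule_contrast`
  (default **3×**) the median of their own compartment — nuclear pixels
  against the nuclear median, cytosolic against the cytosolic median —
  with at least `min_granule_area_px` (default 4) pixels; areas in μm²
  via pixel count × pixel_size². The compartment-relative criterion is
  deliberate: a diffusely nuclear-concentrated cell has a
  nuclear/cytosolic intensity ratio that can exceed any fixed contrast
  factor, and a whole-cell median would call its entire nucleus one
  giant granule. A cell is granule-positive when ≥ 1 granule is
  detected — a declared convention; the minimum-puncta criterion used
  by human scorers is not standardized.

## Pipeline and reproducibility

Every stochastic component takes an explicit seed; per-condition seeds
are spawned from the run seed via `numpy.random.SeedSequence` and
recorded in the run manifest together with a config snapshot, SHA-256
checksums of every output table, and per-stage trace counts. Re-running
a config reproduces every table byte-for-byte (the manifest's
timestamps differ). Tabular interchange is TSV; images are 16-bit
multi-page TIFF; an HDF5 trace container exists for large sets.

## Problem sizes used by the test suite

The recovery claims are made at the sizes the analysis is designed for:
2,000-spot populations for the GFP control and mixture-recovery runs
(binomial sd ≈ 1 percentage point per bin), 100-trace batches for the
exhaustive-oracle comparison (traces capped at 200 frames / 4 change
points, the practical limit of the O(k·n²) dynamic program), 1,000
flat traces for the false-positive rate, cohorts of 50 cells per
nuclear fraction for image recovery, and 1,000 null simulations for the
ANOVA calibration. The whole suite runs in well under a minute.

## Known limitations

- Same-frame double bleaches are counted as one step (see above); at
  high oligomer counts or high bleach rates this biases distributions
  toward fewer steps.
- The self-dimer model adds at most one extra GFP per spot; if real
  GFP self-association chained, both the generator and the bin-shift
  correction would understate the background.
- The deconvolution clips negative intermediate estimates at zero and
  renormalizes, which introduces a small positive bias in downstream
  bins when the true frequencies are near zero.
- No blinking/HMM inference, no intensity-based stoichiometry, no
  watershed splitting of touching cells, no 3D imagery.
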