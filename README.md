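# simpull

Analysis toolkit for **single-molecule pull-down (SiMPull) photobleaching
experiments**, built around the question: *how many copies of a tagged
protein sit in each complex captured from a cell lysate?*

In a SiMPull experiment, antibody-captured GFP-tagged complexes are
immobilized on a passivated surface at ~100–300 spots per 2,500 μm² field
and imaged by TIRF microscopy until every GFP has photobleached. Each
spot yields an intensity time trace; every abrupt, permanent downward
step is one fluorophore bleaching, so the step count estimates the
complex's subunit stoichiometry (monomer, dimer, trimer, ...). The
package targets exactly this workflow — as used, for example, to compare
the oligomerization of wild-type and disease-linked RNA-binding proteins
such as FUS — and replaces the traditional by-eye step counting with a
deterministic, tested algorithm.

It provides five pieces:

1. **`simpull.synthetic`** — generators for photobleaching traces and
   two-channel (nuclear stain + GFP) cell images with exact ground truth,
   so every downstream stage is testable without real data.
2. **`simpull.stepfit`** — automated step counting:
   `PhotobleachingStepModel(trace).fit()` returns a `StepFitResult` with
   change points, levels, the downward step count, and an explicit
   validity flag (traces with upward jumps or too many steps are
   rejected, mirroring manual curation). An exact dynamic-programming
   fit (`brute_force_fit`) serves as an independent oracle.
3. **`simpull.oligomer`** — `OligomerModel(step_counts).fit()` tabulates
   the normalized step distribution, applies the GFP self-dimer
   background correction, and bootstraps the SEM of the average step;
   plus dissolution-difference vectors and t-test/ANOVA comparisons.
4. **`simpull.imagequant`** — nuclear/cytosolic GFP signal fractions,
   granule areas (μm²), and cohort summaries from two-channel images.
5. **`simpull.pipeline` / the `simpull` CLI** — an end-to-end,
   manifest-tracked run: simulate → detect → analyze → report.

## The model

A spot carrying *m* active fluorophores is modelled as

> I(t) = B + u · m(t) + ε(t),  ε(t) ~ N(0, σ²),

where *B* is the surface background, *u* the per-fluorophore intensity
(one step height), m(t) the number of not-yet-bleached fluorophores
(each bleach time geometric with per-frame hazard λ), and σ the camera
read noise; SNR ≡ u/σ. The detector fits a piecewise-constant staircase
by penalized binary segmentation on the residual sum of squares (penalty
per change point ∝ σ̂² log n, with σ̂ estimated robustly from first
differences), merges level changes smaller than `min_step_size`, and
polishes change-point locations by exact coordinate descent.

Because GFP weakly self-dimerizes, a fraction *p* ≈ 0.30 of spots carry
one extra tagged partner: a GFP-only control shows ~70% one-step and
~30% two-step spots even though every complex holds a single molecule.
The standard correction moves min(f₂, p) of total mass from the 2-step
bin back to the 1-step bin; an exact deconvolution of the +1-increment
model (`CorrectionModel(mode="deconvolve")`) is available for
populations that are not purely monomeric. The condition summary is the
average photobleaching step ⟨k⟩ = Σ k·f(k) ± bootstrap SEM.

## Worked example

Simulate the GFP-only control (2,000 spots, one tagged molecule each,
30% self-dimer background, SNR 20), count steps, and fit the corrected
distribution:

```python
from simpull import GFPPhotophysics, OligomerModel, batch_detect
from simpull.synthetic import OligomerSpec, simulate_population

spec = OligomerSpec({1: 1.0}, n_spots=2000, seed=1)
traces = simulate_population(spec, GFPPhotophysics())
batch = batch_detect(traces)
results = OligomerModel(batch, condition="GFP only").fit(seed=1)
print(results.summary())
```

```
Oligomer distribution: GFP only
  N = 1999 valid traces
  correction: bin_shift (GFP dimer fraction 0.30)
  step   raw      corrected
     1   0.6863   0.9863
     2   0.3137   0.0137
  average step (raw):       1.314 ± 0.010
  average step (corrected): 1.014 ± 0.009
```

Reading this: the detector classified 68.6% of spots as one-step and
31.4% as two-step — the expected ~70/30 GFP control split within
sampling error (binomial sd ≈ 1 percentage point at n = 2,000). After
subtracting the 30-point dimer background the population is ~99%
monomeric with a corrected average step of 1.01 ± 0.01, i.e. the known
truth (every simulated complex carried exactly one molecule). One of
2,000 traces was dropped because its single fluorophore survived or
bleached too early to leave a countable step.

The same chain runs from the shell:

```bash
simpull simulate-traces --spec spec.yaml --out run/
simpull detect --traces run/traces.tsv --out run/steps.tsv
simpull analyze --steps run/steps.tsv --condition GFP --out run/report/
simpull run --config config.yaml       # end-to-end with manifest
```

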