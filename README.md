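# starphase

Quantitative image analysis for **RNA nanostar condensates** — micron-scale
liquid- or gel-like droplets formed by star-shaped RNA motifs whose arms
interact through kissing loops (KLs) or sticky ends — plus the sequence
arithmetic used to design orthogonal nanostar pairs.

It is aimed at nucleic-acid nanotechnology and biomolecular-condensate labs
that image condensates by epifluorescence and need reproducible,
scriptable versions of the standard measurements:

* **Segmentation** — background subtraction, Otsu thresholding,
  8-connected labeling, removal of noise objects with area strictly below
  6 px², and best-fit-ellipse shape descriptors from second central
  moments.
* **Chord length distributions (CLD)** — maximal foreground runs along
  every row and column of the binary mask; the mean chord length µ_CLD is
  a shape-agnostic condensate size statistic (for a disk of radius r the
  mean chord is πr/2).
* **Two-channel demixing** — per-pixel angles θ = arctan2(I_FITC, I_Cy3)
  histogrammed over condensate pixels; co-assembled samples whose peaks
  align with individually assembled controls are *demixed*, a single
  intermediate peak means *mixed*.
* **FRAP normalization** — recovery_t =
  (I_bleach,t / I_bleach,max) / (I_unbleach,t / I_unbleach,max), the
  double ratio that cancels global observational photobleaching exactly.
* **Fusion kinetics** — aspect-ratio relaxation AR(t) = 1 + A·e^(−t/τ) of
  a coalescing droplet pair, fitted by constrained least squares; the
  inverse capillary velocity η/γ (viscosity over surface tension) is the
  slope of τ = (η/γ)·ℓ through the origin over events of characteristic
  length ℓ.
* **KL sequence tools** — reverse complements, palindrome tests,
  design-space counts (4⁶ = 4096 RNA 6-mers, 64 palindromes, hence a
  64-fold expansion from non-palindromic heterodimer pairs), heterodimer
  validation (4 G/C + 2 A/U per 6-mer) and single-stranded three-arm
  nanostar strand assembly with 9-nt KL domains (5′-AA…A-3′).
* **Synthetic microscopy generator** — seeded, ground-truthed droplet
  fields, two-channel fields with spectral bleed-through, fusion
  time-lapses and FRAP traces, so every stage is testable without raw
  microscope data.

## Worked example

```python
import starphase as sp

# a seeded synthetic field of 12 stained condensates (0.5 um/px)
spec = sp.FieldSpec(n_droplets=12, seed=42)
stack, truth = sp.generate_droplet_field(spec)

mask = sp.segment_image(stack.frame(), pixel_size=spec.pixel_size)
regions = sp.label_and_measure(mask)
cld = sp.compute_cld(mask)
print("segmented regions:", regions.n_regions)        # -> 12 (matches truth)
print(f"mu_CLD = {cld.mu_cld:.3f} um from {cld.n_chords} chords")
# -> mu_CLD = 3.317 um from 189 chords

# a slowly fusing condensate pair, imaged every 15 min for 10 h
movie = sp.generate_fusion_series(A=0.5, tau=172.0, dt=15.0, duration=600.0)
series = sp.aspect_ratio_series(movie)
fit = sp.fit_relaxation(series)
print(f"A = {fit.A:.3f}, tau = {fit.tau:.1f} min")    # -> A = 0.498, tau = 172.3 min

est = sp.inverse_capillary_velocity([(fit.tau, series.characteristic_length)])
print(f"eta/gamma = {est.eta_over_gamma:.2f} min/um") # -> 5.09 min/um
```

The segmentation recovers all 12 generated droplets; µ_CLD ≈ 3.3 µm is
the mean chord of droplets with 2 µm median radius. The fusion fit
recovers the generator's relaxation constant to a fraction of a percent
from the rendered movie alone, and η/γ for this single (large, synthetic)
event is its τ/ℓ ratio.

The same stages are available from the shell:

```bash
starphase simulate --preset droplets --seed 42 --out-dir run/
starphase segment --input run/field.tiff --min-area 6 --out-dir run/
starphase cld run/mask.tiff --pixel-size 0.5 --out-dir run/
starphase design-space --k 6
```

Every stage writes CSV/JSON plus a `provenance.json` (config hash, seed,
version) so runs are exactly reproducible. See `docs/methods.md` for
models, conventions and limitations.

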