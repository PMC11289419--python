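# Methods

`starphase` quantifies phase-separated RNA-nanostar condensates from
fluorescence micrographs and checks the sequence rules behind kissing-loop
(KL) nanostar designs. This note records the models, the parameters that
matter, and the choices made where more than one reasonable convention
exists.

## Segmentation

Frames are background-subtracted, linearly rescaled to [0, 1], and
thresholded with Otsu's method; connected components use 8-connectivity
(the particle-analysis default). Two background estimators are offered:

* `median` (default): subtract the frame median, clip at 0. Deterministic,
  parameter-free, and exact when the background is spatially flat — which
  is true of the synthetic fields and approximately true of evenly
  illuminated epifluorescence.
* `rolling_ball`: a morphological background for frames with slowly varying
  illumination; `ball_radius` (default 50 px) should exceed the largest
  condensate radius.

Objects with area **strictly below** `min_area = 6 px²` are discarded as
noise; an object of exactly 6 px² is kept. The linear rescale before Otsu
is presentation-only: Otsu's threshold is equivariant under monotone linear
maps, so it changes nothing but keeps thresholds in a fixed range.

Region shape comes from second central moments: axis lengths are those of
the ellipse with the same normalized second moments as the pixel set
(`4·sqrt(eigenvalue)` of the 2×2 covariance of pixel centers), orientation
is the major-axis angle from the image x (column) axis in (−π/2, π/2].
No pixel-extent (1/12) correction is applied, matching the common
regionprops convention; on binarized ellipses with minor semi-axis around
10 px this leaves a ~2% aspect-ratio bias that vanishes as objects grow.
Touching droplets are not watershed-split: the chord statistic below is
robust to merged objects and the fusion tracker wants them merged.

## Chord length distributions

Chords are maximal foreground runs along every pixel row and every pixel
column (exhaustive axis-aligned scan lines; deterministic, no random
oblique lines). Runs touching the image border are right-censored and
excluded by default. Lengths convert to µm via the pixel size; the summary
statistic is the arithmetic mean µ_CLD. For a disk of radius r the mean
chord over parallel lines is πr/2, which the tests use as a closed form.
Replicates pool into a long-format table (one chord per row) so violin
plots can be re-rendered from the CSV alone.

## Two-channel demixing statistic

Each condensate pixel maps to θ = arctan2(I_FITC, I_Cy3) ∈ [0, π/2]. The
two-argument arctangent makes zero denominators well defined; pixels with
both channels exactly zero are excluded and counted. θ depends only on the
intensity ratio, so the histogram is invariant to global illumination
scale. Defaults: 90 bins over [0, π/2] (≈1° per bin), moving-average
smoothing over 5 bins, peak prominence floor 5% of the smoothed maximum;
the smoothed counts are zero-padded so peaks sitting at θ = 0 or π/2 are
still detected. These are this package's declared defaults, not values
inherited from any instrument.

The verdict rule: a co-assembled sample is **demixed** when its peaks
match the pooled peaks of individually assembled controls one-to-one
within `tol = 0.05 rad`; **mixed** when it shows a single peak strictly
between the control peaks and farther than `tol` from all of them;
anything else is **indeterminate**. The ROI is the Otsu foreground of the
channel-sum image, which keeps background pixels out of the histogram.

## FRAP normalization

Recovery is the double ratio
`(I_bleach,t / I_bleach,max) / (I_unbleach,t / I_unbleach,max)` with each
maximum taken over the *full* series including pre-bleach frames. Any
global multiplicative decay (observational photobleaching) enters both
ROIs identically and cancels exactly; the tests verify bit-stability to
1e−9 under `exp(−λt)` decay. Inputs are ROI mean-intensity traces; an
image-mode reader would assume registered frames (drift correction is out
of scope), so the trace CSV is the primary interface. Zero series maxima
raise; a zero reference intensity at an individual frame flags only that
frame (NaN). Replicates aggregate as per-frame mean ± standard error
(ddof = 1); a single replicate reports no standard error. No
diffusion-model fit (τ½, D, mobile fraction) is attempted.

## Fusion kinetics and inverse capillary velocity

A cropped fusion time-lapse is segmented per frame (Otsu); the largest
region per frame is the event (events are assumed manually cropped, so no
multi-object tracking). Aspect ratio is major/minor of the moment ellipse.
The relaxation model AR(t) = 1 + A·exp(−t/τ) is fitted by constrained
nonlinear least squares (A ≥ 0, τ > 0), t measured from the first frame,
initialized at A₀ = AR(0) − 1 and τ₀ = first time AR − 1 drops below A₀/e
(fallback: half the span). A series flat at AR = 1 has unidentifiable τ
and is reported unconverged rather than fitted.

The characteristic length ℓ of an event is defined here as the
equivalent-circle diameter of the fused droplet in the final frame,
2·sqrt(area/π)·pixel_size. The inverse capillary velocity η/γ is the
least-squares slope of τ against ℓ forced through the origin
(η/γ = Στℓ / Σℓ²), because τ → 0 as ℓ → 0 in capillary relaxation; a
single event degenerates to the ratio τ/ℓ.

## Kissing-loop sequence rules

RNA alphabet {A, C, G, U}; reverse complement uses Watson–Crick pairs only
(wobble G·U is *not* complementary here — wobble variants are
affinity mutants, not designed pairs). A KL interaction sequence is
palindromic iff it equals its own reverse complement; odd lengths never
are. Design-space counting: 4^k total k-mers, 4^(k/2) palindromes for even
k (a palindrome is fixed by its first half), hence a 4^(k/2)-fold
expansion when non-palindromic heterodimer pairs are allowed — 64-fold at
k = 6. A valid heterodimer pair is mutually reverse-complementary, has
exactly four G/C and two A/U bases per member (similar duplex stability
across designs, interpreted per-duplex), and neither member palindromic.

Strand assembly for three-arm single-stranded nanostars: each arm is a
stem whose 3′ half must be the reverse complement of its 5′ half, closed
by the 9-nt KL domain `AA + interaction(6) + A`; arms join with two-adenine
spacers, and the third spacer is the nick realized as the strand termini
(the nick's position is not dictated by the design rules; placing it at
the termini is this package's convention). Three 15-bp stems therefore
give 3·(30+9) + 2·2 = 121 nt. The DNA template helper emits the
non-coding template (reverse complement of promoter + transcript) and the
21-nt promoter-complement strand: the 17-nt T7 promoter plus the 4-nt
sealing domain 5′-GCGC, which assumes transcripts begin with GCGC and
warns otherwise. Aptamer-bearing strands are plain concatenation with a
warning — the junction convention is unspecified by the design rules.

## Synthetic data generator

The generator replaces unavailable raw micrographs with fields whose
ground truth is known exactly:

* **Droplet fields.** Radii are lognormal (default median 2 µm, σ_log 0.3
  — the few-µm droplet scale seen in epifluorescence at 0.5 µm/px);
  droplets are uniform disks at amplitude 100 over background 10,
  blurred by a Gaussian PSF (σ = 1 px) and corrupted by additive Gaussian
  noise (σ = 2). Spherical morphology rejection-samples centers so droplets
  never touch (with a PSF-sized gap so blurring cannot merge them);
  placement failure after a bounded retry budget raises. Network
  morphology chains overlapping disks along random walks of at most
  `network_walk_steps` steps, reproducing ramified aggregates
  qualitatively without inventing coarsening physics. Overlaps are painted
  with `max`, keeping the union at uniform amplitude like a uniform dense
  phase.
* **Two-channel fields.** Each droplet gets composition f (fraction of
  species A): m = 0 gives f ∈ {0, 1}, m = 1 gives f = 0.5, linearly
  interpolated between. Channel brightness is `bleed @ (f, 1−f)` times the
  amplitude; the default bleed matrix [[1, 0.2], [0.15, 1]] models the
  spectral overlap of green/orange fluorogenic aptamers imaged in FITC and
  Cy3.
* **Fusion series.** The observable is the moment-ellipse aspect ratio, so
  the generator renders the coarse-grained ellipse itself (constant area,
  AR following the relaxation law) rather than two merging disks — the
  model the downstream fit assumes, realized exactly. Default cadence
  15 min; the default rendered droplet (area 900 µm² at 0.5 µm/px) is
  larger in pixels than the pictured few-µm droplets so that rasterized
  moments stay within the fit's round-trip tolerance.
* **FRAP.** Generated at trace level (two ROI mean series) because the
  normalization consumes ROI means only; bleach drop, single-exponential
  recovery, optional global `exp(−λt)` decay, defaults matching the
  5-s/30-s-pre/5-min-post acquisition cadence.

What the generator does *not* emulate: Poisson shot noise (additive
Gaussian is sufficient to exercise the threshold stage with one fewer
parameter), optical aberrations beyond the Gaussian PSF, stage drift,
nucleation/coarsening kinetics (fields are independent snapshots, not a
growth trajectory), and nanostar binding thermodynamics. Passing tests
therefore validate the measurement chain — segmentation, chord statistics,
angle histograms, normalizations, fits — not the biophysics of any real
sample; experimental numbers that depend on the original raw images
(per-variant condensate counts and chord distributions, measured FRAP
curves) are covered by property-based tests instead of value reproduction.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give bit-identical images, tables and TIFFs. Default test problem
sizes (256²–384² px fields, 10–20 droplets, 20 classification seeds,
100 random oracle masks ≤ 64²) keep the full suite under ~10 s while
leaving every statistic far from its decision boundary. Degenerate inputs
are errors, not silent NaNs: constant frames (Otsu undefined), empty chord
distributions, zero ROI maxima, all-zero characteristic lengths.

## Known limitations

* No watershed splitting; fields dense enough for frequent droplet contact
  will undercount condensates (chords remain valid).
* The demixing verdict compares peak positions only, not peak weights; a
  strongly unbalanced mixture with one vanishing population can read
  `indeterminate`.
* η/γ from a single event inherits the full uncertainty of its one ℓ; the
  pooled regression is preferred when several events are available.
* The aspect-ratio bias of moment ellipses on small rasterized objects
  (~2% near 10 px minor semi-axis) sets the floor on fit accuracy from
  rendered image series; trace-level series have no such floor.
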