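# Methods

## Colour population

Leaf and patch colours come from a single CIE-LAB population. Because the
calibrated forest-floor photograph behind the original palette is not
redistributable, the default population is parametric and synthetic:
lightness L ~ N(45, 12) clipped to [0, 100]; each chromatic axis is a
contaminated normal — 90% of pixels from a tight earth-tone mode
(A ~ N(12, 4), reddish-brown; B ~ N(25, 6), yellow-brown) and 10% from a
5×-wider component emulating atypical pixels (bright foliage, wet dark
ground). The heavy-shouldered mixture matters: after the ±1-SD trim on A
and B (sample SD, n−1, computed once on the input in a single joint
pass, boundary values kept) about 76% of colours survive, as expected of
a natural image dominated by one substrate. Image-derived populations
can be substituted via CSV (columns L, A, B).

Patch colours are drawn uniformly from lightness-percentile bands
(35–45 dark, 55–65 light; ranks by average-tie linear interpolation on
the empirical CDF, endpoints inclusive). A population without usable
lightness contrast raises a degenerate-population error rather than
silently producing a flat texture.

LAB ↔ display conversions go through scikit-image (D65 sRGB) plus the
standard sRGB transfer curves, since scene compositing and shadow
photometry operate in *linear* RGB. Out-of-gamut colours are clipped
channel-wise and flagged (round-trip discrepancy > 0.01); clipping is
deliberate because large edge offsets can push L near the gamut edge.

## Backgrounds

Leaf lengths follow `20 + Gamma(k, θ)` with (k, θ) = (1.12432, 8.04375),
solved so the mode is 21 px and the 95th percentile 46 px; the gamma
family is the simplest positively skewed law with enough freedom for all
three printed constraints. Widths are 20% of length. The silhouette is a
vesica (intersection of two discs): convex, elongated, pointed — any such
mask preserves the statistics that matter downstream (edge density,
size). Stamping is sequential with uniform random position/orientation,
later leaves occluding earlier ones; the same seed reproduces a canvas
bit-identically.

Shadows: each leaf's silhouette translated left by a width drawn from
|N(2.4, 3)| px (rounded to whole pixels for the raster shift), minus the
leaf, stamped immediately before its leaf, multiplying linear intensity
by 0.30. The 95th percentile of the width law converts to 0.23° at the
display scale (20 px = 0.62°, small-angle linear conversion throughout).
The nominal "peak width" of the half-normal in degrees is not asserted
anywhere: at this scale it is a histogram-binning artefact.

Default search canvas: 3500 × 1170 px, so the 350-px target is 1/10 of
the long axis and each of the 8 cells (4 × 2) can hold it. At the
printed leaf size law, 15,000 stamps cover roughly a third of that
canvas (Poisson coverage `exp(−nA/area)` with mean silhouette area
A ≈ 115 px²); the coverage test therefore checks agreement with that
prediction — a guard against mis-sized masks — rather than full
coverage, which the printed numbers cannot produce on this geometry.

## Camouflage texture

White noise is filtered in the Fourier domain by a radial Gaussian
amplitude `exp(−(d−μ_c)²/2w²)`. The recipe's centre parameter 0.048 is
read as a normalised frequency with 1 = Nyquist (the convention of the
numerical environment the recipe comes from), giving an effective centre
μ_c = 0.024 cycles/px, pass-band wavelength ≈ 42 px and posterised patch
width ≈ 21 px — matching the modal leaf length, which is the function of
the texture (a spatial match between camouflage patches and background
elements). The recipe's width parameter (120) is stored verbatim but its
unit convention is not recoverable; the operative bandwidth defaults to
w = 0.010 cycles/px, calibrated so the median patch breadth (median
same-label run length along rows and columns) sits at 21 px while DC
amplitude stays below 6% of the pass-band peak. Both numbers are
configurable on `FilterSpec`.

Posterisation thresholds at the median (ties to the dark class, for
determinism); on continuous textures with even pixel counts the split is
exactly 50/50. Boundary distance is the Euclidean distance to the
nearest opposite-label pixel centre minus one pixel — the two
half-pixels flanking the inter-pixel boundary — so boundary-adjacent
pixels sit at distance 0 and the edge ramp attains the full offset
exactly at the boundary and the plain patch colour exactly at the width.
Light and dark ramps are driven by the same distance map, so they abut
at the boundary, where the pattern's contrast is highest. Lightness is
clipped to [0, 100] with a flag; A and B are never modified.

The snake target is a sinusoidal tube (2 undulation periods, body width
12% of length, elliptical taper) — only the length and an elongated
"snake-like" outline are constrained; compositing copies masked texture
pixels with no blending. The depth-judgement layout restores a leaf-free
central band (4.49° × 13.80°) so occlusion cannot act as a depth cue.

## Designs

Balanced factorials with a single shuffle and per-trial seeds drawn from
the design generator. Search experiment 1: control + full enhancement at
widths {8, 16} × offsets {20, 40}, × 2 shadow levels × 8 cells = 80
trials ("twice within each location" is realised as the two shadow
levels). Experiment 2: control + {no_high, no_low, square} × {20, 40} at
width 16 — the trial total is not printed in the source description, so
the balanced 7 × 2 × 8 = 112 design is the default (configurable).
Experiment 3: {none, both, no_high, no_low} × 2 backgrounds × 25 = 200
trials, central vertical target, width 0.53° (17 px at the default
scale).

## Synthetic observers

Search: `log RT = intercept_p + effect_condition + N(0, σ_w)` with
intercepts N(log 5 s, 0.35) and σ_w = 0.20 — log-normal RTs with
additive effects on the log scale, which makes the analysis's
assumptions exactly true under the null. Error probability is
`clip(error_base + error_slope · (log RT − intercept_p))`, coupling
errors to slow trials (the empirical pattern that rules out a
speed–accuracy trade-off); error trials are generated and then discarded
by the analysis, exercising the exclusion path. Depth: ordinal probit —
unit-variance latent around a per-condition shift, cut at (−0.5, 0.5).

What this generator does *not* emulate: fatigue and learning over a
session, heavy-tailed RT contamination (anticipations, lapses),
participant × condition interactions, and any actual visual search
process over the rendered stimuli (behaviour is driven by the condition
labels, not the pixels). Passing recovery tests therefore validates the
statistical chain, not claims about human vision.

## Statistics

Preprocessing excludes error trials first, then z-scores log RTs with
each participant's own mean and sample SD over their correct trials;
participants with fewer than two correct trials are dropped with a
warning. Control-differencing is per participant within shadow level, so
any per-participant shift cancels exactly.

The JZS Bayes factor integrates the Cauchy(0, r) effect-size prior via
its normal-mixture representation (g ~ InverseGamma(1/2, r²/2)) with
adaptive quadrature; the central-t likelihood ratio is folded into the
integrand so magnitudes stay moderate, and the quadrature's relative
error is reported as `num_error`. Tests pin it against an independent
noncentral-t × Cauchy grid quadrature (10⁻³ relative across a t/n/r
grid) and against a third-party implementation. Two-tailed throughout;
the paired design is realised as a one-sample test on control-relative
differences. Evidence buckets at BF = 1, 3, 10, 30, 100 (natural-log
thresholds), direction H1 if log BF₁₀ > 0 else H0; log BF₁₀ = 0 is
labelled anecdotal-H0 by convention. Bayesian ANOVA model comparison is
deliberately out of scope.

Bootstrap CIs are percentile bootstraps of the mean (default 10,000
resamples, level 0.95). At n = 10 the percentile method's true coverage
is ≈90%, a known small-sample property the tests assert honestly rather
than the nominal 95%. Shapiro–Wilk comes from scipy.

## Problem sizes used in the checks

Generator statistics use 100,000 draws. Texture-scale checks use 20
seeds of 256² textures. Null calibration and effect recovery each use
100 simulated datasets of the full 80-trial, 10-participant design; the
recovery check compares the bootstrap CI against the analytic expected
score `(δ/σ_tot) · E[σ_tot/s]`, where σ_tot² = σ_w² + p(1−p)δ² includes
the between-condition variance the injected effect adds and the last
factor is the exact chi-distribution mean-inverse correction for the
empirical SD at 80 trials. Coverage checks run on a 500 × 500 tile at
the full-display leaf density.

## Known limitations

The exact functional form and units of the original Fourier filter are
unrecoverable from the source material; the Gaussian band-pass here
preserves its one verifiable property (patch scale = leaf scale) and
flags both original parameters as provenance. The synthetic colour
population is a stand-in with matched constraint behaviour, not a
calibrated measurement. The pipeline makes no attempt to reproduce human
reaction times or the published Bayes factors, which require the
original participant data.
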