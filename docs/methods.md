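# Methods

`phenoshoot` implements the analysis half of an automated shoot-phenotyping
workflow for pea-like crops: projected green area from multi-view RGB
images as a biomass proxy, growth statistics over a cold-treatment time
course, and pulse-amplitude-modulation (PAM) chlorophyll-fluorescence
quenching analysis of photosystem II (PSII) efficiency. This note records
the models, the numerical choices, and what the synthetic benchmarks do and
do not demonstrate.

## Green-mask segmentation

A plant's "green" occupies a compact arc of the hue circle, so foreground
extraction happens in HSV space: a pixel is plant if its hue lies on a
configurable arc (default 80°–160°) and it is chromatic (S > 0; hue is
undefined at S = 0, so achromatic pixels are always background). As an
alternative to the fixed arc, Otsu's threshold can split the hue channel;
the fixed arc is the default because acquisition in a phenotyping cabinet
is standardized enough to predefine it. Our Otsu uses the fixed 256-bin
histogram and returns the smallest threshold minimizing within-class
variance; a constant channel is reported as degenerate rather than guessed
at.

Hue thresholding alone is brittle exactly where pea shoots are hardest:
tendrils one or two pixels wide. A single chromatically noisy pixel can
disconnect a whole offshoot. We therefore fuse the hue mask with a Canny
edge map of the value (brightness) channel:

1. **Anchoring.** Edge components (8-connected) within 2 px of the hue mask
   are kept; the 2-px reach is needed because the Canny contour of a thin
   structure runs about one pixel off the structure it outlines. Isolated
   background edges (pot rims, soil texture) are discarded.
2. **Shell exclusion.** Kept edge pixels within 1 px of the hue mask merely
   re-trace its boundary and are not added; only pixels extending beyond
   that shell — a tendril the threshold lost — enter the fused mask. The
   fused mask is thus always a superset of the hue mask and a subset of
   hue ∪ edges.
3. **Bridging.** Canny marks the two flanks of a thin offshoot, not its
   centre line, so edge-derived additions are dilated (default radius 3,
   covering flank offset plus tight curls) and gated on brightness: a
   bridged pixel must be at least as bright as the midpoint between the
   plant and background median values. The gate is what lets bridging fill
   a tendril without leaking onto dark soil; on an image where the hue mask
   is already complete, fusion adds nothing and the mask passes through
   bit-identically.

Post-processing applies, in order: median filter, morphological closing,
opening, and removal of components below `min_component_px` (default 10).
All radii default to 0 — the speckle filter is the component-size rule —
so the default post-processing never moves a mask pixel of a clean
segmentation. Tray images are split into per-plant masks by assigning
connected components to equal-width vertical strips by centroid column.

## Calibration, area, and growth statistics

Pixel areas become mm² through per-view factors measured from reference
objects of known area (mean of `known_mm2 / px_count` per view). The three
projections combine as A = √(Ax² + Ay² + Az²); a missing view counts as
zero projection and is logged (this biases A low but keeps it defined).

Normalized green area (NGA) divides each day's area by the first-day area,
making plants of different initial size comparable; it is unit-free and
hence independent of calibration. Relative growth rate between two
measuring days is

RGR = (mean ln W₂ − mean ln W₁) / (t₂ − t₁)   [per day]

where the mean is over log-areas of the group — not the log of mean
areas; the two differ under size heterogeneity and only the former makes
RGR the mean of per-plant exponential rates. Intervals are consecutive
measuring days by default, with day-1-anchored intervals available as a
flag.

## Fluorescence quenching analysis

The recording protocol (all defaults configurable): measuring flashes only
for 0–5 s (F0 window); an 800 ms saturation pulse at 5 s (FM); 17 s dark
relaxation; 70 s of actinic light with saturation pulses 8, 18, 28, 48 and
68 s after actinic onset. FM′ comes from the last actinic pulse; F(t) is
averaged over a 1 s window immediately before it (a window is
noise-robust; set it to one sample period for a point estimate). Pulse
windows reduce by max by default, with plateau-mean and top-quartile-mean
offered because instruments differ in whether they report the pulse
maximum or a plateau estimate. Pulses during the dark relaxation are
ignored; FM comes only from the dark-adapted pulse. Traces are assumed
already flash-demodulated by the instrument; `demodulate` subtracts raw
before/during-flash pairs when they are not.

The light-adapted minimal fluorescence is estimated as
F0′ = F0 / ((FM − F0)/FM + F0/FM′), evaluated in the single-division form
F0·FM·FM′ / (FM′·(FM − F0) + F0·FM); the no-quenching limit FM′ = FM
reduces algebraically to F0 and is returned as such, keeping that limit
exact in floating point. The six PSII parameters follow their standard
definitions (Φ_Po = FV/FM, Φ_P = (FM′−F(t))/FM′, Φ_PSII = (FM′−F0′)/FM′,
q_P = (FM′−F(t))/(FM′−F0′), Φ_f,D = F(t)/FM, Φ_NPQ = F(t)/FM′ − F(t)/FM).
Two identities hold by construction and serve as numerical self-checks:
Φ_P + Φ_f,D + Φ_NPQ = 1 and Φ_P = q_P·Φ_PSII, both satisfied to ~1e-16 in
practice. All six are invariant to rescaling the levels, so instrument
units never matter.

Pixel-wise maps apply the same window logic along the time axis of an
image stack; yields are computed only where F0 exceeds a noise floor
(default 1e-6) to avoid division blow-ups on background pixels, and
region summaries report medians with lower/upper quartiles.

## Group statistics

Two-group comparisons use the Mann–Whitney U test: exact null enumeration
when n₁·n₂ ≤ 400 and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections (both via
`scipy.stats.mannwhitneyu`). Spearman's ρ is the Pearson correlation of
midranks; its two-sided p value is a permutation p — exhaustive for
n ≤ 8, seeded Monte-Carlo (10 000 resamples, add-one estimator) above.
Quartiles use numpy's linear interpolation rule, and every summary table
records the rule's name so results are auditable. No multiple-testing
correction is applied; per-day p values are reported raw.

## Synthetic data: what it emulates and what it does not

The plant generator renders a random branching skeleton — a jittered stem,
side branches, and curly tendrils of configurable width (1–2 px) — in
plant-green hue with per-pixel hue jitter over a flat or soil-textured
background (low-frequency brightness undulation plus speckle), with
optional Gaussian pixel noise. Ground-truth masks are the rasterized
skeleton itself, exact by construction. The three views are independent
renders, standing in for genuinely different silhouettes. The
tendril-erasure fixture shifts the hue of one whole tendril to soil brown
while preserving brightness: this is precisely the chromatic failure the
edge-fusion step exists to fix. The most isolated tendril is chosen
because an offshoot lying on the plant silhouette has no brightness edge
— that failure mode is physically unrecoverable by edge tracking and is
not what the fixture tests.

The generator does not model leaf venation, specular highlights,
illumination gradients, occlusion between plants, or perspective; passing
its benchmarks shows the pipeline's logic is correct under the stated
noise model, not that the default hue arc or Canny thresholds are optimal
for any particular camera.

Growth series follow W(t) = W₀·e^{rt} with per-observation lognormal noise
(default σ = 0.05, 15 plants, measuring days 1, 5, 8, 12, 15, 19, 21 —
twice-weekly screening over a three-week treatment). Default rates give a
~3.5-fold area gain over days 1–21 for the fast regime (r = ln 3.5/20 ≈
0.063 d⁻¹) and ~2.5-fold for the slow regime (r ≈ 0.046 d⁻¹), the
contrast a cold-acclimation screen is expected to resolve. Quenching
traces are piecewise-exact plateaus under the protocol timing (transients
are truncated exponentials, so plateau windows are bit-exact), which is
what makes noiseless level recovery an equality check rather than a
tolerance check.

## Problem sizes and determinism

The bundled checks use 20 plants × 3 views for segmentation recovery, 200
replicates for RGR coverage, 2000 null replicates for Mann–Whitney type-I
calibration, and 10⁴ random level quadruples for the partition identities
— sizes at which every quantity is stable to well inside its test
tolerance on a single CPU. Every source of randomness flows from an
explicit seed (numpy `SeedSequence` spawning per plant/day/trace), and the
CLI pipeline is bit-deterministic: identical inputs, configuration and
seed reproduce identical CSV bytes.

## Known limitations

* The hue arc, Canny thresholds and bridge radius are defaults for
  standardized cabinet imaging, not fitted constants; field imagery will
  need retuning via the config file.
* Tray splitting assumes pots in a horizontal row; other layouts need a
  different assignment rule.
* An offshoot overlapping the plant body cannot be recovered by edge
  fusion (no brightness contrast), only by the hue mask.
* Quenching analysis covers the single steady-state partition; fast
  induction transients (O-J-I-P) and photoinactivation yields are out of
  scope.
* RGR assumes areas strictly positive; dead or fully occluded plants must
  be excluded upstream.
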