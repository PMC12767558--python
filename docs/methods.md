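# Methods

This note documents the models, conventions and numerical choices behind
`periquant`, in the order data flows through the package.

## Geometry and calibration

All physical measurements assume a square pixel grid with pitch
√(pixel area); the default calibration of 17.43 μm²/pixel gives a pitch of
4.1749 μm ("approximately 4.18 μm" when rounded). Calibration is always
supplied by configuration, never read from image metadata — TIFF resolution
tags vary across scanners and silently wrong units are worse than a hard
error. The grid origin is top-left, indices are row-major and 0-based, and
connectivity is 8-neighbour (3×3 structuring element) everywhere.

The analysis regions around the implant cross-section are:

- **Trephine-defect ROI** — a vertical band of the defect width (default
  5 mm) centred on the implant centroid column, spanning the image rows,
  minus the implant body. The implant disc (default 7 × 1 mm cross-section)
  is deliberately wider than the defect, mirroring press-fit insertion, so
  its lateral ends fall outside the ROI.
- **Implant surface** — dilate the implant mask by one pixel (3×3), remove
  the implant, clip to the defect. This one-pixel ring is the BIC
  denominator; the denominator therefore excludes surface pixels clipped
  away at the defect boundary.
- **Periimplant layers** — per-pixel Euclidean distance (centre to centre,
  scaled by the pitch) to the nearest implant pixel, binned half-open:
  label k covers (k−1)·100 μm < d ≤ k·100 μm, clipped to the defect.
  Half-open bins make the three layers an exact partition of the 300 μm
  band: Σ layer areas = area(band ∩ defect) with no double counting.
  Euclidean distance (not per-row offsets) was chosen; for a
  straight-edged implant the two differ only at corners. At the default
  pitch the immediate layer reaches 23 axial pixel steps (96.0 μm ≤ 100 <
  100.2 μm).

## Segmentation

Bone is detected in HSV space: hue within ±40° of 350° (wrap-around red,
the Alizarin signature), saturation ≥ 0.30, value ≥ 0.15. Hue isolates the
stain robustly under brightness noise; an RGB red-dominance rule is
available as an alternative. The implant is the largest connected
near-black component (max-channel value ≤ 0.35, minimum area 100 px); area
ties break to the top-left-most centroid, and exactly one component is
returned — no component above the minimum area signals an unusable
section. CD31 positivity is a plain threshold on the target fluorescence
channel, Otsu by default.

Two clean-up steps exist but default **off** (radius-0 opening, no
small-component removal): the phantom plants one-pixel-thick contact seams
and exact-count trim pixels, and any default morphology would destroy
them, breaking the noise-free oracle-equivalence guarantee (a noise-free
phantom must segment pixel-exactly). At the generator's default noise
level the colour classes are separated by far more than the noise scale,
so the clean-up is not needed for the accuracy targets either; it becomes
useful only under much heavier, configurable noise.

Per-case "manual adjustment" of parameters is reproduced as explicit
per-image override mappings in the run configuration — never interactive
state — so a rerun is bit-identical.

## Phantom generator

The histology phantom renders, at the study geometry and calibration, a
dark implant rectangle, a defect band, and bone as seeded random discs
(radius 3–10 px) planted zone by zone. Requested quantities are realized
*exactly at pixel quantization*:

- per-zone bone-area fractions (immediate/intermediate/remote/remainder,
  defaults 0.55/0.45/0.40/0.35, spanning the densities reported for such
  defects) — the final disc is trimmed pixel-by-pixel in a fixed order to
  hit round(f·|zone|) exactly;
- the bone–implant contact fraction (default 0.5) — a contiguous collar of
  round(f·|S|) surface pixels starting at a seeded random position.

Zone fills avoid the surface ring so the planted contact stays exact; only
when a zone-fill target is unreachable without surface pixels (extreme
fill requests) does bone overflow onto free surface pixels, and the truth
record then reports the realized (larger) contact. Truth metric values are
computed from the truth masks by the metrics module itself, so truth is
self-consistent by definition, and all randomness flows through one
`default_rng(seed)` in fixed order — identical spec + seed is
bit-identical output.

Colour model: bone (185, 40, 70), background (195, 200, 210), implant
(25, 25, 30) on the 8-bit scale, uniform per class by default, plus
additive Gaussian RGB noise with SD 8 as the default acquisition-noise
level — a modest camera-noise figure chosen so class separations (≈ 40°
hue, ≈ 0.4 value) sit many noise SDs apart, as they do for a well-stained,
well-exposed slide. Nothing in the underlying study design constrains
illumination or colour variability, so these are free design choices,
configurable for robustness sweeps (`ColorModel.spread`, `noise_sd`).

What the phantom does **not** emulate: stain gradients and bleed-through,
slide-scanner vignetting/stitching, out-of-plane (3-D) trephine curvature,
decalcification artefacts, or touching tissue types with intermediate
colours. Passing the recovery tests therefore demonstrates correctness of
the measurement chain (geometry, counting, unit conversion, statistics) —
not segmentation robustness on degraded real-world staining, which is why
the segmentation thresholds remain per-image overridable.

The fluorescence phantom rasterizes a 725 × 543 μm field (floor to the
pixel grid, so a full-field request saturates every pixel) with planted
positive blobs at an exact pixel count, nuclei in a second channel, and
16-bit levels (background 2 000 / positive 30 000, noise SD 200); the
background/positive midpoint is the natural recovery threshold and Otsu
lands next to it.

The paired-cohort generator produces unit × condition matrices
baseline_i + effect_j + ε with per-unit baselines (SD 10 around 50) that
paired tests difference away; it feeds the statistics tests, including
type-I-error simulations.

## Statistics

Wilcoxon signed-rank: zero differences are dropped, |d| midranked,
W = min(T⁺, T⁻). The asymptotic two-sided p uses
z = (W − n(n+1)/4)/√(n(n+1)(2n+1)/24 − Σ(t³−t)/48) **without continuity
correction** — this is the variant whose n = 6, tie-free p-values take the
familiar printed values 0.028 (T⁻ = 0), 0.046 (1), 0.075 (2), 0.116 (3),
…, 0.917 (10); with the correction they would differ. The exact mode
enumerates the null distribution of the rank sum over all 2ⁿ sign
assignments via subset-sum convolution (identical to brute-force
enumeration when magnitudes are untied, which the mode requires);
p = 2·P(T ≤ W), giving the n = 6 floor 2/64 = 0.03125.

Convergence: the exact distribution approaches the *continuity-corrected*
normal CDF with max two-sided gap 0.036 at n = 6 and 0.0066 at n = 25
(below 0.01). The uncorrected variant shipped for report p-values keeps a
larger near-centre gap (0.099 at n = 6, 0.015 at n = 25, at statistics
where p ≈ 0.6); in the tail region that decisions rely on the two agree
closely, and the exact-null size of the uncorrected test at nominal 0.05
and n = 6 is 4/64 = 0.0625.

Friedman: within-unit midranks, Conover's χ² form
T = (k−1)·Σ(R_j − n(k+1)/2)²/(A − C) with A = Σr², C = nk(k+1)²/4, which
equals the classic statistic divided by the tie-correction factor; all-
constant rows yield statistic 0 and p = 1 by convention. p-values are
reported at 3 decimals; pairwise matrices are lower-triangular.

Multiplicity: the per-comparison Bonferroni level fwer/m is computed and
reported (0.05/14 = 0.36 %), but pairwise p-values are also reported raw —
both thresholds appear in output, matching how such results are usually
read. Sample size uses the standard z-approximation
n = ⌈2(z₁₋α/₂ + z_power)²(σ/δ)²⌉ (two-sample; drop the 2 for paired).
Note these standard formulas give n = 16 per group for δ = σ at α = 0.05 /
80 % power, and n = 15 for a paired design at α = 0.36 %; a cohort of 6 is
*not* recoverable from them at δ = σ = 10 % — the study-design number
likely came from a different (unstated) variant, so the module implements
the standard formulas and leaves that discrepancy documented here.

## Release analytics

Loading by depletion: loaded = V·c/1000 − residual (μg), per-area over the
exposed surface; a residual above the offer raises a mass-balance error.
Cumulative release is the running sum over the exchange schedule (days 1,
2, 3, then every 3 days to day 21), non-decreasing and bounded by loading.
Released fraction = 100·cumulative/loaded. The packaged tables carry the
per-condition means (SDs kept as metadata, not propagated — fractions are
point ratios). Two readings of the tables are preserved deliberately:
(i) the four collagen/heparin-PEM growth-factor fractions span 27.7–39.1 %
(the "27–39 %" summary matches all four conditions, though the two BMP-2
fractions alone are both ≈ 28 %); (ii) the three-disc in vitro protocol
line states 3 μg per specimen while 160 μL × 75 μg/mL over three discs
computes to 4 μg — both values are stored
(`release.IN_VITRO_PER_SPECIMEN_UG`), neither silently corrected.

## Aggregation and reporting conventions

Sample SD uses n − 1; a single-section disc reports its value with SD 0
and a `single_section` flag. Percentages print at one decimal and areas at
three in the CLI CSVs. Bone outside the defect ROI is never counted. The
pipeline derives one child seed per (condition, unit, section) via
`SeedSequence` spawn keys, writes per-section and per-disc CSVs, pairwise
p-matrices and a manifest (seed, config hash, version), and a rerun with
the same configuration is byte-identical.

## Problem sizes used in the tests

Unit tests run on a scaled-down geometry (2 × 0.5 mm implant, 1.4 mm
defect) where physical constants are not under test; the study geometry
(7 × 1 mm implant, 5 mm defect, ≈ 2 000 × 530 px) is used wherever the
printed numbers matter — the 1198-column defect width, the 23-pixel
immediate layer, and the 27-phantom (3 contact × 3 immediate-fill × 3
base-fill) × two-noise-level recovery grid. Recovery on that grid is exact
at zero noise and well within 2 % relative at the default noise level.

## Known limitations

2-D band model only (no cylindrical trephine geometry), no subpixel
surface representation, no stain deconvolution or machine-learned
segmentation, no kinetic release-model fitting, and the phantom's colour
simplicity means segmentation-parameter robustness on real slides must be
assessed per dataset via the override mechanism.
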