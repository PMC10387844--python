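# Methods

## Spectral model and measurement procedure

A spectrum is a trace A(ν) on a wavenumber grid, stored ascending; the
default synthetic grid runs 450–3998 cm⁻¹ at 4 cm⁻¹ steps, matching a
mid-IR survey scan at 4 cm⁻¹ resolution. Analysis happens per *region*:

| region      | span (cm⁻¹) | baseline anchors | normalization band |
|-------------|-------------|------------------|--------------------|
| lipid       | 2800–3020   | 2800, 3020       | CH₂ asym, 2924     |
| fingerprint | 890–1478    | 890, 1478        | PO₂⁻ sym, 1082     |

**Baseline.** The model is a straight line through the trace values at the
two anchors (values obtained by linear interpolation onto the anchors, so
anchors need not be grid points). This is the simplest model consistent
with "two selected points" practice; because anchor choice is otherwise
irreproducible, anchors are explicit configuration, defaulting to the
region edges. The lipid region's upper edge is 3020 rather than the 3012
display limit often plotted, so that the olefinic band's full ±8 cm⁻¹
search window lies inside the region. Subtracting a chord makes every
downstream quantity exactly invariant to an additive affine background
a + b·ν; curvature beyond affine is *not* removed (see Limitations).

**Band measurement.** Each catalog band has a search window of
center ± 8 cm⁻¹ (two grid steps): wide enough to follow the observed
position shifts (~1–2 cm⁻¹), narrow enough not to capture the nearest
neighbor (1156 vs 1171 cm⁻¹ are 15 cm⁻¹ apart). The discrete maximum in
the window (ties broken toward the nominal center, then toward lower
wavenumber) is refined by the vertex of the parabola through the apex
sample and its two neighbors. Intensity is the vertex height above the
region baseline — apex height, not integrated area. If the discrete
maximum falls on the window edge the measurement is returned unrefined
with an `edge_flag`; a refined position is therefore only claimed for
apexes whose three-point stencil is interior to the window. On noiseless
pseudo-Voigt bands at 4 cm⁻¹ sampling the worst position error, measured
by scanning planted centers across ±3 cm⁻¹ of sub-grid offsets, is
0.11 cm⁻¹ (FWHM 15) and 0.07 cm⁻¹ (FWHM 20) — comfortably below the
~1–2 cm⁻¹ shifts of interest. The vendor software that motivated this
estimator is undocumented; three-point parabolic refinement is this
package's documented choice, not a claim about any instrument's internals.

**Indices.** Ratio indices (lipid/protein, chain length, olefinic, RNA)
are ratios of apex heights within one region and are scale-free, so they
need no explicit normalization; standalone fingerprint intensities (996,
1156, 1171 cm⁻¹) are referenced to the PO₂⁻ symmetric apex. All metrics
are computed **per replicate**, then summarized as mean ± sample SD
(n−1): group SDs and rank tests require per-replicate values, and the
averaged group spectrum (pointwise mean of baselined replicates on the
finest replicate grid) is produced for display/export only. Percent
changes are computed from group means, 100·(t̄ − c̄)/c̄, which reproduces
the arithmetic of reported mean pairs (e.g. 1.0769 → 1.3018 is +20.9%).

## Statistics

The exact Mann–Whitney U test enumerates all C(n₁+n₂, n₁) labelings of
the pooled ranks and reports the symmetric two-sided p,
P(|U − n₁n₂/2| ≥ |u − n₁n₂/2|), whenever the pooled sample is tie-free
and has ≤ 12 observations (covers n = 3 vs 3 at trivial cost; enumeration
is deterministic). Ties or larger samples fall back to the midrank normal
approximation with tie-corrected variance and continuity correction, and
the result says so. At n = 3 vs 3 the smallest attainable exact two-sided
p is 2/20 = 0.1; published sub-0.1 p-values at that size cannot come from
this test and the package makes no attempt to reproduce them.

The unpaired t-test defaults to the pooled-variance (Student) form, which
is exactly calibrated under normality at these tiny sizes — its simulated
null rejection rate at α = 0.05 (n = 3/3, 5000 reps) sits inside the
binomial 99% CI of 0.05. The Welch form (`equal_var=False`) is available
for clearly heteroscedastic groups but is markedly conservative at
n = 3/3 (rejection rate ≈ 0.036), which is why it is not the default.

## Synthetic data: what is emulated, and what is not

Spectra are sums of unit-apex pseudo-Voigt bands,
η·Lorentzian + (1−η)·Gaussian with η = 0.3, FWHM 15 cm⁻¹ in the C–H
region and 20 cm⁻¹ in the fingerprint (typical condensed-phase widths —
configuration, not claims about any particular cell line), plus a
polynomial baseline (degree ≤ 2, default 0.01 + 2·10⁻⁶·ν) and additive
Gaussian noise (default SD 5·10⁻⁴ absorbance, a realistic survey-scan
noise floor).

**Calibrated planting.** Band parameters are planted *apex heights as the
measurement defines them*. Raw component amplitudes differ from measured
apexes by several percent — band-tail overlap (2852 vs 2872 cm⁻¹ at FWHM
15), baseline-anchor leakage, and the parabola-vertex bias for off-grid
centers (up to ~2.8%) — so the generator calibrates amplitudes by damped
Newton iteration (analytic cross-talk Jacobian, residuals evaluated with
the pipeline's own baseline + apex measurement). A noiseless simulated
spectrum therefore reproduces every planted apex, hence every planted
ratio, to ~10⁻¹² relative error, making planted-parameter recovery a
meaningful end-to-end regression check rather than a loose approximation.

One corner is not exactly attainable: the measured apex is piecewise
smooth in the amplitudes and jumps slightly when the discrete argmax flips
grid points. The knockdown preset's treated olefinic apex (planted at
0.235× of an already small band, on the shoulder of the C–H tail ramp)
falls inside such a jump gap; calibration returns the closest attainable
spectrum, ~0.7% off target. Tests assert the tight (0.2%) recovery on the
cisplatin preset — the standard regression fixture — and the knockdown
olefinic percent change at ±1 percentage point.

**Group structure.** A `GroupEffect` applies multiplicative factors to
selected band apexes and additive center shifts (needed to plant position
shifts such as +2.17 cm⁻¹) in the treated group; replicate variability is
a per-band multiplicative scatter (default CV 0.04, chosen to match
reported group SDs of ~5% on ratio indices) plus optional position jitter
(default 0.3 cm⁻¹). All randomness flows from one seeded generator;
identical seeds give identical groups, which the suite tests.

Presets plant the reported group means of two HeLa contrasts (cisplatin
treatment; antisense lncRNA knockdown), e.g. lipid/protein 1.0769 → 1.3018
(+20.9%), olefinic 0.01283 → 0.011987 (−6.57%), RNA +16.68%, PO₂⁻ sym
1080.92 → 1083.09 cm⁻¹. With the default CV and n = 3, the sampling SD of
a recovered percent change is ≈ 5–6 points; the 1000-repetition 95%
envelope of the recovered lipid/protein change contains the planted
+20.9, and its median sits within ±3 points of it.

**Not emulated:** water-vapor/CO₂ lines, Mie scattering, detector drift,
ATR distortion, amide-band structure, and any curvature the two-anchor
baseline cannot remove. Passing tests therefore demonstrate correctness
of the *procedure* on well-behaved band spectra, not robustness to every
instrumental artifact of real measurements.

**DE tables.** `simulate_deg_pair` plants exact set structure — per-table
significant counts, the shared subset, parallel-up/down splits, discordant
remainder — with padj strictly below/above the 0.05 threshold and log2
fold-change magnitudes |N(0, σ)| + 0.25 (bounded away from zero so every
significant gene has a direction). The generator is its own oracle: the
concordance module must return the planted counts exactly, at any scale
up to genome size. The planted Pearson r is not controlled to a target
value; it emerges from the sign structure and is reported as computed.

## Numerical choices and degenerate inputs

- Argmax ties: nearest the nominal center, then lower wavenumber
  (deterministic reports).
- Collinear/convex three-point stencils: no refinement; the sample value
  is returned.
- Non-positive reference-band intensity → `NormalizationError` (the
  spectrum is noise-only or inverted); zero metric denominators →
  `DegenerateSpectrumError`; zero control mean → percent change undefined.
- Zero variance in both t-test groups: p = 1 for equal means, p = 0
  flagged "degenerate" otherwise.
- log2fc = 0 genes keep "shared" status but are excluded from parallel
  counts; Pearson r needs ≥ 3 shared genes and non-constant vectors,
  otherwise it is reported missing with a reason.
- CSV round trips write `repr(float)` so re-reading is bit-exact.

## Problem sizes

The test suite and acceptance script run simulations sized for a single
CPU: 1000 repetitions of n = 3 vs 3 group pairs for the percent-change
envelope (~70 s), 5000 null repetitions for t-test calibration, 200
random instances for exact-test/enumeration equivalence, 100 planted
centers for position accuracy, and a 20 000-gene DE-table pair. These
sizes give binomial/Monte-Carlo resolution comfortably finer than the
assertions they support.

## Known limitations

- Only two-anchor linear baselining is provided (no rubber-band, ALS or
  polynomial baselines), matching the analysis it implements.
- No multi-band deconvolution: heavily overlapped bands are measured as
  local apexes, and the 996 cm⁻¹ "almost vanished" regime pushes apex
  measurement to its discontinuity floor (see calibrated planting above).
- JCAMP-DX support covers XYPOINTS and uncompressed (X++(Y..Y)) XYDATA
  with wavenumber X-units only; SQZ/DIF/DUP compression and vendor binary
  formats are rejected explicitly.
- Gene identity in concordance is exact string match; no alias resolution.
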