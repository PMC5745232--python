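# Methods

## Scope and model overview

`ifscreen` implements the quantitative core of an immunofluorescence-based
functional drug screen for mixed patient-derived tumor cultures. The
biological setting: early biopsy cultures contain epithelial cancer cells
(cytokeratin-8/18 positive) mixed with stromal fibroblasts and an irradiated
feeder monolayer, so bulk viability readouts (ATP luminescence) cannot
attribute a drug response to the cancer cells. The assay counts cells per
class instead: all nuclei on a pan-nuclear channel (Hoechst), cancer cells by
a cytoplasmic CK8/18 marker channel, and dose-response curves are fitted per
subpopulation.

Because no raw screen images are publicly available, the package includes a
first-class synthetic-plate generator with per-cell ground truth. Every
downstream stage (segmentation, scoring, counting, normalization, fitting) is
validated against that ground truth.

## Population dynamics in the simulator

Each population grows exponentially with a Hill-type inhibition of its net
growth rate:

    n(t) = n0 · 2^((t/Td) · g · (1 − E(d))),
    E(d) = Emax · d^h / (d^h + (IC50·s)^h)

with doubling time `Td` (hours), media growth multiplier `g`, media IC50
shift `s`, and `E = 0` for drug-insensitive populations. Irradiated feeders
have `Td = ∞` and stay at `n0` in expectation regardless of dose, time and
media. With `Emax = 1` the model is cytostatic (full growth arrest at
saturating dose); an optional death-rate term `exp(−k·E·t)` produces
cytotoxic curves that fall below the day-0 level. Observed per-well counts
are Poisson samples of the expectation — counting statistics are the natural
default and match the replicate scatter seen in real well counts.

Default study conditions mirror the assay protocol: 250 cancer cells and a
~500-cell feeder monolayer per well, 12-dose 3-fold dilution series from
10 µM, quadruplicate treatment wells plus 4 vehicle controls and 4 day-0
wells, fixation after ~2 cancer doublings (96 h at Td = 48 h). Media
scenarios: `R10` (reference), `TCM` (growth-factor-rich: cancer growth ×1.25
and IC50 shifted right ×3 — the shift magnitude is a package choice, the
direction is the documented growth-factor effect), and `TCM_minus_E_I`
(EGF/insulin withdrawn: growth retained, shift 1).

## Rendering and morphology

Nuclei are 2-D Gaussians (diameter ~N(10, 1) px; fibroblast/feeder nuclei
elongated, axis ratio 3, area-preserving); marker-positive cells additionally
carry a flat-topped super-Gaussian cytoplasm disc (radius 1.6× the nucleus
radius) on the marker channel only. Drug-affected cancer cells swell: the
nucleus diameter scales by `1 + 0.3·E(d)`, mimicking the enlarged morphology
of drugged cells. Both channels share a Gaussian PSF (σ 1.2 px), an additive
background (100 counts) and Gaussian read noise (σ 8), and are clipped to
the configured bit depth (16-bit default).

Cells are placed by grid-accelerated hard-core dart throwing: centre
separation at least `0.75 · (r_i + r_j)` where `r` is the nucleus radius
along its major axis, so nuclei may touch but never coincide and elongated
nuclei do not merge along their long axis. The packing limit is a nucleus
area fraction of 0.40 of the frame; requests above it (or dart-throwing
saturation) raise an error naming the limit. "Density" in the quality
targets below is quoted relative to this limit.

Default frames are 512×512 px (one full-well site); the canned screen
scenarios use 768×768 px so that an endpoint well (~1500 nuclei) sits at
~20% nucleus area fraction, comfortably inside the regime where segmentation
is near-perfect. Multi-site wells are supported by multinomial splitting of
the well's cells across sites.

What the generator does *not* emulate: uneven illumination, vignetting,
focus drift, staining heterogeneity between wells, debris/apoptotic
fragments, cell clumping into colonies (placement is spatially homogeneous),
and marker expression loss. Passing tests therefore demonstrate the
correctness of the analysis logic under controlled optics, not robustness to
every real-microscope artifact.

## Image quantification

Local background is estimated per channel as a block median: the frame is
tiled into `background_window` (64 px) tiles, the tile medians are bilinearly
upsampled. This is an O(n) estimator of the same spatial scale as a sliding
64-px median and is exact for flat backgrounds.

Nuclear segmentation thresholds the background-subtracted channel at
`nuclear_threshold` (200 counts above local background), fills holes,
removes speckle below 30% of the minimal nucleus area, and — when
`split_touching` is on — separates touching nuclei by a watershed seeded at
local maxima of the lightly smoothed intensity (min peak distance half the
minimal width). Intensity peaks are the right seeds for blob-like nuclei;
distance-transform seeding is inferior for elongated fibroblast nuclei.
Accepted regions must have an equivalent diameter within
`[min_width, max_width]` = [6, 30] px; border-touching nuclei are excluded
(per-field estimates, consistent across conditions). Saturated or blank
frames yield zero regions plus a QC warning, never an exception.

Marker segmentation thresholds the marker channel at 150 counts above local
background and cleans the mask morphologically. Cell scoring expands each
nucleus by 5 px (non-overlapping between neighbours, a stand-in for the
whole-cell region) and calls a cell marker-positive when ≥ 30% of its
expanded region overlaps the marker mask. With the default optics this rule
gives per-class precision/recall ≥ 0.98 on co-culture fields at screen
densities; the residual error mode is marker fluorescence from a cancer cell
spilling over an immediately adjacent stromal nucleus.

All classifications are invariant to a common rescaling of both channels and
both thresholds; counts are invariant to site order and conserved
(`n_positive + n_negative = n_total` by construction).

## Assay logic

Day-0 baselines are arithmetic means across the day-0 replicate wells (a
single well is accepted with dispersion flagged undefined). The endpoint
rule fixes the drug plate at the first growth-plate timepoint where the
untreated marker-positive count reaches `fold_threshold` (default 4×, about
two doublings) of baseline; the rule is invariant to time units and count
scale. Normalization modes: `percent_highest` (each condition mean over the
maximum condition mean of the same drug and population, ×100) and
`fold_of_day0`; both preserve ordering of condition means.

## Dose-response fitting

The 4PL model `f(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill)` is fitted
to condition means by least squares (trust-region reflective). Fits are
unweighted by default: on the doublings scale the replicate variance is
nearly constant across doses, and with quadruplicates the per-condition SD
estimates carry only 3 degrees of freedom — occasional near-zero SDs would
dominate a 1/σ² loss and visibly distort the curve (observed as multi-fold
IC50 errors on otherwise clean plates). SD-weighting remains available as
an option for response scales with real heteroscedasticity. Initialisation:
top/bottom
from the data extremes, IC50 at the geometric mid-dose, hill 1; IC50 bounded
in [min dose/10, max dose×10], hill in [0.05, 20]. Zero-dose controls enter
as data points anchoring the top plateau (the model evaluates to `top` at
d = 0) but play no role on the log-dose axis. Constant responses and
optimizer failures return `converged = False` with a reason. The reported
IC50 is the curve's inflection concentration (relative EC50). 95% CIs come
from the asymptotic covariance.

**Response scale.** Pipeline IC50s are fitted on the *doublings* scale —
log2 of the fold change over the day-0 baseline — not on raw counts. Under
exponential growth the doublings response is affine in the fractional
rate inhibition `E(d)`, so the fitted IC50 estimates the rate-space potency
without bias. Fitting raw counts instead confounds potency with the number
of divisions during the assay: with two doublings and a cytostatic drug the
half-response concentration of the count curve sits near half the true IC50.
This is the same rationale as growth-rate-corrected (GR-metric) dose-response
analysis. `fit_4pl` itself is scale-agnostic; the doublings transform clips
counts at 0.5 before taking logs so empty wells remain finite.

The bulk-viability surrogate models an ATP readout as a per-well weighted
sum of subpopulation counts (default unit weights). In pure cultures it
reproduces the positive-count fit; in mixed cultures with proliferating
insensitive fibroblasts it compresses the curve's relative dynamic range
`(top − bottom)/top` — the quantitative version of why bulk readouts fail on
mixed cultures. Stromal response flatness is tested by regressing the
negative-population doublings on log10 dose and checking that the 95% CI of
the slope covers zero.

## Cohort statistics

Success rates are `100 · finished/total`, displayed with
round-half-away-from-zero (raw values are retained). The two-sided Fisher
test enumerates the full hypergeometric support with exact integer
arithmetic — the probability-mass rule: sum the probabilities of all tables
(margins fixed) whose probability does not exceed the observed table's. Ties
are exact integer comparisons, so no floating-point slack is needed. The
odds ratio is the sample cross-product ratio; zero cells are flagged rather
than continuity-corrected. The package bundles an example cohort CSV
(culture success by tumor type) used by the `cohort` CLI command by default.

## Canned scenarios and problem sizes

Scenarios `alk_mut` (ceritinib IC50 90 nM / crizotinib 1300 nM), `alk_wt`
(53 / 60 nM) and `alk_g1202del` (lorlatinib 2 / crizotinib 166 / ceritinib
268 nM) encode ALK-rearranged lung-cancer cultures with different resistance
profiles as simulator ground truth; `pure` / `mixed` isolate the
bulk-vs-subpopulation comparison; `tiny` is a smoke-test plate. One
12-dose × 4-replicate drug plate (56 wells at 768×768 px) simulates and
quantifies in well under a minute on one core; the test suite runs each
screen scenario at two fixed seeds and the acceptance script reports the
median over ten seeds.

## Known limitations

- The simulator's optics are idealised (flat background, stationary noise);
  segmentation parameters will need re-tuning for real microscope data.
- Hill ground truths default to 1 (the fitted hill is free); steep-curve
  combination effects (e.g. drug synergies) are out of scope.
- The 4PL CIs are asymptotic; no profile likelihood or bootstrap.
- Fisher comparisons are unadjusted for multiplicity, matching the original
  per-pair reporting; `all_pairwise` users should correct as appropriate.
- The death-rate extension is available but off by default; scenario ground
  truths are cytostatic.
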