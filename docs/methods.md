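# Methods

This note documents the models and procedures `floralshift` implements, the
defaults it ships, the choices made where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate about real
data.

## GC-MS volatile processing

Vendor peak tables (one row per integrated peak: retention time, area, top
three tentative library identifications) pass through four filters:

1. **Area** — peaks with area strictly under `min_area` (default 10⁵
   detector counts) are removed. Thresholds phrased as "under X" / "after
   Y" are implemented strictly, so a peak exactly at a boundary is
   retained; this is the literal reading and is tested at the boundary.
2. **Retention** — peaks eluting strictly after `max_retention` (default
   30 min) are removed; heavier late-eluting compounds are unlikely
   airborne attractants.
3. **Blank matching** — a sample peak is removed iff some blank peak shares
   its *top-ranked* library hit, elutes within `blank_rt_window` (default
   0.1 min), and the sample area is under `blank_fold` (default 5) times
   the blank area. Matching on any of the three hits is available
   (`blank_match="any"`). Removal triggers on *any* qualifying blank peak,
   and the triggering peak is recorded; comparing only to the nearest blank
   peak would be a stricter variant the data do not distinguish.
4. **Contaminants** — a peak is removed iff **all three** library hits
   contain a contaminant substring (defaults: `silox`, `silic`, `phthal`;
   case-insensitive). One clean hit retains the peak.

Each predicate depends only on the individual peak and the fixed blank
table, so the cascade's retained set equals the conjunction of the four
predicates in any stage order; this is property-tested against a
brute-force oracle. Manual visual comparison of uncertain spectra is not
automatable; a configurable spectral-similarity stage exists in its place
and is OFF by default.

**Kovats retention index** uses the linear temperature-programmed
(van den Dool–Kratz) convention, RI = 100·n + 100·(t − tₙ)/(tₙ₊₁ − tₙ),
appropriate for a ramped oven program; the isothermal (logarithmic) form
is not offered. Retention times outside the ladder span raise an error
naming the span rather than extrapolating.

**Quantification**: mass_ng = max(0, (area − intercept)/slope) through the
compound's standard curve, then emission = mass / scaling with
scaling = flowers × hours × calibration. Defaults: 2 flowers per
enclosure, 24 h collection, calibration 1. The calibration factor absorbs
elution volume, aliquot concentration and injection volume into one
configurable per-run constant, since these instrument-specific factors
cannot be reconstructed from first principles. Compounds without an
authentic standard are quantified through a named structurally similar
surrogate curve supplied in configuration. Negative back-calculated masses
clip to zero with a warning.

Group comparisons use Welch's unequal-variance *t* (scipy, with the
Welch–Satterthwaite df) and the ratio of group means as the fold change.

## Bee colour vision

Receptor sensitivities are A1 visual-pigment nomograms (Govardovskii-family
alpha band plus the beta-band Gaussian), peak-normalized, with honeybee
defaults λmax = 344/436/544 nm (UV/blue/green); all three are
configurable. The illuminant defaults to equal-energy (flat); a smooth
daylight-like option exists. Spectra are linearly interpolated onto a 1-nm
grid over 300–700 nm before integration, and replicate averaging is
hierarchical (technical replicate → flower → line) so each flower carries
equal weight regardless of replicate count.

For each receptor, quantum catch Q = Σ R·S·I·Δλ is von Kries-adapted by
the catch of the green background (q = Q/Q_bg) and transduced to
E = q/(q+1) ∈ (0, 1). Hexagon coordinates are
x = (√3/2)(E_G − E_UV), y = E_B − (E_UV + E_G)/2; distance from the
origin approximates chromatic contrast against the background. Exactly the
background (or any spectrum proportional to it) maps to the origin — the
invariance holds only for uniform scaling across wavelengths, which is the
property tested. The bundled green-leaf background is a synthetic analytic
curve (UV-dark, chlorophyll bump near 550 nm, red-edge onset); real
vegetation spectra can be supplied per run. Receptor-noise discriminability
models and tetrachromatic (hummingbird) spaces are out of scope.

## EAG normalization

Antennal responsiveness decays over a session, so the positive-control
odorant (default label "PAA") is presented as the first, middle and final
blocks. Contiguous control presentations form anchor blocks; each
contributes the point (mean index, mean amplitude); the drift baseline
interpolates linearly between anchors and extends as a constant beyond
them. Linear interpolation between round means is the minimal drift model;
nearest-anchor stepping would be the alternative and is not the default.
Each response is divided by the baseline at its index ("corrected"), and
corrected values are scaled to the initial control response. The initial
control is taken as the first *block mean* (robust to single-presentation
noise) rather than the very first raw amplitude, so by default
scaled = corrected; passing the raw first amplitude switches conventions.
The first presentation of every test stimulus is removed beforehand
(solvent blow-off inflates it); a stimulus presented once therefore
disappears with a warning.

Linear multiplicative drift is removed exactly between the first and last
anchors (tested); exponential fatigue is removed up to the chord-vs-curve
error of linear interpolation, about (k·gap)²/8 relative — roughly 2% at
the default decay 0.02/presentation and ~20-presentation anchor gaps. The
recovery tests allow for exactly this bias. Mixed-model inference on the
normalized responses is downstream of this module and out of scope.

## Choice statistics

Pooled counts (visits, probes, summed handling seconds rounded to whole
seconds, or per-bee first choices) are tested against a 50:50 null with
the χ² goodness of fit on 1 df, *without* Yates continuity correction —
the uncorrected statistic is the convention under which a 59:30 split
yields χ² = 9.45. Trials whose bee never foraged are recorded but excluded
from pooled statistics. Handling time is reported as totals and contrasted
with Welch's *t*; Poisson GLMMs with per-bee random effects are out of
scope, so per-bee summary tables are provided as their input layer.

## Phenotypes

* Pigment readings standardize as absorbance × dilution / mean corolla
  mass (AU · g⁻¹). Dilution is tracked explicitly so saturated-then-diluted
  samples remain comparable.
* Nectar volume: (h/100) × 103.87 µL for column height h (mm) in a 1.15 mm
  internal-diameter, 100 mm capillary. The constant is the printed
  full-capillary volume; it equals π·0.575²·100 = 103.869 µL to within
  rounding, and linearity against the cylinder formula is tested. Heights
  outside [0, 100] mm are rejected.
* Herkogamy is pistil minus stamen length; negative values (stamens
  overtopping the pistil) are meaningful and preserved.

## Trait integration

All-pairs Pearson correlations are computed pairwise-complete; pairs with
fewer than 3 complete observations or a constant column are undefined and
excluded with a log entry, while globally constant columns are dropped up
front. p-values come from t = r√((n−2)/(1−r²)) on n−2 df, two-sided.
Census percentages are 100 × (#p < α)/(k(k−1)/2) at α = 0.05, unadjusted —
no multiplicity correction enters the census arithmetic. |PCC|
distributions across lines are compared with the classical one-way
ANOVA F. Reflectance principal components are accepted as pre-computed
input columns; the PCA itself is upstream.

## Variant windowing and smoothing

Variant positions (1-based, from VCF) are binned into `window_size`-bp
windows stored 0-based half-open, tiling each chromosome with a possibly
short final window; totals are conserved by construction and by test. Each
record counts one site regardless of allele count. The window size is a
required parameter with no default: both 50 kb and 30 kb are defensible
conventions for genome-scale density tracks and the choice materially
changes the track, so it must be stated per run.

Smoothing is a centred local least-squares quadratic over 2·neighbors + 1
windows (default neighbors = 50 per side, the convention of the plotting
tools this phrasing comes from), evaluated at the centre — the
Savitzky–Golay filter in the interior, verified against
`scipy.signal.savgol_filter`. At the edges the half-window shrinks
symmetrically (and the polynomial order drops when points run short)
instead of extrapolating, so quadratic signals are reproduced exactly
everywhere and constants are always preserved. Cross-species overlays
report per-window differences of smoothed tracks and their Spearman rank
correlation per chromosome.

## Synthetic data

The generators produce inputs with the statistical structure each stage
assumes, with ground truth stored for recovery testing. Defaults are the
study-scale conditions: a 2.3-fold total-emission difference between morph
groups at 15 samples per group; a 2:1 yellow choice preference with 10
bees and Poisson(9) visits each (~90 pooled visits); 9 EAG antennae with
three 4-exposure control rounds, exponential fatigue (0.02/presentation)
and multiplicative 5% noise; red-like corollas (dark below 600 nm with a
long-wavelength shoulder) versus yellow-like (plateau above ~520 nm with a
subtle UV bump); and piecewise-constant variant intensity (10⁻³–6×10⁻³
per bp) along two mock chromosomes of 2.0 and 1.5 Mb. Noise models are
chosen for positivity: log-normal peak areas, Gaussian reflectance noise
(clipped to [0, 1]), multiplicative EAG noise. All generators are
deterministic given a seed (stage seeds derive from the master seed via a
seed sequence) and byte-identical across runs.

What passing recovery tests show: the *estimators are consistent under the
generators' assumptions* — independent log-normal sample totals, iid
Bernoulli choices, exactly multiplicative fatigue, Poisson variant counts.
Real measurements violate these in ways the generators do not emulate:
co-eluting peaks and integration ambiguity, within-bee choice correlation,
non-multiplicative antennal adaptation, pigment-class cross-absorbance,
linked variant clustering. Passing here validates the arithmetic and its
calibration, not field performance.

## Numerical and scale choices

Problem sizes in the test suite (1000 random peak tables of ≤ 20 peaks,
10,000-replicate χ² calibrations via vectorized binomial sampling, 100
generator seeds for the contrast-ordering property, two mock chromosomes)
were chosen as the smallest sizes at which the Monte-Carlo error bounds in
the assertions are meaningful; all derive their tolerances from binomial
or delta-method standard errors rather than fixed magic numbers. Ties and
degenerate inputs fail loudly: empty blank tables and empty emission sets
warn and pass through, zero-variance ANOVA groups and zero background
catches raise, and single-window tracks return unchanged with a warning.

## Known limitations

* The colour model stops at hexagon contrast; it does not predict
  discrimination thresholds (no receptor-noise model).
* EAG normalization assumes fatigue acts multiplicatively and identically
  on control and test responses.
* The χ² preference tests treat pooled visits as independent; per-bee
  heterogeneity is only surfaced descriptively.
* The volatile calibration factor is per-run configuration, not estimated;
  absolute emission rates are only as good as the supplied curves.
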