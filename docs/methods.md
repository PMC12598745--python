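# Methods

This note documents the models implemented in `matsip`, the parameters
that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the published practice
the package codifies leaves room.

## Isotope bookkeeping

Three representations of one measurement are interconverted against the
fixed reference ratios ¹³C/¹²C(VPDB) = 0.0111802 and ¹⁵N/¹⁴N(air) =
0.0036765: δ (‰), heavy/light ratio R, and heavy-atom fraction
x = R/(1+R). Natural-abundance atom fractions (x_C = 0.0110566,
x_N = 0.0036630) are *derived* from the standards rather than stored
separately, so there is a single source of truth. δ values are carried
in ‰ throughout and never mixed with ratios in one field.

Averaging order matters slightly at the third decimal of δ: the δ of a
mean ratio is not the mean of per-observation δ values. The control
summary reports both, labelled (`delta_of_mean_ratio_permil`,
`mean_of_delta_permil`), rather than silently choosing one.

## Bulk rate mass balance

For an element with biomass pool P (μmol/g dry; P_N = n_wt%/100/14.007
× 10⁶) assimilating a substrate pool whose heavy-atom fraction sits
x_E above natural abundance,

    rate = slope_t[ x(t) − x̄_control ] / x_E × P.

This is the only mass balance consistent with μmol/g/h units and a
spike-enrichment description of the substrate pool. Defaults: the
¹³C-DIC pool is a 2% spike above natural (x_E = 0.02; the dissolved
inorganic carbon background is so large that the spike fully defines
the excess); ¹⁵N substrates are 98 atom% label (x_E = 0.98 − x_N).
Both are configuration keys, not constants.

Slopes are ordinary least squares with intercept; duplicate time points
are averaged first; exactly two distinct times fall back to the finite
difference (stderr 0, method flagged). The slope standard error
propagates linearly to the rate. Carbon series can be fit globally or
per light phase by filtering the input table; the packaged scenario
uses a global 48-h fit.

Areal gross productivity = hourly fixation rate × areal dry density
(default 500 g dry/m²) × 24 h, with a companion ×12 h (daylight-period)
figure co-reported. No acid-wash carbonate correction is applied by
default; `inorganic_c_fraction` in the pipeline configuration applies a
user-supplied correction factor when set.

Urea consumption converts the depletion slope of the dissolved
labelled-urea pool by V/(m·R_dry/wet) (R_dry/wet default 0.1) and is
reported positive for consumption, ×2 to express urea-N. The
regression window (default: first 2 h) measures the *window-average*
rate; under first-order depletion this sits below the instantaneous
initial rate (≈13–15% at the packaged kinetics), which is why the
generator manifest records both values and recovery is scored against
the window-average. Replacement-volume dilution during sampling is
checked by the cumulative factor Π(1 − vᵢ/V) and flagged when the
implied bias exceeds 5% of the observed depletion.

## GC–MS ¹⁵N-urea quantification

The raw ¹⁵N fraction of an injection is S₁₅₅/(S₁₅₃+S₁₅₅) — the printed
two-ion formula is primary; an optional three-ion mode
(S₁₅₅+S₁₅₄/2)/(S₁₅₃+S₁₅₄+S₁₅₅) is available behind a flag, default
off. Confirmatory ions 168/170 are parsed and stored but unused.
Calibration regresses known ¹⁵N% (0–100) on raw fraction — the
direction the calibration equation reads — and requires ≥3 distinct
levels. Calibrated percentages are clamped to [0,100] with a flag.
Injections under a configurable total-area floor are reported missing,
never zero.

Concentration arithmetic: with f the calibrated ¹⁵N fraction and a
¹⁴N-urea internal calibrant of 0.05 μmol in 200 μl (0.25 mM),
C₁₅ = f/(1−f) × 0.25 mM. All ¹⁴N signal is attributed to the calibrant,
ignoring natural lake ¹⁴N-urea; at the default lake concentration
(3.9 μM against a 250 μM calibrant) this biases concentrations ≈1.5%
low, which the package accepts as the published convention.

Ambient (pre-spike) urea uses unspiked time-zero injections and the
*second* calibration series (urea:¹⁵N-urea 1:1 … 1:5000, i.e. ¹⁵N
fractions 0.5–0.9998). This matters quantitatively: the ambient ¹⁴N
signal is under 1% of total, so a ~0.2-percentage-point intercept error
in the low-resolution first series (0, 80, 90, 100%) is a ~25% error in
the ambient concentration, while the dense high-enrichment series pins
the curve where the samples sit.

## NSAF community profile

Records failing peptide-FDR ≤ 5%, protein-FDR ≤ 5% or the
protein-unique-peptide requirement are discarded first (removal counts
logged per reason). Proteins identified identically in multiple MAGs
are removed *before* the NSAF denominator is formed, so per-sample MAG
abundances are column-stochastic over MAGs plus the unbinned bucket.
Correlations are Pearson, across samples, restricted to MAGs with
abundance > 0 in every sample; the 0.001 display threshold applies only
to reporting. A zero-variance profile yields a missing correlation,
never 0.

## Protein-SIP

**Forward model.** A peptide's isotopologue pattern on a unit-mass
axis is the convolution of per-element binomial heavy-isotope
distributions (¹³C 0.0110566, ²H 0.000115, ¹⁵N 0.0036630; ¹⁸O 0.00205
and ³⁴S 0.0429 contribute at +2), truncated to the observed number of
bins (default 8) and renormalized. The binomial heads are computed by
the pmf ratio recurrence, which keeps a full fit under a millisecond.

**Inversion.** The label fraction p̂ minimizes the sum of squared
differences between the normalized observed pattern and the forward
model, over p ∈ [0, 0.5]: a 201-point coarse grid brackets the optimum
and bounded scalar minimization (xatol 10⁻¹²) refines it. Noiseless
forward patterns invert to better than 10⁻⁶; at 1% multiplicative
pattern noise the median |p̂ − p| is below 5×10⁻⁴ for peptides of
20–120 carbons. Flat (non-identifiable) patterns raise an error and are
dropped from tables with a count.

**Aggregation.** A peptide counts ⌊intensity/100 000⌋ times (floor,
minimum 1 — a literal remainder would be dimensionless noise); a MAG's
ratio is the weighted *median* of its peptides (a mean is available by
computing on the expanded values directly); a sample's ratio is the
MS-intensity-weighted mean over MAGs plus the unbinned group.
Cross-sample tests only use peptides observed in every sample of the
comparison set, damping spatial-heterogeneity noise.

**Exact quantile test.** Groups are expanded by their weights, pooled
(size N); c is the pooled order statistic at rank ⌈qN⌉ (q default 0.5);
r counts pooled values strictly above c, k those from the treatment;
ties at c count as not-above. Under exchangeability k is hypergeometric
and the one-sided p-value is its upper tail; r = 0 gives p = 1. The
implementation is verified against complete enumeration of all
C(N, n_t) group assignments for every N ≤ 12, with and without ties.
Benjamini–Hochberg correction (step-up, statsmodels) is applied across
the whole batch of MAG × time-point comparisons; adjusted p < 0.05
(strict) flags significance. Both directions can be read from k and r;
only "treatment greater" feeds the headline flags, matching the
directional labelling question.

**Known limitation — weighted pseudoreplication.** Expanding peptides
by intensity weights treats correlated duplicates as independent
observations. For unweighted input the test is exact (empirical size
≈0.036 at n = 50 per group; the attainable level below 0.05 at n = 20
is only 0.013 — discreteness of exact tests). With realistic lognormal
weights (median ≈5) the null rejection rate rises to roughly a third:
the weighted test is strongly anti-conservative, and spuriously
significant unlabeled MAGs — in both directions — are expected in
pipeline output, exactly as heterogeneous field samples show. Treat
weighted flags as a screening readout; the planted labelled MAG is
separated from this background by orders of magnitude in p.

## Synthetic-data generator

The generator runs every mass balance forward with planted parameters
and writes a ground-truth manifest sufficient to score any estimator
output. The packaged default scenario mirrors a diurnal soda-lake-mat
labelling design:

- 0.5 mM ¹⁵N substrates (98 atom%), separate day and night series,
  six time points over 8 h, 3 replicates; planted rates
  (μmol N/g dry/h): urea 5.5 day / 0.98 night, ammonium 1.8 day /
  2.5 night, ammonium+nitrate 2.5 day, nitrate+ammonium 0.91 day /
  0.39 night.
- a 2% ¹³C-DIC spike followed over 48 h; planted gross productivity
  24 g C/m²/day at 500 g dry/m², 40% C, 7% N biomass.
- first-order urea depletion from 0.5 mM whose initial consumption rate
  is 6.5 (day) / 5.5 (night) μmol urea-N/g dry/h, in 100 ml over 25 g
  wet homogenized mat (R_dry/wet 0.1) — a dense slurry, chosen so the
  labelled pool depletes on the few-hour scale the design observes; two
  technical GC injections per liquid sample (two derivatization vials),
  both calibration series, ambient lake water at 3.9 μM urea.
- an 8-sample proteome of 9 MAG buckets whose base composition places
  ~69% of signal in cyanobacteria (37% in the C1–C4 family group, 21%
  in C5), with the C1/C5 pair forced toward r = −0.9 (accepted within
  ±0.1, checked post hoc on the planted abundances) and planted
  FDR/uniqueness/multi-MAG failures in known numbers; PSM counts are
  negative-binomial (dispersion 5) at ~20 000 PSMs/sample.
- peptide isotopologue patterns for three MAGs × 40 peptides ×
  (labelled + control) arms at four time points; C5 steps from natural
  ¹³C toward 0.02 at late time points; peptide-level jitter sd 3×10⁻⁴;
  a few peptides per MAG are dropped from one sample to exercise the
  shared-peptide filter.

Noise defaults are instrument-scale: isotope-ratio sd 2×10⁻⁵ (≈0.2‰),
2% multiplicative GC–MS area noise, 1% isotopologue-bin noise. All
streams derive from one seed via spawned child sequences; fixed seed
gives byte-identical output files.

**What the generator does not emulate** — and therefore what passing
tests do *not* demonstrate about field data: millimetre-scale spatial
heterogeneity of mats (the dominant real error source, an order of
magnitude above instrument noise in control spreads), instrument drift
and retention-time effects, peptide identification errors beyond the
planted FDR flags, realistic peptide sequences (elemental compositions
are drawn from a size model), label recycling and isotope dilution
during long incubations, and community dynamics during the incubation.
Recovery tolerances in the test suite characterize the estimators, not
field uncertainty.

## Numerical choices

- Conversions validate domains strictly (δ ≥ −1000‰, ratios ≥ 0, atom
  fractions in [0,1)) and raise typed errors.
- Weighted medians match `np.median` on the weight-expanded array
  (average of lower/upper medians), computed via cumulative weights.
- The quantile-test cutoff uses the ⌈qN⌉ order statistic; ties at the
  cutoff are not-above (strict inequality), which makes the test
  conservative under heavy ties.
- The isotopologue fit's degenerate-pattern guard triggers when the
  normalized pattern is flat within 10⁻⁹.
- TSV output uses `%.10g` formatting so repeated runs are
  byte-identical.

## Problem sizes

The packaged scenario uses 288 bulk IRMS observations, ~120 GC–MS
injections, ~2 200 protein records over 8 samples, and ~950 peptide
patterns; the recovery studies use 100 randomized experiments and 2 000
null replicates of the quantile test. These sizes make the full test
suite and the acceptance script each complete in well under a minute on
one CPU while leaving all recovery statistics well-resolved.
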