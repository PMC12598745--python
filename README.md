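# matsip

Quantitative machinery for stable-isotope-probing (SIP) studies of
phototrophic microbial mats: inference of carbon-fixation and
nitrogen-assimilation rates from bulk ¹³C/¹⁵N enrichment, GC–MS
internal-standard quantification of ¹⁵N-urea, NSAF-based metaproteome
community profiling, and peptide-level protein-SIP with an exact
two-sample quantile test — plus a synthetic-experiment generator with a
ground-truth manifest, so every estimator can be exercised end-to-end
against known parameters.

It is written for biogeochemists and environmental proteomicists who
run labelling incubations (¹³C-bicarbonate, ¹⁵N-ammonium/nitrate/urea,
¹⁵N₂) on mixed communities such as soda-lake cyanobacterial mats, and
who need the downstream arithmetic — not the instruments — as tested,
reusable code.

## The models

**Isotope notation.** All conversions are anchored to the international
standards ¹³C/¹²C(VPDB) = 0.0111802 and ¹⁵N/¹⁴N(air) = 0.0036765, with
δ = (R/R_std − 1)·10³ ‰ and heavy-atom fraction x = R/(1+R).

**Bulk rate mass balance.** When biomass with elemental pool P (μmol of
C or N per g dry mass) assimilates a substrate whose heavy-atom
fraction sits x_E above natural abundance, the biomass excess atom
fraction e(t) = x(t) − x̄_control grows as

    rate = (de/dt) / x_E × P,

with de/dt by ordinary least squares over the time series. Carbon rates
scale by the areal dry density and 24 h (or 12 daylight hours) to give
gross areal productivity. Urea consumption follows the depletion of the
labelled dissolved pool: rate = −dC/dt · V / (m · R_dry/wet), doubled
to express urea-N.

**GC–MS ¹⁵N-urea.** The derivatized-urea SIM ions at m/z 153/155 give a
raw fraction S₁₅₅/(S₁₅₃+S₁₅₅), linearly calibrated to ¹⁵N% on known
standards; with a known ¹⁴N-urea internal calibrant, the ¹⁵N-urea
concentration is (f/(1−f)) × C_calibrant, and the ambient ¹⁴N-urea
concentration follows symmetrically from the ¹⁴N%.

**NSAF community profile.** NSAF_i = (PSMs_i/AAs_i) / Σ_j(PSMs_j/AAs_j)
per sample; MAG abundance is the NSAF sum over its proteins after
FDR/uniqueness filtering; cross-sample Pearson correlations reveal
anticorrelated (niche-partitioned) populations.

**Protein-SIP.** A peptide's isotopologue pattern is the convolution of
per-element binomial heavy-isotope distributions; bounded least squares
on the observed pattern recovers the ¹³C (or ¹⁵N) atom fraction p̂ and
ratio p̂/(1−p̂). Peptide ratios aggregate to MAGs by weighted median
(weights = MS summed intensity in units of 100 000) and to samples by
intensity-weighted mean. Treatment-vs-control enrichment uses the exact
quantile test: of the r pooled values above the pooled q-quantile, the
number k from the treatment group is hypergeometric under the null;
p = Σ_{i≥k} C(n_t,i)C(n_c,r−i)/C(N,r), Benjamini–Hochberg corrected
across comparisons.

## Worked example

Generate the packaged scenario (a diurnal soda-lake-mat design: 0.5 mM
¹⁵N substrates at 98 atom%, a ~2% ¹³C-DIC spike over 48 h, urea
depletion followed by GC–MS, an 8-sample proteome with an enforced
anticorrelated cyanobacterial pair, and one MAG assimilating ¹³C) and
run the full pipeline:

```bash
matsip simulate --out demo --seed 1
matsip run --config demo.yaml --out demo_results
```

where `demo.yaml` points the inputs at the generated TSVs. The rates
table (`demo_results/rates.tsv`) reads:

```
            substrate light_phase      rate   stderr               units
             ammonium         day  1.811103 0.008634      umol N/g dry/h
             ammonium       night  2.496738 0.008801      umol N/g dry/h
ammonium_with_nitrate         day  2.491824 0.011160      umol N/g dry/h
          bicarbonate         day  0.002006 0.000006         g C/g dry/h
          bicarbonate         day 24.075273 0.076637         g C/m^2/day
          bicarbonate         day 12.037636 0.038319         g C/m^2/12h
nitrate_with_ammonium         day  0.903099 0.006838      umol N/g dry/h
nitrate_with_ammonium       night  0.389394 0.010812      umol N/g dry/h
                 urea         day  5.486173 0.011856      umol N/g dry/h
                 urea       night  0.991336 0.012900      umol N/g dry/h
     urea_consumption         day  5.758392 0.344863 umol urea-N/g dry/h
     urea_consumption       night  4.799988 0.203650 umol urea-N/g dry/h
```

The scenario's true parameters (urea-N 5.5 by day vs 0.98 by night,
ammonium flat at ~2 μmol/g/h, 24 g C/m²/day gross productivity) are
recovered to within a few percent; the day ≫ night urea contrast against
light-independent urea *consumption* is the diurnal signature the design
emulates. The same run reports an ambient dissolved urea concentration
of ~4 μM from the unspiked time-zero injections, and the protein-SIP
stage flags the ¹³C-assimilating MAG (`C5`) as significantly enriched
against its paired control at every time point
(`demo_results/sip_tests.tsv`, BH-adjusted p ≪ 0.05) while its
anticorrelated partner shows r < −0.7 in the proteome abundance matrix
(`demo_results/mag_correlation.tsv`).

## Layout

```
src/matsip/isotope.py     δ / ratio / atom-fraction conversions
src/matsip/bulk_rates.py  assimilation-rate and productivity mass balances
src/matsip/urea_gcms.py   GC–MS ¹⁵N-urea quantification
src/matsip/community.py   NSAF community profiling
src/matsip/sip.py         isotopologue modelling + exact quantile test
src/matsip/simulate.py    synthetic experiments with ground truth
src/matsip/pipeline.py    orchestration, TSV outputs, report.md
src/matsip/cli.py         `matsip` command-line interface
docs/methods.md           models, parameters, design choices, limitations
```
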