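# Methods

## The problem

Deep-rooted perennial crops (the forage legume lucerne, *Medicago sativa*, and
the intermediate wheatgrass kernza, *Thinopyrum intermedium*) move
photosynthate carbon below ground, part of which leaves the root as
rhizodeposits — exudates, mucilage, sloughed cells. Quantifying how much of
that carbon ends up in soil, per depth, and whether microbes route it into
persistent necromass or into short-lived living biomass, requires isotope
tracing: plants are repeatedly pulse-labeled with ¹³CO₂/¹⁴CO₂ (plus a trace
¹⁵N surface application), and soil/root compartments are sampled over depth
intervals (0–25, 25–50, 50–100, 100–150 cm) after the labeling campaign.

`rhizotrace` implements the complete desk side of that experiment: isotope
bookkeeping, the tracer mass balance, compound-specific isotope corrections,
pool aggregation, the relative microbial stabilization index, the treatment
statistics — and a forward simulator that generates such an experiment with
known ground truth so every stage can be validated end to end.

## Isotope bookkeeping (`isotope`)

δ values (per-mil vs. VPDB for ¹³C, vs. air-N₂ for ¹⁵N) convert to atom
percent via AP = 100·R(δ/1000+1)/(1+R(δ/1000+1)); the inverse is closed-form,
so round trips are exact to ~1e-12 ‰. Enrichment (atom% excess, APE) is the
atom-percent difference between a labeled sample and its unlabeled
background. ¹⁴C stays on the activity scale (Bq g⁻¹ dry sample) throughout:
the mass balance only ever uses activity differences and activity × mass
products, so no decay correction or specific-activity conversion is needed.
The per-g-dry-sample convention for activities is assumed everywhere and
encoded in the column name `c14_bq_per_g`.

Reference ratios default to R_VPDB = 0.0111802 and R_air-N₂ = 0.0036765 and
can be overridden. Below-background (negative) excess is preserved and
flagged, never silently clamped, so pool totals stay additive; the one place
the physics demands non-negativity (the adjusted bulk pool, below) clamps
explicitly and logs the deficit.

## Tracer mass balance (`rhizodeposition`)

Per plot × species × depth, compartment tracer pools are per-gram excess ×
compartment mass. Root fragments too fine to pick by hand are recovered by
washing a bulk-soil subsample; their tracer content is scaled to the whole
bulk mass by the mass ratio and subtracted from the bulk pool ("adjusted
bulk"), since fragments are root material physically sitting in the bulk
soil. Then

    %ClvR = 100 · (rhizosphere + adjusted bulk)
                / (adjusted bulk + rhizosphere + root incl. fragments)

    net rhizodeposition = %ClvR · root C / (100 − %ClvR)

with root C (mg C kg⁻¹ soil) = root dry matter × C concentration / soil mass
sampled. The second equation is the unique inversion of
net/(net + root C) = %ClvR/100, and that identity is enforced to 1e-12 in
tests. The ¹⁵N path runs the same algebra with mg excess-¹⁵N pools
(APE × N content) as the currency.

A `strict_literal` mode uses the raw bulk pool and the bare root pool in the
denominator. Note an algebraic identity: adjusted bulk + fragments = raw
bulk, so the two modes coincide exactly unless the adjusted pool was clamped
(fragment tracer exceeding bulk tracer, a noise signature); both modes are
kept so the published and the mass-conserving readings can be compared on
real data.

Computation is per plot first; replicate averaging is left to the caller (or
the `compare` stage) so plot structure is never pooled away. Area stocks
(Mg ha⁻¹) use stock = conc(mg kg⁻¹) × BD(g cm⁻³) × thickness(cm) × 1e-4,
verified in tests by an independent unit expansion.

## Compound-specific isotope probing (`biomarkers`)

Measured δ¹³C of derivatized biomarkers is corrected in a fixed order:

1. **Instrument effects** — offset, drift (per run index) and amount
   dependence (linear in log peak amount), fitted by least squares on co-run
   standards of known δ. The amount term is the simplest standard form; the
   calibration design must decouple amount from run order or the fit is
   declared rank-deficient.
2. **Derivatization dilution** — added carbon dilutes the analyte signal;
   the two-pool balance δ_analyte = ((n_a+n_d)·δ_meas − n_d·δ_reagent)/n_a
   undoes it. The default operates on the δ scale (the standard CSIA linear
   approximation); an exact atom-fraction mode exists, and the two agree to
   ≈0.01 ‰ over the bundled compound panel at natural-abundance contrasts
   (worst case 0.011 ‰ for the 2-carbon analyte at a 40 ‰ analyte–reagent
   contrast). Reagent δ¹³C is reagent-batch specific and therefore a
   required input with no default.

Corrected deltas minus the same-compound unlabeled background give APE;
APE/100 × compound C content (concentration × carbon mass fraction from the
molecular formula) gives ¹³C incorporation. Pools: PLFA (all detected
phospholipid fatty acids; living microbial biomass), amino sugars
(GlcN + GalN + MurN + ManN; necromass), amino acids (an 11-entry panel;
exudate quality — reported but excluded from RMS by construction). A pool's
weighted APE = 100 × total ¹³C incorporation / total pool C. Derivatization
carbon counts per compound ship in `data/compounds.csv`; the counts are
documented illustrative defaults (the true values depend on the exact
derivatization chemistry) and users can supply their own table.

## Relative microbial stabilization (`rms`)

RMS = log₁₀(weighted APE of AS / weighted APE of PLFA). RMS > 0: the tracer
predominantly entered necromass, the precursor of stabilized soil organic
matter; RMS < 0: it sits in the short-lived living biomass. The index is
strictly comparative (depths, species); it claims nothing about absolute
stability. The log base is configurable (default 10) and carried in every
output row. Non-positive pool APEs (zero incorporation or below-background)
yield an explicitly undefined RMS with a reason, never a silent NaN. Depths
whose bottom exceeds 100 cm are tagged `in_reported_range = False` because
field studies of this design report RMS to 100 cm.

## The simulator (`simulate`)

The generator is a first-class, tested model of the experiment, not a test
fixture. Defaults are the study conditions: 3 field plots per species, the
kernza plots carrying 100 and 200 kg N ha⁻¹ subplots; four depth intervals;
doses derived from the pulse schedule (26 pulses, canopy 20→110 cm, 5 mL of
labeling solution per started 20 cm of height, 11 kBq ¹⁴C and 0.1 g of
99 atom% ¹³C-bicarbonate per mL); ¹⁵N 73.5 mg per plot (1 kg N ha⁻¹ at
98 atom% on 0.75 m²); background δ¹³C −27 ‰ (C3 system), δ¹⁵N +2 ‰,
0.3 Bq g⁻¹ ¹⁴C.

Per depth, the belowground dose splits root : rhizodeposit = (1−f) : f with f
the true ClvR fraction (defaults 0.25/0.20/0.15/0.10 — deeper layers export
relatively less; the defaults are illustrative, weakly constrained by field
totals). Rhizodeposits split bulk : rhizosphere 3 : 1; 15 % of root tracer
(and mass) is rerouted to unrecovered fragments, which the simulated bulk
reading includes — exactly the contamination the adjusted-bulk correction
removes. Biomarker ¹³C in the rhizosphere splits AS : PLFA by a per-depth
necromass fraction (defaults 0.35/0.50/0.65/0.80, rising with depth), which
fixes true RMS.

Noise: multiplicative lognormal (unit mean, configurable CV, default 0.10)
on masses, concentrations, activities and peak amounts — how gravimetric and
counting errors behave — and additive Gaussian (default 0.2 ‰) on δ values,
how IRMS errors behave. One seed drives everything; per-plot substreams are
derived deterministically so adding plots never reshuffles existing ones,
and equal seeds give byte-identical outputs.

What the simulator does **not** emulate: plant physiology (allocation
fractions are parameters, not mechanisms), spatial heterogeneity within a
plot, correlated errors between compartments, compound-to-compound APE
variation within a pool, and real chromatography (peak integration,
co-elution). Passing tests therefore demonstrate the correctness of the
accounting and its statistical behavior under a clean error model — not that
a particular field dataset meets the model's assumptions.

## Statistics (`stats`)

Variance homogeneity (Fligner–Killeen) and normality (Shapiro–Wilk on
within-group residuals) are checked at α = 0.05; if either rejects and the
data are positive, the response is log-transformed (non-positive data raise,
offset handling is deliberately left to the user). ANOVA is fixed-effects on
plot means with treatment and depth as crossed categorical factors — the
plot replicate (n = 3) is the experimental unit; no plot random effect is
fitted. Tukey HSD (statsmodels) provides pairwise comparisons with a compact
letter display (insert–absorb algorithm, tie-break by descending group
mean); unadjusted pooled-variance t p-values are reported alongside so the
adjustment is auditable. The kernza fertilizer subplots are merged (averaged
within field plot, relabeled "kernza") only when no requested variable
differs between the 100 and 200 kg N rates by paired t-test at α; the
decision and per-variable p-values are reported, and merging is idempotent.

## Numerical choices and known limitations

* **%ClvR estimator bias.** %ClvR is a ratio of noisy pools, so it carries a
  small positive Jensen bias of order cv². Under the default noise model
  (CV 0.10 on each measured factor, hence ≈0.14 per pool product) the bias
  is ≈ +0.1 percentage points at 10–25 % ClvR — about 0.5–1 % relative, an
  order of magnitude below the ≈3 pp between-plot scatter a 3-plot design
  sees. Monte-Carlo studies with a few hundred replicates resolve this bias,
  so recovery checks at that scale sit near their tolerance; it is a property
  of the ratio estimator itself, not of the implementation.
* **Adjusted-bulk clamp.** Negative adjusted bulk pools (fragment tracer
  exceeding bulk tracer under noise) are clamped to zero with a logged
  warning; at default conditions the clamp fires on ~0.01 % of samples.
* **Problem sizes.** The packaged validation uses 200 simulation replicates
  for recovery studies and 2000 null replicates for the ANOVA type-I
  calibration — enough for ~0.5 % Monte-Carlo precision on a 5 % rate while
  keeping the full validation run in the tens of seconds.
* **Degenerate inputs.** Empty biomarker pools are absent, not zero; missing
  backgrounds, unknown compounds, unpaired subplots, rank-deficient
  calibration designs and zero tracer denominators all raise errors naming
  the offending sample, compound or term.
* **Open choices made here.** Log base 10 for RMS; δ-scale dilution
  correction by default; mass-ratio scaling of fragment tracer from the
  washed subsample to the full bulk mass; per-g-dry-sample ¹⁴C activities;
  fixed correction order (instrument, then dilution). Each is either
  configurable or stated in the output metadata.
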