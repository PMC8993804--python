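# rhizotrace

Isotope-tracer accounting of belowground carbon inputs from deep-rooted
perennial crops.

Field experiments that pulse-label plants with ¹³CO₂/¹⁴CO₂ (plus trace ¹⁵N)
and sample soil over depth produce raw isotope readings — δ¹³C, δ¹⁵N, ¹⁴C
activities — per soil/root compartment, and chromatography tables of
microbial biomarkers. `rhizotrace` turns those into the quantities such
studies report:

* **Net rhizodeposition** by tracer mass balance. Per depth interval, with
  the bulk-soil ¹⁴C pool adjusted for unrecovered root fragments washed from
  a subsample,

  ```
  %ClvR = 100 · ¹⁴C(rhizosphere + adjusted bulk)
              / ¹⁴C(adjusted bulk + rhizosphere + root incl. fragments)

  net rhizodeposition = %ClvR · root C / (100 − %ClvR)
  ```

  where %ClvR is the percent of belowground carbon lost via rhizodeposition
  and root C (mg C kg⁻¹ soil) is root dry matter × C concentration / soil
  mass sampled. The same algebra runs on ¹⁵N for nitrogen rhizodeposition.

* **Compound-specific ¹³C incorporation** into biomarker pools — PLFA
  (living microbial biomass), amino sugars (necromass), amino acids — after
  correcting measured δ¹³C for instrument offset/drift/amount dependence and
  for the carbon added by derivatization.

* **Relative microbial stabilization**,
  `RMS = log₁₀(weighted APE_AS / weighted APE_PLFA)`, where a pool's
  weighted atom% ¹³C excess (APE) is its total ¹³C incorporation over its
  total carbon. RMS > 0 means rhizodeposits predominantly entered the
  persistent necromass pathway.

* **Treatment statistics**: Fligner–Killeen and Shapiro–Wilk assumption
  checks with automatic log transform, fixed-effects ANOVA on plot means,
  Tukey HSD with compact letter display, and the fertilizer-subplot merge
  rule (kernza 100/200 kg N ha⁻¹ subplots averaged when no variable
  separates them).

* A **forward simulator** of the whole experiment (plots, depths, doses
  following the 5 mL-per-20 cm pulse rule, noise) with exported ground
  truth, so every stage is testable against known answers.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Simulate the default experiment (3 lucerne plots, 3 kernza plots with two N
subplots each, four depths), run the mass balance, and summarize:

```python
import rhizotrace as rt

cfg = rt.ScenarioConfig(seed=1)            # defaults = the study conditions
sim = rt.generate(cfg)
part = rt.partition_samples(sim.samples)

print(part.groupby(["species", "depth_top_cm"])
          [["clvr_percent", "net_rhizo_c_mg_per_kg"]]
          .agg(["mean", "sem"]).round(2))
```

```
                     clvr_percent       net_rhizo_c_mg_per_kg
                             mean   sem                  mean    sem
species depth_top_cm
kernza  0                   23.57  1.76                270.94  23.54
        25                  23.19  1.68                 82.21   8.99
        50                  15.57  0.59                 22.30   2.40
        100                 10.77  1.41                  6.01   0.98
lucerne 0                   24.56  1.55                275.86  20.96
        25                  19.64  1.60                 61.92   3.40
        50                  13.91  0.84                 20.45   1.10
        100                 11.52  1.03                  6.27   0.95
```

Under the default 10 % measurement noise the per-depth means recover the
configured truth (25/20/15/10 %ClvR) within replicate scatter; net
rhizodeposited C falls steeply with depth, tracking root C. The merge rule
finds no fertilizer effect in this simulation and averages the kernza
subplots:

```python
merged, report = rt.merge_rule(part, ["clvr_percent", "net_rhizo_c_mg_per_kg"])
print(report.summary())
```

```
K100/K200 merge decision: merged
  clvr_percent: p = 0.6953
  net_rhizo_c_mg_per_kg: p = 0.287
```

The compound-specific path — instrument correction fitted from the simulated
standards, dilution correction, pool aggregation, RMS:

```python
corr = {c: rt.fit_instrument_correction(s)
        for c, s in sim.calibration.groupby("biomarker_class")}
_, pools = rt.process_biomarkers(sim.biomarkers, cfg.reagent_d13c, corr)
prof = rt.rms_profile(pools)
print(prof.groupby("depth_top_cm")["rms"].agg(["mean", "sem"]).round(3))
```

```
               mean  sem
depth_top_cm
0            -1.301  0.0
25           -1.033  0.0
50           -0.781  0.0
100          -0.431  0.0
```

RMS rises monotonically with depth — the simulated necromass share of
biomarker ¹³C increases downward — meaning relatively more of the traced
carbon enters the stabilized necromass pool in deeper soil. (Values are
negative here because the amino-sugar pool holds far more carbon than the
PLFA pool, diluting its APE; the index is comparative across depths, not an
absolute measure.)

The same workflow is available from the shell:

```bash
rhizotrace simulate --seed 1 --out sim/
rhizotrace partition sim/samples.csv --out partition.csv
rhizotrace csia sim/biomarkers.csv --calibration sim/calibration.csv \
    --reagent-d13c 'PLFA=-40,AS=-35,AA=-38' --out csia/
rhizotrace rms csia/pool_summaries.csv --out rms.csv
rhizotrace compare partition.csv --out compare/
rhizotrace report partition.csv --rms-csv rms.csv --out report/
```

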