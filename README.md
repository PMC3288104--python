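# gabashift

Analysis pipeline for PET [¹¹C]flumazenil "GABA-shift" studies: measuring the
increase in benzodiazepine-site binding that follows an acute rise in
extracellular GABA (e.g. after GAT1 blockade with tiagabine), together with
the induced gamma-band EEG summary used to relate that binding change to
cortical network entrainment.

The package is aimed at PET kinetic modellers and cognitive-neuroscience
groups who want the full chain — arterial input function, compartment
modeling, graphical occupancy analysis, group statistics, time-frequency
EEG — as tested, scriptable building blocks.  A synthetic-data generator
with known ground truth stands in for raw scans, so every stage is
verifiable at desk scale.

## The model

**Input function.** Arterial samples give total plasma activity; the
unmetabolized parent fraction, measured at 2, 5, 15, 30, 45, 75 and 90 min,
is fitted to `f(t) = a·exp(−b·t) + c` and used to metabolite-correct the
totals.  The parent curve is fitted to a sum of three exponentials from the
time of peak plasma activity (linear interpolation before the peak).
Clearance = injected dose / AUC; the plasma free fraction f_P comes from
ultrafiltration triplicates with a saline filter-retention correction.

**Kinetics.** Regional time-activity curves (19 frames over 90 min, 5%
blood-volume subtraction) are fitted with the unconstrained two-tissue-
compartment model.  With delivery/efflux constants K₁, k₂ and
binding/dissociation constants k₃, k₄, the total distribution volume is

    V_T = (K₁/k₂)(1 + k₃/k₄)   [mL g⁻¹]

estimated by Levenberg–Marquardt least squares weighted by frame
acquisition time.  Binding potentials follow as BP_P = V_T − V_ND and
BP_ND = V_T/V_ND − 1, with V_ND the pons V_T.

**Affinity shift (Lassen plot).** For each subject, regressing
(V_T,baseline − V_T,post) on V_T,baseline across the ten study ROIs gives a
line with slope ΔBP and x-intercept V_ND; assuming the affinity change is
uniform across regions, the affinity shift is **1 − slope** (a mean slope
of −0.27 ⇒ a 1.27× shift, i.e. a 27% affinity increase).

**EEG.** Cue-locked epochs (−400…+1900 ms, 250 Hz) are screened with
200 µV-range / 60 µV-gradient artifact rules, Morlet-transformed (ω₀ = 7,
20 sub-bands spanning 14–80 Hz), and averaged as induced power (trial mean
of per-trial power, baseline-corrected to −300…−100 ms).  The frontal
summary is the 42 Hz sub-band power in the 500–1500 ms delay window,
contrasting high- vs low-cognitive-control trials.

## Worked example

Simulate a nine-subject high-dose-style cohort (true mean affinity shift
1.27, between-subject SD 0.1, frame noise 5%) and run every stage:

```bash
gabashift run --subjects 9 --dose-group II --seed 7 --out demo
```

or equivalently from Python:

```python
from gabashift.pipeline import RunConfig, run_pipeline
res = run_pipeline(RunConfig(out_dir="demo", n_subjects=9, dose_group="II", seed=7))
print(res["lassen_summary"])
```

which prints (seed 7):

```
group shift 1.229 ± 0.085 (slope -0.229, x-intercept 1.073)
```

The cohort's estimated affinity shift (1.23 ± 0.08) recovers the generating
regime (true mean 1.27), and the Lassen x-intercept (1.07 ± 0.30) recovers
the true nondisplaceable volume of 1.0 mL g⁻¹.  The output directory holds
tidy CSVs for every stage; the composite rows of `stats_vt.csv` from this
run are

```
              region  baseline_mean  post_mean  pct_change  cohen_d      p
  Association Cortex          6.792      8.094       19.17    -2.77  0.000
      Sensory Cortex          6.756      8.062       19.34    -2.85  0.000
Medial Temporal Lobe          5.245      6.195       18.12    -2.78  0.000
                 PON          1.001      1.002        0.11    -0.20  0.566
```

— baseline composite V_T values sit at the study magnitudes (≈6.8, 6.7 and
5.2 mL g⁻¹ with pons ≈ 1.0), the drug condition raises V_T everywhere
except the pure-nonspecific pons, and Cohen's d is negative by the
base-minus-post sign convention.  A `manifest.json` records per-file
checksums; rerunning with the same seed reproduces them exactly.

Individual stages are also exposed as subcommands (`simulate`,
`fit-input`, `fit-2tc`, `lassen`, `stats`, `eeg-gamma`); see
`gabashift --help`.

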