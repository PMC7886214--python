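# mitralflow

Transmitral flow energetics for in-vitro mitral-valve testing: from
particle images to velocity fields (PIV), from velocity fields to
viscous energy dissipation, and from pressure and Doppler recordings to
transvalvular gradients and Gorlin valve area.

## The problem

Mitral annular calcification (MAC) narrows the inflow orifice of the
mitral valve without the commissural fusion of rheumatic stenosis.
Patients often have only a modest resting transvalvular gradient, yet
report exertional dyspnea out of proportion to that gradient.  One
candidate mechanism is **viscous energy dissipation (VED)**: the inflow
jet through the narrowed, tunnel-like orifice is faster, shears harder
against the quasi-stationary ventricular blood, and wastes more of the
heart's work as heat — a loss that standard gradient measurements do
not capture.

This package implements the analysis chain used to study that
mechanism on a left-heart pulse duplicator, with a synthetic-data
module standing in for the physical rig so every stage is testable on a
desk:

1. **synthetic** — kinematic flow fields (uniform, solid rotation, pure
   shear, Lamb–Oseen vortex, transmitral E/A jet), rendered particle
   image pairs, LA/LV pressure traces (4 ms clock) and CW Doppler
   envelopes, with the duplicator's pump settings as defaults
   (rest: 70 bpm / 60.08 mL; exercise: 110 bpm / 90.13 mL; blood
   analogue μ = 4.2 cP, ρ = 1100 kg/m³; 1000 fps at 1632 × 1200 px).
2. **piv** — multi-pass FFT cross-correlation (64 → 16 px windows, 50 %
   overlap), three-point Gaussian sub-pixel peak fit, normalized-median
   vector validation.
3. **energetics** — the planar dissipation integral

   VED = (μ/2) ∫ Σᵢⱼ (∂uᵢ/∂xⱼ + ∂uⱼ/∂xᵢ)² dA  [W/m],

   its temporal evolution over the cycle, the two diastolic peaks
   (E wave and the remnant of the A wave), TVED (the time integral over
   1 s, with periodic extension past the recorded cycle), and a
   replicate-consistency one-way ANOVA.
4. **hemodynamics** — catheter mean gradient (time average of LA − LV
   over the diastolic crossover windows), Doppler mean gradient
   (simplified Bernoulli, ΔP = 4v²), and the Gorlin valve area

   MVA = 0.85 · CO / (44.3 · HR · flow period · √(mean gradient))  [cm²].
5. **pipeline / cli** — one-command orchestration of a full
   valve-by-condition study with replicates, provenance and a
   summary-table report.

## Worked example

Run the four experimental cells (two valve models × rest/exercise,
five replicate recordings each) and compare:

```python
from mitralflow import RunConfig, run_experiment, compare_conditions

reports = [run_experiment(RunConfig(condition=c, valve=v, seed=1))
           for v in ("normal", "mac") for c in ("rest", "exercise")]
table = compare_conditions(reports)
print(table.to_string(index=False))
```

```
                             parameter normal-rest normal-exercise mac-rest mac-exercise normal rise (%) mac rise (%)
                             MVA (cm2)       2.162             ---    1.384          ---
Mean Gradient, Catheter derived (mmHg)       1.315           5.067     3.21        5.978           285.2        86.24
 Mean Gradient, Doppler derived (mmHg)       2.047            8.04    2.632        9.707
                 VED, first peak (W/m)     0.06272          0.3486   0.1991        2.577
                   First peak time (s)    0.006696        0.004261 0.006696     0.004261
                VED, second peak (W/m)      0.1409          0.7828   0.4472        5.787
                  Second peak time (s)      0.5089          0.3239   0.5089       0.3239
                            TVED (J/m)      0.0169         0.09839  0.05367       0.7274           482.1         1255
```

Reading the table: the Gorlin areas (2.16 cm² for the normal model,
1.38 cm² for the calcified one) and the recovered mean gradients follow
from the synthetic traces built with the measured duplicator gradients
(1.3/3.2 mmHg at rest, 5.0/5.9 mmHg at exercise).  The VED rows are
desk-scale quantities of the kinematic jet model, not the rig's
measured dissipation; what carries over is the *ordering* — the
narrowed calcified jet shows a much larger rest→exercise TVED rise
(1255 %) than the normal jet (482 %), the mechanism of interest.
Exercise MVA is not computed because the diastolic flow period under
exercise is not defined (`---`).

The same stages are available as a CLI:

```sh
mitralflow simulate --condition rest --offset 3.2 --outdir sim/
mitralflow piv --pair sim/piv_a.tif sim/piv_b.tif --mag 3.1e-4 --dt 5e-5 --out field.csv
mitralflow hemo --la sim/la.csv --lv sim/lv.csv --doppler sim/doppler.csv
mitralflow run --condition rest --valve mac --seed 1 --outdir out/
```

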