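# amoebatrack

Quantify amoeba colonization behavior from time-lapse microscopy.

When a patch of dormant amoeba cysts (e.g. *Tetramitus*) is placed on an agar
plate next to a bacterial lawn, a time-lapse recording captures a stereotyped
sequence: a quiescent delay, excystation into motile trophozoites that
explore the substrate, and — if the bacteria support growth — proliferation
across the lawn. `amoebatrack` turns such recordings into six interpretable
behavioral parameters:

1. **Activity quantification** — consecutive frames are subtracted, and the
   number of pixels whose absolute intensity change exceeds a
   background-derived threshold is counted per frame pair. The running sum
   is the *cumulative activity* CA(t) (AU).
2. **Two-phase model fit** — CA(t) is fitted with a mono-exponential
   inoculum phase plus a logistic colonization phase:

   CA(t) = cIA·(1 − e^{−(t−tx)/tp})·[t ≥ tx] + cCA/(1 + e^{−(t−tc)/tg})

   where cIA and cCA are the phase amplitudes, tx the excystation delay,
   tp the exploration decay time, tc the colonization half-plateau time and
   tg the growth time (inverse logistic rate). The *relative colonization
   activity* cCA/(cCA + cIA) separates substrates that are colonized from
   those that are not; when no colonization occurs within the recording
   window, tc and tg are reported censored (">200" for a 200 h recording).
3. **Cohort statistics** — replicate fits are aggregated per condition
   (mean ± SD, censoring-aware) and conditions are compared by one-way
   ANOVA + Tukey HSD with compact letter displays.
4. **Synthetic microcosms** — a generator produces both noisy CA curves
   from known parameters and fully rendered image stacks (static cysts,
   random-walking trophozoites, a logistic colonization cohort, sensor
   noise) with complete ground truth, so the entire pipeline is testable
   without any external recordings.

Intended users: microbial-ecology and host–microbiome labs analyzing
plate-scale behavior of protists (or any motile microbe) from low-cost
time-lapse setups.

## Worked example

Fit the model to a noisy simulated colonizing condition
(`examples/01_fit_colonization_curve.py`):

```
parameter     true    fitted
   cIA   100.00     99.31
   cCA   300.00    302.80
    tx     4.00      3.93
    tp     9.00      9.08
    tc    55.00     55.04
    tg     3.00      2.98

relative colonization cCA/(cCA+cIA): 0.753
fit RMSE 0.34 AU, R^2 0.99999
```

All six parameters are recovered from a 200 h curve with 10% increment
noise; the relative colonization of 0.75 says three quarters of the total
activity came from proliferation on the lawn rather than from the initial
inoculum.

The full image pipeline (`examples/02_quantify_time_lapse.py`) renders the
reference synthetic scene (2,400 frames of 128×128 px at 30 s), estimates
the activity threshold from the quiet background, and recovers the scene's
event times from pixels alone:

```
frames: 2400 of (128, 128), window 20.0 h
threshold: 10.73 intensity levels
total cumulative activity: 191802 AU
excystation delay tx: fitted 2.21 h (scene nominal 2.00 h)
colonization half-time tc: fitted 10.17 h (scene nominal 10.00 h)
relative colonization: 0.57
```

`examples/03_censored_no_colonization.py` shows the censored report for a
substrate that is never colonized (relative colonization 0.0, tc and tg
">200"), and `examples/04_compare_conditions.py` builds a seven-condition
summary table with letter groups separating non-colonizing from colonizing
substrates.

A thin CLI mirrors the library for shell pipelines:

```sh
amoebatrack simulate --mode stack --scene scene.json --seed 1 --out run/
amoebatrack quantify --input run/stack.tif --out run/
amoebatrack fit run/ngm_1.csv run/ngm_2.csv --out run/
amoebatrack report --fits run/fits.csv --out run/
```

Every run writes a manifest with the config hash, input hashes and the
numeric decisions taken (threshold, bounds, seeds).

## Layout

```
src/amoebatrack/
  activity.py    frame differencing, threshold estimation, CA curves
  model.py       two-phase model: evaluation, fitting, censoring
  synthetic.py   curve sampler and image-stack renderer with ground truth
  cohort.py      replicate aggregation, ANOVA + Tukey, letter displays
  io.py          TIFF/PNG-sequence readers, CSV/JSON schemas, manifests
  cli.py         simulate / quantify / fit / report subcommands
docs/methods.md  model, estimation and generator details
examples/        one narrative script per capability
```
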