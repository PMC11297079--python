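# gazescene

Analysis pipeline for scene-viewing eye-tracking experiments in which body
posture and viewing task are manipulated — for example, comparing the classic
chin-rest laboratory setup against free sitting, quiet standing or standing on
a balance board while participants view natural photographs through mobile
eye-tracking glasses.

The package covers the complete path from raw binocular sample streams to
mixed-model inference:

1. **Scene mapping** — marker-based plane homographies project gaze from
   scene-camera pixels onto the stimulus image; a linear px↔degree conversion
   puts everything into degrees of visual angle, origin at the image center.
2. **Event detection** — a velocity-based algorithm with median-estimated
   noise thresholds: per eye, samples whose smoothed 2D velocity leaves the
   elliptic threshold `(v_x/λσ_x)² + (v_y/λσ_y)² > 1` for a minimum run are
   monocular saccades; binocular saccades require overlapping detections in
   both eyes. Fixations are the intervals between subsequent saccades; blinks
   come from the tracker's flags.
3. **Preprocessing** — the standard exclusion rules (blinks; fixations
   < 33 ms or ≥ 1000 ms; jittery fixations above 15× the median 2D SD;
   saccades > 25°; each with single-step neighbor removal), a 2°/200 ms
   pre-image fixation check, first-fixation exclusion, and start-position
   balancing. Every removal is logged in an audit ledger.
4. **Gaze statistics** — log fixation durations in 400 ms onset bins, log
   saccade amplitudes with half-SD-bandwidth kernel densities, Shannon
   entropy `S = −Σ pᵢ log₂ pᵢ` of the fixation-location density on a 128×128
   grid (0–14 bits; `exp(S)` as the model response), and the
   central-fixation-bias time course (mean distance to the image center per
   window, with its ~12° uniform reference).
5. **Inference** — maximum-likelihood linear mixed models with crossed
   subject and image random intercepts (optionally an uncorrelated image
   slope), ±½ contrast coding so each coefficient is a named difference of
   condition means (`Task`, `Body`, `Task:Body`; or `C1`, `C2`, `C3` for the
   four-posture design), the start-distance and log-ordinal covariates of the
   distance model, and Wald `t = M/SE` with the |t| > 2 reporting convention.

A synthetic-data generator produces full experiments with known ground truth
(log-normal fixation durations, main-sequence saccades, a time-decaying
central anchor, blinks, binocular noise, condition effects and crossed random
intercepts), so every stage — and the pipeline end to end — is testable
without any recordings.

## Worked example

Simulate a 2×2 (Task × Body) experiment with a −0.03 task effect on log
fixation duration, run detection and filtering, and fit the duration model:

```python
from gazescene import (SimulationParams, make_design, simulate_experiment,
                       significance_report)
from gazescene.pipeline import detect_and_filter, fit_response

params = SimulationParams(rng_seed=42,
    condition_effects={"Guess_Time": {"log_duration": -0.03}})
designs = make_design(1, n_subjects=10, n_images=10, rng_seed=42)
dataset = simulate_experiment(params, designs)

events, ledger = detect_and_filter(dataset.recordings)
fit, table = fit_response(events, dataset.design, experiment=1,
                          response="log_fixdur", window=(0, 8000))
print(significance_report(fit).round(4).to_string(index=False))
```

```
     term  estimate     se        t  significant  degenerate
Intercept    5.3725 0.0439 122.2984         True       False
     Task   -0.0194 0.0115  -1.6945        False       False
     Body    0.0034 0.0119   0.2822        False       False
Task:Body   -0.0202 0.0235  -0.8607        False       False
```

The intercept is the grand mean log duration (exp(5.37) ≈ 215 ms of detected
fixation time); `Task` estimates the Guess_Time − Free_Viewing difference and
recovers the simulated −0.03 within its standard error. At this small scale
(10 subjects × 10 images) the effect does not clear the |t| > 2 convention —
as expected, since the simulated effect equals roughly 1.7 standard errors.

The same interface is available from the shell:

```bash
gazescene simulate --experiment 1 --subjects 10 --images 10 --seed 42 --out data/
gazescene fit --experiment 1 --response log_fixdur --window 0:2000 \
    --data data/ --out fit.json
```

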