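# psykernel

Behavioral-analysis pipeline for a continuous visual displacement-detection
task: simulate a multi-item moving display whose items are occasionally
displaced from their trajectories, generate synthetic observer gaze and
button responses from a known ground-truth detection kernel, detect and
classify target-directed saccades from 60 Hz gaze data, bin trials into
detection categories, estimate per-category *psychophysical kernels*
(covariance ellipses of the non-detection density in motion-normalized
displacement space), and run group statistics on kernel properties.

## Modules

| module | role |
|---|---|
| `psykernel.stimulus` | 10 items at 18°/s in a 30°×22.5° display, wall bounces with ±0.001°/s jitter, displacements every 2000–4000 ms with 8 motion-relative orientations and a 0.5°-step amplitude grid |
| `psykernel.observer` | synthetic gaze (fixation + ballistic saccades at express/regular latencies), button presses; detection probability is logistic in the Mahalanobis distance from a ground-truth kernel |
| `psykernel.saccades` | blink interpolation, acceleration series, adaptive threshold (mean + 1 SD of the 2 s pre-displacement window), ±22.5° direction cone, express [25,150) / regular [150,250] ms classification |
| `psykernel.binning` | mutually exclusive trial categories (express/regular/explicit and mixtures) and detection rates |
| `psykernel.reverse_correlation` | direction/speed normalization, KDE densities on a 101×101 grid over ±0.5, rectified non-detection difference, 1000-point resampled covariance-ellipse fit (area, eccentricity, shift, orientation) |
| `psykernel.stats` | one-way repeated-measures ANOVA with Mauchly sphericity test and Greenhouse–Geisser correction, paired t-tests, post-hoc table |

## CLI

Each stage reads/writes plain CSV:

```sh
psykernel simulate --trials 160 --seed 1 --out session/        # + scene.yaml via --config
psykernel observe  --session session/ --seed 2 --out obs/
psykernel detect   --gaze obs/gaze.csv --stim session/displacements.csv --out saccades.csv
psykernel bin      --saccades saccades.csv --presses obs/presses.csv \
                   --stim session/displacements.csv --out trials.csv
psykernel kernel   --trials trials.csv --stim session/displacements.csv \
                   --out kernels.csv --seed 3
psykernel stats    --kernels kernels.csv --out stats/
```

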