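# headbcg

Heart-rate estimation from ballistocardiographic head movements in facial
video, using unsupervised clustering of spectral features.

The pipeline:

1. **tracking** — detect the face on the first frame (boosted LBP cascade),
   carve forehead and nose sub-regions, pick Shi–Tomasi corners and follow
   them with an iterative Lucas–Kanade tracker, keeping sub-pixel vertical
   coordinates. Recordings at other rates are resampled to the 30 Hz
   working rate.
2. **cardiac** — zero-phase 2nd-order Butterworth bandpass (0.75–2.5 Hz,
   i.e. 45–150 bpm), PCA to five components, and selection of the most
   *periodic* component (max in-band spectral density over total in-band
   power).
3. **features** — the relative power density (RPD): one-sided FFT power in
   the 0.75–2.5 Hz band normalized to sum to one (53 dimensions for a 30 s
   window at 30 Hz). Labels come from ECG via the Pan–Tompkins stages; the
   per-window label is the mean of the instantaneous rates 60/RR.
4. **model** — training samples are split into 10-bpm bins; inside each bin
   k-means runs for every cluster count from 3 to the number of distinct
   labels, and clusters whose member-label Pearson kurtosis exceeds the
   Gaussian value 3 are registered as (centroid, mean bpm) entries.
5. **estimate** — heart rate is the mean label of the *k* nearest model
   entries by Euclidean distance (default k = 1), with peak-detection and
   FFT baselines for comparison.
6. **evaluate** — 30 s / 1 s sliding-window segmentation, leave-one-subject-
   out cross-validation, and MAE / SDAE / RMSE / Pearson CC plus
   Bland–Altman limits of agreement.
7. **synthetic** — generators for trajectory matrices, ECG beat trains,
   textured-patch videos and multi-subject cohorts with known ground truth
   and three artifact levels (`none`, `expressions`, `expressions+motion`).

## CLI

All commands live under one entry point, `bcg`:

```sh
# synthesize a 5-subject cohort with the labeled dataset CSV
bcg simulate --level normal --subjects 5 --duration 180 --seed 1 \
    --out runs/cohort --dataset

# track a video (file or directory of numbered PNGs) into a trajectory CSV
bcg track runs/frames --fps 30 --roi 40,30,80,60 --out runs/traj.csv

# train the clustering model and estimate per-window heart rate
bcg train --dataset runs/cohort/dataset.csv --seed 1 --out runs/model.json
bcg estimate --input runs/cohort/s00_traj.csv --method clustering \
    --model runs/model.json --k 1 --out runs/est.csv

# baselines need no model
bcg estimate --input runs/cohort/s00_traj.csv --method fft --out runs/fft.csv

# leave-one-subject-out evaluation with Bland-Altman points
bcg evaluate --dataset runs/cohort/dataset.csv --method clustering \
    --k 1 --seed 1 --out runs/metrics.json --ba-out runs/ba.csv
```

The `peak` baseline needs the time series, so `bcg evaluate --method peak`
takes `--cohort DIR` (a `simulate` output directory) instead of
`--dataset`. Every pipeline error maps to a distinct nonzero exit code
(see `headbcg/errors.py`).

## File formats

- trajectory CSV: `t_sec,p0,p1,...`, one row per frame
- ECG CSV: `t_sec,mv`
- dataset CSV: `rpd_0..rpd_52,bpm,subject_id,window_start_sec`
- model JSON: `{version, feature_dim, band_hz, entries: [{centroid, bpm}],
  training_meta}`
- estimates CSV: `window_start_sec,bpm,method`
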