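# gazedecode

Decoding viewer identity and group membership from 60 Hz eye-tracking
trials.

Screen-viewing studies record where a participant's gaze lands while they
look at an image.  Two questions recur in visual-attention research: do
individuals carry an endogenous, image-invariant gaze signature, and do
trained and untrained viewers attend to different content?  `gazedecode`
answers both by classification: it segments raw gaze traces into fixations
and saccades, extracts per-trial feature vectors, and measures how well a
classifier can predict who was looking (identity decoding) or which group
they belong to (group decoding), against explicit chance levels.

The pipeline:

1. **Event detection (I-DT).**  A fixation is a maximal sample window
   whose dispersion (max pairwise distance) stays ≤ 0.02 normalized units;
   everything between fixations — saccades, glissades, pursuit — is pooled
   into a broad "saccade" category.
2. **Features** (138 per trial at the default 10×10 grid): fixation
   summary (mean duration, count, mean saccade length, count);
   10-bin fixation-duration and saccade-length histograms; a 14-bin
   velocity histogram of frame-step lengths with bin 1 reserved for
   exactly-zero steps; and a fixation map of cumulative fixation duration
   per grid cell.  Histogram boundaries are equal-frequency (quantile)
   edges refit on each training fold only, so validation data never leaks
   into feature extraction.
3. **Decoding.**  Leave-one-image-out folds for identity (the classifier
   never sees the validation image), repeated 70/30 splits for group
   decoding, and per-image leave-one-participant-out on 20×20 fixation
   maps.  Feature selection by extremely-randomized-trees importance
   (threshold grid {1.7..2.1} × mean) and hyper-parameter tuning
   (C ∈ {0.25, 0.5, 1, 2, 4}) run inside each fold; fold accuracies are
   tested against chance (1/n viewers, or 50%) with a one-sample t test.

A synthetic cohort generator with per-viewer kinematic signatures
(gamma fixation durations, lognormal saccade steps, zero-velocity frames)
and per-group region-of-interest preferences makes the whole pipeline
runnable and testable without any recorded data; recorded trials can be
supplied as a long-format CSV (`participant_id,image_id,group,t_ms,x,y,
valid`) with an adapter hook for foreign layouts.

## Worked example

```python
import gazedecode as gz

# 12 viewers whose saccade kinematics differ, 14 images, 10 s at 60 Hz
cohort = gz.make_separated_cohort(6, 6, seed=0, log_mean_spacing=0.5)
layouts = gz.default_layouts(14, seed=0)
trials = gz.simulate_dataset(cohort, layouts, duration_s=10.0, seed=0)

folds = gz.make_folds(trials, "leave_one_image_out")
res = gz.run_decoding(trials, "individual", folds,
                      gz.ClassifierSpec(family="rbf_svm"), seed=0)
print(f"accuracy {100*res.mean_accuracy:.1f}% "
      f"(chance {100*res.chance:.1f}%), top-5 {100*res.topk_accuracy:.1f}%")
```

Running this (it is `analysis/03_decode_individuals.py`) prints:

```
identity decoding: 98.2 +/- 3.5% over 14 folds (chance 8.3%, top-5 100.0%, t=94.77, p=7.52e-20)
top features by importance:
 feature    block  mean_importance  times_selected
      24 vel_hist         0.067347              14
      36 vel_hist         0.058646              14
      ...
```

98.2% of validation trials are assigned to the right viewer even though
the classifier never saw the validation image — the planted kinematic
signatures are endogenous, and the importance profile shows the velocity
histogram (features 25–38, led by the zero-velocity bin at index 24)
carrying most of the signal.  The t test rejects the 8.3% chance level.

The other drivers follow the same pattern: `analysis/04_decode_groups.py`
decodes group membership from full feature vectors over 14 random 70/30
splits (95.2 ± 1.8% against 50% chance on the default synthetic cohort),
and `analysis/05_decode_per_image.py` runs per-image leave-one-
participant-out decoding on 20×20 fixation maps and renders the
group-difference attention map of the best-decoded image.

## Analysis scripts

| script | what it does |
|--------|--------------|
| `analysis/01_simulate_cohort.py` | generate the full 71-viewer × 14-image cohort (raw CSV to `scratch/`, profile table to `results/`) |
| `analysis/02_events_and_bins.py` | event-level summaries and per-fold quantile bin-range tables |
| `analysis/03_decode_individuals.py` | identity decoding + per-viewer rates, confusion matrix, importance profile |
| `analysis/04_decode_groups.py` | group decoding over repeated 70/30 splits |
| `analysis/05_decode_per_image.py` | per-image group decoding + attention difference maps |

Each writes tidy CSVs (and PNGs where applicable) under `results/`.

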