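#!/usr/bin/env python
"""Segment the cohort into fixations/saccades and tabulate per-fold
histogram bin ranges.

Reads scratch/gaze_dataset.csv if 01_simulate_cohort.py produced it
(regenerates a smaller cohort otherwise), runs dispersion-threshold
detection, and writes:

* results/event_summary.csv — per-trial fixation/saccade counts and times;
* results/bin_ranges.csv — for each histogram, each bin's upper boundary
  averaged over the leave-one-image-out training folds (mean +/- sd), the
  per-fold recalculation that keeps validation data out of feature
  extraction.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
import gazedecode as gz  # noqa: E402

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch",
                       "gaze_dataset.csv")
OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def load_trials():
    if os.path.exists(SCRATCH):
        print(f"loading {SCRATCH}")
        return gz.read_trials(SCRATCH)
    print("scratch dataset not found; generating a reduced cohort")
    cohort = gz.make_cohort(10, 8, seed=0)
    layouts = gz.default_layouts(6, seed=0)
    return gz.simulate_dataset(cohort, layouts, duration_s=10.0, seed=0)


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    trials = load_trials()
    events = {t.key: gz.detect_fixations_idt(t) for t in trials}

    rows = [
        {
            "participant_id": t.participant_id,
            "image_id": t.image_id,
            "group": t.group,
            "n_fixations": len(events[t.key].fixations),
            "n_saccades": len(events[t.key].saccades),
            "fixation_time_s": events[t.key].total_fixation_time,
            "saccade_time_s": events[t.key].total_saccade_time,
        }
        for t in trials
    ]
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(OUT, "event_summary.csv"), index=False)
    print(summary[["n_fixations", "n_saccades", "fixation_time_s"]]
          .describe().round(2))

    by_key = {t.key: t for t in trials}
    folds = gz.make_folds(trials, "leave_one_image_out")
    per_fold = {"fixdur": [], "sacc": [], "vel": []}
    for train_keys, _ in folds.folds:
        train = [by_key[k] for k in train_keys]
        edges = gz.fit_edge_set(train, events, fitted_on="fold")
        for name in per_fold:
            per_fold[name].append(np.asarray(edges[name].boundaries))
    records = []
    for name, arrs in per_fold.items():
        stack = np.vstack(arrs)
        finite = np.isfinite(stack)
        for b in range(stack.shape[1]):
            vals = stack[:, b]
            records.append({
                "histogram": name,
                "bin": b + (2 if name == "vel" else 1),
                "upper_boundary_mean": (
                    vals.mean() if finite[:, b].all() else np.inf
                ),
                "upper_boundary_sd": (
                    vals.std(ddof=1) if finite[:, b].all() else 0.0
                ),
            })
    table = pd.DataFrame(records)
    table.to_csv(os.path.join(OUT, "bin_ranges.csv"), index=False)
    print("\nbin ranges (mean over folds), velocity histogram:")
    print(table[table.histogram == "vel"].round(5).to_string(index=False))


if __name__ == "__main__":
    main()
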