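"""Diagnostic artifacts: importance profiles, histogram overlays, colored
scanpaths and group-difference attention maps.

Every render is deterministic given its inputs (fixed color maps, no
timestamps), and the numbers behind each plot are returned (and writable as
CSV), so tests assert on numbers rather than pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # noqa: E402  (headless rendering)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection

from .event_detection import detect_fixations_idt, velocity_series
from .features import BinEdges, feature_block_slices, fixation_map, histogram_feature
from .gaze_io import SCREEN_HEIGHT, SCREEN_WIDTH, Trial

__all__ = [
    "AttentionGrid", "importance_profile", "velocity_histogram_overlay",
    "scanpath_render", "group_difference_map",
]


def importance_profile(
    importances_per_fold: list[np.ndarray],
    selected_per_fold: list[np.ndarray],
    grid: int = 10,
    out_path: str | None = None,
) -> pd.DataFrame:
    """Mean per-feature importance and times-selected count across folds.

    Returns a tidy frame (feature index, block name, mean_importance,
    times_selected); the optional plot shows the importance line with
    selection-count dots and vertical block boundaries at the
    4/14/24/38/138 feature-index convention.
    """
    if not importances_per_fold:
        raise ValueError("at least one fold is required")
    imp = np.vstack(importances_per_fold)
    n_features = imp.shape[1]
    counts = np.zeros(n_features, dtype=int)
    for sel in selected_per_fold:
        counts[np.asarray(sel, dtype=int)] += 1
    blocks = feature_block_slices(grid)
    block_of = np.empty(n_features, dtype=object)
    for name, sl in blocks.items():
        block_of[sl] = name
    frame = pd.DataFrame(
        {
            "feature": np.arange(n_features),
            "block": block_of,
            "mean_importance": imp.mean(axis=0),
            "times_selected": counts,
        }
    )
    if out_path is not None:
        fig, ax = plt.subplots(figsize=(10, 3.2))
        ax.plot(frame["feature"], frame["mean_importance"], lw=0.9,
                color="tab:blue", label="mean importance")
        ax2 = ax.twinx()
        picked = frame[frame["times_selected"] > 0]
        ax2.plot(picked["feature"], picked["times_selected"], "r.",
                 ms=4, label="times selected")
        for sl in blocks.values():
            ax.axvline(sl.stop - 0.5, color="0.8", lw=0.7)
        ax.set_xlabel("feature index")
        ax.set_ylabel("importance")
        ax2.set_ylabel("selections")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return frame


def velocity_histogram_overlay(
    trials: list[Trial],
    edges: BinEdges,
    out_path: str | None = None,
) -> tuple[np.ndarray, float]:
    """Per-trial velocity histograms of one individual, overlaid.

    Returns the (n_trials, n_bins) histogram matrix and a consistency
    score: the mean pairwise L1 distance between the per-trial histograms
    (0 for identical trials; smaller = more image-invariant signature).
    """
    hists = np.vstack(
        [histogram_feature(velocity_series(t), edges) for t in trials]
    )
    n = hists.shape[0]
    if n < 2:
        score = 0.0
    else:
        dists = [
            np.abs(hists[i] - hists[j]).sum()
            for i in range(n) for j in range(i + 1, n)
        ]
        score = float(np.mean(dists))
    if out_path is not None:
        fig, ax = plt.subplots(figsize=(6, 3.2))
        cmap = plt.get_cmap("viridis")
        for i, row in enumerate(hists):
            ax.plot(np.arange(1, hists.shape[1] + 1), row,
                    color=cmap(i / max(n - 1, 1)), lw=0.9,
                    label=trials[i].image_id)
        ax.set_xlabel("velocity bin")
        ax.set_ylabel("relative frequency")
        ax.set_title(
            f"{trials[0].participant_id} (consistency {score:.3f})"
        )
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return hists, score


def scanpath_render(
    trial: Trial,
    edges: BinEdges,
    out_path: str | None = None,
) -> np.ndarray:
    """Scanpath with each inter-sample segment colored by its velocity bin.

    Returns the 0-based bin index per valid step (-1 for steps spanning an
    invalid sample); zero-velocity frames are drawn as dots rather than
    segments.  The bin-to-color map is a fixed discrete colormap, so equal
    bins always share a color.
    """
    steps = velocity_series(trial)
    bounds = np.asarray(edges.boundaries)
    bins = np.empty(len(steps), dtype=int)
    if edges.zero_bin:
        zero = np.abs(steps) <= 1e-9
        bins[zero] = 0
        bins[~zero] = 1 + np.searchsorted(bounds, steps[~zero], side="left")
    else:
        bins[:] = np.searchsorted(bounds, steps, side="left")

    # re-expand to per-original-step labels (-1 where a step was skipped)
    both = trial.valid[:-1] & trial.valid[1:]
    labels = np.full(trial.n_samples - 1, -1, dtype=int)
    labels[both] = bins

    if out_path is not None:
        cmap = plt.get_cmap("tab20", edges.n_bins)
        fig, ax = plt.subplots(figsize=(6, 6 * SCREEN_HEIGHT / SCREEN_WIDTH))
        pts = np.column_stack([trial.x, trial.y])
        seg_idx = np.flatnonzero(both)
        moving = seg_idx[labels[seg_idx] > 0] if edges.zero_bin else seg_idx
        segs = np.stack([pts[moving], pts[moving + 1]], axis=1)
        lc = LineCollection(
            segs, colors=[cmap(labels[i]) for i in moving], lw=0.8
        )
        ax.add_collection(lc)
        if edges.zero_bin:
            dots = seg_idx[labels[seg_idx] == 0]
            ax.plot(pts[dots + 1, 0], pts[dots + 1, 1], ".",
                    color=cmap(0), ms=3)
        ax.set_xlim(0, SCREEN_WIDTH)
        ax.set_ylim(SCREEN_HEIGHT, 0)  # screen y grows downward
        ax.set_aspect("equal")
        ax.set_title(f"{trial.participant_id} / {trial.image_id}")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return labels


@dataclass
class AttentionGrid:
    """Per-group mean cumulative fixation duration per grid cell (s)."""

    image_id: str
    grid: int
    group_a: np.ndarray  # (G, G) seconds, mean over group-A trials
    group_b: np.ndarray
    difference: np.ndarray  # group_a - group_b

    def to_frame(self) -> pd.DataFrame:
        g = self.grid
        rows, cols = np.divmod(np.arange(g * g), g)
        return pd.DataFrame(
            {
                "image_id": self.image_id,
                "row": rows,
                "col": cols,
                "group_a_s": self.group_a.ravel(),
                "group_b_s": self.group_b.ravel(),
                "difference_s": self.difference.ravel(),
            }
        )


def group_difference_map(
    trials: list[Trial],
    image_id: str,
    grid: int = 20,
    out_path: str | None = None,
    detector_kwargs: dict | None = None,
    groups: tuple[str, str] | None = None,
) -> AttentionGrid:
    """Where the two groups' attention diverges on one image.

    Per-cell values are cumulative fixation durations averaged over each
    group's trials (per-trial means, so unequal group sizes compare
    fairly).  The rendered overlay colors cells by the sign of the
    difference (red = first group dominant, green = second) with alpha
    proportional to |difference| normalized to the per-image maximum, and
    annotates each cell with its per-group durations.
    """
    subset = [t for t in trials if t.image_id == image_id]
    present = sorted({t.group for t in subset})
    if groups is None:
        if len(present) != 2:
            raise ValueError(
                f"need exactly two groups for image {image_id!r}, "
                f"found {present}"
            )
        groups = (present[0], present[1])
    maps = {g: [] for g in groups}
    for trial in subset:
        if trial.group not in maps:
            continue
        ev = detect_fixations_idt(trial, **(detector_kwargs or {}))
        maps[trial.group].append(fixation_map(ev, grid).reshape(grid, grid))
    for g in groups:
        if not maps[g]:
            raise ValueError(f"no trials of group {g!r} for image {image_id!r}")
    mean_a = np.mean(maps[groups[0]], axis=0)
    mean_b = np.mean(maps[groups[1]], axis=0)
    out = AttentionGrid(
        image_id=image_id,
        grid=grid,
        group_a=mean_a,
        group_b=mean_b,
        difference=mean_a - mean_b,
    )
    if out_path is not None:
        diff = out.difference
        vmax = np.abs(diff).max() or 1.0
        rgba = np.zeros((grid, grid, 4))
        rgba[..., 0] = diff > 0  # red where first group dominates
        rgba[..., 1] = diff < 0  # green where second group dominates
        rgba[..., 3] = np.abs(diff) / vmax
        fig, ax = plt.subplots(figsize=(7, 7 * SCREEN_HEIGHT / SCREEN_WIDTH))
        ax.imshow(
            rgba, extent=(0, SCREEN_WIDTH, SCREEN_HEIGHT, 0),
            interpolation="nearest",
        )
        if grid <= 20:
            for r in range(grid):
                for c in range(grid):
                    if mean_a[r, c] or mean_b[r, c]:
                        ax.text(
                            (c + 0.5) / grid * SCREEN_WIDTH,
                            (r + 0.5) / grid * SCREEN_HEIGHT,
                            f"{mean_a[r, c]:.2f}\n{mean_b[r, c]:.2f}",
                            ha="center", va="center", fontsize=3,
                        )
        ax.set_title(f"{image_id}: {groups[0]} (red) vs {groups[1]} (green)")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return out
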