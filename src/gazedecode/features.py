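"""Per-trial gaze features: summaries, quantile histograms, fixation maps.

Five named blocks per trial, concatenated in a fixed order:

==================  ======  ==================================================
block               length  content
==================  ======  ==================================================
fixation_summary    4       mean fixation duration (s), fixation count,
                            mean saccade length (normalized), saccade count
fixdur_hist         10      fixation-duration histogram
sacc_hist           10      saccade-length histogram
vel_hist            14      frame-step velocity histogram; bin 1 reserved
                            for exactly-zero steps
fixmap              G*G     cumulative fixation duration (s) per cell of a
                            G x G grid over the screen rectangle
==================  ======  ==================================================

With the default G = 10 the vector has length 138.

Histogram boundaries are equal-frequency (quantile) edges fitted on pooled
values from *training-fold trials only* — refit on every fold so that
validation data can never influence feature extraction.  Histogram entries
are relative frequencies by default (raw counts via ``normalize=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .event_detection import EventSequence, velocity_series
from .gaze_io import SCREEN_HEIGHT, SCREEN_WIDTH, Trial

__all__ = [
    "ZERO_TOL", "BinEdges", "DegenerateEdgesError", "FeatureVector",
    "fit_bin_edges", "histogram_feature", "fixation_map",
    "assemble_features", "feature_block_slices", "fit_edge_set",
]

#: Values with magnitude at or below this are "exactly zero" for the
#: reserved velocity bin (raw positions carry ~1e-4 resolution, so true
#: frame repeats produce steps of exactly 0).
ZERO_TOL = 1e-9

#: Histogram sizes: 14 velocity bins (one reserved for zero), 10 otherwise.
N_VELOCITY_BINS = 14
N_DURATION_BINS = 10
N_SACCADE_BINS = 10


class DegenerateEdgesError(ValueError):
    """Too few distinct positive values to place the requested boundaries."""


@dataclass(frozen=True)
class BinEdges:
    """Quantile histogram boundaries fitted on one training fold.

    ``boundaries`` are the upper edges of the non-special bins, strictly
    increasing with the last equal to +inf; bins are half-open ``(lo, hi]``.
    With ``zero_bin`` the first bin of the histogram holds exactly-zero
    values only and ``boundaries`` describe the remaining bins.
    """

    boundaries: tuple[float, ...]
    zero_bin: bool = False
    fitted_on: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if b.size == 0 or not np.isposinf(b[-1]):
            raise ValueError("last boundary must be +inf")
        if b.size > 1 and not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + (1 if self.zero_bin else 0)


def fit_bin_edges(
    values, n_bins: int, zero_bin: bool = False, fitted_on: str = ""
) -> BinEdges:
    """Fit equal-frequency (quantile) bin boundaries to training values.

    With ``zero_bin`` the exactly-zero values are set aside into the
    reserved first bin and the remaining ``n_bins - 1`` boundaries split the
    sorted positive values into equal-count groups; without it all values
    are split into ``n_bins`` groups.  The final upper boundary is +inf.

    Raises :class:`DegenerateEdgesError` when there are fewer distinct
    positive values than groups (boundaries would collide).
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("cannot fit bin edges on empty data")
    if zero_bin:
        if n_bins < 2:
            raise ValueError("zero_bin requires n_bins >= 2")
        vals = vals[np.abs(vals) > ZERO_TOL]
        n_groups = n_bins - 1
    else:
        n_groups = n_bins
    vals = np.sort(vals)
    n_distinct = np.unique(vals).size
    if n_distinct < n_groups:
        raise DegenerateEdgesError(
            f"{n_distinct} distinct positive values cannot fill "
            f"{n_groups} equal-frequency groups"
        )
    m = vals.size
    # group i (1-based) covers sorted indices [m(i-1)//k, mi//k); its upper
    # edge is its last member, so group sizes differ by at most one
    cut = (m * np.arange(1, n_groups)) // n_groups
    bounds = vals[cut - 1]
    if np.unique(bounds).size != bounds.size:
        raise DegenerateEdgesError(
            "tied values collapse adjacent boundaries; "
            "not enough distinct values for equal-frequency groups"
        )
    boundaries = tuple(float(b) for b in bounds) + (float("inf"),)
    return BinEdges(boundaries=boundaries, zero_bin=zero_bin, fitted_on=fitted_on)


def histogram_feature(
    values, edges: BinEdges, normalize: bool = True
) -> np.ndarray:
    """Histogram of ``values`` under fitted ``edges``.

    The reserved zero bin (when present) is matched by ``|v| <= 1e-9``;
    other bins are half-open ``(lo, hi]``.  Entries are relative
    frequencies summing to 1 (raw counts with ``normalize=False``); empty
    input yields an all-zero vector.
    """
    vals = np.asarray(values, dtype=float).ravel()
    counts = np.zeros(edges.n_bins)
    if vals.size == 0:
        return counts
    bounds = np.asarray(edges.boundaries)
    if edges.zero_bin:
        is_zero = np.abs(vals) <= ZERO_TOL
        counts[0] = is_zero.sum()
        pos = vals[~is_zero]
        counts[1:] = np.bincount(
            np.searchsorted(bounds, pos, side="left"),
            minlength=bounds.size,
        )[: bounds.size]
    else:
        counts[:] = np.bincount(
            np.searchsorted(bounds, vals, side="left"),
            minlength=bounds.size,
        )[: bounds.size]
    if normalize:
        counts /= vals.size
    return counts


def fixation_map(
    events: EventSequence,
    grid: int = 10,
    region: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Cumulative fixation duration per cell of a ``grid x grid`` tiling.

    Cells tile the screen rectangle (or an explicit ``region``
    ``(x0, y0, x1, y1)``) row-major from the top-left; right/bottom edges
    belong to the last cell.  Each fixation contributes its full duration
    to the cell containing its centroid.  Returns the flattened (row-major)
    ``grid**2`` vector; its sum equals the trial's total fixation time.
    """
    if grid < 1:
        raise ValueError("grid must be >= 1")
    x0, y0, x1, y1 = region if region is not None else (
        0.0, 0.0, SCREEN_WIDTH, SCREEN_HEIGHT
    )
    out = np.zeros(grid * grid)
    for fx in events.fixations:
        cx, cy = fx.centroid
        col = min(int((cx - x0) / (x1 - x0) * grid), grid - 1)
        row = min(int((cy - y0) / (y1 - y0) * grid), grid - 1)
        out[row * grid + col] += fx.duration
    return out


def feature_block_slices(grid: int = 10) -> dict[str, slice]:
    """Index ranges of the five feature blocks in concatenation order."""
    sizes = [
        ("fixation_summary", 4),
        ("fixdur_hist", N_DURATION_BINS),
        ("sacc_hist", N_SACCADE_BINS),
        ("vel_hist", N_VELOCITY_BINS),
        ("fixmap", grid * grid),
    ]
    blocks: dict[str, slice] = {}
    start = 0
    for name, size in sizes:
        blocks[name] = slice(start, start + size)
        start += size
    return blocks


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated named feature blocks of one trial, with labels."""

    values: np.ndarray
    blocks: dict[str, slice] = field(repr=False)
    participant_id: str = ""
    image_id: str = ""
    group: str = "unknown"

    def block(self, name: str) -> np.ndarray:
        return self.values[self.blocks[name]]

    def __len__(self) -> int:
        return int(self.values.size)


def fit_edge_set(
    trials: list[Trial],
    events_by_key: dict[tuple[str, str], EventSequence],
    fitted_on: str = "",
) -> dict[str, BinEdges]:
    """Fit the three histogram edge sets on pooled training-fold values.

    Pools fixation durations, saccade path lengths and frame-step
    velocities across the given (training) trials and fits 10/10/14
    equal-frequency bins; the velocity histogram reserves bin 1 for
    exactly-zero steps.
    """
    fixdur: list[np.ndarray] = []
    sacc: list[np.ndarray] = []
    vel: list[np.ndarray] = []
    for trial in trials:
        ev = events_by_key[trial.key]
        fixdur.append(ev.fixation_durations())
        sacc.append(ev.saccade_lengths())
        vel.append(velocity_series(trial))
    return {
        "fixdur": fit_bin_edges(
            np.concatenate(fixdur), N_DURATION_BINS, False, fitted_on
        ),
        "sacc": fit_bin_edges(
            np.concatenate(sacc), N_SACCADE_BINS, False, fitted_on
        ),
        "vel": fit_bin_edges(
            np.concatenate(vel), N_VELOCITY_BINS, True, fitted_on
        ),
    }


def assemble_features(
    trial: Trial,
    events: EventSequence,
    edge_set: dict[str, BinEdges],
    grid: int = 10,
    normalize: bool = True,
) -> FeatureVector:
    """Build the full per-trial feature vector (length 4+10+10+14+G*G).

    ``edge_set`` must hold fitted edges under keys ``fixdur``, ``sacc`` and
    ``vel``.  A trial without saccades (or fixations) reports count 0 and
    mean 0 for the missing event type.
    """
    for key in ("fixdur", "sacc", "vel"):
        if key not in edge_set:
            raise ValueError(f"edge_set missing fitted edges for {key!r}")
    fixdur = events.fixation_durations()
    sacc = events.saccade_lengths()
    vel = velocity_series(trial)
    summary = np.array(
        [
            fixdur.mean() if fixdur.size else 0.0,
            float(fixdur.size),
            sacc.mean() if sacc.size else 0.0,
            float(sacc.size),
        ]
    )
    parts = [
        summary,
        histogram_feature(fixdur, edge_set["fixdur"], normalize),
        histogram_feature(sacc, edge_set["sacc"], normalize),
        histogram_feature(vel, edge_set["vel"], normalize),
        fixation_map(events, grid),
    ]
    return FeatureVector(
        values=np.concatenate(parts),
        blocks=feature_block_slices(grid),
        participant_id=trial.participant_id,
        image_id=trial.image_id,
        group=trial.group,
    )
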