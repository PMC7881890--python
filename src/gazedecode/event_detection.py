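"""Fixation/saccade segmentation by dispersion threshold (I-DT).

A fixation is a maximal run of samples whose spatial dispersion stays at or
below a threshold (default 0.02 normalized units); everything between
fixations — rapid jumps, glissades, smooth pursuit alike — is pooled into a
single broad "saccade" category.  Detection is the classical greedy
left-to-right window growth: seed a window of ``min_samples``, grow it while
the dispersion stays within the threshold, emit, restart after it; slide by
one sample when even the seed window is too dispersed.

Dispersion defaults to the true diameter of the window (maximum pairwise
Euclidean distance); the classical I-DT surrogate (x-range + y-range) is
selectable via ``metric="range"``.

Only valid samples participate; invalid samples are skipped as if absent,
and the fixation/saccade segments partition the valid-sample range.  Saccade
segments are bounded by the adjacent fixation endpoint samples, so total
fixation time + total saccade time equals the valid-sample time span
exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .gaze_io import Trial

__all__ = [
    "Fixation", "Saccade", "EventSequence", "dispersion",
    "detect_fixations_idt", "velocity_series", "velocity_to_deg",
]

logger = logging.getLogger(__name__)

#: Default dispersion (diameter) threshold in normalized screen units.
DEFAULT_DISPERSION_THRESHOLD = 0.02
#: Default minimum fixation extent in samples (~50 ms at 60 Hz).
DEFAULT_MIN_SAMPLES = 3

#: Physical screen geometry used for visual-angle conversion.
SCREEN_WIDTH_CM = 24.98
VIEWING_DISTANCE_CM = 50.0


@dataclass(frozen=True)
class Fixation:
    """A dispersion-bounded gaze epoch.

    Indices refer to the trial's sample arrays and are inclusive; the
    centroid is the mean of member positions; duration is in seconds.
    """

    start_index: int
    end_index: int
    centroid: tuple[float, float]
    duration: float
    dispersion: float


@dataclass(frozen=True)
class Saccade:
    """Inter-fixation segment (broad category: jumps, glissades, pursuit).

    Endpoints coincide with the bounding fixations' boundary samples (or the
    first/last valid sample for leading/trailing segments).  ``path_length``
    is the sum of inter-sample step lengths along the segment.
    """

    start_index: int
    end_index: int
    path_length: float
    duration: float


@dataclass
class EventSequence:
    """Ordered fixations and saccades of one trial, plus detection config."""

    trial: Trial
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    dispersion_threshold: float = DEFAULT_DISPERSION_THRESHOLD
    min_samples: int = DEFAULT_MIN_SAMPLES
    max_duration: float | None = None

    @property
    def total_fixation_time(self) -> float:
        return float(sum(f.duration for f in self.fixations))

    @property
    def total_saccade_time(self) -> float:
        return float(sum(s.duration for s in self.saccades))

    def fixation_durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations])

    def saccade_lengths(self) -> np.ndarray:
        return np.array([s.path_length for s in self.saccades])


def dispersion(points, metric: str = "diameter") -> float:
    """Spatial dispersion of a point set.

    ``metric="diameter"`` (default) is the maximum pairwise Euclidean
    distance; ``metric="range"`` is the classical I-DT surrogate
    (x-range + y-range).  A single point has dispersion 0.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("dispersion of an empty point set is undefined")
    if metric == "range":
        return float(np.ptp(pts[:, 0]) + np.ptp(pts[:, 1]))
    if metric != "diameter":
        raise ValueError(f"unknown dispersion metric {metric!r}")
    if pts.shape[0] == 1:
        return 0.0
    d = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).max())


def _path_length(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


def detect_fixations_idt(
    trial: Trial,
    dispersion_threshold: float = DEFAULT_DISPERSION_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    max_duration: float | None = None,
    metric: str = "diameter",
) -> EventSequence:
    """Segment a trial into fixations and saccades with greedy I-DT.

    A window of ``min_samples`` consecutive valid samples seeds each
    candidate; if its dispersion is within the threshold it is grown
    rightward until adding one more sample would push the dispersion over
    the threshold (or, when ``max_duration`` is set, the window past that
    time span), then emitted as a fixation and the scan restarts after it.
    Otherwise the window slides by one sample.  Ties (dispersion exactly at
    threshold) include the sample.

    Valid samples outside every fixation form the saccade segments.  A
    trial with fewer than ``min_samples`` valid samples yields an empty
    sequence with a warning, not an exception.
    """
    if dispersion_threshold <= 0:
        raise ValueError("dispersion_threshold must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")

    seq = EventSequence(
        trial=trial,
        dispersion_threshold=dispersion_threshold,
        min_samples=min_samples,
        max_duration=max_duration,
    )
    vidx = np.flatnonzero(trial.valid)
    m = vidx.size
    if m < min_samples:
        warnings.warn(
            f"trial {trial.key} has {m} valid samples "
            f"(< min_samples={min_samples}); no events detected",
            stacklevel=2,
        )
        return seq

    x = trial.x[vidx]
    y = trial.y[vidx]
    t_s = trial.t_ms[vidx] / 1000.0
    pts = np.column_stack([x, y])

    fix_spans: list[tuple[int, int]] = []  # [start, end] in valid-seq index
    i = 0
    while i + min_samples <= m:
        window = pts[i : i + min_samples]
        d = dispersion(window, metric=metric)
        if d <= dispersion_threshold:
            j = i + min_samples  # next candidate sample
            if metric == "diameter":
                while j < m:
                    if (
                        max_duration is not None
                        and t_s[j] - t_s[i] > max_duration
                    ):
                        break
                    step = np.hypot(
                        pts[i:j, 0] - pts[j, 0], pts[i:j, 1] - pts[j, 1]
                    ).max()
                    nd = max(d, float(step))
                    if nd > dispersion_threshold:
                        break
                    d = nd
                    j += 1
            else:
                while j < m:
                    if (
                        max_duration is not None
                        and t_s[j] - t_s[i] > max_duration
                    ):
                        break
                    nd = dispersion(pts[i : j + 1], metric=metric)
                    if nd > dispersion_threshold:
                        break
                    d = nd
                    j += 1
            fix_spans.append((i, j - 1))
            seq.fixations.append(
                Fixation(
                    start_index=int(vidx[i]),
                    end_index=int(vidx[j - 1]),
                    centroid=(
                        float(x[i:j].mean()), float(y[i:j].mean())
                    ),
                    duration=float(t_s[j - 1] - t_s[i]),
                    dispersion=float(d),
                )
            )
            i = j
        else:
            i += 1

    # saccade segments between/around fixations, bounded by fixation
    # endpoint samples so that event durations tile the valid span
    def _emit(a: int, b: int) -> None:
        # a, b: valid-seq indices, inclusive; requires b > a
        seq.saccades.append(
            Saccade(
                start_index=int(vidx[a]),
                end_index=int(vidx[b]),
                path_length=_path_length(x[a : b + 1], y[a : b + 1]),
                duration=float(t_s[b] - t_s[a]),
            )
        )

    if not fix_spans:
        _emit(0, m - 1)
        return seq
    if fix_spans[0][0] > 0:
        _emit(0, fix_spans[0][0])
    for (_, prev_end), (next_start, _) in zip(fix_spans, fix_spans[1:]):
        _emit(prev_end, next_start)
    if fix_spans[-1][1] < m - 1:
        _emit(fix_spans[-1][1], m - 1)
    return seq


def velocity_series(trial: Trial) -> np.ndarray:
    """Per-frame step lengths: Euclidean distance between adjacent samples.

    Only pairs of consecutive samples that are both valid contribute; a
    step spanning an invalid sample is discarded.  Units are normalized
    screen length per frame.
    """
    if trial.n_valid < 2:
        raise ValueError("velocity series requires >= 2 valid samples")
    both = trial.valid[:-1] & trial.valid[1:]
    dx = np.diff(trial.x)[both]
    dy = np.diff(trial.y)[both]
    return np.hypot(dx, dy)


def velocity_to_deg(
    v,
    screen_width_cm: float = SCREEN_WIDTH_CM,
    distance_cm: float = VIEWING_DISTANCE_CM,
) -> float | np.ndarray:
    """Convert normalized-length-per-second velocity to deg/s visual angle.

    Uses ``2 * arctan(v * screen_width / (2 * distance))`` with the default
    geometry of a 24.98 cm wide screen viewed from 50 cm.  Monotone
    increasing and concave in ``v``.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0):
        raise ValueError("velocity must be non-negative")
    out = np.degrees(2.0 * np.arctan(arr * screen_width_cm / (2.0 * distance_cm)))
    if np.isscalar(v) or arr.ndim == 0:
        return float(out)
    return out
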