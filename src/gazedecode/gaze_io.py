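"""Trial-structured gaze recording I/O.

Canonical on-disk form is a long-format UTF-8 CSV with header
``participant_id,image_id,group,t_ms,x,y,valid`` — one row per gaze sample.
Coordinates are normalized screen units with origin at the top-left corner
and y increasing downward: x in [0, 1], y in [0, 0.74] (a 1.0 x 0.74 screen
rectangle).  Timestamps are milliseconds and must increase strictly within a
trial.

Out-of-range samples are flagged invalid on load, never dropped silently;
downstream stages skip invalid samples explicitly.  ``read_trials`` accepts
an ``adapter`` callable so recordings in a foreign layout can be mapped into
this schema without subclassing the loader.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SCREEN_WIDTH", "SCREEN_HEIGHT", "GazeSample", "Trial",
    "SchemaError", "DataError", "read_trials", "write_trials",
]

logger = logging.getLogger(__name__)

#: Normalized screen rectangle: width 1.0, height 0.74.
SCREEN_WIDTH = 1.0
SCREEN_HEIGHT = 0.74

REQUIRED_COLUMNS = ("participant_id", "image_id", "group", "t_ms", "x", "y")


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class DataError(ValueError):
    """Sample-level corruption, e.g. non-monotone timestamps within a trial."""


@dataclass(frozen=True)
class GazeSample:
    """One gaze sample: time (ms), normalized position, validity flag."""

    t: float
    x: float
    y: float
    valid: bool = True


@dataclass
class Trial:
    """One participant x image recording.

    Samples are stored as parallel numpy arrays in recording order;
    ``group`` is a free-form label ("A"/"B", "major"/"non_major", or
    "unknown").
    """

    participant_id: str
    image_id: str
    group: str
    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t_ms.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t_ms.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("sample arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.t_ms) > 0):
            raise DataError(
                f"non-monotone timestamps in trial "
                f"({self.participant_id}, {self.image_id})"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.participant_id, self.image_id)

    @property
    def n_samples(self) -> int:
        return int(self.t_ms.size)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def samples(self) -> list[GazeSample]:
        """Materialize the trace as a list of :class:`GazeSample`."""
        return [
            GazeSample(float(t), float(x), float(y), bool(v))
            for t, x, y, v in zip(self.t_ms, self.x, self.y, self.valid)
        ]

    def copy(self) -> "Trial":
        return replace(
            self,
            t_ms=self.t_ms.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            valid=self.valid.copy(),
        )


def _in_screen(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return (x >= 0.0) & (x <= SCREEN_WIDTH) & (y >= 0.0) & (y <= SCREEN_HEIGHT)


def read_trials(path, adapter=None) -> list[Trial]:
    """Load a trial CSV into a list of :class:`Trial`.

    Parameters
    ----------
    path
        CSV file (or open text buffer) in the canonical schema.
    adapter
        Optional ``DataFrame -> DataFrame`` hook applied before validation,
        for mapping a foreign recording layout onto the canonical columns.

    Rows with coordinates outside the screen rectangle are kept but flagged
    invalid.  Sample order within a trial is the file order; trials are
    returned sorted by (participant_id, image_id).

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    DataError
        If timestamps within some trial are not strictly increasing.
    """
    frame = pd.read_csv(
        path,
        dtype={"participant_id": str, "image_id": str},
        float_precision="round_trip",
    )
    if adapter is not None:
        frame = adapter(frame)
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if "valid" not in frame.columns:
        frame = frame.assign(valid=True)

    trials: list[Trial] = []
    n_invalid = 0
    for (pid, img), sub in frame.groupby(
        ["participant_id", "image_id"], sort=True
    ):
        x = sub["x"].to_numpy(dtype=float)
        y = sub["y"].to_numpy(dtype=float)
        valid = sub["valid"].to_numpy(dtype=bool) & _in_screen(x, y)
        n_invalid += int((~valid).sum())
        group = str(sub["group"].iloc[0])
        trials.append(
            Trial(
                participant_id=str(pid),
                image_id=str(img),
                group=group,
                t_ms=sub["t_ms"].to_numpy(dtype=float),
                x=x,
                y=y,
                valid=valid,
            )
        )
    logger.info(
        "loaded %d trials, %d samples (%d flagged invalid)",
        len(trials), len(frame), n_invalid,
    )
    return trials


def _to_frame(trials: list[Trial]) -> pd.DataFrame:
    parts = []
    for trial in sorted(trials, key=lambda tr: tr.key):
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": trial.participant_id,
                    "image_id": trial.image_id,
                    "group": trial.group,
                    "t_ms": trial.t_ms,
                    "x": trial.x,
                    "y": trial.y,
                    "valid": trial.valid,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_trials(trials: list[Trial], path) -> None:
    """Write trials to CSV deterministically (sorted by participant, image;
    samples in recording order).  ``read_trials(write_trials(d)) == d``.
    """
    if not trials:
        raise ValueError("refusing to write an empty dataset")
    frame = _to_frame(trials)
    # %.17g round-trips IEEE doubles exactly
    if isinstance(path, io.TextIOBase):
        frame.to_csv(path, index=False, float_format="%.17g")
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            frame.to_csv(fh, index=False, float_format="%.17g")


def trials_equal(a: Trial, b: Trial) -> bool:
    """Field-exact equality of two trials (used by round-trip tests)."""
    return (
        a.participant_id == b.participant_id
        and a.image_id == b.image_id
        and a.group == b.group
        and np.array_equal(a.t_ms, b.t_ms)
        and np.array_equal(a.x, b.x)
        and np.array_equal(a.y, b.y)
        and np.array_equal(a.valid, b.valid)
    )
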