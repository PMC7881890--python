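"""Synthetic gaze cohorts with individual kinematics and group ROI bias.

The generator emulates the structure of a screen-viewing study — a cohort of
participants in two groups (A/B), each viewing every image for a fixed
duration at 60 Hz in normalized screen coordinates — so the full event
detection / feature / decoding pipeline can be exercised without recorded
data.

Model.  A trace alternates fixation and saccade epochs:

* fixation: gaze sits on a target point drawn inside a region of interest
  (ROI), with isotropic Gaussian tremor of sd ``tremor_sd``; each frame
  repeats the previous position exactly with probability
  ``zero_velocity_rate`` (populating the zero-velocity histogram bin);
  epoch length is gamma-distributed (``fixation_duration_params``, seconds);
* saccade: the gaze glides linearly to the next ROI-weighted target; the
  per-frame step length is drawn from a lognormal law
  (``saccade_amplitude_params``), so an individual's velocity histogram
  carries their kinematic signature.

Group membership only enters through ROI choice: each ROI carries one
sampling weight per group, so groups with disjoint weight support fixate
disjoint regions.  Positions are clipped to the 1.0 x 0.74 screen.

These distributional families are standard choices for gaze kinematics and
give the downstream histogram features non-degenerate shape; they are
simulation assumptions, not estimates from any recorded dataset.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np

from .gaze_io import SCREEN_HEIGHT, SCREEN_WIDTH, Trial

__all__ = [
    "IndividualProfile", "Roi", "RoiLayout", "make_cohort",
    "make_separated_cohort", "default_layouts", "simulate_trial",
    "simulate_dataset",
]


@dataclass(frozen=True)
class IndividualProfile:
    """Endogenous parameters of one simulated viewer.

    fixation_duration_params : (shape, scale) of the gamma law for fixation
        epoch durations, seconds.
    saccade_amplitude_params : (log-mean, log-sd) of the lognormal law for
        per-frame saccade step length, normalized units.
    tremor_sd : within-fixation positional jitter sd, normalized units.
    zero_velocity_rate : probability a within-fixation frame repeats the
        previous position exactly.
    """

    participant_id: str
    group: str
    fixation_duration_params: tuple[float, float]
    saccade_amplitude_params: tuple[float, float]
    tremor_sd: float
    zero_velocity_rate: float

    def __post_init__(self) -> None:
        shape, scale = self.fixation_duration_params
        _, log_sd = self.saccade_amplitude_params
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma parameters must be strictly positive")
        if log_sd <= 0:
            raise ValueError("lognormal log-sd must be strictly positive")
        if self.tremor_sd < 0:
            raise ValueError("tremor_sd must be non-negative")
        if not 0.0 <= self.zero_velocity_rate <= 1.0:
            raise ValueError("zero_velocity_rate must lie in [0, 1]")
        if self.group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")


@dataclass(frozen=True)
class Roi:
    """Axis-aligned region of interest with per-group sampling weights."""

    rect: tuple[float, float, float, float]  # (x0, y0, x1, y1), normalized
    weight_a: float
    weight_b: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (0 <= x0 < x1 <= SCREEN_WIDTH and 0 <= y0 < y1 <= SCREEN_HEIGHT):
            raise ValueError(f"ROI rect {self.rect} outside screen rectangle")
        if self.weight_a < 0 or self.weight_b < 0:
            raise ValueError("ROI weights must be non-negative")


@dataclass(frozen=True)
class RoiLayout:
    """ROI set of one image; per-group weights must sum to 1 over ROIs."""

    image_id: str
    rois: tuple[Roi, ...]

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("RoiLayout requires at least one ROI")
        for attr in ("weight_a", "weight_b"):
            total = sum(getattr(r, attr) for r in self.rois)
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"{attr} must sum to 1 over ROIs, got {total}")

    def weights(self, group: str) -> np.ndarray:
        if group == "A":
            return np.array([r.weight_a for r in self.rois])
        if group == "B":
            return np.array([r.weight_b for r in self.rois])
        raise ValueError(f"unknown group {group!r}")


# Hyper-distributions for cohort sampling.  Ranges chosen to yield typical
# scene-viewing kinematics: mean fixation durations 0.15-0.35 s, saccade
# per-frame steps ~0.05-0.2 normalized units, tremor well under the 0.02
# dispersion threshold.
_HYPER = {
    "gamma_shape": (2.0, 5.0),
    "mean_fix_duration": (0.15, 0.35),
    "log_mean": (-3.0, -1.6),
    "log_sd": (0.3, 0.6),
    "tremor_sd": (0.001, 0.004),
    "zero_velocity_rate": (0.05, 0.4),
}


def _draw_profile(pid: str, group: str, rng: np.random.Generator) -> IndividualProfile:
    u = {k: rng.uniform(*bounds) for k, bounds in _HYPER.items()}
    shape = u["gamma_shape"]
    scale = u["mean_fix_duration"] / shape
    return IndividualProfile(
        participant_id=pid,
        group=group,
        fixation_duration_params=(shape, scale),
        saccade_amplitude_params=(u["log_mean"], u["log_sd"]),
        tremor_sd=u["tremor_sd"],
        zero_velocity_rate=u["zero_velocity_rate"],
    )


def make_cohort(n_a: int, n_b: int, seed: int) -> list[IndividualProfile]:
    """Draw ``n_a`` group-A and ``n_b`` group-B viewer profiles.

    Per-individual parameters are drawn independently from the documented
    hyper-distributions; the same seed reproduces the cohort exactly.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("both group counts must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = [_draw_profile(f"A{i + 1:03d}", "A", rng) for i in range(n_a)]
    cohort += [_draw_profile(f"B{i + 1:03d}", "B", rng) for i in range(n_b)]
    return cohort


def make_separated_cohort(
    n_a: int,
    n_b: int,
    seed: int,
    log_mean_spacing: float = 0.5,
    log_mean_start: float = -4.0,
) -> list[IndividualProfile]:
    """Cohort whose saccade log-means are evenly spaced on a grid.

    Random hyper-draws give no guarantee on pairwise kinematic separation;
    this variant assigns log-means ``start, start + spacing, ...`` across
    the cohort so every pair is separated by at least ``log_mean_spacing``.
    The remaining parameters are drawn as in :func:`make_cohort`.
    """
    cohort = make_cohort(n_a, n_b, seed)
    out = []
    for i, prof in enumerate(cohort):
        _, log_sd = prof.saccade_amplitude_params
        out.append(
            IndividualProfile(
                participant_id=prof.participant_id,
                group=prof.group,
                fixation_duration_params=prof.fixation_duration_params,
                saccade_amplitude_params=(
                    log_mean_start + i * log_mean_spacing, log_sd
                ),
                tremor_sd=prof.tremor_sd,
                zero_velocity_rate=prof.zero_velocity_rate,
            )
        )
    return out


def default_layouts(
    n_images: int, seed: int = 0, disjoint: bool = False
) -> list[RoiLayout]:
    """Generate ``n_images`` four-ROI layouts.

    With ``disjoint=True`` group A samples only the first two ROIs and
    group B only the last two (disjoint weight support); otherwise both
    groups use all four ROIs with opposite preference (0.35/0.35/0.15/0.15
    vs 0.15/0.15/0.35/0.35).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    layouts = []
    if disjoint:
        wa = (0.5, 0.5, 0.0, 0.0)
        wb = (0.0, 0.0, 0.5, 0.5)
    else:
        wa = (0.35, 0.35, 0.15, 0.15)
        wb = (0.15, 0.15, 0.35, 0.35)
    for img in range(n_images):
        rois = []
        # one ROI per screen quadrant, jittered position, fixed small size
        for q, (cx, cy) in enumerate(
            [(0.25, 0.185), (0.75, 0.185), (0.25, 0.555), (0.75, 0.555)]
        ):
            w = rng.uniform(0.12, 0.2)
            h = rng.uniform(0.08, 0.14)
            jx = rng.uniform(-0.04, 0.04)
            jy = rng.uniform(-0.03, 0.03)
            x0 = float(np.clip(cx + jx - w / 2, 0, SCREEN_WIDTH - w))
            y0 = float(np.clip(cy + jy - h / 2, 0, SCREEN_HEIGHT - h))
            rois.append(
                Roi(rect=(x0, y0, x0 + w, y0 + h),
                    weight_a=wa[q], weight_b=wb[q])
            )
        layouts.append(RoiLayout(image_id=f"img{img + 1:02d}", rois=tuple(rois)))
    return layouts


def _roi_target(
    layout: RoiLayout, group: str, rng: np.random.Generator
) -> np.ndarray:
    weights = layout.weights(group)
    idx = rng.choice(len(layout.rois), p=weights / weights.sum())
    x0, y0, x1, y1 = layout.rois[idx].rect
    return np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, [0.0, 0.0], [SCREEN_WIDTH, SCREEN_HEIGHT])


def simulate_trial(
    profile: IndividualProfile,
    layout: RoiLayout,
    duration_s: float = 10.0,
    rate_hz: float = 60.0,
    seed: int = 0,
    dropout_p: float = 0.0,
    with_epochs: bool = False,
) -> Trial | tuple[Trial, np.ndarray]:
    """Simulate one viewing of ``layout`` by ``profile``.

    Returns ``floor(duration_s * rate_hz)`` samples alternating fixation
    and saccade epochs (see module docstring).  ``dropout_p`` optionally
    marks random samples invalid to exercise I/O validation; it does not
    alter the generated positions.  With ``with_epochs`` the ground-truth
    per-sample epoch labels ("F"/"S") are returned alongside the trial.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration_s and rate_hz must be positive")
    n = int(math.floor(duration_s * rate_hz))
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / rate_hz
    shape, scale = profile.fixation_duration_params
    log_mean, log_sd = profile.saccade_amplitude_params

    xs = np.empty(n)
    ys = np.empty(n)
    epochs = np.empty(n, dtype="<U1")
    i = 0
    target = _roi_target(layout, profile.group, rng)
    prev = _clip(target.copy())
    while i < n:
        # fixation epoch
        m = max(1, round(rng.gamma(shape, scale) * rate_hz))
        for _ in range(m):
            if i > 0 and rng.random() < profile.zero_velocity_rate:
                pos = prev
            else:
                pos = _clip(target + rng.normal(0.0, profile.tremor_sd, 2))
            xs[i], ys[i] = pos
            epochs[i] = "F"
            prev = pos
            i += 1
            if i == n:
                break
        if i == n:
            break
        # saccade epoch: straight glide toward the next target with a fresh
        # lognormal step length per frame (ties in the velocity series
        # would defeat equal-frequency binning)
        target = _roi_target(layout, profile.group, rng)
        while i < n:
            vec = target - prev
            dist = float(np.linalg.norm(vec))
            step = rng.lognormal(log_mean, log_sd)
            if step >= dist or dist == 0.0:
                pos = target.copy()  # arrival frame
            else:
                pos = _clip(prev + vec * (step / dist))
            xs[i], ys[i] = pos
            epochs[i] = "S"
            prev = pos
            i += 1
            if dist == 0.0 or step >= dist:
                break

    valid = np.ones(n, dtype=bool)
    if dropout_p > 0:
        valid &= rng.random(n) >= dropout_p
    trial = Trial(
        participant_id=profile.participant_id,
        image_id=layout.image_id,
        group=profile.group,
        t_ms=np.arange(n) * dt_ms,
        x=xs,
        y=ys,
        valid=valid,
    )
    if with_epochs:
        return trial, epochs
    return trial


def _trial_seed(seed: int, participant_id: str, image_id: str) -> int:
    """Stable per-trial seed below 2**31 from (seed, participant, image)."""
    digest = hashlib.sha256(
        f"{seed}|{participant_id}|{image_id}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_dataset(
    cohort: list[IndividualProfile],
    layouts: list[RoiLayout],
    duration_s: float = 10.0,
    rate_hz: float = 60.0,
    seed: int = 0,
    dropout_p: float = 0.0,
) -> list[Trial]:
    """One trial per (profile, layout) pair; reproducible per-trial seeds.

    Trial seeds are hashed from (seed, participant_id, image_id), so any
    subset of the design regenerates identically.
    """
    if not layouts:
        raise ValueError("at least one layout is required")
    return [
        simulate_trial(
            prof, lay, duration_s, rate_hz,
            seed=_trial_seed(seed, prof.participant_id, lay.image_id),
            dropout_p=dropout_p,
        )
        for prof in cohort
        for lay in layouts
    ]
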