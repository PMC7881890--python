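import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazedecode as gz
from conftest import random_walk_trial
from idt_reference import brute_force_diameter, idt_reference


def trial_from_xy(x, y, rate_hz=60.0, valid=None):
    n = len(x)
    return gz.Trial(
        participant_id="P1", image_id="I1", group="unknown",
        t_ms=np.arange(n) * (1000.0 / rate_hz),
        x=np.asarray(x, float), y=np.asarray(y, float), valid=valid,
    )


class TestDispersion:
    def test_single_point_zero(self):
        assert gz.dispersion([(0.3, 0.3)]) == 0.0

    def test_two_point_diameter(self):
        assert gz.dispersion([(0, 0), (0.01, 0)]) == pytest.approx(0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gz.dispersion([])

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(25):
            pts = rng.uniform(0, 0.74, size=(50, 2))
            assert gz.dispersion(pts) == pytest.approx(
                brute_force_diameter(pts)
            )

    def test_range_metric_is_sum_of_extents(self):
        pts = [(0.0, 0.0), (0.02, 0.01), (0.01, 0.03)]
        assert gz.dispersion(pts, metric="range") == pytest.approx(0.05)

    def test_range_metric_bounds_diameter(self, rng):
        pts = rng.uniform(0, 0.5, size=(30, 2))
        assert gz.dispersion(pts, "range") >= gz.dispersion(pts, "diameter")


class TestIdtDetection:
    def test_constant_trace_single_fixation(self):
        trial = trial_from_xy(np.full(600, 0.5), np.full(600, 0.3))
        seq = gz.detect_fixations_idt(trial)
        assert len(seq.fixations) == 1
        assert len(seq.saccades) == 0
        fx = seq.fixations[0]
        assert fx.dispersion == 0.0
        assert fx.duration == pytest.approx(599 / 60)
        assert fx.centroid == pytest.approx((0.5, 0.3))

    def test_two_clusters_one_saccade(self):
        x = np.concatenate([
            np.full(30, 0.3),
            np.linspace(0.3, 0.5, 7)[1:-1],  # 5 transition samples
            np.full(30, 0.5),
        ])
        trial = trial_from_xy(x, np.full_like(x, 0.3))
        seq = gz.detect_fixations_idt(trial)
        assert len(seq.fixations) == 2
        assert len(seq.saccades) == 1
        sac = seq.saccades[0]
        assert sac.path_length >= 0.2 - 1e-12

    def test_short_trial_warns_and_returns_empty(self):
        trial = trial_from_xy([0.5, 0.5], [0.3, 0.3])
        with pytest.warns(UserWarning):
            seq = gz.detect_fixations_idt(trial, min_samples=3)
        assert seq.fixations == [] and seq.saccades == []

    @pytest.mark.parametrize("max_duration", [None, 0.1])
    def test_matches_exhaustive_reference_on_random_walks(
        self, rng, max_duration
    ):
        """Greedy detector output identical to the brute-force oracle on
        200 random short traces."""
        for k in range(200):
            n = int(rng.integers(3, 41))
            trial = random_walk_trial(rng, n)
            seq = gz.detect_fixations_idt(trial, max_duration=max_duration)
            got = [(f.start_index, f.end_index) for f in seq.fixations]
            want = idt_reference(
                trial.x, trial.y, trial.t_ms / 1000.0,
                threshold=0.02, min_samples=3, max_duration=max_duration,
            )
            assert got == want, f"trace {k} (n={n})"

    def test_partition_and_conservation(self, small_dataset):
        """Every valid sample is covered; fixation + saccade time equals
        the valid-sample span."""
        for trial in small_dataset[:8]:
            seq = gz.detect_fixations_idt(trial)
            covered = np.zeros(trial.n_samples, dtype=bool)
            for f in seq.fixations:
                covered[f.start_index : f.end_index + 1] = True
            for s in seq.saccades:
                covered[s.start_index : s.end_index + 1] = True
            assert covered[trial.valid].all()
            span = (trial.t_ms[trial.valid][-1] - trial.t_ms[trial.valid][0])
            assert seq.total_fixation_time + seq.total_saccade_time == \
                pytest.approx(span / 1000.0)

    def test_saccades_interleave_fixations(self, small_dataset):
        seq = gz.detect_fixations_idt(small_dataset[0])
        assert len(seq.fixations) >= 2
        starts = [f.start_index for f in seq.fixations]
        assert starts == sorted(starts)
        inner = [
            s for s in seq.saccades
            if s.start_index >= seq.fixations[0].end_index
            and s.end_index <= seq.fixations[-1].start_index
        ]
        assert len(inner) == len(seq.fixations) - 1

    def test_lower_threshold_never_lengthens_fixations(self, rng):
        trial = random_walk_trial(rng, 300, step_sd=0.004)
        hi = gz.detect_fixations_idt(trial, dispersion_threshold=0.02)
        lo = gz.detect_fixations_idt(trial, dispersion_threshold=0.01)
        hi_at = {f.start_index: f.duration for f in hi.fixations}
        for f in lo.fixations:
            if f.start_index in hi_at:
                assert f.duration <= hi_at[f.start_index] + 1e-12

    def test_invalid_samples_are_skipped(self):
        # a wild excursion that is marked invalid must not split or
        # contaminate the fixation
        x = np.full(60, 0.5)
        x[10:20] = 0.9
        valid = np.ones(60, bool)
        valid[10:20] = False
        trial = trial_from_xy(x, np.full(60, 0.3), valid=valid)
        seq = gz.detect_fixations_idt(trial)
        assert len(seq.fixations) == 1
        assert seq.fixations[0].dispersion == 0.0
        assert seq.fixations[0].centroid[0] == pytest.approx(0.5)


class TestVelocitySeries:
    def test_constant_trace_all_zeros(self):
        trial = trial_from_xy(np.full(10, 0.5), np.full(10, 0.3))
        v = gz.velocity_series(trial)
        assert v.shape == (9,)
        assert np.all(v == 0.0)

    def test_three_four_five(self):
        trial = trial_from_xy([0.0, 0.3], [0.0, 0.4])
        assert gz.velocity_series(trial) == pytest.approx([0.5])

    def test_steps_spanning_invalid_omitted(self):
        valid = np.array([True, True, False, True, True])
        trial = trial_from_xy(
            [0.1, 0.2, 0.9, 0.3, 0.4], [0.3] * 5, valid=valid
        )
        v = gz.velocity_series(trial)
        assert v == pytest.approx([0.1, 0.1])

    def test_requires_two_valid_samples(self):
        trial = trial_from_xy([0.5, 0.5], [0.3, 0.3],
                              valid=np.array([True, False]))
        with pytest.raises(ValueError):
            gz.velocity_series(trial)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_path_dominates_displacement(self, seed):
        rng = np.random.default_rng(seed)
        trial = random_walk_trial(rng, 50)
        total = gz.velocity_series(trial).sum()
        straight = math.hypot(
            trial.x[-1] - trial.x[0], trial.y[-1] - trial.y[0]
        )
        assert total >= straight - 1e-12


class TestVelocityToDeg:
    def test_zero_maps_to_zero(self):
        assert gz.velocity_to_deg(0.0) == 0.0

    def test_closed_form_full_screen_width(self):
        # one screen width per second with a 24.98 cm screen at 50 cm
        expected = math.degrees(2 * math.atan(24.98 / 100.0))
        assert gz.velocity_to_deg(1.0) == pytest.approx(expected)
        assert gz.velocity_to_deg(1.0) == pytest.approx(28.05, abs=0.01)

    def test_concave_monotone(self):
        v = np.linspace(0.1, 5, 25)
        out = gz.velocity_to_deg(v)
        assert np.all(np.diff(out) > 0)
        assert np.all(gz.velocity_to_deg(2 * v) < 2 * out)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gz.velocity_to_deg(-0.1)
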