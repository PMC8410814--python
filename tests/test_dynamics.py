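"""Contact-stability and trajectory metrics against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodeglia.dynamics import (
    ContactTimeSeries,
    TrackedTip,
    contact_timecourse_from_masks,
    instantaneous_velocities,
    longest_run,
    motility_summary,
    percent_frames_with_contact,
    relative_trajectory,
    split_series,
    step_distances,
)
from nodeglia.synthetic_microscopy import (
    CHANNEL_MICROGLIA,
    generate_scene,
    simulate_contact_series,
)


def brute_force_longest_run(bits, state):
    """Enumerate all runs directly."""
    best = 0
    for val, grp in itertools.groupby(bits):
        if val == state:
            best = max(best, len(list(grp)))
    return best


def series(bits):
    return ContactTimeSeries(np.array(bits, dtype=bool), frame_interval=30.0)


class TestContactSeries:
    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            ContactTimeSeries(np.array([True]), 30.0)

    def test_percent_all_and_half(self):
        assert percent_frames_with_contact(series([1, 1, 1, 1])) == 100.0
        assert percent_frames_with_contact(series([1, 0, 1, 0])) == 50.0

    def test_percent_invariant_to_frame_interval(self):
        bits = [1, 0, 1, 1]
        a = ContactTimeSeries(np.array(bits, bool), 30.0)
        b = ContactTimeSeries(np.array(bits, bool), 600.0)
        assert percent_frames_with_contact(a) == percent_frames_with_contact(b)

    def test_bernoulli_expectation(self):
        """i.i.d. Bernoulli(0.8) of length 21: mean percent ~ 80."""
        rng = np.random.default_rng(8)
        vals = [
            percent_frames_with_contact(
                ContactTimeSeries(rng.random(21) < 0.8, 30.0)
            )
            for _ in range(10_000)
        ]
        assert np.mean(vals) == pytest.approx(80.0, abs=0.5)


class TestLongestRun:
    def test_examples(self):
        assert longest_run(series([1, 1, 0, 1, 1, 1]), True) == 3
        assert longest_run(series([0, 0, 0]), True) == 0
        assert longest_run(series([0, 0, 0]), False) == 3

    def test_exhaustive_up_to_length_12(self):
        for n in range(2, 13):
            for bits in itertools.product([False, True], repeat=n):
                s = series(bits)
                for state in (True, False):
                    assert longest_run(s, state) == brute_force_longest_run(bits, state)

    def test_random_long_series_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            bits = (rng.random(rng.integers(13, 200)) < rng.random()).tolist()
            s = series(bits)
            for state in (True, False):
                assert longest_run(s, state) == brute_force_longest_run(bits, state)

    def test_geometric_mean_run_when_only_detaching(self):
        """Start attached, detach prob q, no re-attach: mean longest True
        run is the mean of a geometric distribution, 1/q."""
        q = 0.1
        s = simulate_contact_series(
            10_000, 200, attach=0.0, detach=q, seed=10, initial=True
        )
        runs = [
            longest_run(ContactTimeSeries(row, 30.0), True) for row in s
        ]
        # truncation at 200 frames biases the mean down by < 1%
        assert np.mean(runs) == pytest.approx(1.0 / q, rel=0.05)


class TestTrajectories:
    def test_relative_trajectory_example(self):
        tip = TrackedTip(np.array([[5.0, 5.0], [8.0, 9.0]]))
        rel = relative_trajectory(tip)
        assert np.array_equal(rel, [[0, 0], [3, 4]])

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(10, 2))
        a = relative_trajectory(TrackedTip(coords))
        b = relative_trajectory(TrackedTip(coords + [17.0, -4.0]))
        assert np.allclose(a, b)

    def test_three_four_five(self):
        tip = TrackedTip(np.array([[0.0, 0.0], [3.0, 4.0]]), voxel_size_xy=1.0)
        assert step_distances(tip) == pytest.approx([5.0])

    def test_stationary_all_zero(self):
        tip = TrackedTip(np.zeros((6, 2)))
        s = motility_summary(tip)
        assert all(v == 0.0 for v in s.values())

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=2,
            max_size=30,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_triangle_inequality(self, points):
        tip = TrackedTip(np.array(points, dtype=float))
        total = step_distances(tip).sum()
        direct = np.linalg.norm(tip.coords[-1] - tip.coords[0])
        assert total >= direct - 1e-9

    def test_velocity_units(self):
        """1 µm per 30-s frame is 2 µm/min; velocity scales with voxel
        size and inversely with frame interval."""
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        tip = TrackedTip(coords, voxel_size_xy=1.0, frame_interval=30.0)
        assert np.allclose(instantaneous_velocities(tip), 2.0)
        half_px = TrackedTip(coords, voxel_size_xy=0.5, frame_interval=30.0)
        slow = TrackedTip(coords, voxel_size_xy=1.0, frame_interval=60.0)
        assert np.allclose(
            instantaneous_velocities(half_px),
            0.5 * instantaneous_velocities(tip),
        )
        assert np.allclose(
            instantaneous_velocities(slow), 0.5 * instantaneous_velocities(tip)
        )

    def test_free_vs_confined_contrast(self):
        """Mean distance from origin is larger for free tips (>= 100 each)."""
        from nodeglia.synthetic_microscopy import simulate_random_walks

        free = simulate_random_walks(150, 21, sigma=1.5, seed=12)
        conf = simulate_random_walks(150, 21, sigma=1.5, kappa=0.5, seed=13)

        def mean_origin_dist(tracks):
            out = []
            for tr in tracks:
                tip = TrackedTip(tr, voxel_size_xy=1.0, frame_interval=30.0)
                out.append(motility_summary(tip)["mean_distance_from_origin_um"])
            return np.mean(out)

        assert mean_origin_dist(free) > mean_origin_dist(conf)


class TestSplitSeries:
    def test_gap_splits(self):
        frames = np.array([0, 1, 2, 5, 6, 7, 8])
        states = np.array([1, 1, 0, 1, 1, 1, 0], dtype=bool)
        parts = split_series(frames, states, 30.0)
        assert [len(p) for p in parts] == [3, 4]
        assert longest_run(parts[1], True) == 3

    def test_singleton_segments_dropped(self):
        parts = split_series(np.array([0, 2, 3]), np.array([1, 1, 0], bool), 30.0)
        assert [len(p) for p in parts] == [2]


class TestTimecourseFromMasks:
    def test_all_zero_microglia(self):
        movie = np.zeros((4, 8, 8), dtype=bool)
        node = np.zeros((8, 8), dtype=bool)
        node[4, 4] = True
        s = contact_timecourse_from_masks(movie, node, frame_interval=30.0)
        assert not s.frames.any()

    def test_recovers_planted_markov_contacts(self, high_snr_movie):
        """Clean-mask timecourse equals ground truth on >= 95% of frames."""
        from nodeglia.masks import binarize_movie

        scene, truth, stacks = high_snr_movie
        movie = binarize_movie(stacks[CHANNEL_MICROGLIA].data)
        agree = []
        for nd in scene.nodes:
            node_mask = np.zeros(scene.shape, dtype=bool)
            yy, xx = np.mgrid[: scene.shape[0], : scene.shape[1]]
            node_mask[
                np.hypot(yy - nd.center[0], xx - nd.center[1]) <= nd.radius + 0.5
            ] = True
            s = contact_timecourse_from_masks(movie, node_mask, frame_interval=30.0)
            agree.append((s.frames == truth.contact_state[nd.id]).mean())
        assert np.mean(agree) >= 0.95
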