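import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multipeak import (
    PeakField,
    ScalarField,
    TrackingConfig,
    evolve_direction,
    propagate_half,
    select_initial_direction,
    select_peak,
    theta_from_radius,
    track_all,
    track_seed,
)
from tests.conftest import build_uniform_field


# ---------------------------------------------------------------- theta


@pytest.mark.parametrize(
    "s,R,expected",
    [(1.0, 1.0, 60.0), (0.3, 0.3, 60.0), (3.0, 0.3, 90.0), (1.0, 100.0, math.degrees(2 * math.asin(0.005)))],
)
def test_theta_from_radius(s, R, expected):
    assert theta_from_radius(s, R) == pytest.approx(expected, abs=1e-12)


def test_theta_rejects_nonpositive():
    with pytest.raises(ValueError):
        theta_from_radius(0.0, 1.0)
    with pytest.raises(ValueError):
        theta_from_radius(1.0, -1.0)


# ------------------------------------------------- initial direction


def test_single_peak_always_chosen():
    rng = np.random.default_rng(0)
    for _ in range(5):
        v = select_initial_direction([np.array([2.0, 0, 0])], rng)
        np.testing.assert_allclose(v, (1, 0, 0))


@pytest.mark.parametrize(
    "peaks,p_first",
    [
        ([(1.0, 0, 0), (0, 1.0, 0)], 0.5),
        ([(3.0, 0, 0), (0, 1.0, 0)], 0.75),
    ],
)
def test_initial_direction_is_norm_weighted(peaks, p_first):
    """Empirical pick frequency matches the norm-proportional law."""
    rng = np.random.default_rng(42)
    peaks = [np.array(p) for p in peaks]
    n = 10_000
    hits = sum(
        1 for _ in range(n) if select_initial_direction(peaks, rng)[0] > 0.5
    )
    assert hits / n == pytest.approx(p_first, abs=0.02)


def test_initial_direction_empty_list_raises():
    with pytest.raises(ValueError):
        select_initial_direction([], np.random.default_rng(0))


# ------------------------------------------------------- select_peak


class TestSelectPeak:
    def test_aligned_peak_wins(self):
        peaks = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0])]
        np.testing.assert_allclose(select_peak(peaks, np.array([1.0, 0, 0])), (1, 0, 0))

    def test_sign_flip_to_incoming_hemisphere(self):
        got = select_peak([np.array([1.0, 0, 0])], np.array([-1.0, 0, 0]))
        np.testing.assert_allclose(got, (-1, 0, 0))

    def test_smallest_angle_among_candidates(self):
        diag = np.array([1.0, 1.0, 0]) / math.sqrt(2)
        got = select_peak([np.array([1.0, 0, 0]), diag], np.array([0, 1.0, 0]))
        np.testing.assert_allclose(got, diag)

    def test_empty_returns_none(self):
        assert select_peak([], np.array([1.0, 0, 0])) is None

    def test_tie_broken_by_storage_index(self):
        a, b = np.array([1.0, 1.0, 0]), np.array([1.0, -1.0, 0])
        got = select_peak([a, b], np.array([1.0, 0, 0]))
        np.testing.assert_allclose(got, a / np.linalg.norm(a))

    def test_magnitude_does_not_bias_selection(self):
        peaks = [np.array([0, 100.0, 0]), np.array([1.0, 0.1, 0])]
        got = select_peak(peaks, np.array([1.0, 0, 0]))
        assert got[0] > 0.9


# -------------------------------------------------- evolve_direction


class TestEvolveDirection:
    @pytest.mark.parametrize("g", [0.0, 0.3, 1.0])
    def test_f_one_returns_peak(self, g):
        v_in = np.array([1.0, 0, 0])
        v_peak = np.array([0, 1.0, 0])
        np.testing.assert_allclose(
            evolve_direction(v_in, v_peak, 1.0, g), v_peak, atol=1e-12
        )

    def test_f_zero_g_zero_returns_incoming(self):
        v_in = np.array([1.0, 0, 0])
        v_peak = np.array([0, 1.0, 0])
        np.testing.assert_allclose(
            evolve_direction(v_in, v_peak, 0.0, 0.0), v_in, atol=1e-12
        )

    def test_f_zero_g_one_returns_peak(self):
        v_in = np.array([1.0, 0, 0])
        v_peak = np.array([0, 1.0, 0])
        np.testing.assert_allclose(
            evolve_direction(v_in, v_peak, 0.0, 1.0), v_peak, atol=1e-12
        )

    def test_blend_coefficients(self):
        got = evolve_direction(
            np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), 0.5, 0.2
        )
        np.testing.assert_allclose(got, (0.4, 0.6, 0) / np.sqrt(0.52), atol=1e-12)
        np.testing.assert_allclose(got, (0.5547, 0.8321, 0), atol=1e-4)

    @settings(derandomize=True, max_examples=200)
    @given(
        f=st.floats(0, 1),
        g=st.floats(0, 1),
        phi=st.floats(0.0, math.pi - 0.2),
    )
    def test_coefficient_expansion_and_unit_norm(self, f, g, phi):
        """f*Vn + (1-f)((1-g)V_{n-1} + g*Vn) == (f+g-fg)Vn + (1-f)(1-g)V_{n-1}."""
        v_in = np.array([1.0, 0, 0])
        v_peak = np.array([math.cos(phi), math.sin(phi), 0.0])
        got = evolve_direction(v_in, v_peak, f, g)
        raw = (f + g - f * g) * v_peak + (1 - f) * (1 - g) * v_in
        if np.linalg.norm(raw) < 1e-12:
            assert got is None
            return
        np.testing.assert_allclose(got, raw / np.linalg.norm(raw), atol=1e-12)
        assert np.linalg.norm(got) == pytest.approx(1.0, abs=1e-12)

    def test_antiparallel_cancellation_signals_stop(self):
        v_in = np.array([1.0, 0, 0])
        v_peak = np.array([-1.0, 0, 0])
        # coefficients chosen so the blend cancels: (f+g-fg) == (1-f)(1-g)
        assert evolve_direction(v_in, v_peak, 0.0, 0.5) is None


# -------------------------------------------------- propagation oracle


def reference_propagate(seed, v0, data, affine, fmap_data, cfg):
    """Naive re-implementation of one-directional propagation.

    Kept deliberately independent: plain Python loops, explicit inverse
    affine solve, exhaustive peak scan.
    """
    inv = np.linalg.inv(affine)
    n_peaks = data.shape[3] // 3
    pos = [float(x) for x in seed]
    v_prev = list(np.asarray(v0, float) / np.linalg.norm(v0))
    pts = [list(pos)]
    length = 0.0
    max_points = math.ceil(cfg.max_length / cfg.step_size) + 1

    def vox(p):
        ijk = [round(sum(inv[r][c] * p[c] for c in range(3)) + inv[r][3]) for r in range(3)]
        for a in range(3):
            if ijk[a] < 0 or ijk[a] >= data.shape[a]:
                return None
        return tuple(int(x) for x in ijk)

    while len(pts) < max_points:
        v = vox(pos)
        if v is None:
            break
        f = float(fmap_data[v])
        if f < cfg.f_threshold:
            break
        peaks = []
        for i in range(n_peaks):
            p = data[v][3 * i : 3 * i + 3]
            if math.sqrt(sum(x * x for x in p)) > 0:
                peaks.append(p)
        if not peaks:
            break
        best, best_dot = None, -1.0
        for p in peaks:
            u = p / math.sqrt(sum(x * x for x in p))
            d = sum(a * b for a, b in zip(v_prev, u))
            if abs(d) > best_dot:
                best_dot = abs(d)
                best = u if d >= 0 else [-x for x in u]
        fcl = min(max(f, 0.0), 1.0)
        blend = [
            fcl * b + (1 - fcl) * ((1 - cfg.g) * a + cfg.g * b)
            for a, b in zip(v_prev, best)
        ]
        nrm = math.sqrt(sum(x * x for x in blend))
        if nrm < 1e-12:
            break
        v_next = [x / nrm for x in blend]
        cosang = sum(a * b for a, b in zip(v_prev, v_next))
        if cosang < math.cos(math.radians(cfg.theta_max)) - 1e-12:
            break
        if length + cfg.step_size > cfg.max_length + 1e-9:
            break
        pos = [p + cfg.step_size * x for p, x in zip(pos, v_next)]
        pts.append(list(pos))
        length += cfg.step_size
        v_prev = v_next
    return np.array(pts)


class TestPropagateHalf:
    def test_uniform_field_steps_straight(self, uniform_x_field):
        field, fmap = uniform_x_field
        cfg = TrackingConfig(step_size=1.0, theta_max=35, g=0.2, max_length=100)
        pts, reason = propagate_half((3.0, 3.0, 3.0), np.array([1.0, 0, 0]), field, fmap, cfg)
        pts = np.asarray(pts)
        assert reason == "out_of_grid"
        # collinear along x, spacing exactly the step size
        assert np.allclose(pts[:, 1:], 3.0)
        np.testing.assert_allclose(np.diff(pts[:, 0]), 1.0, atol=1e-12)
        assert pts[-1, 0] > 19.5  # traversed to the grid edge

    def test_zero_map_stops_at_seed(self, uniform_x_field):
        field, fmap = uniform_x_field
        dead = ScalarField(np.zeros(fmap.shape), fmap.affine)
        cfg = TrackingConfig()
        pts, reason = propagate_half((3.0, 3.0, 3.0), np.array([1.0, 0, 0]), field, dead, cfg)
        assert len(pts) == 1 and reason == "below_threshold"

    def test_max_length_caps_path(self, uniform_x_field):
        field, fmap = uniform_x_field
        cfg = TrackingConfig(step_size=1.0, max_length=5.0)
        pts, reason = propagate_half((1.0, 3.0, 3.0), np.array([1.0, 0, 0]), field, fmap, cfg)
        assert reason == "max_length"
        assert len(pts) == 6  # 5 mm at 1 mm steps

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(data_seed=st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, data_seed):
        """Point-by-point equality with the naive reference on random fields."""
        rng = np.random.default_rng(data_seed)
        dims = (5, 5, 5)
        raw = rng.normal(size=dims + (6,))
        # randomly blank some peaks and some voxels entirely
        raw[rng.random(dims) < 0.2] = 0.0
        raw[..., 3:][rng.random(dims) < 0.4] = 0.0
        fdata = rng.random(dims)
        affine = np.diag([1.3, 1.1, 0.9, 1.0])
        field = PeakField(data=raw, affine=affine)
        fmap = ScalarField(data=fdata, affine=affine)
        cfg = TrackingConfig(
            f_threshold=0.3,
            theta_max=float(rng.uniform(20, 90)),
            step_size=float(rng.uniform(0.3, 1.0)),
            g=float(rng.uniform(0, 1)),
            max_length=float(rng.uniform(2, 8)),
        )
        seed = np.array([2.0, 2.0, 2.0])
        v0 = rng.normal(size=3)
        v0 /= np.linalg.norm(v0)
        pts, _ = propagate_half(seed, v0, field, fmap, cfg)
        ref = reference_propagate(seed, v0, raw, affine, fdata, cfg)
        assert len(pts) == len(ref)
        np.testing.assert_allclose(np.asarray(pts), ref, atol=1e-9)

    def test_prefix_monotone_in_theta_and_threshold(self, fibercup):
        """Stricter stopping can only truncate a path, never alter it."""
        seed = np.array([60.0, 100.0, 3.0])  # on bundle 2/3 crossing
        v0 = np.array([0.0, 1.0, 0.0])
        base = TrackingConfig(f_threshold=0.1, theta_max=60, step_size=3.0, g=0.75)
        loose, _ = propagate_half(seed, v0, fibercup.peaks, fibercup.fmap, base)
        for cfg in (
            TrackingConfig(f_threshold=0.1, theta_max=10, step_size=3.0, g=0.75),
            TrackingConfig(f_threshold=0.5, theta_max=60, step_size=3.0, g=0.75),
        ):
            strict, _ = propagate_half(seed, v0, fibercup.peaks, fibercup.fmap, cfg)
            assert len(strict) <= len(loose)
            np.testing.assert_allclose(
                np.asarray(strict), np.asarray(loose)[: len(strict)], atol=1e-12
            )


# ---------------------------------------------------- full streamlines


class TestTrackSeed:
    def test_bidirectional_merge_spans_bundle(self):
        field, fmap = build_uniform_field(dims=(41, 7, 7))
        cfg = TrackingConfig(step_size=1.0, min_length=0.0)
        rng = np.random.default_rng(0)
        s = track_seed((20.0, 3.0, 3.0), field, fmap, cfg, rng)
        assert s is not None
        assert s[0, 0] < 0.5 and s[-1, 0] > 39.5  # full 40 mm traverse
        np.testing.assert_allclose(np.diff(s[:, 0]), 1.0, atol=1e-12)

    def test_seed_below_threshold_returns_none(self, uniform_x_field):
        field, fmap = uniform_x_field
        dead = ScalarField(np.zeros(fmap.shape), fmap.affine)
        s = track_seed((3, 3, 3), field, dead, TrackingConfig(), np.random.default_rng(0))
        assert s is None

    def test_seed_without_peaks_returns_none(self, uniform_x_field):
        field, fmap = uniform_x_field
        s = track_seed((100, 3, 3), field, fmap, TrackingConfig(), np.random.default_rng(0))
        assert s is None

    def test_min_length_filter(self):
        field, fmap = build_uniform_field(dims=(41, 7, 7))
        cfg = TrackingConfig(step_size=1.0, min_length=100.0, max_length=300.0)
        s = track_seed((20.0, 3.0, 3.0), field, fmap, cfg, np.random.default_rng(0))
        assert s is None  # bundle is only ~40 mm long


class TestTrackAll:
    def test_count_conserved_without_filtering(self):
        field, fmap = build_uniform_field(dims=(30, 9, 9))
        seeds = np.random.default_rng(5).uniform(5, 20, size=(200, 3)) * [1, 0.3, 0.3] + [0, 2, 2]
        t = track_all(seeds, field, fmap, TrackingConfig(min_length=0.0))
        assert len(t) == 200

    def test_empty_seed_list(self, uniform_x_field):
        field, fmap = uniform_x_field
        assert len(track_all([], field, fmap, TrackingConfig())) == 0

    def test_deterministic_under_fixed_seed(self, fibercup):
        from multipeak import mask_seeds

        cfg = TrackingConfig(theta_max=90, step_size=3.0, g=0.75, rng_seed=7)
        seeds = mask_seeds(fibercup.roi_mask(), 1, np.random.default_rng(7)).points
        t1 = track_all(seeds, fibercup.peaks, fibercup.fmap, cfg)
        t2 = track_all(seeds, fibercup.peaks, fibercup.fmap, cfg)
        assert len(t1) == len(t2) > 0
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a, b)


def test_constant_field_straightness():
    """In a uniform single-peak field with f = 1 streamlines are exactly straight."""
    field, fmap = build_uniform_field(direction=(0.6, 0.8, 0.0), dims=(30, 30, 5))
    cfg = TrackingConfig(step_size=0.7, min_length=0.0)
    s = track_seed((10.0, 10.0, 2.0), field, fmap, cfg, np.random.default_rng(0))
    d = np.diff(s, axis=0)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    # every segment parallel to the first: perpendicular deviation < 1e-9 mm
    cross = np.linalg.norm(np.cross(d, d[0]), axis=1)
    assert np.all(cross * cfg.step_size < 1e-9)


def test_crossing_fidelity_straight_through(crossing_phantom):
    """Streamlines seeded in bundle A never exit through bundle B's ROIs."""
    from multipeak import classify_connections, mask_seeds

    ph = crossing_phantom
    # seed inside bundle A proper (the horizontal bundle, pair (1, 2));
    # inside the crossing both peaks are present and the initial draw is
    # a coin flip, so overlap voxels are excluded from seeding
    only_a = ph.bundle_masks[0] & ~ph.bundle_masks[1]
    mask_a = ScalarField(only_a.astype(float), ph.affine)
    seeds = mask_seeds(mask_a, 2, np.random.default_rng(3))
    cfg = TrackingConfig(f_threshold=0.1, theta_max=35, step_size=3.0, g=0.25, rng_seed=3)
    t = track_all(seeds.points, ph.peaks, ph.fmap, cfg)
    assert len(t) > 100
    labels = classify_connections(t, ph.rois, ph.affine, ph.expected_pairs)
    crossed = [pair for kind, pair in labels if pair is not None and set(pair) & {3, 4}]
    assert crossed == []
    # every single streamline traverses bundle A end to end (through the
    # crossing), exiting past both termini at x = 20 and x = 170
    for s in t:
        xs = s[:, 0]
        assert xs.min() <= 23.0 and xs.max() >= 167.0
    # and the large majority also land inside the endpoint ROI balls proper
    n_valid = sum(1 for kind, _ in labels if kind == "valid")
    assert n_valid / len(t) > 0.8
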