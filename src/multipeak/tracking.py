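"""Deterministic multi-peak streamline propagation.

The tracker walks a field of fiber-ODF maxima with a fixed step size.  At
each step the peak best aligned with the incoming direction V_{n-1} is
selected as V_n (peaks are axial, so both orientations of each peak are
considered) and the realized direction is the normalized blend

    V_{n+1} = f * V_n + (1 - f) * ((1 - g) * V_{n-1} + g * V_n)

where ``f`` is the local value of the scalar map (FA, GFA, AFD, a WM
probability, or a binary mask) and ``g`` weights the in/out directions.
High ``f`` lets the streamline follow the local peak; low ``f`` lets the
incoming direction carry it.  ``g`` near 1 forgets the incoming direction
(easier sharp turns), ``g`` near 0 smooths the path.  The single-peak case
(n = 1) degenerates to a tensor-line-style tracker.

Each seed spawns two half-streamlines, propagated along +v0 and -v0 from a
norm-weighted random choice among the seed voxel's peaks, then merged.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .io import PeakField, ScalarField, Tractogram

#: Stop reasons reported by the propagation loop (QA histogram surface).
STOP_OUT_OF_GRID = "out_of_grid"
STOP_THRESHOLD = "below_threshold"
STOP_NO_PEAKS = "no_peaks"
STOP_ANGLE = "angle"
STOP_MAX_LENGTH = "max_length"
STOP_DEGENERATE = "degenerate_direction"


@dataclasses.dataclass
class TrackingConfig:
    """User-tunable tracking parameters.

    Attributes
    ----------
    f_threshold
        Minimum scalar-map value required to continue propagating.
    theta_max
        Maximum angle (degrees) between two consecutive realized step
        directions, in (0, 90].
    step_size
        Step length in mm.
    g
        In/out direction weight in [0, 1].
    min_length, max_length
        Accepted merged streamline length range in mm.
    rng_seed
        Seed for the per-run random generator (initial-direction draws and
        any random seeding).
    """

    f_threshold: float = 0.1
    theta_max: float = 35.0
    step_size: float = 1.0
    g: float = 0.20
    min_length: float = 0.0
    max_length: float = 300.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("g must be in [0, 1]")
        if not 0.0 < self.theta_max <= 90.0:
            raise ValueError("theta_max must be in (0, 90]")
        if not 0.0 <= self.min_length <= self.max_length:
            raise ValueError("need 0 <= min_length <= max_length")

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


def theta_from_radius(s: float, R: float) -> float:
    """Maximum deviation angle (degrees) for step ``s`` on a circle of radius ``R``.

    Two chords of length ``s`` on a circle of radius of curvature ``R``
    subtend an angle of ``2 asin(s / 2R)`` between them; the result is
    clamped to 90 degrees (also covering ``s > 2R``, where no circle of
    that radius can be followed).
    """
    if s <= 0 or R <= 0:
        raise ValueError("step size and radius of curvature must be positive")
    x = s / (2.0 * R)
    if x >= 1.0:
        return 90.0
    return min(math.degrees(2.0 * math.asin(x)), 90.0)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def select_initial_direction(
    peaks: Sequence[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Draw one peak with probability proportional to its norm; return it unit-length."""
    if len(peaks) == 0:
        raise ValueError("cannot pick an initial direction from an empty peak list")
    norms = np.array([np.linalg.norm(p) for p in peaks])
    idx = int(rng.choice(len(peaks), p=norms / norms.sum()))
    return _unit(np.asarray(peaks[idx], dtype=np.float64))


def select_peak(
    peaks: Sequence[np.ndarray], v_in: np.ndarray
) -> np.ndarray | None:
    """The peak orientation forming the smallest angle with the incoming direction.

    Peaks are sign-symmetric (fODF maxima are axes, not vectors), so each
    candidate is considered in both orientations and the one maximizing
    ``dot(v_in, .)`` wins.  Ties go to the lowest storage index.  Returns a
    unit vector, or None for an empty list.
    """
    if len(peaks) == 0:
        return None
    best_dot = -np.inf
    best: np.ndarray | None = None
    for p in peaks:
        u = _unit(np.asarray(p, dtype=np.float64))
        d = float(np.dot(v_in, u))
        if abs(d) > best_dot:  # strict: first index wins ties
            best_dot = abs(d)
            best = u if d >= 0 else -u
    return best


def evolve_direction(
    v_in: np.ndarray, v_peak: np.ndarray, f: float, g: float
) -> np.ndarray | None:
    """Blend the incoming and selected-peak directions into the next step direction.

    Computes ``normalize(f*v_peak + (1-f)*((1-g)*v_in + g*v_peak))``, i.e.
    ``normalize((f + g - f*g) * v_peak + (1-f)*(1-g) * v_in)``.  ``f`` is
    clamped to [0, 1].  Returns None if the blend cancels to (numerically)
    zero, which the caller treats as a stop.
    """
    f = min(max(f, 0.0), 1.0)
    v = f * v_peak + (1.0 - f) * ((1.0 - g) * v_in + g * v_peak)
    n = np.linalg.norm(v)
    if n < 1e-12:
        return None
    return v / n


def propagate_half(
    seed: Sequence[float],
    v0: np.ndarray,
    field: PeakField,
    fmap: ScalarField,
    cfg: TrackingConfig,
) -> tuple[list[np.ndarray], str]:
    """Propagate one half-streamline from ``seed`` along initial direction ``v0``.

    Per iteration: sample ``f`` at the current position (nearest neighbour;
    out-of-grid stops first), stop if ``f`` is below threshold, look up the
    voxel's peaks (none -> stop), evolve the direction, stop if the realized
    turn exceeds ``theta_max`` or the path length would exceed
    ``max_length``; otherwise step ``step_size`` mm and append the point.

    Returns the ordered point list starting at the seed, plus the stop
    reason (one of the ``STOP_*`` constants).
    """
    cos_theta_max = math.cos(math.radians(cfg.theta_max))
    # guard against pathological non-termination
    max_points = math.ceil(cfg.max_length / cfg.step_size) + 1

    pos = np.asarray(seed, dtype=np.float64)
    v_prev = _unit(np.asarray(v0, dtype=np.float64))
    points = [pos.copy()]
    length = 0.0

    while len(points) < max_points:
        if fmap.value_at(pos, outside=-np.inf) == -np.inf:
            return points, STOP_OUT_OF_GRID
        f = fmap.value_at(pos)
        if f < cfg.f_threshold:
            return points, STOP_THRESHOLD
        peaks = field.peaks_at(pos)
        if not peaks:
            return points, STOP_NO_PEAKS
        v_peak = select_peak(peaks, v_prev)
        v_next = evolve_direction(v_prev, v_peak, f, cfg.g)
        if v_next is None:
            return points, STOP_DEGENERATE
        # the constraint governs the realized turn of the path
        if float(np.dot(v_prev, v_next)) < cos_theta_max - 1e-12:
            return points, STOP_ANGLE
        if length + cfg.step_size > cfg.max_length + 1e-9:
            return points, STOP_MAX_LENGTH
        pos = pos + cfg.step_size * v_next
        points.append(pos.copy())
        length += cfg.step_size
        v_prev = v_next

    return points, STOP_MAX_LENGTH


def track_seed(
    seed: Sequence[float],
    field: PeakField,
    fmap: ScalarField,
    cfg: TrackingConfig,
    rng: np.random.Generator,
    stats: dict | None = None,
) -> np.ndarray | None:
    """Track both directions from one seed and merge into a single streamline.

    The initial direction is drawn among the seed voxel's peaks weighted by
    their norms; the two halves run along +v0 and -v0 and are merged with
    the seed point appearing once.  Returns None when the seed voxel has no
    peaks, is below the propagation threshold, or the merged length falls
    outside [min_length, max_length].
    """
    seed = np.asarray(seed, dtype=np.float64)
    peaks = field.peaks_at(seed)
    if not peaks:
        return None
    if fmap.value_at(seed) < cfg.f_threshold:
        return None
    v0 = select_initial_direction(peaks, rng)
    fwd, reason_f = propagate_half(seed, v0, field, fmap, cfg)
    bwd, reason_b = propagate_half(seed, -v0, field, fmap, cfg)
    if stats is not None:
        for reason in (reason_f, reason_b):
            stats[reason] = stats.get(reason, 0) + 1
    merged = bwd[::-1] + fwd[1:]
    if len(merged) < 2:
        return None
    length = (len(merged) - 1) * cfg.step_size
    if not (cfg.min_length <= length <= cfg.max_length):
        return None
    return np.asarray(merged)


def track_all(
    seeds: Sequence[Sequence[float]],
    field: PeakField,
    fmap: ScalarField,
    cfg: TrackingConfig,
) -> Tractogram:
    """Track every seed in order with one seeded RNG; deterministic per config."""
    rng = np.random.default_rng(cfg.rng_seed)
    streamlines = []
    stats: dict = {}
    for seed in seeds:
        s = track_seed(seed, field, fmap, cfg, rng, stats=stats)
        if s is not None:
            streamlines.append(s)
    return Tractogram(
        streamlines=streamlines,
        step_size=cfg.step_size,
        provenance={
            "config": cfg.snapshot(),
            "n_seeds": len(seeds),
            "stop_reasons": stats,
        },
    )
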