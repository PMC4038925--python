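"""Synthetic phantoms: peak fields with known bundle geometry and ground truth.

Each phantom is a set of tubular bundles on a voxel grid.  Inside a tube,
the voxel holds one peak aligned with the local centerline tangent; where
tubes overlap, the voxel holds one peak per bundle (a crossing).  The
scalar map is a two-level mask (``f_inside`` inside any tube,
``f_outside`` elsewhere), so at default thresholds the tube is exactly the
tracking domain.  Endpoint regions of interest (ROIs) are balls at the
centerline termini; each bundle contributes one expected ROI pair, which
is the ground truth for connectivity scoring.

The ``fibercup7`` preset emulates the topology of the classic
seven-bundle coronal-slab validation phantom — straight, crossing and
C-shaped bundles on a 64 x 64 x 3 grid of 3 mm isotropic voxels — as a
structural stand-in, not a metric replica of the physical object: bundle
shapes and ROI placements are this package's own synthetic layout.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import PeakField, ScalarField


@dataclasses.dataclass
class BundleSpec:
    """A tubular bundle: polyline centerline (world mm), tube radius, peak magnitude."""

    centerline: np.ndarray  # (M, 3), M >= 2
    radius: float
    peak_magnitude: float = 1.0

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        if self.centerline.ndim != 2 or len(self.centerline) < 2:
            raise ValueError("centerline needs >= 2 points")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclasses.dataclass
class PhantomData:
    peaks: PeakField
    fmap: ScalarField
    bundle_masks: list[np.ndarray]  # boolean grids, one per bundle
    rois: np.ndarray  # integer label grid; bundle b owns labels 2b+1, 2b+2
    expected_pairs: list[tuple[int, int]]

    @property
    def affine(self) -> np.ndarray:
        return self.peaks.affine

    def roi_mask(self) -> ScalarField:
        """Binary map of all ROI voxels (the ROI-based seeding mask)."""
        return ScalarField(data=(self.rois > 0).astype(float), affine=self.affine)


def line(p0: Sequence[float], p1: Sequence[float], n: int = 50) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) * np.asarray(p0, float) + t * np.asarray(p1, float)


def arc(
    center: Sequence[float],
    radius: float,
    deg_start: float,
    deg_end: float,
    z: float,
    n: int = 120,
) -> np.ndarray:
    """Circular-arc centerline in the xy plane at height ``z``."""
    ang = np.radians(np.linspace(deg_start, deg_end, n))
    cx, cy = center[0], center[1]
    return np.stack(
        [cx + radius * np.cos(ang), cy + radius * np.sin(ang), np.full(n, float(z))],
        axis=1,
    )


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at even arc-length spacing (endpoints preserved)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    t = np.linspace(0.0, total, n)
    return np.stack([np.interp(t, s, points[:, c]) for c in range(3)], axis=1)


def make_phantom(
    specs: Sequence[BundleSpec],
    dims: Sequence[int] = (64, 64, 3),
    voxel_size: float = 3.0,
    f_inside: float = 0.8,
    f_outside: float = 0.0,
    n_peaks: int | None = None,
    roi_radius: float | None = None,
) -> PhantomData:
    """Rasterize bundle tubes into a peak field, scalar map, masks and ROIs.

    For every voxel whose center lies within ``radius`` of a bundle
    centerline, a peak along the local tangent (central differences on the
    densely resampled centerline) scaled by ``peak_magnitude`` is written;
    voxels inside k overlapping tubes hold k peaks.  ``roi_radius`` is the
    endpoint-ROI ball radius in mm (default: 2 voxels).
    """
    if f_inside <= f_outside:
        raise ValueError("need f_inside > f_outside")
    dims = tuple(int(d) for d in dims)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    if roi_radius is None:
        roi_radius = 2.0 * voxel_size

    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * voxel_size

    bundle_masks: list[np.ndarray] = []
    tangents: list[np.ndarray] = []  # per bundle: (n_vox, 3) tangent at nearest sample
    for spec in specs:
        dense = _resample_polyline(spec.centerline, spacing=voxel_size / 4.0)
        tang = np.gradient(dense, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        d = cdist(centers, dense)
        nearest = np.argmin(d, axis=1)
        inside = d[np.arange(len(centers)), nearest] <= spec.radius
        # flat end caps: drop voxels projecting beyond a terminus, so the
        # tube (= tracking domain) ends exactly at the centerline ends and
        # streamline endpoints come to rest inside the endpoint ROIs
        beyond_start = (nearest == 0) & (
            (centers - dense[0]) @ tang[0] < -1e-9
        )
        beyond_end = (nearest == len(dense) - 1) & (
            (centers - dense[-1]) @ tang[-1] > 1e-9
        )
        inside &= ~(beyond_start | beyond_end)
        bundle_masks.append(inside.reshape(dims))
        tangents.append(tang[nearest])

    counts = np.sum([m.reshape(-1) for m in bundle_masks], axis=0)
    needed = int(counts.max()) if len(specs) else 1
    if n_peaks is None:
        n_peaks = max(needed, 1)
    elif needed > n_peaks:
        raise ValueError(
            f"{needed} overlapping bundles exceed the {n_peaks} available peak slots"
        )

    data = np.zeros(dims + (3 * n_peaks,))
    slot = np.zeros(len(centers), dtype=int)
    for spec, mask, tang in zip(specs, bundle_masks, tangents):
        flat = mask.reshape(-1)
        vox = np.nonzero(flat)[0]
        for v in vox:
            s = slot[v]
            data.reshape(-1, 3 * n_peaks)[v, 3 * s : 3 * s + 3] = (
                tang[v] * spec.peak_magnitude
            )
            slot[v] += 1

    any_inside = counts > 0
    fmap = np.where(any_inside, f_inside, f_outside).reshape(dims)

    rois = np.zeros(dims, dtype=np.int32)
    expected_pairs: list[tuple[int, int]] = []
    for b, spec in enumerate(specs):
        for e, terminus in enumerate((spec.centerline[0], spec.centerline[-1])):
            label = 2 * b + 1 + e
            ball = np.linalg.norm(centers - terminus, axis=1) <= roi_radius
            ball = ball.reshape(dims)
            clash = rois[ball] != 0
            if np.any(clash):
                raise ValueError(
                    f"ROI {label} overlaps ROI labels {set(rois[ball][clash])}"
                )
            rois[ball] = label
        expected_pairs.append((2 * b + 1, 2 * b + 2))

    return PhantomData(
        peaks=PeakField(data=data, affine=affine),
        fmap=ScalarField(data=fmap, affine=affine),
        bundle_masks=bundle_masks,
        rois=rois,
        expected_pairs=expected_pairs,
    )


def _fibercup7_specs(voxel_size: float) -> list[BundleSpec]:
    """Seven bundles with two orthogonal crossings and one C-shaped arc.

    Coordinates are in world mm on the 64-voxel (189 mm) plane; the slab
    mid-plane sits at one voxel height.
    """
    z = voxel_size  # center of the middle slice of a 3-slice slab
    r = 2.0 * voxel_size  # tube radius: 2 voxels
    return [
        BundleSpec(line((20, 25, z), (170, 25, z)), r),  # straight, crossed by 2
        BundleSpec(line((60, 10, z), (60, 175, z)), r),  # long vertical, crosses 1 and 3
        BundleSpec(line((20, 100, z), (170, 100, z)), r),  # straight, crossed by 2
        BundleSpec(arc((115, 150), 30.0, 180.0, 360.0, z), r),  # C-shaped
        BundleSpec(line((15, 45, z), (45, 85, z)), r),  # short oblique
        BundleSpec(line((140, 45, z), (170, 85, z)), r),  # short oblique
        BundleSpec(line((20, 115, z), (20, 175, z)), r),  # short vertical
    ]


PRESETS = ("straight", "crossing90", "c_curve", "fibercup7")


def preset_phantom(name: str, rng_seed: int = 0) -> PhantomData:
    """Named phantom layouts on the 64 x 64 x 3 grid of 3 mm isotropic voxels.

    ``rng_seed`` is accepted for interface uniformity; the generator itself
    is fully deterministic.
    """
    vs = 3.0
    z = vs
    r = 2.0 * vs
    if name == "straight":
        specs = [BundleSpec(line((20, 95, z), (170, 95, z)), r)]
    elif name == "crossing90":
        specs = [
            BundleSpec(line((20, 95, z), (170, 95, z)), r),
            BundleSpec(line((95, 20, z), (95, 170, z)), r),
        ]
    elif name == "c_curve":
        specs = [BundleSpec(arc((110, 95), 50.0, 90.0, 270.0, z), r)]
    elif name == "fibercup7":
        specs = _fibercup7_specs(vs)
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return make_phantom(specs, dims=(64, 64, 3), voxel_size=vs)
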