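"""Seed-point generation: VOI grid, mask-complete, and mesh-shell strategies."""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

from .io import ScalarField


@dataclasses.dataclass
class SeedSet:
    points: np.ndarray  # (N, 3) world mm
    origin: str  # "voi" | "mask" | "shell"

    def __len__(self) -> int:
        return len(self.points)


@dataclasses.dataclass
class Mesh:
    vertices: np.ndarray  # (V, 3) world mm
    faces: np.ndarray | None = None  # (F, 3) int, optional for seeding

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=np.int64)
            if self.faces.size and self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")


def load_mesh(path: str | Path) -> Mesh:
    """Read a triangle mesh (Wavefront OBJ and friends); vertices taken as world mm."""
    m = trimesh.load(str(path), process=False, force="mesh")
    return Mesh(vertices=np.asarray(m.vertices), faces=np.asarray(m.faces))


def voi_seeds(
    center: Sequence[float],
    extents: Sequence[float],
    n_per_axis: Sequence[int],
) -> SeedSet:
    """Regular cell-centred grid of seeds inside an axis-aligned box.

    ``n_per_axis = (nx, ny, nz)`` gives ``nx * ny * nz`` seeds; seed ``i``
    along an axis of extent ``e`` sits at ``center + ((i + 0.5) / n - 0.5) * e``,
    strictly inside the box (never on its faces).  With 10 seeds per axis —
    the interactive default — a VOI holds 1000 seeds.
    """
    center = np.asarray(center, dtype=np.float64)
    extents = np.asarray(extents, dtype=np.float64)
    counts = np.asarray(n_per_axis, dtype=int)
    if np.any(extents <= 0):
        raise ValueError("VOI extents must be positive")
    if np.any(counts < 1):
        raise ValueError("seeds per axis must be >= 1")
    axes = [
        center[a] + ((np.arange(counts[a]) + 0.5) / counts[a] - 0.5) * extents[a]
        for a in range(3)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    points = np.stack([g.ravel() for g in grid], axis=1)
    return SeedSet(points=points, origin="voi")


def mask_seeds(
    mask: ScalarField, n_per_voxel: int, rng: np.random.Generator
) -> SeedSet:
    """``n_per_voxel`` uniform-random seeds inside every nonzero mask voxel.

    Placement within each voxel cube is uniform in voxel coordinates and
    mapped to world mm through the mask affine; reproducible under a seeded
    generator.
    """
    if n_per_voxel < 1:
        raise ValueError("n_per_voxel must be >= 1")
    idx = np.argwhere(mask.data != 0)
    if len(idx) == 0:
        warnings.warn("mask is empty; no seeds generated", stacklevel=2)
        return SeedSet(points=np.empty((0, 3)), origin="mask")
    reps = np.repeat(idx, n_per_voxel, axis=0).astype(np.float64)
    jitter = rng.uniform(-0.5, 0.5, size=reps.shape)
    ijk = reps + jitter
    points = ijk @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    return SeedSet(points=points, origin="mask")


def shell_seeds(mesh: Mesh) -> SeedSet:
    """One seed per mesh vertex, in vertex order (no deduplication)."""
    if len(mesh.vertices) == 0:
        raise ValueError("mesh has no vertices")
    return SeedSet(points=mesh.vertices.copy(), origin="shell")
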