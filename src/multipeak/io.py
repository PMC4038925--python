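"""Volumetric and streamline I/O plus field sampling.

Peak fields follow the MRtrix convention: a 4D NIfTI of shape
``[X, Y, Z, 3n]`` where each voxel stores up to ``n`` fiber-ODF maxima as
consecutive (x, y, z) vector triples in world (RAS mm) orientation, with
the vector norm carrying the peak magnitude (e.g. AFD at the maximum).
An all-zero triple marks an absent peak.

All tracking operates in world millimetres through the NIfTI affine, so
step sizes stay in mm regardless of voxel anisotropy.  Field sampling is
nearest-neighbour by design: the intended workflow upsamples the data
once and then reads single voxels during propagation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


class PeakFileError(ValueError):
    """Raised for structurally invalid peak files (wrong dimensionality)."""


@dataclasses.dataclass
class PeakField:
    """Per-voxel sets of up to ``n_peaks`` direction vectors with magnitude.

    Parameters
    ----------
    data
        Array of shape ``(X, Y, Z, 3 * n_peaks)``.  Peak ``i`` of a voxel is
        ``data[x, y, z, 3*i:3*i+3]``; a zero triple means "no peak".
    affine
        4x4 voxel-index -> world-mm transform (RAS).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise PeakFileError(f"peak data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] % 3 != 0:
            raise PeakFileError(
                f"4th dimension ({self.data.shape[3]}) is not a multiple of 3"
            )
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        self._inv_affine = np.linalg.inv(self.affine)

    @property
    def n_peaks(self) -> int:
        return self.data.shape[3] // 3

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Length of each voxel edge in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_index(self, point: Sequence[float]) -> tuple[int, int, int] | None:
        """Nearest voxel index of a world-mm point, or None outside the grid."""
        ijk = self._inv_affine[:3, :3] @ np.asarray(point, float) + self._inv_affine[:3, 3]
        idx = np.rint(ijk).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.shape):
            return None
        return tuple(idx)

    def peaks_at(self, point: Sequence[float]) -> list[np.ndarray]:
        """All nonzero peak vectors of the voxel nearest to a world point.

        Returns the peaks in storage order, magnitudes intact.  A point
        outside the grid yields an empty list (a stopping condition for the
        tracker, never an error).
        """
        idx = self.voxel_index(point)
        if idx is None:
            return []
        vecs = self.data[idx].reshape(self.n_peaks, 3)
        norms = np.linalg.norm(vecs, axis=1)
        return [vecs[i].copy() for i in range(self.n_peaks) if norms[i] > 0]


@dataclasses.dataclass
class ScalarField:
    """3D scalar map (FA / GFA / AFD / WM-probability / binary mask)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"scalar map must be 3D, got {self.data.ndim}D")
        self._inv_affine = np.linalg.inv(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def value_at(self, point: Sequence[float], outside: float = 0.0) -> float:
        """Nearest-neighbour sample at a world-mm point.

        Sampling uses the same rounding rule as peak lookup so the mask and
        the peak field agree on which voxel a position belongs to.  Points
        outside the grid return ``outside`` (default 0, i.e. below any
        sensible propagation threshold).
        """
        ijk = self._inv_affine[:3, :3] @ np.asarray(point, float) + self._inv_affine[:3, 3]
        idx = np.rint(ijk).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.data.shape):
            return outside
        return float(self.data[tuple(idx)])


@dataclasses.dataclass
class Tractogram:
    """An ordered collection of streamlines in world-mm coordinates.

    Each streamline is an ``(N, 3)`` float array with ``N >= 2`` and
    consecutive points ``step_size`` mm apart.  ``provenance`` carries a
    snapshot of the configuration that produced it.
    """

    streamlines: list[np.ndarray]
    step_size: float | None = None
    provenance: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def load_peak_field(path: str | Path) -> PeakField:
    """Read an [X, Y, Z, 3n] peak NIfTI file."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise PeakFileError(f"{path}: expected a 4D peak file, got {data.ndim}D")
    return PeakField(data=data, affine=img.affine)


def save_peak_field(field: PeakField, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(field.data.astype(np.float32), field.affine), str(path))


def load_scalar_field(path: str | Path) -> ScalarField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar map, got {data.ndim}D")
    return ScalarField(data=data, affine=img.affine)


def save_scalar_field(field: ScalarField, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(field.data.astype(np.float32), field.affine), str(path))


def upsample_trilinear(
    data: np.ndarray, affine: np.ndarray, factor: int | Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinearly resample a 3D or 4D volume onto a ``factor``-times finer grid.

    The output grid is node-centred on the input voxel centres: output index
    ``j`` samples the input at continuous index ``j / factor``, so every
    input voxel centre is reproduced exactly (``j = factor * i``) for any
    integer factor, and a linear ramp upsampled by ``f`` becomes a ramp with
    a ``1/f`` per-voxel increment.  Output dims are ``f * (n - 1) + 1`` per
    axis and the affine's spatial columns are divided by ``f``, preserving
    the world positions of all samples.  4D volumes are resampled per
    component (used for peak fields; see the caveat in the methods notes —
    component-wise interpolation of extracted peaks is an approximation to
    upsampling the underlying diffusion data before peak extraction).
    """
    factors = np.broadcast_to(np.asarray(factor, dtype=int), (3,)).copy()
    if np.any(factors < 1):
        raise ValueError(f"upsampling factors must be >= 1, got {factors.tolist()}")
    data = np.asarray(data, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError("expected a 3D or 4D volume")

    in_dims = np.array(data.shape[:3])
    out_dims = factors * (in_dims - 1) + 1
    grids = [np.arange(out_dims[a]) / factors[a] for a in range(3)]
    coords = np.meshgrid(*grids, indexing="ij")

    def interp3(vol: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(vol, coords, order=1, mode="nearest")

    if data.ndim == 3:
        out = interp3(data)
    else:
        out = np.stack([interp3(data[..., c]) for c in range(data.shape[3])], axis=-1)

    new_affine = np.asarray(affine, dtype=np.float64).copy()
    new_affine[:3, :3] = new_affine[:3, :3] / factors[np.newaxis, :]
    return out, new_affine


def save_tractogram(tractogram: Tractogram, path: str | Path) -> None:
    """Write streamlines as TCK (world-mm RAS coordinates)."""
    sequences = [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines]
    nib_t = nib.streamlines.Tractogram(sequences, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(nib_t, str(path))


def load_tractogram(path: str | Path) -> Tractogram:
    """Read a TCK (or TRK) streamline file into world-mm arrays."""
    tfile = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=np.float64) for s in tfile.streamlines]
    return Tractogram(streamlines=streamlines)
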