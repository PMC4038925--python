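"""Bundle comparison and connectivity scoring.

Two evaluation procedures live here:

* **Binary-map comparison** — streamlines are rasterized into a binary
  voxel map (optionally dilated by a millimetre tolerance so parallel
  streamlines one voxel apart still count as the same bundle), then two
  maps are compared with the Dice coefficient
  ``kappa = 2a / (2a + b + c)`` and the asymmetric overlap ratio
  ``r = a / (a + b)``, where ``a`` is the shared voxel count and ``b``,
  ``c`` the voxels unique to each map.

* **Connectivity scoring** — given labeled endpoint ROIs and a list of
  expected ROI pairs, each streamline is classified by where its two
  endpoints land, yielding valid / invalid / no-connection fractions
  (VC / IC / NC), valid and invalid bundle counts (VB / IB), and the
  average bundle and region coverages (ABC / ARC).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import Tractogram


@dataclasses.dataclass
class BinaryMap:
    grid: np.ndarray  # 3D boolean
    affine: np.ndarray
    tolerance_mm: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.tolerance_mm < 0:
            raise ValueError("tolerance_mm must be >= 0")


@dataclasses.dataclass
class ScoreReport:
    VB: int
    IB: int
    VC: float
    IC: float
    NC: float
    ABC: float
    ARC: float
    labels: list[tuple[str, tuple[int, int] | None]]
    n_streamlines: int

    def as_dict(self) -> dict:
        return {
            "VB": self.VB,
            "IB": self.IB,
            "VC": self.VC,
            "IC": self.IC,
            "NC": self.NC,
            "ABC": self.ABC,
            "ARC": self.ARC,
            "n_streamlines": self.n_streamlines,
        }


def _tolerance_structure(affine: np.ndarray, tolerance_mm: float) -> np.ndarray | None:
    """Structuring element of voxel offsets whose world distance <= tolerance."""
    voxel_size = np.linalg.norm(affine[:3, :3], axis=0)
    reach = np.floor(tolerance_mm / voxel_size).astype(int)
    if np.all(reach == 0):
        return None
    offs = [np.arange(-r, r + 1) * s for r, s in zip(reach, voxel_size)]
    dx, dy, dz = np.meshgrid(*offs, indexing="ij")
    return dx**2 + dy**2 + dz**2 <= tolerance_mm**2 + 1e-9


def _world_to_index(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def rasterize(
    tractogram: Tractogram,
    dims: Sequence[int],
    affine: np.ndarray,
    tolerance_mm: float = 0.0,
) -> BinaryMap:
    """Binary map of voxels traversed by any streamline, tolerance-dilated.

    Segments are resampled at half-voxel intervals before voxel marking so
    no traversed voxel is skipped; the tolerance then adds every voxel
    whose center lies within ``tolerance_mm`` (Euclidean, world mm) of a
    marked voxel center.
    """
    dims = tuple(int(d) for d in dims)
    grid = np.zeros(dims, dtype=bool)
    voxel_size = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    max_step = 0.5 * float(voxel_size.min())

    for s in tractogram.streamlines:
        s = np.asarray(s, dtype=np.float64)
        if len(s) == 0:
            continue
        if len(s) == 1:
            pts = s
        else:
            seg_len = np.linalg.norm(np.diff(s, axis=0), axis=1)
            pieces = [s[:1]]
            for p0, p1, L in zip(s[:-1], s[1:], seg_len):
                n = max(int(np.ceil(L / max_step)), 1)
                t = np.linspace(0.0, 1.0, n + 1)[1:, None]
                pieces.append((1 - t) * p0 + t * p1)
            pts = np.concatenate(pieces)
        idx = np.rint(_world_to_index(pts, affine)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(dims)), axis=1)
        idx = idx[ok]
        grid[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    structure = _tolerance_structure(np.asarray(affine), tolerance_mm)
    if structure is not None and grid.any():
        grid = ndimage.binary_dilation(grid, structure=structure)
    return BinaryMap(grid=grid, affine=np.asarray(affine), tolerance_mm=tolerance_mm)


def _overlap_counts(F: BinaryMap, G: BinaryMap) -> tuple[int, int, int]:
    if F.grid.shape != G.grid.shape:
        raise ValueError("maps live on different grids")
    a = int(np.count_nonzero(F.grid & G.grid))
    b = int(np.count_nonzero(F.grid & ~G.grid))
    c = int(np.count_nonzero(~F.grid & G.grid))
    return a, b, c


def dice(F: BinaryMap, G: BinaryMap) -> float:
    """Dice coefficient ``2a / (2a + b + c)``; 1 for identical maps, 0 for disjoint."""
    a, b, c = _overlap_counts(F, G)
    denom = 2 * a + b + c
    if denom == 0:
        raise ValueError("Dice undefined: both maps are empty")
    return 2.0 * a / denom


def overlap_ratio(F: BinaryMap, G: BinaryMap) -> float:
    """Fraction ``r = a / (a + b)`` of F's voxels covered by G (asymmetric)."""
    a, b, _ = _overlap_counts(F, G)
    if a + b == 0:
        raise ValueError("overlap ratio undefined: F is empty")
    return a / (a + b)


def _endpoint_label(point: np.ndarray, rois: np.ndarray, affine: np.ndarray) -> int:
    idx = np.rint(_world_to_index(point[None, :], affine)[0]).astype(int)
    if np.any(idx < 0) or np.any(idx >= rois.shape):
        return 0
    return int(rois[tuple(idx)])


def classify_connections(
    tractogram: Tractogram,
    rois: np.ndarray,
    affine: np.ndarray,
    expected_pairs: Sequence[tuple[int, int]],
) -> list[tuple[str, tuple[int, int] | None]]:
    """Label each streamline valid / invalid / none by its endpoint ROIs.

    A streamline is ``valid`` for pair p when its two endpoints lie in the
    two distinct ROIs of an expected pair, ``invalid`` when they lie in two
    distinct ROIs that do not form an expected pair, and ``none``
    otherwise (an endpoint outside every ROI, or both endpoints in the
    same ROI).
    """
    expected = {tuple(sorted(p)) for p in expected_pairs}
    labels: list[tuple[str, tuple[int, int] | None]] = []
    for s in tractogram.streamlines:
        s = np.asarray(s, dtype=np.float64)
        l0 = _endpoint_label(s[0], rois, affine)
        l1 = _endpoint_label(s[-1], rois, affine)
        if l0 == 0 or l1 == 0 or l0 == l1:
            labels.append(("none", None))
            continue
        pair = tuple(sorted((l0, l1)))
        if pair in expected:
            labels.append(("valid", pair))
        else:
            labels.append(("invalid", pair))
    return labels


def _coverage(
    streamlines: list[np.ndarray], mask: np.ndarray, affine: np.ndarray
) -> float:
    """Fraction of mask voxels crossed by the given streamlines (tolerance 0)."""
    total = int(np.count_nonzero(mask))
    if total == 0:
        return 0.0
    bm = rasterize(Tractogram(streamlines=streamlines), mask.shape, affine, 0.0)
    return int(np.count_nonzero(bm.grid & (mask != 0))) / total


def tractometer_scores(
    tractogram: Tractogram,
    rois: np.ndarray,
    affine: np.ndarray,
    expected_pairs: Sequence[tuple[int, int]],
    bundle_masks: Sequence[np.ndarray] | None = None,
    seed_mask: np.ndarray | None = None,
) -> ScoreReport:
    """Connectivity score report: VB, IB, VC, IC, NC, ABC, ARC.

    * VC / IC / NC — fractions of all streamlines labeled valid / invalid /
      no-connection; they sum to 1.
    * VB — number of expected ROI pairs reached by at least one valid
      streamline; IB — number of distinct unexpected ROI pairs produced.
    * ABC — mean over expected pairs of the fraction of that pair's
      reference-bundle voxels crossed by its valid streamlines
      (``bundle_masks[i]`` matches ``expected_pairs[i]``).
    * ARC — fraction of seed-region voxels crossed by valid streamlines.
    """
    n = len(tractogram.streamlines)
    if n == 0:
        warnings.warn("empty tractogram; all scores zero", stacklevel=2)
        return ScoreReport(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, [], 0)

    labels = classify_connections(tractogram, rois, affine, expected_pairs)
    n_valid = sum(1 for kind, _ in labels if kind == "valid")
    n_invalid = sum(1 for kind, _ in labels if kind == "invalid")
    VC = n_valid / n
    IC = n_invalid / n
    NC = 1.0 - VC - IC

    expected_sorted = [tuple(sorted(p)) for p in expected_pairs]
    valid_pairs = {pair for kind, pair in labels if kind == "valid"}
    invalid_pairs = {pair for kind, pair in labels if kind == "invalid"}
    VB = sum(1 for p in expected_sorted if p in valid_pairs)
    IB = len(invalid_pairs)

    by_pair: dict[tuple[int, int], list[np.ndarray]] = {}
    for (kind, pair), s in zip(labels, tractogram.streamlines):
        if kind == "valid":
            by_pair.setdefault(pair, []).append(np.asarray(s, float))

    ABC = 0.0
    if bundle_masks is not None:
        covers = [
            _coverage(by_pair.get(p, []), m, affine)
            for p, m in zip(expected_sorted, bundle_masks)
        ]
        ABC = float(np.mean(covers)) if covers else 0.0

    ARC = 0.0
    if seed_mask is not None:
        all_valid = list(itertools.chain.from_iterable(by_pair.values()))
        ARC = _coverage(all_valid, seed_mask, affine)

    return ScoreReport(VB, IB, VC, IC, NC, ABC, ARC, labels, n)
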