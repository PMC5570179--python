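"""Transient and conserved pocket regions across an ensemble.

Per-member boolean pocket grids are averaged into a frequency (occupancy)
grid. Relative to the reference pocket, *appearing* regions are points that
are not pocket in the reference but open in at least a threshold fraction of
members; *disappearing* regions are reference pocket points closed in at least
that fraction. Regions are decomposed into compact sub-pockets (26-connected
components above a minimum size) and each sub-pocket's extent of opening is
traced across the members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy import ndimage

from .io_formats import Grid3D
from .pocket_grid import CONNECTIVITY_26, PocketGrid

__all__ = [
    "FrequencyGrid",
    "SubPocket",
    "TransientRegionSet",
    "frequency_grid",
    "transient_regions",
    "split_subpockets",
    "opening_series",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_CONSERVED_FRACTION",
    "DEFAULT_MIN_SUBPOCKET_POINTS",
]

DEFAULT_THRESHOLDS = (0.25, 0.50)
DEFAULT_CONSERVED_FRACTION = 0.9
DEFAULT_MIN_SUBPOCKET_POINTS = 5


class GridGeometryError(ValueError):
    pass


@dataclass
class FrequencyGrid:
    grid: Grid3D  # values in [0,1]: fraction of members where each point is pocket
    n_members: int

    def __post_init__(self) -> None:
        v = self.grid.values
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("frequency values must lie in [0,1]")


@dataclass
class SubPocket:
    label: int
    points: np.ndarray  # (m, 3) int grid indices of one 26-connected component
    centroid: np.ndarray  # (3,) Angstrom
    region: str = ""  # "appearing" | "disappearing" | ...

    @property
    def size(self) -> int:
        return int(self.points.shape[0])

    def mask(self, dims) -> np.ndarray:
        out = np.zeros(dims, dtype=bool)
        out[self.points[:, 0], self.points[:, 1], self.points[:, 2]] = True
        return out


@dataclass
class TransientRegionSet:
    appearing: Grid3D  # boolean
    disappearing: Grid3D  # boolean
    conserved: Grid3D  # boolean
    threshold_fraction: float
    conserved_fraction: float
    subpockets: List[SubPocket] = field(default_factory=list)

    def __post_init__(self) -> None:
        # appearing and disappearing are disjoint by construction; assert always
        overlap = self.appearing.values & self.disappearing.values
        if overlap.any():
            raise AssertionError("appearing and disappearing regions overlap")


def _check_shared_geometry(grids: Sequence[Grid3D]) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise GridGeometryError("pocket grids do not share origin/spacing/dims")


def frequency_grid(pockets: Sequence[PocketGrid]) -> FrequencyGrid:
    """Per-point fraction of members in which the point is pocket."""
    if not pockets:
        raise ValueError("need at least one member pocket grid")
    _check_shared_geometry([p.grid for p in pockets])
    stack = np.stack([p.grid.values for p in pockets]).astype(float)
    freq = stack.mean(axis=0)
    return FrequencyGrid(grid=pockets[0].grid.like(freq), n_members=len(pockets))


def transient_regions(freq: FrequencyGrid, reference_pocket: PocketGrid,
                      threshold_fraction: float,
                      conserved_fraction: float = DEFAULT_CONSERVED_FRACTION,
                      min_subpocket_points: int = DEFAULT_MIN_SUBPOCKET_POINTS) -> TransientRegionSet:
    """Appearing / disappearing / conserved regions at one occurrence threshold.

    * appearing: not pocket in the reference, pocket in >= ``threshold_fraction``
      of the members;
    * disappearing: pocket in the reference, closed in >= ``threshold_fraction``
      of the members;
    * conserved: pocket in >= ``conserved_fraction`` of the members.

    Appearing and disappearing regions are split into sub-pockets of at least
    ``min_subpocket_points`` points.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError(f"threshold_fraction {threshold_fraction} outside (0, 1]")
    _check_shared_geometry([freq.grid, reference_pocket.grid])
    f = freq.grid.values
    ref = reference_pocket.grid.values
    appearing = (~ref) & (f >= threshold_fraction)
    disappearing = ref & ((1.0 - f) >= threshold_fraction)
    conserved = f >= conserved_fraction
    subs: List[SubPocket] = []
    for name, mask in (("appearing", appearing), ("disappearing", disappearing)):
        for sp in split_subpockets(freq.grid.like(mask), min_subpocket_points):
            sp.region = name
            sp.label = len(subs)
            subs.append(sp)
    g = freq.grid
    return TransientRegionSet(
        appearing=g.like(appearing),
        disappearing=g.like(disappearing),
        conserved=g.like(conserved),
        threshold_fraction=threshold_fraction,
        conserved_fraction=conserved_fraction,
        subpockets=subs,
    )


def split_subpockets(region: Grid3D, min_subpocket_points: int = DEFAULT_MIN_SUBPOCKET_POINTS) -> List[SubPocket]:
    """26-connected components of a boolean region, smallest ones dropped.

    Components are labeled by decreasing size; ties break on the
    lexicographically smallest grid index.
    """
    mask = region.values.astype(bool)
    labels, n_lab = ndimage.label(mask, structure=CONNECTIVITY_26)
    comps = []
    for lab in range(1, n_lab + 1):
        pts = np.argwhere(labels == lab)
        if pts.shape[0] < min_subpocket_points:
            continue
        order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
        pts = pts[order]
        comps.append(pts)
    comps.sort(key=lambda p: (-p.shape[0], tuple(p[0])))
    out = []
    for i, pts in enumerate(comps):
        centroid = region.origin + region.spacing * pts.mean(axis=0)
        out.append(SubPocket(label=i, points=pts, centroid=centroid))
    return out


def opening_series(subpocket: SubPocket, pockets: Sequence[PocketGrid]) -> np.ndarray:
    """Fraction of the sub-pocket's points open in each member, in order."""
    if subpocket.size == 0:
        raise ValueError("sub-pocket has no points")
    if pockets:
        _check_shared_geometry([p.grid for p in pockets])
    pts = subpocket.points
    out = np.empty(len(pockets))
    for m, p in enumerate(pockets):
        vals = p.grid.values[pts[:, 0], pts[:, 1], pts[:, 2]]
        out[m] = float(vals.sum()) / subpocket.size
    return out
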