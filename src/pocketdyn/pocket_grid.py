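"""Grid-based cavity detection at the binding site.

Each superposed structure is rasterized onto a shared axis-aligned grid:
points within a van der Waals + probe distance of any heavy atom are protein;
the remaining free points inside the site sphere are scored for buriedness by
a LIGSITE-style scan along 7 directions (the 3 axes and 4 cube diagonals). A
free point is buried when at least ``min_buried_directions`` of the 7 scan
lines hit protein on *both* sides within ``scan_depth``. The pocket is the set
of buried points, restricted to 26-connected components that reach the inner
half of the site sphere, so that disconnected surface dimples far from the
site center are not picked up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .binding_site import BindingSiteDefinition
from .io_formats import Grid3D, ResidueKey, Structure

__all__ = [
    "PocketGrid",
    "PocketStats",
    "build_grid",
    "detect_pocket",
    "pocket_stats",
    "lining_residue_comparison",
    "VDW_RADII",
    "DEFAULT_SPACING",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_MIN_BURIED",
    "DEFAULT_SCAN_DEPTH",
    "DEFAULT_CONTACT_DISTANCE",
]

DEFAULT_SPACING = 1.0  # Angstrom
DEFAULT_PROBE_RADIUS = 1.4  # water-probe radius
DEFAULT_MIN_BURIED = 5  # of the 7 scan directions
DEFAULT_SCAN_DEPTH = 10.0  # Angstrom each way
DEFAULT_CONTACT_DISTANCE = 4.0  # pocket-point / side-chain contact cutoff
MAX_GRID_POINTS = 10_000_000

#: Bondi-style van der Waals radii, Angstrom; unknown elements fall back to C.
VDW_RADII: Dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "H": 1.20, "D": 1.20,
}
DEFAULT_VDW = 1.70

#: The 7 scan directions in grid-index space: 3 axes + 4 cube diagonals.
SCAN_DIRECTIONS = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
], dtype=int)

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class PocketGrid:
    grid: Grid3D  # boolean occupancy
    structure_id: str

    def __post_init__(self) -> None:
        if self.grid.values.dtype != bool:
            self.grid = self.grid.like(self.grid.values.astype(bool))

    @property
    def n_points(self) -> int:
        return int(self.grid.values.sum())

    @property
    def volume(self) -> float:
        return self.n_points * self.grid.spacing ** 3


@dataclass
class PocketStats:
    structure_id: str
    volume: float  # A^3
    surface_area: float  # A^2
    lining_residues: Set[Tuple[str, int, str]]
    lining_residue_keys: List[ResidueKey]
    property_counts: Dict[str, int] = field(default_factory=dict)


def build_grid(site: BindingSiteDefinition, margin: float = 2.0,
               spacing: float = DEFAULT_SPACING) -> Grid3D:
    """Axis-aligned grid box covering the site sphere plus ``margin``.

    The box is snapped so the site center falls exactly on a grid point,
    which makes grids from repeated runs identical and translation tests
    exact.
    """
    if not 0.25 <= spacing <= 2.0:
        raise ValueError(f"spacing {spacing} outside the supported [0.25, 2.0] A range")
    half = site.radius + margin
    n_half = int(np.ceil(half / spacing))
    n = 2 * n_half + 1
    if n ** 3 > MAX_GRID_POINTS:
        raise ValueError(
            f"grid of {n}^3 points exceeds {MAX_GRID_POINTS}; increase spacing"
        )
    origin = site.center - spacing * n_half
    return Grid3D(origin=origin, spacing=spacing, values=np.zeros((n, n, n)))


def _protein_mask(structure: Structure, grid: Grid3D, probe_radius: float) -> np.ndarray:
    """Boolean mask of grid points within vdW+probe of any heavy atom."""
    mask = np.zeros(grid.dims, dtype=bool)
    nx, ny, nz = grid.dims
    for atom in structure.atoms:
        if not atom.is_heavy:
            continue
        r = VDW_RADII.get(atom.element.upper(), DEFAULT_VDW) + probe_radius
        lo = np.floor((atom.coords - r - grid.origin) / grid.spacing).astype(int)
        hi = np.ceil((atom.coords + r - grid.origin) / grid.spacing).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.array([nx - 1, ny - 1, nz - 1]))
        if np.any(lo > hi):
            continue
        ix = np.arange(lo[0], hi[0] + 1)
        iy = np.arange(lo[1], hi[1] + 1)
        iz = np.arange(lo[2], hi[2] + 1)
        px = grid.origin[0] + grid.spacing * ix - atom.coords[0]
        py = grid.origin[1] + grid.spacing * iy - atom.coords[1]
        pz = grid.origin[2] + grid.spacing * iz - atom.coords[2]
        d2 = (px[:, None, None] ** 2 + py[None, :, None] ** 2 + pz[None, None, :] ** 2)
        sub = d2 <= r * r
        mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= sub
    return mask


def _buried_mask(protein: np.ndarray, candidates: np.ndarray, spacing: float,
                 min_buried_directions: int, scan_depth: float) -> np.ndarray:
    """For candidate indices (m,3), count directions hitting protein both ways."""
    dims = np.array(protein.shape)
    m = candidates.shape[0]
    n_buried_dirs = np.zeros(m, dtype=int)
    for d in SCAN_DIRECTIONS:
        step_len = spacing * np.linalg.norm(d)
        max_steps = int(np.floor(scan_depth / step_len))
        hits = np.ones(m, dtype=bool)
        for sign in (1, -1):
            hit_side = np.zeros(m, dtype=bool)
            for s in range(1, max_steps + 1):
                idx = candidates + sign * s * d
                ok = np.all((idx >= 0) & (idx < dims), axis=1)
                rem = ok & ~hit_side
                if not rem.any():
                    break
                sel = idx[rem]
                hit_side[rem] |= protein[sel[:, 0], sel[:, 1], sel[:, 2]]
            hits &= hit_side
        n_buried_dirs += hits
    return n_buried_dirs >= min_buried_directions


def detect_pocket(structure: Structure, grid: Grid3D, site: BindingSiteDefinition,
                  probe_radius: float = DEFAULT_PROBE_RADIUS,
                  min_buried_directions: int = DEFAULT_MIN_BURIED,
                  scan_depth: float = DEFAULT_SCAN_DEPTH) -> PocketGrid:
    """Detect the binding-site cavity of one structure on a shared grid.

    The structure must already be superposed into the reference frame the grid
    was built in. Returns a boolean :class:`PocketGrid` on the same geometry.
    """
    if not any(a.is_heavy for a in structure.atoms):
        raise ValueError(f"{structure.id}: structure has no heavy atoms")
    protein = _protein_mask(structure, grid, probe_radius)

    coords = grid.point_coords()
    d2 = np.sum((coords - site.center) ** 2, axis=1).reshape(grid.dims)
    in_sphere = d2 <= site.radius ** 2
    free = ~protein
    cand_mask = free & in_sphere
    cand_idx = np.argwhere(cand_mask)

    pocket = np.zeros(grid.dims, dtype=bool)
    if cand_idx.size:
        buried = _buried_mask(protein, cand_idx, grid.spacing,
                              min_buried_directions, scan_depth)
        sel = cand_idx[buried]
        pocket[sel[:, 0], sel[:, 1], sel[:, 2]] = True

    # keep 26-connected components that reach the inner half of the site sphere
    if pocket.any():
        labels, n_lab = ndimage.label(pocket, structure=CONNECTIVITY_26)
        core = d2 <= (site.radius / 2.0) ** 2
        keep = np.unique(labels[pocket & core])
        keep = keep[keep > 0]
        pocket = np.isin(labels, keep)
    return PocketGrid(grid=grid.like(pocket), structure_id=structure.id)


# ---------------------------------------------------------------------------
# Physicochemical typing of side-chain heavy atoms
# ---------------------------------------------------------------------------

_POSITIVE = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
             ("HIS", "ND1"), ("HIS", "NE2")}
_NEGATIVE = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_DONOR = _POSITIVE | {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
                      ("TRP", "NE1"), ("ASN", "ND2"), ("GLN", "NE2"), ("CYS", "SG")}
_ACCEPTOR = _NEGATIVE | {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
                         ("ASN", "OD1"), ("GLN", "OE1"), ("HIS", "ND1"), ("MET", "SD")}
_HYDROPHOBIC_RES = {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "PRO", "TRP"}

PROPERTY_NAMES = ("donor", "acceptor", "positive", "negative", "hydrophobic")


def _atom_properties(res_name: str, atom_name: str, element: str) -> Set[str]:
    key = (res_name.upper(), atom_name.upper())
    props: Set[str] = set()
    if key in _POSITIVE:
        props.add("positive")
    if key in _NEGATIVE:
        props.add("negative")
    if key in _DONOR:
        props.add("donor")
    if key in _ACCEPTOR:
        props.add("acceptor")
    if res_name.upper() in _HYDROPHOBIC_RES and element.upper() == "C":
        props.add("hydrophobic")
    return props


_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def pocket_stats(pocket: PocketGrid, structure: Structure,
                 contact_distance: float = DEFAULT_CONTACT_DISTANCE,
                 probe_radius: float = DEFAULT_PROBE_RADIUS) -> PocketStats:
    """Volume, solvent-facing surface area, lining residues and properties.

    * volume = pocket point count x spacing^3 (exact by construction);
    * surface area counts the 6-connected faces between pocket points and
      free solvent (anything that is neither pocket nor protein, including
      space outside the grid), x spacing^2 — a fully enclosed cavity has no
      solvent-exposed faces and reports 0;
    * lining residues have >=1 side-chain heavy atom within
      ``contact_distance`` of >=1 pocket point;
    * property counts tally, per physicochemical class, the pocket points in
      contact with a side-chain atom of that class (a point may count toward
      several classes).
    """
    grid = pocket.grid
    mask = grid.values
    volume = float(mask.sum()) * grid.spacing ** 3

    # surface: pocket faces adjacent to free points; protein blocks the face
    protein = _protein_mask(structure, grid, probe_radius)
    faces = 0
    padded_pocket = np.pad(mask, 1, constant_values=False)
    padded_protein = np.pad(protein, 1, constant_values=False)
    for axis in range(3):
        for shift in (1, -1):
            neighbor_pocket = np.roll(padded_pocket, shift, axis=axis)
            neighbor_protein = np.roll(padded_protein, shift, axis=axis)
            solvent_face = padded_pocket & ~neighbor_pocket & ~neighbor_protein
            faces += int(solvent_face.sum())
    surface = faces * grid.spacing ** 2

    lining: Dict[Tuple[str, int, str], ResidueKey] = {}
    counts = {name: 0 for name in PROPERTY_NAMES}
    pocket_pts = grid.point_coords().reshape(*grid.dims, 3)[mask]
    if len(pocket_pts):
        tree = cKDTree(pocket_pts)
        point_props: Dict[int, Set[str]] = {}
        for atom in structure.atoms:
            if not atom.is_heavy or atom.name in _BACKBONE_NAMES or atom.is_hetero:
                continue
            touched = tree.query_ball_point(atom.coords, contact_distance)
            if not touched:
                continue
            lining.setdefault(atom.residue_key.ident, atom.residue_key)
            props = _atom_properties(atom.residue_key.res_name, atom.name, atom.element)
            for p in touched:
                point_props.setdefault(p, set()).update(props)
        for props in point_props.values():
            for name in props:
                counts[name] += 1
    return PocketStats(
        structure_id=pocket.structure_id,
        volume=volume,
        surface_area=surface,
        lining_residues=set(lining.keys()),
        lining_residue_keys=list(lining.values()),
        property_counts=counts,
    )


def lining_residue_comparison(stats_per_member: List[PocketStats],
                              stats_reference: PocketStats) -> pd.DataFrame:
    """Per-residue lining frequency across members, flagged against the reference.

    ``status`` is "new" for residues lining in members but never in the
    reference, "lost" for reference-lining residues absent from every member,
    and "shared" otherwise.
    """
    all_keys: Dict[Tuple[str, int, str], ResidueKey] = {}
    for st in stats_per_member + [stats_reference]:
        for key in st.lining_residue_keys:
            all_keys.setdefault(key.ident, key)
    n = len(stats_per_member)
    rows = []
    for ident in sorted(all_keys):
        key = all_keys[ident]
        count = sum(1 for st in stats_per_member if ident in st.lining_residues)
        in_ref = ident in stats_reference.lining_residues
        if count and not in_ref:
            status = "new"
        elif in_ref and count == 0:
            status = "lost"
        else:
            status = "shared"
        rows.append({
            "residue": str(key),
            "chain_id": key.chain_id,
            "res_seq": key.res_seq,
            "insertion_code": key.insertion_code,
            "res_name": key.res_name,
            "fraction_lining": count / n if n else 0.0,
            "in_reference": in_ref,
            "status": status,
        })
    return pd.DataFrame(rows)
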