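"""Deterministic synthetic structures, ensembles and alignments.

These generators stand in for experimental ensembles so every pipeline stage
can be exercised with planted, analytically known ground truth:

* :func:`make_shell_structure` builds a hollow pseudo-protein — a cubic lattice
  of alanine-like residues carved so the accessible cavity around the origin is
  a sphere of ``hollow_radius`` (the carving accounts for van der Waals radii
  plus the water probe, so the *detectable* free volume matches the requested
  sphere).
* :func:`make_toy_ensemble` adds, member by member, coordinate noise, a side
  sub-pocket opened in an exact fraction of members (wall residues displaced
  outward), and optional planted conformational clusters (per-cluster rigid
  CB displacements that leave the backbone untouched).
* :func:`make_toy_msa` plants conserved columns and off-target-divergent
  columns in a toy alignment.

All generators are pure functions of their spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .io_formats import MSA, Atom, ResidueKey, Structure, StructureEnsemble
from .pocket_grid import DEFAULT_PROBE_RADIUS, VDW_RADII

__all__ = [
    "ToyEnsembleSpec",
    "ToyEnsemble",
    "make_shell_structure",
    "make_toy_ensemble",
    "make_toy_msa",
]

#: Atom offsets (name, element, offset) of one compact pseudo-alanine residue.
#: The tight 0.3 A offsets keep each residue's steric footprint nearly
#: spherical so cavity walls built from these residues are smooth.
_RESIDUE_TEMPLATE: List[Tuple[str, str, Tuple[float, float, float]]] = [
    ("N", "N", (0.3, 0.0, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (-0.3, 0.0, 0.0)),
    ("O", "O", (0.0, 0.3, 0.0)),
    ("CB", "C", (0.0, 0.0, -0.3)),
]
_MAX_TEMPLATE_OFFSET = 0.3


@dataclass
class ToyEnsembleSpec:
    n_members: int = 10
    hollow_radius: float = 6.0
    wall_spacing: float = 3.0
    subpocket_open_fraction: float = 0.0
    subpocket_offset: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    subpocket_push: float = 4.0  # outward displacement of opened wall residues, A
    subpocket_half_angle: float = 0.7  # radians; angular half-width of the opened cap
    conformational_clusters: int = 1
    cluster_separation: float = 6.0  # A between planted side-chain center offsets
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.subpocket_open_fraction <= 1.0:
            raise ValueError("subpocket_open_fraction must lie in [0,1]")


@dataclass
class ToyEnsemble:
    """A synthetic ensemble together with its planted ground truth."""

    ensemble: StructureEnsemble
    spec: ToyEnsembleSpec
    open_members: List[int] = field(default_factory=list)
    cluster_labels: List[int] = field(default_factory=list)

    def open_exemplar(self) -> Structure:
        """Noise-free structure with the sub-pocket open (the planted truth)."""
        return _build_shell(self.spec, opened=True, structure_id="planted_open")


def _snap_radius(spec: ToyEnsembleSpec) -> float:
    """Inner-wall radius at which a residue's atoms just clear the hollow.

    A residue centered at this radius cannot mark any grid point inside the
    hollow sphere as protein: for its worst atom,
    ``|pos| - (vdw + probe) >= hollow_radius``.
    """
    clearance = max(VDW_RADII[e] for _, e, _ in _RESIDUE_TEMPLATE) + DEFAULT_PROBE_RADIUS
    return spec.hollow_radius + clearance + _MAX_TEMPLATE_OFFSET


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n near-evenly spaced points on a sphere (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * (np.pi * (3.0 - np.sqrt(5.0)))
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return radius * np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


#: Transverse in-plane offsets (A) of the five atoms of a wall residue,
#: expressed in the local tangent basis of its radial direction.
_WALL_TRANSVERSE: List[Tuple[str, str, Tuple[float, float]]] = [
    ("N", "N", (0.5, 0.0)),
    ("CA", "C", (0.0, 0.0)),
    ("C", "C", (-0.5, 0.0)),
    ("O", "O", (0.0, 0.5)),
    ("CB", "C", (0.0, -0.5)),
]


def _tangent_basis(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def _wall_sites(spec: ToyEnsembleSpec) -> List[Tuple[np.ndarray, Optional[np.ndarray]]]:
    """Residue sites of the hollow pseudo-protein as (center, direction) pairs.

    A positive ``hollow_radius`` yields two concentric near-uniform spherical
    layers (golden-angle spirals, inter-residue spacing ~0.6*wall_spacing);
    ``direction`` is each residue's outward radial unit vector, used to place
    its atoms so that every atom's steric clearance surface (vdW + probe)
    touches the hollow sphere exactly. A zero hollow yields a solid
    cubic-lattice ball (direction None) with no cavity.
    """
    if spec.hollow_radius <= 0:
        solid = max(VDW_RADII["C"] + DEFAULT_PROBE_RADIUS, 2 * spec.wall_spacing)
        n = int(np.ceil(solid / spec.wall_spacing))
        axis = np.arange(-n, n + 1) * spec.wall_spacing
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        centers = centers[np.linalg.norm(centers, axis=1) <= solid + 1e-9]
        centers = centers[np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0]))]
        return [(c, None) for c in centers]
    sites: List[Tuple[np.ndarray, Optional[np.ndarray]]] = []
    d = 0.6 * spec.wall_spacing
    r_base = _snap_radius(spec)
    for layer in range(2):
        radius = r_base + layer * d
        n = max(int(np.ceil(4.0 * np.pi * radius ** 2 / d ** 2)), 16)
        for center in _fibonacci_sphere(n, radius):
            direction = center / np.linalg.norm(center)
            sites.append((center, direction))
    return sites


def _build_shell(spec: ToyEnsembleSpec, opened: bool = False,
                 structure_id: str = "shell") -> Structure:
    struct = Structure(id=structure_id)
    u = np.asarray(spec.subpocket_offset, dtype=float)
    norm_u = np.linalg.norm(u)
    u = u / norm_u if norm_u > 0 else np.array([1.0, 0.0, 0.0])
    cos_cap = np.cos(spec.subpocket_half_angle)
    r_base = _snap_radius(spec)
    serial = 0
    res_seq = 0
    for center, direction in _wall_sites(spec):
        res_seq += 1
        key = ResidueKey(chain_id="A", res_seq=res_seq, insertion_code="", res_name="ALA")
        push = np.zeros(3)
        if opened and direction is not None:
            r = np.linalg.norm(center)
            if r <= r_base + spec.wall_spacing and float(center @ u) / r >= cos_cap:
                push = spec.subpocket_push * direction
        if direction is None:  # solid-ball site: compact template placement
            for name, element, offset in _RESIDUE_TEMPLATE:
                serial += 1
                struct.atoms.append(Atom(
                    serial=serial, name=name, element=element,
                    coords=center + np.asarray(offset) + push,
                    residue_key=key, is_hetero=False,
                ))
            continue
        # wall site: each atom's radial position is calibrated so its steric
        # clearance surface (vdW + probe) touches the hollow sphere exactly
        layer_shift = np.linalg.norm(center) - r_base
        e1, e2 = _tangent_basis(direction)
        for name, element, (t1, t2) in _WALL_TRANSVERSE:
            radial = (spec.hollow_radius + DEFAULT_PROBE_RADIUS
                      + VDW_RADII[element] + layer_shift)
            serial += 1
            struct.atoms.append(Atom(
                serial=serial, name=name, element=element,
                coords=direction * radial + t1 * e1 + t2 * e2 + push,
                residue_key=key, is_hetero=False,
            ))
    return struct


def make_shell_structure(spec: ToyEnsembleSpec) -> Structure:
    """Hollow cubic-lattice pseudo-protein with a spherical cavity at the origin.

    The cavity detectable by the grid pocket scan approximates a sphere of
    ``spec.hollow_radius``; ``hollow_radius=0`` yields a solid block with no
    cavity. Deterministic: repeated calls give bit-identical coordinates.
    """
    return _build_shell(spec, opened=False, structure_id="shell")


def _cluster_offsets(k: int, separation: float) -> np.ndarray:
    """k displacement vectors with pairwise distances >= separation."""
    dirs = np.array([
        (0.0, 0.0, 0.0),
        (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0),
        (-1.0, 0.0, 0.0), (0.0, -1.0, 0.0), (0.0, 0.0, -1.0),
    ])
    if k > len(dirs):
        raise ValueError(f"at most {len(dirs)} planted clusters supported")
    return dirs[:k] * separation


def make_toy_ensemble(spec: ToyEnsembleSpec) -> ToyEnsemble:
    """Ensemble of perturbed shells with planted pocket and cluster structure.

    * The side sub-pocket is opened (wall cap pushed outward along
      ``subpocket_offset``) in exactly ``round(subpocket_open_fraction *
      n_members)`` members — the first ones in order.
    * ``conformational_clusters`` > 1 assigns member i to cluster ``i % k`` and
      displaces every CB atom by the cluster's offset vector (backbone
      untouched, so superposition is unaffected and side-chain-center metrics
      separate the clusters by >= ``cluster_separation``).
    * Gaussian coordinate noise of ``noise_sigma`` is added to all atoms.
    """
    rng = np.random.default_rng(spec.seed)
    reference = make_shell_structure(spec)
    n_open = int(round(spec.subpocket_open_fraction * spec.n_members))
    open_members = list(range(n_open))
    k = max(spec.conformational_clusters, 1)
    offsets = _cluster_offsets(k, spec.cluster_separation)
    cluster_labels = [i % k for i in range(spec.n_members)]

    members: List[Structure] = []
    for i in range(spec.n_members):
        base = _build_shell(spec, opened=(i in open_members), structure_id=f"member_{i:03d}")
        off = offsets[cluster_labels[i]]
        for atom in base.atoms:
            if atom.name == "CB":
                atom.coords = atom.coords + off
            if spec.noise_sigma > 0:
                atom.coords = atom.coords + rng.normal(0.0, spec.noise_sigma, 3)
        members.append(base)
    ensemble = StructureEnsemble(reference=reference, members=members)
    return ToyEnsemble(ensemble=ensemble, spec=spec,
                       open_members=open_members, cluster_labels=cluster_labels)


_MSA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


def make_toy_msa(n_on: int, width: int,
                 conserved_columns: Optional[Set[int]] = None,
                 off_divergent_columns: Optional[Set[int]] = None,
                 seed: int = 0) -> Tuple[MSA, str]:
    """Toy on-target alignment plus an aligned off-target row.

    On-target rows share the base sequence at ``conserved_columns`` (and at
    every off-divergent column, so the off-target signal is not masked by
    on-target variability) and vary randomly elsewhere. The off-target row
    equals the base sequence except at ``off_divergent_columns``, where it
    carries a different letter. Returns ``(on_target_msa, off_row)``.
    """
    if n_on < 2:
        raise ValueError("need at least 2 on-target sequences")
    conserved = set(conserved_columns or set())
    divergent = set(off_divergent_columns or set())
    bad = [c for c in conserved | divergent if not 0 <= c < width]
    if bad:
        raise ValueError(f"planted columns out of range: {bad}")
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(_MSA_ALPHABET), size=width))
    fixed = conserved | divergent
    rows = []
    for _ in range(n_on):
        row = [
            base[j] if j in fixed else str(rng.choice(list(_MSA_ALPHABET)))
            for j in range(width)
        ]
        rows.append("".join(row))
    off = list(base)
    for j in sorted(divergent):
        choices = [a for a in _MSA_ALPHABET if a != base[j]]
        off[j] = str(rng.choice(choices))
    ids = [f"on_target_{i + 1}" for i in range(n_on)]
    return MSA(ids=ids, rows=rows), "".join(off)
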