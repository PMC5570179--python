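"""Least-squares (Kabsch) superposition onto the reference and RMSD metrics.

Every ensemble member is rigidly fitted to the reference on the paired
binding-site backbone atoms; all downstream grids and comparisons then live in
the reference frame. Two site RMSD metrics are provided: ``backbone`` (paired
N/CA/C/O atoms, the default) and ``sidechain_center`` (per-residue geometric
centers of the side-chain heavy atoms; residues without a side chain, e.g.
glycine, fall back to all their heavy atoms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .binding_site import BindingSiteDefinition, ResidueMapping, UNMAPPED
from .io_formats import ResidueKey, Structure, StructureEnsemble

__all__ = [
    "RigidTransform",
    "kabsch",
    "superpose_member",
    "site_rmsd",
    "residue_feature_centers",
    "per_residue_rmsd_stats",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
SIDECHAIN_EXCLUDE = frozenset(BACKBONE_ATOMS) | {"OXT"}


class SuperpositionError(ValueError):
    pass


@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3,3), proper
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Tuple[RigidTransform, float]:
    """Optimal rigid fit of ``coords_b`` onto ``coords_a`` (index-paired).

    Returns the transform (proper rotation, reflections corrected) and the
    post-fit RMSD. Collinear/degenerate point sets are solved but may leave a
    rotational degree of freedom; at least 3 points are required.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 paired points, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    fitted = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans), rmsd


def _backbone_pairs(member: Structure, reference: Structure,
                    site: BindingSiteDefinition, mapping: ResidueMapping):
    """Paired site backbone coordinates (ref, member) plus per-residue slices.

    The carbonyl O is used when present in both residues; a residue missing it
    on either side contributes its N/CA/C triplet only.
    """
    ref_idx = reference.residue_index()
    mem_idx = member.residue_index()
    ref_pts: List[np.ndarray] = []
    mem_pts: List[np.ndarray] = []
    slices: Dict[Tuple[str, int, str], slice] = {}
    for key in site.residue_keys:
        partner = mapping.pairs.get(key.ident, UNMAPPED)
        if partner is UNMAPPED:
            continue
        ref_atoms = {a.name: a for a in ref_idx.get(key.ident, [])}
        mem_atoms = {a.name: a for a in mem_idx.get(partner.ident, [])}
        names = [n for n in ("N", "CA", "C") if n in ref_atoms and n in mem_atoms]
        if len(names) < 3:
            continue
        if "O" in ref_atoms and "O" in mem_atoms:
            names.append("O")
        start = len(ref_pts)
        for n in names:
            ref_pts.append(ref_atoms[n].coords)
            mem_pts.append(mem_atoms[n].coords)
        slices[key.ident] = slice(start, len(ref_pts))
    return np.array(ref_pts).reshape(-1, 3), np.array(mem_pts).reshape(-1, 3), slices


def superpose_member(member: Structure, reference: Structure,
                     site: BindingSiteDefinition,
                     mapping: ResidueMapping) -> Tuple[Structure, float]:
    """Fit a member onto the reference using site backbone atoms.

    All member atoms are transformed by the fit; the returned RMSD is the
    post-fit backbone RMSD over the paired site atoms.
    """
    ref_pts, mem_pts, slices = _backbone_pairs(member, reference, site, mapping)
    if len(slices) < 3:
        missing = [str(ResidueKey(*k)) for k in
                   (key.ident for key in site.residue_keys) if k not in slices]
        raise SuperpositionError(
            f"only {len(slices)} site residues with complete backbone in both "
            f"structures (need >=3); unusable: {missing}"
        )
    transform, rmsd = kabsch(ref_pts, mem_pts)
    return member.transformed(transform.rotation, transform.translation), rmsd


def residue_feature_centers(structure: Structure, keys: List[ResidueKey]) -> Dict[Tuple[str, int, str], np.ndarray]:
    """Per-residue geometric center of side-chain heavy atoms.

    Residues without side-chain heavy atoms (Gly, or truncated residues) use
    all their heavy atoms instead, so every residue yields a center.
    """
    idx = structure.residue_index()
    out: Dict[Tuple[str, int, str], np.ndarray] = {}
    for key in keys:
        atoms = idx.get(key.ident, [])
        side = [a.coords for a in atoms if a.is_heavy and a.name not in SIDECHAIN_EXCLUDE]
        if not side:
            side = [a.coords for a in atoms if a.is_heavy]
        if side:
            out[key.ident] = np.mean(side, axis=0)
    return out


def _paired_keys(site: BindingSiteDefinition, mapping: ResidueMapping):
    for key in site.residue_keys:
        partner = mapping.pairs.get(key.ident, UNMAPPED)
        if partner is not UNMAPPED:
            yield key, partner


def per_residue_rmsd(member: Structure, reference: Structure,
                     site: BindingSiteDefinition, mapping: ResidueMapping,
                     metric: str = "backbone") -> Dict[Tuple[str, int, str], float]:
    """Per-site-residue deviation of a superposed member from the reference.

    ``backbone``: RMSD over that residue's paired backbone atoms.
    ``sidechain_center``: distance between side-chain geometric centers.
    """
    if metric not in ("backbone", "sidechain_center"):
        raise ValueError(f"unknown metric {metric!r}")
    out: Dict[Tuple[str, int, str], float] = {}
    if metric == "backbone":
        ref_pts, mem_pts, slices = _backbone_pairs(member, reference, site, mapping)
        for ident, sl in slices.items():
            d2 = np.sum((ref_pts[sl] - mem_pts[sl]) ** 2, axis=1)
            out[ident] = float(np.sqrt(np.mean(d2)))
    else:
        ref_centers = residue_feature_centers(reference, site.residue_keys)
        mem_keys = [p for _, p in _paired_keys(site, mapping)]
        mem_centers = residue_feature_centers(member, mem_keys)
        for key, partner in _paired_keys(site, mapping):
            if key.ident in ref_centers and partner.ident in mem_centers:
                out[key.ident] = float(
                    np.linalg.norm(ref_centers[key.ident] - mem_centers[partner.ident])
                )
    return out


def site_rmsd(member: Structure, reference: Structure,
              site: BindingSiteDefinition, mapping: ResidueMapping,
              metric: str = "backbone") -> float:
    """Site RMSD between two already-superposed structures.

    ``backbone`` pools all paired site backbone atoms; ``sidechain_center``
    treats each residue's side-chain center as one point.
    """
    if metric == "backbone":
        ref_pts, mem_pts, slices = _backbone_pairs(member, reference, site, mapping)
        if not slices:
            raise SuperpositionError("no site residue usable for the backbone metric")
        return float(np.sqrt(np.mean(np.sum((ref_pts - mem_pts) ** 2, axis=1))))
    per_res = per_residue_rmsd(member, reference, site, mapping, metric="sidechain_center")
    if not per_res:
        raise SuperpositionError("no site residue usable for the sidechain_center metric")
    return float(np.sqrt(np.mean(np.square(list(per_res.values())))))


def _cross_mapping(mapping_i: ResidueMapping, mapping_j: ResidueMapping) -> ResidueMapping:
    """Compose ref->i and ref->j mappings into an i->j mapping keyed by i."""
    pairs = {}
    for ident, ki in mapping_i.pairs.items():
        kj = mapping_j.pairs.get(ident, UNMAPPED)
        if ki is UNMAPPED or kj is UNMAPPED:
            continue
        pairs[ki.ident] = kj
    return ResidueMapping(pairs=pairs, identity_fraction=1.0)


def per_residue_rmsd_stats(ensemble: StructureEnsemble,
                           site: BindingSiteDefinition,
                           mappings: List[ResidueMapping],
                           metric: str = "backbone"):
    """Site RMSD matrix and summary statistics for a superposed ensemble.

    Returns ``(matrix, per_member_mean, per_residue_max)`` where

    * ``matrix``: member x member site RMSD (symmetric, zero diagonal);
      members are compared in the common reference frame without re-fitting.
    * ``per_member_mean``: for each member, the mean over site residues of the
      per-residue deviation from the reference.
    * ``per_residue_max``: for each site residue, its maximum deviation from
      the reference over all members.
    """
    members = ensemble.members
    n = len(members)
    matrix = np.zeros((n, n))
    for i in range(n):
        site_i = BindingSiteDefinition(
            center=site.center, radius=site.radius,
            residue_keys=[mappings[i].pairs[k.ident] for k in site.residue_keys
                          if mappings[i].pairs.get(k.ident) is not UNMAPPED],
            source=site.source,
        )
        for j in range(i + 1, n):
            cross = _cross_mapping(mappings[i], mappings[j])
            matrix[i, j] = matrix[j, i] = site_rmsd(
                members[j], members[i], site_i, cross, metric=metric
            )
    per_member = []
    per_residue: Dict[Tuple[str, int, str], float] = {k.ident: 0.0 for k in site.residue_keys}
    for member, mapping in zip(members, mappings):
        res = per_residue_rmsd(member, ensemble.reference, site, mapping, metric=metric)
        per_member.append(float(np.mean(list(res.values()))) if res else np.nan)
        for ident, val in res.items():
            per_residue[ident] = max(per_residue[ident], val)
    return matrix, np.array(per_member), per_residue
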