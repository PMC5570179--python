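"""Binding-site definition and cross-structure residue mapping.

A binding site is resolved on the reference structure either from a bound
ligand (all residues with a heavy atom within ``radius`` of any ligand heavy
atom) or from an explicit center point. Site residues are then carried onto
every ensemble member through a global pairwise sequence alignment so that
homologs with gaps, insertions or point mutations remain comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import ResidueKey, Structure, THREE_TO_ONE

__all__ = [
    "BindingSiteDefinition",
    "ResidueMapping",
    "UNMAPPED",
    "define_site_from_ligand",
    "define_site_from_point",
    "map_site_residues",
]

log = logging.getLogger(__name__)

#: Sentinel marking a reference site residue with no aligned partner.
UNMAPPED = None

DEFAULT_RADIUS = 5.0  # Angstrom; the canonical ligand-proximity cutoff


class EmptySiteError(ValueError):
    pass


class MappingError(ValueError):
    pass


@dataclass
class BindingSiteDefinition:
    center: np.ndarray  # (3,)
    radius: float
    residue_keys: List[ResidueKey]
    source: str  # "ligand" | "point"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not np.all(np.isfinite(self.center)):
            raise ValueError("site center must be finite")
        if self.radius <= 0:
            raise ValueError("site radius must be positive")
        if not self.residue_keys:
            raise EmptySiteError("binding site resolved to zero residues")


@dataclass
class ResidueMapping:
    """Reference site residue -> member residue correspondence.

    ``pairs`` maps every reference site ResidueKey to the member's ResidueKey
    or to :data:`UNMAPPED`. Point mutations (different res_name at aligned
    positions) are tolerated and listed in ``mutations``.
    """

    pairs: Dict[Tuple[str, int, str], Optional[ResidueKey]]
    identity_fraction: float
    mutations: List[Tuple[ResidueKey, ResidueKey]] = field(default_factory=list)

    def mapped(self) -> Dict[Tuple[str, int, str], ResidueKey]:
        return {k: v for k, v in self.pairs.items() if v is not UNMAPPED}

    @property
    def n_unmapped(self) -> int:
        return sum(1 for v in self.pairs.values() if v is UNMAPPED)


def _residue_heavy_coords(structure: Structure) -> List[Tuple[ResidueKey, np.ndarray]]:
    index = structure.residue_index()
    out = []
    for key in structure.residues:
        coords = [a.coords for a in index[key.ident] if a.is_heavy]
        if coords:
            out.append((key, np.array(coords)))
    return out


def _resolve_site(reference: Structure, points: np.ndarray, radius: float,
                  source: str, center: np.ndarray) -> BindingSiteDefinition:
    keys: List[ResidueKey] = []
    nearest = np.inf
    for key, coords in _residue_heavy_coords(reference):
        d = np.linalg.norm(coords[:, None, :] - points[None, :, :], axis=-1)
        dmin = float(d.min())
        nearest = min(nearest, dmin)
        if dmin <= radius:
            keys.append(key)
    if not keys:
        raise EmptySiteError(
            f"no residue within {radius:.2f} A of the site "
            f"(nearest residue at {nearest:.2f} A)"
        )
    return BindingSiteDefinition(center=center, radius=radius, residue_keys=keys, source=source)


def define_site_from_ligand(reference: Structure, ligand: Structure,
                            radius: float = DEFAULT_RADIUS) -> BindingSiteDefinition:
    """Site residues = reference residues with >=1 heavy atom within ``radius``
    of any ligand heavy atom; center = centroid of ligand heavy atoms."""
    lig = np.array([a.coords for a in ligand.atoms if a.is_heavy])
    if lig.size == 0:
        raise ValueError("ligand has no heavy atoms")
    return _resolve_site(reference, lig, radius, "ligand", lig.mean(axis=0))


def define_site_from_point(reference: Structure, center, radius: float = DEFAULT_RADIUS) -> BindingSiteDefinition:
    """Site residues = residues with >=1 heavy atom within ``radius`` of ``center``."""
    center = np.asarray(center, dtype=float).reshape(3)
    return _resolve_site(reference, center[None, :], radius, "point", center)


# ---------------------------------------------------------------------------
# Residue mapping through sequence alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _chain_residues(structure: Structure, chain_id: str) -> List[ResidueKey]:
    hetero = {a.residue_key.ident for a in structure.atoms if a.is_hetero}
    return [k for k in structure.residues
            if k.chain_id == chain_id and k.ident not in hetero]


def _align_chain(ref_keys: List[ResidueKey], mem_keys: List[ResidueKey]):
    """Globally align two residue lists; return (pairs, n_identical, n_aligned)."""
    seq_a = "".join(THREE_TO_ONE.get(k.res_name.upper(), "X") for k in ref_keys)
    seq_b = "".join(THREE_TO_ONE.get(k.res_name.upper(), "X") for k in mem_keys)
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: List[Tuple[ResidueKey, ResidueKey]] = []
    n_id = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            ka, kb = ref_keys[a0 + off], mem_keys[b0 + off]
            pairs.append((ka, kb))
            if seq_a[a0 + off] == seq_b[b0 + off] and seq_a[a0 + off] != "X":
                n_id += 1
    return pairs, n_id, len(pairs)


def map_site_residues(site: BindingSiteDefinition, reference: Structure,
                      member: Structure, min_identity: float = 0.2) -> ResidueMapping:
    """Map the site's reference residues onto a member structure.

    Chains are paired by identical chain id when both structures share one,
    otherwise by the best-identity chain pair. Site residues falling in
    alignment gaps are marked UNMAPPED (and logged); an overall sequence
    identity below ``min_identity`` raises :class:`MappingError`.
    """
    ref_chains = reference.chain_ids
    mem_chains = member.chain_ids
    all_pairs: Dict[Tuple[str, int, str], Optional[ResidueKey]] = {}
    n_id_total = 0
    n_aln_total = 0

    chain_pairs: List[Tuple[str, str]] = []
    shared = [c for c in ref_chains if c in mem_chains]
    if shared:
        chain_pairs = [(c, c) for c in shared]
    else:
        # best-identity pairing over all chain pairs
        best: Dict[str, Tuple[float, str]] = {}
        for rc in ref_chains:
            rk = _chain_residues(reference, rc)
            if len(rk) < 5:
                continue
            for mc in mem_chains:
                mk = _chain_residues(member, mc)
                if len(mk) < 5:
                    continue
                _, n_id, n_aln = _align_chain(rk, mk)
                frac = n_id / max(n_aln, 1)
                if rc not in best or frac > best[rc][0]:
                    best[rc] = (frac, mc)
        chain_pairs = [(rc, mc) for rc, (_, mc) in best.items()]

    aligned_lookup: Dict[Tuple[str, int, str], ResidueKey] = {}
    for rc, mc in chain_pairs:
        rk = _chain_residues(reference, rc)
        mk = _chain_residues(member, mc)
        if len(rk) < 5 or len(mk) < 5:
            continue
        pairs, n_id, n_aln = _align_chain(rk, mk)
        n_id_total += n_id
        n_aln_total += n_aln
        for ka, kb in pairs:
            aligned_lookup[ka.ident] = kb

    identity = n_id_total / max(n_aln_total, 1)
    if identity < min_identity:
        raise MappingError(
            f"sequence identity {identity:.2f} between {reference.id} and "
            f"{member.id} below the {min_identity:.2f} floor"
        )

    mutations: List[Tuple[ResidueKey, ResidueKey]] = []
    for key in site.residue_keys:
        partner = aligned_lookup.get(key.ident, UNMAPPED)
        all_pairs[key.ident] = partner
        if partner is not UNMAPPED and partner.res_name != key.res_name:
            mutations.append((key, partner))
    n_unmapped = sum(1 for v in all_pairs.values() if v is UNMAPPED)
    if n_unmapped:
        log.warning("%d site residues of %s have no aligned partner in %s",
                    n_unmapped, reference.id, member.id)
    return ResidueMapping(pairs=all_pairs, identity_fraction=identity, mutations=mutations)
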