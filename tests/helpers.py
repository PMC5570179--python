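"""Shared test utilities: independent oracles and tiny structure builders.

The pocket oracle reimplements the cavity-detection rules as straightforward
per-point loops, kept deliberately separate from the package's vectorized
implementation so the two can be compared bit-exactly.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from pocketdyn.io_formats import Atom, Grid3D, ResidueKey, Structure

VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
       "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "H": 1.20, "D": 1.20}
DIRECTIONS = [(1, 0, 0), (0, 1, 0), (0, 0, 1),
              (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1)]


def brute_force_pocket(structure: Structure, grid: Grid3D, center, site_radius,
                       probe_radius=1.4, min_buried=5, scan_depth=10.0) -> np.ndarray:
    """Slow, loop-based cavity detection: protein marking, 7-direction
    buriedness scan, 26-connected component filter at half the site radius."""
    center = np.asarray(center, dtype=float)
    nx, ny, nz = grid.dims
    heavy = [(a.coords, VDW.get(a.element.upper(), 1.70) + probe_radius)
             for a in structure.atoms if a.element.upper() not in ("H", "D")]
    atom_xyz = np.array([c for c, _ in heavy])
    atom_r = np.array([r for _, r in heavy])

    protein = np.zeros((nx, ny, nz), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = grid.origin + grid.spacing * np.array([i, j, k])
                d = np.sqrt(((atom_xyz - p) ** 2).sum(axis=1))
                if (d <= atom_r).any():
                    protein[i, j, k] = True

    def hits(idx, d, sign):
        step_len = grid.spacing * float(np.linalg.norm(d))
        for s in range(1, int(np.floor(scan_depth / step_len)) + 1):
            q = (idx[0] + sign * s * d[0], idx[1] + sign * s * d[1],
                 idx[2] + sign * s * d[2])
            if not (0 <= q[0] < nx and 0 <= q[1] < ny and 0 <= q[2] < nz):
                return False
            if protein[q]:
                return True
        return False

    buried = np.zeros((nx, ny, nz), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if protein[i, j, k]:
                    continue
                p = grid.origin + grid.spacing * np.array([i, j, k])
                if ((p - center) ** 2).sum() > site_radius ** 2:
                    continue
                n_dir = 0
                for d in DIRECTIONS:
                    if hits((i, j, k), d, +1) and hits((i, j, k), d, -1):
                        n_dir += 1
                if n_dir >= min_buried:
                    buried[i, j, k] = True

    # flood fill 26-connected components; keep those touching the inner half-sphere
    seen = np.zeros_like(buried)
    keep = np.zeros_like(buried)
    half2 = (site_radius / 2.0) ** 2
    neighbors = [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 for dk in (-1, 0, 1) if (di, dj, dk) != (0, 0, 0)]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not buried[i, j, k] or seen[i, j, k]:
                    continue
                comp = []
                stack = [(i, j, k)]
                seen[i, j, k] = True
                touches = False
                while stack:
                    q = stack.pop()
                    comp.append(q)
                    p = grid.origin + grid.spacing * np.array(q)
                    if ((p - center) ** 2).sum() <= half2:
                        touches = True
                    for di, dj, dk in neighbors:
                        r = (q[0] + di, q[1] + dj, q[2] + dk)
                        if (0 <= r[0] < nx and 0 <= r[1] < ny and 0 <= r[2] < nz
                                and buried[r] and not seen[r]):
                            seen[r] = True
                            stack.append(r)
                if touches:
                    for q in comp:
                        keep[q] = True
    return keep


def make_residue(chain: str, seq: int, res_name: str, atoms: Sequence[Tuple[str, str, Tuple[float, float, float]]],
                 serial_start: int = 1) -> List[Atom]:
    key = ResidueKey(chain_id=chain, res_seq=seq, insertion_code="", res_name=res_name)
    return [Atom(serial=serial_start + i, name=name, element=elem,
                 coords=np.array(xyz, dtype=float), residue_key=key)
            for i, (name, elem, xyz) in enumerate(atoms)]


def make_backbone_residue(chain: str, seq: int, res_name: str, origin,
                          sidechain: Sequence[Tuple[str, str, Tuple[float, float, float]]] = ()) -> List[Atom]:
    """A residue with a full N/CA/C/O backbone near ``origin`` plus optional
    side-chain atoms given as (name, element, absolute xyz)."""
    o = np.asarray(origin, dtype=float)
    atoms = [("N", "N", tuple(o + [-1.2, 0.3, 0.0])),
             ("CA", "C", tuple(o)),
             ("C", "C", tuple(o + [1.3, 0.4, 0.0])),
             ("O", "O", tuple(o + [1.5, 1.6, 0.2]))]
    atoms += [(n, e, tuple(np.asarray(x, dtype=float))) for n, e, x in sidechain]
    return make_residue(chain, seq, res_name, atoms)


def make_peptide(sequence_names: Sequence[str], chain: str = "A",
                 spacing: float = 3.8, structure_id: str = "peptide") -> Structure:
    """Extended pseudo-peptide along x: one full-backbone residue per name."""
    struct = Structure(id=structure_id)
    for i, res_name in enumerate(sequence_names):
        cb = (i * spacing, 1.5, 0.5)
        struct.atoms.extend(
            make_backbone_residue(chain, i + 1, res_name, (i * spacing, 0.0, 0.0),
                                  sidechain=[] if res_name == "GLY"
                                  else [("CB", "C", cb)])
        )
    return struct


def same_partition(labels_a, labels_b) -> bool:
    """True iff the two labelings induce the same partition (Rand index 1)."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        return False
    mapping: Dict = {}
    reverse: Dict = {}
    for a, b in zip(labels_a, labels_b):
        if a in mapping and mapping[a] != b:
            return False
        if b in reverse and reverse[b] != a:
            return False
        mapping[a] = b
        reverse[b] = a
    return True


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    union = np.logical_or(mask_a, mask_b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(mask_a, mask_b).sum() / union)
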