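"""Readers and writers for the formats the pipeline touches.

Structures come in as PDB (single- or multi-model), alignments as FASTA,
volumetric grids go out (and round-trip back in) as OpenDX scalar grids.
Parsing of PDB entities is delegated to :mod:`Bio.PDB`; the lightweight
:class:`Structure` container used throughout the package keeps only what the
downstream geometry needs: atom names, elements, coordinates and residue keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from gridData import Grid as _DXGrid

__all__ = [
    "Atom",
    "ResidueKey",
    "Structure",
    "StructureEnsemble",
    "MSA",
    "Grid3D",
    "read_pdb",
    "write_pdb",
    "write_multimodel_pdb",
    "split_chains",
    "read_msa_fasta",
    "read_dx_grid",
    "write_dx_grid",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class EmptyInputError(ValueError):
    """Raised when a file parses but carries no usable records."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue within one structure.

    ``(chain_id, res_seq, insertion_code)`` is the unique key; ``res_name``
    travels along so mutations between homologous structures at the same key
    can be detected and reported rather than rejected.
    """

    chain_id: str
    res_seq: int
    insertion_code: str = ""
    res_name: str = "UNK"

    @property
    def ident(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)

    def __str__(self) -> str:  # e.g. A:GLY17 or A:GLY17A
        return f"{self.chain_id}:{self.res_name}{self.res_seq}{self.insertion_code}"


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) float, Angstrom
    residue_key: ResidueKey
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite coordinates")
        if not self.element:
            self.element = _element_from_name(self.name)

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


def _element_from_name(name: str) -> str:
    """Infer the element symbol from a PDB atom name (columns 13-16)."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("atom has neither element nor name")
    # Two-letter elements occupy column 13; names like "1HB " are hydrogens.
    if stripped[0].isdigit():
        return stripped[1].upper() if len(stripped) > 1 else "H"
    if len(name) >= 2 and name[0] != " " and name[:2].strip().isalpha() and name[:2].upper() in (
        "FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "CA", "SE",
    ):
        return name[:2].strip().upper()
    return stripped[0].upper()


@dataclass
class Structure:
    """One conformation: an ordered list of atoms grouped into residues."""

    id: str
    atoms: List[Atom] = field(default_factory=list)

    @property
    def residues(self) -> List[ResidueKey]:
        """Residue keys in order of first appearance along the atom list."""
        seen: dict = {}
        for atom in self.atoms:
            seen.setdefault(atom.residue_key.ident, atom.residue_key)
        return list(seen.values())

    @property
    def chain_ids(self) -> List[str]:
        out: List[str] = []
        for key in self.residues:
            if key.chain_id not in out:
                out.append(key.chain_id)
        return out

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        sel = [a.coords for a in self.atoms if (a.is_heavy or not heavy_only)]
        return np.array(sel, dtype=float).reshape(-1, 3)

    def atoms_of(self, key: ResidueKey) -> List[Atom]:
        return [a for a in self.atoms if a.residue_key.ident == key.ident]

    def residue_index(self) -> dict:
        """Map residue ident -> list of its atoms (single pass)."""
        idx: dict = {}
        for atom in self.atoms:
            idx.setdefault(atom.residue_key.ident, []).append(atom)
        return idx

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = Structure(id=self.id)
        for a in self.atoms:
            out.atoms.append(
                Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element,
                    coords=rotation @ a.coords + translation,
                    residue_key=a.residue_key,
                    is_hetero=a.is_hetero,
                )
            )
        return out

    def copy(self) -> "Structure":
        return self.transformed(np.eye(3), np.zeros(3))

    def sequence(self, chain_id: Optional[str] = None) -> str:
        """One-letter sequence of (non-hetero) residues; nonstandard -> X."""
        hetero = {a.residue_key.ident for a in self.atoms if a.is_hetero}
        letters = []
        for key in self.residues:
            if chain_id is not None and key.chain_id != chain_id:
                continue
            if key.ident in hetero:
                continue
            letters.append(THREE_TO_ONE.get(key.res_name.upper(), "X"))
        return "".join(letters)


@dataclass
class StructureEnsemble:
    reference: Structure
    members: List[Structure]
    source_labels: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must contain at least one member")
        if not self.source_labels:
            self.source_labels = [m.id for m in self.members]


@dataclass
class MSA:
    ids: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids in alignment: {dupes}")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            bad = [i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0])]
            raise FormatError(
                f"ragged alignment: rows {bad} differ in length from the first row"
            )

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def without(self, seq_id: str) -> "MSA":
        keep = [i for i, sid in enumerate(self.ids) if sid != seq_id]
        return MSA([self.ids[i] for i in keep], [self.rows[i] for i in keep])

    def with_row(self, seq_id: str, row: str) -> "MSA":
        return MSA(self.ids + [seq_id], self.rows + [row])


@dataclass
class Grid3D:
    """Axis-aligned regular grid: point(i,j,k) = origin + spacing*(i,j,k)."""

    origin: np.ndarray  # (3,)
    spacing: float
    values: np.ndarray  # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a non-empty 3D array")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_points(self) -> int:
        return int(np.prod(self.values.shape))

    def point_coords(self) -> np.ndarray:
        """All grid point coordinates, shape (nx*ny*nz, 3), C order."""
        nx, ny, nz = self.dims
        idx = np.indices((nx, ny, nz)).reshape(3, -1).T
        return self.origin + self.spacing * idx

    def same_geometry(self, other: "Grid3D", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= tol
            and bool(np.all(np.abs(self.origin - other.origin) <= tol))
        )

    def like(self, values: np.ndarray) -> "Grid3D":
        if values.shape != self.values.shape:
            raise ValueError("value array shape does not match grid dims")
        return Grid3D(self.origin.copy(), self.spacing, values)


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path, model_policy: str = "first") -> List[Structure]:
    """Read a PDB file into one :class:`Structure` per selected MODEL.

    Parameters
    ----------
    path:
        PDB file. ATOM and HETATM records are both kept (``is_hetero`` flags
        the latter). Alternate locations are resolved to the highest-occupancy
        conformer (ties broken by alphabetically first altLoc id).
    model_policy:
        ``"first"`` returns only the first MODEL, ``"all"`` one Structure per
        MODEL (the multi-model dialect is how trajectory snapshots enter).
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        entity = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    structures: List[Structure] = []
    for model in entity:
        sid = path.stem if len(entity) == 1 else f"{path.stem}_model{model.id + 1}"
        struct = Structure(id=sid)
        serial = 0
        for chain in model:
            for residue in chain:
                hetflag, resseq, icode = residue.id
                is_het = hetflag.strip() != ""
                key = ResidueKey(
                    chain_id=str(chain.id).strip() or "A",
                    res_seq=int(resseq),
                    insertion_code=icode.strip(),
                    res_name=residue.resname.strip(),
                )
                for atom in residue:
                    if atom.is_disordered():
                        alts = sorted(
                            atom.disordered_get_list(),
                            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                        )
                        chosen = alts[0]
                    else:
                        chosen = atom
                    serial += 1
                    struct.atoms.append(
                        Atom(
                            serial=chosen.get_serial_number() or serial,
                            name=chosen.get_fullname().strip() or chosen.get_name(),
                            element=(chosen.element or "").strip().upper(),
                            coords=np.asarray(chosen.get_coord(), dtype=float),
                            residue_key=key,
                            is_hetero=is_het,
                        )
                    )
        structures.append(struct)
        if model_policy == "first":
            break

    if not structures or all(not s.atoms for s in structures):
        raise EmptyInputError(f"{path}: no ATOM or HETATM records found")
    return structures


_PDB_ATOM_FMT = (
    "{rec:<6}{serial:>5} {name:<4}{altloc:1}{resname:>3} {chain:1}"
    "{resseq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {elem:>2}"
)


def _format_atom_name(name: str, element: str) -> str:
    """PDB column alignment: 1-letter elements start in column 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"[:4]


def _pdb_lines(structure: Structure, b_factors: Optional[dict] = None) -> List[str]:
    lines = []
    for i, atom in enumerate(structure.atoms, start=1):
        key = atom.residue_key
        b = 0.0
        if b_factors is not None:
            b = float(b_factors.get(key.ident, 0.0))
        lines.append(
            _PDB_ATOM_FMT.format(
                rec="HETATM" if atom.is_hetero else "ATOM",
                serial=i % 100000,
                name=_format_atom_name(atom.name, atom.element),
                altloc=" ",
                resname=key.res_name[:3],
                chain=(key.chain_id or "A")[:1],
                resseq=key.res_seq % 10000,
                icode=(key.insertion_code or " ")[:1],
                x=atom.coords[0],
                y=atom.coords[1],
                z=atom.coords[2],
                occ=1.0,
                b=b,
                elem=atom.element[:2],
            )
        )
    return lines


def write_pdb(structure: Structure, path, b_factors: Optional[dict] = None) -> None:
    """Write a Structure as a single-model PDB file.

    ``b_factors`` optionally maps residue idents to a value placed in the
    B-factor column (used to export per-residue conservation scores for
    external viewers).
    """
    lines = _pdb_lines(structure, b_factors)
    Path(path).write_text("\n".join(lines + ["TER", "END"]) + "\n")


def write_multimodel_pdb(structures: Sequence[Structure], path) -> None:
    """Write an ensemble as one multi-model PDB (MODEL/ENDMDL blocks)."""
    chunks: List[str] = []
    for m, structure in enumerate(structures, start=1):
        chunks.append(f"MODEL     {m:>4}")
        chunks.extend(_pdb_lines(structure))
        chunks.append("ENDMDL")
    Path(path).write_text("\n".join(chunks + ["END"]) + "\n")


def split_chains(structure: Structure) -> List[Structure]:
    """Split a structure into one Structure per chain, dropping HETATMs.

    Chains whose records are all HETATM (e.g. a ligand on its own chain id)
    produce no output. Output ids are ``"<id>_<chain>"``.
    """
    by_chain: dict = {}
    for atom in structure.atoms:
        if atom.is_hetero:
            continue
        by_chain.setdefault(atom.residue_key.chain_id, []).append(atom)
    out = []
    for chain_id, atoms in by_chain.items():
        sub = Structure(id=f"{structure.id}_{chain_id}")
        sub.atoms = [
            Atom(a.serial, a.name, a.element, a.coords.copy(), a.residue_key, False)
            for a in atoms
        ]
        out.append(sub)
    return out


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_msa_fasta(path) -> MSA:
    """Read an aligned FASTA file.

    Letters are uppercased and '.' gap characters normalized to '-'. Requires
    at least two records; ragged rows or duplicate ids raise
    :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise EmptyInputError(f"{path}: an alignment needs at least 2 sequences")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper().replace(".", "-") for r in records]
    return MSA(ids=ids, rows=rows)


def write_msa_fasta(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# OpenDX grids
# ---------------------------------------------------------------------------

def write_dx_grid(grid: Grid3D, path) -> None:
    """Write a scalar grid in the OpenDX 'gridpositions' dialect."""
    g = _DXGrid(
        grid.values.astype(float),
        origin=np.asarray(grid.origin, dtype=float),
        delta=float(grid.spacing),
    )
    g.export(str(path), file_format="dx")


def read_dx_grid(path) -> Grid3D:
    g = _DXGrid(str(path))
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise FormatError(f"{path}: anisotropic grids are not supported")
    return Grid3D(origin=np.asarray(g.origin, dtype=float), spacing=float(delta[0]), values=np.asarray(g.grid))
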