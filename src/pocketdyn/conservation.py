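"""Sequence conservation of binding-site residues from an MSA.

Per-column conservation is the Jensen-Shannon divergence between the column's
amino-acid distribution and a background distribution (the marginal amino-acid
frequencies of the BLOSUM62 substitution model), in bits, normalized to [0,1]
and down-weighted by the column's gap fraction — the estimator of Capra &
Singh. Scores are rescaled linearly to the [30, 70] range for display and
mapped onto the reference structure. A differential on/off-target mode scores
each column by how much the profile changes when the off-target sequence is
added: low values mean on- and off-target agree at that position, high values
flag selectivity-relevant differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io_formats import MSA, Structure, THREE_TO_ONE

__all__ = [
    "ConservationProfile",
    "BLOSUM62_BACKGROUND",
    "AMINO_ACIDS",
    "jsd_column_score",
    "conservation_profile",
    "rescale_scores",
    "differential_conservation",
    "map_scores_to_structure",
]

log = logging.getLogger(__name__)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Marginal amino-acid frequencies of the BLOSUM62 model (order ARNDCQEGHILKMFPSTWYV),
# normalized to sum exactly to 1.
_RAW_BG = np.array([
    0.078, 0.051, 0.041, 0.052, 0.024, 0.034, 0.059, 0.083, 0.025, 0.062,
    0.092, 0.056, 0.024, 0.044, 0.043, 0.059, 0.055, 0.014, 0.034, 0.072,
])
BLOSUM62_BACKGROUND = _RAW_BG / _RAW_BG.sum()

DEFAULT_PSEUDOCOUNT = 1e-7
RESCALE_LOW, RESCALE_HIGH = 30.0, 70.0


@dataclass
class ConservationProfile:
    column_scores_raw: np.ndarray  # per-column, [0,1]
    column_scores_rescaled: np.ndarray  # per-column, [30,70]
    mode: str  # "conservation" | "differential"
    residue_scores: Dict[Tuple[str, int, str], float] = field(default_factory=dict)
    column_to_residue: Dict[int, Tuple[str, int, str]] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return len(self.column_scores_raw)


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd_column_score(column: str, background: Optional[np.ndarray] = None,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Jensen-Shannon divergence of one alignment column against the background.

    ``column`` is one letter per sequence; '-' and 'X' are treated as gaps.
    The divergence ``H((p+q)/2) - (H(p)+H(q))/2`` (log base 2, bounded by 1
    bit) is taken between the pseudocounted column distribution ``p`` and the
    background ``q``, then multiplied by ``1 - gap_fraction``. An all-gap
    column scores 0 with a warning.
    """
    if background is None:
        background = BLOSUM62_BACKGROUND
    q = np.asarray(background, dtype=float)
    if q.shape != (20,) or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("background must be a 20-vector summing to 1")
    if not column:
        raise ValueError("empty column")
    counts = np.zeros(20)
    n_gap = 0
    for letter in column.upper():
        i = _AA_INDEX.get(letter)
        if i is None:
            n_gap += 1
        else:
            counts[i] += 1.0
    n = len(column)
    if counts.sum() == 0:
        log.warning("all-gap column scored 0")
        return 0.0
    # pseudocount is added to the normalized frequencies so that columns with
    # the same composition score identically regardless of alignment depth
    p = counts / counts.sum() + pseudocount
    p /= p.sum()
    r = 0.5 * (p + q)
    jsd = _entropy_bits(r) - 0.5 * (_entropy_bits(p) + _entropy_bits(q))
    jsd = min(max(jsd, 0.0), 1.0)  # bounded by 1 bit; clamp numerical noise
    gap_fraction = n_gap / n
    return jsd * (1.0 - gap_fraction)


def rescale_scores(raw: np.ndarray) -> np.ndarray:
    """Linear min-max rescale onto [30, 70]; constant input maps to 50."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one score")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return np.full_like(raw, 0.5 * (RESCALE_LOW + RESCALE_HIGH))
    return RESCALE_LOW + (RESCALE_HIGH - RESCALE_LOW) * (raw - lo) / (hi - lo)


def conservation_profile(msa: MSA, background: Optional[np.ndarray] = None,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ConservationProfile:
    """Per-column JSD conservation profile of an alignment."""
    raw = np.array([
        jsd_column_score(msa.column(j), background, pseudocount)
        for j in range(msa.width)
    ])
    return ConservationProfile(
        column_scores_raw=raw,
        column_scores_rescaled=rescale_scores(raw),
        mode="conservation",
    )


def differential_conservation(msa_on: MSA, off_sequence: str,
                              off_id: str = "off_target",
                              background: Optional[np.ndarray] = None,
                              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ConservationProfile:
    """On/off-target differential conservation profile.

    Scores each column twice — with and without the aligned off-target row —
    and takes the absolute difference, then rescales to [30, 70]. Low values
    mean the off-target resembles the on-target group at that position, high
    values mark positions that discriminate the two.
    """
    off_sequence = off_sequence.upper().replace(".", "-")
    if len(off_sequence) != msa_on.width:
        raise ValueError(
            f"off-target row width {len(off_sequence)} != alignment width {msa_on.width}"
        )
    with_off = msa_on.with_row(off_id, off_sequence)
    raw_on = conservation_profile(msa_on, background, pseudocount).column_scores_raw
    raw_all = conservation_profile(with_off, background, pseudocount).column_scores_raw
    diff = np.abs(raw_all - raw_on)
    return ConservationProfile(
        column_scores_raw=diff,
        column_scores_rescaled=rescale_scores(diff),
        mode="differential",
    )


def map_scores_to_structure(profile: ConservationProfile, msa: MSA,
                            reference: Structure,
                            min_identity: float = 0.9) -> Dict[Tuple[str, int, str], float]:
    """Map rescaled column scores onto the reference structure's residues.

    The MSA row with the best ungapped identity to the structure-derived
    sequence is taken as the reference row (it must exceed ``min_identity``);
    its non-gap columns are walked in order against the structure residues.
    Structure residues beyond the row's length (e.g. expression tags) stay
    unscored with a warning.
    """
    hetero = {a.residue_key.ident for a in reference.atoms if a.is_hetero}
    keys = [k for k in reference.residues if k.ident not in hetero]
    struct_seq = "".join(THREE_TO_ONE.get(k.res_name.upper(), "X") for k in keys)

    best_row, best_ident, best_id = None, -1.0, None
    for sid, row in zip(msa.ids, msa.rows):
        ungapped = row.replace("-", "")
        n = min(len(ungapped), len(struct_seq))
        if n == 0:
            continue
        matches = sum(1 for a, b in zip(ungapped[:n], struct_seq[:n]) if a == b)
        ident = matches / max(len(struct_seq), len(ungapped))
        if ident > best_ident:
            best_row, best_ident, best_id = row, ident, sid
    if best_row is None or best_ident < min_identity:
        raise ValueError(
            f"no MSA row matches the structure sequence above identity "
            f"{min_identity:.2f}; best candidate {best_id!r} at {best_ident:.2f}"
        )

    residue_scores: Dict[Tuple[str, int, str], float] = {}
    col_to_res: Dict[int, Tuple[str, int, str]] = {}
    pos = 0
    for j, letter in enumerate(best_row):
        if letter == "-":
            continue
        if pos >= len(keys):
            break
        residue_scores[keys[pos].ident] = float(profile.column_scores_rescaled[j])
        col_to_res[j] = keys[pos].ident
        pos += 1
    if pos < len(keys):
        log.warning("%d structure residues beyond the MSA row are unscored",
                    len(keys) - pos)
    profile.residue_scores = residue_scores
    profile.column_to_residue = col_to_res
    return residue_scores
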