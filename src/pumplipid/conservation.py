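"""Alignment-column conservation of lipid-contact residues.

Columns of a multiple sequence alignment are scored with an entropy-based
conservation measure in the AL2CO family: score = 1 - H/ln(21), where H is
the Shannon entropy (natural log) of the column's symbol frequencies over
the 20 amino acids plus the gap character as a 21st symbol. A column of one
invariant residue scores 1; a maximally mixed column scores 0. Gap counting
deliberately penalizes gappy columns.

The module also maps 1-based residue numbers of an ungapped reference
sequence onto alignment columns and reports, for a list of lipid-contact
residues, whether the corresponding column is identical across all aligned
pumps, its conservation score, and the mean score over a +-7-residue flank
(the ~15-residue patches used when colouring structures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .errors import FormatError, MappingError

__all__ = [
    "MultipleAlignment",
    "AMINO_ACIDS",
    "GAP",
    "read_alignment",
    "conservation_score",
    "column_scores",
    "map_residue",
    "site_report",
    "DEFAULT_CONTACT_RESIDUES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_ALPHABET = set(AMINO_ACIDS + GAP)

#: Lipid-contact residues of the reference proton pump reported by the
#: contact analysis (sites A1/A2, B, C, D and E).
DEFAULT_CONTACT_RESIDUES = (
    57, 60, 238, 266, 267, 268, 270, 271, 692, 693, 694, 696, 705, 706, 707, 842,
)


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length aligned sequences over the 20 amino acids plus gaps."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) < 2:
            raise FormatError("an alignment needs >= 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            bad = next(i for i, r in enumerate(self.rows) if len(r) != len(self.rows[0]))
            raise FormatError(f"ragged alignment: sequence {self.ids[bad]!r} has a different length")
        for sid, row in zip(self.ids, self.rows):
            extra = set(row) - _ALPHABET
            if extra:
                raise FormatError(f"sequence {sid!r} contains invalid symbols {sorted(extra)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> str:
        return "".join(row[index] for row in self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise MappingError(f"sequence {seq_id!r} not in alignment") from None


def read_alignment(path: str | Path, fmt: str = "fasta") -> MultipleAlignment:
    """Read a FASTA or Clustal alignment into a validated object."""
    if fmt not in ("fasta", "clustal"):
        raise FormatError(f"unsupported alignment format {fmt!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return MultipleAlignment(
        ids=tuple(rec.id for rec in aln),
        rows=tuple(str(rec.seq).upper() for rec in aln),
    )


def write_alignment(aln: MultipleAlignment, path: str | Path, fmt: str = "fasta") -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)]
    )
    AlignIO.write(msa, str(path), fmt)


def conservation_score(column: str) -> float:
    """1 - H/ln(21) with gap as a 21st symbol; 1 = invariant, 0 = maximally mixed."""
    if not column:
        raise FormatError("empty column")
    n = len(column)
    counts: dict[str, int] = {}
    for c in column:
        counts[c] = counts.get(c, 0) + 1
    h = -sum((k / n) * math.log(k / n) for k in counts.values())
    return 1.0 - h / math.log(21.0)


def column_scores(aln: MultipleAlignment) -> np.ndarray:
    return np.array([conservation_score(aln.column(j)) for j in range(aln.n_columns)])


def map_residue(aln: MultipleAlignment, seq_id: str, residue_number: int) -> int:
    """Alignment column (0-based) holding 1-based residue ``residue_number``
    of the ungapped ``seq_id`` sequence."""
    row = aln.row(seq_id)
    if residue_number < 1:
        raise MappingError(f"residue numbers are 1-based; got {residue_number}")
    count = 0
    for col, sym in enumerate(row):
        if sym != GAP:
            count += 1
            if count == residue_number:
                return col
    raise MappingError(
        f"residue {residue_number} beyond the ungapped length ({count}) of {seq_id!r}"
    )


def site_report(
    aln: MultipleAlignment,
    reference_id: str,
    contact_residues: Sequence[int] = DEFAULT_CONTACT_RESIDUES,
    flank: int = 7,
) -> pd.DataFrame:
    """Conservation status of each contact residue of the reference pump.

    Columns: residue, ref_symbol, column, symbols (one per sequence),
    identical_in_all (no gap, single symbol), score, flank_mean_score
    (mean over the +-``flank`` reference residues that exist).
    """
    scores = column_scores(aln)
    ref_row = aln.row(reference_id)
    ungapped_len = sum(1 for c in ref_row if c != GAP)
    missing = [r for r in contact_residues if not (1 <= r <= ungapped_len)]
    if missing:
        raise MappingError(f"contact residues not mappable in {reference_id!r}: {missing}")

    rows = []
    for res in contact_residues:
        col = map_residue(aln, reference_id, res)
        column = aln.column(col)
        flank_cols = [
            map_residue(aln, reference_id, r)
            for r in range(max(1, res - flank), min(ungapped_len, res + flank) + 1)
        ]
        rows.append(
            {
                "residue": res,
                "ref_symbol": ref_row[col],
                "column": col,
                "symbols": column,
                "identical_in_all": len(set(column)) == 1 and GAP not in column,
                "score": scores[col],
                "flank_mean_score": float(np.mean([scores[c] for c in flank_cols])),
            }
        )
    return pd.DataFrame(rows)
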