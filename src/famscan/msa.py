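"""Aligned protein sequence containers and readers.

Alignments are read with :mod:`Bio.AlignIO` (aligned FASTA and Stockholm)
and validated into the light-weight :class:`MSA` container used by the
profile builder and the distance/tree code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

#: The 20 standard amino acids, in alphabetical order. Index into emission
#: vectors everywhere in this package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"


class InputError(ValueError):
    """Malformed user input (bad residues, bad identifiers, bad files)."""


@dataclass
class MSA:
    """A validated multiple sequence alignment.

    Parameters
    ----------
    ids : list of str
        Unique sequence identifiers, one per row.
    rows : list of str
        Equal-length aligned residue strings over the 20 amino acids
        plus ``'-'`` for gaps.
    """

    ids: list[str]
    rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows must have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("sequence identifiers must be unique")
        if self.rows:
            ncol = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise InputError(
                        f"row {sid!r} has length {len(row)}, expected {ncol}"
                    )
                for j, ch in enumerate(row):
                    if ch != GAP and ch not in AA_INDEX:
                        raise InputError(
                            f"unknown residue {ch!r} in row {sid!r}, column {j + 1}"
                        )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        """Return alignment column ``j`` (0-based) as a string."""
        return "".join(row[j] for row in self.rows)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count(GAP) / len(col)


def read_msa(path: str | Path, fmt: str | None = None) -> MSA:
    """Read an alignment from aligned FASTA or Stockholm.

    ``fmt`` is guessed from the file suffix when not given: ``.sto`` /
    ``.stk`` / ``.stockholm`` map to Stockholm, anything else to FASTA.
    Gap characters ``.`` are normalised to ``-`` and residues upper-cased.
    """
    path = Path(path)
    if fmt is None:
        fmt = (
            "stockholm"
            if path.suffix.lower() in {".sto", ".stk", ".stockholm"}
            else "fasta"
        )
    try:
        aln = AlignIO.read(str(path), fmt)
    except Exception as exc:  # pragma: no cover - message wrapping only
        raise InputError(f"could not read alignment {path} as {fmt}: {exc}") from exc
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper().replace(".", GAP) for rec in aln]
    return MSA(ids=ids, rows=rows)


def validate_sequence(seq: str, *, allow_empty: bool = False) -> str:
    """Upper-case and validate an unaligned residue string."""
    seq = seq.upper()
    if not seq and not allow_empty:
        raise InputError("empty sequence")
    for j, ch in enumerate(seq):
        if ch not in AA_INDEX:
            raise InputError(f"unknown residue {ch!r} at position {j + 1}")
    return seq
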