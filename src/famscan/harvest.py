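"""Database scanning: extract significant, envelope-trimmed domains.

One best-scoring envelope is reported per sequence per profile; hits are
retained when their E-value is strictly below the cutoff, and domain
subsequences are trimmed to the Viterbi envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .msa import InputError, validate_sequence
from .profile import DomainHit, ProfileHMM
from .scoring import best_hit


@dataclass
class SequenceDB:
    """An in-memory protein database with unique ids."""

    records: list[tuple[str, str, str]]  # (seq_id, description, residues)
    source_name: str = ""

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate sequence ids in database")
        for sid, _, seq in self.records:
            if not seq:
                raise InputError(f"empty sequence {sid!r}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceDB":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((rec.id, rec.description, validate_sequence(str(rec.seq))))
        return cls(records=records, source_name=str(path))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, desc, seq in self.records:
                header = f">{desc}" if desc.startswith(sid) else f">{sid} {desc}".rstrip()
                fh.write(f"{header}\n{seq}\n")


@dataclass
class HarvestResult:
    hits: list[DomainHit]
    domains: list[tuple[str, str]]  # (seq_id, trimmed residues)
    cutoff: float
    db_size: int
    profile_name: str = ""

    def __post_init__(self) -> None:
        if len(self.hits) != len(self.domains):
            raise ValueError("one trimmed domain required per retained hit")


def trim_envelope(seq: str, hit: DomainHit) -> str:
    """Return the 1-based inclusive envelope substring of ``seq``."""
    if hit.end > len(seq):
        raise ValueError(
            f"envelope ({hit.start}, {hit.end}) exceeds sequence length {len(seq)}"
        )
    return seq[hit.start - 1 : hit.end]


def harvest_domains(
    db: SequenceDB,
    profile: ProfileHMM,
    evalue_cutoff: float = 0.01,
    db_size: int | None = None,
) -> HarvestResult:
    """Scan ``db`` with one calibrated profile.

    ``db_size`` defaults to the number of database records.  Retains
    exactly the hits with ``e_value < evalue_cutoff`` (strict), ordered
    by (seq_id, start).
    """
    if profile.calibration is None:
        raise ValueError(f"profile {profile.name!r} is not calibrated")
    if evalue_cutoff <= 0:
        raise InputError("evalue_cutoff must be positive")
    if db_size is None:
        db_size = len(db)
    if len(db) == 0:
        return HarvestResult([], [], evalue_cutoff, max(db_size, 0), profile.name)

    kept: list[tuple[DomainHit, str]] = []
    for sid, _, seq in db.records:
        hit = best_hit(profile, sid, seq, db_size)
        if hit is not None and hit.e_value < evalue_cutoff:
            kept.append((hit, trim_envelope(seq, hit)))
    kept.sort(key=lambda pair: (pair[0].seq_id, pair[0].start))
    return HarvestResult(
        hits=[h for h, _ in kept],
        domains=[(h.seq_id, dom) for h, dom in kept],
        cutoff=evalue_cutoff,
        db_size=db_size,
        profile_name=profile.name,
    )


def write_hits_tsv(hits: list[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tprofile\tstart\tend\tbit_score\te_value\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.profile_name}\t{h.start}\t{h.end}\t"
                f"{h.bit_score:.4f}\t{h.e_value:.6g}\n"
            )


def write_domains_fasta(domains: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in domains:
            fh.write(f">{sid}\n{seq}\n")


def read_domains_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, validate_sequence(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]
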