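"""Single- vs bi-domain architecture calls from two profiles.

A protein is bi-domain when the N-terminal-domain profile and the
C-terminal-domain profile both hit it significantly, their envelopes do
not overlap beyond the tolerated fraction, and the N envelope starts
before the C envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .classify import ConfigurationError, TAXON_GROUPS, TaxonomyMap, UNKNOWN_GROUP
from .msa import InputError
from .profile import DomainHit, ProfileHMM
from .scoring import best_hit

LABELS = ("N-only", "C-only", "bi-domain", "none")


@dataclass(frozen=True)
class ArchitectureCall:
    seq_id: str
    label: str  # one of LABELS
    n_hit: DomainHit | None = None
    c_hit: DomainHit | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"bad label {self.label!r}")


def detect_architecture(
    seq: tuple[str, str],
    n_profile: ProfileHMM,
    c_profile: ProfileHMM,
    evalue_cutoff: float = 0.01,
    db_size: int = 1,
    max_overlap_frac: float = 0.2,
) -> ArchitectureCall:
    """Classify one protein as N-only, C-only, bi-domain, or none.

    Overlap fraction is envelope intersection over the shorter envelope.
    Overlap beyond ``max_overlap_frac`` resolves to the higher-scoring
    single-domain label; a significant C-before-N pair likewise resolves
    to the higher-scoring label, with a note in both cases.
    """
    if n_profile.name == c_profile.name:
        raise ConfigurationError("N and C profiles must have distinct names")
    if not (0 <= max_overlap_frac <= 1):
        raise InputError("max_overlap_frac must be in [0, 1]")
    sid, residues = seq
    n_hit = best_hit(n_profile, sid, residues, db_size)
    c_hit = best_hit(c_profile, sid, residues, db_size)
    n_ok = n_hit is not None and n_hit.e_value < evalue_cutoff
    c_ok = c_hit is not None and c_hit.e_value < evalue_cutoff

    if n_ok and c_ok:
        overlap = n_hit.overlap(c_hit)
        frac = overlap / min(n_hit.length, c_hit.length)
        if frac > max_overlap_frac:
            winner = "N-only" if n_hit.bit_score >= c_hit.bit_score else "C-only"
            return ArchitectureCall(
                sid,
                winner,
                n_hit,
                c_hit,
                note=f"overlap fraction {frac:.2f} > {max_overlap_frac}; "
                "resolved to higher-scoring domain",
            )
        if n_hit.start >= c_hit.start:
            winner = "N-only" if n_hit.bit_score >= c_hit.bit_score else "C-only"
            return ArchitectureCall(
                sid, winner, n_hit, c_hit, note="both-unordered: C envelope precedes N"
            )
        return ArchitectureCall(sid, "bi-domain", n_hit, c_hit)
    if n_ok:
        return ArchitectureCall(sid, "N-only", n_hit, None)
    if c_ok:
        return ArchitectureCall(sid, "C-only", None, c_hit)
    return ArchitectureCall(sid, "none")


def detect_architectures(
    seqs: list[tuple[str, str]],
    n_profile: ProfileHMM,
    c_profile: ProfileHMM,
    evalue_cutoff: float = 0.01,
    db_size: int | None = None,
    max_overlap_frac: float = 0.2,
) -> list[ArchitectureCall]:
    if db_size is None:
        db_size = max(len(seqs), 1)
    return [
        detect_architecture(
            s, n_profile, c_profile, evalue_cutoff, db_size, max_overlap_frac
        )
        for s in seqs
    ]


def summarize_architectures(
    calls: list[ArchitectureCall], taxmap: TaxonomyMap
) -> pd.DataFrame:
    """Label x taxon-group contingency table; cell total equals len(calls)."""
    cols = list(TAXON_GROUPS) + [UNKNOWN_GROUP]
    table = pd.DataFrame(0, index=list(LABELS), columns=cols, dtype=int)
    for c in calls:
        table.loc[c.label, taxmap.group(c.seq_id)] += 1
    return table


def write_calls_tsv(calls: list[ArchitectureCall], path: str | Path) -> None:
    def span(h: DomainHit | None) -> str:
        return f"{h.start}-{h.end}" if h else ""

    def score(h: DomainHit | None) -> str:
        return f"{h.bit_score:.4f}" if h else ""

    with open(path, "w") as fh:
        fh.write("seq_id\tlabel\tn_envelope\tn_bits\tc_envelope\tc_bits\tnote\n")
        for c in calls:
            fh.write(
                f"{c.seq_id}\t{c.label}\t{span(c.n_hit)}\t{score(c.n_hit)}\t"
                f"{span(c.c_hit)}\t{score(c.c_hit)}\t{c.note}\n"
            )
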