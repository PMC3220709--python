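"""Competitive family assignment and family-by-taxon count matrices.

Each domain is Forward-scored against every family profile; E-values
gate eligibility at the cutoff and the best bit score among eligible
profiles wins.  Exact score ties go to the lexicographically smallest
family name with margin 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .msa import InputError
from .profile import ProfileHMM
from .scoring import evalue, score_forward

#: Fixed taxon-group vocabulary and its output row order.
TAXON_GROUPS = (
    "Viridiplantae",
    "Fungi",
    "Metazoa",
    "Other eukaryotes",
    "Archaea",
    "Bacteria",
)
UNKNOWN_GROUP = "unknown"
UNCLASSIFIED = "unclassified"


class ConfigurationError(ValueError):
    """Invalid classifier configuration (e.g. duplicate profile names)."""


@dataclass(frozen=True)
class FamilyAssignment:
    seq_id: str
    family: str  # profile name or "unclassified"
    best_bit_score: float | None = None
    margin: float | None = None  # best minus second best; None when < 2 pass
    tie: bool = False

    def __post_init__(self) -> None:
        if self.margin is not None and self.margin < -1e-12:
            raise ValueError("margin must be >= 0 when defined")


@dataclass
class TaxonomyMap:
    """seq_id -> taxon group, restricted to the fixed vocabulary."""

    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g in self.pairs.values() if g not in TAXON_GROUPS and g != UNKNOWN_GROUP}
        if bad:
            raise InputError(f"unknown taxon groups: {sorted(bad)}")

    def group(self, seq_id: str) -> str:
        return self.pairs.get(seq_id, UNKNOWN_GROUP)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        pairs = {}
        with open(path) as fh:
            for ln in fh:
                ln = ln.rstrip("\n")
                if not ln or ln.startswith("#"):
                    continue
                parts = ln.split("\t")
                if len(parts) < 2:
                    raise InputError(f"bad taxonomy line: {ln!r}")
                pairs[parts[0]] = parts[1]
        return cls(pairs=pairs)


@dataclass
class TaxonProfile:
    """Family-by-taxon count matrix plus marginal rows.

    ``counts`` is indexed by the six taxon groups (rows, in fixed order)
    and the non-sink family names (columns).  ``unknown_taxon`` counts
    classified assignments lacking a taxon group; ``unclassified`` and
    ``sink`` track assignments excluded from the matrix.
    """

    counts: pd.DataFrame
    unclassified: int = 0
    unknown_taxon: int = 0
    sink: int = 0

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def total_with_marginals(self) -> int:
        return self.grand_total + self.unclassified + self.unknown_taxon + self.sink


def classify_competitive(
    domains: list[tuple[str, str]],
    profiles: list[ProfileHMM],
    evalue_cutoff: float = 0.01,
    db_size: int | None = None,
) -> list[FamilyAssignment]:
    """Assign each (seq_id, residues) domain to its best-matching family.

    ``db_size`` defaults to the number of input domains.
    """
    if not profiles:
        raise ConfigurationError("need at least one profile")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate profile names")
    for p in profiles:
        if p.calibration is None:
            raise ValueError(f"profile {p.name!r} is not calibrated")
    if evalue_cutoff <= 0:
        raise InputError("evalue_cutoff must be positive")
    if db_size is None:
        db_size = max(len(domains), 1)

    out: list[FamilyAssignment] = []
    for sid, seq in domains:
        passing: list[tuple[float, str]] = []
        for p in profiles:
            bits = score_forward(p, seq)
            if math.isfinite(bits) and evalue(bits, p.calibration, db_size) < evalue_cutoff:
                passing.append((bits, p.name))
        if not passing:
            out.append(FamilyAssignment(seq_id=sid, family=UNCLASSIFIED))
            continue
        # best bit score wins; exact ties -> lexicographically smallest name
        passing.sort(key=lambda t: (-t[0], t[1]))
        best_bits, best_name = passing[0]
        tie = len(passing) > 1 and passing[1][0] == best_bits
        margin = best_bits - passing[1][0] if len(passing) > 1 else None
        out.append(
            FamilyAssignment(
                seq_id=sid,
                family=best_name,
                best_bit_score=best_bits,
                margin=0.0 if tie else margin,
                tie=tie,
            )
        )
    return out


def build_taxon_profile(
    assignments: list[FamilyAssignment],
    taxmap: TaxonomyMap,
    families: list[str] | None = None,
    sinks: set[str] | frozenset[str] = frozenset(),
) -> TaxonProfile:
    """Aggregate assignments into the taxon-group x family matrix.

    Assignments to ``sink`` families are counted in a marginal only;
    "unclassified" assignments and classified ones with unknown taxon go
    to their own marginals.  Matrix plus marginals always account for
    every input assignment.
    """
    if families is None:
        families = sorted(
            {a.family for a in assignments if a.family != UNCLASSIFIED} - set(sinks)
        )
    counts = pd.DataFrame(
        0, index=list(TAXON_GROUPS), columns=list(families), dtype=int
    )
    unclassified = unknown_taxon = sink_n = 0
    for a in assignments:
        if a.family == UNCLASSIFIED:
            unclassified += 1
        elif a.family in sinks:
            sink_n += 1
        else:
            g = taxmap.group(a.seq_id)
            if g == UNKNOWN_GROUP:
                unknown_taxon += 1
            else:
                counts.loc[g, a.family] += 1
    return TaxonProfile(
        counts=counts,
        unclassified=unclassified,
        unknown_taxon=unknown_taxon,
        sink=sink_n,
    )


def write_assignments_tsv(assignments: list[FamilyAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tfamily\tbest_bit_score\tmargin\ttie\n")
        for a in assignments:
            bits = "" if a.best_bit_score is None else f"{a.best_bit_score:.4f}"
            margin = "" if a.margin is None else f"{a.margin:.4f}"
            fh.write(f"{a.seq_id}\t{a.family}\t{bits}\t{margin}\t{int(a.tie)}\n")


def write_taxon_profile_tsv(tp: TaxonProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\t" + "\t".join(tp.counts.columns) + "\n")
        for g in tp.counts.index:
            fh.write(g + "\t" + "\t".join(str(v) for v in tp.counts.loc[g]) + "\n")
        fh.write(f"# unclassified\t{tp.unclassified}\n")
        fh.write(f"# unknown_taxon\t{tp.unknown_taxon}\n")
        fh.write(f"# sink\t{tp.sink}\n")
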