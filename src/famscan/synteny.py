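"""Gene-neighborhood co-clustering scan.

Scans ordered gene tables for windows of at most ``window_span``
consecutive genes (inclusive gene count) containing at least
``min_distinct`` distinct family labels, within a single contig; strand
is ignored.  Maximal, non-nested windows are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .msa import InputError


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    contig: str
    ordinal: int  # position within contig, strictly increasing
    strand: str = "+"
    label: str | None = None  # family label, None for unlabeled filler


@dataclass
class GeneTable:
    genome_id: str
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for rec in self.records:
            prev = last.get(rec.contig)
            if prev is not None and rec.ordinal <= prev:
                raise ValueError(
                    f"gene table {self.genome_id!r}: ordinals not strictly "
                    f"increasing on contig {rec.contig!r} at gene {rec.gene_id!r}"
                )
            last[rec.contig] = rec.ordinal


@dataclass(frozen=True)
class SyntenyCall:
    genome_id: str
    contig: str
    start: int  # ordinal of first labeled gene in the window
    end: int  # ordinal of last labeled gene in the window
    gene_ids: tuple[str, ...]
    labels: tuple[str, ...]
    n_distinct: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def synteny_scan(
    table: GeneTable, window_span: int = 7, min_distinct: int = 2
) -> list[SyntenyCall]:
    """All maximal non-nested co-clustering windows in one genome."""
    if window_span < 2:
        raise InputError("window_span must be >= 2")
    if min_distinct < 2:
        raise InputError("min_distinct must be >= 2")

    by_contig: dict[str, list[GeneRecord]] = {}
    for rec in table.records:
        if rec.label is not None:
            by_contig.setdefault(rec.contig, []).append(rec)

    calls: list[SyntenyCall] = []
    for contig, labeled in by_contig.items():
        candidates: list[tuple[int, int]] = []  # index range [i, j] into labeled
        for i in range(len(labeled)):
            j = i
            while (
                j + 1 < len(labeled)
                and labeled[j + 1].ordinal - labeled[i].ordinal + 1 <= window_span
            ):
                j += 1
            members = labeled[i : j + 1]
            if len({m.label for m in members}) >= min_distinct:
                candidates.append((i, j))
        # keep maximal, non-nested candidate windows
        kept = [
            (i, j)
            for (i, j) in candidates
            if not any(
                (i2 <= i and j <= j2) and (i2, j2) != (i, j) for (i2, j2) in candidates
            )
        ]
        for i, j in kept:
            members = labeled[i : j + 1]
            calls.append(
                SyntenyCall(
                    genome_id=table.genome_id,
                    contig=contig,
                    start=members[0].ordinal,
                    end=members[-1].ordinal,
                    gene_ids=tuple(m.gene_id for m in members),
                    labels=tuple(m.label for m in members),
                    n_distinct=len({m.label for m in members}),
                )
            )
    calls.sort(key=lambda c: (c.contig, c.start))
    return calls


def genome_fraction(
    tables: list[GeneTable], window_span: int = 7, min_distinct: int = 2
) -> tuple[int, int, float]:
    """(genomes with >= 1 call, total genomes, fraction)."""
    if not tables:
        raise InputError("empty genome list")
    n_with = sum(
        1 for t in tables if synteny_scan(t, window_span, min_distinct)
    )
    return n_with, len(tables), n_with / len(tables)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gene_table_tsv(path: str | Path) -> list[GeneTable]:
    """Read the simple dialect: genome_id, contig, ordinal, gene_id, strand, label.

    An empty or ``.`` label marks an unlabeled gene.  Several genomes may
    share one file.
    """
    rows: dict[str, list[GeneRecord]] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 6:
                raise InputError(f"bad gene-table line: {ln!r}")
            genome, contig, ordinal, gene_id, strand, label = parts[:6]
            rows.setdefault(genome, []).append(
                GeneRecord(
                    gene_id=gene_id,
                    contig=contig,
                    ordinal=int(ordinal),
                    strand=strand,
                    label=label if label not in {"", "."} else None,
                )
            )
    return [GeneTable(genome_id=g, records=recs) for g, recs in rows.items()]


def write_gene_table_tsv(tables: list[GeneTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# genome_id\tcontig\tordinal\tgene_id\tstrand\tlabel\n")
        for t in tables:
            for r in t.records:
                fh.write(
                    f"{t.genome_id}\t{r.contig}\t{r.ordinal}\t{r.gene_id}\t"
                    f"{r.strand}\t{r.label or '.'}\n"
                )


def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(
    path: str | Path, genome_id: str, label_attr: str = "family"
) -> GeneTable:
    """Order ``gene`` features per contig by start coordinate into ordinals.

    The family label is taken from the ``label_attr`` attribute of column
    nine when present.
    """
    feats: dict[str, list[tuple[int, str, str, str | None]]] = {}
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            cols = ln.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise InputError(f"bad GFF3 line: {ln!r}")
            if cols[2] != "gene":
                continue
            attrs = _gff3_attributes(cols[8])
            gene_id = attrs.get("ID") or attrs.get("Name") or f"{cols[0]}:{cols[3]}"
            feats.setdefault(cols[0], []).append(
                (int(cols[3]), gene_id, cols[6], attrs.get(label_attr))
            )
    records = []
    for contig in sorted(feats):
        for ordinal, (_, gene_id, strand, label) in enumerate(
            sorted(feats[contig]), start=1
        ):
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig=contig,
                    ordinal=ordinal,
                    strand=strand,
                    label=label,
                )
            )
    return GeneTable(genome_id=genome_id, records=records)


def write_calls_tsv(calls: list[SyntenyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tcontig\tstart\tend\tspan\tn_distinct\tgene_ids\tlabels\n"
        )
        for c in calls:
            fh.write(
                f"{c.genome_id}\t{c.contig}\t{c.start}\t{c.end}\t{c.span}\t"
                f"{c.n_distinct}\t{','.join(c.gene_ids)}\t{','.join(c.labels)}\n"
            )
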