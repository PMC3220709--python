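"""Ground-truth-labeled synthetic inputs for every pipeline stage.

Provides random profiles, generative sampling from a profile, planted
protein families with decoys, bi-domain fusion constructs, and genomes
with planted co-clustered gene labels.  Every generator is a pure
function of its arguments and seed: reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .msa import AMINO_ACIDS, InputError
from .profile import (
    DEFAULT_TRANSITIONS,
    N_AA,
    ProfileHMM,
    uniform_background,
)
from .synteny import GeneRecord, GeneTable

_T_MM, _T_MI, _T_MD, _T_IM, _T_II, _T_DM, _T_DD = range(7)


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs for a full synthetic data set."""

    seed: int = 0
    n_families: int = 5
    profile_len_range: tuple[int, int] = (50, 70)
    n_per_family: int = 20
    divergence: float = 0.05  # per-residue substitution probability
    flank_len_range: tuple[int, int] = (5, 30)
    linker_len: int = 10
    n_decoys: int = 50
    n_genomes: int = 10
    genome_size: int = 100
    planted_fraction: float = 0.5
    planted_span: int = 5
    concentration: float = 0.05

    def __post_init__(self) -> None:
        if min(
            self.n_families, self.n_per_family, self.n_decoys, self.n_genomes
        ) < 0:
            raise InputError("counts must be >= 0")
        if not (0 <= self.divergence <= 1 and 0 <= self.planted_fraction <= 1):
            raise InputError("rates must lie in [0, 1]")
        if self.planted_span < 2:
            raise InputError("planted span must be >= 2")


def make_random_profile(
    length: int, concentration: float = 0.05, seed: int = 0
) -> ProfileHMM:
    """Random profile with Dirichlet(concentration) match emissions.

    Small concentrations give near-point-mass columns (an informative,
    easily recoverable family); large ones approach the background.
    """
    if length < 1:
        raise InputError("profile length must be >= 1")
    if concentration <= 0:
        raise InputError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    emis = rng.dirichlet(np.full(N_AA, concentration), size=length)
    # guard against exact zeros from Dirichlet underflow
    emis = emis + 1e-12
    emis = emis / emis.sum(axis=1, keepdims=True)
    prof = ProfileHMM(
        name=f"random-{seed}",
        match_emissions=emis,
        insert_emissions=uniform_background(),
        transitions=np.tile(np.asarray(DEFAULT_TRANSITIONS), (length, 1)),
        background=uniform_background(),
    )
    prof.validate()
    return prof


def sample_from_profile(
    profile: ProfileHMM, seed: int | np.random.Generator = 0
) -> str:
    """Generative traversal of the profile core (no flanks).

    With point-mass emissions and zeroed insert/delete transitions the
    output equals the profile consensus.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[str] = []
    t = profile.transitions
    M = profile.n_match
    k = 0  # current column, 0-based; entry is into match column 1
    state = "M"
    while True:
        if state == "M":
            out.append(AMINO_ACIDS[rng.choice(N_AA, p=profile.match_emissions[k])])
            if k == M - 1:
                break
            nxt = rng.choice(3, p=t[k, [_T_MM, _T_MI, _T_MD]] )
            if nxt == 0:
                k += 1
            elif nxt == 1:
                state = "I"
            else:
                k += 1
                state = "D"
        elif state == "I":
            out.append(AMINO_ACIDS[rng.choice(N_AA, p=profile.insert_emissions)])
            p_im = t[k, _T_IM] / (t[k, _T_IM] + t[k, _T_II])
            if rng.random() < p_im:
                k += 1
                state = "M"
        else:  # delete
            if k == M - 1:
                # exit must be through the last match column
                state = "M"
                continue
            p_dm = t[k, _T_DM] / (t[k, _T_DM] + t[k, _T_DD])
            k += 1
            if rng.random() < p_dm:
                state = "M"
    return "".join(out)


def random_residues(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, N_AA, size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """I.i.d. point substitutions; a hit residue becomes one of the other 19."""
    if not (0 <= rate <= 1):
        raise InputError("substitution rate must lie in [0, 1]")
    chars = list(seq)
    for i, ch in enumerate(chars):
        if rng.random() < rate:
            j = int(rng.integers(0, N_AA - 1))
            repl = AMINO_ACIDS[j] if AMINO_ACIDS[j] != ch else AMINO_ACIDS[N_AA - 1]
            chars[i] = repl
    return "".join(chars)


def shuffle_residues(seq: str, rng: np.random.Generator) -> str:
    """Composition-preserving shuffle (decoy construction)."""
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


@dataclass
class FamilyData:
    """Planted family members plus decoys, with a generation truth table."""

    profiles: list[ProfileHMM]
    sequences: list[tuple[str, str]]  # (seq_id, residues) incl. decoys
    truth: pd.DataFrame  # seq_id, family ("decoy" for decoys), start, end
    spec: SyntheticSpec = field(default=None)  # type: ignore[assignment]


def make_families(spec: SyntheticSpec) -> FamilyData:
    """Sample ``n_per_family`` diverged members per family, embedded in
    random flanks, plus shuffled-member decoys."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.profile_len_range
    profiles = []
    for f in range(spec.n_families):
        prof = make_random_profile(
            length=int(rng.integers(lo, hi + 1)),
            concentration=spec.concentration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        prof.name = f"fam{f:02d}"
        profiles.append(prof)

    sequences: list[tuple[str, str]] = []
    truth_rows = []
    flo, fhi = spec.flank_len_range
    for prof in profiles:
        for i in range(spec.n_per_family):
            core = mutate(sample_from_profile(prof, rng), spec.divergence, rng)
            left = random_residues(int(rng.integers(flo, fhi + 1)), rng)
            right = random_residues(int(rng.integers(flo, fhi + 1)), rng)
            sid = f"{prof.name}_m{i:03d}"
            sequences.append((sid, left + core + right))
            truth_rows.append(
                {
                    "seq_id": sid,
                    "family": prof.name,
                    "start": len(left) + 1,
                    "end": len(left) + len(core),
                }
            )
    members = [s for s in sequences]
    for i in range(spec.n_decoys):
        template = members[int(rng.integers(0, len(members)))][1] if members else (
            random_residues(int(rng.integers(lo, hi + 1)), rng)
        )
        sid = f"decoy_{i:03d}"
        sequences.append((sid, shuffle_residues(template, rng)))
        truth_rows.append({"seq_id": sid, "family": "decoy", "start": 0, "end": 0})
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "family", "start", "end"])
    return FamilyData(profiles=profiles, sequences=sequences, truth=truth, spec=spec)


def make_fusions(
    n_profile: ProfileHMM,
    c_profile: ProfileHMM,
    linker_len: int = 10,
    n: int = 10,
    seed: int = 0,
    divergence: float = 0.0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """N-domain sample + uniform-random linker + C-domain sample, n times."""
    if n < 1:
        raise InputError("n must be >= 1")
    if linker_len < 0:
        raise InputError("linker_len must be >= 0")
    rng = np.random.default_rng(seed)
    seqs = []
    rows = []
    for i in range(n):
        npart = mutate(sample_from_profile(n_profile, rng), divergence, rng)
        cpart = mutate(sample_from_profile(c_profile, rng), divergence, rng)
        linker = random_residues(linker_len, rng)
        sid = f"fusion_{i:03d}"
        seqs.append((sid, npart + linker + cpart))
        rows.append(
            {
                "seq_id": sid,
                "n_len": len(npart),
                "linker_len": linker_len,
                "c_len": len(cpart),
            }
        )
    return seqs, pd.DataFrame(rows, columns=["seq_id", "n_len", "linker_len", "c_len"])


def make_genomes(spec: SyntheticSpec) -> tuple[list[GeneTable], pd.DataFrame]:
    """Single-contig genomes; planted ones carry 2-3 labeled genes within
    ``planted_span`` consecutive positions, the rest scatter labels uniformly."""
    if spec.planted_span > spec.genome_size:
        raise InputError("planted span exceeds genome size")
    rng = np.random.default_rng(spec.seed)
    labels = ("dehydratase_46", "epimerase_35", "reductase_4")
    n_planted = int(round(spec.planted_fraction * spec.n_genomes))
    tables = []
    rows = []
    for g in range(spec.n_genomes):
        genome_id = f"genome{g:03d}"
        planted = g < n_planted
        gene_labels: dict[int, str] = {}
        n_labeled = int(rng.integers(2, 4))  # 2 or 3 labeled genes
        chosen = list(labels[:n_labeled])
        if planted:
            anchor = int(rng.integers(1, spec.genome_size - spec.planted_span + 2))
            positions = anchor + rng.choice(
                spec.planted_span, size=n_labeled, replace=False
            )
        else:
            positions = 1 + rng.choice(
                spec.genome_size, size=n_labeled, replace=False
            )
        for pos, lbl in zip(sorted(int(p) for p in positions), chosen):
            gene_labels[pos] = lbl
        records = [
            GeneRecord(
                gene_id=f"{genome_id}_g{pos:04d}",
                contig="chr1",
                ordinal=pos,
                strand="+" if rng.random() < 0.5 else "-",
                label=gene_labels.get(pos),
            )
            for pos in range(1, spec.genome_size + 1)
        ]
        tables.append(GeneTable(genome_id=genome_id, records=records))
        rows.append(
            {
                "genome_id": genome_id,
                "planted": planted,
                "n_labeled": n_labeled,
                "positions": ",".join(str(p) for p in sorted(gene_labels)),
            }
        )
    truth = pd.DataFrame(rows, columns=["genome_id", "planted", "n_labeled", "positions"])
    return tables, truth


def family_msa_rows(
    profile: ProfileHMM, n_rows: int, divergence: float, rng: np.random.Generator
) -> list[str]:
    """Aligned (indel-free) family samples: one consensus-length row each.

    Uses match emissions only, so rows are mutually aligned by column.
    """
    rows = []
    for _ in range(n_rows):
        core = "".join(
            AMINO_ACIDS[rng.choice(N_AA, p=profile.match_emissions[k])]
            for k in range(profile.n_match)
        )
        rows.append(mutate(core, divergence, rng))
    return rows
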