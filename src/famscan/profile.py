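"""Profile hidden Markov models: construction and plain-text serialization.

The model architecture is a simplified single-hit glocal profile: an
alignment must traverse every match column (through match or delete
states) while consuming an arbitrary contiguous subsequence of the
target; residues outside the consumed envelope are emitted by flanking
states under the background distribution.  Entry is into match column 1
and exit from match column M, so the envelope endpoints are always
match-emitted residues.

Only match emissions are estimated from the alignment (Henikoff
position-based sequence weights blended with background-proportional
pseudocounts).  Insert emissions are fixed to the background and all
transition probabilities are fixed constants, recorded per column in the
serialized model so they remain user-editable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .msa import AA_INDEX, AMINO_ACIDS, GAP, MSA, InputError

N_AA = 20

# Fixed per-column transition constants [M->M, M->I, M->D, I->M, I->I, D->M, D->D].
DEFAULT_TRANSITIONS = (0.90, 0.05, 0.05, 0.50, 0.50, 0.80, 0.20)

# Self-loop probability of the flanking states; the null model uses the same
# loop, so flanking residues are score-neutral.
FLANK_LOOP = 0.99

_FLOAT_FMT = "%.17g"


class ModelBuildError(ValueError):
    """The alignment cannot yield a valid profile (e.g. no match columns)."""


class CalibrationError(RuntimeError):
    """Calibration failed (degenerate score distribution)."""


class ProfileFormatError(ValueError):
    """Malformed serialized profile."""


@dataclass(frozen=True)
class CalibrationParams:
    """Gumbel fit to Forward bit scores of random background sequences.

    ``mu`` is the Gumbel location in bits, ``lam`` the inverse scale
    (per bit, > 0); ``n_samples``, ``sample_len`` and ``seed`` record how
    the calibration set was drawn.
    """

    mu: float
    lam: float
    n_samples: int
    sample_len: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.n_samples < 100:
            raise ValueError("n_samples must be >= 100")


@dataclass(frozen=True)
class DomainHit:
    """One profile-vs-sequence match with a 1-based inclusive envelope."""

    seq_id: str
    profile_name: str
    start: int
    end: int
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid envelope ({self.start}, {self.end}) for {self.seq_id}"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "DomainHit") -> int:
        """Number of residues shared by the two envelopes."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class ProfileHMM:
    name: str
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (20,)
    transitions: np.ndarray  # (M, 7)
    background: np.ndarray  # (20,)
    gap_threshold: float = 0.5
    pseudocount_weight: float = 1.0
    flank_loop: float = FLANK_LOOP
    calibration: CalibrationParams | None = None

    @property
    def n_match(self) -> int:
        return int(self.match_emissions.shape[0])

    def validate(self, atol: float = 1e-9) -> None:
        """Check all probability invariants, raising ``ValueError`` on failure."""
        M = self.n_match
        if M < 1:
            raise ValueError("profile must have at least one match column")
        if self.match_emissions.shape != (M, N_AA):
            raise ValueError("match_emissions must be (M, 20)")
        if self.transitions.shape != (M, 7):
            raise ValueError("transitions must be (M, 7)")
        for arr, what in (
            (self.match_emissions, "match emissions"),
            (self.insert_emissions[None, :], "insert emissions"),
            (self.background[None, :], "background"),
        ):
            if np.any(arr < 0):
                raise ValueError(f"negative probability in {what}")
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > atol):
                raise ValueError(f"{what} rows must sum to 1")
        t = self.transitions
        if np.any(t < 0):
            raise ValueError("negative transition probability")
        sums = np.stack([t[:, 0] + t[:, 1] + t[:, 2], t[:, 3] + t[:, 4], t[:, 5] + t[:, 6]])
        if np.any(np.abs(sums - 1.0) > atol):
            raise ValueError("per-state transition probabilities must sum to 1")
        if not (0 < self.flank_loop < 1):
            raise ValueError("flank_loop must be in (0, 1)")

    def consensus(self) -> str:
        """Most probable residue per match column."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    def with_calibration(self, calib: CalibrationParams) -> "ProfileHMM":
        return replace(self, calibration=calib)


def uniform_background() -> np.ndarray:
    return np.full(N_AA, 1.0 / N_AA)


def henikoff_weights(msa: MSA) -> np.ndarray:
    """Position-based sequence weights, normalized to mean 1.

    Per column, a row holding residue ``a`` contributes ``1 / (r * s_a)``
    where ``r`` is the number of distinct residues in the column and
    ``s_a`` the number of rows carrying ``a``; gap cells contribute
    nothing.
    """
    n = msa.n_rows
    w = np.zeros(n)
    for j in range(msa.n_cols):
        col = msa.column(j)
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, ch in enumerate(col):
            if ch != GAP:
                w[i] += 1.0 / (r * counts[ch])
    total = w.sum()
    if total == 0:
        raise ModelBuildError("all-gap alignment: cannot weight sequences")
    return w * (n / total)


def match_columns(msa: MSA, gap_threshold: float) -> list[int]:
    """0-based indices of columns whose gap fraction is strictly below the threshold."""
    return [j for j in range(msa.n_cols) if msa.gap_fraction(j) < gap_threshold]


def build_profile(
    msa: MSA,
    name: str = "profile",
    gap_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Match columns are exactly those with gap fraction < ``gap_threshold``
    (a column exactly at the threshold becomes an insert column).  Match
    emissions are Henikoff-weighted residue counts blended with
    background-proportional pseudocounts of total weight
    ``pseudocount_weight``.
    """
    if not (0 < gap_threshold <= 1):
        raise InputError("gap_threshold must be in (0, 1]")
    if pseudocount_weight < 0:
        raise InputError("pseudocount_weight must be >= 0")
    if msa.n_rows < 2:
        raise ModelBuildError("need at least 2 aligned sequences to build a model")
    if msa.n_cols == 0:
        raise ModelBuildError("empty alignment")
    bg = uniform_background() if background is None else np.asarray(background, float)
    if bg.shape != (N_AA,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
        raise InputError("background must be 20 positive frequencies summing to 1")

    cols = match_columns(msa, gap_threshold)
    if not cols:
        raise ModelBuildError("no column qualifies as a match column")
    weights = henikoff_weights(msa)

    M = len(cols)
    emis = np.empty((M, N_AA))
    for k, j in enumerate(cols):
        counts = np.zeros(N_AA)
        for i, ch in enumerate(msa.column(j)):
            if ch != GAP:
                counts[AA_INDEX[ch]] += weights[i]
        total = counts.sum()
        denom = total + pseudocount_weight
        if denom == 0:
            raise ModelBuildError(f"column {j + 1}: no counts and no pseudocounts")
        emis[k] = (counts + pseudocount_weight * bg) / denom

    transitions = np.tile(np.asarray(DEFAULT_TRANSITIONS), (M, 1))
    prof = ProfileHMM(
        name=name,
        match_emissions=emis,
        insert_emissions=bg.copy(),
        transitions=transitions,
        background=bg,
        gap_threshold=gap_threshold,
        pseudocount_weight=pseudocount_weight,
    )
    prof.validate()
    return prof


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _fmt_vec(v: np.ndarray) -> str:
    return " ".join(_FLOAT_FMT % x for x in v)


def profile_to_text(profile: ProfileHMM) -> str:
    """Serialize to the documented plain-text format (round-trip stable)."""
    out = io.StringIO()
    out.write("FAMSCAN-PROFILE 1\n")
    out.write(f"NAME {profile.name}\n")
    out.write(f"M {profile.n_match}\n")
    out.write(f"GAP_THRESHOLD {_FLOAT_FMT % profile.gap_threshold}\n")
    out.write(f"PSEUDOCOUNT_WEIGHT {_FLOAT_FMT % profile.pseudocount_weight}\n")
    out.write(f"FLANK_LOOP {_FLOAT_FMT % profile.flank_loop}\n")
    out.write(f"ALPHABET {AMINO_ACIDS}\n")
    out.write(f"BACKGROUND {_fmt_vec(profile.background)}\n")
    out.write(f"INSERT_EMISSIONS {_fmt_vec(profile.insert_emissions)}\n")
    if profile.calibration is not None:
        c = profile.calibration
        out.write(
            "CALIBRATION %s %s %d %d %d\n"
            % (_FLOAT_FMT % c.mu, _FLOAT_FMT % c.lam, c.n_samples, c.sample_len, c.seed)
        )
    for k in range(profile.n_match):
        out.write(
            f"COLUMN {k + 1} EMIT {_fmt_vec(profile.match_emissions[k])} "
            f"TRANS {_fmt_vec(profile.transitions[k])}\n"
        )
    out.write("END\n")
    return out.getvalue()


def write_profile(profile: ProfileHMM, path: str | Path) -> None:
    Path(path).write_text(profile_to_text(profile))


def profile_from_text(text: str) -> ProfileHMM:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("FAMSCAN-PROFILE"):
        raise ProfileFormatError("missing FAMSCAN-PROFILE header")
    fields: dict[str, str] = {}
    columns: list[tuple[np.ndarray, np.ndarray]] = []
    for ln in lines[1:]:
        if ln == "END":
            break
        key, _, rest = ln.partition(" ")
        if key == "COLUMN":
            parts = rest.split()
            try:
                emit_i = parts.index("EMIT")
                trans_i = parts.index("TRANS")
                emit = np.array([float(x) for x in parts[emit_i + 1 : trans_i]])
                trans = np.array([float(x) for x in parts[trans_i + 1 :]])
            except (ValueError, IndexError) as exc:
                raise ProfileFormatError(f"bad COLUMN line: {ln!r}") from exc
            if emit.shape != (N_AA,) or trans.shape != (7,):
                raise ProfileFormatError(f"bad COLUMN line: {ln!r}")
            columns.append((emit, trans))
        else:
            fields[key] = rest
    try:
        M = int(fields["M"])
        calib = None
        if "CALIBRATION" in fields:
            mu_s, lam_s, n_s, len_s, seed_s = fields["CALIBRATION"].split()
            calib = CalibrationParams(
                mu=float(mu_s),
                lam=float(lam_s),
                n_samples=int(n_s),
                sample_len=int(len_s),
                seed=int(seed_s),
            )
        prof = ProfileHMM(
            name=fields["NAME"],
            match_emissions=np.stack([e for e, _ in columns]),
            insert_emissions=np.array([float(x) for x in fields["INSERT_EMISSIONS"].split()]),
            transitions=np.stack([t for _, t in columns]),
            background=np.array([float(x) for x in fields["BACKGROUND"].split()]),
            gap_threshold=float(fields["GAP_THRESHOLD"]),
            pseudocount_weight=float(fields["PSEUDOCOUNT_WEIGHT"]),
            flank_loop=float(fields["FLANK_LOOP"]),
            calibration=calib,
        )
    except KeyError as exc:
        raise ProfileFormatError(f"missing field {exc}") from exc
    if len(columns) != M:
        raise ProfileFormatError(f"expected {M} columns, found {len(columns)}")
    prof.validate()
    return prof


def read_profile(path: str | Path) -> ProfileHMM:
    return profile_from_text(Path(path).read_text())
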