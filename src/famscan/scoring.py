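"""Glocal scoring, Gumbel calibration and E-values for profile HMMs.

Scores are reported in bits: log2 of the ratio between the model
probability of the sequence (summed or maximised over glocal paths) and
a background null model that emits every residue from the background
distribution with the same geometric length persistence as the flanking
states.  Because flank and null share their loop probability, flanking
residues are exactly score-neutral.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

from . import _dp
from .msa import AA_INDEX, InputError, validate_sequence
from .profile import CalibrationError, CalibrationParams, DomainHit, ProfileHMM

LN2 = math.log(2.0)


def encode(seq: str) -> np.ndarray:
    """Map a residue string to int64 alphabet indices (validating it)."""
    seq = validate_sequence(seq)
    return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)


def _ln_arrays(profile: ProfileHMM):
    with np.errstate(divide="ignore"):
        lem = np.log(profile.match_emissions)
        lt = np.log(profile.transitions)
        lb = np.log(profile.background)
    return lem, lt, lb


def _ln_null(obs: np.ndarray, lb: np.ndarray, ln_eta: float, ln_leave: float) -> float:
    return float(lb[obs].sum() + obs.shape[0] * ln_eta + ln_leave)


def score_viterbi(profile: ProfileHMM, seq: str) -> tuple[float, tuple[int, int]]:
    """Best-path bit score and 1-based inclusive envelope.

    Returns ``(-inf, (0, 0))`` when no glocal path exists (sequence
    shorter than the minimum number of match emissions).
    """
    obs = encode(seq)
    lem, lt, lb = _ln_arrays(profile)
    ln_eta = math.log(profile.flank_loop)
    ln_leave = math.log1p(-profile.flank_loop)
    ln_p, start, end = _dp.viterbi_ln(obs, lem, lt, lb, ln_eta, ln_leave)
    if not math.isfinite(ln_p):
        return float("-inf"), (0, 0)
    bits = (ln_p - _ln_null(obs, lb, ln_eta, ln_leave)) / LN2
    return bits, (int(start), int(end))


def score_forward(profile: ProfileHMM, seq: str) -> float:
    """Bit score summed over all glocal paths (``-inf`` if none exist)."""
    obs = encode(seq)
    lem, lt, lb = _ln_arrays(profile)
    ln_eta = math.log(profile.flank_loop)
    ln_leave = math.log1p(-profile.flank_loop)
    ln_p = _dp.forward_ln(obs, lem, lt, lb, ln_eta, ln_leave)
    if not math.isfinite(ln_p):
        return float("-inf")
    return (ln_p - _ln_null(obs, lb, ln_eta, ln_leave)) / LN2


def sample_background(
    profile: ProfileHMM, length: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.choice(len(profile.background), size=length, p=profile.background)


def calibrate(
    profile: ProfileHMM,
    n_samples: int = 1000,
    sample_len: int = 350,
    seed: int = 0,
) -> CalibrationParams:
    """Fit a Gumbel law to Forward scores of random background sequences.

    Deterministic for a fixed seed.  Raises :class:`CalibrationError`
    when the score distribution is degenerate.
    """
    if n_samples < 100:
        raise InputError("n_samples must be >= 100")
    if sample_len < 1:
        raise InputError("sample_len must be >= 1")
    rng = np.random.default_rng(seed)
    lem, lt, lb = _ln_arrays(profile)
    ln_eta = math.log(profile.flank_loop)
    ln_leave = math.log1p(-profile.flank_loop)
    scores = np.empty(n_samples)
    for i in range(n_samples):
        obs = sample_background(profile, sample_len, rng)
        ln_p = _dp.forward_ln(obs, lem, lt, lb, ln_eta, ln_leave)
        scores[i] = (ln_p - _ln_null(obs, lb, ln_eta, ln_leave)) / LN2
    if not np.all(np.isfinite(scores)):
        raise CalibrationError("non-finite calibration scores; increase sample_len")
    if np.ptp(scores) < 1e-12:
        raise CalibrationError("degenerate (constant) calibration score distribution")
    loc, scale = _censored_gumbel_fit(scores)
    if scale <= 0 or not math.isfinite(scale):
        raise CalibrationError("Gumbel fit returned non-positive scale")
    return CalibrationParams(
        mu=float(loc),
        lam=float(1.0 / scale),
        n_samples=n_samples,
        sample_len=sample_len,
        seed=seed,
    )


def _censored_gumbel_fit(
    scores: np.ndarray, censor_frac: float = 0.5
) -> tuple[float, float]:
    """ML Gumbel fit with left-censoring at the ``censor_frac`` quantile.

    Whole-sample MLE is dominated by the bulk of the score distribution
    and systematically misfits the high-score tail that E-values depend
    on; censoring everything below the median (the classical calibration
    trick) restores tail coverage.  Returns (location, scale).
    """
    scores = np.asarray(scores, float)
    c = float(np.quantile(scores, censor_frac))
    tail = scores[scores > c]
    n_cens = scores.size - tail.size
    if tail.size < 10:
        raise CalibrationError("too few uncensored scores for the Gumbel tail fit")

    def nll(params: np.ndarray) -> float:
        mu, log_beta = params
        beta = math.exp(log_beta)
        z = (tail - mu) / beta
        ll = float(np.sum(-z - np.exp(-z)) - tail.size * log_beta)
        ll += n_cens * float(stats.gumbel_r.logcdf(c, mu, beta))
        return -ll

    loc0, scale0 = stats.gumbel_r.fit(scores)
    res = optimize.minimize(
        nll, np.array([loc0, math.log(max(scale0, 1e-9))]), method="Nelder-Mead"
    )
    if not res.success:
        raise CalibrationError(f"Gumbel tail fit did not converge: {res.message}")
    return float(res.x[0]), float(math.exp(res.x[1]))


def gumbel_tail(bit_score: float, calib: CalibrationParams) -> float:
    """P(S > bit_score) under the fitted Gumbel law."""
    u = math.exp(-calib.lam * (bit_score - calib.mu))
    return -math.expm1(-u)


def evalue(bit_score: float, calib: CalibrationParams, db_size: int) -> float:
    """Expected number of scores >= ``bit_score`` in ``db_size`` searches."""
    if db_size <= 0:
        raise InputError("db_size must be a positive integer")
    return db_size * gumbel_tail(bit_score, calib)


def best_hit(
    profile: ProfileHMM, seq_id: str, seq: str, db_size: int
) -> DomainHit | None:
    """Score one sequence, returning its hit or ``None`` if unalignable.

    The bit score and E-value come from the Forward score; the envelope
    from the Viterbi path.  Requires a calibrated profile.
    """
    if profile.calibration is None:
        raise ValueError(f"profile {profile.name!r} is not calibrated")
    fwd = score_forward(profile, seq)
    if not math.isfinite(fwd):
        return None
    _, (start, end) = score_viterbi(profile, seq)
    return DomainHit(
        seq_id=seq_id,
        profile_name=profile.name,
        start=start,
        end=end,
        bit_score=fwd,
        e_value=evalue(fwd, profile.calibration, db_size),
    )
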