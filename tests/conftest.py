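import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from famscan.profile import DEFAULT_TRANSITIONS, N_AA, ProfileHMM, uniform_background
from famscan.msa import AA_INDEX


def make_point_profile(
    consensus: str,
    name: str = "point",
    transitions: tuple[float, ...] | None = None,
) -> ProfileHMM:
    """Point-mass emission profile over a consensus string."""
    M = len(consensus)
    emis = np.zeros((M, N_AA))
    for k, ch in enumerate(consensus):
        emis[k, AA_INDEX[ch]] = 1.0
    t = np.tile(np.asarray(transitions or DEFAULT_TRANSITIONS), (M, 1))
    prof = ProfileHMM(
        name=name,
        match_emissions=emis,
        insert_emissions=uniform_background(),
        transitions=t,
        background=uniform_background(),
    )
    prof.validate()
    return prof


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_profile():
    from famscan.msa import MSA
    from famscan.profile import build_profile

    msa = MSA(
        ids=["s1", "s2", "s3", "s4"],
        rows=["ACDWK", "ACDWK", "ACEWK", "GCDWK"],
    )
    return build_profile(msa, name="small")


@pytest.fixture(scope="session")
def calibrated_family(rng):
    """A specific synthetic family profile calibrated once per session."""
    from famscan.scoring import calibrate
    from famscan.simulate import make_random_profile

    prof = make_random_profile(length=40, concentration=0.05, seed=7)
    return prof.with_calibration(calibrate(prof, n_samples=200, sample_len=120, seed=7))
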