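import numpy as np
import pytest

from famscan.architecture import (
    ArchitectureCall,
    detect_architecture,
    detect_architectures,
    summarize_architectures,
)
from famscan.classify import ConfigurationError, TaxonomyMap
from famscan.scoring import calibrate
from famscan.simulate import (
    make_fusions,
    make_random_profile,
    random_residues,
    sample_from_profile,
    shuffle_residues,
)


@pytest.fixture(scope="module")
def nc_profiles():
    n_prof = make_random_profile(length=50, concentration=0.05, seed=21)
    c_prof = make_random_profile(length=45, concentration=0.05, seed=22)
    n_prof.name, c_prof.name = "Ndom", "Cdom"
    calib = dict(n_samples=200, sample_len=150, seed=2)
    return (
        n_prof.with_calibration(calibrate(n_prof, **calib)),
        c_prof.with_calibration(calibrate(c_prof, **calib)),
    )


class TestDetectArchitecture:
    def test_planted_fusion_is_bi_domain(self, nc_profiles, rng):
        n_prof, c_prof = nc_profiles
        fusion = (
            sample_from_profile(n_prof, rng)
            + random_residues(10, rng)
            + sample_from_profile(c_prof, rng)
        )
        call = detect_architecture(("f1", fusion), n_prof, c_prof, 0.01, db_size=100)
        assert call.label == "bi-domain"
        assert call.n_hit.start < call.c_hit.start

    def test_n_sample_alone_is_n_only(self, nc_profiles, rng):
        n_prof, c_prof = nc_profiles
        call = detect_architecture(
            ("n1", sample_from_profile(n_prof, rng)), n_prof, c_prof, 0.01, db_size=100
        )
        assert call.label == "N-only"

    def test_c_sample_alone_is_c_only(self, nc_profiles, rng):
        n_prof, c_prof = nc_profiles
        call = detect_architecture(
            ("c1", sample_from_profile(c_prof, rng)), n_prof, c_prof, 0.01, db_size=100
        )
        assert call.label == "C-only"

    def test_decoy_is_none(self, nc_profiles, rng):
        n_prof, c_prof = nc_profiles
        seq = shuffle_residues(sample_from_profile(n_prof, rng), rng)
        call = detect_architecture(("d1", seq), n_prof, c_prof, 0.01, db_size=100)
        assert call.label == "none"

    def test_full_overlap_resolved_to_higher_score(self, rng):
        # the same model under two names hits the same span: overlap 1.0
        from dataclasses import replace

        prof = make_random_profile(length=40, concentration=0.05, seed=33)
        calib = calibrate(prof, n_samples=200, sample_len=120, seed=3)
        a = replace(prof, name="A", calibration=calib)
        b = replace(prof, name="B", calibration=calib)
        seq = sample_from_profile(prof, rng)
        call = detect_architecture(("x", seq), a, b, 0.01, db_size=100)
        assert call.label in {"N-only", "C-only"}
        assert "overlap" in call.note

    def test_identical_profile_names_rejected(self, nc_profiles):
        n_prof, _ = nc_profiles
        with pytest.raises(ConfigurationError):
            detect_architecture(("x", "ACDW"), n_prof, n_prof)

    def test_c_removal_flips_to_n_only(self, nc_profiles, rng):
        n_prof, c_prof = nc_profiles
        npart = sample_from_profile(n_prof, rng)
        fusion = npart + random_residues(10, rng) + sample_from_profile(c_prof, rng)
        assert (
            detect_architecture(("f", fusion), n_prof, c_prof, 0.01, db_size=100).label
            == "bi-domain"
        )
        truncated = fusion[: len(npart)]
        assert (
            detect_architecture(("t", truncated), n_prof, c_prof, 0.01, db_size=100).label
            == "N-only"
        )

    def test_make_fusions_all_detected(self, nc_profiles):
        n_prof, c_prof = nc_profiles
        fusions, truth = make_fusions(n_prof, c_prof, linker_len=10, n=8, seed=4)
        assert len(truth) == 8
        calls = detect_architectures(fusions, n_prof, c_prof, 0.01)
        assert all(c.label == "bi-domain" for c in calls)

    def test_intersection_oracle(self, nc_profiles, rng):
        # bi-domain ids = (N-hit ids ∩ C-hit ids) minus overlap/order-resolved
        from famscan.scoring import best_hit

        n_prof, c_prof = nc_profiles
        seqs = []
        fusions, _ = make_fusions(n_prof, c_prof, linker_len=8, n=6, seed=9)
        seqs.extend(fusions)
        for i in range(6):
            seqs.append((f"n{i}", sample_from_profile(n_prof, rng)))
            seqs.append((f"c{i}", sample_from_profile(c_prof, rng)))
            seqs.append((f"r{i}", random_residues(70, rng)))
        db_size = len(seqs)
        calls = detect_architectures(seqs, n_prof, c_prof, 0.01, db_size=db_size)
        bi = {c.seq_id for c in calls if c.label == "bi-domain"}
        resolved = {c.seq_id for c in calls if c.note}

        n_ids = set()
        c_ids = set()
        for sid, seq in seqs:
            h = best_hit(n_prof, sid, seq, db_size)
            if h and h.e_value < 0.01:
                n_ids.add(sid)
            h = best_hit(c_prof, sid, seq, db_size)
            if h and h.e_value < 0.01:
                c_ids.add(sid)
        assert bi == (n_ids & c_ids) - resolved


class TestSummarize:
    def test_empty(self):
        table = summarize_architectures([], TaxonomyMap())
        assert table.to_numpy().sum() == 0

    def test_hand_count(self):
        calls = [
            ArchitectureCall("s1", "bi-domain"),
            ArchitectureCall("s2", "bi-domain"),
            ArchitectureCall("s3", "C-only"),
        ]
        tm = TaxonomyMap(pairs={"s1": "Viridiplantae", "s2": "Viridiplantae", "s3": "Metazoa"})
        table = summarize_architectures(calls, tm)
        assert table.loc["bi-domain", "Viridiplantae"] == 2
        assert table.loc["C-only", "Metazoa"] == 1

    def test_cells_sum_to_call_count(self, rng):
        labels = ["N-only", "C-only", "bi-domain", "none"]
        calls = [
            ArchitectureCall(f"s{i}", labels[int(rng.integers(0, 4))])
            for i in range(37)
        ]
        table = summarize_architectures(calls, TaxonomyMap())
        assert table.to_numpy().sum() == 37
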