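"""Profile-HMM engine: model building, scoring, domains, calibration, I/O."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_protein
from oracle_phmm import enumerate_scores
from wyldomkit.msa_core import Alignment, SequenceRecord
from wyldomkit.phmm_engine import (
    SearchThresholds,
    assign_match_columns,
    build_profile,
    calibrate,
    encode,
    evalue,
    find_domains,
    forward_score,
    random_background_sequence,
    read_hmm,
    scan,
    search,
    viterbi,
    viterbi_score,
    write_hmm,
)


def small_model(M, seed=0, nrows=3, alphabet="ACDE"):
    rng = np.random.default_rng(seed)
    rows = ["".join(rng.choice(list(alphabet), size=M)) for _ in range(nrows)]
    return build_profile(
        Alignment([(f"r{i}", r) for i, r in enumerate(rows)]), name=f"m{M}"
    )


class TestModelConstruction:
    def test_gapfree_alignment_all_match(self, toy_alignment):
        mask = assign_match_columns(toy_alignment)
        assert mask.all() and len(mask) == toy_alignment.n_columns

    def test_majority_gap_column_is_insert(self):
        aln = Alignment([("a", "A-"), ("b", "A-"), ("c", "A-"), ("d", "AC")])
        mask = assign_match_columns(aln, 0.5)
        assert mask.tolist() == [True, False]

    def test_no_match_columns_errors(self):
        aln = Alignment([("a", "A-"), ("b", "-C")])
        with pytest.raises(ValueError, match="curate"):
            assign_match_columns(aln)

    def test_single_sequence_low_pseudocount_approaches_indicator(self):
        aln = Alignment([("a", "ACD")])
        m = build_profile(aln, pseudocount_weight=1e-9)
        assert np.allclose(m.match_emissions.max(axis=1), 1.0, atol=1e-6)
        assert m.consensus() == "ACD"

    def test_emission_rows_normalized_random_alignments(self, rng):
        for _ in range(100):
            n, L = int(rng.integers(1, 6)), int(rng.integers(2, 12))
            rows = []
            for i in range(n):
                chars = [
                    "-" if rng.random() < 0.2 else random_protein(rng, 1)
                    for _ in range(L)
                ]
                rows.append((f"r{i}", "".join(chars)))
            aln = Alignment(rows)
            try:
                m = build_profile(aln)
            except ValueError:
                continue  # all columns gappy: nothing to model
            m.validate()
            assert m.M == int(assign_match_columns(aln).sum())


class TestScoringOracle:
    """DP scores must equal brute-force path enumeration on small problems."""

    @pytest.mark.parametrize("M", [1, 2, 3])
    def test_exhaustive_small_alphabet(self, M):
        model = small_model(M, seed=M)
        for L in range(1, 4):
            for combo in itertools.product("ACDE", repeat=L):
                seq = SequenceRecord("q", "".join(combo))
                enc = encode(seq.residues)
                for multihit in (True, False):
                    ov, of = enumerate_scores(model, enc, multihit)
                    assert viterbi_score(model, seq, multihit) == pytest.approx(
                        ov, abs=1e-9
                    )
                    assert forward_score(model, seq, multihit) == pytest.approx(
                        of, abs=1e-9
                    )

    def test_m5_length8(self):
        model = small_model(5, seed=5)
        rng = np.random.default_rng(2)
        seqs = ["ACDEACDE", "AACCDDEE"] + [
            "".join(rng.choice(list("ACDE"), size=8)) for _ in range(2)
        ]
        for s in seqs:
            seq = SequenceRecord("q", s)
            ov, of = enumerate_scores(model, encode(s), True)
            assert viterbi_score(model, seq) == pytest.approx(ov, abs=1e-9)
            assert forward_score(model, seq) == pytest.approx(of, abs=1e-9)


class TestScoreProperties:
    def test_consensus_beats_noise(self, toy_model):
        good = viterbi_score(toy_model, SequenceRecord("q", "ACDEFGHIKL"))
        bad = viterbi_score(toy_model, SequenceRecord("q", "WWWWWWWWWW"))
        assert good > bad

    def test_score_ignores_metadata(self, toy_model):
        a = SequenceRecord("x", "ACDEFGHIKL", taxon_id="t1")
        b = SequenceRecord("y", "ACDEFGHIKL", taxon_id="t2")
        assert viterbi_score(toy_model, a) == viterbi_score(toy_model, b)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25))
    def test_forward_at_least_viterbi(self, s):
        model = small_model(4, seed=9, alphabet="ACDEFGHIKL")
        seq = SequenceRecord("q", s)
        for multihit in (True, False):
            assert forward_score(model, seq, multihit) >= (
                viterbi_score(model, seq, multihit) - 1e-9
            )

    def test_doubling_never_decreases_multihit_forward(self, toy_model, rng):
        for t in range(12):
            s = random_protein(rng, int(rng.integers(5, 30)))
            if t % 3 == 0:
                s = s[:3] + "ACDEFGHIKL" + s[3:]
            f1 = forward_score(toy_model, SequenceRecord("q", s))
            f2 = forward_score(toy_model, SequenceRecord("q", s + s))
            assert f2 >= f1 - 1e-9


class TestDomains:
    def test_two_planted_copies(self, toy_model):
        linker = "W" * 50
        s = "W" * 20 + "ACDEFGHIKL" + linker + "ACDEFGHIKL" + "W" * 20
        hits = find_domains(toy_model, SequenceRecord("q", s), db_size=10)
        assert len(hits) == 2
        for h, start in zip(hits, (21, 81)):
            assert abs(h.env_start - start) <= 5
            assert abs(h.env_end - (start + 9)) <= 5

    def test_envelope_nesting_invariant(self, toy_model, rng):
        for _ in range(10):
            s = random_protein(rng, 60) + "ACDEFGHIKL" + random_protein(rng, 60)
            for h in find_domains(toy_model, SequenceRecord("q", s)):
                assert 1 <= h.env_start <= h.ali_start <= h.ali_end <= h.env_end
                assert h.env_end <= len(s)
                assert 1 <= h.hmm_start <= h.hmm_end <= toy_model.M

    def test_background_noise_yields_no_included_hits(self, toy_model, rng):
        th = SearchThresholds.scan_defaults()
        n_included = 0
        for _ in range(20):
            seq = SequenceRecord("q", random_protein(rng, 200))
            n_included += sum(h.included for h in scan([toy_model], seq, th))
        assert n_included == 0

    def test_hits_sorted_and_nonoverlapping_core(self, toy_model):
        s = "W" * 10 + "ACDEFGHIKL" + "W" * 30 + "ACDEFGHIKL" + "W" * 10
        hits = find_domains(toy_model, SequenceRecord("q", s))
        starts = [h.env_start for h in hits]
        assert starts == sorted(starts)
        for a, b in zip(hits, hits[1:]):
            assert a.ali_end < b.ali_start


class TestCalibrationAndEvalues:
    def test_reproducible(self, toy_alignment):
        m1 = build_profile(toy_alignment, name="t")
        m2 = build_profile(toy_alignment, name="t")
        c1 = calibrate(m1, n_random=120, length=60, seed=3)
        c2 = calibrate(m2, n_random=120, length=60, seed=3)
        assert c1 == c2

    def test_requires_enough_samples(self, toy_model):
        with pytest.raises(ValueError):
            calibrate(toy_model, n_random=10, length=50, seed=0)

    def test_evalue_closed_form_at_mu(self, toy_model):
        mu, _ = toy_model.calibration
        assert evalue(mu, toy_model, 1) == pytest.approx(1 - np.exp(-1), rel=1e-6)

    def test_evalue_scales_linearly_and_monotone(self, toy_model):
        e1 = evalue(10.0, toy_model, 1)
        assert evalue(10.0, toy_model, 500) == pytest.approx(500 * e1, rel=1e-9)
        assert evalue(20.0, toy_model, 1) < e1

    def test_uncalibrated_errors(self, toy_alignment):
        m = build_profile(toy_alignment)
        with pytest.raises(ValueError):
            evalue(10.0, m, 1)

    def test_tail_matches_heldout_exceedance(self, toy_model):
        rng = np.random.default_rng(77)
        mu, lam = toy_model.calibration
        from scipy import stats

        x90 = stats.gumbel_r.ppf(0.9, loc=mu, scale=1 / lam)
        n = 300
        exceed = sum(
            viterbi_score(toy_model, SequenceRecord("q", random_background_sequence(rng, 80))) > x90
            for _ in range(n)
        )
        p = 0.1
        se = np.sqrt(p * (1 - p) / n)
        assert abs(exceed / n - p) < 4 * se

    def test_consensus_far_in_tail(self, toy_model):
        s = viterbi_score(toy_model, SequenceRecord("q", toy_model.consensus()))
        assert evalue(s, toy_model, 10_000) < 1e-6


class TestSearchScan:
    def test_thresholds_validation_and_defaults(self):
        assert SearchThresholds.search_defaults() == SearchThresholds(1, 1, 0.01, 0.03)
        assert SearchThresholds.scan_defaults() == SearchThresholds(0.1, 0.1, 0.01, 0.03)
        with pytest.raises(ValueError):
            SearchThresholds(0.01, 1, 1, 0.03)
        with pytest.raises(ValueError):
            SearchThresholds(-1, 1, 0.01, 0.03)

    def test_empty_database(self, toy_model):
        assert search(toy_model, []) == []

    def test_planted_database_separation(self, toy_model, rng):
        planted, background = [], []
        for i in range(100):
            flank = random_protein(rng, 40)
            planted.append(
                SequenceRecord(f"p{i}", flank + "ACDEFGHIKL" + random_protein(rng, 40))
            )
            background.append(SequenceRecord(f"b{i}", random_protein(rng, 90)))
        results = search(toy_model, planted + background)
        included = {r.sequence_id for r in results if r.included}
        assert included == {f"p{i}" for i in range(100)}

    def test_scan_wrong_library_no_inclusions(self, toy_model, rng):
        seq = SequenceRecord("q", random_protein(rng, 150))
        hits = scan([toy_model], seq)
        assert all(not h.included for h in hits)

    def test_scan_ordered_architecture(self, reference_models, library, rng):
        parts = [random_protein(rng, 20)]
        for name in ("HTHwB", "WYL", "WCX"):
            parts.append(library[name].consensus)
            parts.append(random_protein(rng, 20))
        seq = SequenceRecord("q", "".join(parts))
        hits = [h for h in scan(reference_models, seq) if h.included]
        assert [h.clan for h in hits] == ["HTH", "WYL", "WCX"]


class TestHmmFileFormat:
    def test_roundtrip_full_precision(self, toy_model, tmp_path):
        path = tmp_path / "toy.hmm"
        toy_model.gathering_threshold = 27.0
        write_hmm(toy_model, path)
        back = read_hmm(path)
        assert back.name == toy_model.name
        assert back.M == toy_model.M
        assert back.calibration == toy_model.calibration
        assert back.gathering_threshold == 27.0
        np.testing.assert_array_equal(back.match_emissions, toy_model.match_emissions)
        for f in ("tmm", "tmi", "tmd", "tim", "tii", "tdm", "tdd", "background"):
            np.testing.assert_array_equal(getattr(back, f), getattr(toy_model, f))

    def test_rejects_other_files(self, tmp_path):
        p = tmp_path / "x.hmm"
        p.write_text("HMMER3/f\n")
        with pytest.raises(ValueError):
            read_hmm(p)
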