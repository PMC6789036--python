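"""Seed maturation: stratification, curation, boundaries, iteration."""

import numpy as np
import pytest

from wyldomkit.hmm_maturation import (
    MaturationConfig,
    MaturationError,
    SeedAlignment,
    curate_seed,
    define_boundaries,
    mature_hmm,
    model_checksum,
    split_wing_groups,
    stratified_sample,
)
from wyldomkit.msa_core import Alignment, SequenceRecord, progressive_align
from wyldomkit.phmm_engine import DomainHit
from wyldomkit.synthetic_data import (
    GeneratorConfig,
    PhylumSpec,
    emit_collection,
    mutate_instance,
    seed_instances,
)


def hit(seq_id, env_start, env_end, score=50.0, ieval=1e-6):
    return DomainHit(
        sequence_id=seq_id, model_name="m", clan="m",
        env_start=env_start, env_end=env_end,
        ali_start=env_start, ali_end=env_end,
        hmm_start=1, hmm_end=2, bit_score=score, i_evalue=ieval,
    )


class TestConfig:
    def test_wyl_defaults(self):
        cfg = MaturationConfig()
        assert cfg.length_threshold == 127
        assert cfg.n_per_stratum == 250
        assert cfg.cluster_identity == 0.70
        assert cfg.gathering_threshold == 27.0
        assert cfg.iterations == 3

    def test_presets(self):
        hth = MaturationConfig.hth()
        assert (hth.cluster_identity, hth.iterations, hth.gathering_threshold) == (
            0.90, 1, 30.0
        )
        wcx = MaturationConfig.wcx()
        assert (wcx.iterations, wcx.gathering_threshold) == (0, 30.0)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = MaturationConfig(seed=9, iterations=2)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert MaturationConfig.from_yaml(p) == cfg


class TestStratifiedSample:
    def test_threshold_assignment(self):
        cfg = MaturationConfig(seed=0)
        hits = [hit("long", 1, 150), hit("short", 1, 100), hit("tie", 1, 127)]
        long_ids, short_ids = stratified_sample(hits, cfg)
        assert long_ids == ["long"]
        assert sorted(short_ids) == ["short", "tie"]

    def test_small_stratum_taken_whole(self):
        cfg = MaturationConfig(seed=1)
        hits = [hit(f"s{i}", 1, 200) for i in range(80)]
        long_ids, short_ids = stratified_sample(hits, cfg)
        assert len(long_ids) == 80 and len(set(long_ids)) == 80
        assert short_ids == []

    def test_partition_and_reproducible(self):
        rng = np.random.default_rng(4)
        hits = [hit(f"s{i}", 1, int(rng.integers(60, 200))) for i in range(40)]
        cfg = MaturationConfig(seed=5, n_per_stratum=10)
        a = stratified_sample(hits, cfg)
        b = stratified_sample(hits, cfg)
        assert a == b
        all_ids = {h.sequence_id for h in hits}
        long_all = {h.sequence_id for h in hits if h.env_length > 127}
        assert set(a[0]) <= long_all and set(a[1]) <= all_ids - long_all


class TestCurateSeed:
    def test_intact_rows_kept(self):
        aln = Alignment([(f"r{i}", "ACDEFGHIKL") for i in range(5)])
        out = curate_seed(aln, MaturationConfig())
        assert out.n_rows == 5

    def test_truncated_instance_dropped(self):
        rows = [(f"r{i}", "ACDEFGHIKL") for i in range(5)]
        rows.append(("trunc", "ACDEF-----"))  # missing the C-terminal half
        out = curate_seed(Alignment(rows), MaturationConfig())
        assert "trunc" not in out.ids
        assert out.n_rows == 5

    def test_idempotent(self):
        rows = [(f"r{i}", "ACDEFGHIKL") for i in range(4)]
        rows += [("bad", "A---------"), ("ok", "ACDE-GHIKL")]
        cfg = MaturationConfig()
        once = curate_seed(Alignment(rows), cfg)
        twice = curate_seed(once, cfg)
        assert twice.rows == once.rows

    def test_all_dropped_errors(self):
        aln = Alignment([("a", "AC--------"), ("b", "--------KL")])
        with pytest.raises(MaturationError):
            curate_seed(aln, MaturationConfig())


class TestDefineBoundaries:
    def test_unanimous_short_ends(self):
        aln = Alignment([(f"r{i}", "ACDEFGHIKL") for i in range(4)])
        assert define_boundaries(aln, [7, 7, 7]) == (1, 7)

    def test_even_count_median_floor(self):
        aln = Alignment([(f"r{i}", "A" * 25) for i in range(4)])
        assert define_boundaries(aln, [10, 20])[1] == 15

    def test_inverted_errors(self):
        aln = Alignment([(f"r{i}", "ACDEFGHIKL") for i in range(4)])
        with pytest.raises((MaturationError, ValueError)):
            define_boundaries(aln, [1])
        with pytest.raises(ValueError):
            define_boundaries(aln, [])


def composite_replicate(rep_seed, library, n_species=20):
    """Shared helper: composite collection + split recovery + maturation."""
    from wyldomkit.phmm_engine import build_profile, calibrate, search
    from wyldomkit.synthetic_data import DomainArchetype

    composite = DomainArchetype(
        "COMPOSITE", "WYL", library["WYL"].consensus + library["WCX"].consensus
    )
    cfg = GeneratorConfig(
        seed=rep_seed,
        phyla=[PhylumSpec("Actino", n_species, 2.0)],
        composite_mode=True,
        background_proteins_per_species=1,
    )
    coll = emit_collection(cfg, library)
    insts = seed_instances(composite, 15, 0.15, 0.02, seed=rep_seed + 1000)
    m0 = build_profile(progressive_align(insts), name="COMPOSITE", clan="WYL")
    calibrate(m0, n_random=150, length=300, seed=rep_seed + 2000)
    results = search(m0, coll.records)
    hits = [
        h for r in results for h in r.hits
        if h.bit_score > 30.0 and h.i_evalue < 0.001
    ]
    mcfg = MaturationConfig(seed=rep_seed)
    long_ids, short_ids = stratified_sample(hits, mcfg)
    by_seq = {}
    for h in hits:
        by_seq.setdefault(h.sequence_id, h)
    by_id = {r.id: r for r in coll.records}
    sampled = [
        SequenceRecord(
            sid, by_id[sid].residues[by_seq[sid].env_start - 1 : by_seq[sid].env_end]
        )
        for sid in long_ids + short_ids
    ]
    aln = progressive_align(sampled)
    rowmap = dict(aln.rows)
    ends = [
        max(j for j, ch in enumerate(rowmap[sid]) if ch != "-") + 1
        for sid in short_ids
    ]
    start_col, end_col = define_boundaries(aln, ends)
    occ = aln.occupancy()
    recovered_len = int(np.sum(occ[start_col - 1 : end_col] >= 0.5))
    boundary_err = abs(recovered_len - library["WYL"].length)
    return coll, aln, start_col, end_col, boundary_err, mcfg


class TestMatureHmm:
    def test_composite_boundary_and_iteration(self, library):
        """One full replicate: split recovery then 3-iteration maturation."""
        coll, aln, start_col, end_col, err, mcfg = composite_replicate(3000, library)
        assert err <= 3
        seed = SeedAlignment(aln, start_col, end_col)
        report: list = []
        model = mature_hmm(coll.records, seed, mcfg, name="WYL", clan="WYL",
                           report=report)
        assert model.gathering_threshold == 27.0
        assert len(report) == mcfg.iterations + 1
        # recall of planted composite regions by the matured WYL model
        from wyldomkit.phmm_engine import search

        got = {
            r.sequence_id
            for r in search(model, coll.records)
            for h in r.hits
            if h.bit_score > mcfg.gathering_threshold
        }
        truth_ids = set(coll.truth["sequence_id"])
        assert len(got & truth_ids) / len(truth_ids) >= 0.95

    def test_zero_iterations_builds_from_seed(self, library):
        insts = seed_instances(library["WCX"], 12, 0.1, 0.0, seed=8)
        aln = progressive_align(insts)
        cfg = MaturationConfig.wcx(seed=2, calibration_n=100, calibration_length=150)
        model = mature_hmm([], SeedAlignment(aln, 1, aln.n_columns), cfg, name="WCX")
        assert model.gathering_threshold == 30.0
        assert abs(model.M - library["WCX"].length) <= 8

    def test_deterministic(self, library):
        insts = seed_instances(library["WCX"], 10, 0.1, 0.0, seed=8)
        aln = progressive_align(insts)
        db = [SequenceRecord("d1", library["WCX"].consensus)]
        cfg = MaturationConfig(seed=4, iterations=1, calibration_n=100,
                               calibration_length=150)
        m1 = mature_hmm(db, SeedAlignment(aln, 1, aln.n_columns), cfg)
        m2 = mature_hmm(db, SeedAlignment(aln, 1, aln.n_columns), cfg)
        assert model_checksum(m1) == model_checksum(m2)
        assert m1.calibration == m2.calibration

    def test_no_hits_reports_iteration(self, library):
        insts = seed_instances(library["WCX"], 10, 0.1, 0.0, seed=8)
        aln = progressive_align(insts)
        rng = np.random.default_rng(1)
        from conftest import random_protein

        db = [SequenceRecord(f"bg{i}", random_protein(rng, 200)) for i in range(5)]
        cfg = MaturationConfig(seed=4, iterations=2, calibration_n=100,
                               calibration_length=150)
        with pytest.raises(MaturationError) as exc:
            mature_hmm(db, SeedAlignment(aln, 1, aln.n_columns), cfg)
        assert exc.value.iteration == 1


class TestSplitWingGroups:
    def _two_archetype_alignment(self, library):
        rows = []
        for name, tag in (("HTHwB", "b"), ("HTHwC", "c")):
            for j in range(6):
                r = np.random.default_rng(j + (0 if tag == "b" else 50))
                rows.append(
                    SequenceRecord(
                        f"{tag}{j}",
                        mutate_instance(library[name].consensus, r, 0.05, 0.0),
                    )
                )
        return progressive_align(rows)

    def test_labels_respected(self, library):
        aln = self._two_archetype_alignment(library)
        labels = {rid: rid[0] for rid in aln.ids}
        g1, g2 = split_wing_groups(aln, labels=labels)
        got = {tuple(sorted(g.provenance)) for g in (g1, g2)}
        want = {
            tuple(sorted(r for r in aln.ids if r.startswith("b"))),
            tuple(sorted(r for r in aln.ids if r.startswith("c"))),
        }
        assert got == want

    def test_unsupervised_recovers_archetypes(self, library):
        aln = self._two_archetype_alignment(library)
        g1, g2 = split_wing_groups(aln)
        got = {tuple(sorted(g.provenance)) for g in (g1, g2)}
        want = {
            tuple(sorted(r for r in aln.ids if r.startswith("b"))),
            tuple(sorted(r for r in aln.ids if r.startswith("c"))),
        }
        assert got == want

    def test_bad_labels_rejected(self, library):
        aln = self._two_archetype_alignment(library)
        with pytest.raises(ValueError):
            split_wing_groups(aln, labels={rid: "same" for rid in aln.ids})
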