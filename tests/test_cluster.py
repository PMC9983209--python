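import numpy as np
import pytest

import eukbench as eb
from conftest import random_seq
from oracles import edlib_identity, sw_align


# ------------------------------------------------------------------ alignment


def test_identical_sequences_align_fully():
    s = random_seq(np.random.default_rng(1), 100)
    assert eb.local_align_identity(s, s) == (1.0, 1.0, 1.0)


def test_single_interior_mismatch_gives_099():
    s = random_seq(np.random.default_rng(2), 100)
    t = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
    ident, ca, cb = eb.local_align_identity(s, t)
    assert ident == pytest.approx(0.99)
    assert ca == cb == 1.0
    assert sw_align(s, t)[0] == pytest.approx(0.99)  # DP oracle


def test_strand_aware_alignment_finds_reverse_complement():
    s = random_seq(np.random.default_rng(3), 80)
    ident, ca, cb = eb.local_align_identity(s, eb.reverse_complement(s), strand_aware=True)
    assert ident == 1.0 and ca == 1.0 and cb == 1.0


def test_identity_symmetric_and_matches_oracles():
    rng = np.random.default_rng(4)
    for _ in range(10):
        a = random_seq(rng, int(rng.integers(60, 150)))
        b = eb.mutate_sequence(a, float(rng.uniform(0, 0.1)), seed=int(rng.integers(1e6)))
        ab = eb.local_align_identity(a, b)[0]
        ba = eb.local_align_identity(b, a)[0]
        assert ab == pytest.approx(ba)
        assert ab == pytest.approx(sw_align(a, b)[0], abs=1e-9)
        # independent cross-check with edlib on the full-length pair
        assert ab == pytest.approx(edlib_identity(a, b), abs=0.02)


def test_empty_and_alphabet_errors():
    with pytest.raises(ValueError):
        eb.local_align("", "ACGT")
    with pytest.raises(ValueError):
        eb.local_align_identity("MKV", "MKV", strand_aware=True, alphabet="protein")


# ----------------------------------------------------------------- clustering


def test_exact_duplicates_form_one_cluster():
    s = random_seq(np.random.default_rng(5), 200)
    recs = [eb.SequenceRecord("a", s), eb.SequenceRecord("b", s)]
    cl = eb.greedy_cluster(recs, eb.ClusteringParams(1.0, 1.0))
    assert len(cl) == 1 and sorted(cl[0].member_ids()) == ["a", "b"]


def test_97pct_pair_splits_under_98pct_threshold():
    rng = np.random.default_rng(6)
    a = random_seq(rng, 1000)
    b = eb.mutate_sequence(a, 0.03, seed=8)
    ident = sw_align(a, b)[0]
    assert ident < 0.98  # oracle confirms the pair sits below threshold
    cl = eb.greedy_cluster(
        [eb.SequenceRecord("a", a), eb.SequenceRecord("b", b)],
        eb.ClusteringParams(0.98, 0.8),
    )
    assert len(cl) == 2


def test_cluster_members_meet_thresholds_posthoc():
    """Every (member, representative) pair re-verified by the brute-force
    aligner meets both thresholds on a random near-duplicate fixture."""
    rng = np.random.default_rng(7)
    recs = []
    for i in range(60):
        base = random_seq(rng, int(rng.integers(150, 300)))
        recs.append(eb.SequenceRecord(f"s{i}", base))
        if i % 2 == 0:
            rate = float(rng.choice([0.0, 0.005, 0.01, 0.05]))
            recs.append(
                eb.SequenceRecord(f"s{i}d", eb.mutate_sequence(base, rate, seed=i))
            )
    params = eb.ClusteringParams(0.98, 0.8)
    clusters = eb.greedy_cluster(recs, params)
    by_id = {r.id: r.seq for r in recs}
    for c in clusters:
        for member, ident, cov in c.members:
            if member == c.representative:
                continue
            o_ident, o_ca, o_cb = sw_align(by_id[member], by_id[c.representative])
            shorter_cov = o_ca if len(by_id[member]) <= len(by_id[c.representative]) else o_cb
            assert o_ident >= params.min_identity
            assert shorter_cov >= params.min_coverage
            assert ident == pytest.approx(o_ident, abs=1e-9)


def test_clustering_invariant_to_input_order():
    rng = np.random.default_rng(8)
    recs = []
    for i in range(40):
        base = random_seq(rng, int(rng.integers(150, 250)))
        recs.append(eb.SequenceRecord(f"s{i}", base))
        recs.append(eb.SequenceRecord(f"s{i}d", eb.mutate_sequence(base, 0.01, seed=i)))
    params = eb.ClusteringParams(0.98, 0.8)
    a = {c.representative: frozenset(c.member_ids()) for c in eb.greedy_cluster(recs, params)}
    b = {
        c.representative: frozenset(c.member_ids())
        for c in eb.greedy_cluster(list(reversed(recs)), params)
    }
    assert a == b


# --------------------------------------------------------------------- merges


def test_merge_assemblies_concatenates_with_provenance():
    rng = np.random.default_rng(9)
    a1 = [eb.SequenceRecord(f"x{i}", random_seq(rng, 100)) for i in range(10)]
    a2 = [eb.SequenceRecord(f"y{i}", random_seq(rng, 100)) for i in range(15)]
    agm, prov = eb.merge_assemblies({"spades": a1, "megahit": a2, "empty": []}, "g1")
    assert len(agm) == 25 and len(prov) == 25
    assert all(r.id.startswith("g1_") for r in agm)
    labels = {prov.loc[prov.contig_id == r.id, "assembler"].item() for r in agm}
    assert labels == {"spades", "megahit"}


def test_merge_rejects_id_collisions():
    r = eb.SequenceRecord("c_1", "ACGT" * 30)
    with pytest.raises(ValueError, match="collision"):
        eb.merge_assemblies({"a": [r], "a_c": [eb.SequenceRecord("1", "ACGT" * 30)]}, "g")


def test_dedup_removes_exact_substring_and_is_idempotent():
    rng = np.random.default_rng(10)
    long = random_seq(rng, 400)
    recs = [
        eb.SequenceRecord("long", long),
        eb.SequenceRecord("sub", long[100:250]),
        eb.SequenceRecord("other", random_seq(rng, 300)),
    ]
    dd = eb.dedup_identical(recs)
    assert sorted(r.id for r in dd) == ["long", "other"]
    assert [r.id for r in eb.dedup_identical(dd)] == [r.id for r in dd]


def test_dedup_keeps_all_unique_contigs():
    rng = np.random.default_rng(11)
    recs = [eb.SequenceRecord(f"u{i}", random_seq(rng, 200)) for i in range(30)]
    dd = eb.dedup_identical(recs)
    assert len(dd) == 30
    # brute-force all-pairs containment check: nothing is contained
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            ident, ca, cb = sw_align(a.seq, b.seq)
            short_cov = ca if len(a.seq) <= len(b.seq) else cb
            assert not (ident == 1.0 and short_cov == 1.0)


def test_cag_collapses_99pct_but_not_95pct_twins():
    rng = np.random.default_rng(12)
    base99 = random_seq(rng, 600)
    base95 = random_seq(rng, 600)
    recs = [
        eb.SequenceRecord("a", base99 + "ACGTACGT"),  # longer twin retained
        eb.SequenceRecord("a99", eb.mutate_sequence(base99, 0.01, seed=1)),
        eb.SequenceRecord("b", base95 + "ACGTACGT"),
        eb.SequenceRecord("b95", eb.mutate_sequence(base95, 0.05, seed=2)),
    ]
    cag, clusters = eb.build_cag(recs)
    ids = {r.id for r in cag}
    assert "a99" not in ids and {"a", "b", "b95"} <= ids
    assert len(cag) <= len(recs)


def test_mad_merging_properties():
    rng = np.random.default_rng(13)
    cag1 = [eb.SequenceRecord(f"c{i}", random_seq(rng, 250)) for i in range(10)]
    mad_single, _ = eb.build_mad([cag1])
    assert {r.id for r in mad_single} == {r.id for r in cag1}
    mad_dup, _ = eb.build_mad([cag1, cag1])
    assert len(mad_dup) == len(cag1)
    cag2 = [eb.SequenceRecord(f"d{i}", random_seq(rng, 250)) for i in range(5)]
    mad_two, _ = eb.build_mad([cag1, cag2])
    assert len(mad_two) <= len(cag1) + len(cag2)
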