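import numpy as np
import pytest

import eukbench as eb
from conftest import random_seq
from oracles import (
    n50_bruteforce,
    ols_normal_equations,
    orf_scan,
    revcomp,
    sw_align,
    welch_formula,
)

# ----------------------------------------------------------------------- ORFs


def _orf_free(rng, n):
    """Random sequence long enough that chance ORFs >= 100 aa are unlikely."""
    return random_seq(rng, n)


def test_reverse_strand_orf_found_with_exact_coordinates():
    rng = np.random.default_rng(41)
    codons = [c for c in eb.panels._CODONS if c != "ATG"]
    inner = "ATG" + "".join(codons[int(i)] for i in rng.integers(0, len(codons), 149)) + "TAA"
    flank5, flank3 = random_seq(rng, 47), random_seq(rng, 31)
    contig = flank5 + revcomp(inner) + flank3
    hits = eb.find_orfs(contig, min_aa=100)
    scan = orf_scan(contig, min_aa=100)
    assert {(o.strand, o.start, o.end) for o in hits} == scan
    rev_hits = [o for o in hits if o.strand == -1]
    assert len(rev_hits) == 1
    o = rev_hits[0]
    assert (o.start, o.end) == (len(flank5), len(flank5) + len(inner))
    assert len(o.protein) == 150 and "*" not in o.protein


def test_orf_requires_start_and_min_length():
    rng = np.random.default_rng(42)
    no_atg = "".join("CG"[int(i)] for i in rng.integers(0, 2, 400))
    assert eb.find_orfs(no_atg, min_aa=10, require_start=True) == []
    short = "ATG" + "GCA" * 50 + "TAA"  # 51 aa
    assert eb.find_orfs(short, min_aa=100) == []
    assert len(eb.find_orfs(short, min_aa=40)) >= 1


def test_orf_scan_agrees_with_bruteforce_on_random_contigs():
    rng = np.random.default_rng(43)
    for _ in range(10):
        contig = random_seq(rng, int(rng.integers(300, 900)))
        got = {(o.strand, o.start, o.end) for o in eb.find_orfs(contig, min_aa=30)}
        assert got == orf_scan(contig, min_aa=30)


# ---------------------------------------------------------------- statistics


def test_n50_by_definition_scan():
    recs = [eb.SequenceRecord(f"c{i}", "A" * l) for i, l in enumerate([10, 9, 8, 7, 5])]
    st = eb.assembly_stats(recs)
    assert st.n50 == 8 == n50_bruteforce([10, 9, 8, 7, 5])
    assert eb.n50([42]) == 42
    assert eb.n50([7] * 13) == 7


def test_assembly_stats_fields(designer):
    _, records, _ = designer
    st = eb.assembly_stats(records)
    assert st.min_length <= st.mean_length <= st.max_length
    assert st.min_length <= st.n50 <= st.max_length
    assert len(st.gc_fractions) == st.n_contigs
    assert st.n50 == n50_bruteforce([len(r) for r in records])
    with pytest.raises(ValueError):
        eb.assembly_stats([])


def test_n50_matches_bruteforce_on_random_lengths():
    rng = np.random.default_rng(44)
    for _ in range(20):
        lengths = rng.integers(100, 3000, size=int(rng.integers(2, 40))).tolist()
        assert eb.n50(lengths) == n50_bruteforce(lengths)


# --------------------------------------------------------------- pseudo-mapping


def test_pseudomap_error_free_reads_all_map(designer):
    _, records, manifest = designer
    r1, r2, _ = eb.simulate_reads(
        records, manifest.weight.tolist(), n_pairs=400,
        quality=eb.QualityProfile.error_free(), seed=4,
    )
    pct, counts, tpm = eb.pseudomap(r1 + r2, records)
    assert pct == 100.0
    assert counts.sum() == 800
    assert tpm.sum() == pytest.approx(1e6)


def test_pseudomap_random_reads_do_not_map():
    rng = np.random.default_rng(45)
    contigs = [eb.SequenceRecord(f"c{i}", random_seq(rng, 500)) for i in range(5)]
    reads = [eb.SequenceRecord(f"r{i}", random_seq(rng, 75)) for i in range(300)]
    pct, _, _ = eb.pseudomap(reads, contigs)
    assert pct == 0.0
    with pytest.raises(ValueError):
        eb.pseudomap(reads, contigs, k=80)


def test_pseudomap_monotone_under_contig_removal(designer):
    _, records, manifest = designer
    r1, r2, _ = eb.simulate_reads(
        records, manifest.weight.tolist(), n_pairs=300,
        quality=eb.QualityProfile.error_free(), seed=5,
    )
    reads = r1 + r2
    pcts = [eb.pseudomap(reads, records[:n])[0] for n in (len(records), 30, 15, 5)]
    assert all(a >= b for a, b in zip(pcts, pcts[1:]))


# ------------------------------------------------------------ protein recovery


def test_designer_self_recovery_is_complete(designer):
    _, records, _ = designer
    rep = eb.protein_recovery(records, records)
    assert rep.counts["unmatched"] == 0
    orf_bearing = rep.counts["matched"]
    assert orf_bearing + rep.counts["no_orf"] == len(records)
    assert orf_bearing == len(records)  # panel contigs are ORF-bearing
    matched = rep.per_contig[rep.per_contig.category == "matched"]
    assert all(
        row.contig_id in row.matched_designer_ids.split(";")
        for row in matched.itertuples()
    )


def test_random_extra_contig_is_unmatched_or_no_orf(designer):
    _, records, _ = designer
    rng = np.random.default_rng(46)
    extra = eb.SequenceRecord("random1k", random_seq(rng, 1000))
    rep = eb.protein_recovery(records, list(records) + [extra])
    row = rep.per_contig[rep.per_contig.contig_id == "random1k"]
    assert row.category.item() in ("unmatched", "no_orf")
    # oracle: no designer protein matches any ORF of the random contig
    designer_prots = [
        o.protein for r in records for o in eb.find_orfs(r.seq, min_aa=100)
    ]
    for orf in eb.find_orfs(extra.seq, min_aa=100):
        for dp in designer_prots:
            ident, _, cov_b = sw_align(orf.protein, dp)
            assert not (ident >= 0.90 and cov_b >= 0.90)


def test_matched_pairs_reverify_at_90pct_identity(designer):
    """Perturbed designer contigs that still match do so at >= 90% protein
    identity when re-aligned by the brute-force DP oracle."""
    _, records, _ = designer
    perturbed = [
        eb.SequenceRecord(r.id + "_m", eb.mutate_sequence(r.seq, 0.02, seed=i))
        for i, r in enumerate(records[:12])
    ]
    rep = eb.protein_recovery(records, perturbed)
    designer_prots = {
        r.id: [o.protein for o in eb.find_orfs(r.seq, min_aa=100)] for r in records
    }
    n_checked = 0
    for row in rep.per_contig.itertuples():
        if row.category != "matched":
            continue
        asm_rec = next(r for r in perturbed if r.id == row.contig_id)
        for did in row.matched_designer_ids.split(";"):
            best = 0.0
            for orf in eb.find_orfs(asm_rec.seq, min_aa=100):
                for dp in designer_prots[did]:
                    ident, _, cov_b = sw_align(orf.protein, dp)
                    if cov_b >= 0.90:
                        best = max(best, ident)
            assert best >= 0.90
            n_checked += 1
    assert n_checked > 0


# ------------------------------------------------- label-based recovery


def test_taxonomic_recovery_categories():
    truth = eb.LabelTable({"c1": "Karenia", "c2": "Karenia", "c3": "Emiliania"})
    same = eb.taxonomic_recovery(truth, truth)
    assert same.counts == {"match": 3, "conflict": 0, "unannotated": 0}
    assert same.abundance["conflict"] == 0.0
    obs = eb.LabelTable({"c1": "Karenia", "c2": "Alexandrium", "c3": "unannotated"})
    rec = eb.taxonomic_recovery(truth, obs, {"c1": 5.0, "c2": 2.0, "c3": 1.0})
    assert rec.counts == {"match": 1, "conflict": 1, "unannotated": 1}
    assert rec.abundance == {"match": 5.0, "conflict": 2.0, "unannotated": 1.0}
    kar = rec.per_label.set_index("label")
    assert kar.loc["Karenia", "truth_abundance"] == 7.0
    assert kar.loc["Karenia", "observed_abundance"] == 5.0


def test_functional_recovery_set_algebra():
    designer = eb.LabelTable({"d1": "K1", "d2": "K2", "d3": "K3"})
    assembly = eb.LabelTable({"a1": "K2", "a2": "K3", "a3": "K4"})
    fr = eb.functional_recovery(designer, assembly)
    assert fr.match == {"K2", "K3"}
    assert fr.false_positive == {"K4"}
    assert fr.not_recovered == {"K1"}
    same = eb.functional_recovery(designer, designer)
    assert not same.false_positive and not same.not_recovered


def test_consensus_support_counts_assemblers():
    rng = np.random.default_rng(47)
    asm = [eb.SequenceRecord(f"c{i}", random_seq(rng, 300)) for i in range(8)]
    dup = eb.consensus_support({"a1": asm, "a2": asm})
    assert (dup["support"] == 2).all()
    other = [eb.SequenceRecord(f"o{i}", random_seq(rng, 300)) for i in range(8)]
    disjoint = eb.consensus_support({"a1": asm, "a2": other})
    assert (disjoint["support"] == 1).all()
    shared = asm[0]
    four = eb.consensus_support(
        {f"asm{k}": [shared, eb.SequenceRecord(f"u{k}", random_seq(rng, 300))] for k in range(4)}
    )
    assert sorted(four["support"])[-1] == 4


# ------------------------------------------------------------ statistics ops


def test_regression_exact_lines():
    x = np.arange(1.0, 11.0)
    res = eb.linear_regression(x, x)
    assert (res.slope, res.intercept, res.pearson_r) == pytest.approx((1.0, 0.0, 1.0))
    res2 = eb.linear_regression(x, 2 * x + 1)
    assert (res2.slope, res2.intercept, res2.pearson_r) == pytest.approx((2.0, 1.0, 1.0))
    origin = eb.linear_regression(x, 2 * x + 1, through_origin=True)
    assert origin.intercept == 0.0
    assert origin.slope == pytest.approx(float((x * (2 * x + 1)).sum() / (x * x).sum()))


def test_regression_matches_normal_equations():
    rng = np.random.default_rng(48)
    x = rng.uniform(0, 10, 50)
    y = 3.2 * x - 1.5 + rng.normal(0, 1, 50)
    res = eb.linear_regression(x, y)
    slope, intercept = ols_normal_equations(x.tolist(), y.tolist())
    assert res.slope == pytest.approx(slope, abs=1e-10)
    assert res.intercept == pytest.approx(intercept, abs=1e-10)
    with pytest.raises(ValueError):
        eb.linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_welch_t_matches_hand_formula():
    a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
    t, df, p = eb.welch_t(a, b)
    ot, odf = welch_formula(a, b)
    assert t == pytest.approx(ot) and df == pytest.approx(odf)
    t2, _, _ = eb.welch_t(b, a)
    assert t2 == pytest.approx(-t)
    t0, _, p0 = eb.welch_t([2.0, 2.0], [2.0, 2.0])
    assert t0 == 0.0 and p0 == 1.0


# --------------------------------------------------------------- degradation


def test_degrading_assembly_shifts_matches_and_functions(small_panel, designer):
    spec, records, manifest = designer
    full = eb.protein_recovery(records, records)
    dropped_ids = set(manifest.contig_id[::3])
    kept = [r for r in records if r.id not in dropped_ids]
    degraded = eb.protein_recovery(records, kept)
    # matched count falls by exactly the dropped (all ORF-bearing) contigs
    assert degraded.counts["matched"] == full.counts["matched"] - len(dropped_ids)
    assert degraded.counts["unmatched"] == 0
    # dropped-only function tokens move to not_recovered
    g2fn = {
        row.contig_id: small_panel.function_labels[row.orthogroup]
        for row in manifest.itertuples()
    }
    designer_lt = eb.LabelTable({cid: g2fn[cid] for cid in manifest.contig_id})
    kept_lt = eb.LabelTable({r.id: g2fn[r.id] for r in kept})
    fr = eb.functional_recovery(designer_lt, kept_lt)
    kept_tokens = {g2fn[r.id] for r in kept}
    dropped_tokens = {g2fn[c] for c in dropped_ids}
    assert fr.not_recovered == dropped_tokens - kept_tokens
    assert not fr.false_positive
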