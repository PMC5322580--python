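"""The reduction chain vs an independently coded brute-force reference."""

import pytest

from nrtx.consolidate import (
    RULE_COVERAGE,
    RULE_EVALUE,
    RULE_PROTEIN_DEDUP,
    apply_three_step_filter,
    collapse_by_ko,
    merge_assemblies,
    select_top_hits,
)
from nrtx.io_formats import AnnotationMap, BlastHit, Contig

from conftest import random_hit_table


def make_hit(q, p, evalue, aln=90, slen=100, bitscore=200.0):
    return BlastHit(
        query_id=q, subject_id=p, pct_identity=95.0, aln_len_aa=aln,
        mismatches=2, gap_opens=0, q_start=1, q_end=3 * aln, s_start=1,
        s_end=aln, evalue=evalue, bitscore=bitscore, subject_len_aa=slen,
    )


# --- independent reference: plain nested loops, no shared code ----------


def reference_top_hits(hits):
    table = {}
    for h in hits:
        table.setdefault(h.query_id, []).append(h)
    out = {}
    for q, hs in table.items():
        best = hs[0]
        for h in hs[1:]:
            if (h.evalue, -h.bitscore, -h.aln_len_aa, h.subject_id) < (
                best.evalue, -best.bitscore, -best.aln_len_aa, best.subject_id
            ):
                best = h
        out[q] = best
    return out


def reference_filter(tophits, clen, evalue_max=1e-10, min_cov=0.8):
    passing = [
        h
        for h in tophits.values()
        if h.evalue <= evalue_max and h.aln_len_aa / h.subject_len_aa >= min_cov
    ]
    kept = {}
    for h in passing:
        prev = kept.get(h.subject_id)
        if prev is None or (h.evalue, -clen[h.query_id], h.query_id) < (
            prev.evalue, -clen[prev.query_id], prev.query_id
        ):
            kept[h.subject_id] = h
    return sorted(kept.values(), key=lambda h: h.query_id)


def reference_ko_collapse(nr_hits, amap, clen):
    kept = {}
    for h in nr_hits:
        ko = amap.ko.get(h.subject_id)
        if ko is None:
            continue
        prev = kept.get(ko)
        if prev is None or (h.evalue, -clen[h.query_id], h.query_id) < (
            prev.evalue, -clen[prev.query_id], prev.query_id
        ):
            kept[ko] = h
    return sorted(kept.values(), key=lambda h: h.query_id)


# --- merge ----------------------------------------------------------------


def test_merge_single_source_keeps_ids():
    contigs = [Contig("c1", "ACGT"), Contig("c2", "GGCC")]
    merged = merge_assemblies({"A": contigs})
    assert [c.id for c in merged] == ["c1", "c2"]


def test_merge_namespaces_cross_source_collisions():
    merged = merge_assemblies(
        {"A": [Contig("c1", "ACGT")], "B": [Contig("c1", "GGCC"), Contig("c9", "AT")]}
    )
    assert sorted(c.id for c in merged) == ["A|c1", "B|c1", "c9"]


def test_merge_counts_are_additive():
    sets = {
        f"S{k}": [Contig(f"S{k}x{i}", "ACGT") for i in range(n)]
        for k, n in enumerate((30, 20, 25, 12))
    }
    assert len(merge_assemblies(sets)) == 87


def test_merge_rejects_within_source_duplicate():
    with pytest.raises(ValueError, match="within source"):
        merge_assemblies({"A": [Contig("c1", "ACGT"), Contig("c1", "AAAA")]})


# --- top hits -------------------------------------------------------------


def test_top_hit_minimal_evalue():
    hits = [make_hit("q1", "P1", 1e-12), make_hit("q1", "P2", 1e-30)]
    assert select_top_hits(hits)["q1"].subject_id == "P2"


def test_top_hit_bitscore_tie_break():
    hits = [
        make_hit("q1", "P1", 0.0, bitscore=240.0),
        make_hit("q1", "P2", 0.0, bitscore=250.0),
    ]
    assert select_top_hits(hits)["q1"].subject_id == "P2"


@pytest.mark.parametrize("seed", range(5))
def test_top_hits_match_reference(seed):
    hits, _, _ = random_hit_table(seed, n_hits=400)
    assert select_top_hits(hits) == reference_top_hits(hits)


# --- three-step filter ----------------------------------------------------


def test_boundary_hit_is_retained():
    # E-value exactly 1e-10 and coverage exactly 0.80 both pass (inclusive)
    h = make_hit("q1", "P1", 1e-10, aln=80, slen=100)
    nr = apply_three_step_filter({"q1": h}, {"q1": 300})
    assert nr.records == [h] and nr.removals == []


def test_evalue_just_over_threshold_removed():
    h = make_hit("q1", "P1", 1e-9, aln=95, slen=100)
    nr = apply_three_step_filter({"q1": h}, {"q1": 300})
    assert nr.records == [] and nr.removals[0].rule == RULE_EVALUE


def test_coverage_fail_removed():
    h = make_hit("q1", "P1", 1e-30, aln=79, slen=100)
    nr = apply_three_step_filter({"q1": h}, {"q1": 300})
    assert nr.removals[0].rule == RULE_COVERAGE


def test_protein_dedup_keeps_best_evalue():
    tophits = {
        "q1": make_hit("q1", "P1", 1e-20),
        "q2": make_hit("q2", "P1", 1e-15),
        "q3": make_hit("q3", "P2", 1e-12),
    }
    clen = {"q1": 300, "q2": 300, "q3": 300}
    nr = apply_three_step_filter(tophits, clen)
    assert {h.query_id for h in nr.records} == {"q1", "q3"}
    dedup = [r for r in nr.removals if r.rule == RULE_PROTEIN_DEDUP]
    assert [r.query_id for r in dedup] == ["q2"]


def test_protein_dedup_tie_goes_to_longer_contig():
    tophits = {
        "q1": make_hit("q1", "P1", 1e-20),
        "q2": make_hit("q2", "P1", 1e-20),
    }
    nr = apply_three_step_filter(tophits, {"q1": 900, "q2": 1200})
    assert [h.query_id for h in nr.records] == ["q2"]


def test_missing_subject_length_names_protein():
    h = BlastHit(
        query_id="q1", subject_id="P9", pct_identity=95.0, aln_len_aa=90,
        mismatches=0, gap_opens=0, q_start=1, q_end=270, s_start=1, s_end=90,
        evalue=1e-30, bitscore=200.0, subject_len_aa=None,
    )
    with pytest.raises(ValueError, match="P9"):
        apply_three_step_filter({"q1": h}, {"q1": 300})


def test_filter_is_idempotent(hit_fixture):
    hits, clen, _ = hit_fixture
    nr = apply_three_step_filter(select_top_hits(hits), clen)
    again = apply_three_step_filter({h.query_id: h for h in nr.records}, clen)
    assert again.records == nr.records
    assert again.removals == []


@pytest.mark.parametrize("seed", range(5))
def test_chain_matches_reference_and_shrinks(seed):
    hits, clen, _ = random_hit_table(seed, n_hits=500, n_queries=60, n_proteins=20)
    amap = AnnotationMap()
    # KO map over a subset of proteins, with sharing
    for i in range(20):
        if i % 4:
            amap.ko[f"P{i:03d}"] = f"K{i % 7:05d}"
    top = select_top_hits(hits)
    nr = apply_three_step_filter(top, clen)
    ko = collapse_by_ko(nr, amap, clen)

    assert nr.records == reference_filter(top, clen)
    ref_ko = reference_ko_collapse(nr.records, amap, clen)
    assert [(r.contig_id, r.ko) for r in ko.records] == [
        (h.query_id, amap.ko[h.subject_id]) for h in ref_ko
    ]
    # monotone shrinkage and uniqueness
    assert len(ko.records) <= len(nr.records) <= len(top) <= len(hits)
    assert len({h.subject_id for h in nr.records}) == len(nr.records)
    assert len({r.ko for r in ko.records}) == len(ko.records)


# --- KO collapse ----------------------------------------------------------


def _nr_of(hits):
    from nrtx.consolidate import NonRedundantSet

    return NonRedundantSet(records=list(hits))


def test_ko_collapse_keeps_best_evalue():
    amap = AnnotationMap(ko={"P1": "K1", "P2": "K1"})
    nr = _nr_of([make_hit("q1", "P1", 1e-50), make_hit("q2", "P2", 1e-20)])
    ko = collapse_by_ko(nr, amap, {"q1": 300, "q2": 300})
    assert [r.contig_id for r in ko.records] == ["q1"]


def test_ko_collapse_tie_prefers_longer_contig():
    amap = AnnotationMap(ko={"P1": "K1", "P2": "K1"})
    nr = _nr_of([make_hit("q1", "P1", 1e-50), make_hit("q2", "P2", 1e-50)])
    ko = collapse_by_ko(nr, amap, {"q1": 900, "q2": 1200})
    assert [r.contig_id for r in ko.records] == ["q2"]


def test_ko_collapse_distinct_kos_all_kept_and_unannotated_dropped():
    amap = AnnotationMap(ko={"P1": "K1", "P2": "K2"})
    nr = _nr_of(
        [make_hit("q1", "P1", 1e-50), make_hit("q2", "P2", 1e-50),
         make_hit("q3", "P3", 1e-50)]
    )
    ko = collapse_by_ko(nr, amap, {"q1": 1, "q2": 1, "q3": 1})
    assert {r.contig_id for r in ko.records} == {"q1", "q2"}
    assert any(r.rule == "no-ko" and r.query_id == "q3" for r in ko.removals)
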