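"""Event-type cascade on constructed pairs and planted groups."""

import numpy as np
import pytest

from nrtx.align import pairwise_align
from nrtx.consolidate import select_top_hits
from nrtx.events import (
    ALT_SPLICING,
    ALT_START_END,
    EXON_SKIPPING,
    FALSE_ASSEMBLY,
    GENE_BREAKAGE,
    EventThresholds,
    RedundancyGroup,
    classify_group,
    classify_pair,
    classify_redundant,
    subject_overlap,
)
from nrtx.fixtures import (
    _events_plan,
    generate_blast_table,
    generate_contigs,
    generate_proteome,
    plan_for,
)
from nrtx.io_formats import BlastHit, Contig


def hit(q, p="P1", s_start=1, s_end=100, slen=120):
    aln = s_end - s_start + 1
    return BlastHit(
        query_id=q, subject_id=p, pct_identity=95.0, aln_len_aa=aln,
        mismatches=0, gap_opens=0, q_start=1, q_end=3 * aln,
        s_start=s_start, s_end=s_end, evalue=1e-40, bitscore=200.0,
        subject_len_aa=slen,
    )


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.mark.parametrize(
    "ia,ib,expected",
    [((1, 100), (150, 300), 0), ((1, 100), (50, 200), 51), ((10, 20), (10, 20), 11)],
)
def test_subject_overlap(ia, ib, expected):
    a = hit("a", s_start=ia[0], s_end=ia[1], slen=400)
    b = hit("b", s_start=ib[0], s_end=ib[1], slen=400)
    assert subject_overlap(a, b) == expected


def test_subject_overlap_requires_same_subject():
    with pytest.raises(ValueError):
        subject_overlap(hit("a", p="P1"), hit("b", p="P2"))


def test_thresholds_validated():
    with pytest.raises(ValueError):
        EventThresholds(identity_min=1.2)
    with pytest.raises(ValueError):
        EventThresholds(min_gap_block=-1)


def test_internal_deletion_is_exon_skipping_like():
    rng = np.random.default_rng(0)
    a = rand_seq(rng, 360)
    b = a[:150] + a[210:]  # 60-nt internal deletion, flanks exact
    call = classify_pair(pairwise_align(a, b), hit("a"), hit("b"))
    assert call.event_type == ALT_SPLICING
    assert call.splice_subtype == EXON_SKIPPING


def test_disjoint_subject_hits_are_gene_breakage():
    rng = np.random.default_rng(1)
    gene = rand_seq(rng, 900)
    a, b = gene[:360], gene[540:]
    call = classify_pair(
        pairwise_align(a, b),
        hit("a", s_start=1, s_end=120, slen=300),
        hit("b", s_start=181, s_end=300, slen=300),
    )
    assert call.event_type == GENE_BREAKAGE


def test_five_prime_extension_is_isoform():
    rng = np.random.default_rng(2)
    a = rand_seq(rng, 300)
    b = rand_seq(rng, 100) + a
    call = classify_pair(pairwise_align(a, b), hit("a"), hit("b"))
    assert call.event_type == ALT_START_END


def test_shuffled_segment_is_false_assembly():
    rng = np.random.default_rng(3)
    a = rand_seq(rng, 500)
    b = a[:150] + rand_seq(rng, 200) + a[350:]
    call = classify_pair(pairwise_align(a, b), hit("a"), hit("b"))
    assert call.event_type == FALSE_ASSEMBLY


def test_near_identical_pair_is_isoform_with_note():
    rng = np.random.default_rng(4)
    a = rand_seq(rng, 300)
    call = classify_pair(pairwise_align(a, a), hit("a"), hit("b"))
    assert call.event_type == ALT_START_END
    assert "near-identical" in call.note


def test_group_label_uses_severity_order():
    rng = np.random.default_rng(5)
    gene = rand_seq(rng, 600)
    iso = rand_seq(rng, 60) + gene          # isoform vs gene
    spliced = gene[:240] + gene[330:]       # splicing vs gene
    members = [
        (Contig("a", gene), hit("a", s_end=120, slen=200)),
        (Contig("b", iso), hit("b", s_end=120, slen=200)),
        (Contig("c", spliced), hit("c", s_end=120, slen=200)),
    ]
    call = classify_group(RedundancyGroup("P1", members))
    labels = {pc.call.event_type for pc in call.pair_calls}
    assert ALT_SPLICING in labels and ALT_START_END in labels
    assert call.event_type == ALT_SPLICING  # splicing outranks isoform


def test_singleton_group_rejected():
    with pytest.raises(ValueError):
        classify_group(RedundancyGroup("P1", [(Contig("a", "ACGT"), hit("a"))]))


def test_group_call_invariant_under_member_order():
    rng = np.random.default_rng(6)
    gene = rand_seq(rng, 450)
    members = [
        (Contig("a", gene), hit("a")),
        (Contig("b", gene[:150] + gene[240:]), hit("b")),
        (Contig("c", rand_seq(rng, 60) + gene), hit("c")),
    ]
    fwd = classify_group(RedundancyGroup("P1", members))
    rev = classify_group(RedundancyGroup("P1", members[::-1]))
    assert fwd == rev


@pytest.mark.parametrize("noise", [0.0, 0.01])
def test_planted_group_recovery(noise):
    """Every planted event type is recovered from the generated fixture."""
    proteome = generate_proteome(20, len_range=(150, 300), seed=31)
    plan = plan_for(proteome, _events_plan(5))
    contigs, truth = generate_contigs(proteome, plan, noise_rate=noise, seed=31)
    hits = generate_blast_table(contigs, truth, proteome, seed=31)
    calls = {
        gc.protein_id: gc.event_type
        for gc in classify_redundant(contigs, select_top_hits(hits))
    }
    for ev in truth.events:
        assert calls[ev["protein_id"]] == ev["event_type"]
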