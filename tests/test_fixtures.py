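"""Generator purity, planted-truth consistency and validator round-trips."""

import pytest

from nrtx.consolidate import apply_three_step_filter, select_top_hits
from nrtx.diffexpr import call_de
from nrtx.events import ALT_SPLICING, GENE_BREAKAGE
from nrtx.fixtures import (
    PlanEntry,
    generate_blast_table,
    generate_contigs,
    generate_de_table,
    generate_preset,
    generate_proteome,
)
from nrtx.io_formats import (
    read_annotation_map,
    read_blast_tab,
    read_de_table,
    read_fasta,
)
from nrtx.metrics import compute_gc
from nrtx.events import subject_overlap
from nrtx.align import pairwise_align


def test_proteome_deterministic_and_valid():
    a = generate_proteome(50, seed=9)
    b = generate_proteome(50, seed=9)
    assert a.equals(b)
    assert a["protein_id"].is_unique and len(a) == 50
    assert a["length"].between(150, 400).all()
    with pytest.raises(ValueError):
        generate_proteome(0)
    with pytest.raises(ValueError):
        generate_proteome(5, len_range=(100, 50))


def test_contigs_deterministic_per_seed():
    proteome = generate_proteome(10, seed=1)
    c1, t1 = generate_contigs(proteome, seed=1)
    c2, t2 = generate_contigs(proteome, seed=1)
    assert c1 == c2 and t1 == t2
    c3, _ = generate_contigs(proteome, seed=2)
    assert c1 != c3


def test_unknown_protein_in_plan_rejected():
    proteome = generate_proteome(3, seed=0)
    with pytest.raises(ValueError, match="PX"):
        generate_contigs(proteome, {"PX": PlanEntry(ALT_SPLICING)})


def test_gc_target_is_met():
    proteome = generate_proteome(100, len_range=(300, 400), seed=3)  # ~100 kb
    contigs, _ = generate_contigs(proteome, gc_target=0.54, seed=3)
    assert abs(compute_gc(contigs) - 0.54) < 0.01


def test_noise_free_contigs_are_exact_surgeries():
    proteome = generate_proteome(6, seed=4)
    plan = {"P0001": PlanEntry(ALT_SPLICING)}
    contigs, truth = generate_contigs(proteome, plan, noise_rate=0.0, seed=4)
    base, variant = truth.events[0]["contigs"][:2]
    by_id = {c.id: c for c in contigs}
    aln = pairwise_align(by_id[base].sequence, by_id[variant].sequence)
    assert aln.identity == 1.0
    assert len(aln.gap_blocks) == 1 and aln.gap_blocks[0].length >= 30


def test_breakage_pair_has_disjoint_subject_intervals():
    proteome = generate_proteome(4, seed=5)
    plan = {"P0002": PlanEntry(GENE_BREAKAGE)}
    contigs, truth = generate_contigs(proteome, plan, seed=5)
    hits = generate_blast_table(contigs, truth, proteome, seed=5)
    by_q = {h.query_id: h for h in hits}
    a, b = truth.events[0]["contigs"]
    assert subject_overlap(by_q[a], by_q[b]) == 0


def test_decoy_free_table_passes_filter_everywhere():
    proteome = generate_proteome(25, seed=6)
    contigs, truth = generate_contigs(proteome, seed=6)
    hits = generate_blast_table(contigs, truth, proteome, seed=6, decoy_rate=0.0)
    for h in hits:
        assert h.evalue <= 1e-10
        assert h.aln_len_aa / h.subject_len_aa >= 0.8


def test_filter_preset_nr_count_equals_truth(tmp_path):
    """Decoys and junk never displace a true hit from the non-redundant set."""
    paths = generate_preset("filter", tmp_path, seed=13)
    contigs = read_fasta(paths["contigs"])
    hits = read_blast_tab(paths["hits"])
    truth_nr = {c.id for c in contigs if not c.id.startswith("JUNK")}
    nr = apply_three_step_filter(
        select_top_hits(hits), {c.id: len(c) for c in contigs}
    )
    assert nr.query_ids == truth_nr


def test_de_table_recovers_planted_calls():
    proteome = generate_proteome(40, seed=7)
    contigs, _ = generate_contigs(proteome, seed=7)
    planted = sorted(c.id for c in contigs)[:8]
    records, truth = generate_de_table(contigs, planted, effect=4.0, seed=7)
    calls = call_de(records)
    assert set(calls.up) == set(planted) == set(truth.expected_up)
    assert not calls.down


def test_de_effect_must_be_at_least_one():
    with pytest.raises(ValueError):
        generate_de_table([], [], effect=0.5)


@pytest.mark.parametrize("preset", ["filter", "enrichment"])
def test_preset_files_pass_validators(tmp_path, preset):
    paths = generate_preset(preset, tmp_path / preset, seed=21)
    contigs = read_fasta(paths["contigs"])
    assert contigs
    hits = read_blast_tab(paths["hits"])
    assert {h.query_id for h in hits} == {c.id for c in contigs}
    amap = read_annotation_map(paths["annotation_map"])
    assert amap.proteins
    if "de_table" in paths:
        assert read_de_table(paths["de_table"])


def test_preset_regeneration_is_byte_identical(tmp_path):
    p1 = generate_preset("full", tmp_path / "a", seed=42)
    p2 = generate_preset("full", tmp_path / "b", seed=42)
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes(), name
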