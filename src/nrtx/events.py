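"""Classification of redundant contigs into non-top-hit event types.

When several contigs hit the same protein accession, the redundancy has
one of four explanations:

* ``false_assembly``      — a chimeric or mis-assembled contig;
* ``alt_start_end_isoform`` — isoforms differing only at transcription
  start/end;
* ``gene_breakage``       — fragments of one gene assembled separately;
* ``alternative_splicing`` — exon-skipping- or intron-retention-like
  internal differences.

Each unordered contig pair is classified from its global alignment and
its hit geometry by a fixed decision cascade (thresholds configurable):

1. subject-interval overlap < O_min residues      -> gene_breakage
2. alignment identity < I_min                     -> false_assembly
3. an internal gap block >= G_min nt              -> alternative_splicing
   (exon_skipping_like if the block sits in the shorter sequence,
   intron_retention_like if in the longer, unresolved otherwise)
4. a terminal overhang > T_end nt                 -> alt_start_end_isoform
5. otherwise                                      -> alt_start_end_isoform
   (near-identical pair)

Gap runs closer than T_end to an alignment end are treated as terminal
variation in steps 3-4, because an end gap can slide inward past
coincidentally matching bases without changing the alignment score.

A group is labelled by its most severe pair under the order
false_assembly > alternative_splicing > gene_breakage >
alt_start_end_isoform.  Alternative 5'/3' splice sites and mutually
exclusive exons cannot be told apart from a pairwise nucleotide
alignment alone and fold into the subtypes above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .align import AlignParams, PairAlignment, pairwise_align
from .io_formats import BlastHit, Contig

FALSE_ASSEMBLY = "false_assembly"
ALT_START_END = "alt_start_end_isoform"
GENE_BREAKAGE = "gene_breakage"
ALT_SPLICING = "alternative_splicing"

EVENT_TYPES = (FALSE_ASSEMBLY, ALT_START_END, GENE_BREAKAGE, ALT_SPLICING)

# group label = most severe pair label, descending severity:
SEVERITY_ORDER = (FALSE_ASSEMBLY, ALT_SPLICING, GENE_BREAKAGE, ALT_START_END)

EXON_SKIPPING = "exon_skipping_like"
INTRON_RETENTION = "intron_retention_like"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class EventThresholds:
    """Decision-cascade thresholds.

    identity_min in [0,1]; min_gap_block (nt), end_tolerance (nt) and
    min_subject_overlap (aa residues) are non-negative.  Defaults are
    chosen so a codon-scale indel is not called splicing but an
    exon-scale one is.
    """

    identity_min: float = 0.90
    min_gap_block: int = 30
    end_tolerance: int = 15
    min_subject_overlap: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_min <= 1.0:
            raise ValueError("identity_min must lie in [0, 1]")
        if min(self.min_gap_block, self.end_tolerance, self.min_subject_overlap) < 0:
            raise ValueError("length thresholds must be non-negative")


@dataclass(frozen=True)
class EventCall:
    """Classification of one contig pair with its evidence summary."""

    event_type: str
    splice_subtype: str | None
    identity: float
    overlap_aa: int
    max_internal_gap: int
    max_overhang: int
    note: str = ""


@dataclass(frozen=True)
class PairCall:
    contig_a: str
    contig_b: str
    call: EventCall


@dataclass
class RedundancyGroup:
    """All contigs whose best hit is the same protein accession."""

    protein_id: str
    members: list[tuple[Contig, BlastHit]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"group {self.protein_id}: duplicate member contigs")
        for _, h in self.members:
            if h.subject_id != self.protein_id:
                raise ValueError(
                    f"group {self.protein_id}: member hit targets {h.subject_id}"
                )


@dataclass(frozen=True)
class GroupCall:
    protein_id: str
    event_type: str
    pair_calls: tuple[PairCall, ...]


def subject_overlap(hit_a: BlastHit, hit_b: BlastHit) -> int:
    """Residues shared by the two subject intervals (1-based inclusive)."""
    if hit_a.subject_id != hit_b.subject_id:
        raise ValueError(
            f"hits target different subjects: {hit_a.subject_id} vs {hit_b.subject_id}"
        )
    lo = max(hit_a.s_start, hit_b.s_start)
    hi = min(hit_a.s_end, hit_b.s_end)
    return max(0, hi - lo + 1)


def classify_pair(
    pair_alignment: PairAlignment,
    hit_a: BlastHit,
    hit_b: BlastHit,
    thresholds: EventThresholds = EventThresholds(),
) -> EventCall:
    """Run the decision cascade on one aligned contig pair."""
    t = thresholds
    overlap = subject_overlap(hit_a, hit_b)
    aln = pair_alignment
    len_a = len(aln.aligned_a.replace("-", ""))
    len_b = len(aln.aligned_b.replace("-", ""))

    def call(event, subtype=None, note=""):
        return EventCall(
            event_type=event,
            splice_subtype=subtype,
            identity=aln.identity,
            overlap_aa=overlap,
            max_internal_gap=aln.max_internal_gap,
            max_overhang=aln.max_overhang,
            note=note,
        )

    if overlap < t.min_subject_overlap:
        return call(GENE_BREAKAGE, note="disjoint or barely-overlapping subject hits")
    if aln.identity < t.identity_min:
        return call(FALSE_ASSEMBLY, note="low identity over matched columns")
    # A gap run within end_tolerance of an alignment end is start/end
    # variation, not internal splicing: a terminal gap can slide inward
    # past coincidentally matching bases at equal alignment score.
    ncols = len(aln.aligned_a)
    big = []
    slid_overhangs = [0]
    for g in aln.gap_blocks:
        dist = min(g.col_start, ncols - (g.col_start + g.length))
        if dist <= t.end_tolerance:
            slid_overhangs.append(g.length + dist)
        elif g.length >= t.min_gap_block:
            big.append(g)
    overhang = max([aln.max_overhang] + slid_overhangs)
    if big:
        sides = {g.side for g in big}
        if len_a == len_b or len(sides) > 1:
            subtype = UNRESOLVED
        else:
            shorter = "a" if len_a < len_b else "b"
            subtype = EXON_SKIPPING if sides == {shorter} else INTRON_RETENTION
        return call(ALT_SPLICING, subtype=subtype)
    if overhang > t.end_tolerance:
        return call(ALT_START_END, note="terminal extension beyond end tolerance")
    return call(ALT_START_END, note="near-identical pair")


def classify_group(
    group: RedundancyGroup,
    thresholds: EventThresholds = EventThresholds(),
    params: AlignParams = AlignParams(),
) -> GroupCall:
    """Classify all unordered pairs of a group and label the group.

    The group label is the pair label of highest severity; the full
    per-pair table is retained.
    """
    if len(group.members) < 2:
        raise ValueError(f"group {group.protein_id}: need >= 2 members")
    members = sorted(group.members, key=lambda cb: cb[0].id)
    pair_calls = []
    for (ca, ha), (cb, hb) in combinations(members, 2):
        aln = pairwise_align(ca.sequence, cb.sequence, params)
        pair_calls.append(PairCall(ca.id, cb.id, classify_pair(aln, ha, hb, thresholds)))
    label = min(
        (pc.call.event_type for pc in pair_calls), key=SEVERITY_ORDER.index
    )
    return GroupCall(group.protein_id, label, tuple(pair_calls))


def build_groups(
    contigs: Iterable[Contig], tophits: Mapping[str, BlastHit]
) -> list[RedundancyGroup]:
    """Group contigs whose top hit targets the same protein (size >= 2)."""
    by_id = {c.id: c for c in contigs}
    by_protein: dict[str, list[tuple[Contig, BlastHit]]] = {}
    for qid in sorted(tophits):
        h = tophits[qid]
        if qid in by_id:
            by_protein.setdefault(h.subject_id, []).append((by_id[qid], h))
    return [
        RedundancyGroup(protein_id=pid, members=members)
        for pid, members in sorted(by_protein.items())
        if len(members) >= 2
    ]


def classify_redundant(
    contigs: Sequence[Contig],
    tophits: Mapping[str, BlastHit],
    thresholds: EventThresholds = EventThresholds(),
    params: AlignParams = AlignParams(),
) -> list[GroupCall]:
    """Group redundant contigs by shared best-hit protein and classify."""
    return [
        classify_group(g, thresholds, params) for g in build_groups(contigs, tophits)
    ]
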