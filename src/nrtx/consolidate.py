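"""Assembly merging and reduction of BLASTX hits to a non-redundant set.

The chain is: merge contig sets from several assemblers, keep one best
("top") hit per query contig, apply the three-step criterion

1. E-value <= 1e-10 (inclusive),
2. aligned length >= 80% of the subject protein length (inclusive),
3. at most one contig per subject protein accession,

then, for pathway-level analysis, collapse further to one transcript per
KEGG Orthology group (best E-value first, longer contig on ties).  Every
removal is logged with the rule that caused it so the reduction is fully
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import AnnotationMap, BlastHit, Contig

EVALUE_MAX_DEFAULT = 1e-10
MIN_COVERAGE_DEFAULT = 0.80

RULE_EVALUE = "evalue-fail"
RULE_COVERAGE = "coverage-fail"
RULE_PROTEIN_DEDUP = "protein-dedup"
RULE_KO_DEDUP = "ko-dedup"
RULE_NO_KO = "no-ko"


@dataclass(frozen=True)
class Removal:
    """One audit-log entry: why a query's hit left the retained set."""

    query_id: str
    subject_id: str
    rule: str


@dataclass(frozen=True)
class AnnotationRecord:
    """A retained transcript with its protein hit and term annotations."""

    contig_id: str
    protein_id: str
    kegg_gene: str | None
    ko: str | None
    go_terms: frozenset[str]
    evalue: float
    contig_len: int


@dataclass
class NonRedundantSet:
    """Survivors of the three-step filter plus the removal audit log."""

    records: list[BlastHit] = field(default_factory=list)
    removals: list[Removal] = field(default_factory=list)

    @property
    def query_ids(self) -> set[str]:
        return {h.query_id for h in self.records}

    @property
    def protein_ids(self) -> set[str]:
        return {h.subject_id for h in self.records}


@dataclass
class KOUniqueSet:
    """One annotated transcript per KO, plus the collapse audit log."""

    records: list[AnnotationRecord] = field(default_factory=list)
    removals: list[Removal] = field(default_factory=list)

    @property
    def kos(self) -> set[str]:
        return {r.ko for r in self.records if r.ko is not None}


def merge_assemblies(contig_sets: Mapping[str, Sequence[Contig]]) -> list[Contig]:
    """Union contig sets from several assembly sources.

    Ids colliding *across* sources are namespaced as ``"<source>|<id>"``;
    a collision *within* one source is an error.  The merged count always
    equals the sum of the source counts.
    """
    if not contig_sets:
        raise ValueError("at least one contig source is required")
    from dataclasses import replace

    tally: dict[str, int] = {}
    for source, contigs in contig_sets.items():
        ids: set[str] = set()
        for c in contigs:
            if c.id in ids:
                raise ValueError(f"duplicate contig id {c.id!r} within source {source!r}")
            ids.add(c.id)
        for i in ids:
            tally[i] = tally.get(i, 0) + 1
    colliding = {i for i, n in tally.items() if n > 1}
    merged: list[Contig] = []
    for source, contigs in contig_sets.items():
        for c in contigs:
            cid = f"{source}|{c.id}" if c.id in colliding else c.id
            merged.append(replace(c, id=cid, source=source))
    return merged


def select_top_hits(hits: Iterable[BlastHit]) -> dict[str, BlastHit]:
    """Keep the single best hit per query contig.

    Best = minimal E-value; ties broken by maximal bitscore, then maximal
    aligned length, then lexicographically smallest subject accession.
    """
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return best


def _hit_rank(h: BlastHit) -> tuple:
    return (h.evalue, -h.bitscore, -h.aln_len_aa, h.subject_id)


def apply_three_step_filter(
    tophits: Mapping[str, BlastHit],
    contig_lengths: Mapping[str, int],
    protein_lengths: Mapping[str, int] | None = None,
    evalue_max: float = EVALUE_MAX_DEFAULT,
    min_coverage: float = MIN_COVERAGE_DEFAULT,
) -> NonRedundantSet:
    """Reduce a top-hit table to a non-redundant annotated set.

    A hit survives iff ``evalue <= evalue_max`` and
    ``aln_len_aa / subject_len_aa >= min_coverage`` (both inclusive);
    among survivors sharing a subject protein exactly one is kept —
    minimal E-value, ties by longer query contig, then lexicographic
    query id.  All removals are logged by rule.

    ``protein_lengths`` supplies subject lengths for hits parsed from the
    plain 12-column dialect; a survivor candidate whose subject length
    cannot be resolved raises ``ValueError`` naming the protein.
    """
    nr = NonRedundantSet()
    survivors: list[BlastHit] = []
    for query_id in sorted(tophits):
        h = tophits[query_id]
        if h.evalue > evalue_max:
            nr.removals.append(Removal(h.query_id, h.subject_id, RULE_EVALUE))
            continue
        slen = h.subject_len_aa
        if slen is None and protein_lengths is not None:
            slen = protein_lengths.get(h.subject_id)
        if slen is None:
            raise ValueError(
                f"no subject length for protein {h.subject_id!r} "
                f"(hit by {h.query_id!r})"
            )
        if h.aln_len_aa / slen < min_coverage:
            nr.removals.append(Removal(h.query_id, h.subject_id, RULE_COVERAGE))
            continue
        survivors.append(h)

    by_protein: dict[str, list[BlastHit]] = {}
    for h in survivors:
        by_protein.setdefault(h.subject_id, []).append(h)
    for protein in sorted(by_protein):
        group = by_protein[protein]
        group.sort(key=lambda h: (h.evalue, -contig_lengths[h.query_id], h.query_id))
        nr.records.append(group[0])
        nr.removals.extend(
            Removal(h.query_id, h.subject_id, RULE_PROTEIN_DEDUP) for h in group[1:]
        )
    nr.records.sort(key=lambda h: h.query_id)
    return nr


def annotate(
    nrset: NonRedundantSet,
    annotation_map: AnnotationMap,
    contig_lengths: Mapping[str, int],
) -> list[AnnotationRecord]:
    """Attach KEGG gene / KO / GO annotations to the retained hits."""
    records = []
    for h in nrset.records:
        records.append(
            AnnotationRecord(
                contig_id=h.query_id,
                protein_id=h.subject_id,
                kegg_gene=annotation_map.kegg_gene.get(h.subject_id),
                ko=annotation_map.ko.get(h.subject_id),
                go_terms=annotation_map.go.get(h.subject_id, frozenset()),
                evalue=h.evalue,
                contig_len=contig_lengths[h.query_id],
            )
        )
    return records


def collapse_by_ko(
    nrset: NonRedundantSet,
    annotation_map: AnnotationMap,
    contig_lengths: Mapping[str, int],
) -> KOUniqueSet:
    """Collapse the non-redundant set to one transcript per KO.

    Records without a KO assignment are dropped from this set (they remain
    in the non-redundant set); within each KO group the record with the
    smallest E-value wins, ties going to the longer contig and then the
    lexicographically smallest contig id.
    """
    annotated = annotate(nrset, annotation_map, contig_lengths)
    out = KOUniqueSet()
    by_ko: dict[str, list[AnnotationRecord]] = {}
    for rec in annotated:
        if rec.ko is None:
            out.removals.append(Removal(rec.contig_id, rec.protein_id, RULE_NO_KO))
            continue
        by_ko.setdefault(rec.ko, []).append(rec)
    for ko in sorted(by_ko):
        group = by_ko[ko]
        group.sort(key=lambda r: (r.evalue, -r.contig_len, r.contig_id))
        out.records.append(group[0])
        out.removals.extend(
            Removal(r.contig_id, r.protein_id, RULE_KO_DEDUP) for r in group[1:]
        )
    out.records.sort(key=lambda r: r.contig_id)
    return out
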