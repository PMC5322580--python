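"""Seeded synthetic inputs with machine-readable planted truth.

Every file the pipeline consumes — contig FASTA, BLAST tabular hits,
annotation map, DE table, core-gene list — can be generated here as a
pure function of (parameters, seed), together with a truth record of
what was planted: which protein each contig derives from, which
redundancy events were engineered, which term is enriched, which
transcripts should be called differentially expressed.  That makes the
whole chain testable end-to-end without any database download.

The sequence model is deliberately simple: i.i.d. bases at a target GC,
one synthetic "gene" per protein (3 nt per residue), and contigs cut or
edited from it by event-specific surgery — an internal deletion for
splicing-like variants, a terminal extension for start/end isoforms,
disjoint fragments for gene breakage, and a shuffled-in random segment
for false assembly.  Simulated E-values decrease monotonically with
aligned length and identity; only their ordering and their position
relative to the 1e-10 threshold matter downstream, so no attempt is made
to reproduce real BLAST statistics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import ALT_SPLICING, ALT_START_END, EVENT_TYPES, FALSE_ASSEMBLY, GENE_BREAKAGE
from .io_formats import (
    AnnotationMap,
    BlastHit,
    Contig,
    DERecord,
    write_annotation_map,
    write_blast_tab,
    write_de_table,
    write_fasta,
    write_id_list,
    write_protein_lengths,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PLANTED_TERM = "GO:0099999"


@dataclass(frozen=True)
class PlanEntry:
    """One redundancy group to plant: its event type and size."""

    event_type: str
    group_size: int = 2

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")


@dataclass
class FixtureTruth:
    """Planted ground truth serialized alongside generated files."""

    seed: int
    params: dict = field(default_factory=dict)
    contig_protein: dict[str, str] = field(default_factory=dict)
    # per contig: s_start, s_end, aln_len_aa, pct_identity, q_start
    contig_hits: dict[str, dict] = field(default_factory=dict)
    # planted redundancy events: {protein_id, event_type, contigs}
    events: list[dict] = field(default_factory=list)
    # junk contigs and which filter rule should reject them
    junk_rule: dict[str, str] = field(default_factory=dict)
    # enrichment / DE truth
    planted_term: str | None = None
    planted_genes: list[str] = field(default_factory=list)
    expected_up: list[str] = field(default_factory=list)
    expected_down: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def generate_proteome(
    n_proteins: int, len_range: tuple[int, int] = (150, 400), seed: int = 0
) -> pd.DataFrame:
    """Synthetic protein table: ``protein_id, length`` (residues).

    Lengths are uniform over ``len_range`` (inclusive); deterministic per
    seed.
    """
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    lo, hi = len_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {len_range}")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "protein_id": [f"P{i:04d}" for i in range(1, n_proteins + 1)],
            "length": rng.integers(lo, hi + 1, size=n_proteins),
        }
    )


def generate_contigs(
    proteome: pd.DataFrame,
    redundancy_plan: Mapping[str, PlanEntry] | None = None,
    gc_target: float = 0.54,
    noise_rate: float = 0.0,
    seed: int = 0,
    n_junk: int = 0,
) -> tuple[list[Contig], FixtureTruth]:
    """Emit contigs for each protein, applying planted event surgeries.

    Proteins absent from ``redundancy_plan`` yield one full-length
    contig.  Planned proteins yield a redundancy group engineered to be
    classified as the planned event type.  ``n_junk`` extra contigs are
    unrelated sequences destined to fail the annotation filter (half on
    E-value, half on coverage).  Substitution noise at ``noise_rate`` is
    applied to every contig after surgery.
    """
    plan = dict(redundancy_plan or {})
    known = set(proteome["protein_id"])
    unknown = set(plan) - known
    if unknown:
        raise ValueError(f"redundancy plan references unknown proteins: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    truth = FixtureTruth(
        seed=seed,
        params={
            "gc_target": gc_target,
            "noise_rate": noise_rate,
            "n_junk": n_junk,
            "n_proteins": int(len(proteome)),
        },
    )
    contigs: list[Contig] = []

    def add(cid: str, seq: str, pid: str, s_start: int, s_end: int,
            aln_len: int, q_start: int = 1) -> None:
        seq = _substitute(rng, seq, noise_rate)
        ident = round(100.0 * (1.0 - min(noise_rate * 2, 0.2)), 1) if noise_rate else 99.0
        contigs.append(Contig(id=cid, sequence=seq, source="sim"))
        truth.contig_protein[cid] = pid
        truth.contig_hits[cid] = {
            "s_start": int(s_start),
            "s_end": int(s_end),
            "aln_len_aa": int(aln_len),
            "pct_identity": ident,
            "q_start": int(q_start),
        }

    for pid, aa_len in zip(proteome["protein_id"], proteome["length"]):
        aa_len = int(aa_len)
        gene = _random_seq(rng, 3 * aa_len, gc_target)
        entry = plan.get(pid)
        if entry is None:
            add(f"{pid}_t1", gene, pid, 1, aa_len, aa_len)
            continue
        members = _plant_group(rng, pid, gene, aa_len, entry, gc_target, add)
        truth.events.append(
            {"protein_id": pid, "event_type": entry.event_type, "contigs": members}
        )

    for j in range(1, n_junk + 1):
        cid = f"JUNK{j:04d}"
        seq = _random_seq(rng, int(rng.integers(400, 801)), gc_target)
        contigs.append(Contig(id=cid, sequence=seq, source="sim"))
        truth.junk_rule[cid] = "evalue" if j % 2 else "coverage"
    return contigs, truth


def _plant_group(rng, pid, gene, aa_len, entry: PlanEntry, gc, add) -> list[str]:
    """Apply the event-specific sequence surgery for one group."""
    L = 3 * aa_len
    ids: list[str] = []
    etype = entry.event_type

    if etype == GENE_BREAKAGE:
        # disjoint fragments with an unassembled gap between them
        k = entry.group_size
        cuts = np.linspace(0, aa_len, k + 1).astype(int)
        for idx in range(k):
            a_lo, a_hi = cuts[idx], cuts[idx + 1]
            # shave the ends so consecutive subject intervals are disjoint
            pad = max(5, (a_hi - a_lo) // 10)
            s_start, s_end = a_lo + (pad if idx > 0 else 0) + 1, a_hi - (
                pad if idx < k - 1 else 0
            )
            frag = gene[(s_start - 1) * 3 : s_end * 3]
            cid = f"{pid}_t{idx + 1}"
            add(cid, frag, pid, s_start, s_end, s_end - s_start + 1)
            ids.append(cid)
        return ids

    # other event types: member 1 is the intact gene, the rest are variants
    cid = f"{pid}_t1"
    add(cid, gene, pid, 1, aa_len, aa_len)
    ids.append(cid)
    for idx in range(2, entry.group_size + 1):
        cid = f"{pid}_t{idx}"
        if etype == ALT_SPLICING:
            # internal in-frame deletion, exon-scale, keeping coverage >= 80%
            d_aa = int(max(12, min(0.15 * aa_len, 50)))
            pos_aa = int(rng.integers(int(0.2 * aa_len), int(0.8 * aa_len) - d_aa))
            var = gene[: pos_aa * 3] + gene[(pos_aa + d_aa) * 3 :]
            add(cid, var, pid, 1, aa_len, aa_len - d_aa)
        elif etype == ALT_START_END:
            ext = int(rng.integers(30, 121))
            if rng.random() < 0.5:
                var = _random_seq(rng, ext, gc) + gene
                add(cid, var, pid, 1, aa_len, aa_len, q_start=ext + 1)
            else:
                var = gene + _random_seq(rng, ext, gc)
                add(cid, var, pid, 1, aa_len, aa_len)
        elif etype == FALSE_ASSEMBLY:
            # replace a large internal window with unrelated sequence
            w = int(0.4 * L)
            pos = int(rng.integers(int(0.2 * L), int(0.6 * L) - 1))
            var = gene[:pos] + _random_seq(rng, w, gc) + gene[pos + w :]
            add(cid, var, pid, 1, aa_len, aa_len)
        else:  # pragma: no cover - PlanEntry already validates
            raise ValueError(etype)
        ids.append(cid)
    return ids


def generate_blast_table(
    contigs: Sequence[Contig],
    truth: FixtureTruth,
    proteome: pd.DataFrame,
    seed: int = 0,
    decoy_rate: float = 0.0,
) -> list[BlastHit]:
    """One plausible hit per contig plus optional decoy hits.

    The true hit reflects the planted surgery (subject interval, aligned
    length).  Decoys target a random other protein and are built to fail
    the three-step filter — E-value above 1e-10 or coverage below 80% —
    while always ranking below the contig's true hit, so they exercise
    top-hit selection and the filter without disturbing the truth.
    """
    rng = np.random.default_rng(seed)
    plen = dict(zip(proteome["protein_id"], (int(x) for x in proteome["length"])))
    pids = list(proteome["protein_id"])
    hits: list[BlastHit] = []

    def evalue_for(aln_len: int, ident_frac: float) -> float:
        expo = min(aln_len * ident_frac * 0.25, 180.0)
        return 10.0 ** (-expo)

    def make_hit(cid, pid, s_start, s_end, aln_len, ident, q_start, evalue=None):
        ident_frac = ident / 100.0
        ev = evalue_for(aln_len, ident_frac) if evalue is None else evalue
        return BlastHit(
            query_id=cid,
            subject_id=pid,
            pct_identity=ident,
            aln_len_aa=aln_len,
            mismatches=int(round(aln_len * (1 - ident_frac))),
            gap_opens=0,
            q_start=q_start,
            q_end=q_start + 3 * aln_len - 1,
            s_start=s_start,
            s_end=s_end,
            evalue=ev,
            bitscore=round(2.0 * aln_len * ident_frac, 1),
            subject_len_aa=plen[pid],
        )

    for c in contigs:
        if c.id in truth.junk_rule:
            pid = pids[int(rng.integers(len(pids)))]
            aa = plen[pid]
            if truth.junk_rule[c.id] == "evalue":
                aln = max(int(0.9 * aa), 1)
                hits.append(
                    make_hit(c.id, pid, 1, aln, aln, 35.0, 1,
                             evalue=float(10.0 ** -rng.uniform(3, 9)))
                )
            else:  # coverage failure: short but confident alignment
                aln = max(int(0.5 * aa), 1)
                hits.append(make_hit(c.id, pid, 1, aln, aln, 95.0, 1))
            continue
        info = truth.contig_hits[c.id]
        true_hit = make_hit(
            c.id,
            truth.contig_protein[c.id],
            info["s_start"],
            info["s_end"],
            info["aln_len_aa"],
            info["pct_identity"],
            info["q_start"],
        )
        hits.append(true_hit)
        if rng.random() < decoy_rate:
            others = [p for p in pids if p != true_hit.subject_id]
            pid = others[int(rng.integers(len(others)))]
            aa = plen[pid]
            if rng.random() < 0.5:  # weak decoy: fails the E-value rule
                aln = max(int(0.85 * aa), 1)
                ev = float(10.0 ** -rng.uniform(2, 9))
            else:  # fragment decoy: fails coverage, still worse than true
                aln = max(int(rng.uniform(0.3, 0.7) * aa), 1)
                ev = min(max(true_hit.evalue * 1e3, 1e-170), 1e-12)
            hits.append(make_hit(c.id, pid, 1, aln, aln, 45.0, 1, evalue=ev))
    return hits


def generate_annotation_map(
    proteome: pd.DataFrame,
    seed: int = 0,
    ko_fraction: float = 0.85,
    ko_share: float = 0.15,
    n_go_pool: int = 20,
    planted_term: str | None = None,
    planted_proteins: Sequence[str] = (),
) -> AnnotationMap:
    """Synthetic protein -> KEGG gene / KO / GO associations.

    ``ko_fraction`` of proteins receive a KO; ``ko_share`` of those share
    a KO with another protein (to exercise the KO collapse).  Each
    protein draws 1-3 GO terms from a pool of ``n_go_pool``; if a
    ``planted_term`` is given it is attached to exactly the listed
    proteins and to no others.
    """
    rng = np.random.default_rng(seed)
    amap = AnnotationMap()
    pids = list(proteome["protein_id"])
    n_kos = max(1, int(len(pids) * ko_fraction * (1 - ko_share)))
    pool = [f"GO:{i:07d}" for i in range(1, n_go_pool + 1)]
    ko_counter = 0
    for pid in pids:
        amap.kegg_gene[pid] = f"dtx:{pid.lower()}"
        if rng.random() < ko_fraction:
            ko_counter += 1
            amap.ko[pid] = f"K{1 + (ko_counter % n_kos):05d}"
        gos = set(rng.choice(pool, size=int(rng.integers(1, 4)), replace=False))
        if planted_term and pid in set(planted_proteins):
            gos.add(planted_term)
        amap.go[pid] = frozenset(gos)
    return amap


def generate_de_table(
    contigs: Sequence[Contig],
    planted_ids: Sequence[str],
    effect: float = 4.0,
    seed: int = 0,
) -> tuple[list[DERecord], FixtureTruth]:
    """DE table with a planted up-regulated gene set.

    Planted contigs get signed fold change >= ``effect`` with PPEE well
    under the 0.05 call threshold; background contigs get |FC| < 2 with
    PPEE uniform on [0, 1], so at the default cutoffs the called set is
    exactly the planted set.
    """
    if effect < 1:
        raise ValueError("effect size must be >= 1")
    rng = np.random.default_rng(seed)
    planted = set(planted_ids)
    records = []
    truth = FixtureTruth(seed=seed, params={"effect": effect})
    for c in contigs:
        if c.id in planted:
            fc = effect * (1.0 + rng.uniform(0, 1))
            ppee = rng.uniform(0, 0.02)
            truth.expected_up.append(c.id)
        else:
            fc = (1.0 + rng.uniform(0, 0.3)) * (1 if rng.random() < 0.5 else -1)
            ppee = rng.uniform(0, 1)
        records.append(DERecord(contig_id=c.id, fold_change_signed=float(fc), ppee=float(ppee)))
    truth.expected_up.sort()
    return records, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESETS = ("filter", "events", "enrichment", "full")


def generate_preset(preset: str, outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete named fixture into ``outdir``.

    Presets: ``filter`` (singleton groups, junk contigs and decoy hits to
    exercise the three-step filter), ``events`` (planted redundancy
    groups of every type), ``enrichment`` (planted enriched term plus a
    matching DE table), ``full`` (everything, plus a core-gene list).
    Returns the paths written; ``truth.json`` holds the planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)
    if preset == "filter":
        proteome = generate_proteome(50, seed=rng_seed)
        contigs, truth = generate_contigs(proteome, seed=rng_seed, n_junk=15)
        hits = generate_blast_table(contigs, truth, proteome, seed=rng_seed, decoy_rate=0.3)
        amap = generate_annotation_map(proteome, seed=rng_seed)
        de, core = None, None
    elif preset == "events":
        plan = _events_plan(10)
        proteome = generate_proteome(4 * 10, len_range=(150, 300), seed=rng_seed)
        contigs, truth = generate_contigs(proteome, plan_for(proteome, plan), seed=rng_seed)
        hits = generate_blast_table(contigs, truth, proteome, seed=rng_seed)
        amap = generate_annotation_map(proteome, seed=rng_seed)
        de, core = None, None
    elif preset == "enrichment":
        proteome = generate_proteome(120, seed=rng_seed)
        contigs, truth = generate_contigs(proteome, seed=rng_seed)
        hits = generate_blast_table(contigs, truth, proteome, seed=rng_seed)
        planted_proteins = sorted(proteome["protein_id"])[:12]
        amap = generate_annotation_map(
            proteome, seed=rng_seed, planted_term=PLANTED_TERM,
            planted_proteins=planted_proteins,
        )
        planted_contigs = sorted(
            cid for cid, pid in truth.contig_protein.items() if pid in set(planted_proteins)
        )
        de, de_truth = generate_de_table(contigs, planted_contigs, effect=4.0, seed=rng_seed)
        truth.planted_term = PLANTED_TERM
        truth.planted_genes = planted_contigs
        truth.expected_up = de_truth.expected_up
        core = None
    elif preset == "full":
        plan_types = _events_plan(3)
        proteome = generate_proteome(60, len_range=(150, 300), seed=rng_seed)
        plan = plan_for(proteome, plan_types)
        contigs, truth = generate_contigs(proteome, plan, seed=rng_seed, n_junk=10)
        hits = generate_blast_table(contigs, truth, proteome, seed=rng_seed, decoy_rate=0.2)
        planted_proteins = sorted(set(proteome["protein_id"]) - set(plan))[:10]
        amap = generate_annotation_map(
            proteome, seed=rng_seed, planted_term=PLANTED_TERM,
            planted_proteins=planted_proteins,
        )
        planted_contigs = sorted(
            f"{p}_t1" for p in planted_proteins
        )
        de, de_truth = generate_de_table(contigs, planted_contigs, effect=4.0, seed=rng_seed)
        truth.planted_term = PLANTED_TERM
        truth.planted_genes = planted_contigs
        truth.expected_up = de_truth.expected_up
        # core catalogue: mostly singleton proteins (annotatable) plus ids
        # the transcriptome cannot contain
        singles = sorted(set(proteome["protein_id"]) - set(plan))
        core = set(singles[:22]) | {f"CEGX{i:03d}" for i in range(3)}
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")

    paths = {
        "contigs": outdir / "contigs.fasta",
        "hits": outdir / "hits.tsv",
        "annotation_map": outdir / "annotation_map.tsv",
        "protein_lengths": outdir / "protein_lengths.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(contigs, paths["contigs"])
    write_blast_tab(hits, paths["hits"])
    write_annotation_map(amap, paths["annotation_map"])
    write_protein_lengths(
        dict(zip(proteome["protein_id"], (int(x) for x in proteome["length"]))),
        paths["protein_lengths"],
    )
    if de is not None:
        paths["de_table"] = outdir / "de_table.tsv"
        write_de_table(de, paths["de_table"])
    if core is not None:
        paths["core_genes"] = outdir / "core_genes.txt"
        write_id_list(core, paths["core_genes"])
    truth.to_json(paths["truth"])
    return paths


def _events_plan(per_type: int) -> list[str]:
    out = []
    for et in (FALSE_ASSEMBLY, ALT_START_END, GENE_BREAKAGE, ALT_SPLICING):
        out.extend([et] * per_type)
    return out


def plan_for(proteome: pd.DataFrame, event_types: Sequence[str]) -> dict[str, PlanEntry]:
    """Assign the listed event types to the first proteins of the table."""
    pids = list(proteome["protein_id"])
    if len(event_types) > len(pids):
        raise ValueError("more planned events than proteins")
    return {pid: PlanEntry(et) for pid, et in zip(pids, event_types)}
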