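"""End-to-end orchestration: merge, filter, collapse, score, classify.

``run_pipeline`` wires the stages together with a single declarative
config, writes every product as deterministic TSV/FASTA/JSON, and
returns a run report carrying per-stage input/output counts, the
thresholds used, the package version and a SHA-256 digest of every
output file, so two runs on the same inputs can be compared byte for
byte.  Per-record rejections go to the audit TSV, not the log.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .consolidate import (
    annotate,
    apply_three_step_filter,
    collapse_by_ko,
    merge_assemblies,
    select_top_hits,
)
from .diffexpr import call_de
from .enrichment import enrich_terms
from .events import EventThresholds, classify_redundant
from .io_formats import (
    read_annotation_map,
    read_blast_tab,
    read_de_table,
    read_fasta,
    read_id_list,
    read_protein_lengths,
    write_fasta,
    write_id_list,
)
from .metrics import completeness, compute_stats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run.

    ``fasta_inputs`` maps an assembly-source label to its FASTA path.
    Optional stages are enabled by supplying their inputs (DE table,
    core-gene list) or the ``classify_events`` toggle.
    """

    fasta_inputs: dict[str, str] = field(default_factory=dict)
    blast_tsv: str = ""
    blast_dialect: str = "std12+slen"
    annotation_map_tsv: str = ""
    protein_lengths_tsv: str | None = None
    de_table_tsv: str | None = None
    core_genes_txt: str | None = None
    out_dir: str = "nrtx_out"
    evalue_max: float = 1e-10
    min_coverage: float = 0.80
    fc_cut: float = 2.0
    ppee_cut: float = 0.05
    identity_min: float = 0.90
    min_gap_block: int = 30
    end_tolerance: int = 15
    min_subject_overlap: int = 10
    classify_events: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must lie in (0, 1]")
        if self.evalue_max < 0:
            raise ValueError("evalue_max must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the run report (also written
    as ``report.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "thresholds": {
            "evalue_max": config.evalue_max,
            "min_coverage": config.min_coverage,
            "fc_cut": config.fc_cut,
            "ppee_cut": config.ppee_cut,
        },
        "stages": {},
        "outputs": {},
    }

    # merge
    contig_sets = {
        src: read_fasta(path, source=src) for src, path in sorted(config.fasta_inputs.items())
    }
    merged = merge_assemblies(contig_sets)
    contig_len = {c.id: len(c) for c in merged}
    merged_path = out / "merged.fasta"
    write_fasta(merged, merged_path)
    report["stages"]["merge"] = {
        "sources": {s: len(v) for s, v in contig_sets.items()},
        "merged_contigs": len(merged),
    }
    logger.info("merged %d contigs from %d sources", len(merged), len(contig_sets))

    # assembly metrics
    stats = compute_stats(merged)
    report["stages"]["metrics"] = asdict(stats)

    # top hits + three-step filter + KO collapse
    hits = read_blast_tab(config.blast_tsv, dialect=config.blast_dialect)
    protein_lengths = (
        read_protein_lengths(config.protein_lengths_tsv)
        if config.protein_lengths_tsv
        else None
    )
    tophits = select_top_hits(hits)
    nr = apply_three_step_filter(
        tophits,
        contig_len,
        protein_lengths=protein_lengths,
        evalue_max=config.evalue_max,
        min_coverage=config.min_coverage,
    )
    amap = read_annotation_map(config.annotation_map_tsv)
    nr_records = annotate(nr, amap, contig_len)
    ko_set = collapse_by_ko(nr, amap, contig_len)
    report["stages"]["consolidate"] = {
        "hits": len(hits),
        "top_hits": len(tophits),
        "non_redundant": len(nr.records),
        "ko_unique": len(ko_set.records),
    }

    _write_tsv(
        out / "nr_annotation.tsv",
        ["contig_id", "protein_id", "kegg_gene", "ko", "go_terms", "evalue", "contig_len"],
        [
            [r.contig_id, r.protein_id, r.kegg_gene or "", r.ko or "",
             ";".join(sorted(r.go_terms)), repr(r.evalue), r.contig_len]
            for r in nr_records
        ],
    )
    _write_tsv(
        out / "ko_unique.tsv",
        ["contig_id", "protein_id", "ko", "evalue", "contig_len"],
        [[r.contig_id, r.protein_id, r.ko, repr(r.evalue), r.contig_len]
         for r in ko_set.records],
    )
    audit_rows = [[r.query_id, r.subject_id, r.rule] for r in nr.removals]
    audit_rows += [[r.query_id, r.subject_id, r.rule] for r in ko_set.removals]
    audit_rows.sort()
    _write_tsv(out / "removal_audit.tsv", ["contig_id", "protein_id", "rule"], audit_rows)

    # completeness against a core-gene catalogue
    if config.core_genes_txt:
        core = read_id_list(config.core_genes_txt)
        frac = completeness({r.protein_id for r in nr_records}, core)
        report["stages"]["completeness"] = {"core_genes": len(core), "fraction": frac}

    # DE calling + enrichment
    if config.de_table_tsv:
        de_records = read_de_table(config.de_table_tsv)
        calls = call_de(de_records, fc_cut=config.fc_cut, ppee_cut=config.ppee_cut)
        write_id_list(calls.up, out / "de_up.txt")
        write_id_list(calls.down, out / "de_down.txt")
        report["stages"]["diffexpr"] = {
            "records": len(de_records),
            "up": len(calls.up),
            "down": len(calls.down),
        }
        gene_terms = {
            r.contig_id: amap.go.get(r.protein_id, frozenset()) for r in nr_records
        }
        background = set(gene_terms)
        up_in_bg = set(calls.up) & background
        table = enrich_terms(up_in_bg, background, gene_terms)
        table.to_csv(out / "enrichment_go_up.tsv", sep="\t", index=False)
        report["stages"]["enrichment"] = {
            "terms_scored": int(len(table)),
            "top_term": table.iloc[0]["term_id"] if len(table) else None,
            "top_score": float(table.iloc[0]["score"]) if len(table) else None,
        }

    # redundancy-event classification (pre-filter hits, so redundant
    # contigs survive)
    if config.classify_events:
        thr = EventThresholds(
            identity_min=config.identity_min,
            min_gap_block=config.min_gap_block,
            end_tolerance=config.end_tolerance,
            min_subject_overlap=config.min_subject_overlap,
        )
        group_calls = classify_redundant(merged, tophits, thr)
        rows = []
        for gc in group_calls:
            for pc in gc.pair_calls:
                rows.append(
                    [gc.protein_id, pc.contig_a, pc.contig_b,
                     f"{pc.call.identity:.4f}", pc.call.overlap_aa,
                     pc.call.event_type, pc.call.splice_subtype or ""]
                )
        _write_tsv(
            out / "redundancy_events.tsv",
            ["protein_id", "contig_a", "contig_b", "identity", "overlap_aa",
             "event_type", "subtype"],
            rows,
        )
        report["stages"]["events"] = {
            "groups": len(group_calls),
            "by_type": _count_by(gc.event_type for gc in group_calls),
        }

    for path in sorted(out.iterdir()):
        if path.name != "report.json" and path.is_file():
            report["outputs"][path.name] = _sha256(path)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _count_by(items) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in items:
        out[i] = out.get(i, 0) + 1
    return dict(sorted(out.items()))
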