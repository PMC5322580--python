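"""Readers and writers for every external file the toolkit touches.

All tabular formats are plain TSV; sequences travel as FASTA.  Readers
validate aggressively and raise :class:`FormatError` with the offending
record named, writers emit deterministic, byte-stable output (records
sorted by their primary identifier) so repeated runs can be compared by
digest.

Conventions
-----------
* Nucleotide sequences are uppercased on read; the alphabet is
  ``{A, C, G, T, N}``.  ``U`` is rejected: contigs are DNA.
* BLAST tabular coordinates stay 1-based inclusive exactly as emitted by
  ``blastx -outfmt 6``; conversion to half-open intervals happens only
  inside geometry computations.
* The canonical BLAST dialect is ``std12+slen`` (the 12 standard columns
  plus ``slen``, the subject protein length, as a 13th column) because the
  subject-coverage filter needs the subject length on every row.  Plain
  ``std12`` is accepted, leaving ``subject_len_aa`` unset, to be joined
  later from a protein-length table.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

FASTA_WRAP = 70

_VALID_SEQ = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """An assembled transcript sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a contig set.
    sequence : str
        Uppercase nucleotide sequence over ``{A, C, G, T, N}``.
    source : str
        Assembly-source label (which assembler/run produced it).
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("contig id must be non-empty")
        if not self.sequence:
            raise FormatError(f"contig {self.id!r}: empty sequence")
        bad = _VALID_SEQ.search(self.sequence)
        if bad:
            raise FormatError(
                f"contig {self.id!r}: illegal symbol {bad.group()!r} at "
                f"position {bad.start() + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BlastHit:
    """One BLASTX alignment record (nucleotide query vs. protein subject).

    Coordinates are 1-based inclusive; ``q_start > q_end`` encodes a
    reverse-frame hit.  ``subject_len_aa`` is ``None`` when the input
    dialect did not carry it.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len_aa: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_len_aa: int | None = None

    def __post_init__(self) -> None:
        if self.pct_identity < 0 or self.pct_identity > 100:
            raise FormatError(f"hit {self.query_id}: pct_identity outside [0,100]")
        if self.aln_len_aa < 1:
            raise FormatError(f"hit {self.query_id}: alignment length < 1")
        if self.mismatches < 0 or self.gap_opens < 0:
            raise FormatError(f"hit {self.query_id}: negative count field")
        if self.s_start > self.s_end:
            raise FormatError(
                f"hit {self.query_id} vs {self.subject_id}: s_start > s_end"
            )
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}: negative E-value")
        if self.subject_len_aa is not None and self.subject_len_aa < self.s_end:
            raise FormatError(
                f"hit {self.query_id} vs {self.subject_id}: subject length "
                f"{self.subject_len_aa} < s_end {self.s_end}"
            )


@dataclass
class AnnotationMap:
    """Protein accession -> KEGG gene / KO / GO-term-set associations.

    Each protein maps to at most one KO; the GO set may be empty.
    """

    kegg_gene: dict[str, str] = field(default_factory=dict)
    ko: dict[str, str] = field(default_factory=dict)
    go: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def proteins(self) -> set[str]:
        return set(self.kegg_gene) | set(self.ko) | set(self.go)


@dataclass(frozen=True)
class DERecord:
    """Per-contig differential-expression evidence from an upstream fit.

    ``fold_change_signed`` uses the signed convention: a ratio r >= 1 is
    reported as +r, a ratio r < 1 as -1/r, so its magnitude is always >= 1.
    ``ppee`` is the posterior probability of equal expression, used as an
    FDR-like quantity.
    """

    contig_id: str
    fold_change_signed: float
    ppee: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ppee <= 1.0:
            raise FormatError(f"{self.contig_id}: PPEE {self.ppee} outside [0,1]")
        if abs(self.fold_change_signed) < 1.0:
            raise FormatError(
                f"{self.contig_id}: |signed fold change| "
                f"{self.fold_change_signed} < 1"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, source: str = "") -> list[Contig]:
    """Read a FASTA file into validated :class:`Contig` records.

    Wrapped sequence lines are concatenated and uppercased; input order is
    preserved.  Duplicate ids, empty sequences and symbols outside
    ``{A,C,G,T,N}`` raise :class:`FormatError`.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, sequence=str(rec.seq).upper(), source=source))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    """Write contigs sorted by id, wrapped at 70 columns."""
    ordered = sorted(contigs, key=lambda c: c.id)
    with open(path, "w") as fh:
        for c in ordered:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), FASTA_WRAP):
                fh.write(c.sequence[i : i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

_BLAST_DIALECTS = ("std12", "std12+slen")


def _num(value: str, kind, what: str, lineno: int):
    try:
        return kind(value)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric {what} field {value!r}") from exc


def read_blast_tab(path: str | Path, dialect: str = "std12+slen") -> list[BlastHit]:
    """Parse BLAST ``-outfmt 6`` style TSV into :class:`BlastHit` records.

    ``dialect`` is ``"std12"`` (the 12 standard columns) or
    ``"std12+slen"`` (13th column = subject protein length in residues).
    """
    if dialect not in _BLAST_DIALECTS:
        raise ValueError(f"unknown BLAST dialect {dialect!r}")
    want = 13 if dialect == "std12+slen" else 12
    hits: list[BlastHit] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != want:
                raise FormatError(
                    f"{path}: line {lineno}: expected {want} columns "
                    f"({dialect}), found {len(row)}"
                )
            hits.append(
                BlastHit(
                    query_id=row[0],
                    subject_id=row[1],
                    pct_identity=_num(row[2], float, "identity", lineno),
                    aln_len_aa=_num(row[3], int, "alignment-length", lineno),
                    mismatches=_num(row[4], int, "mismatch", lineno),
                    gap_opens=_num(row[5], int, "gap-open", lineno),
                    q_start=_num(row[6], int, "q_start", lineno),
                    q_end=_num(row[7], int, "q_end", lineno),
                    s_start=_num(row[8], int, "s_start", lineno),
                    s_end=_num(row[9], int, "s_end", lineno),
                    evalue=_num(row[10], float, "evalue", lineno),
                    bitscore=_num(row[11], float, "bitscore", lineno),
                    subject_len_aa=(
                        _num(row[12], int, "subject-length", lineno) if want == 13 else None
                    ),
                )
            )
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Write hits as TSV, sorted for byte-stable output.

    Floats are written with ``repr`` so a read-back round-trips exactly.
    """
    ordered = sorted(
        hits, key=lambda h: (h.query_id, h.evalue, -h.bitscore, h.subject_id, h.s_start)
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in ordered:
            row = [
                h.query_id,
                h.subject_id,
                repr(h.pct_identity),
                h.aln_len_aa,
                h.mismatches,
                h.gap_opens,
                h.q_start,
                h.q_end,
                h.s_start,
                h.s_end,
                repr(h.evalue),
                repr(h.bitscore),
            ]
            if h.subject_len_aa is not None:
                row.append(h.subject_len_aa)
            w.writerow(row)


def join_subject_lengths(
    hits: Sequence[BlastHit], protein_lengths: Mapping[str, int]
) -> list[BlastHit]:
    """Fill ``subject_len_aa`` from a protein-length table for std12 input."""
    out = []
    for h in hits:
        if h.subject_len_aa is None:
            length = protein_lengths.get(h.subject_id)
            if length is None:
                raise FormatError(
                    f"no subject length available for protein {h.subject_id!r}"
                )
            h = replace(h, subject_len_aa=length)
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# annotation map / DE table / id lists / protein lengths
# ---------------------------------------------------------------------------

_MAP_HEADER = ["protein_id", "kegg_gene", "ko", "go_terms"]


def read_annotation_map(path: str | Path) -> AnnotationMap:
    """Read the annotation map TSV.

    Header: ``protein_id<TAB>kegg_gene<TAB>ko<TAB>go_terms`` with go_terms
    semicolon-separated (possibly empty).  Unknown columns are ignored with
    a warning.  A protein assigned two different KOs is an error.
    """
    amap = AnnotationMap()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _MAP_HEADER if c not in header]
        if missing:
            raise FormatError(f"{path}: missing annotation-map columns {missing}")
        extra = [c for c in header if c not in _MAP_HEADER]
        if extra:
            logger.warning("%s: ignoring unknown columns %s", path, extra)
        for row in reader:
            pid = row["protein_id"].strip()
            if not pid:
                raise FormatError(f"{path}: empty protein_id")
            ko = row["ko"].strip()
            if ko:
                prev = amap.ko.get(pid)
                if prev is not None and prev != ko:
                    raise FormatError(
                        f"{path}: protein {pid!r} mapped to two KOs ({prev}, {ko})"
                    )
                amap.ko[pid] = ko
            gene = row["kegg_gene"].strip()
            if gene:
                amap.kegg_gene[pid] = gene
            gos = frozenset(t for t in row["go_terms"].strip().split(";") if t)
            amap.go[pid] = amap.go.get(pid, frozenset()) | gos
    return amap


def write_annotation_map(amap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MAP_HEADER)
        for pid in sorted(amap.proteins):
            w.writerow(
                [
                    pid,
                    amap.kegg_gene.get(pid, ""),
                    amap.ko.get(pid, ""),
                    ";".join(sorted(amap.go.get(pid, frozenset()))),
                ]
            )


_FC_COLUMNS = ("fold_change", "PostFC", "RealFC")


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read the per-contig DE table.

    Header ``contig_id<TAB>fold_change<TAB>ppee``; the fold-change column
    may also be named ``PostFC`` or ``RealFC`` (upstream naming varies).
    """
    records: list[DERecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        fc_col = next((c for c in _FC_COLUMNS if c in header), None)
        if fc_col is None or "contig_id" not in header or "ppee" not in header:
            raise FormatError(
                f"{path}: DE table needs columns contig_id, "
                f"one of {_FC_COLUMNS}, and ppee; found {header}"
            )
        extra = [c for c in header if c not in ("contig_id", fc_col, "ppee")]
        if extra:
            logger.warning("%s: ignoring unknown columns %s", path, extra)
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    DERecord(
                        contig_id=row["contig_id"],
                        fold_change_signed=float(row[fc_col]),
                        ppee=float(row["ppee"]),
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: line {lineno}: bad numeric field") from exc
    return records


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig_id", "fold_change", "ppee"])
        for r in sorted(records, key=lambda r: r.contig_id):
            w.writerow([r.contig_id, repr(r.fold_change_signed), repr(r.ppee)])


def read_id_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line list; ``#`` starts a comment."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return ids


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(i + "\n")


def read_protein_lengths(path: str | Path) -> dict[str, int]:
    """Read a ``protein_id<TAB>length`` TSV (header optional)."""
    lengths: dict[str, int] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if lineno == 1 and row[0] == "protein_id":
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            lengths[row[0]] = _num(row[1], int, "length", lineno)
    return lengths


def write_protein_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "length"])
        for pid in sorted(lengths):
            w.writerow([pid, lengths[pid]])
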