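"""Descriptive assembly statistics: length distribution, N50, GC, completeness.

N50 is the length of the contig at which the cumulative length of contigs
sorted in descending order first reaches at least half of the total
assembly size; the threshold comparison uses exact integer arithmetic
(``2 * cumulative >= total``) so odd totals never hit a floating-point
halving.  GC content is pooled over all contigs (total G+C over total
unambiguous bases), matching the genome-level convention used in
cross-species comparisons, with ``N`` excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable, Sequence

from .io_formats import Contig


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_len: int
    max_len: int
    mean_len: float
    n50: int
    gc_fraction: float | None = None


def compute_length_stats(contigs: Sequence[Contig]) -> AssemblyStats:
    """Contig-count, total/max/mean length and N50 for a contig set."""
    if not contigs:
        raise ValueError("cannot compute length statistics of an empty contig set")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for length in lengths:
        cum += length
        if 2 * cum >= total:
            n50 = length
            break
    return AssemblyStats(
        n_contigs=len(lengths),
        total_len=total,
        max_len=lengths[0],
        mean_len=total / len(lengths),
        n50=n50,
    )


def compute_gc(contigs: Iterable[Contig]) -> float:
    """Pooled GC fraction: (G+C) / (A+C+G+T) over all contigs."""
    gc = 0
    acgt = 0
    for c in contigs:
        seq = c.sequence
        gc += seq.count("G") + seq.count("C")
        acgt += len(seq) - seq.count("N")
    if acgt == 0:
        raise ValueError("no unambiguous bases: GC fraction undefined")
    return gc / acgt


def compute_stats(contigs: Sequence[Contig]) -> AssemblyStats:
    """Length statistics plus pooled GC in one record."""
    base = compute_length_stats(contigs)
    return AssemblyStats(
        n_contigs=base.n_contigs,
        total_len=base.total_len,
        max_len=base.max_len,
        mean_len=base.mean_len,
        n50=base.n50,
        gc_fraction=compute_gc(contigs),
    )


def completeness(
    annotated_protein_ids: Collection[str], core_gene_ids: Collection[str]
) -> float:
    """Fraction of a core-gene catalogue recovered by the annotation.

    The catalogue is supplied as a precomputed id list (the operation is
    catalogue-agnostic); the value is |annotated ∩ core| / |core|.
    """
    core = set(core_gene_ids)
    if not core:
        raise ValueError("core gene set is empty")
    return len(core & set(annotated_protein_ids)) / len(core)
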