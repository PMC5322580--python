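"""Differential-expression calling on upstream posterior fold changes.

Quantification and the posterior model run upstream (e.g. RSEM followed
by EBSeq); this module only applies the call thresholds to their output:
a transcript is called when |signed fold change| >= 2 and PPEE <= 0.05,
both boundaries inclusive.  PPEE (posterior probability of equal
expression) is treated as an FDR-like quantity and not corrected further.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import DERecord

FC_CUT_DEFAULT = 2.0
PPEE_CUT_DEFAULT = 0.05


@dataclass(frozen=True)
class DECallSet:
    """Up- and down-regulated id sets plus the thresholds that made them."""

    up: frozenset[str]
    down: frozenset[str]
    fc_cut: float
    ppee_cut: float

    @property
    def called(self) -> frozenset[str]:
        return self.up | self.down


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Expression ratio in the signed convention.

    r = mean_a / mean_b is returned as +r when r >= 1 and as -1/r when
    r < 1, so the magnitude is always >= 1 and the sign encodes the
    direction of change.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("means must be positive")
    r = mean_a / mean_b
    return r if r >= 1 else -1.0 / r


def call_de(
    de_records: Iterable[DERecord],
    fc_cut: float = FC_CUT_DEFAULT,
    ppee_cut: float = PPEE_CUT_DEFAULT,
) -> DECallSet:
    """Apply the fold-change / PPEE cutoffs (both inclusive).

    Up: fold_change_signed >= fc_cut and ppee <= ppee_cut.
    Down: fold_change_signed <= -fc_cut and ppee <= ppee_cut.
    """
    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1")
    if not 0 <= ppee_cut <= 1:
        raise ValueError("ppee_cut must lie in [0, 1]")
    up, down = set(), set()
    for r in de_records:
        if r.ppee > ppee_cut:
            continue
        if r.fold_change_signed >= fc_cut:
            up.add(r.contig_id)
        elif r.fold_change_signed <= -fc_cut:
            down.add(r.contig_id)
    return DECallSet(frozenset(up), frozenset(down), fc_cut, ppee_cut)
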