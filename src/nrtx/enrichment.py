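"""Hypergeometric term-enrichment scoring for GO / KO / pathway terms.

For a background of N annotated genes of which M carry term b, and a
condition gene set of n genes of which m carry b, the over-representation
p-value is the hypergeometric upper tail

    p = sum_{k=m}^{min(n, M)} C(M, k) C(N-M, n-k) / C(N, n)

and the enrichment score is -log10(p).  Scores are comparable only within
one background; no cross-study normalisation is attempted.  Raw scores
are reported as-is; a Benjamini-Hochberg FDR column is added to the table
as an optional convenience.
"""

from __future__ import annotations

from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_upper_tail(N: int, M: int, n: int, m) -> float | np.ndarray:
    """Upper-tail hypergeometric p-value P(X >= m).

    Parameters are the background size ``N``, term-annotated background
    count ``M``, condition-set size ``n`` and overlap ``m``; ``m`` may be
    a scalar or an array.  The result lies in (0, 1]; ``m = 0`` gives
    exactly 1.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= M <= N and 0 <= n <= N, got N={N} M={M} n={n}")
    m_arr = np.asarray(m)
    if np.any(m_arr < 0) or np.any(m_arr > np.minimum(M, n)):
        raise ValueError(f"require 0 <= m <= min(M, n), got m={m} M={M} n={n}")
    # sf(m-1) = P(X >= m); exact 1.0 at m = 0.
    p = hypergeom.sf(m_arr - 1, N, M, n)
    p = np.minimum(p, 1.0)
    if np.isscalar(m) or m_arr.ndim == 0:
        return float(p)
    return p


def enrichment_score(p_value: float) -> float:
    """-log10 of the p-value; larger means more over-represented."""
    if not 0.0 < p_value <= 1.0:
        raise ValueError(f"p-value {p_value} outside (0, 1]")
    return -np.log10(p_value)


def enrich_terms(
    gene_set: Collection[str],
    background: Collection[str],
    gene_terms: Mapping[str, Collection[str]],
) -> pd.DataFrame:
    """Score every term observed in the gene set against the background.

    ``gene_terms`` maps each gene id to the terms of one ontology (GO, KO
    or pathway).  The background size N counts only background genes
    bearing at least one term of that ontology, and n is the number of
    condition genes among those; unannotated genes carry no evidence for
    or against any term.  Returns one row per term with m >= 1, columns
    ``term_id, N, M, n, m, p_value, score, bh_fdr``, sorted by descending
    score then term id.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    gene_set = set(gene_set)
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of the background")

    annotated = {g for g in background if gene_terms.get(g)}
    N = len(annotated)
    selected = gene_set & annotated
    n = len(selected)

    term_bg: dict[str, int] = {}
    term_sel: dict[str, int] = {}
    for g in annotated:
        for t in gene_terms[g]:
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in selected:
                term_sel[t] = term_sel.get(t, 0) + 1

    rows = []
    for term, m in term_sel.items():
        M = term_bg[term]
        p = hypergeom_upper_tail(N, M, n, m)
        rows.append((term, N, M, n, m, p, enrichment_score(p)))
    df = pd.DataFrame(
        rows, columns=["term_id", "N", "M", "n", "m", "p_value", "score"]
    )
    if len(df):
        df["bh_fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["bh_fdr"] = pd.Series(dtype=float)
    df = df.sort_values(
        ["score", "term_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
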