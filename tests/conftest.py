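import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nrtx.io_formats import BlastHit, Contig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_hit_table(seed, n_hits=200, n_queries=40, n_proteins=15):
    """Random BLAST hits with deliberate E-value/bitscore ties.

    Discrete E-value exponents and bitscores make exact ties common, so
    tie-break rules are genuinely exercised.  Returns (hits,
    contig_lengths, protein_lengths).
    """
    rng = np.random.default_rng(seed)
    plen = {f"P{i:03d}": int(rng.integers(100, 500)) for i in range(n_proteins)}
    clen = {f"Q{i:03d}": int(rng.integers(200, 2000)) for i in range(n_queries)}
    hits = []
    proteins = sorted(plen)
    queries = sorted(clen)
    for _ in range(n_hits):
        pid = proteins[int(rng.integers(n_proteins))]
        qid = queries[int(rng.integers(n_queries))]
        aln = int(rng.integers(20, plen[pid] + 1))
        s_start = int(rng.integers(1, plen[pid] - aln + 2))
        hits.append(
            BlastHit(
                query_id=qid,
                subject_id=pid,
                pct_identity=float(rng.integers(40, 101)),
                aln_len_aa=aln,
                mismatches=int(rng.integers(0, 20)),
                gap_opens=int(rng.integers(0, 3)),
                q_start=1,
                q_end=3 * aln,
                s_start=s_start,
                s_end=s_start + aln - 1,
                evalue=10.0 ** -int(rng.integers(2, 40)),
                bitscore=float(rng.integers(50, 301)),
                subject_len_aa=plen[pid],
            )
        )
    return hits, clen, plen


def random_contigs(seed, n=20, len_range=(50, 400)):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGTN", dtype=np.uint8)
    out = []
    for i in range(n):
        length = int(rng.integers(*len_range))
        seq = bases[rng.integers(0, 5, size=length)].tobytes().decode()
        # guarantee at least one unambiguous base
        seq = "A" + seq[1:]
        out.append(Contig(id=f"c{i:04d}", sequence=seq, source="rand"))
    return out


@pytest.fixture(scope="session")
def hit_fixture():
    return random_hit_table(seed=11)
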