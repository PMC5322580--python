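"""Assembly quality metrics: N50, GC content and core-gene completeness.

N50 is the contig length at which the descending cumulative length first
reaches half the assembly; GC is pooled over all contigs; completeness
is the fraction of a supplied core-gene catalogue recovered by the
annotation.
"""

from pathlib import Path

from nrtx.consolidate import apply_three_step_filter, select_top_hits
from nrtx.fixtures import generate_preset
from nrtx.io_formats import read_blast_tab, read_fasta, read_id_list
from nrtx.metrics import completeness, compute_stats

out = Path("scratch_example_metrics")
paths = generate_preset("full", out, seed=42)

contigs = read_fasta(paths["contigs"])
stats = compute_stats(contigs)
print(f"contigs:        {stats.n_contigs}")
print(f"total length:   {stats.total_len} bp")
print(f"max length:     {stats.max_len} bp")
print(f"mean length:    {stats.mean_len:.1f} bp")
print(f"N50:            {stats.n50} bp")
print(f"GC content:     {100 * stats.gc_fraction:.1f} %")

nr = apply_three_step_filter(
    select_top_hits(read_blast_tab(paths["hits"])), {c.id: len(c) for c in contigs}
)
core = read_id_list(paths["core_genes"])
frac = completeness(nr.protein_ids, core)
print(f"completeness:   {100 * frac:.1f} % of {len(core)} core genes recovered")
# The core list deliberately contains ids absent from the transcriptome,
# so completeness sits below 100% — as with any real core-gene catalogue.
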