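"""Full run: simulate a small single-cell long-read dataset and plot it.

Builds a 7-exon toy gene with three isoforms at cell-type-specific
proportions, writes it in every input dialect, then runs the whole
pipeline: clustering by intron chain, coordinate compression,
alternative-exon calling, mismatch finding and rendering.
"""

import json

from isostack import RunConfig, default_truth, run_plot, simulate_reads

truth = default_truth(seed=0)
ds = simulate_reads(truth, n_per_celltype={ct: 100 for ct in truth.cell_types},
                    seed=1, outdir="scratch/example01/fixture")

report = run_plot(RunConfig(
    gene_id="GENE1",
    outdir="scratch/example01/out",
    allinfo=str(ds.paths["allinfo"]),
    annotation=str(ds.paths["annotation"]),
    alignments=str(ds.paths["sam"]),
    fasta=str(ds.paths["fasta"]),
    formats=["svg", "pdf"],
))
print(json.dumps(report, indent=1))

print(f"""
What the numbers mean:
- {report['reads_retained']}/{report['reads_in']} reads retained: the default
  'chain' clustering needs no TSS/PolyA, so nothing is excluded.
- {report['n_clusters']} clusters = 3 intron chains x 3 cell types: reads with
  identical intron chains stack together within each cell type.
- {report['n_alternative_exons']} of {report['n_candidate_exons']} candidate exons
  are alternative: their pooled inclusion lies inside the 5-95% window.
- {report['n_passing_sites']} of {report['n_mismatch_sites']} mismatch sites pass
  the 5-95% frequency filter (the ~1% site looks like sequencing error,
  the ~96% site like a genome difference; both are suppressed).
- plot axis {report['plot_axis_length']:.0f} bases vs a {truth.gene.span.end - truth.gene.span.start}-base
  gene: each exon-free intron shrank to 100 plot bases.
""")
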