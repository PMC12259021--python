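"""Apply the four QC exclusion criteria and library-size log normalization.

Reads the fixture written by example 01 (run that first), filters cells
and genes, and prints the per-criterion exclusion report.
"""

import stagehet as sh

adata = sh.read_matrix("scratch/example_counts")
norm, report = sh.run_qc(adata, sh.QCThresholds())

print(f"input cells: {report.n_input_cells}")
print(f"excluded by UMI bounds:   {report.exclusions['umi']}")
print(f"excluded by gene bounds:  {report.exclusions['genes']}")
print(f"excluded by mito fraction:{report.exclusions['mito']}")
print(f"retained: {report.n_retained_cells} cells × {report.n_retained_genes} genes")
# Values in `norm.X` are ln(1 + count · 10,000 / cell_total); raw counts
# stay available in norm.layers["counts"]. A cell may fail several
# criteria at once, so exclusion counts can exceed cells removed.
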