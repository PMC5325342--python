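"""Mesenchymal/proneural scoring, subtype calls and paired treatment shifts.

Scores are mean z-scored log2(RPKM+1) over signature genes.  The planted
design has adherent lines mesenchymal and stem lines proneural, with VPA
boosting the opposite signature without flipping any call — the paired
exact Wilcoxon test quantifies the shift per lineage.
"""

from common import RESULTS, dataset_dir
from vpaglio.diffexpr import rpkm
from vpaglio.io import read_annotation, read_count_matrix, read_gmt, write_table
from vpaglio.subtype import classify

ds = dataset_dir()
cm = read_count_matrix(ds / "counts.tsv", ds / "meta.tsv")
ann = read_annotation(ds / "annotation.tsv")
coll = read_gmt(ds / "gene_sets.gmt")

expr = rpkm(cm, ann)
res = classify(expr, coll["MESENCHYMAL"], coll["PRONEURAL"])
write_table(res.scores, RESULTS / "06_subtype_scores.tsv")
write_table(res.tests, RESULTS / "06_subtype_tests.tsv")

print(res.tests.to_string(index=False))
flips = (
    res.scores.pivot(index="cell_line", columns="condition", values="call").nunique(axis=1) > 1
)
print(f"subtype calls changed by treatment in {int(flips.sum())} of {len(flips)} lines")
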