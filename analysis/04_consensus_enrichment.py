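"""Cross-line consensus signatures per fold-change tier and family enrichment.

Applies the >=4-of-7-in-both-lineages rule at cutoffs 5/4/3/2,
intersects with the euchromatinization consensus, and tests the planted
family for over-representation against the 5,000-gene universe.
"""

import pandas as pd

from common import RESULTS, SCRATCH, dataset_dir
from vpaglio.integrate import family_enrichment, fc_tier_table
from vpaglio.io import read_count_matrix, read_gmt, read_table, write_table

ds = dataset_dir()
cm = read_count_matrix(ds / "counts.tsv", ds / "meta.tsv")
lineages = {s.cell_line: s.lineage for s in cm.samples}
de_dir = SCRATCH / "de"
if not de_dir.exists():
    raise SystemExit("run 02_differential_expression.py first")
tables = {p.stem: read_table(p) for p in sorted(de_dir.glob("*.tsv"))}
calls = read_table(SCRATCH / "euchromatin_calls.tsv", index_col="gene_id").astype(bool)

tier_df, tier_lists = fc_tier_table(tables, lineages, euchromatin=calls)
write_table(tier_df, RESULTS / "04_tier_table.tsv")

family = read_gmt(ds / "gene_sets.gmt")["FAMILY"]
rows = []
for cutoff in (5.0, 4.0, 3.0, 2.0):
    for which in ("expression", "expression_and_euchromatin"):
        res = family_enrichment(tier_lists[cutoff][which], family, N=len(cm.gene_ids))
        rows.append(
            {"fc_cutoff": cutoff, "list": which, "k": res.k, "n": res.n, "K": res.K,
             "N": res.N, "expected": res.expected, "odds_ratio": res.odds_ratio, "p": res.p}
        )
enr = pd.DataFrame(rows)
write_table(enr, RESULTS / "04_family_enrichment.tsv")

print(tier_df.to_string(index=False))
print(enr.round(6).to_string(index=False))
best = enr[enr["list"] == "expression_and_euchromatin"].iloc[-1]
print(
    f"at fc>=2, {best.k} of the {best.K} family genes are up-regulated AND "
    f"euchromatinized (p = {best.p:.3g})"
)
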