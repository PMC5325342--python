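# vpaglio

Integrative RNA-Seq/ChIP-Seq analysis of the valproic acid (VPA)
response in glioma cell line panels.

VPA is an antiepileptic commonly co-administered to glioblastoma
patients and acts as a class I/IIa histone-deacetylase inhibitor.  This
package implements, as a reusable and fully tested pipeline, the
statistics needed to ask what VPA does to a panel of glioma cell lines
profiled once untreated and once treated — no replicates — on both the
transcriptional and the chromatin (H3 acetylation) level:

- **Differential expression without replicates** — the Audic–Claverie
  exact test for one count against another given two library sizes,
  with BH adjustment per cell line, CPM fold changes, RPKM, and PCA.
- **Promoter euchromatinization** — strand-aware −1000..0 TSS windows
  intersected with treated-condition ChIP-enriched regions (BED).
- **Consensus signatures** — genes up-regulated (q < 0.01, FC above a
  tier cutoff of 5/4/3/2) in ≥ 4 of 7 adherent **and** ≥ 4 of 7
  stem-like lines, optionally intersected with the analogous
  euchromatinization consensus.
- **Gene-family enrichment** — Fisher's exact test of a family (e.g.
  SLC transporters) in a signature against the whole-genome reference.
- **GSEA** — weighted running-sum enrichment score with a gene-set
  permutation null, NES, nominal p and pooled-null FDR, written from
  scratch (no phenotype permutation is possible in this design).
- **Subtype scoring** — mesenchymal/proneural signature scores per
  sample and exact Wilcoxon signed-rank tests of paired
  naive/treated shifts.
- **Pharmacology** — 4-parameter logistic temozolomide dose-response
  fits, relative IC50 reduction (sensitization), siRNA rescue ratios,
  and ΔΔCt qPCR fold changes.
- **Synthetic data** — seeded generators that emulate the full study
  design (14 lines × 2 conditions, planted effects, concordant ChIP
  regions, 4PL plates) with a ground-truth manifest, so every stage is
  testable end to end without any sequencing data.

The core test: the probability of observing `y` counts in a library of
`N2` reads given `x` counts in one of `N1` reads, under equal
expression, is

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) )

(the negative-binomial law with x+1 successes and success probability
N1/(N1+N2)); up-regulation p-values are its upper tail, evaluated
exactly via the regularized incomplete beta function.

## Worked example

Everything is scriptable from Python or the `vpaglio` CLI.  The
family-enrichment calculator, on the reference counts of a 497-gene
signature containing 16 of the genome's 397 SLC transporters among
46,111 genes:

```
$ vpaglio enrich --k 16 --n 497 --family-size 397 --universe-size 46111
k=16 n=497 K=397 N=46111 expected=4.279 odds_ratio=3.830 p=1.1784e-05
```

i.e. the signature contains ~3.7× more family members than the 4.3
expected by chance, p ≈ 1.18 × 10⁻⁵ (one-sided Fisher against the
whole-genome reference column).

A full synthetic study — simulate, test every line, call promoters,
build the consensus tiers, and test the planted 30-gene family:

```python
from vpaglio.simulate import simulate_dataset
from vpaglio.pipeline import PipelineConfig, run_all

simulate_dataset("ds", seed=17, n_genes=5000)
run_all(PipelineConfig(
    counts="ds/counts.tsv", meta="ds/meta.tsv", annotation="ds/annotation.tsv",
    regions_dir="ds/regions", gene_sets="ds/gene_sets.gmt", out="run", seed=17,
))
```

which writes per-stage TSVs plus `run/summary.json`; the tier table for
this seed is

```
fc_cutoff  n_expression  n_expression_and_euchromatin
      5.0            32                            32
      4.0            65                            65
      3.0            94                            94
      2.0           100                           100
```

— 100 genes were planted with concordant promoter regions, so the
ChIP layer confirms the expression consensus at every tier.  The number
of *family* members among the up-regulated-and-euchromatinized genes
grows as the cutoff relaxes (4 at fc ≥ 5, 8 at ≥ 4, 11 at ≥ 3, 12 at
≥ 2), reaching all 12 planted members at the loosest tier with family
enrichment p = 1.12 × 10⁻¹¹.  GSEA at 1,000 permutations ranks the
planted family first (ES 0.917, NES 2.10, p at the 1/1001 floor) while
the random decoy sets stay null.  The paired subtype tests show the
planted treatment shift (exact Wilcoxon p = 0.015625 with 7 pairs per
lineage) with zero subtype calls flipped — scores move, classifications
do not.

The `analysis/` directory holds the same chain as numbered narrative
drivers (`01_simulate.py` … `07_pharmacology.py`), each printing what it
found and writing its summary tables under `results/`.

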