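"""Cross-cell-line consensus filtering and gene-family enrichment.

The consensus rule: a gene enters the VPA-response signature at a fold
change tier iff it is called up-regulated (q below threshold, fc at or
above the tier cutoff) in at least ``min_support`` of the adherent cell
lines AND at least ``min_support`` of the stem cell lines (default 4 of
7 in each).  The same majority rule applies to promoter
euchromatinization calls when intersecting the RNA and ChIP layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io import DataValidationError


@dataclass
class ConsensusSignature:
    fc_cutoff: float
    genes: list[str]
    support: pd.DataFrame  # index gene_id; columns n_adherent_up, n_stem_up
    q_thresh: float
    min_support: int
    group_sizes: tuple[int, int]


@dataclass
class EnrichmentResult:
    """One-sided (or two-sided) Fisher enrichment of a family in a gene list.

    The 2x2 table compares the candidate list against the whole gene
    universe as an independent reference column:
    [[k, n-k], [K, N-K]].
    """

    k: int
    n: int
    K: int
    N: int
    p: float
    expected: float
    odds_ratio: float
    sided: str


def _support_counts(
    de_tables: dict[str, pd.DataFrame],
    lineages: dict[str, str],
    q_thresh: float,
    fc_cutoff: float,
) -> pd.DataFrame:
    """Per-gene count of supporting lines in each lineage.

    A line supports a gene iff q < q_thresh and fc >= fc_cutoff (and fc > 1).
    Genes absent from a line's table count as non-supporting there.
    """
    all_genes: dict[str, None] = {}
    for df in de_tables.values():
        for g in df["gene_id"]:
            all_genes.setdefault(g, None)
    genes = list(all_genes)
    counts = pd.DataFrame(0, index=genes, columns=["n_adherent_up", "n_stem_up"])
    for line, df in de_tables.items():
        lineage = lineages[line]
        sup = df.loc[
            (df["q"] < q_thresh) & (df["fc"] >= fc_cutoff) & (df["fc"] > 1), "gene_id"
        ]
        col = "n_adherent_up" if lineage == "adherent" else "n_stem_up"
        counts.loc[sup, col] += 1
    return counts


def consensus_upregulated(
    de_tables: dict[str, pd.DataFrame],
    lineages: dict[str, str],
    q_thresh: float = 0.01,
    fc_cutoff: float = 5.0,
    min_support: int = 4,
) -> ConsensusSignature:
    """Genes up-regulated in >= min_support lines of BOTH lineages."""
    by_lineage = {"adherent": 0, "stem": 0}
    for line in de_tables:
        if line not in lineages:
            raise DataValidationError(f"no lineage declared for cell line {line!r}")
        if lineages[line] not in by_lineage:
            raise DataValidationError(f"unknown lineage {lineages[line]!r} for {line!r}")
        by_lineage[lineages[line]] += 1
    for lineage, n in by_lineage.items():
        if n < min_support:
            raise DataValidationError(
                f"lineage {lineage!r} has {n} cell lines, fewer than min_support={min_support}"
            )
    support = _support_counts(de_tables, lineages, q_thresh, fc_cutoff)
    keep = (support["n_adherent_up"] >= min_support) & (support["n_stem_up"] >= min_support)
    return ConsensusSignature(
        fc_cutoff=fc_cutoff,
        genes=support.index[keep].tolist(),
        support=support,
        q_thresh=q_thresh,
        min_support=min_support,
        group_sizes=(by_lineage["adherent"], by_lineage["stem"]),
    )


def euchromatin_consensus(
    call_matrix: pd.DataFrame, lineages: dict[str, str], min_support: int = 4
) -> list[str]:
    """Genes euchromatinized in >= min_support lines of both lineages."""
    adh = [c for c in call_matrix.columns if lineages.get(c) == "adherent"]
    stem = [c for c in call_matrix.columns if lineages.get(c) == "stem"]
    if not adh or not stem:
        raise DataValidationError("call matrix must contain both lineages")
    keep = (call_matrix[adh].sum(axis=1) >= min_support) & (
        call_matrix[stem].sum(axis=1) >= min_support
    )
    return call_matrix.index[keep].tolist()


def fc_tier_table(
    de_tables: dict[str, pd.DataFrame],
    lineages: dict[str, str],
    euchromatin: pd.DataFrame | None = None,
    cutoffs: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0),
    q_thresh: float = 0.01,
    min_support: int = 4,
) -> tuple[pd.DataFrame, dict[float, dict[str, list[str]]]]:
    """Consensus signature per fold-change tier, optionally intersected with ChIP.

    Returns (summary table, per-tier gene lists).  Signatures at stricter
    cutoffs are always subsets of looser ones; counts are therefore
    non-decreasing as the cutoff is relaxed.
    """
    if any(b >= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly decreasing")
    eu_genes: set[str] | None = None
    if euchromatin is not None:
        de_genes = set().union(*(set(df["gene_id"]) for df in de_tables.values()))
        missing = de_genes - set(euchromatin.index)
        if missing:
            raise DataValidationError(
                f"{len(missing)} DE genes absent from euchromatin matrix, "
                f"e.g. {sorted(missing)[:5]}"
            )
        eu_genes = set(euchromatin_consensus(euchromatin, lineages, min_support=min_support))
    rows = []
    lists: dict[float, dict[str, list[str]]] = {}
    for cutoff in cutoffs:
        sig = consensus_upregulated(
            de_tables, lineages, q_thresh=q_thresh, fc_cutoff=cutoff, min_support=min_support
        )
        entry = {"expression": sig.genes}
        row = {"fc_cutoff": cutoff, "n_expression": len(sig.genes)}
        if eu_genes is not None:
            both = [g for g in sig.genes if g in eu_genes]
            entry["expression_and_euchromatin"] = both
            row["n_expression_and_euchromatin"] = len(both)
        rows.append(row)
        lists[cutoff] = entry
    return pd.DataFrame(rows), lists


def family_enrichment_counts(
    k: int, n: int, K: int, N: int, sided: str = "greater"
) -> EnrichmentResult:
    """Fisher's exact test of family over-representation from the four counts.

    k family members among the n-gene candidate list, versus K family
    members among the N-gene universe; table [[k, n-k], [K, N-K]] (the
    universe margin is not reduced by the list).
    """
    if sided not in ("greater", "two_sided"):
        raise ValueError("sided must be 'greater' or 'two_sided'")
    if not (0 <= k <= min(n, K)):
        raise DataValidationError(f"inconsistent counts: k={k}, n={n}, K={K}")
    if n > N or K > N:
        raise DataValidationError("list or family larger than universe")
    table = [[k, n - k], [K, N - K]]
    alternative = "greater" if sided == "greater" else "two-sided"
    odds, p = fisher_exact(table, alternative=alternative)
    return EnrichmentResult(
        k=k, n=n, K=K, N=N, p=float(p), expected=n * K / N, odds_ratio=float(odds), sided=sided
    )


def family_enrichment(
    list_genes,
    family_genes,
    universe=None,
    N: int | None = None,
    sided: str = "greater",
) -> EnrichmentResult:
    """Family over-representation for explicit gene lists.

    ``universe`` may be a gene list (its size becomes N and both inputs
    are intersected with it) or omitted in favour of an integer ``N``.
    Duplicate inputs are deduplicated with a warning.
    """
    lst = list(list_genes)
    fam = list(family_genes)
    if len(set(lst)) != len(lst) or len(set(fam)) != len(fam):
        warnings.warn("duplicate gene ids in enrichment input; deduplicated", stacklevel=2)
    lset, fset = set(lst), set(fam)
    if universe is not None:
        uni = set(universe)
        if N is not None and N != len(uni):
            raise DataValidationError("both universe list and N given but inconsistent")
        N = len(uni)
        lset &= uni
        fset &= uni
    if N is None:
        raise DataValidationError("either a universe list or N must be provided")
    return family_enrichment_counts(
        k=len(lset & fset), n=len(lset), K=len(fset), N=N, sided=sided
    )
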