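"""Gene set enrichment analysis: weighted running-sum statistic with a
gene-set permutation null.

With a single treated/naive pair per cell line there are no phenotype
replicates to permute, so the null is built by drawing random gene sets
of matching size from the ranked universe.  The enrichment score is the
signed extremum of the running sum that increments by the hit gene's
|metric|^p (normalized over hits) and decrements by 1/(N - N_hits) at
misses; NES normalizes by the mean magnitude of same-signed null scores,
the nominal p uses the add-one rule, and the FDR q pools sign-matched
null NES values across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataValidationError, GeneSetCollection


@dataclass
class GseaResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str]
    n_permutations: int
    seed: int


def ranking_metric(de_tables: dict[str, pd.DataFrame]) -> pd.Series:
    """Mean log2 fold change across cell lines, sorted descending.

    Genes missing from some tables are averaged over the tables where
    they appear; ties in the metric break lexicographically by gene id so
    the ranking is deterministic and invariant to table order.
    """
    if not de_tables:
        raise DataValidationError("at least one DE table required")
    frames = [df.set_index("gene_id")["fc"] for _, df in sorted(de_tables.items())]
    merged = pd.concat(frames, axis=1)
    metric = np.log2(merged).mean(axis=1, skipna=True)
    dropped = metric.index[metric.isna()]
    if len(dropped):
        warnings.warn(f"{len(dropped)} genes absent from all tables; dropped", stacklevel=2)
        metric = metric.dropna()
    order = sorted(metric.index, key=lambda g: (-metric[g], g))
    return metric.loc[order]


def enrichment_score(ranked: pd.Series, gene_set, exponent: float = 1.0):
    """ES, full running sum, and hit positions for one gene set.

    ``ranked`` is the descending metric indexed by gene id.  The ES is
    the running-sum value of largest magnitude (first occurrence).
    """
    n = len(ranked)
    members = set(gene_set)
    hits = np.fromiter((g in members for g in ranked.index), dtype=bool, count=n)
    n_h = int(hits.sum())
    if n_h == 0:
        raise DataValidationError("gene set has empty intersection with the ranked list")
    if n_h == n:
        raise DataValidationError("gene set covers the whole ranked list")
    w = np.abs(ranked.to_numpy(dtype=float)) ** exponent
    n_r = w[hits].sum()
    if n_r == 0:
        raise DataValidationError("all hit metrics are zero at this exponent")
    step = np.where(hits, w / n_r, -1.0 / (n - n_h))
    running = np.cumsum(step)
    es = float(running[np.argmax(np.abs(running))])
    hit_positions = np.flatnonzero(hits)
    return es, running, hit_positions


def leading_edge_genes(ranked: pd.Series, gene_set, exponent: float = 1.0) -> list[str]:
    """Hit genes at or before (after, for negative ES) the running-sum extremum."""
    es, running, hit_pos = enrichment_score(ranked, gene_set, exponent)
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        keep = hit_pos[hit_pos <= peak]
    else:
        keep = hit_pos[hit_pos >= peak]
    return [ranked.index[i] for i in keep]


def _es_from_positions(pos_sorted: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many permutations given sorted hit-position rows.

    Candidate extrema of the running sum occur immediately before and at
    each hit; between hits the sum only decreases linearly.
    """
    n_perm, k = pos_sorted.shape
    wh = w[pos_sorted]  # (n_perm, k)
    cum = np.cumsum(wh, axis=1)
    n_r = cum[:, -1][:, None]
    miss_before = pos_sorted - np.arange(k)[None, :]  # misses strictly before hit i
    after = cum / n_r - miss_before / (n - k)
    before = (cum - wh) / n_r - miss_before / (n - k)
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), idx]


def gsea(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA over every set of a collection.

    Returns a frame with set, size, es, nes, p_nominal, fdr_q and the
    leading-edge genes; identical seed and inputs give identical output.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    rng = np.random.default_rng(seed)
    w = np.abs(ranked.to_numpy(dtype=float)) ** exponent

    rows = []
    null_nes_pos: list[np.ndarray] = []
    null_nes_neg: list[np.ndarray] = []
    for name in collection.names():
        members = [g for g in collection[name] if g in ranked.index]
        k = len(members)
        if k == 0:
            warnings.warn(f"set {name!r} has no genes in the ranked list; skipped", stacklevel=2)
            continue
        if k >= n:
            raise DataValidationError(f"set {name!r} is not smaller than the universe")
        es, _, _ = enrichment_score(ranked, members, exponent)
        # null: random same-size sets from the ranked universe
        u = rng.random((n_perm, n))
        pos = np.argpartition(u, k - 1, axis=1)[:, :k]
        pos.sort(axis=1)
        null_es = _es_from_positions(pos, w, n)
        pos_mean = np.abs(null_es[null_es > 0]).mean() if (null_es > 0).any() else np.nan
        neg_mean = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.nan
        if es >= 0:
            denom = pos_mean if np.isfinite(pos_mean) else np.abs(null_es).mean()
        else:
            denom = neg_mean if np.isfinite(neg_mean) else np.abs(null_es).mean()
        nes = es / denom if denom > 0 else np.nan
        # null scores at least as extreme in magnitude, add-one rule
        as_extreme = int((np.abs(null_es) >= abs(es)).sum())
        p_nom = (1 + as_extreme) / (n_perm + 1)
        if np.isfinite(pos_mean):
            null_nes_pos.append(null_es[null_es > 0] / pos_mean)
        if np.isfinite(neg_mean):
            null_nes_neg.append(-np.abs(null_es[null_es < 0]) / neg_mean)
        rows.append(
            GseaResult(
                set_name=name,
                size=k,
                es=es,
                nes=float(nes),
                p_nominal=p_nom,
                fdr_q=np.nan,
                leading_edge=leading_edge_genes(ranked, members, exponent),
                n_permutations=n_perm,
                seed=seed,
            )
        )

    # sign-matched pooled-null FDR
    pool_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.array([])
    pool_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.array([])
    obs = np.array([r.nes for r in rows])
    for r in rows:
        if not np.isfinite(r.nes):
            r.fdr_q = np.nan
            continue
        if r.nes >= 0:
            null_frac = (
                (pool_pos >= r.nes).sum() / len(pool_pos) if len(pool_pos) else np.nan
            )
            obs_pos = obs[np.isfinite(obs) & (obs >= 0)]
            obs_frac = (obs_pos >= r.nes).sum() / len(obs_pos) if len(obs_pos) else np.nan
        else:
            null_frac = (
                (pool_neg <= r.nes).sum() / len(pool_neg) if len(pool_neg) else np.nan
            )
            obs_neg = obs[np.isfinite(obs) & (obs < 0)]
            obs_frac = (obs_neg <= r.nes).sum() / len(obs_neg) if len(obs_neg) else np.nan
        if not (np.isfinite(null_frac) and np.isfinite(obs_frac)) or obs_frac == 0:
            r.fdr_q = np.nan
        else:
            r.fdr_q = float(min(1.0, null_frac / obs_frac))

    return pd.DataFrame(
        {
            "set": [r.set_name for r in rows],
            "size": [r.size for r in rows],
            "es": [r.es for r in rows],
            "nes": [r.nes for r in rows],
            "p_nominal": [r.p_nominal for r in rows],
            "fdr_q": [r.fdr_q for r in rows],
            "leading_edge": [",".join(r.leading_edge) for r in rows],
            "n_permutations": [r.n_permutations for r in rows],
            "seed": [r.seed for r in rows],
        }
    )
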