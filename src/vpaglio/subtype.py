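"""Mesenchymal/proneural signature scoring and paired subtype statistics.

A sample's signature score is the mean, over signature genes, of the
per-gene z-scored log2(RPKM+1) — the simplest monotone per-sample
enrichment.  The subtype call is the argmax of the two scores.  Paired
naive/VPA comparisons across the cell lines of a lineage use an exact
Wilcoxon signed-rank test (full null distribution, mid-ranks for ties,
zero differences dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .diffexpr import ExpressionMatrix
from .io import DataValidationError

EXACT_LIMIT = 25  # beyond this, normal approximation with continuity correction


@dataclass
class SubtypeResult:
    scores: pd.DataFrame  # sample_id, cell_line, lineage, condition, mes, pn, call
    tests: pd.DataFrame  # lineage, signature, W, p_two_sided, n_pairs


def signature_score(expr: ExpressionMatrix, signature) -> pd.Series:
    """Mean z-scored log2(RPKM+1) of the signature genes, per sample."""
    if expr.values.shape[1] < 2:
        raise DataValidationError("signature scoring needs >= 2 samples")
    present = [g for g in signature if g in expr.values.index]
    if not present:
        raise DataValidationError("no signature gene present in the expression matrix")
    logv = np.log2(expr.values.loc[present] + 1.0)
    mu = logv.mean(axis=1)
    sd = logv.std(axis=1, ddof=1)
    z = (logv.sub(mu, axis=0)).div(sd.where(sd > 0, 1.0), axis=0)
    return z.mean(axis=0)


def _exact_signed_rank_p(w: float, ranks: np.ndarray) -> float:
    """Two-sided p by convolving the exact null distribution of the rank sum.

    Mid-ranks are doubled so every rank is integral; the distribution of
    the positive-rank sum over all 2^n sign assignments is built by
    dynamic programming (identical to full enumeration).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in r2:
        dp[r:] = dp[r:] + dp[:-r] if r > 0 else 2 * dp[r:]
    n_assign = 2.0 ** len(ranks)
    w2 = int(np.rint(2 * w))
    p_le = dp[: w2 + 1].sum() / n_assign
    p_ge = dp[w2:].sum() / n_assign
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank_exact(before, after):
    """Exact two-sided Wilcoxon signed-rank test on paired scores.

    Returns (W, p_two_sided, n_pairs) where W is the sum of ranks of
    positive differences (after - before).  Zero differences are dropped;
    ties in |difference| receive mid-ranks.  Exact null for n <= 25,
    normal approximation with continuity and tie correction beyond.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise DataValidationError("before/after must have equal length")
    d = after - before
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DataValidationError("degenerate: all differences are zero")
    if n < 3:
        raise DataValidationError(f"need >= 3 non-zero differences, got {n}")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        p = _exact_signed_rank_p(w, ranks)
    else:
        mu = n * (n + 1) / 4
        _, counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24 - (counts**3 - counts).sum() / 48
        z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(sigma2)
        p = min(1.0, 2.0 * norm.sf(abs(z)))
    return w, p, n


def classify(
    expr: ExpressionMatrix, mes_signature, pn_signature
) -> SubtypeResult:
    """Per-sample subtype calls plus paired naive/VPA score shifts per lineage.

    The call is mesenchymal or proneural by the larger score
    (``indeterminate`` on an exact tie).  For each lineage and each
    signature, the naive and VPA scores of its cell lines are compared
    with the exact Wilcoxon signed-rank test.
    """
    mes = signature_score(expr, mes_signature)
    pn = signature_score(expr, pn_signature)
    meta = {s.sample_id: s for s in expr.samples}
    call = np.where(mes > pn, "mesenchymal", np.where(pn > mes, "proneural", "indeterminate"))
    scores = pd.DataFrame(
        {
            "sample_id": mes.index,
            "cell_line": [meta[s].cell_line for s in mes.index],
            "lineage": [meta[s].lineage for s in mes.index],
            "condition": [meta[s].condition for s in mes.index],
            "mesenchymal_score": mes.to_numpy(),
            "proneural_score": pn.to_numpy(),
            "call": call,
        }
    )
    tests = []
    for lineage in ("adherent", "stem"):
        sub = scores[scores["lineage"] == lineage]
        if sub.empty:
            continue
        for signame, col in (("mesenchymal", "mesenchymal_score"), ("proneural", "proneural_score")):
            piv = sub.pivot(index="cell_line", columns="condition", values=col)
            if not {"naive", "vpa"} <= set(piv.columns) or piv.isna().any().any():
                continue
            try:
                w, p, npairs = wilcoxon_signed_rank_exact(
                    piv["naive"].to_numpy(), piv["vpa"].to_numpy()
                )
            except DataValidationError:
                continue
            tests.append(
                {
                    "lineage": lineage,
                    "signature": signame,
                    "W": w,
                    "p_two_sided": p,
                    "n_pairs": npairs,
                }
            )
    return SubtypeResult(scores=scores, tests=pd.DataFrame(tests))
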