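"""Per-cell-line differential expression for unreplicated count data.

The study design has exactly one VPA-naive and one VPA-treated library
per cell line, so replicated-design models do not apply.  Differential
calls use the Audic-Claverie test: given a gene observed ``x`` times in
a library of ``N1`` total mapped reads, the probability of observing
``y`` counts in a second library of ``N2`` reads under the null of equal
underlying expression is

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

which is the negative-binomial law with ``x+1`` successes and success
probability ``N1/(N1+N2)``.  Tail probabilities are therefore evaluated
exactly through the regularized incomplete beta function instead of
term-by-term summation; the point mass itself is computed in log space
(lgamma) so large counts never overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln
from sklearn.decomposition import PCA

from .io import CountMatrix, DataValidationError, GeneAnnotation, SampleMeta

ALTERNATIVES = ("up", "down", "two_sided")


@dataclass
class ExpressionMatrix:
    """Non-negative real expression values (RPKM) with sample metadata."""

    values: pd.DataFrame  # genes x samples
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise DataValidationError("expression columns do not match sample metadata")
        if not np.isfinite(self.values.to_numpy()).all():
            raise DataValidationError("non-finite expression value")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def rpkm(counts: CountMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Reads per kilobase of exonic length per million mapped reads.

    value = count * 1e9 / (exonic_length_bp * library_size)
    """
    counts.require_genes()
    annotation.require_covers(counts.gene_ids)
    libs = counts.library_sizes.to_numpy(dtype=float)
    if (libs <= 0).any():
        raise DataValidationError("zero or negative library size")
    lengths = annotation.table.loc[counts.gene_ids, "exonic_length"].to_numpy(dtype=float)
    vals = counts.counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * libs[None, :])
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        samples=list(counts.samples),
    )


def _check_counts(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise DataValidationError("counts must be non-negative")
    if not (np.equal(np.mod(x, 1), 0).all() and np.equal(np.mod(y, 1), 0).all()):
        raise DataValidationError("counts must be integers")
    return x.astype(np.int64), y.astype(np.int64)


def ac_conditional(y, x, n1, n2):
    """Audic-Claverie conditional probability p(y | x) for library sizes N1, N2.

    Evaluated in log space; for fixed ``x`` the values over all ``y`` sum to 1.
    Broadcasts over array inputs.
    """
    x, y = _check_counts(x, y)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 <= 0).any() or (n2 <= 0).any():
        raise DataValidationError("library sizes must be positive")
    logr = np.log(n2) - np.log(n1)
    log_p = (
        y * logr
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.logaddexp(0.0, logr)
    )
    out = np.exp(log_p)
    return out if out.ndim else float(out)


def ac_pvalue(x, y, n1, n2, alternative: str = "up"):
    """Tail probability of the Audic-Claverie conditional law.

    ``up``:   P(Y >= y | x)  — treated count y at least as large as observed
    ``down``: P(Y <= y | x)
    ``two_sided``: 2 * min(up, down), capped at 1.

    The conditional law of Y given x is NegBin(x+1, N1/(N1+N2)), so the
    tails are regularized incomplete beta values (exact, no truncation).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x, y = _check_counts(x, y)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 <= 0).any() or (n2 <= 0).any():
        raise DataValidationError("library sizes must be positive")
    x, y, n1, n2 = np.broadcast_arrays(x, y, n1, n2)
    q0 = n2 / (n1 + n2)  # NB "failure" probability
    p0 = n1 / (n1 + n2)

    def _up(xv, yv, q0v):
        # P(Y >= y) = I_{q0}(y, x+1) for y >= 1, else 1
        out = np.ones_like(q0v, dtype=float)
        pos = yv >= 1
        out[pos] = betainc(yv[pos].astype(float), xv[pos] + 1.0, q0v[pos])
        return out

    def _down(xv, yv, p0v):
        # P(Y <= y) = I_{p0}(x+1, y+1)
        return betainc(xv + 1.0, yv + 1.0, p0v)

    if alternative == "up":
        out = _up(x, y, q0)
    elif alternative == "down":
        out = _down(x, y, p0)
    else:
        out = np.minimum(1.0, 2.0 * np.minimum(_up(x, y, q0), _down(x, y, p0)))
    # extreme tails can underflow to 0.0 in double precision; floor at the
    # smallest normal float so p stays in (0, 1] for downstream adjustment
    out = np.asarray(np.clip(out, np.finfo(float).tiny, 1.0))
    return out if out.ndim else float(out)


def fold_change(x, y, n1, n2, pseudo: float = 0.5):
    """Library-size-normalized fold change treated/naive on the CPM scale.

    fc = (CPM_treated + pseudo) / (CPM_naive + pseudo).  ``pseudo`` (in CPM
    units) keeps the ratio defined at zero counts; with pseudo=0 a zero
    naive count is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    if pseudo == 0 and (x == 0).any():
        raise DataValidationError("fold change undefined: x=0 with pseudo=0")
    cpm_x = x / np.asarray(n1, dtype=float) * 1e6
    cpm_y = y / np.asarray(n2, dtype=float) * 1e6
    out = (cpm_y + pseudo) / (cpm_x + pseudo)
    return out if out.ndim else float(out)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise DataValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    counts: CountMatrix,
    cell_line: str,
    fc_pseudo: float = 0.5,
    alpha: float = 0.01,
    alternative: str = "up",
) -> pd.DataFrame:
    """Pairwise VPA-treated vs. naive test for one cell line, all genes.

    Returns one row per gene with columns
    gene_id, cell_line, x, y, N1, N2, fc, p_raw, q, direction.
    ``q`` is BH-adjusted across the genes of this cell line; direction is
    ``up`` iff fc > 1 and q < alpha, ``down`` iff fc < 1 and q < alpha.
    """
    counts.require_genes()
    naive = counts.sample_for(cell_line, "naive")
    treated = counts.sample_for(cell_line, "vpa")
    x = counts.counts[naive.sample_id].to_numpy()
    y = counts.counts[treated.sample_id].to_numpy()
    n1, n2 = naive.library_size, treated.library_size
    p_raw = ac_pvalue(x, y, n1, n2, alternative=alternative)
    fc = fold_change(x, y, n1, n2, pseudo=fc_pseudo)
    q = bh_adjust(p_raw)
    direction = np.where(
        (q < alpha) & (fc > 1), "up", np.where((q < alpha) & (fc < 1), "down", "none")
    )
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "cell_line": cell_line,
            "x": x,
            "y": y,
            "N1": n1,
            "N2": n2,
            "fc": fc,
            "p_raw": p_raw,
            "q": q,
            "direction": direction,
        }
    )


def all_differential_tables(
    counts: CountMatrix, fc_pseudo: float = 0.5, alpha: float = 0.01, alternative: str = "up"
) -> dict[str, pd.DataFrame]:
    """differential_table for every cell line present in the metadata."""
    return {
        line: differential_table(counts, line, fc_pseudo=fc_pseudo, alpha=alpha, alternative=alternative)
        for line in counts.cell_lines()
    }


def pca_top_variable(
    expr: ExpressionMatrix,
    n_top: int = 1800,
    n_components: int = 5,
    log_transform: bool = True,
):
    """Centered PCA of samples on the top ``n_top`` most variable genes.

    Genes are ranked by cross-sample variance of log2(RPKM+1) (or raw RPKM
    with ``log_transform=False``); ties break lexicographically by gene id.
    Sign convention: within each component the largest-magnitude gene
    loading is made positive, so results are reproducible across runs.

    Returns (scores, loadings, variance_explained_ratio).
    """
    vals = expr.values
    if vals.shape[1] < 2:
        raise DataValidationError("PCA requires at least 2 samples")
    if n_top > vals.shape[0]:
        raise DataValidationError(f"n_top={n_top} exceeds gene count {vals.shape[0]}")
    mat = np.log2(vals + 1.0) if log_transform else vals.copy()
    variances = mat.var(axis=1, ddof=1)
    order = sorted(vals.index, key=lambda g: (-variances[g], g))
    top = order[:n_top]
    sub = mat.loc[top]
    if np.allclose(sub.to_numpy().var(), 0):
        raise DataValidationError("expression matrix is constant; PCA undefined")
    n_components = min(n_components, vals.shape[1] - 1, n_top)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(sub.to_numpy().T)
    loadings = pca.components_.T  # genes x components
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i+1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=vals.columns, columns=cols),
        pd.DataFrame(loadings, index=top, columns=cols),
        pca.explained_variance_ratio_,
    )
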