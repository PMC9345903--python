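"""Margin-aware mutual-exclusivity test on a binary somatic mutation matrix.

Synthetic-lethal pairs should rarely be mutated in the same tumor, but raw
co-mutation counts are confounded by per-gene mutation frequency and
per-sample mutational burden.  The null model here conditions on both: cell
probabilities p_ij = logistic(u_i + v_j) are fit so that expected row and
column sums match the observed margins, and the co-mutation count of a gene
pair is then Poisson-binomial with per-sample success probability
p_a,i * p_b,i.  Exclusivity is evidenced by a small lower tail
P(C <= observed), computed exactly by dynamic-programming convolution.  A
curveball permutation oracle (degree-preserving swaps) provides an
independent empirical p-value for validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BackgroundRates",
    "MutexResult",
    "estimate_background",
    "poisson_binomial_lower_tail",
    "exclusivity_test",
    "permutation_oracle",
    "adjust_and_flag",
]


@dataclass
class BackgroundRates:
    """Per-(gene, sample) null mutation probabilities with fit diagnostics."""

    p: pd.DataFrame  # genes x samples, values in (0,1)
    fit_report: dict = field(default_factory=dict)

    def row(self, gene: str) -> np.ndarray:
        return self.p.loc[gene].to_numpy()


@dataclass
class MutexResult:
    gene_a: str
    gene_b: str
    n_co: int
    expected_co: float
    p_value: float
    p_adjust: float | None = None
    passed: bool | None = None


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def estimate_background(
    mut: pd.DataFrame, max_iter: int = 500, tol: float = 1e-6
) -> BackgroundRates:
    """Fit p_ij = logistic(u_i + v_j) matching observed margins.

    Rows (genes) or columns (samples) that are all-zero or all-one are
    dropped with a warning: their margin constraint forces a parameter to
    +/- infinity and they carry no pairwise information.

    Alternating per-coordinate Newton updates on the row offsets u and the
    column offsets v; each one-dimensional margin equation
    sum_j logistic(u_i + v_j) = r_i is smooth and monotone, so the scheme
    converges quickly on non-degenerate matrices.
    """
    m = mut.astype(float)
    if not m.isin([0.0, 1.0]).all().all():
        raise ValueError("mutation matrix must be binary")
    rs = m.sum(axis=1)
    degenerate_rows = m.index[(rs == 0) | (rs == m.shape[1])]
    if len(degenerate_rows):
        warnings.warn(
            f"dropping {len(degenerate_rows)} all-zero/all-one gene row(s): "
            f"{list(degenerate_rows[:5])}",
            stacklevel=2,
        )
        m = m.drop(index=degenerate_rows)
    cs = m.sum(axis=0)
    degenerate_cols = m.columns[(cs == 0) | (cs == m.shape[0])]
    if len(degenerate_cols):
        warnings.warn(
            f"dropping {len(degenerate_cols)} all-zero/all-one sample column(s)",
            stacklevel=2,
        )
        m = m.drop(columns=degenerate_cols)
    if m.empty:
        raise ValueError("mutation matrix degenerate after dropping constant margins")

    x = m.to_numpy()
    n_genes, n_samples = x.shape
    row_tgt = x.sum(axis=1)
    col_tgt = x.sum(axis=0)
    # logit-frequency initialization
    u = np.log(row_tgt / (n_samples - row_tgt))
    v = np.zeros(n_samples)

    for it in range(max_iter):
        # Newton step on each u_i holding v fixed (vectorized over rows)
        for _ in range(5):
            p = _logistic(u[:, None] + v[None, :])
            f = p.sum(axis=1) - row_tgt
            fp = (p * (1 - p)).sum(axis=1)
            u -= f / np.maximum(fp, 1e-12)
        for _ in range(5):
            p = _logistic(u[:, None] + v[None, :])
            f = p.sum(axis=0) - col_tgt
            fp = (p * (1 - p)).sum(axis=0)
            v -= f / np.maximum(fp, 1e-12)
        p = _logistic(u[:, None] + v[None, :])
        row_err = np.abs(p.sum(axis=1) - row_tgt).max()
        col_err = np.abs(p.sum(axis=0) - col_tgt).max()
        if max(row_err, col_err) < tol:
            break
    else:
        raise RuntimeError(
            "background fit did not converge: "
            f"row margin error {row_err:.3g}, column margin error {col_err:.3g} "
            f"after {max_iter} iterations"
        )
    return BackgroundRates(
        pd.DataFrame(p, index=m.index, columns=m.columns),
        fit_report={
            "iterations": it + 1,
            "row_margin_error": float(row_err),
            "col_margin_error": float(col_err),
            "dropped_rows": list(degenerate_rows),
            "dropped_cols": list(degenerate_cols),
        },
    )


def poisson_binomial_lower_tail(q: np.ndarray, k: int) -> float:
    """P(C <= k) for C a sum of independent Bernoulli(q_i), by exact DP.

    The distribution vector is truncated above k: mass escaping past k never
    returns, so the retained entries are exact.
    """
    q = np.asarray(q, dtype=float)
    if k < 0:
        return 0.0
    if k >= len(q):
        return 1.0
    dist = np.zeros(k + 1)
    dist[0] = 1.0
    for qi in q:
        shifted = np.empty_like(dist)
        shifted[0] = 0.0
        shifted[1:] = dist[:-1]
        dist = dist * (1.0 - qi) + shifted * qi
    return float(min(1.0, dist.sum()))


def exclusivity_test(
    row_a: str, row_b: str, mut: pd.DataFrame, rates: BackgroundRates
) -> MutexResult:
    """One-sided lower-tail exclusivity p-value for a gene pair."""
    for g in (row_a, row_b):
        if g not in rates.p.index:
            raise KeyError(f"gene {g!r} missing from background rates")
    samples = rates.p.columns
    a = mut.loc[row_a, samples].to_numpy().astype(int)
    b = mut.loc[row_b, samples].to_numpy().astype(int)
    n_co = int((a & b).sum())
    q = rates.row(row_a) * rates.row(row_b)
    return MutexResult(
        gene_a=row_a,
        gene_b=row_b,
        n_co=n_co,
        expected_co=float(q.sum()),
        p_value=poisson_binomial_lower_tail(q, n_co),
    )


def _curveball_step(rows: list[set[int]], rng: np.random.Generator) -> None:
    """One curveball trade between two random rows (margins preserved)."""
    i, j = rng.choice(len(rows), size=2, replace=False)
    a, b = rows[i], rows[j]
    only_a = list(a - b)
    only_b = list(b - a)
    n_a, n_b = len(only_a), len(only_b)
    if n_a == 0 or n_b == 0:
        return
    pool = only_a + only_b
    perm = rng.permutation(len(pool))
    new_a = {pool[p] for p in perm[:n_a]}
    new_b = {pool[p] for p in perm[n_a:]}
    shared = a & b
    rows[i] = shared | new_a
    rows[j] = shared | new_b


def permutation_oracle(
    mut: pd.DataFrame,
    pair: tuple[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    n_steps_per_perm: int | None = None,
) -> float:
    """Empirical exclusivity p-value from curveball-permuted matrices.

    Trades preserve exact row and column sums.  Between recorded matrices,
    ``n_steps_per_perm`` trades are applied (default 2x the gene count).
    Returns (1 + #{permuted co-count <= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    x = mut.to_numpy().astype(int)
    gene_index = {g: i for i, g in enumerate(mut.index)}
    ia, ib = gene_index[pair[0]], gene_index[pair[1]]
    obs = int((x[ia] & x[ib]).sum())

    rows = [set(np.flatnonzero(x[i])) for i in range(x.shape[0])]
    # a matrix with no checkerboard admits no swap: every pair of rows nested
    swappable = any(
        (rows[i] - rows[j]) and (rows[j] - rows[i])
        for i in range(len(rows))
        for j in range(i + 1, len(rows))
    )
    if not swappable:
        warnings.warn("matrix has no swappable checkerboard; returning p=1", stacklevel=2)
        return 1.0

    steps = n_steps_per_perm or 2 * x.shape[0]
    # burn-in to decorrelate from the observed configuration
    for _ in range(10 * x.shape[0]):
        _curveball_step(rows, rng)
    hits = 0
    for _ in range(n_perm):
        for _ in range(steps):
            _curveball_step(rows, rng)
        if len(rows[ia] & rows[ib]) <= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def adjust_and_flag(
    results: list[MutexResult], threshold: float = 0.15
) -> list[MutexResult]:
    """Benjamini-Hochberg over all tested pairs; pass iff p_adjust < threshold.

    The default threshold is 0.15; 0.1 is the documented alternative and can
    be passed explicitly.
    """
    if not results:
        raise ValueError("no mutex results to adjust")
    pvals = np.array([r.p_value for r in results])
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    for r, pa in zip(results, padj):
        r.p_adjust = float(pa)
        r.passed = bool(pa < threshold)
    return results
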